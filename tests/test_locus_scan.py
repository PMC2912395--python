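"""Quasi-binomial locus fits, Storey q-values, and the sign-trend summary."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from methclass import (
    fit_locus_glm,
    scan,
    sign_trend,
    simulate_exposure_scan,
    storey_qvalues,
)

from oracles import bh_adjust, irls_quasibinomial


def test_constant_half_beta_gives_zero_intercept():
    y = np.full(20, 0.5)
    X = np.ones((20, 1))
    fit = fit_locus_glm(y, X, target_index=0)
    assert fit.coefficient == pytest.approx(0.0, abs=1e-8)


def test_saturated_two_group_slope_is_logit_difference():
    y = np.array([0.2] * 10 + [0.8] * 10)
    X = np.column_stack([np.ones(20), np.repeat([0.0, 1.0], 10)])
    fit = fit_locus_glm(y, X)
    assert fit.coefficient == pytest.approx(logit(0.8) - logit(0.2), abs=1e-4)
    assert fit.coefficient == pytest.approx(np.log(4) - np.log(0.25), abs=1e-4)


def test_fit_matches_independent_irls_oracle():
    rng = np.random.default_rng(14)
    for _ in range(5):
        n = 40
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
        y = np.clip(rng.beta(3, 3, n), 1e-3, 1 - 1e-3)
        fit = fit_locus_glm(y, X, target_index=1)
        coef, se, t, p, phi = irls_quasibinomial(y, X)
        assert fit.coefficient == pytest.approx(coef[1], rel=1e-6)
        assert fit.se == pytest.approx(se[1], rel=1e-6)
        assert fit.t == pytest.approx(t[1], rel=1e-6)
        assert fit.p == pytest.approx(p[1], rel=1e-6)
        assert fit.dispersion == pytest.approx(phi, rel=1e-6)


def test_fit_matches_statsmodels_glm_oracle():
    import statsmodels.api as sm

    rng = np.random.default_rng(77)
    n = 60
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = np.clip(rng.beta(2, 4, n), 1e-3, 1 - 1e-3)
    fit = fit_locus_glm(y, X)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(
            scale="X2", use_t=True
        )
    assert fit.coefficient == pytest.approx(res.params[1], rel=1e-6)
    assert fit.se == pytest.approx(res.bse[1], rel=1e-6)
    assert fit.p == pytest.approx(res.pvalues[1], rel=1e-6)
    assert fit.dispersion == pytest.approx(res.scale, rel=1e-6)


def test_fit_invariances():
    rng = np.random.default_rng(5)
    n = 50
    x = rng.normal(size=n)
    X = np.column_stack([np.ones(n), x])
    y = np.clip(rng.beta(2, 5, n), 1e-3, 1 - 1e-3)
    base = fit_locus_glm(y, X)
    # sample reordering
    perm = rng.permutation(n)
    reord = fit_locus_glm(y[perm], X[perm])
    assert reord.coefficient == pytest.approx(base.coefficient, abs=1e-10)
    assert reord.p == pytest.approx(base.p, abs=1e-10)
    # covariate rescaling x -> 10x divides the slope by 10, t and p unchanged
    scaled = fit_locus_glm(y, np.column_stack([np.ones(n), 10 * x]))
    assert scaled.coefficient == pytest.approx(base.coefficient / 10, rel=1e-8)
    assert scaled.t == pytest.approx(base.t, rel=1e-8)
    assert scaled.p == pytest.approx(base.p, rel=1e-8)


def test_fit_requires_enough_complete_cases():
    with pytest.raises(ValueError):
        fit_locus_glm(np.array([0.5, 0.4, 0.6]), np.ones((3, 2)))


def test_scan_rejects_degenerate_covariate():
    beta, x, _ = simulate_exposure_scan(30, 10, seed=0)
    cov = pd.DataFrame({"flat": np.ones(30)}, index=beta.sample_ids)
    with pytest.raises(ValueError, match="degenerate"):
        scan(beta, cov, "flat")


def test_scan_attaches_monotone_qvalues():
    beta, x, _ = simulate_exposure_scan(60, 80, n_affected=10, effect=0.8, seed=4)
    cov = pd.DataFrame({"exposure": x})
    res = scan(beta, cov, "exposure")
    tab = res.table.dropna(subset=["q"]).sort_values("p")
    assert (tab["q"].diff().dropna() >= -1e-12).all()
    assert res.table["q"].max() <= 1.0
    assert 0 < res.pi0 <= 1.0


def test_storey_all_ones_gives_unit_qvalues():
    q, pi0 = storey_qvalues(np.ones(50))
    assert pi0 == pytest.approx(1.0)
    assert np.allclose(q, 1.0)


def test_storey_fixed_pi0_equals_benjamini_hochberg():
    rng = np.random.default_rng(8)
    p = np.concatenate([rng.uniform(0, 1e-3, 20), rng.uniform(0, 1, 180)])
    q, pi0 = storey_qvalues(p, pi0=1.0)
    assert pi0 == 1.0
    np.testing.assert_allclose(q, bh_adjust(p), rtol=0, atol=1e-14)


def test_storey_pi0_near_one_under_uniform_null():
    rng = np.random.default_rng(123)
    p = rng.uniform(0, 1, 1000)
    _, pi0 = storey_qvalues(p)
    assert pi0 >= 0.8


def test_storey_rejects_bad_pvalues():
    with pytest.raises(ValueError):
        storey_qvalues(np.array([0.1, 1.5]))
    with pytest.raises(ValueError):
        storey_qvalues(np.array([0.2]))


def test_sign_trend_counts_and_zero_category():
    beta, x, _ = simulate_exposure_scan(50, 30, seed=6)
    res = scan(beta, pd.DataFrame({"exposure": x}), "exposure")
    tr = sign_trend(res)
    assert tr.n_negative + tr.n_positive + tr.n_zero == res.table["converged"].sum()
    # synthetic table with all-negative coefficients
    res2 = res
    res2.table["coefficient"] = -np.abs(res2.table["coefficient"]) - 1e-6
    tr2 = sign_trend(res2)
    assert tr2.n_positive == 0 and tr2.n_zero == 0
    res2.table["coefficient"] = 0.0
    tr3 = sign_trend(res2)
    assert tr3.n_zero == len(res2.table) and tr3.n_positive == 0


def test_planted_negative_effect_detected_by_sign_test():
    rng_effect = -0.4
    beta, x, aff = simulate_exposure_scan(120, 150, n_affected=150,
                                          effect=rng_effect, seed=9)
    res = scan(beta, pd.DataFrame({"exposure": x}), "exposure")
    tr = sign_trend(res)
    assert tr.n_negative > tr.n_positive
    assert tr.sign_test_p < 0.05
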