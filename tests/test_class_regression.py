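"""Ridge multinomial fitting, BIC tuning, Wald tests and probability curves."""

import numpy as np
import pandas as pd
import pytest

from methclass import (
    build_design,
    default_referent,
    fit_ridge_multinomial,
    membership_curves,
    select_lambda_bic,
    wald_tests,
)
from methclass.class_regression import _neg_loglik_grad_hess


def _sim_multinomial(n=200, K=3, p=2, scale=1.0, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.normal(size=(n, p)), columns=[f"x{j + 1}" for j in range(p)]
    )
    B = rng.normal(scale=scale, size=(K - 1, p + 1))
    eta = np.column_stack(
        [np.zeros(n), np.column_stack([np.ones(n), X.to_numpy()]) @ B.T]
    )
    prob = np.exp(eta - eta.max(axis=1, keepdims=True))
    prob /= prob.sum(axis=1, keepdims=True)
    y = np.array([rng.choice(K, p=pi) for pi in prob]) + 1
    return y, X, B


def test_unpenalized_fit_matches_mnlogit_oracle():
    import statsmodels.api as sm

    y, X, _ = _sim_multinomial(seed=1)
    fit = fit_ridge_multinomial(y, X, lam=0.0, referent=1)
    oracle = sm.MNLogit(y - 1, sm.add_constant(X.to_numpy())).fit(
        disp=0, method="newton", maxiter=200
    )
    np.testing.assert_allclose(
        fit.coef.to_numpy(), oracle.params.T, rtol=0, atol=1e-5
    )


def test_analytic_gradient_matches_finite_differences():
    rng = np.random.default_rng(2)
    n, K, P = 40, 3, 3
    X = np.column_stack([np.ones(n), rng.normal(size=(n, P - 1))])
    Y = np.zeros((n, K - 1))
    Y[np.arange(n) % 3 == 0, 0] = 1
    Y[np.arange(n) % 3 == 1, 1] = 1
    pen = np.array([0.0, 1.0, 1.0])
    theta = rng.normal(scale=0.5, size=(K - 1, P))
    lam = 0.7
    _, grad, _, _ = _neg_loglik_grad_hess(theta, X, Y, lam, pen)
    eps = 1e-6
    for k in range(K - 1):
        for j in range(P):
            tp, tm = theta.copy(), theta.copy()
            tp[k, j] += eps
            tm[k, j] -= eps
            fp, _, _, _ = _neg_loglik_grad_hess(tp, X, Y, lam, pen, want_hess=False)
            fm, _, _, _ = _neg_loglik_grad_hess(tm, X, Y, lam, pen, want_hess=False)
            fd = (fp - fm) / (2 * eps)
            assert grad[k, j] == pytest.approx(fd, abs=1e-6, rel=1e-6)


def test_large_lambda_shrinks_slopes_and_recovers_class_frequencies():
    y, X, _ = _sim_multinomial(seed=3)
    fit = fit_ridge_multinomial(y, X, lam=1e8, referent=1)
    assert np.abs(fit.coef_std[:, 1:]).max() < 1e-4
    counts = pd.Series(y).value_counts()
    expected = np.log(counts.loc[[2, 3]].to_numpy() / counts.loc[1])
    np.testing.assert_allclose(fit.coef_std[:, 0], expected, atol=1e-4)


def test_penalized_loglik_nondecreasing_over_iterations():
    y, X, _ = _sim_multinomial(seed=4)
    fit = fit_ridge_multinomial(y, X, lam=0.5, referent=1)
    diffs = np.diff(fit.trace)
    assert (diffs >= -1e-10).all()


def test_single_lambda_grid_returned_as_is():
    y, X, _ = _sim_multinomial(n=120, seed=5)
    lam, fits = select_lambda_bic(y, X, [0.3], referent=1)
    assert lam == 0.3 and set(fits) == {0.3}


def test_df_eff_full_at_zero_and_nonincreasing():
    y, X, _ = _sim_multinomial(n=150, seed=6)
    grid = [0.0, 0.5, 2.0, 10.0, 100.0]
    _, fits = select_lambda_bic(y, X, grid, referent=1)
    dfs = [fits[l].df_eff for l in grid]
    K, p = 3, 2
    assert dfs[0] == pytest.approx((K - 1) * (p + 1), abs=1e-6)
    assert all(d1 >= d2 - 1e-9 for d1, d2 in zip(dfs, dfs[1:]))


def test_bic_prefers_shrinkage_for_sparse_truth():
    # true model: most coefficients zero, weak signal -> lambda* > 0 usually
    wins = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        n = 120
        X = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("abcd"))
        eta = np.column_stack(
            [np.zeros(n), 0.3 * X["a"].to_numpy()[:, None] * np.ones((n, 2))]
        )
        prob = np.exp(eta - eta.max(axis=1, keepdims=True))
        prob /= prob.sum(axis=1, keepdims=True)
        y = np.array([rng.choice(3, p=pi) for pi in prob]) + 1
        lam, _ = select_lambda_bic(y, X, [0.0, 0.5, 1.0, 2.0, 5.0], referent=1)
        wins += int(lam > 0)
    assert wins >= 7


def test_wald_zero_coefficients_give_zero_statistic():
    y, X, _ = _sim_multinomial(n=100, seed=7)
    fit = fit_ridge_multinomial(y, X, lam=1.0, referent=1)
    fit.coef_std[:, 1:] = 0.0  # force the null
    overall, per_class = wald_tests(fit)
    np.testing.assert_allclose(overall["wald_chi2"].to_numpy(), 0.0, atol=1e-12)
    np.testing.assert_allclose(overall["p"].to_numpy(), 1.0, atol=1e-12)


def test_wald_quadratic_form_matches_explicit_inverse():
    y, X, _ = _sim_multinomial(n=150, seed=8)
    fit = fit_ridge_multinomial(y, X, lam=0.5, referent=1)
    overall, _ = wald_tests(fit)
    Km1, P = fit.coef_std.shape
    for j, name in enumerate(fit.columns):
        if name == "intercept":
            continue
        idx = [k * P + j for k in range(Km1)]
        v = fit.coef_std[:, j]
        block_inv = np.linalg.inv(fit.cov_std[np.ix_(idx, idx)])
        assert overall.loc[name, "wald_chi2"] == pytest.approx(
            float(v @ block_inv @ v), rel=1e-10
        )


def test_wald_power_under_strong_planted_effect():
    hits = 0
    for seed in range(10):
        y, X, _ = _sim_multinomial(n=250, K=3, p=2, scale=1.2, seed=100 + seed)
        fit = fit_ridge_multinomial(y, X, lam=0.5, referent=1)
        overall, _ = wald_tests(fit)
        hits += int((overall["p"] < 0.001).any())
    assert hits >= 9


def test_referent_change_leaves_probabilities_unchanged_at_lambda_zero():
    y, X, _ = _sim_multinomial(n=150, seed=9)
    f1 = fit_ridge_multinomial(y, X, lam=0.0, referent=1)
    f2 = fit_ridge_multinomial(y, X, lam=0.0, referent=2)
    p1 = f1.predict_proba(X).to_numpy()
    p2 = f2.predict_proba(X).to_numpy()
    np.testing.assert_allclose(p1, p2, atol=1e-8)


def test_probability_curves_normalize_and_zero_model_is_uniform():
    y, X, _ = _sim_multinomial(n=90, seed=10)
    fit = fit_ridge_multinomial(y, X, lam=1e8, referent=1)
    # intercepts remain, so force a fully null model for the uniform check
    fit.coef_std[:] = 0.0
    curve = membership_curves(
        fit, "x1", np.linspace(-1, 1, 5), reference={"x2": 0.0}
    )
    np.testing.assert_allclose(curve.probabilities.sum(axis=0), 1.0, atol=1e-10)
    np.testing.assert_allclose(curve.probabilities.to_numpy(), 1.0 / 3.0, atol=1e-12)


def test_probability_curves_monotone_for_dominant_slope():
    y, X, _ = _sim_multinomial(n=200, seed=11)
    fit = fit_ridge_multinomial(y, X, lam=0.1, referent=1)
    slopes = dict(zip(fit.nonreferent_labels, fit.coef_std[:, 1]))
    slopes[fit.referent] = 0.0
    top = max(slopes, key=slopes.get)
    grid = np.linspace(X["x1"].min(), X["x1"].max(), 25)
    curve = membership_curves(fit, "x1", grid, reference={"x2": 0.0})
    probs = curve.probabilities.loc[top].to_numpy()
    assert probs[-1] > probs[0]


def test_probability_curve_outside_support_warns():
    y, X, _ = _sim_multinomial(n=90, seed=12)
    fit = fit_ridge_multinomial(y, X, lam=0.5, referent=1)
    with pytest.warns(RuntimeWarning, match="outside"):
        membership_curves(fit, "x1", np.array([100.0]), reference={"x2": 0.0})


def test_default_referent_is_median_size_class():
    labels = np.array([1] * 10 + [2] * 5 + [3] * 2)
    assert default_referent(labels) == 2


def test_build_design_transforms_and_dummies():
    cov = pd.DataFrame(
        {
            "folate": [100.0, 400.0, 900.0],
            "race": ["a", "b", "a"],
        },
        index=list("xyz"),
    )
    design = build_design(cov, ["folate", "race"], transforms={"folate": "sqrt"})
    assert "sqrt(folate)" in design.columns
    np.testing.assert_allclose(design["sqrt(folate)"], np.sqrt([100, 400, 900]))
    assert design["race[b]"].tolist() == [0.0, 1.0, 0.0]


def test_negative_lambda_rejected():
    y, X, _ = _sim_multinomial(n=60, seed=13)
    with pytest.raises(ValueError):
        fit_ridge_multinomial(y, X, lam=-1.0)
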