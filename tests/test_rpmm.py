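"""Beta-mixture machinery: weighted MLE, fuzzy EM, the recursive tree,
profiles and posterior classification."""

import numpy as np
import pandas as pd
import pytest

from methclass import (
    BetaMatrix,
    beta_mle_weighted,
    class_profiles,
    classify,
    em_two_class,
    fit_rpmm,
    simulate_class_matrix,
)


def test_beta_mle_symmetric_sample_gives_symmetric_shapes():
    rng = np.random.default_rng(1)
    x = rng.beta(5, 5, 1000)
    a, b = beta_mle_weighted(x)
    assert abs(a - b) / a < 0.05


def test_beta_mle_zero_weights_equal_dropping_those_points():
    rng = np.random.default_rng(2)
    x = rng.beta(3, 6, 200)
    w = np.ones(200)
    w[150:] = 0.0
    a1, b1 = beta_mle_weighted(x, w)
    a2, b2 = beta_mle_weighted(x[:150])
    assert a1 == pytest.approx(a2, rel=1e-8)
    assert b1 == pytest.approx(b2, rel=1e-8)


def test_beta_mle_consistency_on_large_sample():
    rng = np.random.default_rng(3)
    x = rng.beta(2, 8, 10_000)
    a, b = beta_mle_weighted(x)
    assert a == pytest.approx(2.0, rel=0.1)
    assert b == pytest.approx(8.0, rel=0.1)


def test_beta_mle_degenerate_input_caps_concentration():
    with pytest.warns(RuntimeWarning, match="degenerate"):
        a, b = beta_mle_weighted(np.full(50, 0.4))
    assert np.isfinite(a) and np.isfinite(b) and a > 0 and b > 0


def test_beta_mle_rejects_zero_total_weight():
    with pytest.raises(ValueError):
        beta_mle_weighted(np.array([0.2, 0.4]), np.zeros(2))


def _two_class_data(seed=0, n=100, J=50):
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 2, n)
    means = np.where(labels[:, None] == 0, 0.2, 0.8)
    X = rng.beta(means * 20, (1 - means) * 20, (n, J))
    return X, labels


def test_em_recovers_well_separated_classes():
    X, labels = _two_class_data(seed=4)
    res = em_two_class(X)
    hard = res.responsibilities.argmax(axis=1)
    acc = max((hard == labels).mean(), (hard != labels).mean())
    assert acc >= 0.99
    assert res.converged


def test_em_loglik_monotone_and_rows_normalized():
    X, _ = _two_class_data(seed=5, n=60, J=20)
    res = em_two_class(X)
    diffs = np.diff(res.trace)
    assert (diffs >= -1e-6 * np.maximum(1.0, np.abs(res.trace[:-1]))).all()
    np.testing.assert_allclose(res.responsibilities.sum(axis=1), 1.0, atol=1e-10)
    assert res.mixing.sum() == pytest.approx(1.0)


def test_em_invariant_to_locus_order():
    X, _ = _two_class_data(seed=6, n=40, J=30)
    res1 = em_two_class(X)
    perm = np.random.default_rng(0).permutation(30)
    res2 = em_two_class(X[:, perm])
    assert np.max(np.abs(res1.responsibilities - res2.responsibilities)) < 1e-8


def test_fit_rpmm_recovers_four_planted_classes():
    beta, truth = simulate_class_matrix(n_samples=150, n_loci=500, seed=0)
    model = fit_rpmm(beta)
    assert model.n_classes == 4
    from sklearn.metrics import adjusted_rand_score

    assert adjusted_rand_score(truth, model.labels) >= 0.9


def test_fit_rpmm_single_class_rejects_split():
    accepted = 0
    for seed in range(10):
        beta, _ = simulate_class_matrix(
            n_samples=60, n_loci=40, n_classes=1, mean_levels=(0.4,), seed=seed
        )
        model = fit_rpmm(beta)
        accepted += int(model.n_classes == 1)
    assert accepted >= 9


def test_fit_rpmm_depth_zero_gives_single_class():
    beta, _ = simulate_class_matrix(n_samples=30, n_loci=20, seed=1)
    model = fit_rpmm(beta, max_depth=0)
    assert model.n_classes == 1
    np.testing.assert_allclose(model.W.to_numpy(), 1.0)
    assert (model.labels == 1).all()


def test_fit_rpmm_membership_invariants():
    beta, _ = simulate_class_matrix(n_samples=80, n_loci=60, seed=2)
    model = fit_rpmm(beta)
    W = model.W.to_numpy()
    np.testing.assert_allclose(W.sum(axis=1), 1.0, atol=1e-8)
    assert model.class_weights().sum() == pytest.approx(1.0, abs=1e-8)
    # hard labels follow argmax with ties to the lower index
    np.testing.assert_array_equal(model.labels.to_numpy(), W.argmax(axis=1) + 1)


def test_fit_rpmm_sample_relabeling_equivariance():
    beta, _ = simulate_class_matrix(n_samples=60, n_loci=40, seed=3)
    model = fit_rpmm(beta)
    perm = np.random.default_rng(1).permutation(60)
    beta_perm = BetaMatrix(beta.values.iloc[perm])
    model_perm = fit_rpmm(beta_perm)
    if model_perm.n_classes == model.n_classes:
        np.testing.assert_allclose(
            model_perm.W.to_numpy(),
            model.W.to_numpy()[perm],
            atol=1e-6,
        )


def test_fit_rpmm_missing_values_require_flag():
    beta, _ = simulate_class_matrix(n_samples=30, n_loci=20, seed=4)
    vals = beta.values.copy()
    vals.iloc[0, 0] = np.nan
    with pytest.raises(ValueError, match="missing"):
        fit_rpmm(BetaMatrix(vals))
    model = fit_rpmm(BetaMatrix(vals), impute_missing=True)
    assert model.diagnostics[0].get("imputed_missing")


def test_class_profiles_single_class_equals_column_means():
    beta, _ = simulate_class_matrix(n_samples=30, n_loci=20, seed=5)
    model = fit_rpmm(beta, max_depth=0)
    prof = class_profiles(model, beta)
    np.testing.assert_allclose(
        prof.iloc[0].to_numpy(), beta.values.mean(axis=0).to_numpy(), atol=1e-12
    )


def test_class_profiles_match_brute_force_weighted_means():
    beta, _ = simulate_class_matrix(n_samples=80, n_loci=40, seed=6)
    model = fit_rpmm(beta)
    prof = class_profiles(model, beta)
    W = model.W.to_numpy()
    X = beta.to_numpy()
    for k in range(model.n_classes):
        expected = (W[:, k][:, None] * X).sum(axis=0) / W[:, k].sum()
        np.testing.assert_allclose(prof.iloc[k].to_numpy(), expected, atol=1e-10)
    assert prof.to_numpy().min() >= 0 and prof.to_numpy().max() <= 1


def test_classify_training_data_reproduces_memberships():
    beta, _ = simulate_class_matrix(n_samples=100, n_loci=60, seed=7)
    model = fit_rpmm(beta)
    assert model.n_classes >= 2
    W2 = classify(model, beta)
    np.testing.assert_allclose(W2.to_numpy(), model.W.to_numpy(), atol=1e-6)


def test_classify_mean_profile_sample_lands_in_its_class():
    beta, _ = simulate_class_matrix(n_samples=100, n_loci=60, seed=8)
    model = fit_rpmm(beta)
    prof = class_profiles(model, beta)
    probe = BetaMatrix(
        pd.DataFrame(prof.to_numpy(), index=[f"probe{k}" for k in range(model.n_classes)],
                     columns=beta.locus_ids)
    )
    W = classify(model, probe)
    assert (W.to_numpy().argmax(axis=1) == np.arange(model.n_classes)).all()


def test_classify_locus_mismatch_and_empty_input():
    beta, _ = simulate_class_matrix(n_samples=40, n_loci=20, seed=9)
    model = fit_rpmm(beta)
    bad = BetaMatrix(beta.values.iloc[:, :10])
    with pytest.raises(ValueError, match="loci missing"):
        classify(model, bad)
    empty = BetaMatrix(beta.values.iloc[:0])
    W = classify(model, empty)
    assert W.shape == (0, model.n_classes)


def test_fit_rpmm_empty_matrix_errors():
    with pytest.raises(ValueError):
        fit_rpmm(BetaMatrix(pd.DataFrame()))
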