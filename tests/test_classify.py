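"""PCA retention rule, k-means determinism, DFA validation, parsimony."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from divebout.classify import (
    BOUT_VARIABLES,
    DIVE_VARIABLES,
    ClusterSolution,
    classify_bouts,
    classify_dives,
    fit_pca,
    kmeans_scan,
    name_types,
    select_parsimonious,
    validate_dfa,
)
from divebout.synth import sample_bout_metrics, sample_dive_metrics


def _table(X, prefix="v"):
    return pd.DataFrame(X, columns=[f"{prefix}{j}" for j in range(X.shape[1])])


def _whitened(rng, n=400, p=8):
    """Data whose sample covariance is exactly the identity."""
    X = rng.standard_normal((n, p))
    X = X - X.mean(0)
    cov = X.T @ X / (n - 1)
    L = np.linalg.cholesky(cov)
    return X @ np.linalg.inv(L).T


def test_equal_eigenvalues_need_seven_of_eight_components(rng):
    t = _table(_whitened(rng))
    pca = fit_pca(t)
    # cumulative variance is k/8; 7/8 = 87.5 % is the first >= 80 %
    assert pca.n_components == 7


def test_rank_one_data_needs_one_component(rng):
    f = rng.standard_normal(300)
    X = np.outer(f, rng.uniform(0.5, 2.0, 8))
    assert fit_pca(_table(X)).n_components == 1


def test_rank_two_data_needs_at_most_two_components(rng):
    F = rng.standard_normal((300, 2))
    X = F @ rng.uniform(0.5, 2.0, (2, 8))
    assert fit_pca(_table(X)).n_components <= 2


def test_constant_variable_dropped(rng, caplog):
    X = rng.standard_normal((100, 4))
    X[:, 2] = 3.0
    with caplog.at_level("WARNING"):
        pca = fit_pca(_table(X))
    assert "v2" not in pca.variables
    assert len(pca.variables) == 3


def test_reconstruction_error_equals_discarded_eigenvalues(rng):
    X = rng.standard_normal((200, 6)) @ rng.uniform(0.2, 2.0, (6, 6))
    t = _table(X)
    pca = fit_pca(t, variance_target=0.6)
    Z = pca.standardize(t)
    m = pca.n_components
    scores = Z @ pca.components_[:m].T
    recon = scores @ pca.components_[:m]
    sse = ((Z - recon) ** 2).sum() / (len(Z) - 1)
    total_var = (Z**2).sum() / (len(Z) - 1)
    discarded = pca.explained_variance_ratio_[m:].sum() * total_var
    assert sse == pytest.approx(discarded, rel=1e-10)


def _blobs(rng, k=4, n=600, p=5, sep=12.0):
    centers = rng.uniform(-1, 1, (k, p)) * sep
    labels = rng.integers(0, k, n)
    return centers[labels] + rng.standard_normal((n, p)), labels


def test_separated_blobs_recovered(rng):
    X, truth = _blobs(rng)
    t = _table(X)
    pca = fit_pca(t, variance_target=0.99)
    (sol,) = kmeans_scan(t, pca, k_range=(4, 4), seed=0)
    assert adjusted_rand_score(truth, sol.labels) == 1.0


def test_kmeans_determinism(rng):
    X, _ = _blobs(rng)
    t = _table(X)
    pca = fit_pca(t, variance_target=0.99)
    s1 = kmeans_scan(t, pca, k_range=(4, 6), seed=3)
    s2 = kmeans_scan(t, pca, k_range=(4, 6), seed=3)
    for a, b in zip(s1, s2):
        assert a.inertia == b.inertia
        assert np.array_equal(a.labels, b.labels)


def test_dfa_perfect_on_separated_clusters(rng):
    X, truth = _blobs(rng)
    t = _table(X)
    pca = fit_pca(t, variance_target=0.99)
    (sol,) = kmeans_scan(t, pca, k_range=(4, 4), seed=0)
    assert validate_dfa(sol, t) == 100.0


def test_dfa_on_permuted_labels_near_chance(rng):
    X, truth = _blobs(rng, k=2, n=500)
    t = _table(X)
    pca = fit_pca(t, variance_target=0.99)
    (sol,) = kmeans_scan(t, pca, k_range=(2, 2), seed=0)
    sol.labels = rng.permutation(sol.labels)
    acc = validate_dfa(sol, t)
    chance = 100.0 * max(np.bincount(sol.labels)[1:]) / len(sol.labels)
    assert abs(acc - chance) < 6.0


def _dummy(k, accuracy):
    sol = ClusterSolution(
        k=k, variables=[], pca=None, centroids=np.empty(0),
        labels=np.empty(0, dtype=int), inertia=0.0, seed=0,
    )
    sol.accuracy = accuracy
    return sol


def test_parsimony_rule_arithmetic():
    sols = [_dummy(k, a) for k, a in
            [(4, 90.0), (5, 95.0), (6, 95.2), (7, 95.3), (8, 95.1)]]
    assert select_parsimonious(sols, tolerance=1.0).k == 5
    assert select_parsimonious([_dummy(4, 88.0)]).k == 4
    equal = [_dummy(k, 95.0) for k in (4, 5, 6)]
    assert select_parsimonious(equal).k == 4


def test_dive_type_names_from_centroids():
    df = pd.DataFrame(
        {
            "max_depth": [62.0, 16.0],
            "btd": [0.59, 0.36],
            "is_wiggle_dive": [1.05, 0.2],
            "duration": [300.0, 150.0],
        }
    )
    sol = _dummy(2, None)
    sol.labels = np.array([1, 2])
    named = name_types(sol, df, role="dive")
    assert sol.type_names[1] == "deep square wiggle"
    assert sol.type_names[2] == "shallow V no-wiggle"
    assert set(named.index) == set(sol.type_names.values())


def test_bout_type_names_resting_class():
    df = pd.DataFrame(
        {
            "mean_depth": [44.7, 19.0, 18.9],
            "mean_duration": [289.0, 165.0, 193.0],
            "mean_surface_interval": [45.0, 39.0, 3139.0],
            "bout_duration": [2267.0, 1355.0, 20214.0],
        }
    )
    sol = _dummy(3, None)
    sol.labels = np.array([1, 2, 3])
    name_types(sol, df, role="bout")
    assert sol.type_names == {1: "I", 2: "II", 3: "III"}


def test_name_types_role_mismatch_errors():
    sol = _dummy(2, None)
    sol.labels = np.array([1, 2])
    with pytest.raises(ValueError):
        name_types(sol, pd.DataFrame({"x": [1.0, 2.0]}), role="dive")
    with pytest.raises(ValueError):
        name_types(sol, pd.DataFrame({"x": [1.0, 2.0]}), role="other")


def test_pipeline_invariant_to_affine_rescaling():
    df = sample_dive_metrics(n=800, seed=1, sd_scale=0.5)
    lab1, _, sol1 = classify_dives(df, seed=0)
    scaled = df.copy()
    scaled["max_depth"] = scaled["max_depth"] * 3.5 + 100.0
    lab2, _, sol2 = classify_dives(scaled, seed=0)
    assert np.array_equal(sol1.labels, sol2.labels)
    assert sol1.accuracy == pytest.approx(sol2.accuracy)


def test_six_type_recovery_at_half_dispersion():
    df = sample_dive_metrics(n=3000, seed=0, sd_scale=0.5)
    _, sols, _ = classify_dives(df, seed=0)
    k6 = next(s for s in sols if s.k == 6)
    assert adjusted_rand_score(df.shape_id, k6.labels) >= 0.9
    assert k6.accuracy >= 90.0


def test_three_bout_types_recovered_at_half_dispersion():
    df = sample_bout_metrics(n=1500, seed=0, sd_scale=0.5)
    _, sols, _ = classify_bouts(df, seed=0)
    k3 = next(s for s in sols if s.k == 3)
    truth = df.bout_type.map({"I": 1, "II": 2, "III": 3})
    assert adjusted_rand_score(truth, k3.labels) >= 0.9
    assert k3.accuracy >= 90.0


def test_solution_roundtrip_through_json():
    df = sample_dive_metrics(n=300, seed=2, sd_scale=0.5)
    _, _, sol = classify_dives(df, k_range=(4, 5), seed=0)
    back = ClusterSolution.from_json(sol.to_json())
    assert back.k == sol.k
    assert np.array_equal(back.labels, sol.labels)
    assert back.accuracy == sol.accuracy
    assert back.type_names == sol.type_names
    np.testing.assert_allclose(back.centroids, sol.centroids)
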