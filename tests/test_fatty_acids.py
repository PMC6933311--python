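"""Compositional FA pipeline: subsetting, CLR, Ward, dynamic cut, LDA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

from sealflux.fatty_acids import (
    DEFAULT_DIETARY_FAS,
    clr_transform,
    cluster_profiles,
    discriminating_fas,
    dynamic_tree_cut,
    select_dietary_fas,
    ward_cluster,
)
from sealflux.simulate import DEFAULT_CLUSTER_CENTROIDS


def dirichlet_profiles(rng, n, probs, concentration=400.0):
    labels = rng.choice(len(probs), size=n, p=probs)
    rows = []
    for c in labels:
        cen = DEFAULT_CLUSTER_CENTROIDS[c]
        rows.append(rng.dirichlet(concentration * cen / cen.sum()) * 100.0)
    return pd.DataFrame(rows, columns=list(DEFAULT_DIETARY_FAS)), labels + 1


# -- dietary subsetting -----------------------------------------------------


def test_all_abundant_fas_kept(rng):
    prof, _ = dirichlet_profiles(rng, 30, [0.5, 0.5, 0.0, 0.0])
    out = select_dietary_fas(prof, threshold=0.5)
    assert set(out.columns) <= set(DEFAULT_DIETARY_FAS)
    assert np.allclose(out.sum(axis=1), 100.0, atol=1e-9)


def test_rare_fa_dropped():
    df = pd.DataFrame({"14:0": [50.0, 49.6], "16:0": [49.6, 50.0], "18:0": [0.4, 0.4]})
    out = select_dietary_fas(df, threshold=0.5)
    assert "18:0" not in out.columns
    assert np.allclose(out.sum(axis=1), 100.0)


def test_too_few_survivors_rejected():
    df = pd.DataFrame({"14:0": [99.9], "16:0": [0.1]})
    with pytest.raises(ValueError):
        select_dietary_fas(df)


# -- clr --------------------------------------------------------------------


def test_uniform_composition_maps_to_zero():
    df = pd.DataFrame([[25.0, 25.0, 25.0, 25.0]], columns=list("abcd"))
    assert np.allclose(clr_transform(df).values, 0.0)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(0.1, 100.0), min_size=3, max_size=10))
def test_clr_rows_sum_to_zero_and_scale_invariant(vals):
    df = pd.DataFrame([vals])
    out = clr_transform(df)
    assert abs(out.values.sum()) < 1e-9
    scaled = clr_transform(df * 3.7)
    assert np.allclose(out.values, scaled.values, atol=1e-9)


def test_zero_replacement_keeps_transform_finite():
    df = pd.DataFrame([[40.0, 0.0, 60.0]], columns=list("abc"))
    out = clr_transform(df)
    assert np.isfinite(out.values).all()


# -- Ward -------------------------------------------------------------------


def test_two_points_merge_at_squared_distance():
    X = np.array([[0.0, 0.0], [3.0, 4.0]])
    Z = ward_cluster(X)
    assert Z[0, 2] == pytest.approx(25.0)


def test_collinear_points_merge_nearest_first():
    X = np.array([[0.0], [1.0], [10.0]])
    Z = ward_cluster(X)
    assert set(Z[0, :2].astype(int)) == {0, 1}


def brute_force_ward(X):
    """Greedy Ward: merge the pair minimizing the increase in total
    within-cluster sum of squares; returns the partition after each merge."""
    clusters = [[i] for i in range(len(X))]
    partitions = []
    while len(clusters) > 1:
        best, best_cost = None, np.inf
        for a, b in itertools.combinations(range(len(clusters)), 2):
            ca, cb = X[clusters[a]], X[clusters[b]]
            na, nb = len(ca), len(cb)
            delta = (
                na * nb / (na + nb)
                * np.sum((ca.mean(axis=0) - cb.mean(axis=0)) ** 2)
            )
            if delta < best_cost - 1e-12:
                best, best_cost = (a, b), delta
        a, b = best
        merged = clusters[a] + clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)] + [merged]
        partitions.append({frozenset(c) for c in clusters})
    return partitions


def linkage_partitions(Z, n):
    members = {i: frozenset([i]) for i in range(n)}
    partitions = []
    for i, (a, b, *_rest) in enumerate(Z):
        members[n + i] = members.pop(int(a)) | members.pop(int(b))
        partitions.append(set(members.values()))
    return partitions


def test_ward_merges_match_brute_force_objective(rng):
    for _ in range(8):
        n = int(rng.integers(4, 9))
        X = rng.normal(0, 1, (n, 3))
        Z = ward_cluster(X)
        assert linkage_partitions(Z, n) == brute_force_ward(X)


def test_duplicate_points_allowed():
    X = np.array([[1.0, 1.0], [1.0, 1.0], [5.0, 5.0]])
    Z = ward_cluster(X)
    assert Z[0, 2] == pytest.approx(0.0)


# -- dynamic tree cut -------------------------------------------------------


def test_four_separated_blobs_recovered(rng):
    centers = np.array([[0, 0], [8, 0], [0, 8], [8, 8]], dtype=float)
    labels_true = np.repeat(np.arange(4), 30)
    X = centers[labels_true] + rng.normal(0, 0.4, (120, 2))
    Z = ward_cluster(X)
    labels = dynamic_tree_cut(Z, min_cluster_size=10)
    assert labels.max() == 4
    assert adjusted_rand_score(labels_true, labels) == 1.0


def test_two_blobs_recovered(rng):
    X = np.vstack([rng.normal(0, 0.3, (40, 3)), rng.normal(4, 0.3, (40, 3))])
    labels = dynamic_tree_cut(ward_cluster(X), min_cluster_size=10)
    assert labels.max() == 2


def test_min_cluster_size_exceeding_n_gives_single_cluster(rng):
    X = rng.normal(0, 1, (30, 2))
    labels = dynamic_tree_cut(ward_cluster(X), min_cluster_size=100)
    assert labels.max() == 1


def test_identical_profiles_single_cluster():
    X = np.ones((12, 4))
    labels = dynamic_tree_cut(ward_cluster(X), min_cluster_size=2)
    assert labels.max() == 1


def test_row_order_invariance(rng):
    prof, _ = dirichlet_profiles(rng, 120, [0.5, 0.5, 0.0, 0.0])
    m1 = cluster_profiles(prof, min_cluster_size=15)
    perm = rng.permutation(len(prof))
    m2 = cluster_profiles(prof.iloc[perm].reset_index(drop=True), min_cluster_size=15)
    assert adjusted_rand_score(m1.labels[perm], m2.labels) == 1.0


# -- LDA --------------------------------------------------------------------


def test_single_discriminating_fa_ranked_first(small_profiles):
    prof, labels = small_profiles
    clr = clr_transform(prof)
    loadings = discriminating_fas(clr, labels)
    assert loadings.index[0] in ("FA_0", "FA_1")  # the two FAs that move


def test_label_permutation_preserves_ranking(small_profiles):
    prof, labels = small_profiles
    clr = clr_transform(prof)
    l1 = discriminating_fas(clr, labels)
    l2 = discriminating_fas(clr, 3 - labels)  # swap the two label values
    assert list(l1.index) == list(l2.index)


def test_degenerate_cluster_sizes_rejected(small_profiles):
    prof, _ = small_profiles
    clr = clr_transform(prof)
    labels = np.array([1] * 29 + [2])
    with pytest.raises(ValueError):
        discriminating_fas(clr, labels)


# -- full pipeline ----------------------------------------------------------


def test_study_scale_dirichlet_recovery(rng):
    prof, labels_true = dirichlet_profiles(rng, 291, [0.38, 0.27, 0.23, 0.12])
    model = cluster_profiles(prof)
    assert model.n_clusters == 4
    assert adjusted_rand_score(labels_true, model.labels) >= 0.9
    assert model.loadings is not None
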