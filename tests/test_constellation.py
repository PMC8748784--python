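"""Dendrograms, Robinson-Foulds distances, and the combined
(tissue, timepoint) constellation distance."""

import itertools

import numpy as np
import pandas as pd
import pytest

from crestatlas.constellation import (
    ConstellationDistance,
    TissueDendrogram,
    build_dendrogram,
    build_distance,
    embed,
    group_nodes,
    rf_distance,
)
from crestatlas.containers import ValidationError


# ----------------------------------------------------------------- dendrogram
def test_nearest_pair_merges_first():
    # pairwise distances AB=1, AC~10, BC~10
    scores = pd.DataFrame(
        {"A": [0.0, 0.0], "B": [1.0, 0.0], "C": [10.0, 0.0]}
    )
    d = build_dendrogram(scores, "T0")
    assert frozenset({"A", "B"}) in d.clusters()


def test_duplicate_tissues_merge_at_height_zero():
    scores = pd.DataFrame({"A": [1.0, 2.0], "B": [1.0, 2.0], "C": [9.0, 9.0]})
    d = build_dendrogram(scores, "T0")
    assert d.linkage[0, 2] == 0.0


def _naive_average_linkage_clusters(X: np.ndarray, labels):
    """O(n^3) agglomerative oracle: average of pairwise Euclidean
    distances between cluster members."""
    pts = {i: [i] for i in range(len(labels))}
    dist = lambda a, b: np.mean(
        [np.linalg.norm(X[i] - X[j]) for i in pts[a] for j in pts[b]]
    )
    clusters = []
    next_id = len(labels)
    while len(pts) > 1:
        pairs = list(itertools.combinations(pts, 2))
        a, b = min(pairs, key=lambda p: dist(*p))
        pts[next_id] = pts.pop(a) + pts.pop(b)
        clusters.append(frozenset(labels[i] for i in pts[next_id]))
        next_id += 1
    return clusters


def test_dendrogram_matches_naive_agglomerative_oracle():
    rng = np.random.default_rng(2)
    labels = list("ABCDEF")
    scores = pd.DataFrame(
        rng.normal(size=(12, 6)), columns=labels
    )
    d = build_dendrogram(scores, "T0")
    oracle = _naive_average_linkage_clusters(
        scores.to_numpy().T, labels
    )
    assert set(d.clusters()) == set(oracle)


def test_single_tissue_rejected():
    with pytest.raises(ValidationError):
        build_dendrogram(pd.DataFrame({"A": [1.0, 2.0]}), "T0")


# -------------------------------------------------------------- RF distance
def test_rf_identical_topologies_zero():
    t = TissueDendrogram.from_nested((("A", "B"), ("C", "D")))
    assert rf_distance(t, t) == 0


def test_rf_four_leaf_swap_is_two():
    """((A,B),(C,D)) vs ((A,C),(B,D)): bipartitions {AB|CD} vs {AC|BD},
    symmetric difference of size 2."""
    t1 = TissueDendrogram.from_nested((("A", "B"), ("C", "D")))
    t2 = TissueDendrogram.from_nested((("A", "C"), ("B", "D")))
    assert rf_distance(t1, t2) == 2


def test_rf_bounds_on_binary_trees():
    t1 = TissueDendrogram.from_nested(((("A", "B"), ("C", "D")), ("E", "F")))
    t2 = TissueDendrogram.from_nested(((("A", "F"), ("C", "E")), ("B", "D")))
    rf = rf_distance(t1, t2)
    assert 0 <= rf <= 2 * (6 - 3)


def test_rf_leaf_mismatch_rejected():
    t1 = TissueDendrogram.from_nested((("A", "B"), ("C", "D")))
    t2 = TissueDendrogram.from_nested((("A", "B"), ("C", "E")))
    with pytest.raises(ValidationError):
        rf_distance(t1, t2)


def _random_topology(labels, rng):
    """Random binary topology by random leaf insertion (nested tuples)."""
    tree = (labels[0], labels[1])
    for leaf in labels[2:]:
        # attach at a uniformly random edge via recursive descent
        def insert(node):
            if rng.random() < 0.5 or isinstance(node, str):
                return (node, leaf)
            a, b = node
            if rng.random() < 0.5:
                return (insert(a), b)
            return (a, insert(b))

        tree = insert(tree)
    return tree


def test_rf_matches_phylogenetics_library():
    dendropy = pytest.importorskip("dendropy")
    from dendropy.calculate import treecompare

    rng = np.random.default_rng(5)
    labels = list("ABCDEF")
    tns = dendropy.TaxonNamespace()
    for _ in range(30):
        n1 = TissueDendrogram.from_nested(_random_topology(labels, rng))
        n2 = TissueDendrogram.from_nested(_random_topology(labels, rng))
        d1 = dendropy.Tree.get(
            data=n1.to_newick(), schema="newick", taxon_namespace=tns,
            rooting="force-unrooted",
        )
        d2 = dendropy.Tree.get(
            data=n2.to_newick(), schema="newick", taxon_namespace=tns,
            rooting="force-unrooted",
        )
        expected = treecompare.symmetric_difference(d1, d2)
        assert rf_distance(n1, n2) == expected


# -------------------------------------------------------- combined distance
def _three_tissue_scores():
    t1 = pd.DataFrame({"A": [0.0, 0.0], "B": [3.0, 4.0], "C": [0.0, 5.0]})
    t2 = pd.DataFrame({"A": [1.0, 1.0], "B": [1.0, 1.0], "C": [4.0, 5.0]})
    return {"T0": t1, "T1": t2}


def test_three_tissue_hand_computation():
    """Full 6x6 matrix against hand-computed Euclidean distances; with
    three tissues no non-trivial bipartition exists, so the RF term is 0
    and D = D_tissue."""
    dist = build_distance(_three_tissue_scores(), a=12.0)
    s10 = np.sqrt(10.0)
    # node order: (A,T0),(B,T0),(C,T0),(A,T1),(B,T1),(C,T1)
    expected = np.array(
        [
            [0.0, 5.0, 5.0, 0.0, 2.5, 5.0],
            [5.0, 0.0, s10, 2.5, 0.0, (s10 + 5) / 2],
            [5.0, s10, 0.0, 5.0, (s10 + 5) / 2, 0.0],
            [0.0, 2.5, 5.0, 0.0, 0.0, 5.0],
            [2.5, 0.0, (s10 + 5) / 2, 0.0, 0.0, 5.0],
            [5.0, (s10 + 5) / 2, 0.0, 5.0, 5.0, 0.0],
        ]
    )
    np.testing.assert_allclose(dist.D, expected, atol=1e-12)
    np.testing.assert_allclose(dist.D_timepoint, 0.0)


def _four_tissue_scores():
    t1 = pd.DataFrame(
        {
            "A": [0.0, 0.0], "B": [0.0, 1.0],
            "C": [10.0, 0.0], "D": [10.0, 1.0],
        }
    )
    t2 = pd.DataFrame(
        {
            "A": [0.0, 0.0], "C": [0.0, 1.0],
            "B": [10.0, 0.0], "D": [10.0, 1.0],
        }
    )[["A", "B", "C", "D"]]
    return {"T0": t1, "T1": t2}


def test_four_tissue_rf_term_weighted_by_a():
    """Trees ((A,B),(C,D)) at T0 vs ((A,C),(B,D)) at T1 give RF=2, so
    every cross-timepoint entry carries + a*2."""
    dist = build_distance(_four_tissue_scores(), a=12.0)
    nodes = {n: i for i, n in enumerate(dist.nodes)}
    iA0, iA1 = nodes[("A", "T0")], nodes[("A", "T1")]
    iB1 = nodes[("B", "T1")]
    assert dist.D_timepoint[iA0, iA1] == 2
    assert dist.D[iA0, iA1] == pytest.approx(24.0)  # D_tissue self = 0
    assert dist.D[iA0, iB1] == pytest.approx((1.0 + 10.0) / 2 + 24.0)
    # same-timepoint block: D = D_tissue exactly
    iB0 = nodes[("B", "T0")]
    assert dist.D_timepoint[iA0, iB0] == 0
    assert dist.D[iA0, iB0] == pytest.approx(1.0)


def test_distance_invariants_and_scaling():
    scores = {
        tp: pd.DataFrame(
            np.random.default_rng(i).normal(size=(20, 5)),
            columns=list("ABCDE"),
        )
        for i, tp in enumerate(["T0", "T1", "T2"])
    }
    dist = build_distance(scores, a=12.0)
    np.testing.assert_array_equal(dist.D, dist.D.T)
    np.testing.assert_array_equal(np.diag(dist.D), 0.0)
    np.testing.assert_allclose(
        dist.D, dist.D_tissue + 12.0 * dist.D_timepoint
    )
    # D_timepoint depends only on the timepoint pair
    for t1 in ["T0", "T1", "T2"]:
        for t2 in ["T0", "T1", "T2"]:
            block = dist.D_timepoint[
                np.ix_(
                    [i for i, n in enumerate(dist.nodes) if n[1] == t1],
                    [i for i, n in enumerate(dist.nodes) if n[1] == t2],
                )
            ]
            assert np.unique(block).size == 1 or (t1 == t2)
    # scaling scores by c scales D_tissue by c, leaves RF term unchanged
    scaled = build_distance(
        {tp: 3.0 * df for tp, df in scores.items()}, a=12.0
    )
    np.testing.assert_allclose(scaled.D_tissue, 3.0 * dist.D_tissue, rtol=1e-9)
    np.testing.assert_array_equal(scaled.D_timepoint, dist.D_timepoint)


def test_missing_score_column_rejected():
    scores = _three_tissue_scores()
    scores["T1"] = scores["T1"][["A", "B"]]
    with pytest.raises(ValidationError):
        build_distance(scores)


# ----------------------------------------------------------------- embedding
def _planted_two_group_distance(n_per=12, gap=50.0, seed=0):
    rng = np.random.default_rng(seed)
    n = 2 * n_per
    D = rng.uniform(0.5, 1.5, size=(n, n))
    D = (D + D.T) / 2
    D[:n_per, n_per:] += gap
    D[n_per:, :n_per] += gap
    np.fill_diagonal(D, 0.0)
    nodes = [(f"t{i}", "T0") for i in range(n)]
    return ConstellationDistance(
        nodes=nodes, D=D, D_tissue=D, D_timepoint=np.zeros_like(D), a=12.0
    )


def test_embed_deterministic_and_separates_planted_groups():
    from sklearn.cluster import KMeans
    from sklearn.metrics import adjusted_rand_score

    dist = _planted_two_group_distance()
    c1 = embed(dist, seed=0, n_neighbors=5)
    c2 = embed(dist, seed=0, n_neighbors=5)
    np.testing.assert_array_equal(c1.to_numpy(), c2.to_numpy())
    km = KMeans(n_clusters=2, n_init=10, random_state=0).fit_predict(
        c1[["x", "y"]].to_numpy()
    )
    truth = [0] * 12 + [1] * 12
    assert adjusted_rand_score(truth, km) >= 0.9


def test_embed_single_node_and_nan_rejection():
    single = ConstellationDistance(
        nodes=[("A", "T0")],
        D=np.zeros((1, 1)),
        D_tissue=np.zeros((1, 1)),
        D_timepoint=np.zeros((1, 1)),
        a=12.0,
    )
    coords = embed(single, seed=0)
    assert coords.shape == (1, 2)
    bad = _planted_two_group_distance()
    bad.D[0, 1] = np.nan
    with pytest.raises(ValidationError):
        embed(bad, seed=0)


# ------------------------------------------------------------------- groups
def test_group_nodes_trivial_cuts():
    dist = _planted_two_group_distance()
    n = len(dist.nodes)
    singletons = group_nodes(dist, n)
    assert singletons.nunique() == n
    one = group_nodes(dist, 1)
    assert one.nunique() == 1
    two = group_nodes(dist, 2)
    assert two.nunique() == 2
    with pytest.raises(ValidationError):
        group_nodes(dist, n + 1)
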