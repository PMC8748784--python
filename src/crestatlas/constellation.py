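"""The (tissue, timepoint) constellation distance and its 2D embedding.

For nodes (A, t1) and (B, t2):

    D = D_tissue + a * D_timepoint
    D_tissue   = [ d_(A,B),t1 + d_(A,B),t2 ] / 2
    D_timepoint = RF(t1, t2)

where ``d_(A,B),t`` is the Euclidean distance between the per-cell module
score vectors of tissues A and B at timepoint t, and RF is the
Robinson-Foulds distance between the tissue-score dendrograms of the two
timepoints. The weight ``a`` (default 12) puts the timepoint term on the
same scale as the tissue term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator

from .containers import ValidationError


@dataclass
class TissueDendrogram:
    """Rooted binary tree over tissue labels with merge heights."""

    timepoint: str
    linkage: np.ndarray  # scipy linkage matrix
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.labels) < 2:
            raise ValidationError("dendrogram needs at least 2 tissues")

    def clusters(self) -> list[frozenset]:
        """Leaf sets of all internal nodes (including the root)."""
        n = len(self.labels)
        members: dict[int, frozenset] = {
            i: frozenset([self.labels[i]]) for i in range(n)
        }
        out = []
        for k, (a, b, _, _) in enumerate(self.linkage):
            merged = members[int(a)] | members[int(b)]
            members[n + k] = merged
            out.append(merged)
        return out

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions, canonicalized by their smaller side.

        Topology only; heights are ignored.
        """
        n = len(self.labels)
        full = frozenset(self.labels)
        out = set()
        for c in self.clusters():
            if 2 <= len(c) <= n - 2:
                comp = full - c
                out.add(min((c, comp), key=lambda s: sorted(s)))
        return out

    @classmethod
    def from_nested(cls, tree, timepoint: str = "") -> "TissueDendrogram":
        """Build from a nested tuple of leaf labels (topology only).

        Nodes of arity > 2 are left-folded into binary merges; under the
        bipartition canonicalization this never changes the bipartition
        set, so RF distances are those of the original (possibly
        unrooted-style) topology. Merge heights encode merge order only.
        """
        labels: list[str] = []

        def collect(node):
            if isinstance(node, str):
                labels.append(node)
            else:
                for child in node:
                    collect(child)

        collect(tree)
        index = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        rows: list[list[float]] = []
        sizes: dict[int, int] = {i: 1 for i in range(n)}

        def build(node) -> int:
            if isinstance(node, str):
                return index[node]
            ids = [build(child) for child in node]
            cur = ids[0]
            for other in ids[1:]:
                new_id = n + len(rows)
                size = sizes[cur] + sizes[other]
                rows.append([cur, other, float(len(rows) + 1), size])
                sizes[new_id] = size
                cur = new_id
            return cur

        build(tree)
        return cls(
            timepoint=timepoint,
            linkage=np.asarray(rows, dtype=float),
            labels=labels,
        )

    def to_newick(self) -> str:
        n = len(self.labels)
        reps: dict[int, str] = {
            i: self.labels[i] for i in range(n)
        }
        heights: dict[int, float] = {i: 0.0 for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.linkage):
            a, b = int(a), int(b)
            la = max(h - heights[a], 0.0)
            lb = max(h - heights[b], 0.0)
            reps[n + k] = f"({reps[a]}:{la:.6g},{reps[b]}:{lb:.6g})"
            heights[n + k] = h
        return reps[n + len(self.linkage) - 1] + ";"


def build_dendrogram(
    scores: pd.DataFrame, timepoint: str = "", method: str = "average"
) -> TissueDendrogram:
    """Agglomerate tissue score vectors (columns) into a rooted tree.

    Euclidean metric, average linkage by default.
    """
    if scores.shape[1] < 2:
        raise ValidationError("need at least 2 tissues to build a dendrogram")
    X = scores.to_numpy(float).T  # tissues x cells
    Z = hierarchy.linkage(X, method=method, metric="euclidean")
    return TissueDendrogram(
        timepoint=timepoint, linkage=Z, labels=list(scores.columns)
    )


def rf_distance(t1: TissueDendrogram, t2: TissueDendrogram) -> int:
    """Robinson-Foulds distance: bipartitions present in exactly one tree."""
    if set(t1.labels) != set(t2.labels):
        raise ValidationError("trees have different leaf sets")
    return len(t1.bipartitions() ^ t2.bipartitions())


@dataclass
class ConstellationDistance:
    nodes: list[tuple[str, str]]  # (tissue, timepoint)
    D: np.ndarray
    D_tissue: np.ndarray
    D_timepoint: np.ndarray
    a: float

    def frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_tuples(self.nodes, names=["tissue", "timepoint"])
        return pd.DataFrame(self.D, index=idx, columns=idx)

    def subset(self, keep: list[tuple[str, str]]) -> "ConstellationDistance":
        pos = {n: i for i, n in enumerate(self.nodes)}
        idx = np.array([pos[n] for n in keep])
        return ConstellationDistance(
            nodes=list(keep),
            D=self.D[np.ix_(idx, idx)],
            D_tissue=self.D_tissue[np.ix_(idx, idx)],
            D_timepoint=self.D_timepoint[np.ix_(idx, idx)],
            a=self.a,
        )


def build_distance(
    scores_by_timepoint: dict[str, pd.DataFrame],
    a: float = 12.0,
    linkage_method: str = "average",
    dendrograms: dict[str, TissueDendrogram] | None = None,
    rms_normalize: bool = False,
) -> ConstellationDistance:
    """Assemble the full (tissue, timepoint) distance matrix.

    ``rms_normalize`` divides each within-timepoint Euclidean distance by
    sqrt(n_cells), making stages with different cell counts comparable
    (off by default: raw Euclidean distances).
    """
    if a < 0:
        raise ValidationError("weight a must be >= 0")
    tps = list(scores_by_timepoint)
    tissues = list(scores_by_timepoint[tps[0]].columns)
    for tp in tps:
        if list(scores_by_timepoint[tp].columns) != tissues:
            raise ValidationError(
                f"timepoint {tp!r} is missing score columns; every tissue "
                "must be scored at every timepoint"
            )

    # within-timepoint tissue-pair Euclidean distances
    d_t: dict[str, np.ndarray] = {}
    for tp in tps:
        M = scores_by_timepoint[tp].to_numpy(float)
        if np.isnan(M).any():
            raise ValidationError(f"NaN module scores at timepoint {tp!r}")
        dm = squareform(pdist(M.T, metric="euclidean"))
        if rms_normalize:
            dm = dm / np.sqrt(M.shape[0])
        d_t[tp] = dm

    if dendrograms is None:
        dendrograms = {
            tp: build_dendrogram(scores_by_timepoint[tp], tp, linkage_method)
            for tp in tps
        }
    rf = {
        (t1, t2): (
            0 if t1 == t2 else rf_distance(dendrograms[t1], dendrograms[t2])
        )
        for t1 in tps
        for t2 in tps
    }

    nodes = [(tissue, tp) for tp in tps for tissue in tissues]
    n = len(nodes)
    ti = {t: i for i, t in enumerate(tissues)}
    D_tissue = np.zeros((n, n))
    D_time = np.zeros((n, n))
    for i, (A, t1) in enumerate(nodes):
        for j, (B, t2) in enumerate(nodes):
            if i == j:
                continue
            D_tissue[i, j] = 0.5 * (
                d_t[t1][ti[A], ti[B]] + d_t[t2][ti[A], ti[B]]
            )
            D_time[i, j] = rf[(t1, t2)]
    D = D_tissue + a * D_time
    return ConstellationDistance(
        nodes=nodes, D=D, D_tissue=D_tissue, D_timepoint=D_time, a=a
    )


def embed(
    dist: ConstellationDistance,
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> pd.DataFrame:
    """2D manifold embedding of the precomputed distance matrix.

    Deterministic under a fixed seed. A single node maps to the origin.
    """
    import umap  # deferred: numba jit on first import

    if np.isnan(dist.D).any():
        raise ValidationError("distance matrix contains NaN")
    n = len(dist.nodes)
    idx = pd.MultiIndex.from_tuples(dist.nodes, names=["tissue", "timepoint"])
    if n == 1:
        return pd.DataFrame({"x": [0.0], "y": [0.0]}, index=idx)
    nn = min(n_neighbors, n - 1)
    reducer = umap.UMAP(
        n_components=2,
        metric="precomputed",
        n_neighbors=nn,
        min_dist=min_dist,
        random_state=seed,
    )
    coords = reducer.fit_transform(dist.D)
    return pd.DataFrame(coords, columns=["x", "y"], index=idx)


def group_nodes(
    dist: ConstellationDistance, k: int, method: str = "average"
) -> pd.Series:
    """Hierarchical cut of the distance matrix into ``k`` groups."""
    n = len(dist.nodes)
    if k > n:
        raise ValidationError(f"k={k} exceeds node count {n}")
    if k < 1:
        raise ValidationError("k must be >= 1")
    idx = pd.MultiIndex.from_tuples(dist.nodes, names=["tissue", "timepoint"])
    if k == n:
        return pd.Series(np.arange(1, n + 1), index=idx, name="group")
    Z = hierarchy.linkage(squareform(dist.D, checks=False), method=method)
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=idx, name="group")


class ConstellationEmbedding(BaseEstimator):
    """sklearn-style wrapper: fit on per-timepoint score matrices.

    Fitted attributes: ``distance_`` (:class:`ConstellationDistance`),
    ``embedding_`` (DataFrame of 2D coordinates), ``groups_`` when
    ``n_groups`` is set.
    """

    def __init__(
        self,
        a: float = 12.0,
        linkage_method: str = "average",
        n_neighbors: int = 15,
        min_dist: float = 0.1,
        n_groups: int | None = None,
        random_state: int = 0,
        rms_normalize: bool = False,
    ):
        self.a = a
        self.linkage_method = linkage_method
        self.n_neighbors = n_neighbors
        self.min_dist = min_dist
        self.n_groups = n_groups
        self.random_state = random_state
        self.rms_normalize = rms_normalize

    def fit(self, X: dict[str, pd.DataFrame], y=None):
        self.distance_ = build_distance(
            X,
            a=self.a,
            linkage_method=self.linkage_method,
            rms_normalize=self.rms_normalize,
        )
        self.embedding_ = embed(
            self.distance_,
            seed=self.random_state,
            n_neighbors=self.n_neighbors,
            min_dist=self.min_dist,
        )
        if self.n_groups is not None:
            self.groups_ = group_nodes(self.distance_, self.n_groups)
        return self

    def fit_transform(self, X: dict[str, pd.DataFrame], y=None) -> np.ndarray:
        self.fit(X)
        return self.embedding_[["x", "y"]].to_numpy()
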