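"""Cross-timepoint cell graph in projected LSI space.

Each timepoint's TF-IDF-weighted matrix is factorized by truncated SVD
(M = U S Vt, cells x peaks orientation). To link stage t to stage t-1 the
LSI basis of t is projected backwards: U^p_{t-1} = M_{t-1} V_t S_t^{-1},
the least-squares solution of M_{t-1} = U^p_{t-1} S_t Vt_t. U_t and
U^p_{t-1} rows (components 2..30 by default) are concatenated, scaled to
unit length, and each cell of t is linked to its k nearest t-1 cells.
Intra-timepoint kNN edges come from each stage's own LSI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.neighbors import NearestNeighbors

from .containers import CellAccessibilityMatrix, ValidationError


def tfidf(m, scale: float = 1e4) -> np.ndarray:
    """log(1 + TF * IDF * scale) weighting, cells x peaks.

    TF = count / cell total; IDF = n_cells / number of cells the peak is
    observed in. Peaks observed in no cell get a zero column (warned):
    dropping them would break the shared peak space the cross-timepoint
    projection requires.
    """
    if isinstance(m, CellAccessibilityMatrix):
        X = m.cell_major()
    elif sp.issparse(m):
        X = m.tocsr()
    else:
        X = sp.csr_matrix(np.asarray(m, dtype=float))
    if X.nnz and X.data.min() < 0:
        raise ValidationError("tfidf requires non-negative counts")
    cell_totals = np.asarray(X.sum(axis=1)).ravel()
    if np.any(cell_totals == 0):
        raise ValidationError("tfidf: empty cells present")
    occurrence = np.asarray((X > 0).sum(axis=0)).ravel()
    empty = occurrence == 0
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} peaks observed in no cell; their tf-idf "
            "columns are zero",
            stacklevel=2,
        )
    idf = np.where(empty, 0.0, X.shape[0] / np.maximum(occurrence, 1))
    tf = X.multiply(1.0 / cell_totals[:, None]).toarray()
    return np.log1p(tf * idf[None, :] * scale)


@dataclass
class LSIFactorization:
    timepoint: str
    U: np.ndarray  # cells x rank
    S: np.ndarray  # rank, descending
    Vt: np.ndarray  # rank x peaks
    rank: int
    component_range: tuple[int, int] = (2, 30)

    def components(self) -> np.ndarray:
        """U restricted to the downstream component range (1-based,
        inclusive): the default (2, 30) drops the depth-dominated first
        component."""
        lo, hi = self.component_range
        return self.U[:, lo - 1 : hi]


def _fix_signs(U: np.ndarray, Vt: np.ndarray):
    # deterministic sign convention: largest-|.| entry of each right
    # singular vector is positive
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    return U, Vt


def lsi(
    weighted: np.ndarray,
    rank: int = 30,
    timepoint: str = "",
    component_range: tuple[int, int] | None = None,
) -> LSIFactorization:
    """Truncated SVD of a TF-IDF-weighted matrix (cells x peaks)."""
    W = np.asarray(weighted, dtype=float)
    max_rank = min(W.shape)
    if rank > max_rank:
        warnings.warn(
            f"rank {rank} exceeds matrix rank bound {max_rank}; reduced",
            stacklevel=2,
        )
        rank = max_rank
    if rank >= max_rank:
        U, S, Vt = np.linalg.svd(W, full_matrices=False)
        U, S, Vt = U[:, :rank], S[:rank], Vt[:rank]
    else:
        U, S, Vt = spla.svds(W, k=rank, random_state=0)
        order = np.argsort(S)[::-1]
        U, S, Vt = U[:, order], S[order], Vt[order]
    U, Vt = _fix_signs(U, Vt)
    if component_range is None:
        component_range = (min(2, rank), rank)
    return LSIFactorization(
        timepoint=timepoint,
        U=U,
        S=S,
        Vt=Vt,
        rank=rank,
        component_range=component_range,
    )


class LSI(BaseEstimator, TransformerMixin):
    """sklearn-style LSI transformer (TF-IDF then truncated SVD).

    ``fit`` learns the factorization of the fit data; ``transform`` maps
    (already weighted or raw count) matrices into the learned basis via
    X V S^{-1}. Fitted attributes: ``factorization_``, ``U_``, ``S_``,
    ``Vt_``.
    """

    def __init__(
        self,
        rank: int = 30,
        component_range: tuple[int, int] = (2, 30),
        apply_tfidf: bool = True,
        scale: float = 1e4,
    ):
        self.rank = rank
        self.component_range = component_range
        self.apply_tfidf = apply_tfidf
        self.scale = scale

    def _weight(self, X) -> np.ndarray:
        if self.apply_tfidf:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return tfidf(X, scale=self.scale)
        if isinstance(X, CellAccessibilityMatrix):
            return np.asarray(X.cell_major().todense(), dtype=float)
        return np.asarray(
            X.todense() if sp.issparse(X) else X, dtype=float
        )

    def fit(self, X, y=None):
        W = self._weight(X)
        lo, hi = self.component_range
        self.factorization_ = lsi(
            W,
            rank=self.rank,
            component_range=(lo, min(hi, self.rank)),
            timepoint=getattr(X, "timepoint", ""),
        )
        self.U_ = self.factorization_.U
        self.S_ = self.factorization_.S
        self.Vt_ = self.factorization_.Vt
        return self

    def transform(self, X) -> np.ndarray:
        W = self._weight(X)
        return project_lsi(W, self.factorization_)


def project_lsi(m_prev: np.ndarray, fact: LSIFactorization) -> np.ndarray:
    """Project a weighted matrix into another timepoint's LSI basis.

    ``U^p = M_prev V S^{-1}``: the least-squares solution of
    ``M_prev = U^p S Vt`` in the given factor basis. Projecting the
    matrix that produced ``fact`` returns ``fact.U``.
    """
    M = np.asarray(m_prev, dtype=float)
    if M.shape[1] != fact.Vt.shape[1]:
        raise ValidationError(
            "peak spaces differ: projection requires the shared union "
            f"peak list ({M.shape[1]} vs {fact.Vt.shape[1]})"
        )
    zero = np.flatnonzero(fact.S <= 0)
    if zero.size:
        raise ValidationError(
            f"zero singular value at component {int(zero[0]) + 1}"
        )
    return (M @ fact.Vt.T) / fact.S[None, :]


def _unit_rows(X: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return X / norms


def link_timepoints(
    U_t: np.ndarray, U_prev_proj: np.ndarray, k_link: int = 10
) -> pd.DataFrame:
    """kNN links from cells at stage t to cells at stage t-1.

    Rows of both factors are unit-scaled; Euclidean kNN in that space.
    Returns columns (source, target, distance) with source indexing t
    cells and target t-1 cells.
    """
    if U_t.shape[1] != U_prev_proj.shape[1]:
        raise ValidationError("component ranges of the two factors differ")
    n_prev = U_prev_proj.shape[0]
    if k_link >= n_prev:
        warnings.warn(
            f"k_link={k_link} >= {n_prev} cells at t-1; clipped",
            stacklevel=2,
        )
        k_link = n_prev if k_link > n_prev else k_link
    k_link = min(k_link, n_prev)
    A = _unit_rows(np.asarray(U_t, dtype=float))
    B = _unit_rows(np.asarray(U_prev_proj, dtype=float))
    nn = NearestNeighbors(n_neighbors=k_link).fit(B)
    dist, idx = nn.kneighbors(A)
    src = np.repeat(np.arange(A.shape[0]), k_link)
    return pd.DataFrame(
        {
            "source": src,
            "target": idx.ravel(),
            "distance": dist.ravel(),
        }
    )


def _intra_edges(U: np.ndarray, k: int) -> pd.DataFrame:
    n = U.shape[0]
    k = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(U)
    dist, idx = nn.kneighbors(U)
    rows = []
    for i in range(n):
        for d, j in zip(dist[i], idx[i]):
            if j == i:
                continue
            rows.append((i, int(j), float(d)))
    return pd.DataFrame(rows, columns=["source", "target", "distance"])


def build_temporal_graph(
    matrices: list[CellAccessibilityMatrix],
    k_intra: int = 20,
    k_link: int = 10,
    rank: int = 30,
    component_range: tuple[int, int] = (2, 30),
) -> nx.Graph:
    """Full cross-timepoint cell graph on a shared peak space.

    Nodes are ``(timepoint, cell_index)`` with barcode attributes; edge
    weights are 1/(1 + distance), typed ``intra`` or ``cross``.
    """
    if len(matrices) < 2:
        warnings.warn("single timepoint: intra edges only", stacklevel=2)
    n_peaks = {m.n_peaks for m in matrices}
    if len(n_peaks) != 1:
        raise ValidationError(
            "timepoints must share the union peak space before graph "
            "construction"
        )
    rank_eff = min(rank, *(min(m.n_cells, m.n_peaks) - 1 for m in matrices))
    lo = min(component_range[0], rank_eff)
    hi = min(component_range[1], rank_eff)

    weighted = []
    facts = []
    for m in matrices:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            W = tfidf(m)
        weighted.append(W)
        facts.append(
            lsi(
                W,
                rank=rank_eff,
                timepoint=m.timepoint,
                component_range=(lo, hi),
            )
        )

    G = nx.Graph()
    for m in matrices:
        for i, bc in enumerate(m.barcodes):
            G.add_node((m.timepoint, i), barcode=bc, timepoint=m.timepoint)

    for m, fact in zip(matrices, facts):
        edges = _intra_edges(fact.components(), k_intra)
        for s, t, d in edges.itertuples(index=False):
            G.add_edge(
                (m.timepoint, int(s)),
                (m.timepoint, int(t)),
                weight=1.0 / (1.0 + d),
                kind="intra",
            )

    for prev_i in range(len(matrices) - 1):
        m_prev, m_t = matrices[prev_i], matrices[prev_i + 1]
        fact_t = facts[prev_i + 1]
        U_prev_p = project_lsi(weighted[prev_i], fact_t)
        lo_, hi_ = fact_t.component_range
        links = link_timepoints(
            fact_t.components(), U_prev_p[:, lo_ - 1 : hi_], k_link
        )
        for s, t, d in links.itertuples(index=False):
            G.add_edge(
                (m_t.timepoint, int(s)),
                (m_prev.timepoint, int(t)),
                weight=1.0 / (1.0 + d),
                kind="cross",
            )
    return G


def write_graph(G: nx.Graph, outdir: str | Path, stem: str = "temporal_graph") -> None:
    """Edge-list CSV plus GraphML for external force-directed layout."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "source": f"{u[0]}:{u[1]}",
            "target": f"{v[0]}:{v[1]}",
            "weight": data["weight"],
            "type": data["kind"],
        }
        for u, v, data in G.edges(data=True)
    ]
    pd.DataFrame(rows).to_csv(outdir / f"{stem}.csv", index=False)
    H = nx.relabel_nodes(G, {n: f"{n[0]}:{n[1]}" for n in G.nodes})
    nx.write_graphml(H, outdir / f"{stem}.graphml")


def read_graph_edges(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
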