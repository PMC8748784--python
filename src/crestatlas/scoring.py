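"""Bias-corrected deviation z-scores for peak-set annotations and
cluster-enriched peak detection.

The deviation model follows the standard background-matched construction
for sparse accessibility data: for an annotation (peak set) S and cell i
with total count ``T_i``, the expected annotation count is
``E_i = T_i * (sum_{j in S} t_j / T)`` (``t_j`` peak totals, ``T`` grand
total), the raw deviation is ``Y_i = (X_i - E_i) / E_i``, and the z-score
standardizes ``Y_i`` against deviations of background peak sets matched on
GC content and mean accessibility:

    z_i = (Y_i - mean_b Y_i^b) / sd_b(Y_i^b)

Cells where the background standard deviation vanishes are flagged (NaN),
never silently zeroed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.neighbors import NearestNeighbors
from statsmodels.api import Logit
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .containers import (
    CellAccessibilityMatrix,
    ModuleScoreMatrix,
    PeakSetCollection,
    ValidationError,
)


def _cell_major(m) -> sp.csr_matrix:
    if isinstance(m, CellAccessibilityMatrix):
        return m.cell_major()
    if sp.issparse(m):
        return m.tocsr()
    return sp.csr_matrix(np.asarray(m))


def expected_counts(m, peak_set) -> np.ndarray:
    """Per-cell expected annotation counts under the uniform-share model.

    Conserves the annotation total exactly: ``sum_i E_i = sum_i X_i(S)``.
    """
    X = _cell_major(m)
    peak_set = np.asarray(peak_set, dtype=np.intp)
    if peak_set.size == 0:
        raise ValidationError("annotation peak set is empty")
    cell_totals = np.asarray(X.sum(axis=1)).ravel()
    peak_totals = np.asarray(X.sum(axis=0)).ravel()
    grand = cell_totals.sum()
    if grand <= 0:
        raise ValidationError("matrix has zero total count")
    share = peak_totals[peak_set].sum() / grand
    if share <= 0:
        raise ValidationError("annotation has zero total counts")
    return cell_totals * share


def raw_deviation(observed: np.ndarray, expected: np.ndarray) -> np.ndarray:
    """``(X - E) / E``; >= -1 by construction, 0 iff X == E."""
    expected = np.asarray(expected, dtype=float)
    if np.any(expected <= 0):
        raise ValidationError("expected counts must be positive")
    return (np.asarray(observed, dtype=float) - expected) / expected


def sample_background_sets(
    peak_meta: pd.DataFrame,
    peak_set,
    n_background: int,
    seed: int,
    k_neighbors: int = 100,
) -> np.ndarray:
    """Sample background peak sets matched on (GC, mean accessibility).

    For each member peak, candidates are its ``k_neighbors`` nearest peaks
    in the standardized covariate plane (the peak itself included);
    backgrounds are drawn with replacement. Returns an integer array of
    shape ``(n_background, len(peak_set))``.
    """
    if n_background < 2:
        raise ValidationError("n_background must be >= 2")
    peak_set = np.asarray(peak_set, dtype=np.intp)
    n_peaks = len(peak_meta)
    if n_peaks < peak_set.size:
        raise ValidationError(
            f"only {n_peaks} candidate peaks for a set of {peak_set.size}"
        )
    cov = peak_meta[["gc", "mean_accessibility"]].to_numpy(float)
    sd = cov.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (cov - cov.mean(axis=0)) / sd
    k = min(k_neighbors, n_peaks)
    nn = NearestNeighbors(n_neighbors=k).fit(Z)
    _, neighbors = nn.kneighbors(Z[peak_set])  # (set_size, k)
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, k, size=(n_background, peak_set.size))
    return neighbors[np.arange(peak_set.size)[None, :], picks]


class ChromVARDeviations(BaseEstimator, TransformerMixin):
    """Background-matched deviation z-scores, one annotation per column.

    sklearn-style transformer: ``X`` is a cells x peaks count matrix.
    ``fit`` derives peak covariates from the fit data (or an explicitly
    supplied GC vector) and samples the matched background sets;
    ``transform`` computes z-scores for the same or new cells on the same
    peak space.

    Parameters
    ----------
    peak_sets
        :class:`PeakSetCollection` or mapping name -> peak indices.
    n_background
        Number of matched background sets (default 50).
    k_neighbors
        Candidate pool size per member peak for covariate matching.
    random_state
        Seed for the background sampling.
    gc
        Optional per-peak GC fractions; defaults to 0.5 everywhere, which
        reduces matching to mean accessibility alone.
    """

    def __init__(
        self,
        peak_sets=None,
        n_background: int = 50,
        k_neighbors: int = 100,
        random_state: int = 0,
        gc=None,
    ):
        self.peak_sets = peak_sets
        self.n_background = n_background
        self.k_neighbors = k_neighbors
        self.random_state = random_state
        self.gc = gc

    def _collection(self) -> PeakSetCollection:
        if isinstance(self.peak_sets, PeakSetCollection):
            return self.peak_sets
        if isinstance(self.peak_sets, dict):
            return PeakSetCollection(sets=dict(self.peak_sets))
        raise ValidationError("peak_sets must be a PeakSetCollection or dict")

    def fit(self, X, y=None):
        X = _cell_major(X)
        coll = self._collection()
        coll.check_bounds(X.shape[1])
        gc = (
            np.full(X.shape[1], 0.5)
            if self.gc is None
            else np.asarray(self.gc, dtype=float)
        )
        meta = pd.DataFrame(
            {
                "gc": gc,
                "mean_accessibility": np.asarray(X.mean(axis=0)).ravel(),
            }
        )
        self.annotation_names_ = coll.names()
        self.n_peaks_ = X.shape[1]
        self.backgrounds_ = {}
        for offset, (name, idx) in enumerate(coll.sets.items()):
            self.backgrounds_[name] = sample_background_sets(
                meta,
                idx,
                self.n_background,
                seed=self.random_state + 7919 * offset,
                k_neighbors=self.k_neighbors,
            )
        self.peak_sets_ = coll
        return self

    def transform(self, X) -> pd.DataFrame:
        return self.score(X).scores

    def score(self, X, timepoint: str = "") -> ModuleScoreMatrix:
        """Full result: z-scores, raw deviations, expectations, flags."""
        if not hasattr(self, "backgrounds_"):
            raise ValidationError("ChromVARDeviations is not fitted")
        index = None
        if isinstance(X, CellAccessibilityMatrix):
            index = pd.Index(X.barcodes, name="barcode")
            timepoint = timepoint or X.timepoint
        Xc = _cell_major(X)
        if Xc.shape[1] != self.n_peaks_:
            raise ValidationError(
                f"matrix has {Xc.shape[1]} peaks; fitted on {self.n_peaks_}"
            )
        n_cells = Xc.shape[0]
        names = self.annotation_names_
        cell_totals = np.asarray(Xc.sum(axis=1)).ravel()
        peak_totals = np.asarray(Xc.sum(axis=0)).ravel()
        grand = cell_totals.sum()
        if grand <= 0:
            raise ValidationError("matrix has zero total count")

        # one sparse indicator with foreground + all background columns;
        # with-replacement background draws keep their multiplicity
        nb = self.n_background
        cols: list[np.ndarray] = []
        for name in names:
            cols.append(self.peak_sets_.sets[name])
            cols.extend(self.backgrounds_[name])
        rows_idx = np.concatenate(cols)
        cols_idx = np.concatenate(
            [np.full(c.size, j, dtype=np.intp) for j, c in enumerate(cols)]
        )
        indic = sp.coo_matrix(
            (np.ones(rows_idx.size), (rows_idx, cols_idx)),
            shape=(self.n_peaks_, len(cols)),
        ).tocsc()

        shares = np.asarray(peak_totals @ indic).ravel() / grand
        if np.any(shares[:: nb + 1] <= 0):
            raise ValidationError("an annotation has zero total counts")
        # counts from the simulator are near-dense at desk scale; dense
        # matmul is the fast path there
        if Xc.nnz > 0.25 * Xc.shape[0] * Xc.shape[1]:
            obs = Xc.toarray() @ indic.toarray()
        else:
            obs = np.asarray((Xc @ indic).todense())
        exp = cell_totals[:, None] * shares[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            Y = (obs - exp) / exp

        zs = np.empty((n_cells, len(names)))
        raw = np.empty((n_cells, len(names)))
        expect = np.empty((n_cells, len(names)))
        degenerate = []
        for a, name in enumerate(names):
            base = a * (nb + 1)
            fg = Y[:, base]
            bg = Y[:, base + 1 : base + 1 + nb]
            mu = bg.mean(axis=1)
            sd = bg.std(axis=1, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                z = (fg - mu) / sd
            z[sd == 0] = np.nan
            if np.all(sd == 0):
                degenerate.append(name)
            zs[:, a] = z
            raw[:, a] = fg
            expect[:, a] = exp[:, base]
        if degenerate and len(degenerate) == len(names):
            raise ValidationError(
                "all annotations degenerate (zero background variance)"
            )
        idx = index if index is not None else pd.RangeIndex(n_cells)
        return ModuleScoreMatrix(
            scores=pd.DataFrame(zs, index=idx, columns=names),
            raw_deviations=pd.DataFrame(raw, index=idx, columns=names),
            expectations=pd.DataFrame(expect, index=idx, columns=names),
            n_background=nb,
            seed=self.random_state,
            timepoint=timepoint,
        )


def deviation_zscore(
    m,
    peak_set,
    n_background: int = 50,
    seed: int = 0,
    gc=None,
) -> np.ndarray:
    """Per-cell z-score for a single annotation (thin wrapper)."""
    est = ChromVARDeviations(
        peak_sets={"set": np.asarray(peak_set)},
        n_background=n_background,
        random_state=seed,
        gc=gc,
    ).fit(m)
    return est.score(m).scores["set"].to_numpy()


def score_all(
    matrices: list[CellAccessibilityMatrix],
    peak_sets: PeakSetCollection,
    n_background: int = 50,
    seed: int = 0,
) -> list[ModuleScoreMatrix]:
    """Score every timepoint with the same (late-stage) peak sets.

    This is the retrograde step: peak sets derived at the latest stage are
    applied unchanged to every earlier matrix. Input matrices are never
    mutated.
    """
    out = []
    for m in matrices:
        peak_sets.check_bounds(m.n_peaks)
        gc = (
            m.peaks["gc"].to_numpy(float)
            if "gc" in m.peaks.columns
            else None
        )
        est = ChromVARDeviations(
            peak_sets=peak_sets,
            n_background=n_background,
            random_state=seed,
            gc=gc,
        ).fit(m)
        out.append(est.score(m))
    return out


# ---------------------------------------------------------------------------
# cluster-enriched peaks
# ---------------------------------------------------------------------------


@dataclass
class EnrichedPeakResult:
    table: pd.DataFrame  # cluster, peak, lfc, pval, padj, flagged
    selected: dict[str, np.ndarray]
    alpha: float


def enriched_peaks(
    m: CellAccessibilityMatrix,
    alpha: float = 0.001,
    cluster_col: str = "cluster",
) -> EnrichedPeakResult:
    """Likelihood-ratio screen for cluster-enriched peaks.

    Binarized accessibility of each peak is modelled by logistic
    regression on {in-cluster indicator, log fragments-in-peaks} versus
    the depth-only null; the LR statistic is referred to chi^2(1) and
    p-values are BH-adjusted across peaks within each cluster. Selected
    peaks have adjusted p < alpha and a positive in-cluster effect.
    Degenerate fits (separation) are flagged and excluded from selection.
    """
    if cluster_col not in m.cells.columns:
        raise ValidationError(f"cells lack a {cluster_col!r} column")
    clusters = m.cells[cluster_col].astype(str).to_numpy()
    uniq = pd.unique(clusters)
    if len(uniq) < 2:
        raise ValidationError("need at least 2 clusters")
    counts_small = pd.Series(clusters).value_counts()
    if (counts_small < 3).any():
        raise ValidationError("every cluster needs >= 3 cells")

    B = (m.cell_major() > 0).astype(np.float64)  # cells x peaks, 0/1
    Bd = np.asarray(B.todense())
    logdepth = np.log(
        np.maximum(m.cells["fragments_in_peaks"].to_numpy(float), 1.0)
    )
    base = np.column_stack([np.ones(m.n_cells), logdepth])

    rows = []
    selected: dict[str, np.ndarray] = {}
    for cl in uniq:
        member = (clusters == cl).astype(float)
        full_design = np.column_stack([base, member])
        pvals = np.full(m.n_peaks, np.nan)
        lfcs = np.full(m.n_peaks, np.nan)
        flagged = np.zeros(m.n_peaks, dtype=bool)
        for j in range(m.n_peaks):
            y = Bd[:, j]
            p_in = y[member == 1].mean()
            p_out = y[member == 0].mean()
            lfcs[j] = np.log((p_in + 1e-9) / (p_out + 1e-9))
            if y.min() == y.max():
                # accessible (or closed) in every cell: no information
                pvals[j] = 1.0
                lfcs[j] = 0.0
                continue
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    null = Logit(y, base).fit(disp=0, maxiter=50)
                    full = Logit(y, full_design).fit(disp=0, maxiter=50)
                lr = 2.0 * (full.llf - null.llf)
                if not np.isfinite(lr):
                    raise ValueError("non-finite LR")
                pvals[j] = stats.chi2.sf(max(lr, 0.0), df=1)
            except (PerfectSeparationError, ValueError, np.linalg.LinAlgError):
                flagged[j] = True
        ok = ~np.isnan(pvals)
        padj = np.full(m.n_peaks, np.nan)
        if ok.any():
            padj[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
        sel = np.flatnonzero(
            ok & ~flagged & (padj < alpha) & (lfcs > 0)
        )
        selected[str(cl)] = sel
        for j in range(m.n_peaks):
            rows.append(
                {
                    "cluster": str(cl),
                    "peak": j,
                    "lfc": lfcs[j],
                    "pval": pvals[j],
                    "padj": padj[j],
                    "flagged": bool(flagged[j]),
                }
            )
    return EnrichedPeakResult(
        table=pd.DataFrame(rows), selected=selected, alpha=alpha
    )
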