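"""Core in-memory containers shared across the pipeline.

The central object is :class:`CellAccessibilityMatrix`, a peak-by-cell
fragment-count matrix for one timepoint with per-peak and per-cell
metadata. Peaks follow the BED convention (0-based, half-open).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

PEAK_COLUMNS = ("chrom", "start", "end")


class ValidationError(ValueError):
    """Raised when an input container violates its invariants."""


@dataclass
class CellAccessibilityMatrix:
    """Sparse peak x cell fragment counts for one timepoint.

    Parameters
    ----------
    counts
        Non-negative integer sparse matrix of shape ``(n_peaks, n_cells)``.
    peaks
        DataFrame with at least ``chrom``, ``start``, ``end`` (0-based,
        half-open). Optional covariate columns: ``gc`` (fraction of G/C
        bases in the peak) and ``mean_accessibility``.
    cells
        DataFrame indexed by barcode. Optional columns:
        ``fragments_in_peaks``, ``frip`` (fraction of reads in peaks),
        ``cluster``, ``lineage``.
    timepoint
        Label of the developmental stage the matrix was collected at.
    """

    counts: sp.spmatrix
    peaks: pd.DataFrame
    cells: pd.DataFrame
    timepoint: str = ""

    def __post_init__(self) -> None:
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        self.counts = self.counts.tocsr()
        self.validate()
        if "fragments_in_peaks" not in self.cells.columns:
            self.cells = self.cells.copy()
            self.cells["fragments_in_peaks"] = np.asarray(
                self.counts.sum(axis=0)
            ).ravel()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        n_peaks, n_cells = self.counts.shape
        if n_cells == 0:
            raise ValidationError("no cells: matrix has zero columns")
        if n_peaks == 0:
            raise ValidationError("no peaks: matrix has zero rows")
        if len(self.peaks) != n_peaks:
            raise ValidationError(
                f"peak table has {len(self.peaks)} rows but matrix has "
                f"{n_peaks} peak rows"
            )
        if len(self.cells) != n_cells:
            raise ValidationError(
                f"cell table has {len(self.cells)} rows but matrix has "
                f"{n_cells} cell columns"
            )
        for col in PEAK_COLUMNS:
            if col not in self.peaks.columns:
                raise ValidationError(f"peak table missing column {col!r}")
        starts = self.peaks["start"].to_numpy()
        ends = self.peaks["end"].to_numpy()
        if np.any(starts >= ends):
            bad = int(np.argmax(starts >= ends))
            raise ValidationError(
                f"peak {bad} has start >= end "
                f"({starts[bad]} >= {ends[bad]}); BED intervals are "
                "half-open and must be non-empty"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("counts must be non-negative")
        if "frip" in self.cells.columns:
            frip = self.cells["frip"].to_numpy(float)
            if np.any((frip < 0) | (frip > 1)):
                raise ValidationError("frip values must lie in [0, 1]")

    # -- convenience -----------------------------------------------------
    @property
    def n_peaks(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def barcodes(self) -> list[str]:
        return list(self.cells.index)

    def cell_major(self) -> sp.csr_matrix:
        """Counts as a cells x peaks CSR matrix (sklearn orientation)."""
        return self.counts.T.tocsr()

    def peak_covariates(self) -> pd.DataFrame:
        """GC fraction and mean accessibility per peak.

        Mean accessibility is computed from the counts when the peak table
        does not already carry a ``mean_accessibility`` column.
        """
        cov = pd.DataFrame(index=self.peaks.index)
        if "gc" in self.peaks.columns:
            cov["gc"] = self.peaks["gc"].to_numpy(float)
        else:
            cov["gc"] = 0.5
        if "mean_accessibility" in self.peaks.columns:
            cov["mean_accessibility"] = self.peaks[
                "mean_accessibility"
            ].to_numpy(float)
        else:
            cov["mean_accessibility"] = np.asarray(
                self.counts.mean(axis=1)
            ).ravel()
        return cov

    def subset_cells(self, mask: np.ndarray) -> "CellAccessibilityMatrix":
        """Return a new matrix containing only the selected cells."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CellAccessibilityMatrix(
            counts=self.counts[:, idx].tocsr(),
            peaks=self.peaks,
            cells=self.cells.iloc[idx].copy(),
            timepoint=self.timepoint,
        )

    def binarized(self) -> sp.csr_matrix:
        out = self.counts.copy()
        out.data = np.ones_like(out.data)
        return out


@dataclass
class PeakSetCollection:
    """Named peak-index sets (tissue modules or motif annotations)."""

    sets: dict[str, np.ndarray]
    kind: str = "module"  # "module" | "motif"

    def __post_init__(self) -> None:
        if self.kind not in ("module", "motif"):
            raise ValidationError(f"unknown peak-set kind {self.kind!r}")
        clean: dict[str, np.ndarray] = {}
        for name, idx in self.sets.items():
            idx = np.asarray(idx, dtype=np.intp)
            if idx.size == 0:
                raise ValidationError(f"peak set {name!r} is empty")
            clean[name] = idx
        self.sets = clean

    def check_bounds(self, n_peaks: int) -> None:
        for name, idx in self.sets.items():
            if idx.min() < 0 or idx.max() >= n_peaks:
                raise ValidationError(
                    f"peak set {name!r} references peak indices outside "
                    f"[0, {n_peaks})"
                )

    def names(self) -> list[str]:
        return list(self.sets)

    def membership_matrix(self, n_peaks: int) -> sp.csc_matrix:
        """Peaks x annotations 0/1 membership matrix."""
        self.check_bounds(n_peaks)
        rows, cols = [], []
        for j, idx in enumerate(self.sets.values()):
            rows.append(idx)
            cols.append(np.full(idx.size, j, dtype=np.intp))
        return sp.csc_matrix(
            (
                np.ones(sum(r.size for r in rows)),
                (np.concatenate(rows), np.concatenate(cols)),
            ),
            shape=(n_peaks, len(self.sets)),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (name, int(i)) for name, idx in self.sets.items() for i in idx
        ]
        return pd.DataFrame(rows, columns=["annotation", "peak_index"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, kind: str = "module") -> "PeakSetCollection":
        sets = {
            str(name): grp["peak_index"].to_numpy(np.intp)
            for name, grp in df.groupby("annotation", sort=False)
        }
        return cls(sets=sets, kind=kind)


@dataclass
class ModuleScoreMatrix:
    """Bias-corrected deviation z-scores for one timepoint.

    ``scores``, ``raw_deviations`` and ``expectations`` are cells x
    annotations DataFrames sharing index and columns. Entries where the
    background standard deviation vanished are NaN in ``scores`` and True
    in ``undefined``.
    """

    scores: pd.DataFrame
    raw_deviations: pd.DataFrame
    expectations: pd.DataFrame
    n_background: int
    seed: int
    timepoint: str = ""
    undefined: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        shapes = {
            self.scores.shape,
            self.raw_deviations.shape,
            self.expectations.shape,
        }
        if len(shapes) != 1:
            raise ValidationError(
                "scores, raw_deviations and expectations must share shape"
            )
        if self.undefined is None:
            self.undefined = self.scores.isna()
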