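"""Reading/writing the 10x-style MTX/BED/TSV triplet, QC filtering, and
union peak merging."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .containers import CellAccessibilityMatrix, ValidationError

_CELL_META = "cell_meta.tsv"
_PEAK_META = "peak_meta.tsv"


def write_atlas(m: CellAccessibilityMatrix, outdir: str | Path) -> Path:
    """Write one timepoint as matrix.mtx / peaks.bed / barcodes.tsv.

    The MTX file stores integer counts 1-based on disk (MatrixMarket
    coordinate format); peaks.bed is BED3 (0-based half-open). Cell and
    peak metadata go to sidecar TSVs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sio.mmwrite(str(outdir / "matrix.mtx"), m.counts.astype(np.int64))
    m.peaks[["chrom", "start", "end"]].to_csv(
        outdir / "peaks.bed", sep="\t", header=False, index=False
    )
    pd.Series(m.barcodes).to_csv(
        outdir / "barcodes.tsv", sep="\t", header=False, index=False
    )
    m.cells.to_csv(outdir / _CELL_META, sep="\t")
    extra = m.peaks.drop(columns=list("chrom start end".split()))
    if not extra.empty:
        extra.to_csv(outdir / _PEAK_META, sep="\t", index=False)
    return outdir


def read_atlas(indir: str | Path, timepoint: str = "") -> CellAccessibilityMatrix:
    """Read a MTX/BED/TSV triplet written by :func:`write_atlas`.

    Raises :class:`ValidationError` naming the offending file when the
    triplet members disagree on dimensions.
    """
    indir = Path(indir)
    mtx_path = indir / "matrix.mtx"
    try:
        counts = sp.csr_matrix(sio.mmread(str(mtx_path)))
    except Exception as exc:  # malformed header or body
        raise ValidationError(f"malformed MatrixMarket file {mtx_path}: {exc}")
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise ValidationError(f"no cells: {mtx_path} is empty")
    peaks = pd.read_csv(
        indir / "peaks.bed",
        sep="\t",
        header=None,
        names=["chrom", "start", "end"],
    )
    barcodes = pd.read_csv(
        indir / "barcodes.tsv", sep="\t", header=None
    )[0].astype(str)
    if len(peaks) != counts.shape[0]:
        raise ValidationError(
            f"{indir / 'peaks.bed'} has {len(peaks)} intervals but "
            f"{mtx_path} has {counts.shape[0]} rows"
        )
    if len(barcodes) != counts.shape[1]:
        raise ValidationError(
            f"{indir / 'barcodes.tsv'} has {len(barcodes)} barcodes but "
            f"{mtx_path} has {counts.shape[1]} columns"
        )
    cells = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    meta_path = indir / _CELL_META
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        meta.index = meta.index.astype(str)
        cells = meta.loc[barcodes]
    peak_meta_path = indir / _PEAK_META
    if peak_meta_path.exists():
        extra = pd.read_csv(peak_meta_path, sep="\t")
        peaks = pd.concat(
            [peaks.reset_index(drop=True), extra.reset_index(drop=True)],
            axis=1,
        )
    return CellAccessibilityMatrix(
        counts=counts, peaks=peaks, cells=cells, timepoint=timepoint
    )


@dataclass
class QCReport:
    n_input: int
    n_removed_frip: int
    n_removed_fragments: int
    n_retained: int


def qc_filter_cells(
    m: CellAccessibilityMatrix,
    frip_min: float,
    frag_range: tuple[float, float],
) -> tuple[CellAccessibilityMatrix, QCReport]:
    """Remove low-quality cells.

    A cell is retained iff its fraction of reads in peaks is *strictly*
    greater than ``frip_min`` and its fragments-in-peaks count lies within
    the inclusive range ``frag_range``. Retained counts are untouched.
    """
    lo, hi = frag_range
    if not np.isfinite(frip_min) or not np.isfinite(lo):
        raise ValidationError("QC thresholds must be finite (hi may be inf)")
    if lo >= hi:
        raise ValidationError(f"fragment range ({lo}, {hi}) requires lo < hi")
    frags = m.cells["fragments_in_peaks"].to_numpy(float)
    if "frip" in m.cells.columns:
        frip = m.cells["frip"].to_numpy(float)
    else:
        frip = np.ones(m.n_cells)
    pass_frip = frip > frip_min
    pass_frag = (frags >= lo) & (frags <= hi)
    keep = pass_frip & pass_frag
    report = QCReport(
        n_input=m.n_cells,
        n_removed_frip=int((~pass_frip).sum()),
        n_removed_fragments=int((~pass_frag).sum()),
        n_retained=int(keep.sum()),
    )
    if report.n_retained == 0:
        raise ValidationError(
            "QC removed every cell "
            f"(input {report.n_input}, FRIP failures {report.n_removed_frip}, "
            f"fragment-range failures {report.n_removed_fragments}); "
            f"thresholds were frip>{frip_min}, fragments in [{lo}, {hi}]"
        )
    return m.subset_cells(keep), report


def _read_bed3(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValidationError(f"{path} is not BED3+: fewer than 3 columns")
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    if (df["start"] >= df["end"]).any():
        raise ValidationError(f"{path} contains an interval with start >= end")
    return df


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse intervals into the minimal disjoint covering set.

    Overlapping *or bookended* (half-open adjacent) intervals merge; the
    result is per-chromosome sorted.
    """
    out = []
    for chrom, grp in df.groupby("chrom", sort=True):
        ivals = grp.sort_values(["start", "end"])[["start", "end"]].to_numpy()
        cur_s, cur_e = int(ivals[0, 0]), int(ivals[0, 1])
        for s, e in ivals[1:]:
            if s <= cur_e:  # overlap or bookend under half-open coords
                cur_e = max(cur_e, int(e))
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = int(s), int(e)
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def merge_peak_files(bed_files: Sequence[str | Path] | Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Merge per-cluster peak files into a union peak profile.

    Accepts BED3+ file paths or already-loaded BED DataFrames. Warns when
    chromosome naming styles are mixed (e.g. ``chr1`` vs ``1``); such
    chromosomes are treated as distinct.
    """
    frames = []
    for item in bed_files:
        if isinstance(item, pd.DataFrame):
            frames.append(item[["chrom", "start", "end"]])
        else:
            frames.append(_read_bed3(item))
    if not frames:
        raise ValidationError("no peak files to merge")
    allp = pd.concat(frames, ignore_index=True)
    chroms = allp["chrom"].astype(str)
    prefixed = chroms.str.startswith("chr")
    if prefixed.any() and (~prefixed).any():
        warnings.warn(
            "mixed chromosome naming (with and without 'chr' prefix); "
            "styles are treated as distinct chromosomes",
            stacklevel=2,
        )
    return merge_intervals(allp)
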