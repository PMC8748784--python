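"""Synthetic multi-timepoint accessibility atlases with planted lineage
structure.

The generator emulates the study design the pipeline is built for: cells
sampled at several developmental stages, a rooted binary lineage tree over
terminal tissues, tissue-specific peak sets whose accessibility rises in
lineage cells only at/after a planted establishment stage, lognormal
per-cell depth, per-peak GC covariates, and motif-deviation / TF-activity
features correlated in planted lineage-priming pairs.

Sampling model
--------------
Counts for cell *i* and peak *j* are ``Poisson(depth_i * q_j * m_ij)``
where ``q_j`` is a base accessibility probability (normalized gamma
weights), ``depth_i ~ LogNormal(mu, sigma)``, and the multiplier ``m_ij``
is ``effect_size`` when peak *j* is specific to the cell's own tissue and
the tissue is established at that timepoint, ``1 + (effect_size - 1) *
family_effect`` when the peak belongs to an established sister tissue of
the same lineage family, and 1 otherwise. Progenitor cells before
establishment carry base accessibility everywhere: competency is encoded
purely as the peak-probability shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CellAccessibilityMatrix, PeakSetCollection, ValidationError
from .io import write_atlas

Tree = tuple  # nested tuples of tissue labels; leaves are strings


def _tree_leaves(tree) -> list[str]:
    if isinstance(tree, str):
        return [tree]
    out: list[str] = []
    for child in tree:
        out.extend(_tree_leaves(child))
    return out


def _balanced_tree(labels: list[str]):
    if len(labels) == 1:
        return labels[0]
    mid = (len(labels) + 1) // 2
    return (_balanced_tree(labels[:mid]), _balanced_tree(labels[mid:]))


@dataclass
class LineageSpec:
    """Parameters of the planted lineage and the sampling model.

    Defaults encode the study-scale conditions the downstream stages are
    validated on: 5 stages, 10 terminal tissues in families of two,
    2,000 cells per stage, 100 specific peaks per tissue over 2,000
    background peaks, a three-fold accessibility gain after establishment,
    and per-cell depth matching the fragment counts of typical snATAC
    nuclei (median ~8,000 fragments in peaks).
    """

    tissues: list[str] = field(
        default_factory=lambda: [f"tissue{i:02d}" for i in range(10)]
    )
    timepoints: list[str] = field(
        default_factory=lambda: [f"T{i}" for i in range(5)]
    )
    tree: Tree | None = None
    establishment_time: dict[str, int] | None = None
    family_size: int = 2
    cells_per_timepoint: int = 2000
    peaks_per_tissue: int = 100
    background_peaks: int = 2000
    effect_size: float = 3.0
    family_effect: float = 0.5
    depth_lognormal: tuple[float, float] = (9.0, 0.45)
    n_priming_pairs: int = 10
    n_decoy_motifs: int = 200
    priming_strength: float = 2.0
    tf_coupling: float = 0.8
    gc_confounded: bool = False
    binarize: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.tissues) < 2:
            raise ValidationError("need at least 2 tissues")
        if len(self.timepoints) < 2:
            raise ValidationError("need at least 2 timepoints")
        if self.peaks_per_tissue < 1 or self.background_peaks < 1:
            raise ValidationError("peak counts must be positive")
        if self.cells_per_timepoint < 1:
            raise ValidationError("cells_per_timepoint must be positive")
        if self.effect_size < 1:
            raise ValidationError("effect_size must be >= 1")
        if self.n_priming_pairs > len(self.tissues):
            raise ValidationError(
                "n_priming_pairs cannot exceed the number of tissues"
            )
        if self.tree is None:
            fams = self.families()
            self.tree = _balanced_tree(
                [_balanced_tree(f) for f in fams]  # type: ignore[arg-type]
            )
        if sorted(_tree_leaves(self.tree)) != sorted(self.tissues):
            raise ValidationError("tree leaves must equal the tissue list")
        if self.establishment_time is None:
            # spread establishment over the timepoints, round robin
            self.establishment_time = {
                t: i % len(self.timepoints)
                for i, t in enumerate(self.tissues)
            }
        for t, e in self.establishment_time.items():
            if not 0 <= e < len(self.timepoints):
                raise ValidationError(
                    f"establishment time {e} for {t!r} outside timepoint range"
                )

    def families(self) -> list[list[str]]:
        k = max(1, self.family_size)
        return [
            self.tissues[i : i + k] for i in range(0, len(self.tissues), k)
        ]

    def family_of(self) -> dict[str, int]:
        return {
            t: fi for fi, fam in enumerate(self.families()) for t in fam
        }

    @property
    def n_peaks(self) -> int:
        return self.background_peaks + self.peaks_per_tissue * len(self.tissues)


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted alongside the simulated atlas."""

    lineage: LineageSpec
    priming_pairs: list[tuple[str, str, str]]  # (motif, tf, tissue)
    cell_assignments: dict[str, pd.DataFrame]  # timepoint -> per-cell table

    def establishment(self) -> dict[str, int]:
        return dict(self.lineage.establishment_time)

    def family_labels(self) -> dict[str, int]:
        return self.lineage.family_of()


@dataclass
class SyntheticAtlas:
    """Everything :func:`simulate_atlas` produces."""

    matrices: list[CellAccessibilityMatrix]
    modules: PeakSetCollection
    motif_deviations: list[pd.DataFrame]  # per timepoint, cells x motifs
    tf_activity: list[pd.DataFrame]  # per timepoint, cells x TFs
    pairing_table: pd.DataFrame  # columns motif_id, tf_id
    truth: SyntheticTruth


def simulate_atlas(spec: LineageSpec) -> SyntheticAtlas:
    """Draw a full multi-timepoint atlas from the planted model.

    Fully reproducible from ``spec.seed``; with ``effect_size == 1`` no
    peak set distinguishes any tissue.
    """
    rng = np.random.default_rng(spec.seed)
    n_tis = len(spec.tissues)
    n_tp = len(spec.timepoints)
    n_peaks = spec.n_peaks

    # base accessibility probabilities (shared across timepoints)
    q = rng.gamma(2.0, 1.0, size=n_peaks)
    q /= q.sum()

    # tissue-specific peak sets: blocks after the background peaks
    modules = PeakSetCollection(
        sets={
            t: np.arange(
                spec.background_peaks + i * spec.peaks_per_tissue,
                spec.background_peaks + (i + 1) * spec.peaks_per_tissue,
            )
            for i, t in enumerate(spec.tissues)
        },
        kind="module",
    )

    # per-peak GC; optionally confounded with tissue peaks to stress-test
    # the background matching
    gc = rng.beta(5.0, 5.0, size=n_peaks)
    if spec.gc_confounded:
        for idx in modules.sets.values():
            gc[idx] = rng.beta(8.0, 3.0, size=idx.size)

    peaks = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(n_peaks) * 5000,
            "end": np.arange(n_peaks) * 5000 + 500,
            "gc": gc,
        }
    )

    fam_of = spec.family_of()
    families = spec.families()
    est = spec.establishment_time
    boost = 1.0 + (spec.effect_size - 1.0) * spec.family_effect

    # priming features
    planted_tissues = spec.tissues[: spec.n_priming_pairs]
    priming_pairs = [
        (f"motif_{t}", f"tf_{t}", t) for t in planted_tissues
    ]
    decoy_motifs = [f"motif_decoy{i:03d}" for i in range(spec.n_decoy_motifs)]
    decoy_tfs = [f"tf_decoy{i:03d}" for i in range(spec.n_decoy_motifs)]
    motif_ids = [p[0] for p in priming_pairs] + decoy_motifs
    tf_ids = [p[1] for p in priming_pairs] + decoy_tfs
    pairing = pd.DataFrame(
        {
            "motif_id": [p[0] for p in priming_pairs] + decoy_motifs,
            "tf_id": [p[1] for p in priming_pairs] + decoy_tfs,
        }
    )

    mu, sigma = spec.depth_lognormal
    matrices: list[CellAccessibilityMatrix] = []
    motif_frames: list[pd.DataFrame] = []
    tf_frames: list[pd.DataFrame] = []
    assignments: dict[str, pd.DataFrame] = {}

    for ti, tp in enumerate(spec.timepoints):
        n_cells = spec.cells_per_timepoint
        lineage = rng.integers(0, n_tis, size=n_cells)
        depth = rng.lognormal(mu, sigma, size=n_cells)

        # per-tissue multiplier rows (n_tis x n_peaks); a cell of tissue x
        # sees its own established peaks at effect_size and established
        # sister peaks at the family boost
        mult = np.ones((n_tis, n_peaks))
        if spec.effect_size > 1:
            for xi, x in enumerate(spec.tissues):
                for y in families[fam_of[x]]:
                    if est[y] <= ti:
                        factor = (
                            spec.effect_size if y == x else boost
                        )
                        mult[xi, modules.sets[y]] = factor

        counts = np.empty((n_cells, n_peaks), dtype=np.int64)
        for xi in range(n_tis):
            rows = np.flatnonzero(lineage == xi)
            if rows.size == 0:
                continue
            rate = depth[rows, None] * (q[None, :] * mult[xi])
            counts[rows] = rng.poisson(rate)
        if spec.binarize:
            counts = (counts > 0).astype(np.int64)

        frip = rng.beta(30.0, 18.0, size=n_cells)  # mean ~0.62
        barcodes = [f"{tp}_cell{i:05d}" for i in range(n_cells)]
        tissue_labels = np.array(spec.tissues)[lineage]
        established = np.array([est[t] <= ti for t in tissue_labels])
        state = np.where(
            established, tissue_labels, "progenitor:" + tissue_labels
        )
        cells = pd.DataFrame(
            {
                "fragments_in_peaks": counts.sum(axis=1),
                "frip": frip,
                "lineage": tissue_labels,
                "cluster": state,
            },
            index=pd.Index(barcodes, name="barcode"),
        )
        matrices.append(
            CellAccessibilityMatrix(
                counts=sp.csr_matrix(counts.T),
                peaks=peaks.copy(),
                cells=cells,
                timepoint=tp,
            )
        )
        assignments[tp] = cells[["lineage", "cluster"]].copy()

        # motif deviations: planted motifs are affine in lineage
        # membership; TF activities affine in the paired motif deviation
        motifs = rng.standard_normal((n_cells, len(motif_ids)))
        tfs = rng.standard_normal((n_cells, len(tf_ids)))
        for k, (_, _, x) in enumerate(priming_pairs):
            member = (tissue_labels == x).astype(float)
            motifs[:, k] += spec.priming_strength * member
            tfs[:, k] = (
                spec.tf_coupling * motifs[:, k]
                + rng.standard_normal(n_cells)
            )
        motif_frames.append(
            pd.DataFrame(motifs, index=barcodes, columns=motif_ids)
        )
        tf_frames.append(pd.DataFrame(tfs, index=barcodes, columns=tf_ids))

    truth = SyntheticTruth(
        lineage=spec,
        priming_pairs=priming_pairs,
        cell_assignments=assignments,
    )
    return SyntheticAtlas(
        matrices=matrices,
        modules=modules,
        motif_deviations=motif_frames,
        tf_activity=tf_frames,
        pairing_table=pairing,
        truth=truth,
    )


def truth_report(truth: SyntheticTruth) -> pd.DataFrame:
    """Tabular ground truth: one establishment row per tissue, one row per
    priming pair."""
    rows = []
    fam = truth.family_labels()
    for tissue, e in truth.lineage.establishment_time.items():
        rows.append(
            {
                "record": "establishment",
                "tissue": tissue,
                "timepoint": truth.lineage.timepoints[e],
                "family": fam[tissue],
                "motif": "",
                "tf": "",
            }
        )
    for motif, tf, tissue in truth.priming_pairs:
        rows.append(
            {
                "record": "priming_pair",
                "tissue": tissue,
                "timepoint": "",
                "family": fam[tissue],
                "motif": motif,
                "tf": tf,
            }
        )
    return pd.DataFrame(
        rows, columns=["record", "tissue", "timepoint", "family", "motif", "tf"]
    )


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    truth_report(truth).to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)


def write_synthetic_atlas(atlas: SyntheticAtlas, outdir: str | Path) -> Path:
    """Write every timepoint triplet plus annotations and truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for m in atlas.matrices:
        write_atlas(m, outdir / m.timepoint)
    atlas.modules.to_frame().to_csv(
        outdir / "modules.tsv", sep="\t", index=False
    )
    atlas.pairing_table.to_csv(outdir / "pairing.tsv", sep="\t", index=False)
    for m, dev, act in zip(
        atlas.matrices, atlas.motif_deviations, atlas.tf_activity
    ):
        dev.to_csv(outdir / m.timepoint / "motif_deviations.tsv", sep="\t")
        act.to_csv(outdir / m.timepoint / "tf_activity.tsv", sep="\t")
    write_truth(atlas.truth, outdir / "truth.tsv")
    return outdir
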