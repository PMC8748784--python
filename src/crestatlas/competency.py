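"""Skewness-based competency calling.

A tissue's module-score distribution at a timepoint is called *skewed*
(lineage-specific accessibility established) when its sample skewness
exceeds a hard cutoff; at the earliest stage, where overall skewness runs
lower, a relaxed cutoff is combined with a minimum on the maximum module
score to exclude modules that are uniformly near zero. A tissue's
establishment timepoint is the earliest stage called skewed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ValidationError

DIFFUSE = "diffuse"
SKEWED = "skewed"
NOT_ESTABLISHED = "not_established"


def skewness(x) -> float:
    """Adjusted Fisher-Pearson standardized third moment.

    ``G1 = g1 * sqrt(n(n-1)) / (n-2)`` with ``g1 = m3 / m2^(3/2)``.
    Returns NaN for constant input (undefined, flagged downstream).
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise ValidationError("skewness needs at least 3 finite values")
    if np.ptp(x) == 0:
        return math.nan
    return float(stats.skew(x, bias=False))


@dataclass
class CompetencyConfig:
    """Cutoffs of the skewness rule.

    ``skew_cutoff`` applies at every stage except the earliest, where the
    relaxed ``earliest_skew_cutoff`` is combined with the requirement
    ``max(score) > earliest_max_score``.
    """

    skew_cutoff: float = 1.0
    earliest_skew_cutoff: float = 0.4
    earliest_max_score: float = 15.0
    earliest_timepoint: str | None = None

    def __post_init__(self) -> None:
        for v in (self.skew_cutoff, self.earliest_skew_cutoff, self.earliest_max_score):
            if not np.isfinite(v):
                raise ValidationError("competency cutoffs must be finite")
        if self.earliest_skew_cutoff > self.skew_cutoff:
            raise ValidationError(
                "earliest_skew_cutoff must not exceed skew_cutoff"
            )


def classify(scores, timepoint: str, cfg: CompetencyConfig) -> str:
    """Call one (tissue, timepoint) diffuse or skewed.

    Both cutoffs are strict: skewness exactly at the cutoff stays diffuse.
    Undefined skewness (constant scores) is diffuse.
    """
    scores = np.asarray(scores, dtype=float)
    g = skewness(scores)
    if math.isnan(g):
        return DIFFUSE
    if cfg.earliest_timepoint is not None and timepoint == cfg.earliest_timepoint:
        return (
            SKEWED
            if g > cfg.earliest_skew_cutoff
            and np.nanmax(scores) > cfg.earliest_max_score
            else DIFFUSE
        )
    return SKEWED if g > cfg.skew_cutoff else DIFFUSE


@dataclass
class CompetencyReport:
    """Per-(tissue, timepoint) statuses plus per-tissue establishment."""

    table: pd.DataFrame  # tissue, timepoint, skewness, max_score, status
    timepoints: list[str]

    def establishment_table(self) -> pd.DataFrame:
        """Earliest skewed timepoint per tissue (first skewed wins, even
        if later stages revert to diffuse)."""
        order = {tp: i for i, tp in enumerate(self.timepoints)}
        rows = []
        for tissue, grp in self.table.groupby("tissue", sort=False):
            skewed = grp[grp["status"] == SKEWED]
            if skewed.empty:
                rows.append((tissue, NOT_ESTABLISHED, -1))
            else:
                first = min(skewed["timepoint"], key=order.get)
                rows.append((tissue, first, order[first]))
        return pd.DataFrame(
            rows, columns=["tissue", "establishment", "timepoint_index"]
        ).set_index("tissue")

    def status_of(self, tissue: str, timepoint: str) -> str:
        sel = self.table[
            (self.table["tissue"] == tissue)
            & (self.table["timepoint"] == timepoint)
        ]
        return sel["status"].iloc[0]


def competency_report(
    scores_by_timepoint: dict[str, pd.DataFrame],
    cfg: CompetencyConfig | None = None,
    timepoint_order: list[str] | None = None,
) -> CompetencyReport:
    """Evaluate every (tissue, timepoint) pair.

    ``scores_by_timepoint`` maps timepoint label to a cells x tissues
    module-score DataFrame (all cells of that stage). The earliest
    timepoint defaults to the first of ``timepoint_order``.
    """
    if timepoint_order is None:
        timepoint_order = list(scores_by_timepoint)
    cfg = cfg or CompetencyConfig()
    if cfg.earliest_timepoint is None:
        cfg = CompetencyConfig(
            skew_cutoff=cfg.skew_cutoff,
            earliest_skew_cutoff=cfg.earliest_skew_cutoff,
            earliest_max_score=cfg.earliest_max_score,
            earliest_timepoint=timepoint_order[0],
        )
    rows = []
    for tp in timepoint_order:
        scores = scores_by_timepoint[tp]
        for tissue in scores.columns:
            x = scores[tissue].to_numpy(float)
            x = x[np.isfinite(x)]
            g = skewness(x)
            rows.append(
                {
                    "tissue": tissue,
                    "timepoint": tp,
                    "skewness": g,
                    "max_score": float(np.max(x)),
                    "status": classify(x, tp, cfg),
                }
            )
    return CompetencyReport(
        table=pd.DataFrame(rows), timepoints=list(timepoint_order)
    )
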