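"""Lineage-priming factor discovery.

Each tissue module score is regressed (per-feature univariate OLS) on
every motif accessibility and every TF gene activity; slope p-values are
BH-adjusted within tissue, negative or non-significant coefficients are
clipped to zero, and a curated motif<->TF pairing table turns the clipped
coefficients into co-enrichment calls: a (tissue, motif, TF) triple is
flagged iff both members keep a positive coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .containers import ValidationError


def _ols_univariate(y: np.ndarray, X: np.ndarray):
    """Vectorized per-column simple linear regression of y on each column.

    Returns (slope, two-sided p, zero-variance mask).
    """
    n = y.shape[0]
    if n < 10:
        raise ValidationError("need at least 10 cells for the regression")
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    sxx = (Xc**2).sum(axis=0)
    zero_var = sxx == 0
    sxx_safe = np.where(zero_var, 1.0, sxx)
    sxy = Xc.T @ yc
    beta = sxy / sxx_safe
    syy = (yc**2).sum()
    rss = np.maximum(syy - beta * sxy, 0.0)
    dof = n - 2
    se = np.sqrt(rss / dof / sxx_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    pval = 2.0 * stats.t.sf(np.abs(tstat), df=dof)
    pval[~np.isfinite(tstat)] = 0.0  # perfect fit: rss == 0
    beta[zero_var] = np.nan
    pval[zero_var] = np.nan
    return beta, pval, zero_var


class PrimingRegressor(BaseEstimator):
    """Per-feature OLS of a module score on motif/TF features.

    sklearn-style: ``fit(X, y)`` with ``X`` a cells x features matrix and
    ``y`` the per-cell module score. Fitted attributes: ``coef_``,
    ``pvalues_``, ``padj_``, ``clipped_coef_``, ``excluded_`` (zero
    variance features).
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y.shape[0]:
            raise ValidationError("X and y must share the cell axis")
        beta, pval, zero_var = _ols_univariate(y, X)
        padj = np.full_like(pval, np.nan)
        ok = ~np.isnan(pval)
        if ok.any():
            padj[ok] = multipletests(pval[ok], method="fdr_bh")[1]
        self.coef_ = beta
        self.pvalues_ = pval
        self.padj_ = padj
        self.excluded_ = zero_var
        self.clipped_coef_ = clip_coefficients(beta, padj, self.alpha)
        return self


def regress_features(
    module_score: pd.Series | np.ndarray,
    features: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Raw per-feature regression results for one tissue module."""
    reg = PrimingRegressor(alpha=alpha).fit(
        features.to_numpy(float), np.asarray(module_score, float)
    )
    return pd.DataFrame(
        {
            "feature": features.columns,
            "coef": reg.coef_,
            "pval": reg.pvalues_,
            "padj": reg.padj_,
            "clipped_coef": reg.clipped_coef_,
            "excluded": reg.excluded_,
        }
    )


def clip_coefficients(coef, padj, alpha: float = 0.05) -> np.ndarray:
    """Zero out negative or non-significant coefficients (idempotent)."""
    coef = np.asarray(coef, dtype=float).copy()
    padj = np.asarray(padj, dtype=float)
    kill = np.isnan(coef) | np.isnan(padj) | (coef < 0) | (padj > alpha)
    coef[kill] = 0.0
    return coef


def clip_and_filter(raw: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    out = raw.copy()
    out["clipped_coef"] = clip_coefficients(
        out["coef"].to_numpy(), out["padj"].to_numpy(), alpha
    )
    return out


def pair_motif_tf(
    results_by_tissue: dict[str, pd.DataFrame],
    pairing: pd.DataFrame,
) -> pd.DataFrame:
    """Co-enrichment calls per (tissue, motif, TF).

    ``results_by_tissue`` maps tissue -> regression table (with
    ``clipped_coef``) over the pooled motif+TF feature space. A pair is
    flagged iff both clipped coefficients are > 0. Pairs whose motif or
    TF is missing from the results are skipped with a warning.
    """
    import warnings

    rows = []
    for tissue, res in results_by_tissue.items():
        coefs = res.set_index("feature")["clipped_coef"]
        for motif, tf in pairing[["motif_id", "tf_id"]].itertuples(index=False):
            if motif not in coefs.index or tf not in coefs.index:
                warnings.warn(
                    f"pair ({motif}, {tf}) missing from regression results; "
                    "skipped",
                    stacklevel=2,
                )
                continue
            cm, ct = float(coefs[motif]), float(coefs[tf])
            rows.append(
                {
                    "tissue": tissue,
                    "motif_id": motif,
                    "tf_id": tf,
                    "motif_coef": cm,
                    "tf_coef": ct,
                    "co_enriched": cm > 0 and ct > 0,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "tissue", "motif_id", "tf_id", "motif_coef", "tf_coef",
            "co_enriched",
        ],
    )


def find_priming_pairs(
    module_scores: pd.DataFrame,
    motif_features: pd.DataFrame,
    tf_features: pd.DataFrame,
    pairing: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """End-to-end priming screen over all tissues at one stage.

    Motif and TF features are pooled per tissue for the BH adjustment.
    """
    features = pd.concat([motif_features, tf_features], axis=1)
    results = {
        tissue: regress_features(module_scores[tissue], features, alpha)
        for tissue in module_scores.columns
    }
    return pair_motif_tf(results, pairing)
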