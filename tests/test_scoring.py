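"""Deviation z-scores: expectation model, background matching, null
calibration, planted-signal detection, and the enriched-peak screen."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crestatlas.containers import (
    CellAccessibilityMatrix,
    PeakSetCollection,
    ValidationError,
)
from crestatlas.scoring import (
    ChromVARDeviations,
    deviation_zscore,
    enriched_peaks,
    expected_counts,
    raw_deviation,
    sample_background_sets,
    score_all,
)
from crestatlas.simulate import simulate_atlas

from conftest import small_spec


# ------------------------------------------------------------- expectations
def test_full_annotation_expectation_equals_cell_totals(small_atlas):
    m = small_atlas.matrices[0]
    E = expected_counts(m, np.arange(m.n_peaks))
    totals = np.asarray(m.counts.sum(axis=0)).ravel()
    np.testing.assert_allclose(E, totals, rtol=1e-12)
    X = totals  # full set: observed == totals
    np.testing.assert_allclose(raw_deviation(X, E), 0.0, atol=1e-12)


def test_two_cell_two_peak_toy_deviations():
    """Counts [[2,0],[0,2]], set={peak0}: T=4, t0=2, E=(1,1), X=(2,0),
    raw deviations (+1,-1) by hand arithmetic."""
    counts = np.array([[2, 0], [0, 2]])  # peaks x cells
    E = expected_counts(counts.T, [0])
    np.testing.assert_allclose(E, [1.0, 1.0])
    X = counts[0, :]
    np.testing.assert_allclose(raw_deviation(X, E), [1.0, -1.0])


def test_uniform_matrix_has_zero_deviation():
    counts = np.full((30, 8), 3)  # cells x peaks
    for set_ in ([0], [1, 2], list(range(8))):
        E = expected_counts(counts, set_)
        X = counts[:, set_].sum(axis=1)
        np.testing.assert_allclose(raw_deviation(X, E), 0.0, atol=1e-12)


def test_expectation_conserves_annotation_totals_exactly(small_atlas):
    m = small_atlas.matrices[1]
    X = m.cell_major()
    for name, idx in small_atlas.modules.sets.items():
        E = expected_counts(m, idx)
        assert E.sum() == pytest.approx(X[:, idx].sum(), rel=1e-12)


def test_zero_count_annotation_rejected():
    counts = np.zeros((5, 4))
    counts[:, :2] = 1
    with pytest.raises(ValidationError):
        expected_counts(counts, [3])


def test_raw_deviation_simple_cases():
    E = np.array([2.0, 5.0])
    np.testing.assert_allclose(raw_deviation(E, E), 0.0)
    np.testing.assert_allclose(raw_deviation(2 * E, E), 1.0)
    assert (raw_deviation(np.zeros(2), E) == -1).all()


# --------------------------------------------------------------- backgrounds
def test_background_sampling_uniform_when_covariates_identical():
    """With identical covariates and a candidate pool covering all peaks,
    matched sampling reduces to uniform sampling (chi-square over 1e4
    draws)."""
    n_peaks = 80
    meta = pd.DataFrame(
        {"gc": np.full(n_peaks, 0.5), "mean_accessibility": np.ones(n_peaks)}
    )
    sets = sample_background_sets(meta, [0, 1, 2, 3], 2500, seed=0, k_neighbors=100)
    assert sets.shape == (2500, 4)
    counts = np.bincount(sets.ravel(), minlength=n_peaks)
    chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
    # df = 79; 99.9th percentile ~ 124
    assert chi2 < stats.chi2.ppf(0.999, df=n_peaks - 1)


def test_background_minimal_and_full_set_cases():
    meta = pd.DataFrame(
        {"gc": np.linspace(0, 1, 20), "mean_accessibility": np.ones(20)}
    )
    two = sample_background_sets(meta, np.arange(5), 2, seed=1)
    assert two.shape == (2, 5)
    full = sample_background_sets(meta, np.arange(20), 3, seed=1)
    assert full.shape == (3, 20)
    assert full.max() < 20 and full.min() >= 0
    with pytest.raises(ValidationError):
        sample_background_sets(meta, np.arange(25), 5, seed=0)
    with pytest.raises(ValidationError):
        sample_background_sets(meta, [0], 1, seed=0)


def test_background_sampling_reproducible():
    meta = pd.DataFrame(
        {"gc": np.linspace(0, 1, 50), "mean_accessibility": np.ones(50)}
    )
    a = sample_background_sets(meta, [1, 5, 7], 10, seed=3)
    b = sample_background_sets(meta, [1, 5, 7], 10, seed=3)
    np.testing.assert_array_equal(a, b)


# ----------------------------------------------------------------- z-scores
def test_null_zscores_centered(small_atlas):
    """A uniformly random annotation on homogeneous data has mean z ~ 0."""
    atlas = simulate_atlas(
        small_spec(effect_size=1.0, cells_per_timepoint=500, seed=6)
    )
    m = atlas.matrices[0]
    rng = np.random.default_rng(0)
    set_ = rng.choice(m.n_peaks, 60, replace=False)
    z = deviation_zscore(m, set_, n_background=50, seed=0,
                         gc=m.peaks["gc"].to_numpy())
    assert abs(np.nanmean(z)) < 0.2


def test_planted_tissue_scores_higher_on_own_module(small_atlas):
    m = small_atlas.matrices[-1]  # all tissues established by T2
    z = deviation_zscore(
        m, small_atlas.modules.sets["tissue02"], n_background=50, seed=0,
        gc=m.peaks["gc"].to_numpy(),
    )
    lineage = m.cells["lineage"].to_numpy()
    stat = stats.mannwhitneyu(
        z[lineage == "tissue02"], z[lineage != "tissue02"],
        alternative="greater",
    )
    assert stat.pvalue < 1e-10


def test_zero_background_variance_flagged():
    counts = np.full((4, 10), 2.0)  # cells x peaks, fully uniform
    est = ChromVARDeviations(
        peak_sets={"s": [0, 1]}, n_background=5, random_state=0
    ).fit(counts)
    with pytest.raises(ValidationError, match="degenerate"):
        est.score(counts)


def test_score_all_shapes_and_purity(small_atlas):
    mats = small_atlas.matrices
    before = [m.counts.copy() for m in mats]
    scored = score_all(mats, small_atlas.modules, n_background=20, seed=0)
    assert len(scored) == len(mats)
    for s, m in zip(scored, mats):
        assert s.scores.shape == (m.n_cells, len(small_atlas.modules.sets))
        assert list(s.scores.columns) == small_atlas.modules.names()
    for b, m in zip(before, mats):  # retrograde scoring never mutates
        assert (b != m.counts).nnz == 0


def test_score_all_matches_single_annotation_path(small_atlas):
    m = small_atlas.matrices[0]
    coll = PeakSetCollection(
        sets={"tissue00": small_atlas.modules.sets["tissue00"]}
    )
    scored = score_all([m], coll, n_background=20, seed=0)[0]
    direct = deviation_zscore(
        m, coll.sets["tissue00"], n_background=20, seed=0,
        gc=m.peaks["gc"].to_numpy(),
    )
    np.testing.assert_allclose(
        scored.scores["tissue00"].to_numpy(), direct
    )


def test_out_of_range_annotation_rejected(small_atlas):
    bad = PeakSetCollection(sets={"bad": [10**6]})
    with pytest.raises(ValidationError):
        score_all(small_atlas.matrices[:1], bad)


# ------------------------------------------------------------ enriched peaks
def _two_cluster_matrix(p_in, p_out, n_per=120, n_peaks=30, seed=0):
    rng = np.random.default_rng(seed)
    n = 2 * n_per
    probs = np.full((n, n_peaks), 0.3)
    probs[:n_per, 0] = p_in  # peak 0 enriched in cluster A
    probs[n_per:, 0] = p_out
    counts = rng.binomial(1, probs) * rng.poisson(2, size=(n, n_peaks))
    counts[:, 1] = 1  # peak 1: accessible everywhere (no information)
    cells = pd.DataFrame(
        {
            "cluster": ["A"] * n_per + ["B"] * n_per,
            "frip": 0.6,
            "fragments_in_peaks": counts.sum(axis=1) + 1,
        },
        index=pd.Index([f"c{i}" for i in range(n)], name="barcode"),
    )
    peaks = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(n_peaks) * 1000,
            "end": np.arange(n_peaks) * 1000 + 500,
        }
    )
    return CellAccessibilityMatrix(
        counts=counts.T, peaks=peaks, cells=cells, timepoint="T0"
    )


def test_enriched_peak_detected_and_uninformative_ignored():
    m = _two_cluster_matrix(p_in=0.9, p_out=0.05, n_per=200)
    res = enriched_peaks(m, alpha=0.001)
    assert 0 in res.selected["A"]
    assert 1 not in res.selected["A"] and 1 not in res.selected["B"]
    row = res.table[(res.table.cluster == "A") & (res.table.peak == 1)]
    assert row["pval"].iloc[0] > 0.9  # LR ~ 0 for the everywhere-open peak


def test_alpha_zero_selects_nothing():
    m = _two_cluster_matrix(p_in=0.9, p_out=0.05)
    res = enriched_peaks(m, alpha=0.0)
    assert all(len(v) == 0 for v in res.selected.values())


def test_enriched_agrees_with_fisher_screen_on_balanced_toy():
    """Top peaks by LR p-value match a 2x2 chi-square screen's ranking on
    depth-balanced data."""
    rng = np.random.default_rng(1)
    m = _two_cluster_matrix(p_in=0.8, p_out=0.2, n_per=150, n_peaks=20, seed=1)
    res = enriched_peaks(m, alpha=0.001)
    tab = res.table[res.table.cluster == "A"].set_index("peak")
    B = np.asarray((m.cell_major() > 0).todense())
    member = m.cells["cluster"].to_numpy() == "A"
    chi_p = []
    for j in range(20):
        table = pd.crosstab(member, B[:, j] > 0)
        if table.shape != (2, 2):
            chi_p.append(1.0)
            continue
        chi_p.append(stats.chi2_contingency(table)[1])
    lr_rank = tab["pval"].sort_values().index[:3]
    chi_rank = np.argsort(chi_p)[:3]
    assert set(lr_rank) == set(chi_rank)


def test_enriched_requires_clusters(small_atlas):
    m = small_atlas.matrices[0].subset_cells(np.arange(10))
    m.cells["cluster"] = "same"
    with pytest.raises(ValidationError):
        enriched_peaks(m)
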