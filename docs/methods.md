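# Methods

This note documents the models, estimators, numerical choices and known
limitations of `crestatlas`. It describes what the code computes; every
empirical statement here is recomputed by the test suite or by
`scripts/acceptance.py`.

## Synthetic atlas model

The generator (`crestatlas.simulate`) emulates a multi-stage snATAC-seq
study of a diversifying progenitor population. Its defaults are the
conditions the downstream stages are validated under:

| parameter | default | meaning |
|---|---|---|
| `timepoints` | 5 stages | ordered developmental stages |
| `tissues` | 10 | terminal fates, grouped in families of `family_size=2` on a balanced binary lineage tree |
| `cells_per_timepoint` | 2000 | cells retained per stage |
| `peaks_per_tissue` | 100 | tissue-specific peaks |
| `background_peaks` | 2000 | non-specific peaks |
| `effect_size` | 3 | fold-increase of accessibility probability in established lineage cells |
| `family_effect` | 0.5 | fraction of the effect shared by established sister tissues |
| `depth_lognormal` | (9.0, 0.45) | per-cell fragments-in-peaks ~ LogNormal; median ≈ 8100, matching the fragment depth of typical snATAC nuclei and lying inside the QC band 1000–20000 |
| `establishment_time` | round-robin | stage at which each tissue's peaks first open |

Counts are `Poisson(depth_i · q_j · m_ij)` with base probabilities `q_j`
(normalized Gamma(2,1) weights shared across stages) and multiplier
`m_ij ∈ {effect, 1+(effect−1)·family_effect, 1}` depending on lineage
membership and establishment. Progenitor cells before establishment
carry base accessibility everywhere: competency is encoded purely as the
peak-probability shift, mirroring the operational definition of
competency as chromatin accessibility. GC covariates are Beta(5,5),
independent of lineage by default; `gc_confounded=True` ties GC to
tissue peaks to stress-test background matching. Priming features are
generated directly: planted motif deviations are affine in lineage
membership (`priming_strength=2` over N(0,1) noise), paired TF
activities are affine in the motif (`tf_coupling=0.8`) plus independent
noise, and decoys are pure noise.

What the generator does **not** emulate: fragment-level data, doublets,
batch effects, peak-calling noise, non-stationary base accessibility
across stages, and the extreme peak-space sparsity of genome-wide data
(3000 peaks at realistic depth gives a much denser matrix than 400k
peaks would). Passing tests therefore demonstrate correctness of the
statistical machinery under the stated model, not robustness to every
artifact of real libraries.

## QC and peak handling

FRIP filtering is strict (`frip > frip_min`) following the ">" phrasing
of the thresholds it reproduces; the fragments-in-peaks range is treated
as inclusive (the source convention is unstated; documented here).
Union peak merging collapses overlapping *and bookended* intervals
(half-open BED coordinates), is idempotent and order-invariant, and is
oracle-tested against a per-base boolean mask. Mixed chromosome naming
triggers a warning and the styles are kept distinct.

## Deviation z-scores

Expectations use the uniform-share model `E_i = T_i (Σ_{j∈S} t_j / T)`,
which conserves the annotation total exactly. Backgrounds match each
member peak on standardized (GC, mean accessibility) via k-nearest
neighbors (k = 100 candidates, sampling with replacement; the candidate
pool includes the member itself). `n_background = 50` follows the
convention of the deviation-score method this reimplements. Cells whose
background deviations have zero variance get NaN, never silent zeros;
an all-degenerate annotation set raises. Under a homogeneous atlas with
random annotations the z-scores are calibrated (|mean| < 0.2, variance
≈ 1, consistent with a t-statistic on 49 background degrees of freedom).
Scores are computed per timepoint with that timepoint's own totals and
covariates; whether a joint fit across concatenated stages would be
preferable is an open modelling question — per-stage was chosen because
each stage is an independently processed library.

## Enriched peaks

Binarized accessibility is modelled by logistic regression on
{in-cluster indicator, log fragments-in-peaks} against the depth-only
null; the LR statistic is referred to χ²(1), BH-adjusted across peaks
within cluster (default α = 0.001), and selection requires a positive
in-cluster effect. Separation and failed fits are flagged and excluded.
Counts are binarized here but kept raw for deviations, matching the
conventions of the respective upstream tools. The per-peak statsmodels
fits are exact but not fast; the pipeline's retrograde scoring consumes
provided peak sets, with enriched-peak derivation an optional step.

## Competency

Skewness is the adjusted Fisher–Pearson estimator
`G1 = g1·√(n(n−1))/(n−2)` (scipy `skew(bias=False)`), the default of
common statistics toolkits; it is affine-invariant and antisymmetric
under negation. Cutoffs: skewed iff `G1 > 1` (strict) at all stages
except the earliest, where `G1 > 0.4` *and* `max score > 15`. The
establishment stage is the first skewed stage; later diffuse calls do
not veto it (first appearance is what the trajectory summary reports).
Skewness is computed over all cells at a stage.

## Constellation distance

`d_(A,B),t` is the Euclidean distance between the two tissues' per-cell
score vectors, so stages with different cell counts contribute on
different scales; the default follows the construction literally, and
`rms_normalize=True` divides by √n_cells as an opt-in comparability
fix. Dendrograms use average linkage on Euclidean distances (the
linkage behind "tissue score dendrogram" is not pinned down anywhere;
it is configurable and recorded). RF distances count non-trivial
bipartitions, topology only, satisfying `0 ≤ RF ≤ 2(n−3)`.
`D = D_tissue + a·D_timepoint` with a = 12 is symmetric with zero
diagonal and a timepoint term constant per stage pair; it is **not** a
metric (the triangle inequality is not asserted). Diffuse nodes are
retained and flagged rather than dropped. Embedding uses UMAP on the
precomputed matrix (n_neighbors = 15 clipped to n−1, min_dist = 0.1,
fixed seed); a single node maps to the origin. Groups come from an
average-linkage cut of D; planted lineage families are evaluated on
final-stage nodes, where every tissue is established and the family
signal fully exists.

## Priming regression

Per-feature univariate OLS was chosen over a joint fit: with hundreds
of motif/TF features and embryo-scale cell counts a joint design is
rank-deficient; slopes, two-sided t p-values and BH adjustment are
computed vectorized per tissue over the pooled motif+TF feature space.
Coefficients with adjusted p > 0.05 or negative sign are set to 0
(idempotent clipping), and a pair is co-enriched iff both members stay
positive. Regression cells default to the stage where the tissue's
competency was first called skewed. Recovery statistics are counted
over distinct (motif, TF) pairs: a planted pair recovered for its
planted tissue is a hit; a flagged pair absent from the planted list is
false. Sibling-tissue co-enrichment of a planted pair — a real
consequence of the shared family signal — is thereby not miscounted as
a false discovery.

## LSI projection and temporal graph

TF-IDF is `log(1 + tf·idf·10⁴)` with `tf = count/cell total` and
`idf = n_cells / n_cells containing the peak`, applied independently per
stage. Peaks observed in no cell keep a zero column (with a warning)
instead of being dropped, because the backward projection requires all
stages to share one union peak space. The truncated SVD uses a
deterministic sign convention (largest-|·| entry of each right singular
vector positive); components 2–30 are used downstream, dropping the
depth-dominated first component. The backward projection
`U^p_{t−1} = M_{t−1} V_t Σ_t^{−1}` is the least-squares solution of
`M_{t−1} = U^p Σ_t V_tᵀ` and reproduces `U` exactly on self-projection;
zero singular values raise with the offending component named. Cross
links concatenate `U_t` and `U^p_{t−1}`, unit-scale rows, and take
Euclidean kNN (k_link per t-cell); intra-stage edges are kNN in each
stage's own components (k_intra = 20). Edge weights are `1/(1+d)` — the
weighting is not specified by the construction this follows and is
configurable in spirit (documented here); only the specified projection
and default neighbor finding are implemented, with no extra
edge-filtering heuristics. The graph is exported (edge-list CSV,
GraphML) for external force-directed layout rather than laid out here.

## Problem sizes and determinism

Validation runs use 5 stages × 2000 cells × 3000 peaks atlases (seeds
0–4) for recovery statistics, 500-cell homogeneous atlases with 100
random annotations for calibration, 200×500 matrices for the projection
oracles, and the exhaustive 105-topology set for RF — sizes chosen so
the whole suite re-runs in a couple of minutes on one CPU while keeping
every estimate's Monte-Carlo error well inside its tolerance. All
randomness flows through `numpy.random.default_rng` seeds carried in
specs, estimators and the CLI; identical seeds give bit-identical
atlases and checksum-identical pipeline runs.

## Known limitations

- The deviation model assumes counts scale with per-cell depth; strong
  copy-number or batch structure would violate the expectation model.
- The constellation distance mixes units (score-space Euclidean vs
  dendrogram-topology counts); the a = 12 weight is a convention of the
  construction, not estimated from data.
- Establishment calling is threshold-based; no uncertainty is attached
  to the recovered stage.
- The temporal graph links adjacent stages only and assumes the union
  peak space is shared; it does not correct for stage-specific batch
  effects.
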