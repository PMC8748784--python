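# crestatlas

Retrograde lineage-competency mapping and temporal graph construction for
multi-timepoint single-cell chromatin accessibility (snATAC-seq) atlases.

## The problem

During vertebrate development, progenitor populations progressively open
chromatin at the enhancers of the cell types they will later produce.
Given snATAC-seq profiles collected at several developmental stages —
for example cranial neural crest derivatives sampled across the zebrafish
lifetime — one can ask *when* the accessibility signature of each mature
tissue first appears, and which transcription factors prime each lineage.
`crestatlas` implements that retrograde analysis as a tested, reusable
pipeline, together with a synthetic-atlas generator with planted ground
truth so every stage is verifiable without large downloads.

## What it computes

1. **Module scores.** For a late-stage cluster-specific peak set *S* the
   per-cell deviation z-score is the background-matched statistic

       E_i = T_i · (Σ_{j∈S} t_j / T),   Y_i = (X_i − E_i)/E_i,
       z_i = (Y_i − mean_b Y_i^b) / sd_b(Y_i^b)

   with backgrounds sampled from peaks matched on GC content and mean
   accessibility. Peak sets are applied *retrogradely*: sets defined at
   the latest stage score every earlier stage.
2. **Competency calls.** A (tissue, timepoint) is *skewed* (competency
   established) when the sample skewness G1 of its module-score
   distribution exceeds 1; at the earliest stage the cutoff relaxes to
   0.4 combined with max score > 15. A tissue's establishment stage is
   its first skewed timepoint.
3. **Constellation distance.** Nodes (A, t₁), (B, t₂) are embedded by

       D = D_tissue + a · D_timepoint,
       D_tissue = [d_(A,B),t₁ + d_(A,B),t₂] / 2,
       D_timepoint = RF(t₁, t₂),

   where d is the Euclidean distance between per-cell score vectors and
   RF the Robinson–Foulds distance between the stages' tissue-score
   dendrograms (weight a = 12). The matrix is embedded in 2D by UMAP
   (`metric="precomputed"`) and cut hierarchically into lineage groups.
4. **Priming regression.** Each tissue module score is regressed
   (univariate OLS, BH-adjusted within tissue, adjusted p ≤ 0.05,
   negative coefficients clipped to 0) on all motif accessibilities and
   TF gene activities; a curated motif↔TF pairing table yields
   co-enrichment calls.
5. **Temporal graph.** Per-stage LSI (TF-IDF + truncated SVD, components
   2–30), backward projection U^p_{t−1} = M_{t−1} V_t Σ_t^{−1}, and kNN
   linking of unit-scaled factors connect cells across adjacent stages
   into one graph (exported as edge list + GraphML for force-directed
   layout).

## Worked example

```python
from crestatlas import (LineageSpec, simulate_atlas, score_all,
                        competency_report)

spec = LineageSpec(seed=0)              # 5 stages, 10 tissues, 2000 cells/stage
atlas = simulate_atlas(spec)
scored = score_all(atlas.matrices, atlas.modules, n_background=50, seed=0)
scores = {s.timepoint: s.scores for s in scored}
report = competency_report(scores, timepoint_order=spec.timepoints)
print(report.establishment_table().to_string())
```

prints

```
         establishment  timepoint_index
tissue
tissue00            T0                0
tissue01            T1                1
tissue02            T2                2
tissue03            T3                3
tissue04            T4                4
tissue05            T0                0
tissue06            T1                1
tissue07            T2                2
tissue08            T3                3
tissue09            T4                4
```

Each row is the first stage at which that tissue's module-score
distribution turns right-skewed — here exactly the planted establishment
stages (the generator plants tissues round-robin across stages). The
per-(tissue, stage) detail shows why: an established tissue at T0 has
skewness ≈ 1.8 and max score ≈ 27, an unestablished one skewness ≈ 0.1
and max score ≈ 4:

```
  tissue timepoint  skewness  max_score  status
tissue00        T0  1.826137  27.295617  skewed
tissue01        T0  0.053062   4.081973 diffuse
```

The same objects feed the other stages, or run everything at once:

```bash
atlas run-all --preset zebrafish-cncc --seed 0 --out run/
```

which writes module scores, the competency and establishment tables, the
constellation map and distance matrix, priming co-enrichment calls, the
temporal graph, and a `manifest.json` with parameters, seeds and output
checksums. Individual steps are exposed as `atlas simulate | qc |
merge-peaks | enriched-peaks | score-modules | competency |
constellation | priming | stitch`.

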