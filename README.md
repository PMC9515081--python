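# lbx

Liquid-biopsy rare-event detection, enumeration, and cohort
stratification.

A non-enrichment liquid biopsy plates **all** nucleated cells of a blood
draw on slides and images them in four immunofluorescence channels —
DAPI (DNA), pan-cytokeratin (PanCK, epithelial), vimentin (VIM,
mesenchymal), and CD45/CD31 (leukocyte/endothelial, one shared channel).
Circulating tumor cells (CTCs), other marker-discordant rare cells, and
anucleate tumor-associated large extracellular vesicles (LEVs) occur at
frequencies down to one in millions of cells; finding, classifying, and
counting them per ml of blood provides a minimally invasive readout of
disease state — e.g. for separating cancer from normal donors and
early-stage from late-stage breast cancer. `lbx` implements that
analysis chain end to end, together with a synthetic-data layer (slide
renderer and calibrated cohort generator) that makes every stage
testable without any instrument data.

## The pipeline

1. **Synthetic slides** (`lbx.synthetic_slides`) — seeded 4-channel
   frames of a leukocyte monolayer with spiked rare cells and LEVs,
   plus a ground-truth table.
2. **Segmentation & descriptors** (`lbx.segmentation`) — Otsu + watershed
   nucleus segmentation, marker-constrained cell extent, DAPI− PanCK+
   candidates, and a frozen descriptor vector: sizes, eccentricities,
   equivalent diameter `d = 2√(A/π)`, four channel means (min–max
   normalized per slide), and all pairwise feature ratios.
3. **Rare-event detection** (`lbx.rare_detection`) — per slide, PCA
   retaining ≥ 90% variance, Ward clustering, and a small-and-separated
   cluster rule; anucleate candidates bypass to the vesicle gate.
4. **Classification** (`lbx.classification`) — DAPI+ candidates map onto
   the 2³ combinations of (PanCK, VIM, CD45/CD31) positivity:
   epi.CTC, mes.CTC, dp.CTC, tp.CTC, vim.cell, hem.cell, vim.hem.cell,
   dapi.only; DAPI− PanCK+ events of 1–10 µm are LEVs.
5. **Enumeration** (`lbx.enumeration`) — with `N` nuclei counted on a
   sample's two slides and CBC concentration `W`, a count `k` becomes
   `k·W/N` events per ml.
6. **Cohort synthesis** (`lbx.cohort`) — zero-inflated truncated
   log-normal rate models calibrated to published per-group summary
   statistics (mean/median/range/detected fraction).
7. **Group statistics** (`lbx.group_stats`) — tie-corrected
   Kruskal–Wallis planned comparisons, Welch t, Pearson correlations.
8. **Stratification** (`lbx.stratification`) — random oversampling to
   74/74/148, stratified 75/25 split, 10-tree random forest with
   10-fold CV (merged-fold ROC/AUC), held-out test confusion matrix and
   F1, information-gain feature ranking.

See `docs/methods.md` for models, defaults, and design rationale.

## Worked example

```python
import numpy as np
from lbx import (
    CohortSpec, default_slide_spec, generate_cohort, match_ground_truth,
    process_slide, render_slide, run_stratification, spike_in_recovery,
)
from lbx.labels import ENUMERATED_CLASSES

# image chain: render a slide with known spikes, recover them
frames, truth = render_slide(default_slide_spec(seed=1))
labelled, _ = process_slide(frames)
rec = spike_in_recovery(match_ground_truth(truth, labelled), list(ENUMERATED_CLASSES))
print(rec)

# cohort chain: calibrated cohort -> random-forest stratification
cohort = generate_cohort(CohortSpec(seed=0))
report = run_stratification(cohort, "cancer-vs-normal", seed=0)
print(f"AUC {report.cv_auc:.3f}  F1 {report.test_f1:.3f}")
print(report.feature_ranking.head(3).to_string(index=False))
```

prints

```
{'n_rare': 28, 'detection_rate': 1.0, 'classification_rate': 1.0}
AUC 0.990  F1 0.972
      feature  information_gain
rate_vim.cell          0.298108
     rate_LEV          0.264939
 rate_mes.CTC          0.133603
```

All 28 spiked rare events on the synthetic slide are detected and
correctly classified; on the synthetic cohort the forest separates
cancer from normal donors with a merged-fold AUC of 0.990. At this
seed the vimentin-only cell rate edges out the LEV rate in information
gain; across seeds the LEV rate ranks first in the large majority of
cohorts.

A CLI mirrors the library: `lbx simulate-slide`, `segment`, `detect`,
`classify`, `enumerate`, `simulate-cohort`, `stats`, `stratify`.

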