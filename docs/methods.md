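# Methods

`lbx` models a non-enrichment liquid-biopsy workflow: all nucleated cells
of a blood draw are plated as a monolayer on two slides, imaged in four
immunofluorescence channels (DAPI, PanCK, VIM, CD45/CD31), and searched
for rare circulating events — circulating tumor cells (CTCs) of
epithelial, mesenchymal, and mixed phenotype, other marker-discordant
nucleated cells, and anucleate large extracellular vesicles (LEVs).
Per-sample class counts are converted to events per ml of blood and used
to compare cohort groups and to train a stratification model. This note
records the models, the defaults that matter, and the choices made where
the design was genuinely open.

## Synthetic slides

The slide generator exists so that every image-domain stage can be
tested against known ground truth.

**Object model.** Each cell or vesicle is an anisotropic
Gaussian-profile ellipse with hard support at 1.5 σ; the support ellipse
is the specified outline, so the rendered object has (up to
thresholding) the specified equivalent diameter and eccentricity. The
amplitude is scaled by the analytic mean of the profile over its support
(`(2/R²)(1 − e^{−R²/2})` with `R = 1.5`, ≈ 0.6005) so that the *mean*
foreground intensity equals the requested per-channel value — this makes
photometric assertions exact rather than empirical. Nucleated objects
draw their DAPI signal at the nucleus diameter and the membrane/
cytoplasm markers at the cell diameter; LEVs carry no DAPI by
definition. Objects are placed by rejection sampling (max 1,000 retries)
with no overlap.

**Defaults.** 16 frames of 1024×1024 px at 0.33 µm/px with ~2,000
leukocytes (DAPI+ | CD45/CD31+, 7 µm nuclei / 9 µm cells) — a desk-scale
stand-in for a production slide of ~3 million cells over thousands of
frames, at a realistic per-frame density. The default spike panel adds
3 cells of each of the 8 nucleated rare classes (10–16 µm, positive
markers at mean 0.35–0.55, negative markers at autofluorescence level
0.02) and 4 LEVs (6 µm, PanCK 0.5, DAPI 0). Noise is additive Gaussian
(sd 0.01 of dynamic range) on a 0.02 baseline. Channel intensity
distributions per class are free parameters of the generator, not
estimates of any particular instrument.

**What it does not emulate:** optical PSF, uneven illumination,
staining-batch variation, multi-z acquisition, cell clumping and debris.
Passing spike-in tests therefore demonstrates that the algorithmic chain
is correct and self-consistent, not that it is robust to every artifact
of real scans.

**I/O.** Frames are written as one 4-page 16-bit TIFF each with the
pixel scale and channel order in the image description. In memory,
intensities are floats in [0, 1]; quantization to 16 bits happens only
at write time, so a first round trip is exact to 0.5/65535 and any
subsequent round trip is bit-lossless.

## Segmentation and descriptors

Per channel and frame, foreground is `intensity > max(Otsu, floor)` with
an absolute floor (default 0.08) so blank or noise-only frames produce
no foreground. Nuclei come from the DAPI mask (holes filled, objects
< 10 µm² removed) split by watershed on the distance transform (peak
separation 2.5 µm). Cell extent grows each nucleus into the union of
all channel foregrounds, contested pixels going to the nearest nucleus,
capped at 3× the nucleus equivalent radius. PanCK+ connected components
overlapping the DAPI mask by < 10% of their area are emitted as
anucleate candidates with nucleus area 0.

The descriptor vector is frozen in code: nucleus/cell area (µm²),
nucleus/cell eccentricity, equivalent diameter (2·√(area/π)), the four
raw channel means over the cell area, and the ratios of every ordered
pair of those nine base features (72 ratio columns; a zero denominator
yields the sentinel 0 and sets a row flag). Channel means are min–max
normalized to [0, 1] *within each slide*; normalizing twice is an error
because the raw scale is gone after the first pass.

## Rare-event detection

Per slide, the standardized descriptor matrix is projected onto the
smallest number of principal components explaining ≥ 90% of variance
(full SVD, sign fixed by making each component's largest-magnitude
loading positive), then clustered by Ward/Euclidean agglomeration and
cut into 12 flat clusters. A cluster is called rare when:

- its size is below `rarity_fraction` (default 1%) of the slide's
  events, and
- its centroid lies at least `separation_min` (default 6.0)
  background-RMS radii from the dominant cluster's centroid in PCA
  space.

The separation guard distinguishes marker-discordant populations (which
land tens of radii away) from ordinary distribution-tail clusters of a
homogeneous background (within a few radii); without it a unimodal
leukocyte population occasionally sheds tiny tail clusters that would be
flagged by size alone. The dominant cluster is always common, and the
rare-candidate share is capped at 5% per slide (smallest clusters
admitted first). Slides with fewer than 50 events pass everything
through as rare-candidates with a warning. DAPI− PanCK+ candidates
bypass this path entirely and are merged in tagged for the vesicle gate;
DAPI− events without PanCK signal return as common. All sub-choices
(variance fraction, cluster count, rarity fraction, separation guard)
are config-exposed defaults, since the emulated workflow specifies only
the PCA + hierarchical-clustering structure.

## Classification

Positivity is a fixed threshold (default 0.1 for every channel) on the
per-slide-normalized mean — a deterministic stand-in for the trained
analyst review of production workflows, echoed in all outputs. DAPI+
candidates map exhaustively and exclusively onto the 8 combinations of
(PanCK, VIM, CD45/CD31) positivity; CD45 and CD31 share one fluorescence
channel, so their positivity is necessarily joint. DAPI− candidates are
LEVs iff PanCK-positive with equivalent diameter in the closed interval
[1, 10] µm; everything else returns to common. (Reported LEV *size
statistics* in real data can exceed the candidate gate because diameter
definitions differ between detection and curation; the gate here is the
candidate rule, and the size range of accepted LEVs is available as a
report statistic.)

## Enumeration

With N DAPI nuclei counted across a sample's two slides and a CBC
nucleated-cell concentration W (cells/ml), the analyzed blood-volume
equivalent is N/W ml and a raw count k converts to k·W/N events per ml.
Counts and nuclei are pooled across the two slides before division;
per-slide rates are never averaged. "Detected" defaults to rate > 0 for
cells and rate ≥ 1/ml for LEVs, mirroring the two conventions used in
practice. The default study layout is 155 draws (74 early-stage, 51
late-stage draws from 26 patients, 30 normal donors) × 2 slides = 310
slides. W is interpreted as the nucleated-cell concentration from the
CBC; this is configurable.

## Cohort synthesis

Per-sample rates of each class are zero-inflated truncated log-normals:
zero with probability 1 − p, otherwise a log-normal truncated at the
published range maximum. The form is forced by the data's shape — group
medians of 0 with positive means require a point mass at zero, and the
long tails a right-skewed body; truncation keeps simulated ranges inside
printed ranges. Calibration solves (µ, σ, p) against the target (mean,
median, detected fraction):

- printed detected fraction at threshold 0 pins p directly; the body is
  solved from mean and (when positive) median by root-finding
  (tolerance 1e-6);
- median 0 leaves only the mean as a body constraint, so σ stays at its
  default 1.2 and p falls back to 0.4 when unreported (0.6 when the
  median is positive) — these defaults are reported, not estimated;
- a detected fraction defined at ≥ 1/ml (the LEV convention) makes p a
  dependent quantity, p = d / (1 − F_body(1)); the late-stage LEV target
  quadruple is not exactly representable in this family (pinning median
  and fraction caps the achievable mean ~10% below the target), so that
  entry is fit by weighted least squares and verified against the
  generator's own tolerance bands (20% on mean/median, 3 points on the
  detected fraction) instead of the solver tolerance. The fitted model
  lands within 1.5% of all three targets.

Classes without published per-group statistics (dp.CTC, hem.cell,
vim.hem.cell, dapi.only) use one group-invariant, package-chosen profile
each, so they contribute realistic but uninformative features. Per-class
rates are independent within a sample, consistent with the weak
cross-class correlations seen in real cohorts. Default cohort sizes are
74 early / 26 late / 30 normal; W and N are plausible constants (6×10⁶
cells/ml, 6×10⁶ nuclei per two slides → exactly 1 ml analyzed), and raw
counts are the rates rounded onto that countable grid so the k·W/N
identity holds exactly.

## Group statistics

Kruskal–Wallis (tie-corrected, chi-square p even at small n — the
approximation is anticonservative below ~5 observations per group) is
the primary comparison; Welch's t-test is secondary. Planned comparisons
are reported unadjusted by design; Benjamini–Hochberg is available but
off by default. Pearson correlations over per-ml rates flag
zero-variance classes with an undefined sentinel.

## Stratification

Rebalancing duplicates original rows at random (late → early-stage size,
then normal → combined cancer size; 74/26/30 → 74/74/148 = 296). The
75/25 split is stratified per class with a fixed rounding rule (ceil for
the alphabetically first class, floor for the second), reproducing the
canonical 111/111–37/37 and 56/55–18/19 partitions. A 10-tree random
forest (other hyperparameters at library defaults, recorded in the
report) is assessed by 10-fold stratified cross-validation, with the ROC
built from merged out-of-fold predictions; the model is then refit on
the full training partition and scored on the held-out test set
(confusion matrix, F1, test ROC). Both views are reported because
published figures mix them. Features are ranked by information gain on
equal-frequency-discretized values (≤ 10 bins; features with few
distinct values are grouped by value so ties never leak row order).

Because oversampling precedes the split, duplicates of one sample can
sit on both sides of it. This leakage is faithful to the protocol being
modelled and is flagged in every report; the permutation-null test
therefore permutes labels *after* rebalancing, where chance performance
is the correct expectation.

## Problem sizes and runtime choices

Simulation-backed checks use 25 seeds for AUC summaries, 2,000
replicates for the type-I-error check (30 samples/group), 10,000 draws
for rate-model self-calibration, and two default slides for spike-in
recovery — sizes at which the binomial/Monte-Carlo noise is comfortably
inside the asserted tolerances.

## Known limitations

- The renderer's blobs are convex, isolated, and noise-stationary; real
  scans contain clumps, debris, and illumination fields that would
  stress the watershed and per-slide normalization.
- The clustering separation guard is calibrated in units of the
  background's PCA RMS radius; a strongly multimodal *common* population
  (e.g. two leukocyte lineages with distinct morphology) could shift
  its scale.
- The cohort generator reproduces per-group marginals, not
  within-patient serial-draw correlation; draws are treated as
  independent samples.
- The stratification AUCs measure performance under the calibrated
  generator — a stand-in for, not a reproduction of, performance on the
  real cohort.
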