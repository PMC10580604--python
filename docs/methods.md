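# Methods

This note documents the models, parameters and numerical choices behind
`histoarea`, and what the synthetic experiments do and do not show.

## Pipeline overview

A slide is a rectangular grid of non-overlapping patches (0-based,
row-major (row, col)). The pipeline runs: patch sampling → patch
classification → tissue map → tissue-area features → per-tissue deep Cox
features → cutpoint discretization → feature merge → cross-validated
survival models. A single global seed fans out to per-stage seeds through
SHA-256 of `"{seed}:{stage}"`, so any stage can be re-run in isolation;
artifact CSVs carry the config hash and seed as header comments.

## Tissue classes and maps

Nine patch classes (ADI, BACK, DEB, LYM, MUC, MUS, NORM, STR, TUM) in fixed
alphabetical enum order; the integer codes double as the deterministic
tie-break for majority voting (a tie goes to the earlier class). The
four-class reduction maps TUM→tumor, LYM→lymphocyte, STR→stroma and
everything else — including background and mucus — to "other". Mucus still
contributes to the deep-feature branch; background is excluded from all
feature extraction.

Patch sampling takes max(1, round-half-up(ratio · N)) positions uniformly
without replacement (default ratio 0.05). Sampling with replacement is
available but adds no information at a fixed ratio.

The desk-scale patch classifier is multinomial logistic regression on raw
pixels (cross-entropy, seeded); synthetic textures are separable enough
that it exceeds 90% held-out accuracy. An oracle classifier backed by the
generator's label grid decouples downstream stages from classifier quality.
Deep backbones for real H&E patches can be plugged in behind the same
`predict(patch) → (class, confidence)` surface.

## Morphology

Masks live on the patch grid. Dilation and erosion use a centered
rectangular structuring element (default 5 × 5, odd dimensions enforced)
with the mask taken as zero outside the grid; erosion therefore removes
foreground touching the border. Closing is computed on a domain padded by
the element radius and cropped back — the infinite-domain closing
restricted to the grid. This border choice is deliberate: composing the two
grid operators directly would lose foreground near the border and break
extensivity; the padded composition keeps closing extensive, increasing and
idempotent everywhere, which the tests check against shift-accumulate
oracles on all 4 × 4 masks. Connected components default to
8-connectivity (4 available), labels in row-major first-encounter order;
hole filling floods the background from the border with 4-connectivity,
the standard dual of 8-connected foreground.

## Tissue-area features

* `max_tumor_area`: largest 8-connected component of the closed tumor
  mask, measured **on the closed mask**, so gap cells filled by closing
  count toward the area. Closing precedes component analysis by design —
  it repairs classifier fragmentation.
* inside/around lymphocytes: "inside" means within the hole-filled closed
  tumor region, so a lymphocyte fully surrounded by tumor counts as
  infiltrating; "around" means within a Chebyshev band (default width 2
  patches) outside the region. The band width is a config knob
  (`BandConfig`); 2 patches ≈ 0.2 mm at 224 px / 0.5 µm per pixel. No
  closing is applied to the lymphocyte mask itself.
* `around_inside_ratio = (around + 1)/(inside + 1)` exactly; the add-one
  smoothing makes the empty map yield 1.0.
* `total_stroma_area`: total (all components) area of the closed stroma
  mask.

All areas are patch counts; no micron conversion.

## Deep Cox features

The extractor is a small convolutional network implemented in numpy:
strided 3 × 3 convolutions (default channels 8→16→32 on 32 px patches),
ReLU, a fully connected 32-unit feature layer and a scalar risk head. He
initialization, Adam (default learning rate 1e-4), trained on the negative
log Cox partial likelihood averaged over events with Breslow handling of
tied times. Risk sets are computed within each optimization batch;
full-batch by default, and with minibatches any batch without an event is
merged into the next so the likelihood stays defined. The analytic gradient
is verified against central finite differences to 1e-5. The contract is the
32-dimensional feature layer, not the backbone; architecture and input
edge are configurable.

Each patch inherits its patient's (time, event). One extractor is trained
per tissue type. The slide-level feature of tissue t is
(n_t / n_total) · mean(patch features), where n_total counts the slide's
sampled **non-background** patches — weights over a tissue subset sum to at
most 1, with equality when the subset covers all sampled non-background
patches. Tissues with no patches contribute a zero vector. The fixed
concatenation order TUM, LYM, STR, MUC gives 4 × 32 = 128 features. For
multi-slide patients, each slide yields a vector, the patient vector is the
slide mean, and cross-validation folds split by patient.

The combination-search harness enumerates all 2^8 − 1 = 255 non-empty
subsets of the non-background classes (or any sub-lattice) and reports the
cross-validated C-index per subset and model.

## Cutpoints, discretization, evaluation

Maximally selected rank statistics: candidate cutoffs are observed feature
values whose split `x > c` leaves at least ceil(0.1 · n) patients on each
side (the customary minimal proportion); the selected cutoff maximizes the
absolute standardized two-group log-rank statistic. The p-value is the
permutation tail probability of the **maximal** statistic under random
reassignment of feature values (default 1,000 permutations) — the same
multiplicity-honest null as the improved-Bonferroni approximation used by
the common R implementation, evaluated by Monte Carlo instead.
Discretization is strict: 1 iff value > cutoff.

The merged vector is the 128 deep features followed by the five binarized
area features (133 total). The concordance index is implemented literally
with strict inequalities — ties in risk earn nothing; Harrell's 0.5 tie
credit is available behind `tie_credit=True` and cross-checked against
scikit-survival.

Six models run through scikit-survival: Coxnet (l1_ratio 1) for LASSO-Cox,
ridge-penalized Cox for RIDGE-Cox, Coxnet (l1_ratio 0.5) for EN-Cox,
FastSurvivalSVM, RandomSurvivalForest and
GradientBoostingSurvivalAnalysis. Hyperparameters are fixed defaults
(lasso/EN alpha 0.1, ridge alpha 1.0, SVM alpha 1.0, 100 trees,
GBRT depth 2/learning rate 0.1) and config-overridable; the Coxnet solver's
penalty is escalated ×10 (up to six times) if coordinate descent overflows
on near-separable folds. Features are z-scored inside the fit. Model
orientation is normalized: if training-set concordance of raw predictions
is below 0.5 the sign is flipped, so higher predicted risk always means
worse.

Cross-validation is fivefold, split at the patient level and stratified by
event indicator; maxstat cutoffs and model fits use training folds only
(the whole-cohort cutoffs in the run report are for description, not
evaluation — selecting them before CV would leak outcome information).

## Synthetic cohorts

The generator emulates the *structure* of a WSI survival cohort, not its
biology or appearance:

* Tumor blobs are solid squares (Chebyshev discs, radius 0 = one cell),
  stroma is solid rectangles. Planted components keep Chebyshev distance
  ≥ 8 from one another so the 5 × 5 closing acts on each component in
  isolation and the recorded ground truth coincides **exactly** with the
  extractor's output — the basis of the 50-seed exact-recovery test.
  Inside-lymphocytes sit strictly in the blob interior within 2 cells of
  the boundary, so closing provably re-fills the holes they punch;
  around-lymphocytes occupy the width-2 ring, matching the extractor's
  default band.
* Per-patient geometry: 1–3 blobs with radius 1–5 drawn from a
  patient-specific substream (an explicit blob list makes all patients
  identical, for tests). Defaults: 48 × 48 grids, inside/around lymphocyte
  rates 0.15/0.25, stroma fraction 0.08, 32 px patches.
* Patch textures: class mean color + Gaussian noise + optional stripes;
  one noise parameter controls learnability. Optionally a patient's
  log-hazard shifts patch brightness (`hazard_texture_scale`) so the deep
  branch can recover outcome signal from pixels.
* Survival: exponential proportional hazards with baseline rate 1 and
  log-hazard = β · z-scored planted area features; default
  β = (0.8, 0.3, −0.3, −0.4, 0.4) encodes larger tumors/more infiltration/
  more stroma as harmful and peritumoral lymphocytes as protective.
  Censoring is independent Uniform(0, c) with c solved (Brent) so the
  expected censored fraction equals the target; tests assert the realized
  rate within ±5%. Default censor rate 0.3, a typical cohort value.

What passing tests show: the implementation computes what it claims on
cohorts whose generating process is known. What they do not show: anything
about real H&E appearance, stain variation, spatial statistics of real
lymphocyte infiltration, or clinical effect sizes.

## Problem sizes

The test suite and examples run cohorts of 20–120 patients on 36–48 patch
grids with 32 px patches and 3–10 training epochs — sizes at which a
single CPU reproduces every stage in seconds to a few minutes. The
signal/noise separation study uses 120 patients, a hazard driven purely by
tumor area (β = 1.5 on the first feature) with texture encoding
(scale 25), against a β = 0 cohort.

## Known limitations

* The conv backbone is desk-scale; no pretrained deep backbone or stain
  normalization is included (both can be plugged in at the classifier and
  extractor surfaces).
* The maxstat p-value is Monte Carlo; at 1,000 permutations its resolution
  is about 1e-3.
* The strict concordance index ignores pairs tied in time and gives no
  credit for tied risks; heavily discretized feature sets therefore read
  lower than under Harrell's variant.
* The pipeline's run report recomputes whole-cohort cutoffs for
  description; only the per-fold cutoffs are ever used for evaluation.
* Stage outputs are written once per run with config-hash provenance;
  there is no incremental cache, as desk-scale runs complete in minutes.
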