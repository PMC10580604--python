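# histoarea

Survival prediction for colorectal cancer from whole-slide histopathology,
combining **deep Cox histopathological features** with **tissue-area
features** computed from per-slide tissue maps.

## Who this is for

Computational-pathology researchers who want a tested, desk-scale
implementation of a two-branch WSI survival pipeline: one branch extracts
per-patch features from a convolutional network trained with the Cox
partial likelihood; the other localizes and quantifies tumor, lymphocyte
and stroma regions on the slide's tissue map with binary morphology. A
synthetic-cohort generator with exact ground truth stands in for clinical
data, so every stage is runnable and verifiable offline.

## The method

A slide is cropped into a grid of patches; each patch is classified into
one of nine colorectal tissue classes (ADI, BACK, DEB, LYM, MUC, MUS, NORM,
STR, TUM), giving the slide's *tissue map*.

**Histopathological branch.** A fraction (default 5%) of patch positions is
sampled per slide. For each tissue type t, a conv net with an FC-32 feature
layer and scalar risk head is trained on that tissue's patches, each patch
inheriting its patient's overall survival label (T_i, δ_i), by minimizing
the negative log Cox partial likelihood

    L = −(1/m) Σ_{i: δ_i=1} [ r_i − log Σ_{j: T_j ≥ T_i} exp(r_j) ]

(He initialization, Adam, Breslow ties). The slide-level feature of tissue
t is the patch-mean FC-32 vector times the weight n_t / n_total (tissue's
share of sampled non-background patches). Concatenating tumor, lymphocyte,
stroma and mucus gives the 4 × 32 = **128-dimensional** histopathological
vector.

**Tissue-area branch.** On the four-class (tumor/lymphocyte/stroma/other)
map: the tumor mask is closed with a 5 × 5 rectangle and 8-connected
components are labeled; the largest component's area is `max_tumor_area`.
Lymphocytes are split into `lymphocyte_inside_tumor` (within the
hole-filled closed tumor region) and `lymphocyte_around_tumor` (a Chebyshev
band of 2 patches around it), with the smoothed ratio
`around_inside_ratio = (around + 1)/(inside + 1)`; `total_stroma_area` is
the closed stroma mask's total area. Units are patch counts.

**Evaluation.** Each area feature is binarized at the cutpoint maximizing
the absolute standardized log-rank statistic (maximally selected rank
statistics; permutation p-value for the maximal statistic). The five binary
features are appended to the 128 deep features (**133** total) and six
survival models — LASSO-Cox, RIDGE-Cox, EN-Cox, survival SVM, random
survival forest, gradient-boosted trees — are compared by fivefold
cross-validated concordance index

    C = #{(i,j): δ_i=1, T_j > T_i, R_i > R_j} / #{(i,j): δ_i=1, T_j > T_i}

with strict inequalities (0.5 = chance, 1 = perfect). Folds split by
patient, stratified by event; cutpoints are re-selected on each training
fold.

## Worked example

Five area features from a handcrafted 15 × 15 map
(`python examples/02_area_features.py`):

```
max_tumor_area         25
lymphocyte_inside      1
lymphocyte_around      2
around_inside_ratio    1.5
total_stroma_area      9
```

The 5 × 5 tumor square keeps area 25 even though a lymphocyte sits inside
it — closing re-fills the hole — and the ratio is (2+1)/(1+1) = 1.5.

End to end on a 60-patient synthetic cohort whose planted tumor area
drives the hazard (`python examples/05_end_to_end.py`):

```
merged feature width: 133

fivefold CV, merged 133 features:
    model  mean_cindex  std_cindex
lasso_cox        0.720       0.127
ridge_cox        0.615       0.087
   en_cox        0.682       0.135
     ssvm        0.585       0.089
      rsf        0.777       0.092
     gbrt        0.791       0.079
```

Every model ranks patients clearly better than chance (C > 0.5) because
both branches carry the planted signal. The same pipeline is available as a
CLI: `histoarea-surv run --config run.yaml` (see also `simulate`,
`area-features`, `discretize`, `evaluate`).

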