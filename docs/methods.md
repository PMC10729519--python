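# Methods

This note documents the models, conventions, and design choices behind
`metabolip`, in the spirit of a statistical-software methods appendix.

## Study design emulated by the synthetic cohort

The generator models a retrospective three-class HCV-positive cohort:
69 HCC, 23 chronic-HCV, and 10 mixed-cryoglobulinemia (MC) patients, with
8 pooled quality-control (QC) injections per block.  Two LC-MS blocks are
simulated: 160 annotated polar metabolites and 120 lipids plus one
constant-spike internal-standard (IS) feature per lipid class.

**Abundance model.**  Feature *j* has a baseline log₁₀ level drawn once
from U(μ₀ − 1.5, μ₀ + 1.5) with μ₀ = 5 (so abundances span ~3 decades,
giving the left-censoring a low-abundance tail to act on).  A study sample
of class *g* observes `10^(b_j + δ_{g,tag(j)} + ε)`, ε ~ N(0, σ), σ = 0.2
log₁₀ units — a within-class biological CV of roughly 50 %, typical for
plasma metabolomics.  Class offsets δ are attached to feature-group tags
mirroring the field's reported trends: short- and long-chain
acylcarnitines +0.6 in HCC, medium-chain acylcarnitines +0.6 in HCV,
polar marker metabolites (+0.6 HCC, +0.3 HCV), LPCs −0.6 in HCC, PCs
elevated in HCC and HCV relative to MC.  The main offsets equal 3 baseline
SDs; exactly 20 feature columns (12 metabolites, 8 lipids) carry signal,
the rest are noise — this is what "planted signal recovery" counts
against.  `CohortConfig.null()` zeroes every offset for negative controls.

**QC pools** are the feature-wise mean of all study samples times
log-normal multiplicative noise with CV 10 % (mean-one parameterisation),
matching the platform stability the CV filter assumes; ≥90 % of features
land below 20 % QC CV, with the median at the configured 10 %.

**Missingness** is left-censored: cells below the 5th percentile of the
block's study abundances go missing with probability 0.3.  This makes the
min/5 imputation rule meaningful (imputed values sit below the detection
floor) without triggering the 75 %/50 % missingness filter on typical
draws — annotated, curated feature panels rarely lose features to that
filter, and the filter logic is exercised by dedicated unit tests instead.

**AFP** is a two-component log-normal mixture per class: membership in the
positive component is Bernoulli with the class fraction (35/69 HCC, 1/23
HCV, 0 MC), positives truncated above 20 ng/mL, negatives truncated at or
below it, so the expected exceedance equals the configured fraction
exactly.  AFP is recorded as not determined (NaN) for MC patients and those
samples are excluded from AFP-rule evaluation.  Age and gender are drawn
to match the cohort's marginal bins (e.g. 75 % of HCC patients over 65).

**What the generator does not emulate:** retention times, adducts, CCS
values, batch drift, inter-feature correlation beyond shared class
offsets, and non-lognormal heavy tails.  Passing tests therefore
demonstrate that the pipeline recovers structure of this idealised form;
they do not certify performance on real acquisitions, where annotation
error and correlated lipid families make discrimination harder.

## Preprocessing

Order: missingness filter → QC CV filter → normalization → min/5
imputation → log₁₀ → autoscaling.  Choices worth noting:

* The missingness rule removes a feature when **either** threshold is
  exceeded (strictly): >75 % missing among study samples or >50 % among
  QCs.  The OR reading is the conservative quality interpretation; both
  thresholds are parameters.
* The QC CV filter runs on raw intensities by default (configurable);
  CVs are recomputed after normalization for reporting.  Features with
  fewer than two observed QC values, or QC mean 0, have undefined CV and
  are removed with a log note.
* Zeros are treated as missing for imputation (log₁₀ requires positive
  values) but counted separately in the report.
* Autoscaling uses the sample SD (n−1).  Constant columns are dropped
  with a record.  Two scaling policies exist: parameters learned on the
  training partition and applied to the test partition (default —
  leakage-free), or learned globally on all study samples
  (`scaling="global"`), the variant that reproduces a scale-before-split
  workflow end to end.

## Multiblock fusion and splitting

SUM-PCA weights each autoscaled block by 1/√p_b (equal total sum of
squares per block; options: no weighting, or 1/√λ₁ scaling by the block's
first eigenvalue), concatenates, and fits PCA by SVD.  A deterministic
sign convention (largest-magnitude loading element positive per component)
makes scores platform-reproducible.  Eigenvalues are S²/(n−1).

Hotelling ellipses use T²crit = 2(n−1)/(n−2)·F(1−α; 2, n−2) with the
sample covariance of the 2-D scores; `contains()` tests Mahalanobis² ≤
T²crit, which covers ≈95 % of a large bivariate-normal cloud at α = 0.05.

Kennard–Stone initialises with the farthest pair (lexicographically
smallest pair on ties) and grows by maximin distance with lowest-index
tie-breaks, making the split a pure function of the data.  The per-class
training size is ⌈0.7·n⌉ — the rounding that yields 49/17/7 for classes of
69/23/10 — and KS distances are measured on the first 3 per-class SUM-PCA
super-score columns (both configurable; three components match the
variance structure visualised in exploratory score plots).

## Classifiers

**PLS-DA** is NIPALS PLS2 against a column-centered one-hot indicator
matrix.  Per component the explained-Y sum of squares SS_a = (tᵀt)(qᵀq)
is stored; VIP uses the multi-response form
`VIP_j = sqrt(p·Σ_a SS_a (w_aj/‖w_a‖)² / Σ_a SS_a)`, whose squares average
to 1 exactly.  Class assignment is argmax of the predicted indicators with
lowest-class-index tie-breaks; no Bayesian threshold is applied.  At full
rank the fit coincides with least squares on the indicator matrix (tested
as an oracle equivalence).  Component counts come from leave-one-out
misclassification, smallest count winning ties (parsimony).

**SIMCA** fits one autoscaled PCA per class on that class's training rows.
T² limits use k(n−1)/(n−k)·F(1−α; k, n−k); Q limits use the Box
moment-matched scaled chi-square g·χ²_h with g = θ₂/θ₁, h = θ₁²/θ₂ over
the residual eigenvalues.  Membership combines both distances as
d_c = sqrt[(T²/T²crit)² + (Q/Qcrit)²] with acceptance radius √2 — a common
convention whose self-acceptance rate at α = 0.05 sits near 95 % (verified
by Monte-Carlo coverage).  Discriminant mode assigns argmin d_c.
In-class columns that are constant get unit scale rather than being
dropped, so every class model sees the same feature space.

**Metrics** use standard one-vs-rest definitions: TP the class's correctly
classified samples, FN its samples assigned elsewhere, FP other-class
samples assigned to it, TN the rest; sensitivity = TP/(TP+FN), specificity
= TN/(TN+FP), accuracy = trace/total.  (Informal textual definitions of
these counts sometimes circulate in inconsistent forms; the implementation
sticks to the standard ones and the tests assert the identities.)

## Benchmarking and univariate audits

The AFP rule calls a sample HCC-positive iff AFP > 20 ng/mL — a value
exactly at the threshold is negative, matching the "≤ 20" clinical bin —
and its accuracy is computed over HCC samples only, per split partition of
the shared Kennard–Stone assignment.  Cohort characteristic tables are
tested with Pearson chi-square (r×c, no continuity correction) and
two-sided Fisher exact tests (2×2, p = sum of hypergeometric probabilities
not exceeding the observed table's); the r×c/2×2 mapping reproduces the
reference cohort's printed p-values (0.3354 gender; 0.0196 ALT, 0.266 AST,
0.0071 GGT).  One-way fixed-effects ANOVA audits each feature across
classes (degenerate features get F = 0, p = 1 by convention); Pearson
correlation with age flags age-driven variables; over-representation
analysis is a generic upper-tail hypergeometric test against user-supplied
feature sets (GMT reader included) — no curated pathway library ships with
the package, so pathway-level p-values depend entirely on the sets given.

ROC curves sweep the distinct score values; tied scores move together,
making the trapezoidal area equal to the Mann–Whitney statistic with
midrank ties, U/(n₊n₋) (tested against brute-force pair counting).
Multi-class problems are reduced to HCC-vs-rest for ROC purposes, HCC
being the clinically relevant positive class.

## Problem sizes and numerical choices

The test suite and acceptance script run the full workflow on the default
cohort (102 study samples, 285 retained features, LOO over 73 training
samples with up to 8 latent variables), Monte-Carlo coverage at 10,000
points (Hotelling) and 5,000 points (SIMCA), and a 1,000-feature null for
ANOVA p-value uniformity; the whole suite completes in well under a
minute.  Convergence: NIPALS iterates to a relative score change of 1e-10
(cap 500 iterations); components are extracted until the requested count
or rank exhaustion, whichever comes first.  Matrix comparisons in tests
use absolute tolerances of 1e-8 on unit-scale quantities.

## Known limitations

* The generator draws features independently given class; real lipid
  families are strongly correlated, which inflates effective sample size
  here relative to real data.
* SIMCA component counts are selected jointly (one k per run) when chosen
  by LOO; per-class counts can be supplied explicitly.
* The AFP mixture is calibrated only in its exceedance fraction, not in
  its full distribution shape; analyses of continuous AFP beyond the
  20 ng/mL rule should not rely on it.
* No batch/drift correction is implemented; QC monitoring is assumed to
  have passed upstream.
* The library is the interface: functions plus the `examples/` scripts
  replace a command-line layer, which the workflow — typically driven from
  notebooks or scripts — does not need.
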