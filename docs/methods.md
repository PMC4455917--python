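# Methods

## The model

`mechsig` predicts non-response (NR) to anti-TNF therapy from pre-treatment
blood gene expression. The modelling chain is:

```
log2 expression  →  within-cohort median referencing  →  mechanism
strength scores  →  lasso logistic regression  →  affine rescale to
[0.5, 9.5]  →  clip test scores to [0, 10]  →  threshold at 60% training
NR sensitivity
```

**Differential expression.** Each cohort (one study / one platform) is
handled separately: `d_gj = x_gj − median_j' x_gj'`, the per-gene midpoint
median over that cohort's samples. Comparing every sample with its
cohort's median sample puts heterogeneous platforms on an approximately
common log2-ratio footing and removes additive per-gene batch offsets
exactly. The limitation is inherited from the design: the median patient
is assumed comparable across cohorts, which degrades when cohorts differ
strongly in case mix.

**Strength scores.** A mechanism is a signed gene set
`{(g, s_g): s_g ∈ {+1, −1}}`. Its strength in sample *j* is the
sign-weighted mean of `d_gj` over the member genes measured in the cohort
(`G'_m`), with the denominator equal to `|G'_m|`, not the full set size —
platforms measure different subsets, so support varies by cohort.
Mechanisms with fewer than `min_genes = 4` measured genes in any cohort
are excluded before analysis (coverage filtering is done once, globally,
not inside each CV split). The score is linear in the data, so its class-
conditional distribution is available in closed form under the synthetic
generator — this is what the oracle tests exploit.

**Classifier.** L1-penalized logistic regression of NR status on the
pooled training strengths (NR is the positive class throughout).
Features enter unstandardized — strength scores already share log2-fold-
change units — with a `standardize` toggle. The penalty is chosen by
stratified 5-fold cross-validation over a 20-point geometric lambda grid
(from the data-derived `lambda_max` down to `lambda_max/100`), minimizing
binomial deviance and then taking the sparsest model within one standard
error of the minimum. The backend is scikit-learn's liblinear solver;
liblinear nominally penalizes the intercept, which we neutralize with a
large `intercept_scaling` and, in the null-model limit, by setting the
intercept to the exact unpenalized solution (the log-odds of the NR
prevalence). After rescaling, any residual intercept shrinkage is
absorbed by the affine map and cannot affect sample ranking.

**Rescaling, clipping, threshold.** The training linear predictor is
mapped affinely (positive slope) onto [0.5, 9.5]; the map is folded into
the coefficients so scoring stays one affine form. Test scores are
clipped to [0, 10]. The decision threshold is the `floor((1−0.6)·n)`-th
order statistic of the n training-NR scores, with ties pushed toward a
lower threshold, guaranteeing at least 60% training-NR sensitivity. With
k = 0 the threshold sits one ULP below the minimum NR score. A fit that
selects no mechanism has a constant linear predictor and cannot be
rescaled; by default this raises, but validation schemes pass
`allow_degenerate=True`, yielding a constant score of 5.0 (midpoint) so
that label-permuted CV repeats — where empty models are the norm — score
every sample identically and contribute tie-AUROC 0.5 rather than
crashing.

**Gene contributions.** For reporting, gene g's contribution to the score
is `Σ_m β_m s_{g,m} / |G'_m|` over selected mechanisms containing it —
large mechanisms dilute each member gene's influence.

## Validation schemes

*Repeated batch-balanced 10-fold CV*: each cohort is shuffled and dealt
round-robin (random starting fold) into the k folds, so per-cohort fold
sizes differ by at most one. Per fold, the entire pipeline (lasso,
rescale, threshold) is refit without the held-out samples; out-of-fold
scores are pooled per repeat and the per-repeat AUROC/sensitivity/
specificity/precision/likelihood-ratio are summarized as medians with
2.5/97.5 percentile intervals across repeats. Fold plans that leave a
training split single-class are re-drawn (derived seed, capped at 100
attempts). Per-repeat statistics are computed on the pooled scores, not
averaged over folds, matching the one-score-per-patient stratification
view.

*Leave-one-batch-out*: one model per held-out cohort, the test cohort's
strengths computed against its own median reference; per-cohort reports
plus their mean.

*Permutation null*: labels are permuted over the pooled sample set before
each full CV repeat; the null AUROC distribution, its median, and the
exceedance count against a reference AUROC are returned. All randomness
descends from one root `SeedSequence` via named substreams, so any scheme
is reproducible in isolation.

## Performance statistics

Confusion statistics use exact rational arithmetic before presentation
rounding. Proportion CIs are Clopper–Pearson (Beta quantiles; verified
against binomial-tail bisection). The positive likelihood ratio
`LR+ = sens/(1−spec)` gets the standard log-method CI
`exp(ln LR ± z·√(1/tp − 1/(tp+fn) + 1/fp − 1/(fp+tn)))`, reported N/A
when fp = 0 (LR infinite). AUROC is the Mann–Whitney statistic with
half-credit ties; its one-sided p-value is the Wilcoxon rank-sum test,
exact when the pooled size is ≤ 20 without ties, otherwise the tie-
corrected normal approximation. Single-shot AUROC intervals use DeLong.
ROC curves emit one point per distinct threshold so the trapezoid area
equals the AUROC identically.

## Clinical response layer

The EULAR grid (improvement cut-offs 1.2/0.6; attained-DAS28 cut-offs
3.2/5.1) is implemented from the standard EULAR definition — an external
standard dependency. Supported dichotomizations: moderate-or-good = R;
good-only (moderate excluded as unknown); and the plain ΔDAS28-1.2
criterion with a strict/inclusive flag, since cohorts differ in whether
Δ = 1.2 counts as response.

The DAS28 noise ceiling adds independent Gaussian noise (default SD 0.6,
the instrument's known measurement SD) to baseline and follow-up
separately — so Δ noise has SD 0.6·√2 — recomputes labels from the noisy
values, and scores each subject by its original Δ (a perfect classifier
of the underlying disease trajectory). Repetitions with single-class
noisy labels are skipped and logged rather than scored 0.5. The median
AUROC over repetitions bounds what any expression classifier can achieve
against DAS28-derived labels. Perturbing both measurements independently
(rather than Δ once) is a repo convention; the alternative shrinks the
effective noise by √2 and raises the ceiling slightly.

## Synthetic studies

The generator emulates: four cohorts of 44/15/30/27 samples (the study
scale the pipeline targets), 27% non-responders per cohort (exact rounded
counts, not binomial draws, for stable test conditions), a 2000-gene
universe of which each platform retains a random 80%, 200 mechanisms with
log-uniform sizes 5–120 and overlapping membership, 10 informative
mechanisms whose effect directions alternate ±1 (two oppositely signed
groups, echoing the lower-inflammatory/higher-metabolic contrast expected
in non-responder blood), additive class effect 0.5 log2 per informative
mechanism, per-gene batch offsets (SD 0.5) and i.i.d. gene noise (SD 1).
DAS28 records use baseline ~ N(6, 1) truncated to [2, 10] and class-
specific improvements N(2.0, 0.8²) for R and N(0.3, 0.5²) for NR, chosen
so EULAR calling reproduces the labels for ≥80% of subjects.

What the generator does **not** model: probe-level structure, intensity-
dependent (heteroskedastic) noise, correlated gene-gene background,
platform-specific dynamic ranges, or confounding between batch and class
beyond what random sampling induces. Passing tests therefore demonstrate
the pipeline's correctness and calibration under the assumed additive
model, not its clinical performance on real microarray data.

## Numerical choices and degenerate inputs

- Midpoint median for even sample counts; genes left incomplete after
  probe collapse are dropped per cohort with a warning (no imputation).
- Probes mapping to multiple genes are omitted; multiple probes per gene
  are averaged.
- Lasso grid: 20 lambdas, `lambda_min_ratio = 0.01`, liblinear tolerance
  1e-6; the internal CV is stratified and seeded, folds capped by the
  minority class count.
- Tie rules in the baseline signature scorers (tied cluster call, tied
  k-NN vote, equidistant sample) all favour NR, keeping the positive call
  conservative; each resolution is logged. Their clustering default —
  agglomerative, average linkage, correlation distance, cut at two — is a
  convention, configurable, not a reconstruction of the original
  signature publications.
- Problem sizes in the shipped tests and acceptance script (100
  permutation repeats, 25 CV repeats, 50 recovery seeds) are chosen so a
  full run completes in minutes on one core while keeping Monte-Carlo
  error well inside the asserted bands.

## Known limitations

- The coverage filter is global; re-filtering inside each CV training
  split (flag available at the strength level) would be marginally more
  conservative.
- The liblinear intercept treatment is exact only in the null-model
  limit; at interior penalties the intercept is shrunk by ~1/100 of the
  coefficient penalty, which rescaling renders irrelevant for ranking and
  thresholding but which means raw intercepts are not glmnet-identical.
- Leave-one-batch-out assumes the held-out cohort contains every selected
  mechanism; cross-platform deployments where a mechanism loses coverage
  raise rather than silently renormalizing.
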