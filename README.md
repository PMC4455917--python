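# mechsig

Blood-transcriptome prediction of **non-response to anti-TNF therapy** in
rheumatoid arthritis, built around prior-knowledge *mechanism* scoring of
gene expression.

Roughly 30–40% of RA patients fail first-line anti-TNF biologics such as
infliximab. A pre-treatment test that flags likely non-responders with high
specificity would let those patients move straight to an alternative
biologic. `mechsig` implements such a classifier pipeline for researchers
working with multi-cohort blood expression data:

1. **Mechanism strength scoring.** A *mechanism* is a signed gene set: genes
   known to go up (+1) or down (−1) when an upstream biological entity is
   active. With per-gene log2 differential expression `d_gj` taken against
   the within-cohort median sample, the activity of mechanism *m* in sample
   *j* is the sign-weighted mean

   `Strength(m, j) = (1/|G'_m|) Σ_{g ∈ G'_m} s_g · d_gj`

   over the member genes `G'_m` measured on that cohort's platform
   (mechanisms with fewer than 4 measured genes are dropped). Median
   referencing within each cohort makes scores comparable across platforms.

2. **Classifier.** L1-penalized (lasso) logistic regression of the
   non-responder label on the strength scores pooled over training cohorts,
   with the penalty chosen by internal stratified 5-fold cross-validation
   (one-standard-error rule). The linear predictor is affinely rescaled so
   training scores span [0.5, 9.5]; test scores are clipped to [0, 10]; the
   decision threshold is placed so 60% of training non-responders score
   above it, trading sensitivity for the high specificity the clinical use
   case demands.

3. **Validation.** Repeated batch-balanced 10-fold cross-validation,
   leave-one-batch-out cross-validation, label-permutation nulls,
   leave-one-sample-out evaluation of previously published gene-list
   signatures, and confusion statistics with exact binomial (Clopper–
   Pearson) and log-method likelihood-ratio confidence intervals, AUROC
   (Mann–Whitney) with one-sided rank-sum p-values.

4. **Clinical layer.** EULAR DAS28 response calling (good/moderate/none)
   and a Monte-Carlo bound on the best achievable AUROC given the known
   DAS28 measurement noise (SD 0.6).

5. **Synthetic studies.** A generator that emulates the assumed data
   structure — multiple cohorts on partial gene universes, batch offsets,
   ~2.5:1 responder:non-responder imbalance, mechanism-driven class signal,
   DAS28 trajectories — so the full pipeline is testable without any
   external data.

## Worked example

```python
from mechsig import NonResponseModel
from mechsig.model import stack_strengths
from mechsig.pipeline import cohorts_to_strengths
from mechsig.simulate import SimulationConfig, simulate_study

study = simulate_study(SimulationConfig(), seed=1)        # 4 cohorts, n=116
strengths, kb = cohorts_to_strengths(study["cohorts"], study["kb"])
X, cohorts = stack_strengths(strengths)                   # 116 x 189 design
labels = study["labels"].loc[X.index]

res = NonResponseModel(X, labels, cohorts=cohorts).fit(seed=3)
print(res.summary())
```

```
Non-response mechanism classifier (lasso logistic, 0-10 scale)
==============================================================
Training samples: 116  (NR: 31, R: 85)
Training cohorts: SYN0, SYN1, SYN2, SYN3
Penalty (lambda): 0.00127303   Selected mechanisms: 8
Decision threshold: 7.707 (target training NR sensitivity 60%)
--------------------------------------------------------------
Mechanism                                Coefficient
(Constant)                                     4.063
M0007                                         -3.535
M0005                                         -2.523
M0000                                          2.159
M0002                                          1.973
M0009                                         -0.996
M0006                                          0.405
M0008                                          0.132
M0151                                         -0.009
==============================================================
```

The score is the 0–10 classifier scale: samples above the threshold are
predicted non-responders. Seven of the ten truly informative simulated
mechanisms were selected, every one with its injected effect direction
(even-numbered mechanisms carry +1 effects, odd-numbered −1), plus one
small spurious coefficient — typical lasso behaviour at this effect size.
`res.score(new_strengths)` scores held-out samples;
`mechsig.validation.repeated_kfold` and `leave_one_batch_out` estimate
in-batch and cross-cohort performance.

A CLI covers the same flow from the shell:

```bash
mechsig simulate --out data/ --seed 1
mechsig crossval --config run.yaml --scheme repeated-kfold --repeats 100 --seed 2
mechsig das28-sim --annotations data/annotations.tsv --sd 0.6 --reps 1000 --seed 3
```

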