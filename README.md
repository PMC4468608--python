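# p53sig

Expression-signature discovery and validation for p53–HDM2 inhibitor
sensitivity.

Inhibitors of the p53–HDM2 interaction only work in tumors whose p53
pathway can still be activated — but wild-type *TP53* status alone is a
poor patient-selection marker (most wild-type lines are insensitive).
This package implements the full biomarker workflow that addresses this:
it calls sensitivity from dose-response screens (IC50 ≤ 4 µM and
Amax ≤ −50 %), discovers a compact predictive gene signature by
bootstrapped Wilcoxon ranking with a one-SEM model-size rule and
100-bootstrap stability selection, trains a naïve Bayes response
classifier with tunable decision thresholds, evaluates it by repeated
stratified cross-validation (ROC/AUC, precision–recall, PPV/NPV), scans a
multi-type feature landscape with local BH FDR and affinity-propagation
deduplication, tests compound target classes for genotype-stratified
selectivity enrichment, and validates predictions in vivo against
RECIST-adapted tumor-volume response calls (PD > +35 % growth =
insensitive; prediction threshold 0.2 for xenografts).

Because the original screen data are proprietary, the package ships a
first-class synthetic cohort generator that reproduces the study's
statistical structure — 47 sensitive vs 204 insensitive samples, 13
signature genes planted with the published fold changes (HDM2 2.18,
CDKN1A 3.88, …, AEN 1.46), TP53 genotype coupled to response at the
screen's contingency rates — so every stage is testable end to end.
It is aimed at computational biologists building or auditing
drug-sensitivity classifiers over expression data.

## The model in brief

For sample *x* with signature genes *g*, the classifier is naïve Bayes
with Gaussian class-conditionals on log2 expression:

    P(sensitive | x) ∝ π_s · Π_g N(x_g; μ_gs, σ_gs)

with empirical priors (π_s = 47/251 on the training strata), per-class
sample sds floored at 1e-6 + 1e-3·pooled sd, and call = sensitive iff
the posterior meets the threshold (Youden-optimal by default, fixed 0.2
in PDX mode). Signature membership is decided by selection frequency
across 100 stratified 2/3 bootstrap splits, at the size k\* chosen as
the smallest k within one SEM of the scan's accuracy maximum.

## Worked example

The numbered drivers under `analysis/` run the study as a narrative;
each writes its tables under `results/`:

```sh
python analysis/01_simulate_cohort.py      # cohort + dose-response + PDX curves
python analysis/02_sensitivity_calls.py    # IC50/Amax calls + Fisher test
python analysis/03_signature_discovery.py  # scan, 1-SEM rule, stability
python analysis/04_classifier_validation.py
python analysis/07_pdx_validation.py       # RECIST calls + confusion metrics
```

Output of steps 02, 03 and 07 on the default seed:

```
calls: 47 sensitive / 204 training-insensitive / 0 intermediate
sensitivity x TP53 2x2 [[45, 2], [34, 170]]: Fisher p = 1.59e-25, OR = 112.5

variance filter: 2000 -> 1000 genes
size scan: max accuracy 1.000 at k=6; smallest k within 1 SEM: k*=6
stability selection: 9 features seen at least once; final signature
(6 genes) recovers 6 planted signature genes
signature: CDKN1A, ZMAT3, DDB2, SESN1, FDXR, RRM2B

RECIST categories: {'PD': 204, 'PR': 23, 'SD': 21, 'CR': 3}
all models: n=251  TP=47 FP=0 FN=0 TN=204
  PPV 100%  NPV 100%  sensitivity 100%  specificity 100%
  baseline response rate 19%
```

Reading this: the simulated screen reproduces the strong
sensitivity-genotype association (Fisher p ≈ 10⁻²⁵ on the 251-sample
strata); discovery recovers planted signature genes and — because the
synthetic signal is cleaner than real screen data — saturates at a
smaller-than-13 optimal size; the xenograft stage converts trajectories
into RECIST categories and shows the classifier enriching response far
above the 19 % baseline rate. The same machinery is exposed as a CLI
(`p53sig simulate | call | discover | train | predict | evaluate |
landscape | selectivity | predict-cohort | run`).

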