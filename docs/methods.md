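# Methods

`p53sig` re-implements, as a tested pipeline over synthetic cohorts, a
biomarker-discovery workflow for p53–HDM2 inhibitor sensitivity: from
dose-response sensitivity calling, through bootstrapped gene-signature
selection and naïve Bayes response prediction, to genotype-stratified
compound-selectivity enrichment and RECIST-style in-vivo validation.
This note records the models, the parameters that matter, and the design
choices made where the procedure left room.

## Sensitivity calling

Cell-line-like samples are called from viability summaries: *sensitive*
iff IC50 ≤ 4 µM **and** Amax ≤ −50 %; the *training-insensitive* stratum
is IC50 ≥ 8 µM (rule version `v1`); everything else is *intermediate* and
excluded from training. `v1` deliberately ignores Amax for the
insensitive stratum — the IC50 ≥ 8 µM bound alone already excludes every
sensitive line — but a stricter `v2` (additionally Amax ≤ −50 %) is
selectable because the stratum definition is genuinely ambiguous. An
external-panel rule calls sensitive at IC50 ≤ 3 µM (binary, inclusive).
Right-censored IC50 values are expected as their censoring bound.

Xenograft-like samples are called from tumor-volume trajectories
(percent change vs day 0). Best response is the minimum over the series
(the maximum-effect time point). Categories: CR at −100 exactly, PR in
(−100, −50), SD in [−50, +35], PD above +35; a model is *sensitive*
unless it progresses. Both band boundaries are assigned to SD, i.e. the
stated strict inequalities are honored.

## Signature discovery

The matrix (log2, RMA-like) is first variance-filtered: the
`ceil(0.5·F)` highest-variance genes are retained (18 106 → 9 053 at
array scale). "Bootstrapped data splits" are stratified random 2/3 / 1/3
subsampling **without** replacement — matching the split description
rather than classical resampling. Within each split, genes are ranked by
two-sided Wilcoxon rank-sum p on the *training* side only; ties are
broken by |log2 fold change| descending, then gene id (a deterministic
rule the source procedure does not specify). The exact rank-sum null is
used when both groups have ≤ 25 samples; otherwise a vectorised normal
approximation with continuity and tie correction (equivalence with the
reference implementation is asserted in tests; the hand-vectorised
version exists because the reference call was an order of magnitude
slower inside the 100-bootstrap loops).

The size scan fits a naïve Bayes classifier on the top-k genes for
k = 5…100 over 20 splits and records held-out accuracy, sensitivity and
specificity. The model size k\* is the smallest k whose mean accuracy is
within one SEM (taken at the argmax) of the maximum. Stability selection
re-runs the top-k ranking on 100 fresh splits and tabulates selection
counts; the final signature is the k\* most frequent genes, with any
gene on an exclusion list replaced by the next most frequent candidate
(the generalisation of replacing one unannotated feature). The 20-repeat
scan and the 100-repeat stability run use independent seeded split
sequences.

## Naïve Bayes classifier

Continuous features get class-conditional normals with per-class mean
and sd (sample sd, ddof = 1); the sd is floored at
`1e-6 + 1e-3·pooled within-class sd` so degenerate features cannot
produce singular densities (they then contribute nothing to
discrimination). Discrete features get add-α categorical tables (α = 1)
with one reserved unseen-level bucket. Priors are empirical class
frequencies (47/251 ≈ 0.187 at the study's strata). Posteriors are
computed in log space and are shift-invariant; posteriors match R's
`e1071::naiveBayes` — the implementation the original analysis used — to
machine precision (asserted in tests).

A sample is called sensitive when posterior ≥ threshold. The
Youden-style threshold maximises sensitivity + specificity over all
cuts, returned as the midpoint of the two adjacent distinct posteriors
bracketing the optimum; ties prefer higher sensitivity, then the lowest
threshold; an all-sensitive optimum returns the lowest posterior with a
warning. Threshold search inside cross-validation uses the
training-fold posteriors of each fold (recorded here because the
procedure's description does not say whether train or pooled posteriors
were used). PDX-mode predictions use a fixed 0.2 threshold (precision
over recall).

## Evaluation

Confusion metrics are exact rationals of counts; reported percentages
round half-away-from-zero to integers, so comparisons with reported
values cannot be perturbed by floating-point rounding. AUC is the
rank/pairwise statistic (Mann–Whitney U / n₊n₋, half credit for ties),
identical to the trapezoidal area over distinct thresholds.
Cross-validation is 5 repeats of stratified 5-fold; any feature
selection in the model specification is re-run inside each training
fold. Fisher's exact test is two-sided by probability-mass summation
(the common convention; conventions differ in asymmetric tails), with
the sample odds ratio (a·d)/(b·c); a zero margin yields p = 1 with a
warning.

## Feature landscape (multi-type selection)

Features are typed (expression / copy number / pathway: continuous;
mutation / tumor-suppressor status / lineage: discrete). Within each
type, features are first deduplicated by affinity propagation (exemplars
only are tested, matching the cluster-before-test order; a
test-then-cluster flag exists for comparison). Similarity is the Pearson
correlation of feature value vectors (categorical features as category
codes), preference the median off-diagonal similarity, damping 0.9,
max 1000 iterations with a 50-iteration stable-exemplar convergence
window — none of these is given by the source, so they are package
defaults. Non-convergence returns the current assignment flagged.
Continuous exemplars get the Wilcoxon test, binary discrete ones
Fisher's 2×2; discrete features with > 2 levels use level-vs-rest 2×2
tests with a Bonferroni factor over levels (a documented alternative to
the Freeman–Halton test). BH FDR is applied *within* each type
("local" FDR, cutoff 0.25), and per-type minimum/maximum counts
(defaults 1/100 — the bounds existed but their values are unstated) are
enforced irrespective of the FDR, with forced inclusions flagged.

Affinity propagation is implemented directly (responsibility /
availability message passing with deterministic tie-breaking jitter)
because the contract requires a partial assignment plus a non-converged
flag. On balanced exact-duplicate groups its fixed point provably equals
the exhaustive exemplar-set optimum and is tested against it; on
unstructured random similarity matrices the algorithm — like the
scikit-learn estimator, which behaves identically on the same
instances — reaches a slightly suboptimal fixed point in a few percent
of cases. That is a property of approximate message passing, not of this
implementation.

## Compound selectivity

Per compound, the (positive) sensitivity metric is log2-transformed,
Z-scored across all samples (not per stratum), and weighted by
|log2 metric| — the transformed-scale reading of "absolute value of the
metric"; a raw-scale weighting is selectable. TP53 WT vs mutant strata
are compared per compound by two-sided Wilcoxon, BH-corrected across
compounds; direction is the sign of the median score difference (lower
in WT = WT-selective). Target classes are then tested for enrichment in
selective compounds (q ≤ 0.25) with Fisher's exact test and a second BH
pass across classes, reporting directional proportions per class. Note
that scaling all metrics by a constant leaves the Z-scores unchanged but
shifts the |log2 m| weights, so per-compound p-values are only
asymptotically scale-stable (the weight becomes effectively constant for
metrics far from 1); tests assert Z-invariance exactly and rank
stability under large scalings.

## Synthetic cohort generator

The generator defines the study conditions for every downstream test:

* **Strata**: 47 sensitive vs 204 insensitive samples (the training
  strata), optional intermediates.
* **Signature**: 13 genes planted with the published linear fold changes
  (HDM2 2.18 … CDKN1A 3.88 … AEN 1.46), all up-regulated in sensitive
  samples; within-group sd 0.5 log2 (the source gives no within-group
  variance — it is a free parameter).
* **Background**: per-gene means uniform on [5, 10] log2 (RMA-like);
  per-gene sds log-normal with median `within_group_sd` and log2-spread
  `baseline_sd`/2. This places signature genes — whose planted class
  shift adds variance — in the upper half of the variance distribution,
  as the variance filter presumes of informative genes; with a constant
  background sd above the signature sd the filter would discard the very
  genes the screen found, which contradicts the emulated design.
* **Genotype**: TP53 status is drawn per class from the Bayes inversion
  of P(sensitive|WT) = 43/100, P(sensitive|MUT) = 4/256 and
  P(WT) = 100/356, reproducing the screen's contingency structure.
* **Dose-response / trajectories**: class-conditional lognormal IC50 and
  normal Amax / best-response draws, truncated to the class's calling
  band (sensitive IC50 ≤ 4 µM, Amax ≤ −50 %; insensitive IC50 ≥ 8 µM,
  best response ≥ +36 %; intermediate IC50 in [4.01, 7.99] µM).
  Truncation margins are wide enough to survive the writers' 6
  significant digits. Growing tumors attain their best (minimum)
  response at the first measurement; deep regressions (≤ −50 %) shrink
  monotonically through the last day.
* **RNG**: one root seed spawns independent child streams per component,
  so identical (config, seed) reproduce every table bit-for-bit.

What the generator does **not** emulate: inter-lineage expression
heterogeneity, probe-level noise or normalization artifacts, correlated
gene modules in the background, censored dose-response curves, and
measurement error in tumor volumes beyond additive noise. Consequently
the planted signal is cleaner than real screen data: on default cohorts
the size scan often saturates below 13 genes and cross-validated
metrics approach 1.0. Passing tests therefore demonstrate correctness of
the machinery under the stated statistical structure, not expected
field performance.

## Problem sizes and known limitations

Multi-seed experiments run at a reduced gene space (2 000 generated /
1 000 post-filter for stability selection, 300–500 for CV and PPV
comparisons) rather than the 18 106-gene array: selection statistics
scale with log G, so the competitive structure is preserved while the
bootstrap loops stay quick; the 18 106 → 9 053 filter count is exercised
at full scale. Each experiment uses 20 seeds with per-seed child
streams.

Two documented negative results, both visible as failing assertions in
the acceptance suite and reported numerically by
`scripts/acceptance.py`:

1. **Null stability frequencies.** With no planted effect one might
   expect every gene's stability-selection frequency to stay low
   (≤ 60/100). In fact successive 2/3 subsamples correlate ≈ 0.81 with
   the full-sample rank statistic, so the luckiest null gene of a given
   cohort is re-selected in roughly half the bootstraps; its frequency
   exceeded 60/100 in most seeds at G = 2 000 and in about a third of
   seeds at G = 9 053. High stability frequency alone is therefore not
   evidence of signal — only the planted-signal contrast (all 13 genes
   near 100/100 with unambiguous separation from the background) is.
2. **Affinity-propagation optimality.** See above; exhaustive-search
   agreement holds on structured instances, not universally on random
   ones.
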