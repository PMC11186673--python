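# Methods

This note documents the models, the synthetic-data generator, the numerical
conventions and the open design choices in `methylcascade`, in the spirit of
a package methods appendix: what is computed, under which assumptions, and
what a green test does and does not establish.

## Preprocessing

Input is a probe-by-sample beta matrix (β = methylated / total intensity,
in [0,1], possibly with missing entries).

* **Filtering.** Three rules, applied in a fixed order so the removal report
  always reconciles (a probe is counted under the *first* rule that removes
  it): (1) blacklist membership — the blacklist is an input file of probe
  IDs, not a vendored copy of any published list, because such lists are
  externally versioned; (2) chromosome — only probes annotated to chr1–22,
  chrX or chrY are kept ("chrN" and "N" spellings both accepted; mitochondrial
  and unplaced contigs, and unannotated probes, are removed); (3) missingness
  — probes with a missing fraction **strictly greater** than 5% (default) are
  dropped; exactly 5% is retained.
* **Imputation.** k-nearest-neighbour over probe rows (defaults k = 10,
  rowmax = 0.25, mirroring the R `impute` package semantics): the distance
  between two probe rows is the Euclidean distance over their mutually
  observed samples, rescaled to the full sample count; each missing entry is
  the mean of that sample's value over the k nearest rows observed in that
  sample (ties in distance broken by row order); rows missing more than
  `rowmax` fall back to per-sample column means. This is implemented in
  the package rather than via `sklearn.impute.KNNImputer` because the
  nan-Euclidean/weighting conventions differ, and tests require exact
  agreement with a brute-force restatement of the definition above.
* **Transform.** M = log2(β/(1−β)), with β clipped to [ε, 1−ε], ε = 1e-6,
  so β ∈ {0,1} stays finite rather than dropping probes — this preserves
  feature alignment with a trained model. The inverse transform
  β = 2^M/(1+2^M) round-trips to < 1e-12 away from the clip boundary.
* **Multi-cohort feature space.** The multiclass feature list is the
  intersection of the per-tissue probe sets, in one canonical sorted order.
* **External cohorts.** When raw methylated/unmethylated counts are given,
  β = meth/(meth+unmeth) (zero totals = missing). The matrix is reindexed to
  the training feature list; absent probes and residual missing entries are
  set to a constant β = 0.5 (M = 0) *per sample*, with no cohort-level
  imputation, so single samples can be scored in isolation.

## The cascade

* **Boost stage.** `sklearn.ensemble.GradientBoostingClassifier` with the
  published hyperparameters as defaults: binary (450 estimators, depth 10,
  learning rate 0.189), multiclass (800, 3, 0.189), both with 50% feature
  subsampling per tree and 50% row subsampling per iteration. Importance is
  the ensemble's total loss-reduction ("gain") per feature, normalized to
  sum 1. Whether the binary models also used the 50%/50% subsampling is
  ambiguous in the source description; it is applied to both by default and
  is configurable. Training is deterministic given the seed
  (single-threaded exact splits).
* **Gate.** Features with importance strictly > 0 are selected, sorted by
  descending importance with probe-ID tie-breaks for determinism. The
  importance > 0 rule is stated for the multiclass model; it is applied to
  binary models too, for uniformity.
* **Network stage.** A plain numpy MLP: He initialization, ReLU (or tanh),
  inverted dropout, minibatch Adam with softmax cross-entropy. Defaults —
  hidden layers (256, 64), dropout 0.3, learning rate 1e-3, batch 32 — are
  placeholders where the source defers the architecture to a hyperparameter
  search; `hyperparameter_search` re-derives a configuration from a declared
  space under the same 30%-validation protocol. Inputs are the **raw gated
  M-values**: no per-feature standardization. This is deliberate — M-values
  already share a log2 scale, and standardizing amplifies low-variance noise
  probes, which measurably degrades robustness to batch-shifted external
  cohorts in the package's own tests.
* **Early stopping.** Training always runs the full epoch budget
  (default 500); after every epoch the validation accuracy (stratified 30%
  of the training split) is recorded, and the weights of the epoch with the
  **highest** validation accuracy are restored at the end, ties resolved to
  the earliest epoch. The evaluator is injectable, which is how the argmax
  contract is unit-tested.
* **Class imbalance.** No reweighting by default (MCC is reported instead);
  an optional `class_weighting` flag enables inverse-frequency weights.
* **Prediction.** Probes absent from an input matrix are filled at M = 0
  (the β = 0.5 missing-data policy) by default, or rejected with the missing
  list if `fill_missing=False`. Probability rows sum to 1; labels are the
  argmax with class-order tie-breaks.

## Metrics

Confusion matrices (rows = truth), accuracy, per-class precision/recall/F1,
MCC, ROC AUC (tie-corrected Mann-Whitney statistic), PR AUC (step-wise
average precision, no interpolation) and one-vs-all per-class AUCs.
Conventions fixed here because sources are silent: precision, recall, F1 and
MCC are all 0 when their denominator is 0; multiclass MCC is the standard
covariance-form generalization, whose reduction to the 2×2 formula at two
classes is the correctness anchor. Computation delegates to scikit-learn
where the definitions coincide; tests check everything against independent
brute-force oracles.

## Interpretation

* **Shapley values.** shap-style attributions of the network's class
  probabilities via the permutation-sampling estimator (Štrumbelj-
  Kononenko): for sampled feature orderings and background rows, features
  are switched one at a time from background to explained values and the
  output change is credited to the switched feature. The background set is a
  stratified 10% of the training split and the explanation set a stratified
  10% of all samples (minimum one per class, recorded when the rule fires);
  a feature the network provably ignores receives exactly zero. The
  estimator is stochastic; `n_permutations` (default 20) controls its
  variance, and the seed fixes the draws.
* **Probe→gene mapping.** Coordinates are 0-based half-open internally (BED
  native; GTF converted on read; the TSS is `start` on +, `end−1` on −). A
  probe maps to every gene whose body contains it, or whose promoter window
  — the 1500 bases immediately upstream of the TSS, excluding the TSS base,
  boundary-inclusive at the far end so exactly 1500 bases are eligible —
  contains it. Body takes precedence over promoter in the reported reason.
  Manual curation of multi-gene probes is modelled as an optional exclusion
  file of (probe, gene) pairs applied after mapping.
* **Differential methylation.** Per-probe two-sample Wilcoxon rank-sum on
  M-values with BH adjustment across all tested probes; significant iff
  adjusted p < .01 **and** |mean difference (case − control)| > 2 — the
  threshold is interpreted on the M scale (the analysis input is M-values)
  and is configurable. Constant probes get p = 1 by convention. The rank-sum
  p uses exact enumeration for tie-free groups of ≤ 25 and the tie-corrected
  normal approximation otherwise (scipy's exact path does not handle ties).
* **Over-representation.** One-sided (enrichment) Fisher exact test via the
  hypergeometric upper tail, after intersecting both query and set with the
  background.
* **Subset property battery.** For any gene subset (e.g. the model's
  lncRNAs) vs its background: reference-list overlap (Fisher), nearest-SNP
  within 1/10/100 kb (Fisher per threshold), within-1-kb of a reference gene
  (Fisher, reference genes excluded from both sides), and Wilcoxon rank-sum
  on log gene length, log exon length of the longest transcript, and log
  expression. Battery Fisher tests are two-sided (the questions are
  directionless a priori); each row records its sidedness.

## Survival

Expression is rank-based inverse-normal transformed (Blom offset) by
default, with `normalize=False` for variance-stabilized input produced
upstream. Covariates: age (numeric), stage (ordinal I–IV → 1–4; unknown
stage drops the sample with logging), gender (omitted automatically for
single-gender cohorts). Phase 1 fits one Cox model per gene
(gene + covariates; lifelines), selects genes at Wald p < .05, fits a joint
model over the selection (covariates included by default, excludable by
flag), and splits samples at the median joint linear predictor (ties → low
group) for Kaplan-Meier curves and a log-rank test. Non-converged
single-gene fits are dropped with logging; the joint fit falls back to a
small ridge penalty (0.1) when unpenalized Newton iterations fail, e.g.
under exact collinearity. Phase 2 repeats, thirty times: a 75/25 split
stratified by event status, in-fold re-screening (no leakage — tests assert
the screen only ever sees training rows), three Cox fits (genes /
covariates / both) and the 5-year cumulative/dynamic time-dependent ROC AUC
with inverse-probability-of-censoring weights from a Kaplan-Meier estimate
of the censoring distribution (timeROC-like); folds with too few events are
skipped and recorded.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes, not
array chemistry:

* per-probe baselines from a 50/50 mixture of two Beta modes (defaults 0.2
  and 0.8, concentration 40) — the bimodality typical of 450K marginals;
* tissue identity via M-scale offsets (SD 1.5) on a random 5% probe subset
  per tissue;
* cancer effects planted on the M scale (default ±3, sign recorded in the
  truth table) on disjoint per-tissue probe subsets, mapped back to β
  through the inverse transform so `effect_size_m` aligns with the
  differential-methylation threshold of 2;
* Beta-distributed sampling noise around each expected β (concentration
  100, within-group SD ≈ 0.04 at mid-range);
* independent missingness at a configurable rate;
* "independent" external cohorts re-drawn from the same generative model
  with a global M-scale batch shift, including adenoma samples modelled as
  attenuated cancers (`adenoma_fraction_of_effect` × effect) — able to
  produce, not guaranteeing, adenoma-classified-as-cancer behaviour;
* expression and survival: exponential proportional hazards with log-hazard
  = Σ effect·z(expression) + 0.02·(age−63) + 0.3·(stage−2.5), baseline rate
  ln2/5 (median 5-year survival at linear predictor 0), and independent
  exponential censoring whose rate is solved numerically so the expected
  censored fraction matches the request.

Default cohort sizes keep the normal fraction at 0.135 per tissue (the
pan-cancer average imbalance); per-tissue counts of the original data are
not public in the text, so the defaults are a regime, not a reconstruction.
Every operation draws from an RNG stream keyed by (seed, operation name):
identical configs give bit-identical output and new operations never perturb
existing draws. Not modelled: Infinium I/II chemistry, CNV/SNP artefacts,
tumour purity, probe cross-reactivity. A green test on this world therefore
establishes algorithmic correctness and statistical calibration under clean
separability — not clinical performance.

## Reproducibility

All training and sampling is deterministic given seeds (numpy Generators;
single-threaded tree construction — a test-environment contract, not a
runtime restriction). Model persistence writes a JSON manifest plus native
serializations of both stages, and reloading reproduces predictions
bit-for-bit. The pipeline orchestrator validates its YAML config strictly
(unknown keys rejected before any work), fans per-stage seeds out from the
global seed, persists stage outputs as they complete (failures name the
stage; `resume=True` continues from the first incomplete stage) and writes a
manifest with a SHA-256 content hash of every output, so a re-run with the
same config is verifiably byte-identical.

## Known limitations

* The boosted stage is scikit-learn's exact-split gradient boosting, not
  the histogram/regularized variant of dedicated boosting libraries; gain
  importances are impurity-based analogues. Absolute importances are not
  comparable across libraries, but the importance > 0 gate and ranking are.
* The Shapley estimator is sampling-based; rankings stabilize quickly but
  individual values carry Monte-Carlo error at small `n_permutations`.
* The hyperparameter search is a budgeted grid/random evaluator, not a
  full search framework.
* With small validation splits the best-epoch rule can saturate early
  (accuracy ties resolve to the earliest epoch); on real-scale validation
  sets this is immaterial, and the injectable evaluator allows finer
  criteria where it is not.
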