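# Methods

## The model

The pipeline predicts a binary case/control outcome y from biallelic SNP
dosages x ∈ {0,1,2} in cohorts where cases are scarce (the defaults emulate
205 individuals with ~25% cases).  Its core is *preconditioned random forest
regression* (PRFR):

1. **Univariate screen.**  Each QC-passing SNP is tested against case status
   with the Cochran–Armitage trend test at scores (0,1,2).  The trend
   statistic is algebraically identical to the Rao score test of a logistic
   regression of outcome on dosage (an equality the test suite checks to
   1e-8 on random tables), so "chi-square under an additive model" and
   "logistic score test" are the same screen.  SNPs with p < 0.001 (strict)
   proceed.  The cutoff trades false negatives against the dimensionality a
   small-n model can bear; most SNPs passing it in a null cohort are false
   positives by construction, which is why a second, model-based filter
   exists downstream.

2. **Preconditioning.**  The filtered dosage columns are centered and
   scaled to unit variance; the first n_pc = 2 right singular vectors give
   component scores; a logistic regression of y on the scores with a small
   L2 penalty (1e-6) yields fitted probabilities ỹ ∈ [0,1] for the
   *training samples only*.  Validation outcomes stay binary.  The penalty
   keeps quasi-separated fits finite and deterministic; with it → 0 on
   non-separable data the fitted values converge to the unpenalized ones.
   Unit-variance scaling stops high-MAF SNPs from dominating the PCA.
   Component signs are fixed by making each loading's largest-magnitude
   entry positive, which makes the whole pipeline bit-reproducible.

3. **Regression forest.**  1000 CART trees, each grown on a bootstrap
   sample of size n drawn with replacement, terminal leaves ≥ 5 samples,
   mtry = ⌊√p⌋ candidate features per split.  A tree predicts the mean ỹ of
   the terminal leaf; the forest prediction is the mean over trees — a
   continuous risk score, never thresholded.  The bootstrap is drawn in the
   package (base trees are scikit-learn CARTs) so each tree's out-of-bag
   (OOB) membership is retained.

4. **Permutation importance (VIM).**  Per tree and feature, the feature's
   values are shuffled across that tree's OOB samples and the increase in
   OOB MSE over the unshuffled baseline recorded; the VIM is the raw mean
   increase over trees (unscaled — not divided by its across-tree SD).
   Ranks descend by VIM with ties broken by SNP id.  Trees with no OOB
   samples are skipped.

5. **VIM re-filtering.**  The top 25/50/75% of SNPs by VIM (count =
   round-half-up of fraction × n, all value-ties at the boundary included)
   are re-modeled; the fraction maximizing validation AUC defines the SNP
   set carried into annotation.

## Evaluation protocol

The cohort is split once into training and validation, stratified exactly
on case/control (rounded half-up; a 205/52 cohort gives 137 training with
35 cases and 68 validation with 17).  Further balance on clinical variables
is greedy: among 1,000 seeded candidate splits, the one minimizing the
lexicographic imbalance vector over the priority variables (standardized
mean difference for continuous, total-variation distance for categorical)
wins — a perfect split is generally unattainable, so earlier variables take
priority.

Within the training set, shuffled 5-fold CV is repeated 100 times.  *Every*
fold refits the whole pipeline — univariate filter, preconditioning, model —
on its 80% portion and scores the fixed validation set, giving 500 hold-out
AUCs per model family.  AUC is the Mann–Whitney concordance (ties 1/2); its
one-sided p-value uses exact enumeration for small tie-free samples and the
tie-corrected normal approximation otherwise; the CI around a single AUC is
a stratified percentile bootstrap (2,000 resamples, cases and controls
resampled separately).  Families are compared with Welch's t-test on their
AUC vectors.  Comparators: a classification forest on the raw binary
outcomes, L1-penalized logistic regression (penalty at minimum
cross-validated deviance), an L1 least-squares fit to the preconditioned
outcomes, and a logistic model on the first 3 unsupervised (ancestry) PCs
of all QC-passing SNPs.

**Leakage guard.**  Refitting the univariate filter inside each fold is
load-bearing: a deliberately leaky variant (filter fitted once on the full
training set, kept in the package as a test fixture) inflates out-of-fold
AUC on a null cohort from ~0.50 to well above 0.9 — the classic
feature-selection bias.  The fixed hold-out validation set is immune to
this particular leak (selection never saw it), so the guard is demonstrated
on out-of-fold scoring.

If a fold's filter returns fewer than n_pc SNPs (possible on null cohorts),
the n_pc most-associated SNPs are used instead of aborting the whole
repeated-CV run; a warning is logged.

## Synthetic cohorts

The generator emulates what the analysis assumes and nothing more:

* **Genotypes.**  Per-SNP MAF uniform on a configurable range (default
  0.05–0.5); independent SNPs are two Bernoulli(MAF) allele draws summed
  (Hardy–Weinberg by construction).  LD blocks, when requested, threshold
  exchangeably-correlated latent Gaussians at the HWE genotype-frequency
  quantiles — per-SNP margins stay HWE while within-block dosage
  correlation becomes tunable.
* **Outcomes.**  logit P(case) = β₀ + Σ βⱼ(xⱼ − 2·MAFⱼ) with β₀ solved by
  bisection so the mean case probability hits the target prevalence
  (default 52/205 ≈ 0.254) to 1e-4.  Centering the dosages decouples the
  intercept solve from the MAFs.
* **Covariates.**  Seven clinical variables (menarche age group, family
  history, treatment, parity, registry, age at diagnosis, radiation dose)
  with realistic marginals but *no* outcome effect — mirroring the
  motivating cohort, where no clinical variable reached p < 0.05 and the
  model used SNPs only.
* **Missingness.**  Each cell independently missing with a configurable
  rate; imputation fills the per-SNP modal dosage (ties toward the smaller
  dosage) — a deliberately simple stand-in adequate for sporadic
  missingness, not a reference-panel imputation.

Not emulated: recombination-map LD, population stratification, relatedness,
dosage-uncertainty genotypes.  Passing tests therefore certify the
machinery and its calibration under the stated generative model, not
robustness to structure or relatedness in real cohorts (the λ diagnostic
and ancestry-PC baseline exist to flag the former).

## Numerical and design choices

* Association tests run pre-imputation with pairwise deletion of missing
  dosages; model fitting runs post-imputation on complete matrices.
* QC order is fixed: sample missing rate → SNP missing rate → MAF → HWE
  (cases and controls pooled; HWE is an array-QC filter here, not an
  analysis filter).  Keep rules: MAF ≥ 0.01 and missing ≤ 0.05 inclusive,
  HWE p strictly > 1e-5.
* HWE uses the 1-df chi-square goodness of fit (monomorphic SNPs: p = 1),
  not the exact test.
* λ = median(χ²)/0.4549364231; QQ bands come from Beta(i, n−i+1) order
  statistics.
* Internal coordinates are 1-based inclusive everywhere; only the BED
  reader converts.  Gene mapping measures distance to the nearest gene
  boundary (0 inside), window inclusive at 50,000 bp.
* Gene-set enrichment is the upper-tail hypergeometric test with
  Benjamini–Hochberg FDR (significant at fdr_p ≤ 0.05 inclusive); LD
  expansion treats r² pairs as undirected with r² ≥ 0.8 inclusive.
* All stage seeds derive from one master seed as sha256(master:stage)
  truncated to 31 bits; identical config + seed reproduces a run directory
  byte for byte.

## Problem sizes in the test suite

Statistical checks run at sizes chosen to make their bands sharp but the
suite practical: null calibration on a 200 × 20,000 cohort with 10×5-fold
CV; signal recovery on 2,000 × 5,000 with 30 causal SNPs (OR 1.5–2) at
10×5-fold; the acceptance script scales the causal cohort to 1,200
individuals and 5 repeats.  The VIM signal-recovery check trains the
importance forest on the causal SNPs plus an equal number of *randomly
drawn* null SNPs (preconditioning still fitted on the pipeline's filtered
set): association-selected nulls are selection-biased and genuinely enter
the preconditioned target, so they are not an exchangeable null group for
an importance comparison.

## Known limitations

* The modal-dosage imputation ignores LD; it is adequate only for sporadic
  missingness after the ≤ 5% missing-rate QC.
* The supervised PCA uses a fixed association threshold, not the
  cross-validated threshold search of the full Bair–Tibshirani procedure.
* No covariate-adjusted or mixed-model association; stratification control
  is limited to the λ diagnostic and the ancestry-PC baseline.
* X-chromosome dosages are treated like autosomes.
* LASSO selection frequency resamples 80% training subsets; other
  resampling schemes would give somewhat different frequencies.
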