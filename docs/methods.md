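# Methods

This note documents the models implemented in `neurosig`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely
open.

## Case-control GLMs

Every feature of a panel is fit by ordinary least squares with diagnostic
group as a reference-coded categorical (controls as reference) and the
panel's covariate set:

| panel        | covariates                                              |
|--------------|---------------------------------------------------------|
| connectivity | age, age², age×sex, sex, head motion, site              |
| thickness    | age, age², age×sex, sex, site                           |
| cognition    | age, age², age×sex, sex, testing centre (= site column) |

optionally plus the three PRS columns (all-in or all-out; mixing subsets of
genetic covariates is disallowed because the scores are correlated and a
partial set changes the interpretation of the remaining ones). Age is
centered before squaring: the raw age/age² pair in a cohort aged 45–82 is
nearly collinear, and centering improves conditioning without changing the
group contrasts. Site enters as reference-coded indicators — linear site
effects, no site-by-covariate interactions.

Numerically, one QR decomposition of the shared design is reused across
the whole feature panel, so a 1,000-permutation refit over several hundred
features costs a few matrix products per permutation rather than per
feature. Tests verify per-feature equivalence with `statsmodels.OLS` to
1e-8.

The joint group effect is the F statistic of the group-indicator block
(full vs group-free design). Its significance comes from permutation:
shuffle the outcome rows, refit, compare. The permutation p-value uses the
(1+b)/(1+n_perm) convention so that p is never zero and ties count against
rejection. Naive outcome shuffling is the default (the design matrix is
never permuted); a Freedman–Lane scheme — permute only the covariate-model
residuals and add the covariate fit back, preserving covariate association
under the null — is available via `scheme="freedman-lane"`. Per-feature
independent shuffling is available via `mode="independent"`, while the
default applies one row permutation to the whole panel per iteration,
preserving inter-feature correlation under the null.

Per-contrast t statistics convert to Cohen's d via `d = 2t/√df` (so
t = 5 at df = 12,203 is d = 0.09). Post hoc case-vs-control contrasts are
flagged at p < 0.0125 (Bonferroni over the four case groups). Cognitive
outcomes are z-scored over the complete-case analysis sample before
fitting, making group betas standardized effect sizes; the
group-by-test p-value family is corrected by Benjamini–Hochberg FDR with
the family size left to the caller (default: all group×test p-values
jointly — the natural reading when four groups are each tested on four
outcomes).

## Control matching

Greedy exact matching on (sex, integer age), sampling controls without
replacement, case order randomized by seed because greedy exact matching is
order-dependent. Exhausted strata produce `unmatched_case_ids` rather than
approximate matches — no caliper widening, no nearest-neighbour fallback —
so the caller can decide whether to drop unmatched cases or rerun with a
different seed. Both counts are reported.

## Disorder similarity

Signatures are correlated with plain Pearson r; connectivity and thickness
panels are never mixed in one call. The permutation null refits the
*identical* GLM on row-permuted outcomes and recomputes all pairwise
correlations, with one shared permutation per iteration across contrasts.
This matters: all case-vs-control contrasts share the control group, which
alone induces a positive correlation between their t vectors (about
`1/(1 + n_ctrl/n_case)` scaled across the two contrasts — ≈ 0.5 for equal
group sizes, ≈ 0.14 when controls outnumber cases six-fold). A null that
broke this dependence would overstate significance of ordinary
shared-control correlation. p-values are two-sided on |r| by default
(conservative); a one-sided option exists.

Two consequences worth knowing when planting or interpreting signatures:

* because Pearson r centers each vector, a signature whose effects all
  share one sign has a shifted mean, and disjoint supports then
  *anticorrelate* through the means; realistic mixed-sign effects do not.
* a planted "50% shared support" between two disorders yields a signal
  correlation of ~0.5, which is only detectable against the shared-control
  baseline when the control group is larger than the case groups (as it is
  in population cohorts).

`compare_similarity_settings` reports elementwise r deltas between analysis
settings (e.g. with vs without PRS covariates) against the first-named
setting.

## Brain-cognition PLS

Confound residualization is a fitted transform (`ConfoundResidualizer`):
OLS projection on the confound design, then z-scoring with the training
residuals' mean/SD. In hold-out evaluation the transform is fitted on the
training folds and applied to the test fold by default — the
whole-sample single-pass variant is available (`leakage_free=False`) but
leaks test-set means into training.

The PLS itself is PLS2 (NIPALS, via scikit-learn) with `scale=False` on
the already-standardized residuals. Per-component % variance of Y explained
is the marginal gain of the cumulative reconstruction
`Ŷ_c = T_{1..c} Q'_{1..c}`; the sum over retained components equals
1 − SSE/SST of the full regression prediction (asserted to 1e-8 in tests).
Three components are retained by default, with the retained count a
configuration knob; joint significance is a permutation test of the
*total* % variance (rows of Y permuted; permuting X instead is selectable).

Bootstrap ratios: resample rows with replacement (optionally stratified by
diagnosis), refit, align replicate components to the full-sample solution
by greedy maximal-|correlation| matching of weight vectors with sign flips
(PLS components have sign and, occasionally, order indeterminacy), then
Z = full-sample weight / bootstrap SD of the aligned weights, thresholded
at |Z| > 3. Resamples that leave a constant column are redrawn and counted.
Under the null the |Z| > 3 rate behaves like 2Φ(−3) ≈ 0.0027, which the
acceptance test checks against the exact binomial envelope.

Per-group PLS is the same code path as the pooled analysis — only the row
selection differs; a row-permutation-invariance test pins this down.

## Cognition PCA and group comparison

PC1 is extracted from the z-scored test battery; loadings are unit-norm
with the sign fixed so the largest-|loading| test loads positively (the
correlation signs downstream depend on this, so the convention is explicit).
By default loadings are fitted pooled and scores computed per group, which
keeps scores comparable across groups; per-group PCA is available.
Correlation differences use Fisher's r-to-z with the standard
√(1/(n₁−3)+1/(n₂−3)) denominator, flagged at |Z| > 1.96 uncorrected — this
scan is reported as exploratory and no multiplicity correction is applied.

## Polygenic scores

QC thresholds are strict inequalities (INFO > 0.8, HWE p > 1e-10,
missingness < 5%, MAF > 0.1%); a variant exactly at a boundary is excluded.
LD pruning after p < 0.05 thresholding is greedy **best-p-first**: variants
are ranked by ascending p (ties: higher minor-allele frequency first — the
frequency-informed rule — then position) and kept only if no already-kept
variant on the same chromosome within 500 kb has in-sample genotype
r² ≥ 0.5. Best-p-first realizes "remove the higher-p member of every
violating pair" globally and guarantees the output invariant that no
surviving pair within the window violates the r² bound — a position-order
scan with eviction cannot guarantee the p-value preference in chains of
violations. In-sample genotypes (mean-imputed) provide the LD estimates;
no external reference panel is used. Scoring is the weighted allele-count
sum with per-variant mean imputation of missing calls; scores are z-scored
over the reference sample and residualized on the first 10 genotype PCs.

Allele harmonization (strand flips, ambiguous A/T-C/G variants) is out of
scope; synthetic summary statistics are pre-harmonized by construction.

## The synthetic-data generator

`generate_cohort` emulates, at the post-preprocessing level, the data
structure the analyses assume. What it reproduces:

* five mutually exclusive groups with study-scale defaults — group sizes
  21,727 / 3,233 / 664 / 676 / 832; ages ~63 ± 7.5; ~50% female controls
  vs ~64% female cases; three sites; head motion elevated in cases
  (0.13 vs 0.11); active-symptom and medication flags at group-specific
  rates; PRS columns with small case-group elevations;
* covariates that genuinely confound the features (per-feature coefficients
  drawn once per call: age scale 0.01/yr, sex 0.05, motion 0.5 on
  connectivity only, site offsets 0.05 — all in residual-SD units);
* group mean shifts applied **additively on the post-covariate residual
  scale in units of noise_sd**, so a planted shift of d is exactly the
  Cohen's d the GLM estimates (this makes parameter recovery testable to
  closed-form tolerances). The default imaging effect map plants |d| ≈ 0.1
  (1.3× for the comorbid group) on 40 connectivity / 60 thickness features
  with 50% sharing among the depressive/anxiety trio and a small disjoint
  stress-related signature; default cognition effects are the study-scale
  standardized deficits (largest: −0.28 SD on DSST for the comorbid group;
  TMT oriented so larger = worse);
* a rank-1 (optionally rank-k) latent factor linking 20 connectivity
  features (loadings ±0.5) to all four cognitive tests (loadings ±0.18,
  i.e. ~3% of each test's variance) — the target of the PLS stage;
* block-structured residual correlation (network-pair blocks for
  connectivity, 12 contiguous blocks for thickness, within-block r = 0.2 by
  default). The true covariance of real connectivity panels is not
  prescribed anywhere, so this is a declared modelling choice, exposed as
  `block_correlation`;
* completely-at-random cognition missingness (default 12% per cell, which
  leaves ~60% of cases complete on all four tests; the analyses are
  complete-case).

What it does **not** emulate: raw images, time series, or IC
decomposition; spatial autocorrelation of cortical maps; informative
(non-random) missingness; site-by-covariate interactions; genetic
relatedness between participants. Passing tests therefore demonstrate
correctness of the statistical machinery under the stated generative
assumptions, not robustness to violations real data may exhibit.

`generate_genotypes` draws each haplotype allele as a thresholded Gaussian
whose latent variables share a block factor (correlation `ld_rho` within
LD blocks), giving allele-frequency-faithful counts in {0, 1, 2} with
higher within- than between-block genotype correlation, plus
missing-at-random calls. One seeded RNG stream drives each generate call;
identical configs are bitwise-reproducible.

`assign_network_label` maps a component's voxel scores onto an atlas:
voxels strictly above the threshold (z > 3 by default) are counted per
network, proportions include an "unassigned" bin (which never wins the
label), and a component with no supra-threshold voxel is explicitly
unassignable rather than an error.

## Pipeline driver

`run_pipeline` executes simulate/load → match → case-control (per
covariate set) → similarity (per setting) → PLS → group comparison from a
single config. Sensitivity analyses (`active_only`, `unmedicated_only`)
are row filters feeding the identical stage code. Every run writes a
provenance record (config hash, seeds, package version); re-running a
config reproduces all outputs bitwise.

## Problem sizes used in the test suite

Simulation-backed tests are sized to where each property is decidable:
type-I calibration of the permutation tests uses 200 replicates of n = 500
cohorts with 200 permutations each; signature-recovery scenarios use
800 cases/group against 4,800 controls (d = 0.2); PLS factor recovery uses
n = 3,000 with 200 permutations and 500 bootstrap resamples; desk-scale
identities (effect-size conversion, fold sizes, pruning fixtures) are
exact. The p-value floors and binomial envelopes quoted in the tests are
derived from these sizes.

## Known limitations

* The GLMs are ordinary least squares — no robust/heteroscedastic errors,
  no mixed effects for site.
* The similarity permutation null uses naive outcome shuffling only; the
  Freedman–Lane option exists for the group-F test but is not wired into
  the similarity refit.
* LD pruning is in-sample; with small n the r² estimates are noisy.
* The generator's block-correlation and confound-coefficient defaults are
  plausible but not estimated from real data.
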