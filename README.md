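# neurosig

Statistical pipeline for deriving **disorder-specific neural signatures**
from multimodal population-imaging data, quantifying **cross-disorder
similarity** with permutation nulls, and relating **functional connectivity
to cognitive function** via partial least squares (PLS) regression with
bootstrap feature selection — together with a synthetic-cohort generator
that makes every stage testable without access-restricted data.

The package targets biobank-style case–control studies of major depressive
disorder (MDD), anxiety disorders (ANX), their comorbidity (MDD+ANX), and
stress-related disorders (STR) against healthy controls, with 210
functional-connectivity features (all pairs of 21 independent components),
360 regional cortical-thickness features, four cognitive tests (TMT, Gf,
PAL, DSST), and polygenic risk scores (PRS).

## The statistics at the core

**Neural signatures.** Each feature *y* is modelled by OLS,

```
y ~ group + age + age² + age×sex + sex + (motion) + site [+ PRS_MDD + PRS_ANX + PRS_PTSD]
```

with group reference-coded against controls (motion enters for connectivity
only). The per-feature *t* statistics of one case-vs-control contrast form
that disorder's signature; *t* converts to Cohen's d via **d = 2t/√df**
(t = 5 at df = 12,203 ↔ d = 0.09). The joint group effect is an F test
assessed by outcome permutation (n = 1,000, P_PERM < 0.05), with Bonferroni
post hoc contrasts at p < 0.0125. Cognitive outcomes are z-scored before
fitting so group betas are SD units, with Benjamini–Hochberg FDR (q < 0.05).

**Disorder similarity.** Pearson correlation between two contrasts'
signature vectors over a common panel; significance from a refit null —
permute the outcome rows, refit every contrast's GLM, recompute the pairwise
correlations (P_PERM < 0.01). The null preserves the dependence induced by
the shared control group.

**Brain–cognition PLS.** Age/sex/site (+motion for fMRI) are regressed out
of both sides; z-scored residuals form X (n × 210) and Y (n × 4). PLS2
extracts components maximizing cov(Xw, Yc); inference by (i) permutation of
Y against total % variance explained, (ii) bootstrap ratios
(weight / bootstrap SD, n = 5,000, threshold |Z| > 3), and (iii) 4-fold
hold-out (train 75% / test 25%) correlating predicted with observed
cognition.

**Group comparison.** Cognition is reduced to its first principal
component; per-feature correlations with PC1 are compared between two
groups with Fisher's r-to-z:
`Z = (atanh r₁ − atanh r₂) / √(1/(n₁−3) + 1/(n₂−3))`, flagged at |Z| > 1.96.

**PRS.** Prune-and-threshold scoring: variant QC (INFO > 0.8,
HWE p > 1e-10, missingness < 5%, MAF > 0.1%), p < 0.05 thresholding, greedy
LD pruning to r² < 0.5 in a 500-kb window (frequency-informed tie-break),
additive scoring with mean imputation, standardization, and residualization
on 10 genotype PCs.

## Worked example

```python
import neurosig as ns

cfg = ns.SimulationConfig(
    n_per_group={"CTRL": 1200, "MDD": 400, "ANX": 250, "MDDANX": 250, "STR": 250},
    seed=7,
)
cohort, conn, thick, cog = ns.generate_cohort(cfg)

fit = ns.fit_feature_glm(cohort, thick, panel="thickness")
print(round(ns.t_to_d(fit.signature("MDD").abs().max(), fit.df_), 3))

sim = ns.permutation_null_similarity(cohort, conn, n_perm=500, seed=1)
print(sim.r.round(2))
print(sim.p_perm.round(3))
```

prints (Cohen's d of the strongest MDD thickness effect, then the
connectivity similarity matrix and its permutation p-values):

```
0.158
         MDD   ANX  MDDANX   STR
MDD     1.00  0.35    0.33  0.19
ANX     0.35  1.00    0.30  0.18
MDDANX  0.33  0.30    1.00  0.16
STR     0.19  0.18    0.16  1.00

          MDD    ANX  MDDANX    STR
MDD     0.000  0.062   0.080  0.655
ANX     0.062  0.000   0.084  0.501
MDDANX  0.080  0.084   0.000  0.617
STR     0.655  0.501   0.617  0.000
```

The gradient mirrors the planted structure: the depressive/anxiety pairs
correlate most and carry the smallest permutation p-values, while every
stress-related pair sits at the shared-control noise baseline. (At this
demonstration scale — a few hundred cases per group, d ≈ 0.1 — the 0.01
significance threshold is not yet reached; it is at study scale, as the
acceptance tests verify with larger planted cohorts.) The same analyses run
from the shell:

```bash
neurosig simulate --config sim.yaml --out data/
neurosig casecontrol --cohort data/cohort.tsv --features data/connectivity.tsv \
    --panel connectivity --nperm 1000 --seed 1 --out cc.tsv
neurosig pls --cohort data/cohort.tsv --features data/connectivity.tsv \
    --cognition data/cognition.tsv --nboot 5000 --seed 1 --out pls/
neurosig run --config pipeline.yaml --out results/
```

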