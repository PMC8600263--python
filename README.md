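# crosspas

Crosstalk-aware pathway activity scoring for prognostic subtyping of
expression cohorts with survival follow-up.

## The problem

Molecular subtypes of solid tumors (the motivating case is colorectal
cancer) are usually discovered from gene-level expression, which transfers
poorly across platforms and cohorts. Pathway-level features are more stable
and interpretable — but because curated pathways share genes ("crosstalk"),
whole-pathway activity scores are partially collinear and lose specificity.
`crosspas` implements a pipeline for building a prognostic subtype
classifier from *crosstalk-factored* pathway activity scores, for anyone
with: a genes × samples expression matrix per cohort (RNA-seq or
microarray, any monotone normalization), per-sample overall-survival
follow-up, and a gene-set collection in GMT format.

## The method

**Pathway activity score (PAS).** Each gene *g* is dichotomized within a
cohort at its median expression: samples strictly above the median score
+1, all others (ties included) −1. For a pathway *P* and sample *s*,

    PAS_P(s) = (1/|P|) Σ_{g∈P} score_g(s)  ∈ [−1, +1].

The score depends only on within-gene ranks, so any strictly increasing
per-gene transform — i.e. a platform change — leaves it unchanged, which is
what makes cross-cohort validation meaningful.

**Crosstalk decomposition.** Every pathway pair (P_i, P_j) sharing at least
3 genes is factored into three sub-pathways scored as features in their own
right: the shared set P_i ∩ P_j and the two specific remainders
P_i − (P_i ∩ P_j) and P_j − (P_i ∩ P_j).

**Survival screening.** Each feature gets a univariate Cox
proportional-hazards score test (the log-rank-type statistic, computed
vectorized over all features and verified against R's `coxph`). Per cohort:
keep the top 100 features (sure independence screening), decompose their
crosstalk, re-score, apply Benjamini–Hochberg and keep q < 0.01. Features
surviving in every training cohort form the final panel.

**Subtyping and classification.** K-means (k = 2…6; silhouette,
Calinski–Harabasz and a prognostic C-index select k) clusters the primary
cohort's 4:1 training split in panel-PAS space; clusters are named by
survival (G2 = aggressive, worst survival). A K-nearest-neighbor classifier
(5 neighbors, Minkowski power 2, leaf size 30) then assigns G1/G2 to
held-out and external samples; the fraction of G2 neighbors is the
continuous risk score.

**Evaluation.** Harrell's C-index, IPCW Brier score at median follow-up,
Kaplan–Meier curves with the log-rank test, and ROC-AUC.

Because every stage needs ground truth to be testable, the package ships a
synthetic study generator: multi-cohort expression with planted G1/G2
subtypes (expression effect size in SD units, exponential survival with a
chosen hazard ratio, calibrated uniform censoring), per-cohort monotone
platform transforms, and gene sets with designed overlaps.

## Worked example

The numbered scripts under `analysis/` run the default benchmark study
(seed 1): one RNA-seq-like cohort of 500 samples plus microarray-like
externals of 60, 60 and 200, hazard ratio 3 between planted subtypes,
effect size 1.5, ~30% censoring.

```sh
python analysis/01_simulate_cohorts.py
python analysis/02_discover_subtypes.py
```

prints

```
panel (15 features): ['P001', 'P006', 'P003', 'P005|P006|P006.spec', ...]
selected k = 2; training ARI vs planted truth = 1.000
held-out accuracy = 1.000, log-rank p = 2.07e-08
10-fold CV accuracy = 1.000
```

— the discovered panel is exactly the 6 planted prognostic pathways plus
their 9 crosstalk sub-pathways; clustering the training split recovers the
planted subtypes perfectly (adjusted Rand index 1.0), and the classifier
separates held-out survival (log-rank p ≈ 2×10⁻⁸).
`analysis/03_validate_external.py` tabulates C-index ≈ 0.58–0.64, Brier ≈
0.21–0.23 and log-rank p ≤ 0.006 across all cohort slices, and
`analysis/04_recovery_experiment.py` repeats the study over 20 seeds (joint
recovery in 19/20) with a hazard-ratio-1 null control whose held-out
log-rank p is uniform.

The same pipeline runs from the shell on your own files:

```sh
crosspas simulate --seed 1 --outdir sim/
crosspas discover --gmt sim/gene_sets.gmt \
    --cohort C1=sim/C1_expression.tsv:sim/C1_survival.tsv \
    --cohort C2=sim/C2_expression.tsv:sim/C2_survival.tsv \
    --seed 1 --outdir run/
crosspas predict --model-dir run/ --expr sim/C3_expression.tsv \
    --surv sim/C3_survival.tsv --outdir pred/
```

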