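# Methods

This note records how the pipeline's pieces are defined, the parameter
defaults and why, what the synthetic benchmark does and does not emulate,
and the numerical conventions (tie rules, degenerate inputs) that change
results on real data.

## Pathway activity score

A gene's expression row is split at its within-cohort quantile (default:
median). Samples strictly above the split score +1, all others −1; a
pathway's activity in a sample is the mean of its member genes' scores over
the genes present in the matrix. Consequences worth knowing:

* **Ties score −1.** "Strictly above the median" is the conservative
  reading of a +1-for-the-higher-group rule. On continuous data this only
  affects the one middle sample of odd-sized cohorts; on discrete or
  heavily rounded data it can push many samples into the −1 group, and a
  constant gene scores −1 everywhere (warned). The split quantile is
  configurable.
* **Rank invariance.** PAS depends only on within-gene ranks, so any
  strictly increasing per-gene transform leaves the matrix bit-identical.
  This is the formal content of "cross-platform" here, and it is what the
  synthetic microarray transform exercises.
* **Cohort-relative.** PAS is always computed within one cohort, never on
  merged cohorts: the median split is cohort-relative and merging platforms
  would break the invariance rationale. The pipeline recomputes panel PAS
  inside every cohort it touches, including prediction-time cohorts.
* Genes of a pathway absent from a matrix are dropped (counted per
  feature); a pathway with no present genes is dropped from scoring and is
  an error if it leaves nothing.

## Crosstalk decomposition

Pairs of pathways sharing ≥ `min_overlap` genes (default 3 — shared
categories below that are considered noise) are factored into the shared
gene set and the two pathway-specific remainders; empty remainders are
omitted, remainders of size 1–2 are kept (a configurable floor can raise
this). Feature ids are deterministic functions of the parent pathway ids
with pairs enumerated in lexicographic order, so the same sub-pathway gets
the same id in every cohort — required for the cross-cohort intersection.
Sub-pathways (or originals) with identical gene sets are collapsed onto one
feature to avoid perfectly collinear columns; merges are recorded.
Decomposition is applied to the post-screening pathway list, not the full
collection, and only pairwise crosstalk is modeled.

## Survival screening

Each feature is tested with a univariate Cox proportional-hazards model,
PAS as the single continuous covariate. The ranking p-value is the score
test at β = 0 — the log-rank-type statistic, identical to the two-sample
log-rank test for a binary covariate — and the reported coefficient is the
Breslow partial-likelihood estimate (Newton iteration, step clipped to ±2,
|β| capped at 15 with a `non_convergent` flag when the likelihood is
monotone). Both agree with R's `coxph` (score χ² and coefficient to ≥ 6
significant digits on tie-free data). The score test needs no iterative
fit, so screening is one vectorized pass over risk-set cumulative sums.
Zero-variance features get p = 1 and sink to the bottom rather than being
dropped, keeping output lengths predictable.

Per cohort the flow is: rank all pathway features by p → keep the top
`sis_d` = 100 (sure independence screening; ties at the boundary break
lexicographically) → decompose crosstalk among the screened pathways →
re-score the sub-pathway features → Benjamini–Hochberg within cohort →
keep q < `fdr_alpha` = 0.01. Features selected in **every** intersection
cohort form the panel, ordered by mean rank.

**Which cohorts gate the panel.** By default the intersection runs over the
`n_intersection_cohorts` = 2 largest cohorts; the remaining cohorts are
untouched validation sets. This is a deliberate power requirement: a cohort
with d events can at best produce score statistics with noncentrality
λ ≈ d·p(1−p)·ln²(HR), and at d ≈ 42 (n = 60, 30% censoring) and HR = 3
that gives λ ≈ 11 — barely 80% power at unadjusted α = 0.01 and roughly
55% after BH across ~100 features. A cohort of that size in the gate makes
the panel vanish in nearly half of otherwise identical studies; feature
*determination* should therefore be restricted to cohorts with adequate
event counts, with small cohorts reserved for validation. Both the count
and the explicit cohort list are configurable.

## Subtyping

K-means (squared Euclidean on raw PAS values — already bounded in [−1, 1],
so no standardization; 10 restarts, best inertia) for k = 2…6. Three
indices score each k: mean silhouette width, Calinski–Harabasz, and a
prognostic C-index defined here as Harrell's C of the cluster-wise survival
rank used as a per-sample risk score (clusters ordered by KM median
survival, restricted-mean survival time breaking ties — KM medians are
routinely undefined at realistic censoring — then cluster index). That
C-index definition is an interpretation: "prognostic difference of a
clustering" has no canonical scalar.

Aggregation: a k that outright wins more indices beats any mean-rank
arithmetic; remaining ties fall to best mean rank, then to the smaller k.
The wins-first rule matters because the cluster-rank C-index is nearly flat
in k (every k recovers the dominant survival split, and finer partitions
inflate C marginally), so pure mean rank lets a hair's-width C-index loss
overturn decisive silhouette and Calinski–Harabasz wins and drags k upward.

Clusters are named by survival: best KM median = G1, worst = G2,
intermediates G1a, G1b, … (the k > 2 naming is an extension; the reference
analyses only encountered k = 2). Identical survival ties break toward the
smaller cluster index. New samples are assigned by nearest centroid
(squared Euclidean, lower index on exact ties) and mapped through the same
labels.

## Classification

The KNN classifier memorizes the training panel matrix; prediction is a
majority vote among the 5 nearest training samples (Euclidean; leaf size 30
only tunes the search index and never changes predictions). The continuous
risk score is the fraction of neighbors labelled G2. Vote ties — impossible
at k = 5 with two classes, possible under overrides — break toward the
lower-risk label to avoid over-calling the aggressive subtype. Distance
weighting is uniform. The 4:1 train/test split is stratified by event
status (an unstratified split can starve the test set of events and break
the log-rank evaluation); stratification falls back to a plain random
split when a stratum has fewer than two members. Cross-validation is
stratified 10-fold, reducing the fold count to the minority class size
when needed.

## Evaluation

* **C-index**: Harrell's C via lifelines; pairs are usable when their
  ordering is determinable under censoring; risk ties count 0.5.
* **Brier**: IPCW (Graf) Brier score via scikit-survival, at t* = the
  cohort's median follow-up by default (reported alongside); the per-sample
  survival prediction is the KM curve of the sample's own predicted group
  within the evaluated cohort.
* **Log-rank**: two-or-more-sample statistic, χ² reference on
  (groups − 1) df.
* **AUC**: rank-based, over the classifier score against the clustering's
  own nearest-centroid assignment (model-recovery AUC) — the only reading
  under which a training/test AUC of an unsupervised subtype model is
  well-defined; a survival-at-horizon AUC is a different quantity and out
  of scope.

## Synthetic benchmark

The generator emulates the *structure* of a multi-platform survival study:
shared gene universe, designed pathway overlaps (consecutive pairs share
exactly `overlap_genes` genes, other pairs disjoint), two planted subtypes
(Bernoulli prevalence 0.4), prognostic-pathway genes shifted by
`effect_size` SD in G2, exponential event times (G1 mean 1500 days) with
the G2 hazard multiplied by `hazard_ratio`, and uniform administrative
censoring on [0, c_max] with c_max solved numerically for the target
censoring fraction (realized fraction within ±5 points of target for
n ≥ 300). Microarray-like cohorts pass every gene through
x → a·sinh(b·x) + c with gene-specific a, b > 0 — strictly increasing, so
PAS is provably identical across platforms of the same latent cohort.

Defaults, chosen once as a realistic desk-scale mirror of a four-cohort
colorectal study: cohort sizes (500, 60, 60, 200), 800 genes, 40 pathways
of 15 genes, overlap 5, 6 prognostic pathways, effect size 1.5, hazard
ratio 3, 30% censoring. The exponential event-time model gives closed-form
medians (scale·ln 2 / HR) used as oracles.

**What it does not emulate** — hence what passing tests do not show about
real data: gene–gene correlation beyond the subtype shift, library-size
and batch effects, non-proportional hazards, informative censoring,
overlapping/nested pathway hierarchies, or marginal distributions of any
real platform. Recovery rates measured here are upper bounds for cohorts
whose pathway effects are weaker or whose censoring is informative.

## Determinism

One integer seed drives everything: per-cohort generator seeds and
per-stage pipeline seeds (split, K-means, CV) are spawned with numpy's
`SeedSequence`, and two runs at the same seed produce bit-identical
manifests, models and predictions (asserted in tests). Problem sizes used
in the shipped analyses — 20 study replicates, 50 null cohorts for FDR
control, 100 random instances per metric oracle — keep every script in the
minutes range on a single CPU while leaving Monte-Carlo error well inside
the asserted tolerances.

## Known limitations

* The FDR-gate power analysis above means studies whose *largest* cohorts
  are small (≲ 100 events) will often produce empty panels at q < 0.01;
  the error message suggests relaxing `fdr_alpha` or changing the
  intersection set, but no automatic fallback is attempted.
* PAS discards all within-group magnitude information by design; genes
  informative only in their tails lose signal.
* The prognostic C-index used in k selection is computed in-sample; it is
  a ranking heuristic, not an unbiased performance estimate.
* Survival modeling is univariate throughout — no multivariate or
  penalized Cox, no time-varying covariates, no competing risks.
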