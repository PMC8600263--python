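"""Synthetic multi-cohort expression + survival studies with planted subtypes.

The generator emulates the structure of a multi-platform colorectal-cancer
study — one large RNA-seq-like primary cohort and several smaller
microarray-like cohorts sharing a gene universe — with ground truth for
every downstream stage:

* two planted prognostic subtypes, G1 (moderate) and G2 (aggressive);
* gene sets with controlled pairwise overlap, so crosstalk decomposition
  has known intersections to find;
* genes of designated prognostic pathways shifted in G2 by a chosen effect
  size (in within-gene SD units), all other genes i.i.d. noise;
* exponential event times with the G2 hazard multiplied by a chosen hazard
  ratio, under administrative uniform censoring calibrated numerically to a
  target censoring fraction;
* for microarray-like cohorts, a gene-specific strictly increasing
  nonlinear transform x -> a*sinh(b*x) + c of the latent values, which
  changes every marginal distribution but no within-gene rank — the PAS
  matrix is provably identical on both platforms.

Defaults are the study conditions used throughout the package's analyses:
cohort sizes (500, 60, 60, 200), 40 pathways of 15 genes with 5 shared
genes on consecutive pairs, 6 prognostic pathways, effect size 1.5,
hazard ratio 3, 30% censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .io_formats import ExpressionMatrix, GeneSetCollection, SurvivalTable

RNASEQ_LIKE = "rnaseq_like"
MICROARRAY_LIKE = "microarray_like"


@dataclass
class SimulationConfig:
    """All knobs of one synthetic cohort; defaults are the package's study conditions."""

    n_samples: int = 500
    n_genes: int = 800
    n_pathways: int = 40
    genes_per_pathway: int = 15
    overlap_genes: int = 5
    n_prognostic_pathways: int = 6
    effect_size: float = 1.5  # G2 mean shift of prognostic-pathway genes, in SD units
    hazard_ratio: float = 3.0  # G2 vs G1
    baseline_scale: float = 1500.0  # mean G1 survival, days (exponential scale)
    censoring_rate: float = 0.30  # target fraction censored
    subtype_prevalence: float = 0.40  # fraction of G2
    platform: str = RNASEQ_LIKE
    seed: int = 0
    cohort_id: str = "C1"

    def __post_init__(self) -> None:
        if self.overlap_genes > self.genes_per_pathway:
            raise ValueError("overlap_genes cannot exceed genes_per_pathway")
        if not 0 < self.subtype_prevalence < 1:
            raise ValueError("subtype_prevalence must be in (0, 1)")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must be in [0, 1)")
        if self.hazard_ratio <= 0 or self.baseline_scale <= 0:
            raise ValueError("hazard_ratio and baseline_scale must be positive")
        if self.platform not in (RNASEQ_LIKE, MICROARRAY_LIKE):
            raise ValueError(f"unknown platform {self.platform!r}")
        if self.n_prognostic_pathways > self.n_pathways:
            raise ValueError("more prognostic pathways than pathways")


@dataclass
class SyntheticCohort:
    expr: ExpressionMatrix
    surv: SurvivalTable
    true_labels: list[str]  # "G1"/"G2" per sample, aligned with expr.sample_ids
    truth: SimulationConfig = field(repr=False)


def generate_gene_sets(config: SimulationConfig) -> GeneSetCollection:
    """Pathway collection with exact, designed pairwise overlaps.

    Consecutive pathway pairs (P01,P02), (P03,P04), ... share exactly
    ``overlap_genes`` genes; all other pairs are disjoint.  Gene ids are
    G0001..G{n_genes}; genes not assigned to any pathway are background.
    """
    gpp, ov = config.genes_per_pathway, config.overlap_genes
    n_pairs, odd = divmod(config.n_pathways, 2)
    needed = n_pairs * (2 * gpp - ov) + odd * gpp
    if needed > config.n_genes:
        raise ValueError(
            f"gene budget insufficient: pathways need {needed} genes, have {config.n_genes}"
        )
    width = max(4, len(str(config.n_genes)))
    genes = [f"G{i + 1:0{width}d}" for i in range(config.n_genes)]
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    cursor = 0
    for k in range(config.n_pathways):
        pid = f"P{k + 1:03d}"
        if k % 2 == 0:
            members = genes[cursor : cursor + gpp]
            cursor += gpp
            shared = members[gpp - ov :] if ov else []
        else:
            members = shared + genes[cursor : cursor + gpp - ov]
            cursor += gpp - ov
        sets[pid] = (f"synthetic pathway {k + 1}", frozenset(members))
    return GeneSetCollection(sets)


def prognostic_genes(config: SimulationConfig, gene_sets: GeneSetCollection) -> frozenset[str]:
    """Union of the first ``n_prognostic_pathways`` pathways' genes."""
    ids = gene_sets.ids()[: config.n_prognostic_pathways]
    out: set[str] = set()
    for pid in ids:
        out |= gene_sets.genes(pid)
    return frozenset(out)


def censoring_horizon(config: SimulationConfig) -> float:
    """Upper bound c_max of the uniform censoring window hitting the target rate.

    With T exponential (mixture over subtypes) and C ~ U(0, c_max),
    P(censored) = E[S(C)] = (1/c_max) * sum_g pi_g (1 - exp(-lam_g c_max)) / lam_g,
    solved for c_max by bisection.  Returns inf when censoring_rate = 0.
    """
    if config.censoring_rate == 0:
        return np.inf
    lam1 = 1.0 / config.baseline_scale
    lam2 = config.hazard_ratio / config.baseline_scale
    pi2 = config.subtype_prevalence

    def p_cens(c: float) -> float:
        return (
            (1 - pi2) * (1 - np.exp(-lam1 * c)) / lam1
            + pi2 * (1 - np.exp(-lam2 * c)) / lam2
        ) / c

    lo, hi = 1e-6 * config.baseline_scale, 1e4 * config.baseline_scale
    return float(brentq(lambda c: p_cens(c) - config.censoring_rate, lo, hi, xtol=1e-9))


def _platform_transform(latent: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Gene-specific strictly increasing map x -> a*sinh(b*x) + c, a,b > 0."""
    n_genes = latent.shape[0]
    a = rng.uniform(0.5, 3.0, size=(n_genes, 1))
    b = rng.uniform(0.3, 2.0, size=(n_genes, 1))
    c = rng.normal(0.0, 2.0, size=(n_genes, 1))
    return a * np.sinh(b * latent) + c


def generate_cohort(config: SimulationConfig, gene_sets: GeneSetCollection) -> SyntheticCohort:
    """One cohort: expression, right-censored survival, true subtype labels."""
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = [f"{config.cohort_id}_S{i + 1:04d}" for i in range(n)]
    is_g2 = rng.random(n) < config.subtype_prevalence
    labels = ["G2" if g else "G1" for g in is_g2]

    width = max(4, len(str(config.n_genes)))
    gene_ids = [f"G{i + 1:0{width}d}" for i in range(config.n_genes)]
    latent = rng.normal(size=(config.n_genes, n))
    prog = prognostic_genes(config, gene_sets)
    prog_rows = [i for i, g in enumerate(gene_ids) if g in prog]
    latent[np.ix_(prog_rows, np.nonzero(is_g2)[0])] += config.effect_size

    values = latent
    if config.platform == MICROARRAY_LIKE:
        values = _platform_transform(latent, rng)
    expr = ExpressionMatrix(gene_ids, sample_ids, values)

    lam = np.where(is_g2, config.hazard_ratio, 1.0) / config.baseline_scale
    event_time = rng.exponential(1.0 / lam)
    c_max = censoring_horizon(config)
    if np.isfinite(c_max):
        cens_time = rng.uniform(0.0, c_max, size=n)
        time = np.minimum(event_time, cens_time)
        event = (event_time <= cens_time).astype(int)
    else:
        time, event = event_time, np.ones(n, dtype=int)
    time = np.maximum(time, 1e-6)
    surv = SurvivalTable(sample_ids, time, event)
    return SyntheticCohort(expr, surv, labels, config)


def default_study_configs(
    seed: int,
    sizes: tuple[int, ...] = (500, 60, 60, 200),
    platforms: tuple[str, ...] | None = None,
    **overrides,
) -> list[SimulationConfig]:
    """Configs for the default study: one RNA-seq-like primary + microarray externals.

    Per-cohort seeds are spawned deterministically from ``seed``; any keyword
    override (hazard_ratio, effect_size, ...) applies to every cohort.
    """
    if platforms is None:
        platforms = (RNASEQ_LIKE,) + (MICROARRAY_LIKE,) * (len(sizes) - 1)
    if len(platforms) != len(sizes):
        raise ValueError("sizes and platforms lengths differ")
    child_seeds = np.random.SeedSequence(seed).generate_state(len(sizes)) & 0x7FFFFFFF
    base = SimulationConfig(**overrides) if overrides else SimulationConfig()
    return [
        replace(
            base,
            n_samples=sz,
            platform=pl,
            seed=int(cs),
            cohort_id=f"C{i + 1}",
        )
        for i, (sz, pl, cs) in enumerate(zip(sizes, platforms, child_seeds))
    ]


def generate_multi_cohort_study(
    configs: list[SimulationConfig],
) -> tuple[GeneSetCollection, list[SyntheticCohort]]:
    """Cohorts sharing one gene universe and gene-set collection.

    All configs must agree on the gene-space parameters; samples, platform
    transforms and survival draws are independent across cohorts.
    """
    ref = configs[0]
    for cfg in configs[1:]:
        same = (
            cfg.n_genes == ref.n_genes
            and cfg.n_pathways == ref.n_pathways
            and cfg.genes_per_pathway == ref.genes_per_pathway
            and cfg.overlap_genes == ref.overlap_genes
            and cfg.n_prognostic_pathways == ref.n_prognostic_pathways
        )
        if not same:
            raise ValueError("cohort configs disagree on the shared gene space")
    ids = [cfg.cohort_id for cfg in configs]
    if len(set(ids)) != len(ids):
        raise ValueError("cohort_ids must be unique")
    gene_sets = generate_gene_sets(ref)
    return gene_sets, [generate_cohort(cfg, gene_sets) for cfg in configs]
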