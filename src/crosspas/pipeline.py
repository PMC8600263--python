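"""End-to-end discovery and prediction orchestration.

The discovery flow, per cohort and in order: pathway PAS -> univariate Cox
ranking -> sure independence screen (top 100) -> pairwise crosstalk
decomposition of the screened pathways -> PAS on sub-pathways -> Cox +
Benjamini–Hochberg (FDR < 0.01) -> intersect the surviving feature ids
across the training cohorts into the final panel -> split the primary
cohort 4:1 -> K-means subtype discovery on the training split -> KNN
classifier -> predict held-out and external cohorts -> evaluate everything.

One integer seed reproduces a full run: per-stage seeds (split, K-means,
cross-validation) are spawned from it with numpy's SeedSequence, and the
manifest records every stage's input/output counts, so two runs with the
same seed produce bit-identical manifests, models and predictions.
"""

from __future__ import annotations

import json
import logging
import time as _time
from dataclasses import asdict, dataclass, field

import numpy as np

from . import classification, subtyping
from .crosstalk import build_crosstalk_features, subpathways_to_collection
from .evaluation import EvaluationReport, evaluate_cohort
from .io_formats import ExpressionMatrix, GeneSetCollection, SurvivalTable, align_cohort
from .pas import PASMatrix, compute_pas_matrix
from .survival_features import fdr_filter, intersect_cohorts, rank_by_survival, sis_screen

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline constants; defaults are the method's published settings."""

    sis_d: int = 100
    min_overlap: int = 3
    fdr_alpha: float = 0.01
    k_min: int = 2
    k_max: int = 6
    train_fraction: float = 0.8  # 4:1 split
    n_neighbors: int = 5
    leaf_size: int = 30
    minkowski_power: int = 2
    cv_folds: int = 10
    n_intersection_cohorts: int = 2
    intersection_cohorts: list[str] | None = None  # explicit cohort ids; None = largest
    quantile: float = 0.5
    seed: int = 0

    def stage_seeds(self) -> dict[str, int]:
        state = np.random.SeedSequence(self.seed).generate_state(3) & 0x7FFFFFFF
        return {"split": int(state[0]), "kmeans": int(state[1]), "cv": int(state[2])}


@dataclass
class Cohort:
    cohort_id: str
    expr: ExpressionMatrix
    surv: SurvivalTable


@dataclass
class DiscoveryResult:
    config: RunConfig
    panel_ids: list[str]
    panel_collection: GeneSetCollection
    subtype_model: subtyping.SubtypeModel
    classifier: classification.ClassifierModel
    split: classification.SplitSpec
    cv: dict
    predictions: dict[str, dict] = field(default_factory=dict)  # cohort -> {sample_id: (label, score)}
    evaluations: dict[str, EvaluationReport] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the manifest built so far."""

    def __init__(self, stage: str, manifest: dict, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest
        self.cause = cause


def _stage(name: str, manifest: dict):
    class _Ctx:
        def __enter__(self):
            self.t0 = _time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = _time.perf_counter() - self.t0
            logger.info("stage=%s wall=%.2fs", name, dt)
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(name, manifest, exc) from exc
            return False

    return _Ctx()


def _intersection_cohort_ids(aligned: list[Cohort], config: RunConfig) -> list[str]:
    """Cohorts whose FDR-passing features are intersected into the panel.

    Explicit ids win when configured; otherwise the ``n_intersection_cohorts``
    largest cohorts (ties by input order).  Larger cohorts carry the power
    the per-cohort FDR stage needs; the remaining cohorts stay untouched as
    pure validation sets.
    """
    if config.intersection_cohorts is not None:
        known = {c.cohort_id for c in aligned}
        missing = [cid for cid in config.intersection_cohorts if cid not in known]
        if missing:
            raise ValueError(f"unknown intersection cohorts: {missing}")
        if len(config.intersection_cohorts) < 2:
            raise ValueError("need at least 2 intersection cohorts")
        return list(config.intersection_cohorts)
    n = min(config.n_intersection_cohorts, len(aligned))
    by_size = sorted(
        range(len(aligned)), key=lambda i: (-aligned[i].expr.n_samples, i)
    )[:n]
    return [aligned[i].cohort_id for i in sorted(by_size)]


def run_discovery(
    cohorts: list[Cohort], gene_sets: GeneSetCollection, config: RunConfig
) -> DiscoveryResult:
    """Full discovery on aligned cohorts; the first cohort is the primary one."""
    if len(cohorts) < 2:
        raise ValueError("discovery needs at least 2 cohorts for the intersection step")
    seeds = config.stage_seeds()
    manifest: dict = {"seed": config.seed, "config": asdict(config), "cohorts": {}}

    aligned: list[Cohort] = []
    with _stage("align", manifest):
        for c in cohorts:
            expr, surv = align_cohort(c.expr, c.surv)
            aligned.append(Cohort(c.cohort_id, expr, surv))
            manifest["cohorts"][c.cohort_id] = {
                "n_samples": expr.n_samples,
                "n_genes": expr.n_genes,
                "n_events": int(surv.event.sum()),
            }

    per_cohort_selected: list[list[str]] = []
    feature_genes: dict[str, tuple[str, frozenset[str]]] = {}
    for c in aligned:
        m = manifest["cohorts"][c.cohort_id]
        with _stage(f"screen[{c.cohort_id}]", manifest):
            pas0 = compute_pas_matrix(c.expr, gene_sets, quantile=config.quantile)
            ranked = rank_by_survival(pas0, c.surv)
            screened = sis_screen(ranked, config.sis_d)
            m["n_pathways_scored"] = pas0.n_features
            m["n_screened"] = len(screened)
        with _stage(f"crosstalk[{c.cohort_id}]", manifest):
            screened_coll = GeneSetCollection(
                {pid: gene_sets.sets[pid] for pid in screened}
            )
            subs = build_crosstalk_features(screened_coll, min_overlap=config.min_overlap)
            sub_coll = subpathways_to_collection(subs)
            for fid, entry in sub_coll.items():
                feature_genes.setdefault(fid, entry)
            m["n_crosstalk_features"] = len(subs)
        with _stage(f"fdr[{c.cohort_id}]", manifest):
            pas1 = compute_pas_matrix(c.expr, sub_coll, quantile=config.quantile)
            stats = rank_by_survival(pas1, c.surv)
            selected, _ = fdr_filter(stats, alpha=config.fdr_alpha)
            per_cohort_selected.append(selected)
            m["n_fdr_selected"] = len(selected)

    with _stage("intersect", manifest):
        train_ids_ = _intersection_cohort_ids(aligned, config)
        selected_by_cohort = dict(zip([c.cohort_id for c in aligned], per_cohort_selected))
        panel_ids = intersect_cohorts([selected_by_cohort[cid] for cid in train_ids_])
        manifest["intersection_cohorts"] = train_ids_
        manifest["panel"] = panel_ids
        manifest["panel_size"] = len(panel_ids)
    panel_collection = GeneSetCollection({fid: feature_genes[fid] for fid in panel_ids})

    primary = aligned[0]
    with _stage("split", manifest):
        split = classification.split_train_test(
            primary.expr.sample_ids, primary.surv, seeds["split"],
            train_fraction=config.train_fraction,
        )
        manifest["split"] = {"n_train": len(split.train_ids), "n_test": len(split.test_ids)}

    # PAS is always recomputed within a cohort on the panel's gene sets: a
    # cohort's screened list need not contain every panel feature, and the
    # cohort-relative median split must never leak across cohorts.
    pas_primary = compute_pas_matrix(
        primary.expr, panel_collection, quantile=config.quantile
    ).subset_features(panel_ids)
    with _stage("subtype", manifest):
        feats_train = pas_primary.subset_samples(split.train_ids)
        surv_train = primary.surv.subset(split.train_ids)
        model = subtyping.fit_subtypes(feats_train, surv_train, seed=seeds["kmeans"])
        manifest["k_selected"] = model.k
        manifest["subtype_sizes"] = {
            l: model.training_labels.count(l) for l in sorted(set(model.training_labels))
        }

    with _stage("classify", manifest):
        X_train = feats_train.values.T
        clf = classification.train_knn(
            X_train, model.training_labels, panel_ids,
            n_neighbors=config.n_neighbors, leaf_size=config.leaf_size,
            minkowski_power=config.minkowski_power,
        )
        cv = classification.cross_validate(
            X_train, model.training_labels, folds=config.cv_folds, seed=seeds["cv"],
            n_neighbors=config.n_neighbors, leaf_size=config.leaf_size,
            minkowski_power=config.minkowski_power,
        )
        manifest["cv"] = {k: v for k, v in cv.items() if k != "notes"}

    result = DiscoveryResult(
        config=config, panel_ids=panel_ids, panel_collection=panel_collection,
        subtype_model=model, classifier=clf, split=split, cv=cv, manifest=manifest,
    )

    with _stage("evaluate", manifest):
        # training split: cluster labels + self-neighbor KNN score
        _, train_scores = classification.predict(clf, X_train)
        _record(result, f"{primary.cohort_id}:train", split.train_ids,
                model.training_labels, train_scores, surv_train, model, feats_train)
        # held-out split of the primary cohort
        feats_test = pas_primary.subset_samples(split.test_ids)
        test_labels, test_scores = classification.predict(clf, feats_test.values.T)
        _record(result, f"{primary.cohort_id}:test", split.test_ids,
                test_labels, test_scores, primary.surv.subset(split.test_ids),
                model, feats_test)
        # external cohorts: PAS always computed within the cohort
        for c in aligned[1:]:
            feats_ext = compute_pas_matrix(
                c.expr, panel_collection, quantile=config.quantile
            ).subset_features(panel_ids)
            labels, scores = classification.predict(clf, feats_ext.values.T)
            _record(result, c.cohort_id, c.surv.sample_ids, labels, scores,
                    c.surv, model, feats_ext)
    manifest["evaluations"] = {
        cid: rep.to_dict() for cid, rep in sorted(result.evaluations.items())
    }
    return result


def _record(result, key, sample_ids, labels, scores, surv, model, feats):
    """Store predictions and the evaluation report for one cohort slice."""
    result.predictions[key] = {
        s: {"label": l, "score": float(sc)} for s, l, sc in zip(sample_ids, labels, scores)
    }
    # model-recovery reference: the clustering's own nearest-centroid assignment
    centroid_labels = subtyping.assign_subtype(model, feats)
    auc_truth = np.array([l == "G2" for l in centroid_labels], dtype=int)
    if len(np.unique(auc_truth)) < 2:
        auc_truth = None
    result.evaluations[key] = evaluate_cohort(
        key, labels, scores, surv, auc_truth=auc_truth
    )


def run_predict(
    panel_collection: GeneSetCollection,
    classifier: classification.ClassifierModel,
    cohort: Cohort,
    *,
    quantile: float = 0.5,
    subtype_model: subtyping.SubtypeModel | None = None,
) -> tuple[dict, EvaluationReport | None]:
    """Score a new cohort: PAS within the cohort on the panel's gene sets, then KNN.

    Survival is optional; without it only labels/scores are returned.  Panel
    features whose genes are entirely absent from the cohort abort with a
    per-feature coverage listing.
    """
    gene_pool = set(cohort.expr.gene_ids)
    coverage = {
        fid: (len(panel_collection.genes(fid) & gene_pool),
              len(panel_collection.genes(fid)))
        for fid in classifier.feature_ids
    }
    missing = [fid for fid, (present, _) in coverage.items() if present == 0]
    if missing:
        raise ValueError(
            f"panel features with no genes in cohort {cohort.cohort_id}: {missing}; "
            f"coverage (present/total) per feature: {coverage}"
        )
    pas = compute_pas_matrix(cohort.expr, panel_collection, quantile=quantile)
    pas = pas.subset_features(classifier.feature_ids)
    labels, scores = classification.predict(classifier, pas.values.T)
    predictions = {
        s: {"label": l, "score": float(sc)}
        for s, l, sc in zip(pas.sample_ids, labels, scores)
    }
    report = None
    if cohort.surv is not None:
        _, surv = align_cohort(cohort.expr, cohort.surv)
        auc_truth = None
        if subtype_model is not None:
            centroid_labels = subtyping.assign_subtype(subtype_model, pas)
            truth = np.array([l == "G2" for l in centroid_labels], dtype=int)
            if len(np.unique(truth)) == 2:
                auc_truth = truth
        report = evaluate_cohort(cohort.cohort_id, labels, np.asarray(scores), surv,
                                 auc_truth=auc_truth)
    else:
        logger.info("cohort %s has no survival data; evaluation skipped", cohort.cohort_id)
    return predictions, report


def manifest_json(manifest: dict) -> str:
    """Canonical JSON serialization (sorted keys) for bit-identical comparison."""

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not serializable: {type(o)}")

    return json.dumps(manifest, sort_keys=True, indent=1, default=_default)
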