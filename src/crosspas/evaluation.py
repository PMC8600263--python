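"""Prognostic performance metrics.

Thin, contract-checked wrappers around the field's standard implementations:
Harrell's concordance index and Kaplan–Meier/log-rank via lifelines, the
IPCW (censoring-weighted) Brier score via scikit-survival, rank-based
ROC-AUC via scikit-learn.  Conventions fixed here once: risk scores are
"higher = worse outcome" everywhere, the Brier estimate is the predicted
probability of surviving beyond the horizon, and log-rank handles two or
more groups with a chi-square reference on (groups - 1) degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index as _lifelines_cindex
from lifelines.utils import restricted_mean_survival_time
from sklearn.metrics import roc_auc_score
from sksurv.metrics import brier_score as _sksurv_brier
from sksurv.util import Surv

from .io_formats import SurvivalTable


def concordance_index(risk: np.ndarray, surv: SurvivalTable) -> float:
    """Harrell's C of a risk score (higher risk = expected earlier event).

    Pairs are usable when their ordering is determinable under censoring;
    tied risks count 0.5.  Raises when no pair is usable.
    """
    risk = np.asarray(risk, dtype=float)
    if risk.shape != (surv.n_samples,):
        raise ValueError("risk vector does not match the survival table")
    if surv.event.sum() == 0:
        raise ValueError("no events: no usable pairs for the concordance index")
    # lifelines scores "higher prediction = longer survival"; negate the risk
    return float(_lifelines_cindex(surv.time, -risk, surv.event))


def km_curve(surv: SurvivalTable) -> pd.DataFrame:
    """Product-limit survival estimate: columns ``time`` and ``survival``.

    Starts at (0, 1); non-increasing, right-continuous.
    """
    kmf = KaplanMeierFitter()
    kmf.fit(surv.time, surv.event)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(dtype=float),
                         "survival": sf.iloc[:, 0].to_numpy(dtype=float)})


def km_median(surv: SurvivalTable) -> float:
    """KM median survival time; inf when the curve never reaches 0.5."""
    kmf = KaplanMeierFitter().fit(surv.time, surv.event)
    return float(kmf.median_survival_time_)


def km_rmst(surv: SurvivalTable, horizon: float | None = None) -> float:
    """Restricted mean survival time up to ``horizon`` (default: last observed time)."""
    kmf = KaplanMeierFitter().fit(surv.time, surv.event)
    t = float(horizon) if horizon is not None else float(np.max(surv.time))
    return float(restricted_mean_survival_time(kmf, t=t))


def logrank_test(groups: list | np.ndarray, surv: SurvivalTable) -> tuple[float, float]:
    """Two-or-more-sample log-rank test; returns (chi2, p).

    Requires every named group to be non-empty and at least two groups.
    """
    groups = np.asarray(groups)
    if groups.shape != (surv.n_samples,):
        raise ValueError("group labels do not match the survival table")
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise ValueError("log-rank test needs at least 2 non-empty groups")
    res = multivariate_logrank_test(surv.time, groups, surv.event)
    return float(res.test_statistic), float(res.p_value)


def brier_score(
    predicted_survival_prob: np.ndarray, surv: SurvivalTable, t_star: float
) -> float:
    """IPCW Brier score at horizon ``t_star``.

    ``predicted_survival_prob`` is each sample's predicted probability of
    surviving beyond ``t_star``.  Weights come from the Kaplan–Meier
    estimate of the censoring distribution of the same cohort; samples
    censored before ``t_star`` contribute only through the weights.
    Raises when ``t_star`` is outside the follow-up range or the censoring
    KM vanishes at a required time.
    """
    est = np.asarray(predicted_survival_prob, dtype=float)
    if est.shape != (surv.n_samples,):
        raise ValueError("prediction vector does not match the survival table")
    y = Surv.from_arrays(event=surv.event.astype(bool), time=surv.time)
    _, score = _sksurv_brier(y, y, est[:, None], [float(t_star)])
    return float(score[0])


def roc_auc(scores: np.ndarray, binary_truth: np.ndarray) -> float:
    """Rank-based AUC: probability a positive outranks a negative, ties 0.5."""
    truth = np.asarray(binary_truth)
    if len(np.unique(truth)) != 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(truth, np.asarray(scores, dtype=float)))


@dataclass
class EvaluationReport:
    """Prognostic evaluation of one cohort's predicted risk groups."""

    cohort_id: str
    c_index: float | None = None
    brier: float | None = None
    brier_time: float | None = None
    logrank_chi2: float | None = None
    logrank_p: float | None = None
    auc: float | None = None
    group_sizes: dict[str, int] = field(default_factory=dict)
    km_curves: dict[str, pd.DataFrame] = field(default_factory=dict, repr=False)
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {
            "cohort_id": self.cohort_id,
            "c_index": self.c_index,
            "brier": self.brier,
            "brier_time": self.brier_time,
            "logrank_chi2": self.logrank_chi2,
            "logrank_p": self.logrank_p,
            "auc": self.auc,
            "group_sizes": dict(self.group_sizes),
            "notes": list(self.notes),
        }
        return out


def evaluate_cohort(
    cohort_id: str,
    labels: list | np.ndarray,
    risk_scores: np.ndarray,
    surv: SurvivalTable,
    *,
    auc_truth: np.ndarray | None = None,
    brier_time: float | None = None,
) -> EvaluationReport:
    """Assemble the standard report for one cohort.

    ``labels`` are predicted risk groups (G1/G2/...), ``risk_scores`` the
    continuous risk (classifier G2-neighbor fraction, or binary G2=1).
    ``auc_truth`` — binary reference labels for the model-recovery AUC.
    ``brier_time`` defaults to the cohort's median follow-up; the per-sample
    survival prediction is the KM curve of the sample's own predicted group.
    """
    labels = np.asarray(labels)
    report = EvaluationReport(cohort_id=cohort_id)
    uniq = sorted(pd.unique(labels))
    report.group_sizes = {str(g): int((labels == g).sum()) for g in uniq}
    for g in uniq:
        report.km_curves[str(g)] = km_curve(surv.subset(
            [s for s, l in zip(surv.sample_ids, labels) if l == g]))

    try:
        report.c_index = concordance_index(risk_scores, surv)
    except ValueError as exc:
        report.notes.append(f"c_index skipped: {exc}")
    if len(uniq) >= 2:
        report.logrank_chi2, report.logrank_p = logrank_test(labels, surv)
    else:
        report.notes.append("log-rank skipped: single predicted group")

    t_star = float(np.median(surv.time)) if brier_time is None else float(brier_time)
    group_km = {}
    for g in uniq:
        mask = labels == g
        sub = surv.subset([s for s, keep in zip(surv.sample_ids, mask) if keep])
        kmf = KaplanMeierFitter().fit(sub.time, sub.event)
        group_km[g] = kmf
    pred = np.array(
        [float(group_km[g].predict(t_star)) for g in labels], dtype=float
    )
    try:
        report.brier = brier_score(pred, surv, t_star)
        report.brier_time = t_star
    except (ValueError, ZeroDivisionError) as exc:
        report.notes.append(f"brier skipped: {exc}")

    if auc_truth is not None:
        try:
            report.auc = roc_auc(risk_scores, auc_truth)
        except ValueError as exc:
            report.notes.append(f"auc skipped: {exc}")
    return report
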