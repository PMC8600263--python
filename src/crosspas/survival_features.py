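"""Survival-supervised feature screening.

Each PAS feature is tested one at a time against overall survival with a
univariate Cox proportional-hazards model.  The ranking p-value is the
model's score test at β = 0 — the log-rank-type statistic, identical to the
two-sample log-rank test when the covariate is binary and well-defined for
continuous PAS — and the reported coefficient is the Breslow partial-
likelihood estimate (Newton iteration).  The score test needs no iterative
fit, so screening thousands of features is a vectorized pass over risk-set
cumulative sums rather than thousands of model fits.

Screening then proceeds: keep the top ``d`` features per cohort (sure
independence screening, d = 100), decompose their crosstalk, re-score, apply
Benjamini–Hochberg within cohort at FDR < 0.01, and intersect the surviving
feature ids across cohorts into the final panel.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io_formats import SurvivalTable
from .pas import PASMatrix

logger = logging.getLogger(__name__)

_MAX_NEWTON = 30
_BETA_CAP = 15.0


def _risk_set_stats(X_sorted, beta, first_idx):
    """Breslow risk-set sums S0, S1, S2 for every (feature, sample) position."""
    W = np.exp(np.clip(beta[:, None] * X_sorted, -500, 500))
    WX = W * X_sorted
    WXX = WX * X_sorted
    # reverse cumulative sums -> sums over {j : t_j >= t_i}, tie groups shared
    S0 = np.cumsum(W[:, ::-1], axis=1)[:, ::-1][:, first_idx]
    S1 = np.cumsum(WX[:, ::-1], axis=1)[:, ::-1][:, first_idx]
    S2 = np.cumsum(WXX[:, ::-1], axis=1)[:, ::-1][:, first_idx]
    return S0, S1, S2


def cox_univariate(
    X: np.ndarray, time: np.ndarray, event: np.ndarray
) -> pd.DataFrame:
    """Univariate Cox PH per feature row of ``X`` (features x samples), vectorized.

    Returns a frame with columns ``coef`` (Breslow MLE, capped when the
    partial likelihood is monotone), ``p`` (score test at β = 0),
    ``chi2`` and ``flag`` ("ok", "zero_variance", "non_convergent").
    Zero-variance and degenerate features get p = 1 and never raise.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    m, n = X.shape
    if time.shape != (n,) or event.shape != (n,):
        raise ValueError("time/event length does not match the feature matrix")
    order = np.argsort(time, kind="stable")
    t_s, e_s, X_s = time[order], event[order], X[:, order]
    first_idx = np.searchsorted(t_s, t_s, side="left")
    ev = e_s == 1

    flags = np.full(m, "ok", dtype=object)
    var_zero = X.std(axis=1) == 0
    flags[var_zero] = "zero_variance"
    if not ev.any():
        flags[:] = "zero_variance"  # no events: no information in any feature

    # score test at beta = 0
    beta0 = np.zeros(m)
    S0, S1, S2 = _risk_set_stats(X_s, beta0, first_idx)
    mu = S1 / S0
    U = (X_s[:, ev] - mu[:, ev]).sum(axis=1)
    V = (S2 / S0 - mu**2)[:, ev].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(V > 0, U**2 / V, 0.0)
    p = np.where(V > 0, sps.chi2.sf(chi2, df=1), 1.0)
    p[flags == "zero_variance"] = 1.0
    chi2[flags == "zero_variance"] = 0.0

    # Newton iteration on the Breslow partial likelihood for the coefficient
    beta = np.zeros(m)
    active = (flags == "ok")
    for _ in range(_MAX_NEWTON):
        if not active.any():
            break
        S0, S1, S2 = _risk_set_stats(X_s[active], beta[active], first_idx)
        mu = S1 / S0
        U_b = (X_s[active][:, ev] - mu[:, ev]).sum(axis=1)
        I_b = (S2 / S0 - mu**2)[:, ev].sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(I_b > 0, U_b / np.maximum(I_b, 1e-300), 0.0)
        step = np.clip(step, -2.0, 2.0)
        beta[active] = beta[active] + step
        moved = np.zeros(m, dtype=bool)
        moved[active] = np.abs(step) > 1e-9
        active = moved & (np.abs(beta) < _BETA_CAP)
    runaway = np.abs(beta) >= _BETA_CAP
    if runaway.any():
        flags[runaway & (flags == "ok")] = "non_convergent"
        beta = np.clip(beta, -_BETA_CAP, _BETA_CAP)
        n_bad = int(runaway.sum())
        logger.warning("%d features with monotone partial likelihood; coefficient capped", n_bad)
    beta[flags == "zero_variance"] = 0.0

    return pd.DataFrame({"coef": beta, "p": p, "chi2": chi2, "flag": flags})


def rank_by_survival(pas: PASMatrix, surv: SurvivalTable) -> pd.DataFrame:
    """Univariate Cox screen of every PAS feature, sorted ascending by p.

    Output columns: feature_id, coef, p, chi2, flag, rank (1-based).  Ties in
    p are broken lexicographically by feature_id so the ordering — and hence
    the SIS cut — is deterministic.  Zero-variance or degenerate features get
    p = 1 and sink to the bottom.
    """
    if pas.sample_ids != surv.sample_ids:
        raise ValueError("PAS matrix and survival table are not aligned on samples")
    res = cox_univariate(pas.values, surv.time, surv.event)
    res.insert(0, "feature_id", pas.feature_ids)
    res = res.sort_values(["p", "feature_id"], kind="stable").reset_index(drop=True)
    res["rank"] = np.arange(1, len(res) + 1)
    return res


def sis_screen(ranked: pd.DataFrame, d: int = 100) -> list[str]:
    """Sure independence screening: keep the top min(d, m) feature ids.

    ``ranked`` must come from :func:`rank_by_survival` (ascending p, ties
    already broken by feature_id).
    """
    if d < 1:
        raise ValueError("d must be positive")
    if not ranked["p"].is_monotonic_increasing:
        ranked = ranked.sort_values(["p", "feature_id"], kind="stable")
    return ranked["feature_id"].head(min(d, len(ranked))).tolist()


def fdr_filter(stats: pd.DataFrame, alpha: float = 0.01) -> tuple[list[str], pd.DataFrame]:
    """Benjamini–Hochberg step-up over one cohort's feature p-values.

    Returns (feature ids with q < alpha, stats frame with a ``q`` column).
    """
    stats = stats.copy()
    if stats.empty:
        stats["q"] = pd.Series(dtype=float)
        return [], stats
    _, q, _, _ = multipletests(stats["p"].to_numpy(), method="fdr_bh")
    stats["q"] = q
    # keep the incoming (p-ranked) order rather than re-sorting by q
    ids = stats.loc[stats["q"] < alpha, "feature_id"].tolist()
    return ids, stats


def intersect_cohorts(per_cohort_selected: list[list[str]]) -> list[str]:
    """Features selected in every training cohort, ordered by mean rank.

    Requires >= 2 cohorts; an empty intersection raises with advice to relax
    alpha.  Mean positional rank (0-based within each cohort's selected list)
    orders the panel; ties break lexicographically.
    """
    if len(per_cohort_selected) < 2:
        raise ValueError("need selections from at least 2 cohorts to intersect")
    common = set(per_cohort_selected[0])
    for sel in per_cohort_selected[1:]:
        common &= set(sel)
    if not common:
        raise ValueError(
            "no feature passes the FDR filter in every cohort; "
            "consider a larger fdr_alpha or fewer intersection cohorts"
        )
    mean_rank = {
        f: float(np.mean([sel.index(f) for sel in per_cohort_selected])) for f in common
    }
    return sorted(common, key=lambda f: (mean_rank[f], f))
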