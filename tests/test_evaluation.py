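import numpy as np
import pytest
from lifelines import KaplanMeierFitter

from crosspas.evaluation import (
    brier_score,
    concordance_index,
    km_curve,
    logrank_test,
    roc_auc,
)
from tests.conftest import make_survival


# ---------------------------------------------------------------------------
# independent brute-force oracles


def cindex_bruteforce(risk, time, event):
    """Exhaustive Harrell's C over pairs whose ordering is determinable under
    right censoring: the strictly shorter time had the event, or — at tied
    times — exactly one of the pair had the event (it failed first, the
    censored one is known to have survived past it).  Tied-time both-event
    pairs are indeterminable and excluded; ties in risk count 0.5."""
    conc = usable = 0.0
    n = len(risk)
    for i in range(n):
        for j in range(i + 1, n):
            if time[i] == time[j]:
                if event[i] == event[j]:
                    continue  # both events or both censored: indeterminable
                a = i if event[i] else j  # the event sample failed first
                b = j if a == i else i
            else:
                a, b = (i, j) if time[i] < time[j] else (j, i)
                if not event[a]:
                    continue
            usable += 1
            if risk[a] > risk[b]:
                conc += 1
            elif risk[a] == risk[b]:
                conc += 0.5
    return conc / usable


def auc_bruteforce(scores, truth):
    pos = [s for s, t in zip(scores, truth) if t == 1]
    neg = [s for s, t in zip(scores, truth) if t == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def logrank_chi2_by_tabulation(time, event, group):
    """Two-sample log-rank by explicit observed-minus-expected tabulation."""
    o1 = e1 = v = 0.0
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == 1)).sum()
        o1 += d1
        e1 += n1 * d / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (o1 - e1) ** 2 / v


# ---------------------------------------------------------------------------


class TestConcordanceIndex:
    def test_perfect_and_reversed(self):
        surv = make_survival([10, 8, 6, 4], [1, 1, 1, 1])
        assert concordance_index(np.array([1, 2, 3, 4.0]), surv) == 1.0
        assert concordance_index(np.array([4, 3, 2, 1.0]), surv) == 0.0

    def test_worked_censored_example(self):
        """times [2,4,6,8], events [1,1,0,1], risks [4,3,2,1]: the (6,8) pair
        is unusable (shorter time censored), the other five concordant."""
        time, event = np.array([2, 4, 6, 8.0]), np.array([1, 1, 0, 1])
        risk = np.array([4, 3, 2, 1.0])
        surv = make_survival(time, event)
        expected = cindex_bruteforce(risk, time, event)
        assert expected == 1.0  # hand enumeration: 5 usable, all concordant
        assert concordance_index(risk, surv) == expected

    def test_matches_bruteforce_on_random_instances(self):
        """100 random censored instances (n <= 30), ties in risks and times."""
        for rep in range(100):
            r = np.random.default_rng(rep)
            n = int(r.integers(4, 31))
            time = r.integers(1, 12, n).astype(float)
            event = r.integers(0, 2, n)
            if event.sum() == 0:
                event[0] = 1
            risk = r.integers(0, 6, n).astype(float)
            surv = make_survival(time, event)
            got = concordance_index(risk, surv)
            want = cindex_bruteforce(risk, time, event)
            assert got == pytest.approx(want, abs=1e-12), f"rep {rep}"

    def test_negation_symmetry_without_ties(self, rng):
        n = 25
        time = rng.permutation(np.arange(1.0, n + 1))
        event = np.ones(n, int)
        risk = rng.permutation(np.arange(n, dtype=float))
        surv = make_survival(time, event)
        assert concordance_index(risk, surv) + concordance_index(-risk, surv) == 1.0


class TestBrierScore:
    def test_perfect_oracle_no_censoring_is_zero(self):
        surv = make_survival([1, 2, 8, 9.0], [1, 1, 1, 1])
        pred = np.array([0.0, 0.0, 1.0, 1.0])  # deaths before t*=5, survivors after
        assert brier_score(pred, surv, 5.0) == 0.0

    def test_constant_half_no_censoring_is_quarter(self):
        surv = make_survival([1, 2, 8, 9.0], [1, 1, 1, 1])
        assert brier_score(np.full(4, 0.5), surv, 5.0) == pytest.approx(0.25)

    def test_censored_case_matches_hand_ipcw_sum(self):
        """6 samples, one censored before the horizon: equals the explicit
        inverse-probability-of-censoring-weighted (Graf) sum."""
        time = np.array([2.0, 4, 5, 7, 9, 10])
        event = np.array([1, 1, 0, 1, 1, 1])
        pred = np.array([0.9, 0.7, 0.6, 0.45, 0.3, 0.2])
        t_star = 6.0
        kmf = KaplanMeierFitter().fit(time, 1 - event)  # censoring KM
        terms = []
        for ti, di, si in zip(time, event, pred):
            if ti <= t_star and di == 1:
                terms.append(si**2 / float(kmf.predict(ti - 1e-9)))
            elif ti > t_star:
                terms.append((1 - si) ** 2 / float(kmf.predict(t_star)))
            else:
                terms.append(0.0)  # censored before t*: contributes via weights only
        hand = float(np.mean(terms))
        surv = make_survival(time, event)
        assert brier_score(pred, surv, t_star) == pytest.approx(hand, abs=1e-12)

    def test_horizon_outside_followup_errors(self):
        surv = make_survival([1, 2, 3.0], [1, 1, 1])
        with pytest.raises(ValueError):
            brier_score(np.full(3, 0.5), surv, 99.0)


class TestKmCurve:
    def test_all_events_product_limit_steps(self):
        curve = km_curve(make_survival([1, 2, 3.0], [1, 1, 1]))
        lookup = dict(zip(curve["time"], curve["survival"]))
        assert lookup[1.0] == pytest.approx(2 / 3)
        assert lookup[2.0] == pytest.approx(1 / 3)
        assert lookup[3.0] == 0.0

    def test_no_events_flat_at_one(self):
        curve = km_curve(make_survival([5, 6, 7.0], [0, 0, 0]))
        assert (curve["survival"] == 1.0).all()

    def test_censoring_after_last_event_leaves_curve(self):
        a = km_curve(make_survival([1, 2, 3.0], [1, 1, 0]))
        assert a["survival"].iloc[-1] == pytest.approx(1 / 3)

    def test_monotone_from_one_total_drop_bounded(self, rng):
        for rep in range(10):
            r = np.random.default_rng(rep)
            n = int(r.integers(3, 40))
            surv = make_survival(r.integers(1, 15, n) + 0.0, r.integers(0, 2, n))
            curve = km_curve(surv)
            s = curve["survival"].to_numpy()
            assert s[0] <= 1.0 and (np.diff(s) <= 1e-12).all() and s[-1] >= 0.0


class TestLogrankTest:
    def test_identical_groups_null(self):
        time = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
        event = np.array([1, 1, 0, 1, 1, 1, 0, 1])
        surv = make_survival(time, event)
        chi2, p = logrank_test(np.array([0, 0, 0, 0, 1, 1, 1, 1]), surv)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_small_case_matches_hand_tabulation(self):
        time = np.array([3.0, 5, 7, 2, 4, 6, 8, 9])
        event = np.array([1, 1, 0, 1, 1, 1, 0, 1])
        group = np.array([1, 1, 1, 0, 0, 0, 0, 0])
        surv = make_survival(time, event)
        chi2, _ = logrank_test(group, surv)
        assert chi2 == pytest.approx(logrank_chi2_by_tabulation(time, event, group),
                                     rel=1e-9)

    def test_p_value_close_to_permutation_p(self, rng):
        n = 16
        time = rng.exponential(1, n) + 0.01
        event = rng.integers(0, 2, n)
        event[:4] = 1
        group = np.array([1] * 8 + [0] * 8)
        surv = make_survival(time, event)
        chi2_obs, p_asym = logrank_test(group, surv)
        perms = 800
        count = 0
        for _ in range(perms):
            g = rng.permutation(group)
            chi2, _ = logrank_test(g, surv)
            count += chi2 >= chi2_obs - 1e-12
        p_perm = count / perms
        assert abs(p_asym - p_perm) < 0.08  # Monte-Carlo + asymptotic slack

    def test_label_swap_symmetry(self, rng):
        n = 20
        surv = make_survival(rng.exponential(1, n) + 0.01, rng.integers(0, 2, n))
        group = rng.integers(0, 2, n)
        chi2_a, _ = logrank_test(group, surv)
        chi2_b, _ = logrank_test(1 - group, surv)
        assert chi2_a == pytest.approx(chi2_b, rel=1e-12)

    def test_single_group_rejected(self):
        surv = make_survival([1, 2.0], [1, 1])
        with pytest.raises(ValueError):
            logrank_test(np.array([1, 1]), surv)


class TestRocAuc:
    def test_perfect_and_null_extremes(self, rng):
        truth = np.array([1, 1, 0, 0])
        assert roc_auc(np.array([0.9, 0.8, 0.2, 0.1]), truth) == 1.0
        n = 4000
        truth_big = rng.integers(0, 2, n)
        assert roc_auc(rng.random(n), truth_big) == pytest.approx(0.5, abs=0.05)

    def test_tied_scores_match_bruteforce(self):
        scores = np.array([0.9, 0.8, 0.4, 0.2, 0.4])
        truth = np.array([1, 1, 0, 0, 1])
        assert roc_auc(scores, truth) == pytest.approx(
            auc_bruteforce(scores, truth), abs=1e-12)

    def test_matches_bruteforce_on_random_instances(self):
        for rep in range(100):
            r = np.random.default_rng(500 + rep)
            n = int(r.integers(4, 31))
            truth = r.integers(0, 2, n)
            if len(np.unique(truth)) < 2:
                truth[:2] = [0, 1]
            scores = r.integers(0, 5, n) / 4.0
            assert roc_auc(scores, truth) == pytest.approx(
                auc_bruteforce(scores, truth), abs=1e-12), f"rep {rep}"
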