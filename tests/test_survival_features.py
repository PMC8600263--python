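import numpy as np
import pandas as pd
import pytest

from crosspas.io_formats import SurvivalTable
from crosspas.pas import PASMatrix
from crosspas.survival_features import (
    cox_univariate,
    fdr_filter,
    intersect_cohorts,
    rank_by_survival,
    sis_screen,
)
from tests.conftest import make_survival


def _pas(values, prefix="f"):
    values = np.atleast_2d(np.asarray(values, float))
    return PASMatrix(
        [f"{prefix}{i + 1}" for i in range(values.shape[0])],
        [f"s{j + 1}" for j in range(values.shape[1])],
        values,
    )


class TestCoxUnivariate:
    def test_matches_lifelines_on_tie_free_data(self, rng):
        """Coefficient agrees with lifelines' Cox fit and the score test with
        the two-sample log-rank statistic (binary covariate, no tied times:
        Breslow and Efron coincide)."""
        from lifelines import CoxPHFitter
        from lifelines.statistics import logrank_test as ll_logrank

        n = 120
        x = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(np.exp(-1.0 * x))
        c = rng.exponential(2.0, n)
        time, event = np.minimum(t, c), (t <= c).astype(int)
        res = cox_univariate(x, time, event)

        cph = CoxPHFitter().fit(
            pd.DataFrame({"T": time, "E": event, "x": x}), "T", "E"
        )
        assert res.coef[0] == pytest.approx(cph.params_["x"], rel=1e-4)

        lr = ll_logrank(time[x == 1], time[x == 0], event[x == 1], event[x == 0])
        assert res.chi2[0] == pytest.approx(lr.test_statistic, rel=1e-9)
        assert res.p[0] == pytest.approx(lr.p_value, rel=1e-9)

    def test_continuous_covariate_matches_lifelines_coefficient(self, rng):
        from lifelines import CoxPHFitter

        n = 150
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.7 * x))
        time, event = t, np.ones(n, int)
        res = cox_univariate(x, time, event)
        cph = CoxPHFitter().fit(
            pd.DataFrame({"T": time, "E": event, "x": x}), "T", "E"
        )
        assert res.coef[0] == pytest.approx(cph.params_["x"], rel=1e-4)

    def test_zero_variance_feature_flagged_p_one(self):
        res = cox_univariate(np.zeros((1, 6)), np.arange(1.0, 7), np.ones(6, int))
        assert res.p[0] == 1.0 and res.flag[0] == "zero_variance"

    def test_monotone_likelihood_capped_not_crashed(self):
        # covariate perfectly ordered with survival: partial likelihood is monotone
        time = np.arange(1.0, 9)
        x = -time
        res = cox_univariate(x, time, np.ones(8, int))
        assert res.flag[0] == "non_convergent"
        assert np.isfinite(res.coef[0]) and res.p[0] < 0.05


class TestRankBySurvival:
    def test_constant_feature_sinks_to_bottom(self, rng):
        surv = make_survival(rng.exponential(1, 30) + 0.01, np.ones(30, int))
        X = np.vstack([np.clip(rng.normal(size=30), -1, 1), np.full(30, 0.25)])
        ranked = rank_by_survival(
            _pas(X), SurvivalTable(_pas(X).sample_ids, surv.time, surv.event)
        )
        assert ranked.iloc[-1]["feature_id"] == "f2"
        assert ranked.iloc[-1]["p"] == 1.0

    def test_planted_prognostic_feature_ranks_first(self, rng):
        """One feature tracking a hazard-ratio-3 subtype outranks 30 noise
        features in >= 95% of 20 replicates (n = 300)."""
        wins = 0
        for rep in range(20):
            r = np.random.default_rng(1000 + rep)
            n = 300
            g2 = r.random(n) < 0.4
            lam = np.where(g2, 3.0, 1.0)
            t = r.exponential(1 / lam)
            c = r.uniform(0, 2.2, n)
            time, event = np.minimum(t, c), (t <= c).astype(int)
            X = r.normal(size=(31, n)) * 0.5
            X[0] = np.where(g2, 0.6, -0.4) + r.normal(size=n) * 0.2
            surv = make_survival(time + 1e-9, event)
            pas = PASMatrix([f"f{i}" for i in range(31)], surv.sample_ids,
                            np.clip(X, -1, 1))
            ranked = rank_by_survival(pas, surv)
            wins += ranked.iloc[0]["feature_id"] == "f0"
        assert wins >= 19

    def test_sample_order_permutation_invariance(self, rng):
        n = 40
        X = rng.normal(size=(3, n)) * 0.3
        time, event = rng.exponential(1, n) + 0.01, rng.integers(0, 2, n)
        pas = _pas(X)
        surv = make_survival(time, event)
        perm = rng.permutation(n)
        pas_p = PASMatrix(pas.feature_ids, [pas.sample_ids[i] for i in perm],
                          X[:, perm])
        surv_p = SurvivalTable([surv.sample_ids[i] for i in perm],
                               time[perm], event[perm])
        a = rank_by_survival(pas, surv)
        b = rank_by_survival(pas_p, surv_p)
        pd.testing.assert_frame_equal(a, b)


class TestSisScreen:
    def test_returns_min_d_and_length(self, rng):
        m = 500
        ranked = pd.DataFrame({
            "feature_id": [f"f{i:04d}" for i in range(m)],
            "p": np.sort(rng.random(m)),
        })
        assert len(sis_screen(ranked, 100)) == 100
        assert sis_screen(ranked.head(40), 100) == ranked.head(40)["feature_id"].tolist()

    def test_boundary_tie_broken_lexicographically(self):
        ranked = pd.DataFrame({
            "feature_id": ["b", "a", "c"], "p": [0.1, 0.1, 0.1],
        }).sort_values(["p", "feature_id"], kind="stable")
        assert sis_screen(ranked, 2) == ["a", "b"]


class TestFdrFilter:
    def test_bh_hand_example(self):
        """p = [.001, .002, .5], m = 3: q = [.003, .003, .5]; two pass at 0.01."""
        stats = pd.DataFrame({"feature_id": ["a", "b", "c"],
                              "p": [0.001, 0.002, 0.5]})
        ids, with_q = fdr_filter(stats, alpha=0.01)
        np.testing.assert_allclose(with_q["q"], [0.003, 0.003, 0.5])
        assert ids == ["a", "b"]

    def test_all_p_one_selects_nothing(self):
        ids, _ = fdr_filter(pd.DataFrame({"feature_id": ["a", "b"], "p": [1.0, 1.0]}))
        assert ids == []

    def test_single_p_is_its_own_q(self):
        ids, with_q = fdr_filter(pd.DataFrame({"feature_id": ["a"], "p": [0.005]}))
        assert with_q["q"].iloc[0] == pytest.approx(0.005)
        assert ids == ["a"]

    def test_empty_input(self):
        ids, with_q = fdr_filter(pd.DataFrame({"feature_id": [], "p": []}))
        assert ids == [] and "q" in with_q

    def test_q_monotone_and_at_least_p(self, rng):
        p = rng.random(50)
        stats = pd.DataFrame({"feature_id": [f"f{i}" for i in range(50)], "p": p})
        _, with_q = fdr_filter(stats)
        assert (with_q["q"] >= with_q["p"] - 1e-12).all()
        s = with_q.sort_values("p")
        assert s["q"].is_monotonic_increasing

    def test_null_fdr_fraction_controlled(self):
        """Global null (hazard ratio 1, pure noise features): the fraction of
        q < 0.01 discoveries over 50 simulated cohorts stays within
        0.01 + 3 binomial SEs."""
        n_pass = n_total = 0
        for rep in range(50):
            r = np.random.default_rng(2000 + rep)
            n, m = 150, 60
            time = r.exponential(1, n) + 1e-9
            event = (r.random(n) < 0.7).astype(int)
            X = np.clip(r.normal(size=(m, n)) * 0.4, -1, 1)
            surv = make_survival(time, event)
            pas = PASMatrix([f"f{i}" for i in range(m)], surv.sample_ids, X)
            ids, _ = fdr_filter(rank_by_survival(pas, surv), alpha=0.01)
            n_pass += len(ids)
            n_total += m
        frac = n_pass / n_total
        se = np.sqrt(0.01 * 0.99 / n_total)
        assert frac <= 0.01 + 3 * se


class TestIntersectCohorts:
    def test_common_features_ordered_by_mean_rank(self):
        panel = intersect_cohorts([["a", "b", "c"], ["b", "c", "d"], ["c", "b", "e"]])
        assert set(panel) == {"b", "c"}
        # mean ranks: b = (1+0+1)/3, c = (2+1+0)/3 -> b first
        assert panel == ["b", "c"]

    def test_identical_lists_unchanged(self):
        assert intersect_cohorts([["x", "y"], ["x", "y"]]) == ["x", "y"]

    def test_disjoint_lists_error(self):
        with pytest.raises(ValueError, match="alpha"):
            intersect_cohorts([["a"], ["b"]])

    def test_single_cohort_rejected(self):
        with pytest.raises(ValueError):
            intersect_cohorts([["a"]])
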