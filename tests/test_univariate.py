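import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from radrobust import _glm
from radrobust.univariate import (
    compare_groups,
    fit_cox_univariate,
    fit_logistic_univariate,
    harrell_c,
    holm_adjust,
    orient_ratio,
    roc_auc,
    run_univariate_screen,
    wilcoxon_mw,
)


class TestRocAuc:
    def test_perfect_ranking(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_three_quarters(self):
        # pair enumeration: pos {0.9, 0.2} vs neg {0.1, 0.8} -> 3/4 concordant
        assert roc_auc([0.9, 0.1, 0.8, 0.2], [1, 0, 0, 1]) == 0.75

    def test_all_ties(self):
        assert roc_auc([1.0] * 6, [1, 0, 1, 0, 0, 1]) == 0.5

    def test_one_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.standard_normal(80)
        y = (rng.uniform(size=80) < 0.35).astype(int)
        assert roc_auc(scores, y) == pytest.approx(roc_auc_score(y, scores))

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_invariances(self, seed):
        gen = np.random.default_rng(seed)
        n = 30
        scores = gen.normal(0, 1, n)
        y = (gen.uniform(size=n) < 0.4).astype(int)
        if y.sum() in (0, n):
            return
        a = roc_auc(scores, y)
        # strictly increasing transform leaves the AUC unchanged
        assert roc_auc(np.tanh(scores), y) == pytest.approx(a)
        # reflection (no ties among scores)
        assert roc_auc(-scores, y) == pytest.approx(1 - a)


class TestHarrellC:
    def test_perfect_ordering(self):
        assert harrell_c([4, 3, 2, 1], [1, 2, 3, 4], [1, 1, 1, 1]) == 1.0

    def test_constant_risk(self):
        assert harrell_c([1, 1, 1, 1], [1, 2, 3, 4], [1, 1, 1, 1]) == 0.5

    def test_censored_example_by_enumeration(self):
        # usable pairs (earlier member has the event):
        # (1,2) (1,3) (1,4) (2,3) (2,4) — all concordant for risks 4>3>2>1;
        # patient 3 is censored so (3,4) is not usable
        assert harrell_c([4, 3, 2, 1], [1, 2, 3, 4], [1, 1, 0, 1]) == 1.0

    def test_matches_lifelines(self, rng):
        from lifelines.utils import concordance_index

        risk = rng.standard_normal(60)
        time = rng.exponential(10, 60)
        event = (rng.uniform(size=60) < 0.6).astype(int)
        assert harrell_c(risk, time, event) == pytest.approx(
            1 - concordance_index(time, risk, event)
        )

    def test_equals_auc_when_times_order_labels(self):
        # all events, times split early/late: C equals the AUC of
        # (-risk) against "early event" labels by pair enumeration
        risk = np.array([3.0, 1.0, 2.5, 0.5])
        time = np.array([1.0, 10.0, 2.0, 11.0])
        event = np.array([1, 1, 1, 1])
        c = harrell_c(risk, time, event)
        oracle = 0.0
        usable = 0
        for i in range(4):
            for j in range(4):
                if time[i] < time[j]:
                    usable += 1
                    oracle += (risk[i] > risk[j]) + 0.5 * (risk[i] == risk[j])
        assert c == pytest.approx(oracle / usable)

    def test_no_usable_pairs(self):
        with pytest.raises(ValueError):
            harrell_c([1, 2], [3, 3], [0, 0])


class TestOrientRatio:
    @pytest.mark.parametrize("r,expected", [(0.5, 2.0), (1.0, 1.0), (1.3, 1.3)])
    def test_values(self, r, expected):
        assert orient_ratio(r) == pytest.approx(expected)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.floats(1e-6, 1e6))
    def test_inversion_symmetry(self, r):
        assert orient_ratio(r) == pytest.approx(orient_ratio(1 / r), rel=1e-9)
        assert orient_ratio(r) >= 1.0

    def test_nonpositive(self):
        with pytest.raises(ValueError):
            orient_ratio(0.0)


class TestLogisticUnivariate:
    def test_null_covariate_small_beta(self, rng):
        x = rng.standard_normal(300)
        y = (rng.uniform(size=300) < 0.3).astype(int)
        fit = fit_logistic_univariate(x, y)
        assert not fit.flagged
        assert abs(fit.beta) < 0.3

    def test_matches_newton_solver(self, rng):
        x = rng.standard_normal(150)
        y = (rng.uniform(size=150) < 1 / (1 + np.exp(-1.2 * x))).astype(int)
        fit = fit_logistic_univariate(x, y)
        xs = (x - x.mean()) / x.std(ddof=1)
        beta_ref, _, _ = _glm.logistic_fit(xs[:, None], y)
        assert fit.beta == pytest.approx(beta_ref[1], abs=1e-6)
        assert fit.intercept == pytest.approx(beta_ref[0], abs=1e-6)

    def test_separation_flagged(self, rng):
        x = rng.standard_normal(200)
        y = (x > np.median(x)).astype(int)
        fit = fit_logistic_univariate(x, y)
        assert fit.flagged
        assert abs(fit.beta) <= 20.0

    def test_duplication_invariance_of_likelihood(self, rng):
        # duplicating every observation doubles the log-likelihood and
        # leaves the maximizer unchanged
        x = rng.standard_normal(80)
        y = (rng.uniform(size=80) < 1 / (1 + np.exp(-x))).astype(int)
        b1, ll1, _ = _glm.logistic_fit(x[:, None], y)
        b2, ll2, _ = _glm.logistic_fit(np.r_[x, x][:, None], np.r_[y, y])
        assert b1 == pytest.approx(b2, abs=1e-7)
        assert ll2 == pytest.approx(2 * ll1, rel=1e-9)


class TestCoxUnivariate:
    def test_null_covariate_small_beta(self, rng):
        x = rng.standard_normal(300)
        t = rng.exponential(10, 300)
        e = (rng.uniform(size=300) < 0.7).astype(int)
        fit = fit_cox_univariate(x, t, e)
        assert abs(fit.beta) < 0.3

    def test_three_patient_grid_oracle(self):
        # distinct event times, x = [0, 1, 0]: maximize the exact Efron
        # (= Breslow here) partial likelihood on a grid
        x = np.array([0.0, 1.0, 0.0])
        t = np.array([1.0, 2.0, 3.0])
        e = np.array([1, 1, 1])
        xs = (x - x.mean()) / x.std(ddof=1)

        def pll(b):
            eta = b * xs
            ll = 0.0
            for i in np.argsort(t):
                risk = eta[t >= t[i]]
                ll += eta[i] - np.log(np.exp(risk).sum())
            return ll

        grid = np.linspace(-5, 5, 200001)
        best = grid[np.argmax([pll(b) for b in grid[:: 100]]) * 100]
        fine = grid[np.abs(grid - best) < 0.1]
        oracle = fine[np.argmax([pll(b) for b in fine])]
        fit = fit_cox_univariate(x, t, e)
        assert fit.beta == pytest.approx(oracle, abs=1e-3)

    def test_duplication_near_invariance_efron(self, rng):
        # duplicating every patient creates tied pairs; Efron's correction
        # keeps the estimate close to the untied fit (Breslow drifts more)
        x = rng.standard_normal(40)
        t = rng.exponential(5, 40)
        e = np.ones(40, dtype=int)
        b1, _, _ = _glm.cox_fit(x[:, None], t, e)
        b2, _, _ = _glm.cox_fit(np.r_[x, x][:, None], np.r_[t, t], np.r_[e, e])
        assert b2[0] == pytest.approx(b1[0], abs=0.02)

    def test_zero_events(self):
        with pytest.raises(ValueError):
            fit_cox_univariate([1.0, 2.0], [1.0, 2.0], [0, 0])


class TestWilcoxonHolm:
    def test_identical_samples(self, rng):
        a = rng.standard_normal(30)
        assert wilcoxon_mw(a, a) > 0.9

    def test_holm_hand_examples(self):
        assert holm_adjust({"a": 0.01, "b": 0.04}) == pytest.approx(
            {"a": 0.02, "b": 0.04}
        )
        # monotonicity enforcement raises the second-ranked value
        assert holm_adjust({"a": 0.03, "b": 0.02}) == pytest.approx(
            {"a": 0.04, "b": 0.04}
        )

    def test_matches_statsmodels(self, rng):
        raw = {f"k{i}": float(p) for i, p in enumerate(rng.uniform(0, 0.3, 7))}
        mine = holm_adjust(raw)
        ref = multipletests(list(raw.values()), method="holm")[1]
        for k, r in zip(raw, ref):
            assert mine[k] == pytest.approx(r)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=10))
    def test_holm_dominates_raw(self, ps):
        raw = {i: p for i, p in enumerate(ps)}
        adj = holm_adjust(raw)
        for k in raw:
            assert raw[k] <= adj[k] <= 1.0

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            wilcoxon_mw([], [1.0])


class TestScreen:
    def test_result_schema_and_groups(self, screen_cohort):
        proc, rec, _ = screen_cohort
        res = run_univariate_screen(proc, rec, "recurrence", "A")
        n_robust = int(rec["robust"].sum())
        n_non = len(rec) - n_robust
        assert len(res) == n_robust + 2 * n_non
        assert set(res["group"]) == {"robust", "nonrobust_HD", "nonrobust_LD"}
        assert res["metric"].between(0, 1).all()
        ok = res.loc[~res["flagged"], "oriented_ratio"]
        assert (ok >= 1.0).all()

    def test_robust_features_win_externally(self):
        # outcome depends only on latents proxied by robust features, so
        # robust-group apparent AUC dominates in the external center
        from radrobust.preprocessing import preprocess_cohort
        from radrobust.robustness import concordance_table
        from radrobust.simulate import _design_preset, simulate_cohort
        import warnings

        cfg = _design_preset(
            n_a=250, n_b=120, p=24, n_dual=60, robust_names=None,
            n_robust=6, n_icc_only=6, n_signal_robust=5,
            n_signal_nonrobust=0, seed=11,
        )
        ds, _ = simulate_cohort(cfg)
        rec = concordance_table(ds)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            proc, _ = preprocess_cohort(ds)
        res = run_univariate_screen(proc, rec, "recurrence", "B")
        med = res.groupby("group")["metric"].median()
        assert med["robust"] > med["nonrobust_HD"]
        assert med["robust"] > med["nonrobust_LD"]

    def test_permuted_labels_center_half(self, screen_cohort, rng):
        proc, rec, _ = screen_cohort
        clone = proc.subset(proc.patient_ids)
        ids = clone.center_ids("A")
        perm = rng.permutation(clone.outcomes.loc[ids, "recurrence"].to_numpy())
        clone.outcomes.loc[ids, "recurrence"] = perm
        res = run_univariate_screen(clone, rec, "recurrence", "A")
        assert abs(res["metric"].median() - 0.5) < 0.05

    def test_survival_screen(self, screen_cohort):
        proc, rec, _ = screen_cohort
        res = run_univariate_screen(proc, rec, "rfs", "A")
        assert res["metric"].between(0, 1).all()

    def test_group_comparisons_structure(self, screen_cohort):
        proc, rec, _ = screen_cohort
        res = pd.concat(
            [
                run_univariate_screen(proc, rec, "recurrence", c)
                for c in ("A", "B")
            ]
        )
        comp = compare_groups(res)
        assert set(comp["center"]) == {"A", "B"}
        assert (comp["p_holm"] >= comp["p_raw"] - 1e-12).all()
        assert comp["p_holm"].le(1.0).all()
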