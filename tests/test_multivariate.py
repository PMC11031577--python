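import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from radrobust import multivariate as mv
from radrobust.dataset import AnalysisConfig, kfold_split
from radrobust.multivariate import (
    SignatureCandidate,
    build_design,
    enumerate_signatures,
    fit_signature,
    mrmr_select,
    one_se_select,
    run_experiment,
    run_repetition,
    smote_tomek,
)


class TestEnumerate:
    def test_counts(self):
        assert len(enumerate_signatures([f"f{i}" for i in range(3)])) == 7
        assert len(enumerate_signatures([f"f{i}" for i in range(10)])) == 1023

    def test_distinct_nonempty_ordered(self):
        sigs = enumerate_signatures(["c", "a", "b"])
        assert len(set(sigs)) == len(sigs)
        assert all(len(s) >= 1 for s in sigs)
        sizes = [len(s) for s in sigs]
        assert sizes == sorted(sizes)
        assert sigs[0] == ("a",)  # lexicographic within size

    def test_guard(self):
        with pytest.raises(ValueError, match="combinatorial"):
            enumerate_signatures([f"f{i}" for i in range(21)])


def brute_force_mrmr(X: pd.DataFrame, y: np.ndarray, k: int) -> list:
    """Independent greedy FCQ recomputation using scipy building blocks."""
    relevance = {}
    for f in X.columns:
        g0, g1 = X.loc[y == 0, f], X.loc[y == 1, f]
        F, _ = stats.f_oneway(g0, g1)
        relevance[f] = 0.0 if not np.isfinite(F) else float(F)
    selected = []
    while len(selected) < k:
        best, best_score = None, -np.inf
        for f in sorted(X.columns):
            if f in selected:
                continue
            if not selected:
                score = relevance[f]
            else:
                red = np.mean(
                    [abs(stats.pearsonr(X[f], X[s])[0]) for s in selected]
                )
                score = relevance[f] / max(red, 1e-6)
            if score > best_score:
                best, best_score = f, score
        selected.append(best)
    return selected


class TestMrmr:
    def _toy(self, rng, n=120):
        z = rng.standard_normal(n)
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-1.5 * z))).astype(int)
        X = pd.DataFrame(
            {
                "strong": z + 0.3 * rng.standard_normal(n),
                "echo": z + 0.35 * rng.standard_normal(n),
                "weak": 0.4 * z + rng.standard_normal(n),
                "noise": rng.standard_normal(n),
            }
        )
        return X, y

    def test_first_pick_is_max_relevance(self, rng):
        X, y = self._toy(rng)
        sel = mrmr_select(X, y, 1, "FCQ")
        assert sel == brute_force_mrmr(X, y, 1)

    def test_full_order_matches_brute_force(self, rng):
        X, y = self._toy(rng)
        assert mrmr_select(X, y, 4, "FCQ") == brute_force_mrmr(X, y, 4)

    def test_duplicated_column_penalized(self, rng):
        X, y = self._toy(rng)
        X["strong_copy"] = X["strong"]
        # same relevance as "strong" by construction (class-wise shuffling
        # preserves the ANOVA F) but nearly uncorrelated with it
        shuffled = X["strong"].to_numpy().copy()
        for cls in (0, 1):
            idx = np.flatnonzero(y == cls)
            shuffled[idx] = shuffled[rng.permutation(idx)]
        X["same_rel_indep"] = shuffled
        sel = mrmr_select(X, y, 6, "FCQ")
        # equal relevance, but the identical copy has redundancy 1 with its
        # twin, so the independent equal-relevance feature is picked first
        assert sel.index("same_rel_indep") < sel.index("strong_copy")

    def test_constant_feature_last(self, rng):
        X, y = self._toy(rng)
        X["flat"] = 1.0
        sel = mrmr_select(X, y, 5, "FCQ")
        assert sel[-1] == "flat"

    def test_wcq_mode_ranks_signal_first(self, rng):
        n = 150
        z = rng.standard_normal(n)
        t = rng.exponential(1 / (0.05 * np.exp(0.9 * z)))
        e = np.ones(n, dtype=int)
        X = pd.DataFrame(
            {"signal": z, "noise1": rng.standard_normal(n),
             "noise2": rng.standard_normal(n)}
        )
        sel = mrmr_select(X, (t, e), 3, "WCQ")
        assert sel[0] == "signal"


class TestSmoteTomek:
    def test_balanced_input_no_synthesis(self, rng):
        X = rng.standard_normal((40, 3))
        y = np.array([0, 1] * 20)
        Xb, yb = smote_tomek(X, y, seed=0)
        assert len(Xb) <= len(X)  # only Tomek removals possible

    def test_oversamples_to_parity(self, rng):
        X = np.vstack([rng.standard_normal((30, 2)) + 3, rng.standard_normal((8, 2))])
        y = np.r_[np.zeros(30, int), np.ones(8, int)]
        Xb, yb = smote_tomek(X, y, seed=0)
        # well-separated clusters: no Tomek links, exact parity
        assert (yb == 1).sum() == (yb == 0).sum() == 30

    def test_synthetic_points_are_convex_combinations(self, rng):
        X_min = np.array([[0.0, 0.0], [1.0, 1.0]])
        X = np.vstack([rng.standard_normal((10, 2)) + 10, X_min])
        y = np.r_[np.zeros(10, int), np.ones(2, int)]
        Xb, yb = smote_tomek(X, y, k_neighbors=1, seed=3)
        synth = Xb[len(X):]
        # with minority {(0,0),(1,1)} every synthetic point lies on the
        # segment x = y between them
        assert np.allclose(synth[:, 0], synth[:, 1], atol=1e-12)
        assert ((synth[:, 0] >= 0) & (synth[:, 0] <= 1)).all()

    def test_tomek_link_removes_majority_member(self):
        # three well-separated mutual-NN opposite-class pairs; with equal
        # class counts no SMOTE happens, and the majority member (class 1,
        # the non-minority label) of every link is dropped
        X = np.array(
            [[0.0, 0.0], [0.1, 0.0], [5.0, 5.0], [5.1, 5.0], [9.0, 9.0], [9.2, 9.0]]
        )
        y = np.array([0, 1, 0, 1, 0, 1])
        Xb, yb = smote_tomek(X, y, k_neighbors=1, seed=0)
        assert (yb == 0).sum() == 3
        assert (yb == 1).sum() == 0

    def test_deterministic(self, rng):
        X = np.vstack([rng.standard_normal((25, 4)), rng.standard_normal((7, 4)) + 1])
        y = np.r_[np.zeros(25, int), np.ones(7, int)]
        out1 = smote_tomek(X, y, seed=11)
        out2 = smote_tomek(X, y, seed=11)
        assert np.array_equal(out1[0], out2[0]) and np.array_equal(out1[1], out2[1])

    def test_single_minority_errors(self, rng):
        X = rng.standard_normal((10, 2))
        y = np.r_[np.zeros(9, int), np.ones(1, int)]
        with pytest.raises(ValueError):
            smote_tomek(X, y, seed=0)


class TestFitSignature:
    def _binary_data(self, rng, n=80):
        X = pd.DataFrame(
            rng.standard_normal((n, 4)), columns=["a", "b", "c", "d"]
        )
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-X["a"]))).astype(int)
        return X, y.to_numpy()

    def test_nested_loglik_monotone(self, rng):
        X, y = self._binary_data(rng)
        _, aic_s = fit_signature(("a",), X, y, "recurrence")
        _, aic_t = fit_signature(("a", "b"), X, y, "recurrence")
        ll_s = (2 * 2 - aic_s) / 2
        ll_t = (2 * 3 - aic_t) / 2
        assert ll_t >= ll_s - 1e-8

    def test_logistic_aic_grid_oracle(self):
        # printed 8-row toy table; 1-feature logistic AIC from a direct
        # likelihood grid maximization
        x = np.array([-1.5, -1.0, -0.5, -0.2, 0.2, 0.5, 1.0, 1.5])
        y = np.array([0, 0, 1, 0, 1, 0, 1, 1])
        X = pd.DataFrame({"x": x})

        def ll(b0, b1):
            eta = b0 + b1 * x
            return float(y @ eta - np.logaddexp(0, eta).sum())

        grid = np.linspace(-6, 6, 601)
        best = max(ll(b0, b1) for b0 in grid for b1 in grid)
        _, aic = fit_signature(("x",), X, y, "recurrence")
        assert aic == pytest.approx(2 * 2 - 2 * best, abs=1e-3)

    def test_collinear_design_infinite_aic(self, rng):
        X, y = self._binary_data(rng)
        X["a2"] = 2 * X["a"]
        coef, aic = fit_signature(("a", "a2"), X, y, "recurrence")
        assert coef is None and np.isinf(aic)

    def test_pure_noise_prefers_small_signatures(self, rng):
        n = 120
        X = pd.DataFrame(rng.standard_normal((n, 6)), columns=list("abcdef"))
        y = (rng.uniform(size=n) < 0.4).astype(int)
        small = np.mean(
            [fit_signature((f,), X, y, "recurrence")[1] for f in "abc"]
        )
        large = fit_signature(tuple("abcdef"), X, y, "recurrence")[1]
        assert small < large

    def test_cox_signature(self, rng):
        n = 100
        X = pd.DataFrame(rng.standard_normal((n, 3)), columns=["a", "b", "c"])
        t = rng.exponential(1 / (0.05 * np.exp(0.8 * X["a"])))
        e = (rng.uniform(size=n) < 0.8).astype(int)
        coef, aic = fit_signature(("a",), X, (t, e), "rfs")
        assert np.isfinite(aic) and coef[0] > 0.3


class TestOneSeRule:
    def _cand(self, sig, aics):
        return SignatureCandidate(tuple(sig), list(aics))

    def test_spec_hand_case_smaller_wins(self):
        # best mean 100 with SE 3: the 1-feature model at 102 is eligible
        s2 = self._cand(("a", "b", "c"), [100 + d for d in (-3, -1, 0, 1, 3)])
        assert s2.mean_aic == pytest.approx(100)
        se = s2.se_aic
        s1 = self._cand(("a",), [102] * 5)
        chosen = one_se_select([s1, s2])
        assert 102 <= 100 + se or chosen.signature == s2.signature
        if 102 <= 100 + se:
            assert chosen.signature == ("a",)

    def test_hand_cases_explicit_se(self):
        # construct fold AICs with mean 100, sd sqrt(5)*3 -> se exactly 3
        spread = np.array([-1.0, -0.5, 0.0, 0.5, 1.0])
        spread = spread / spread.std(ddof=1) * 3 * np.sqrt(5) / np.sqrt(5)
        base = 100 + spread * np.sqrt(5)
        s2 = self._cand(("a", "b", "c"), base)
        assert s2.mean_aic == pytest.approx(100)
        assert s2.se_aic == pytest.approx(3.0)
        s1_close = self._cand(("a",), [102] * 5)
        assert one_se_select([s1_close, s2]).signature == ("a",)
        s1_far = self._cand(("z",), [105] * 5)
        assert one_se_select([s1_far, s2]).signature == ("a", "b", "c")

    def test_single_candidate(self):
        c = self._cand(("a",), [10, 11, 12, 13, 14])
        assert one_se_select([c]) is c

    def test_never_larger_than_min_aic_signature(self, rng):
        cands = []
        for size in (1, 2, 3, 4):
            for j in range(3):
                sig = tuple(f"f{size}{j}{i}" for i in range(size))
                cands.append(self._cand(sig, 100 + rng.normal(0, 5, 5)))
        chosen = one_se_select(cands)
        best = min(cands, key=lambda c: c.mean_aic)
        assert len(chosen.signature) <= len(best.signature)
        assert chosen.mean_aic <= best.mean_aic + best.se_aic + 1e-12

    def test_min_folds_requirement(self):
        sparse = self._cand(("a",), [100, np.nan, np.nan, np.nan, np.nan])
        full = self._cand(("a", "b"), [110] * 5)
        assert one_se_select([sparse, full]).signature == ("a", "b")

    def test_all_infinite_errors(self):
        with pytest.raises(ValueError):
            one_se_select([self._cand(("a",), [np.nan] * 5)])


class TestRepetitionAndExperiment:
    def _setup(self, screen_cohort):
        proc, rec, _ = screen_cohort
        A = proc.subset(proc.center_ids("A"))
        B = proc.subset(proc.center_ids("B"))
        cfg = AnalysisConfig(
            n_selected_features=4, n_folds=3, n_repetitions=2, seed=3
        )
        return proc, rec, A, B, cfg

    def test_repetition_deterministic(self, screen_cohort):
        proc, rec, A, B, cfg = self._setup(screen_cohort)
        X = build_design(A, rec, "robust")
        frame = A.endpoint_frame("recurrence")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m1 = run_repetition(X, frame, "recurrence", cfg, seed=5)
            m2 = run_repetition(X, frame, "recurrence", cfg, seed=5)
        assert m1.signature == m2.signature
        assert np.allclose(m1.coef, m2.coef)

    def test_no_leakage_into_selection(self, screen_cohort, monkeypatch):
        """mRMR and rebalancing must only ever see fold-train rows."""
        proc, rec, A, B, cfg = self._setup(screen_cohort)
        X = build_design(A, rec, "HD_all")
        frame = A.endpoint_frame("recurrence")
        ids = sorted(frame.index.intersection(X.index))
        folds = kfold_split(ids, cfg.n_folds, frame.loc[ids, "y"], seed=5)
        allowed = [frozenset(train) for train, _ in folds]
        seen = []
        orig_mrmr = mv.mrmr_select
        orig_st = mv.smote_tomek

        def spy_mrmr(Xf, target, k, mode):
            seen.append(frozenset(Xf.index))
            return orig_mrmr(Xf, target, k, mode)

        sizes = []

        def spy_st(Xa, ya, k_neighbors=5, seed=0):
            sizes.append(len(Xa))
            return orig_st(Xa, ya, k_neighbors=k_neighbors, seed=seed)

        monkeypatch.setattr(mv, "mrmr_select", spy_mrmr)
        monkeypatch.setattr(mv, "smote_tomek", spy_st)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            run_repetition(X, frame, "recurrence", cfg, seed=5)
        assert len(seen) == cfg.n_folds
        for s in seen:
            assert s in allowed  # exactly a fold-train id set, never more
        fold_sizes = [len(t) for t, _ in folds]
        assert sizes == fold_sizes  # rebalancing input rows = fold-train rows

    def test_experiment_bookkeeping_and_determinism(self, screen_cohort):
        proc, rec, A, B, cfg0 = self._setup(screen_cohort)
        cfg = AnalysisConfig(
            n_selected_features=3, n_folds=3, n_repetitions=1, seed=9
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep1 = run_experiment(A, B, rec, cfg)
            rep2 = run_experiment(A, B, rec, cfg)
        assert len(rep1["metrics"]) == 12  # 4 subsets x 3 endpoints x 1 rep
        pd.testing.assert_frame_equal(rep1["metrics"], rep2["metrics"])
        assert rep1["metrics"]["n_features"].le(3).all()
        m = rep1["metrics"][["train", "internal_validation"]]
        assert m.stack().dropna().between(0, 1).all()

    def test_subset_designs(self, screen_cohort):
        proc, rec, A, B, cfg = self._setup(screen_cohort)
        n_feat = len(A.feature_names)
        n_robust = int(rec["robust"].sum())
        assert build_design(A, rec, "HD_all").shape[1] == n_feat
        assert build_design(A, rec, "LD_all").shape[1] == n_feat
        assert build_design(A, rec, "HD_and_LD").shape[1] == 2 * n_feat
        rob = build_design(A, rec, "robust")
        assert rob.shape[1] == n_robust
        assert all(c.endswith("__HD") for c in rob.columns)
        # robust columns are a subset of the combined design
        combined = build_design(A, rec, "HD_and_LD")
        assert set(rob.columns) <= set(combined.columns)
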