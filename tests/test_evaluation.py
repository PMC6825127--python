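import itertools

import numpy as np
import pandas as pd
import pytest

from germline_nog.evaluation import (
    accuracy_recall,
    compare_groups,
    comparisons_to_frame,
    cox_covariates,
    km_logrank,
    logrank_statistic,
)


def calls_series(low_ids, high_ids, unpred_ids=()):
    return pd.Series({**{s: "low" for s in low_ids},
                      **{s: "high" for s in high_ids},
                      **{s: "unpredicted" for s in unpred_ids}})


class TestAccuracyRecall:
    def test_footnote_arithmetic(self):
        # predicted-low: 9 non-recurred + 1 recurred; predicted-high: 1 + 1
        low = [f"L{i}" for i in range(10)]
        high = ["H0", "H1"]
        labels = pd.Series({**{s: "non-recurred" for s in low[:9]},
                            low[9]: "recurred",
                            "H0": "non-recurred", "H1": "recurred"})
        rep = accuracy_recall(calls_series(low, high), labels)
        assert rep.low_accuracy == pytest.approx(90.0)
        assert rep.low_recall == pytest.approx(90.0)
        assert rep.high_accuracy == pytest.approx(50.0)
        assert rep.high_recall == pytest.approx(50.0)
        # reconstructible from the emitted 2x2 counts
        c = rep.counts
        assert 100 * c.loc["low", "non-recurred"] / c.loc["low"].sum() == rep.low_accuracy
        assert rep.n == 12

    def test_empty_denominators_are_na(self):
        labels = pd.Series({"A": "non-recurred", "B": "non-recurred"})
        rep = accuracy_recall(calls_series(["A", "B"], []), labels)
        assert rep.low_accuracy == 100.0
        assert np.isnan(rep.high_accuracy) and np.isnan(rep.high_recall)

    def test_unpredicted_excluded(self):
        labels = pd.Series({"A": "non-recurred", "B": "recurred", "C": "recurred"})
        rep = accuracy_recall(calls_series(["A"], ["B"], ["C"]), labels)
        assert rep.n == 2
        assert rep.high_recall == pytest.approx(100.0)

    def test_order_invariance(self):
        labels = pd.Series({"A": "non-recurred", "B": "recurred",
                            "C": "non-recurred", "D": "recurred"})
        r1 = accuracy_recall(calls_series(["A", "B"], ["C", "D"]), labels)
        r2 = accuracy_recall(calls_series(["B", "A"], ["D", "C"])[::-1], labels)
        assert r1.low_accuracy == r2.low_accuracy
        assert r1.counts.equals(r2.counts)

    def test_all_unpredicted_rejected(self):
        labels = pd.Series({"A": "recurred"})
        with pytest.raises(ValueError):
            accuracy_recall(calls_series([], [], ["A"]), labels)


def survival_frame(times, events, groups):
    return pd.DataFrame({"dfs_months": times, "event": events, "group": groups})


class TestKMLogrank:
    def test_identical_groups_give_null_statistic(self):
        t = [5, 10, 15, 20]
        e = [1, 1, 0, 1]
        rec = survival_frame(t + t, e + e, ["low"] * 4 + ["high"] * 4)
        curves, chi2, p = km_logrank(rec)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)
        assert set(curves) == {"low", "high"}

    def test_statistic_matches_lifelines(self, rng):
        t = rng.exponential(50, 40).round(2)
        e = rng.random(40) < 0.7
        g = np.where(rng.random(40) < 0.5, "low", "high")
        if len(set(g)) < 2 or e.sum() == 0:  # pragma: no cover
            pytest.skip("degenerate draw")
        rec = survival_frame(t, e.astype(int), g)
        _, chi2, _ = km_logrank(rec)
        assert logrank_statistic(t, e, g) == pytest.approx(chi2, rel=1e-8)

    def test_single_group_rejected(self):
        rec = survival_frame([1, 2, 3], [1, 1, 0], ["low"] * 3)
        with pytest.raises(ValueError):
            km_logrank(rec)

    def test_no_events_rejected(self):
        rec = survival_frame([1, 2], [0, 0], ["low", "high"])
        with pytest.raises(ValueError):
            km_logrank(rec)

    def test_permutation_oracle_small_fixture(self, rng):
        """Monte-Carlo permutation p using the package statistic agrees with
        exhaustive enumeration over all balanced group assignments."""
        t = np.array([3.0, 6.0, 9.0, 12.0, 20.0, 30.0])
        e = np.array([1, 1, 0, 1, 1, 0])
        g = np.array(["high", "high", "high", "low", "low", "low"])
        obs = logrank_statistic(t, e, g)

        def exact_p():
            hits = total = 0
            for pos in itertools.combinations(range(6), 3):
                gg = np.array(["low"] * 6)
                gg[list(pos)] = "high"
                total += 1
                if logrank_statistic(t, e, gg) >= obs - 1e-12:
                    hits += 1
            return hits / total

        mc = np.mean([
            logrank_statistic(t, e, rng.permutation(g)) >= obs - 1e-12
            for _ in range(4000)
        ])
        p_exact = exact_p()
        se = np.sqrt(p_exact * (1 - p_exact) / 4000)
        assert abs(mc - p_exact) <= 4 * se + 1e-9


class TestCox:
    def test_binary_covariate_matches_logrank(self, rng):
        n = 500
        grp = rng.integers(0, 2, n)
        t_ev = rng.exponential(1 / np.where(grp == 1, 0.013, 0.009))
        c = rng.uniform(0, 120, n)
        df = pd.DataFrame({
            "dfs_months": np.minimum(t_ev, c),
            "event": (t_ev <= c).astype(int),
            "group": np.where(grp == 1, "high", "low"),
            "bin": grp,
        })
        _, _, p_lr = km_logrank(df)
        rep = cox_covariates(df, covariates=("bin",))
        assert rep.loc[rep.model == "bin", "converged"].all()
        assert rep.loc[rep.model == "bin", "p"].iloc[0] == pytest.approx(
            p_lr, abs=0.01)

    def test_null_covariate_small_coefficient(self, rng):
        n = 400
        t_ev = rng.exponential(80, n)
        c = rng.uniform(0, 120, n)
        df = pd.DataFrame({"dfs_months": np.minimum(t_ev, c),
                           "event": (t_ev <= c).astype(int),
                           "noise": rng.normal(0, 1, n)})
        rep = cox_covariates(df, covariates=("noise",))
        coef = rep.iloc[0]["coefficients"]["noise"]
        assert abs(coef) < 0.25

    def test_zero_variation_covariate_dropped(self, rng):
        df = pd.DataFrame({"dfs_months": rng.uniform(1, 50, 30),
                           "event": rng.integers(0, 2, 30),
                           "flat": np.ones(30)})
        with pytest.raises(ValueError):
            cox_covariates(df, covariates=("flat",))

    def test_stage_encoded_ordinally(self, rng):
        n = 60
        df = pd.DataFrame({
            "dfs_months": rng.uniform(1, 80, n),
            "event": rng.integers(0, 2, n),
            "stage": rng.choice(["I", "II", "III", "X"], n),
            "age": rng.normal(60, 8, n),
        })
        rep = cox_covariates(df, covariates=("stage", "age"))
        assert set(rep.model) == {"stage", "age", "joint"}


class TestCompareGroups:
    def test_identical_groups_null(self):
        X = pd.DataFrame([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]], index=["f"],
                         columns=[f"S{i}" for i in range(6)])
        calls = calls_series(["S0", "S1", "S2"], ["S3", "S4", "S5"])
        res = compare_groups(X, calls)[0]
        assert res.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_welch_matches_textbook_formula(self, rng):
        from scipy import stats as ss

        a = rng.normal(0, 1, 18)
        b = rng.normal(0.8, 2, 25)
        X = pd.DataFrame([np.concatenate([a, b])], index=["f"],
                         columns=[f"S{i}" for i in range(43)])
        calls = calls_series([f"S{i}" for i in range(18)],
                             [f"S{i}" for i in range(18, 43)])
        res = compare_groups(X, calls)[0]
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        p = 2 * ss.t.sf(abs(t), df)
        assert res.t_statistic == pytest.approx(t, abs=1e-10)
        assert res.df == pytest.approx(df, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_small_group_gives_na(self):
        X = pd.DataFrame([[1.0, 2.0, 3.0]], index=["f"],
                         columns=["S0", "S1", "S2"])
        calls = calls_series(["S0", "S1"], ["S2"])
        res = compare_groups(X, calls)[0]
        assert np.isnan(res.p_value)

    def test_bh_adjustment_flag(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (5, 30)),
                         index=[f"f{i}" for i in range(5)],
                         columns=[f"S{i}" for i in range(30)])
        calls = calls_series([f"S{i}" for i in range(15)],
                             [f"S{i}" for i in range(15, 30)])
        res = compare_groups(X, calls, adjust=True)
        frame = comparisons_to_frame(res)
        assert (frame["q"].dropna() >= frame["p"].dropna() - 1e-12).all()
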