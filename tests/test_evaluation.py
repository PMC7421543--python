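import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import wristahi as wa
from wristahi.evaluation import (
    ContingencyTable2x2,
    binary_table,
    kappa_statistics,
    weighted_kappa_max,
)


class TestKappaStatistics:
    def test_closed_form_table(self):
        # hand-computed: po=0.8, pe=0.5 -> kappa 0.6; balanced marginals
        stats = kappa_statistics(ContingencyTable2x2(tp=40, fp=10, fn=10, tn=40))
        assert stats["kappa"] == pytest.approx(0.6, abs=1e-12)
        assert stats["prevalence_index"] == pytest.approx(0.0)
        assert stats["bias_index"] == pytest.approx(0.0)
        assert stats["kappa_max"] == pytest.approx(1.0)  # matched marginals

    def test_perfect_and_degenerate_predictions(self):
        y = np.array([1, 1, 0, 0, 1, 0])
        m = wa.epoch_metrics(y, y, y.astype(float), np.ones(6))
        assert m["kappa"] == pytest.approx(1.0)
        assert m["roc_auc"] == pytest.approx(1.0)
        m2 = wa.epoch_metrics(y, np.zeros(6), np.zeros(6), np.ones(6))
        assert m2["sensitivity"] == 0.0
        assert m2["specificity"] == 1.0

    def test_empty_contributing_set_fatal(self):
        with pytest.raises(ValueError, match="contributing"):
            wa.epoch_metrics(np.ones(5), np.ones(5), np.ones(5), np.zeros(5))

    @given(
        st.tuples(
            st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(1, 50)
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_kappa_never_exceeds_max(self, counts):
        table = ContingencyTable2x2(*counts)
        stats = kappa_statistics(table)
        assert stats["kappa"] <= stats["kappa_max"] + 1e-12


class TestWeightedKappa:
    def test_one_class_shift_matches_hand_formula(self):
        ref = np.array([0, 1, 2, 3, 1, 2, 3, 3])
        est = np.maximum(ref - 1, 0)  # uniformly one class down
        rep = wa.screening_and_severity(
            np.array([1, 10, 20, 40, 10, 20, 40, 40.0]),
            np.array([1, 1, 10, 20, 1, 10, 20, 20.0]),
        )
        # hand linear-weight formula on the 4x4 table
        conf = rep.severity_confusion
        n = conf.sum()
        v = np.abs(np.subtract.outer(np.arange(4), np.arange(4)))
        row = conf.sum(axis=1) / n
        col = conf.sum(axis=0) / n
        d_o = np.sum(v * conf) / n
        d_e = np.sum(v * np.outer(row, col))
        assert rep.weighted_kappa == pytest.approx(1 - d_o / d_e, abs=1e-10)
        assert rep.weighted_kappa <= rep.weighted_kappa_max + 1e-12

    def test_perfect_agreement(self):
        ref = np.array([2.0, 10.0, 20.0, 40.0, 7.0])
        rep = wa.screening_and_severity(ref, ref.copy())
        assert rep.weighted_kappa == pytest.approx(1.0)
        assert rep.spearman_rho == pytest.approx(1.0)
        assert rep.bias == pytest.approx(0.0)
        assert rep.loa == pytest.approx(0.0)

    def test_lp_maximum_matches_enumeration(self):
        """Integer enumeration oracle for the marginal-constrained maximum."""
        conf = np.array([[2, 1, 0, 0], [0, 1, 1, 0], [1, 0, 2, 0], [0, 0, 1, 1]])
        n = conf.sum()
        v = np.abs(np.subtract.outer(np.arange(4), np.arange(4)))
        rows, cols = conf.sum(axis=1), conf.sum(axis=0)

        def tables(row_left, col_left, i):
            if i == 3:
                yield [list(col_left)]
                return
            for combo in itertools.product(*[range(min(row_left[i], c) + 1) for c in col_left]):
                if sum(combo) == rows[i] if i == 0 else sum(combo) == row_left[i]:
                    rest = [c - x for c, x in zip(col_left, combo)]
                    for t in tables(row_left, rest, i + 1):
                        yield [list(combo)] + t

        best = np.inf
        for t in tables(list(rows), list(cols), 0):
            t = np.array(t)
            if np.all(t.sum(axis=1) == rows) and np.all(t.sum(axis=0) == cols):
                best = min(best, np.sum(v * t) / n)
        d_e = np.sum(v * np.outer(rows / n, cols / n))
        expected = 1 - best / d_e
        assert weighted_kappa_max(conf) == pytest.approx(expected, abs=1e-9)

    def test_binary_reduces_to_min_marginal_form(self):
        conf = np.array([[30, 10], [5, 55]])
        n = conf.sum()
        row = conf.sum(axis=1) / n
        col = conf.sum(axis=0) / n
        po_max = min(row[0], col[0]) + min(row[1], col[1])
        pe = row @ col
        assert weighted_kappa_max(conf) == pytest.approx((po_max - pe) / (1 - pe), abs=1e-10)


class TestIcc:
    def test_hand_anova_three_recordings(self):
        ref = np.array([10.0, 20.0, 30.0])
        est = np.array([12.0, 18.0, 33.0])
        # independent two-way ANOVA closed form
        x = np.column_stack([ref, est])
        n, k = x.shape
        grand = x.mean()
        msr = k * np.sum((x.mean(axis=1) - grand) ** 2) / (n - 1)
        msc = n * np.sum((x.mean(axis=0) - grand) ** 2) / (k - 1)
        mse = (np.sum((x - grand) ** 2) - (n - 1) * msr - (k - 1) * msc) / (
            (n - 1) * (k - 1)
        )
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        got = wa.icc21(ref, est)
        assert got["icc"] == pytest.approx(expected, abs=1e-10)

    def test_matches_pingouin_including_ci(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(20)
        ref = rng.uniform(0, 60, 15)
        est = 0.8 * ref + rng.normal(0, 5, 15)
        got = wa.icc21(ref, est)
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(15), 2),
                "raters": ["a", "b"] * 15,
                "scores": np.column_stack([ref, est]).ravel(),
            }
        )
        r = pg.intraclass_corr(df, targets="targets", raters="raters", ratings="scores")
        row = r[r.Type == "ICC(A,1)"].iloc[0] if "ICC(A,1)" in set(r.Type) else r[r.Type == "ICC2"].iloc[0]
        assert got["icc"] == pytest.approx(row.ICC, abs=1e-8)
        assert got["ci95"][0] == pytest.approx(row.CI95[0], abs=0.01)
        assert got["ci95"][1] == pytest.approx(row.CI95[1], abs=0.01)

    def test_too_few_recordings_fatal(self):
        with pytest.raises(ValueError):
            wa.icc21([1.0, 2.0], [1.0, 2.0])


class TestAgreement:
    def test_constant_shift(self):
        ref = np.array([5.0, 15.0, 25.0, 40.0])
        rep = wa.ahi_agreement(ref, ref + 5.0)
        assert rep.spearman_rho == pytest.approx(1.0)
        assert rep.bias == pytest.approx(-5.0)  # reference minus estimated
        assert rep.loa == pytest.approx(0.0, abs=1e-9)
        assert rep.icc < 1.0

    def test_limits_match_raw_differences(self):
        rng = np.random.default_rng(21)
        ref = rng.uniform(0, 60, 30)
        est = ref + rng.normal(3, 8, 30)
        rep = wa.ahi_agreement(ref, est)
        diff = ref - est
        assert rep.bias == pytest.approx(diff.mean(), abs=1e-12)
        assert rep.loa == pytest.approx(1.96 * diff.std(ddof=1), abs=1e-12)


class TestScreening:
    def test_sensitivity_monotone_in_threshold(self):
        rng = np.random.default_rng(22)
        ref = rng.uniform(0, 60, 60)
        est = ref + rng.normal(0, 8, 60)
        rep = wa.screening_and_severity(ref, est, thresholds=(5, 10, 15, 20, 30))
        sens = [r["sensitivity"] for r in rep.screening]
        assert all(a >= b - 1e-12 for a, b in zip(sens, sens[1:]))

    def test_single_reference_class_flags_auc_undefined(self):
        ref = np.array([40.0, 50.0, 45.0, 60.0])
        est = ref + np.array([1.0, -2.0, 3.0, 0.0])
        rep = wa.screening_and_severity(ref, est, thresholds=(5.0,))
        assert not rep.screening[0]["auc_defined"]
        assert np.isnan(rep.screening[0]["roc_auc"])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_roc_auc_rank_equals_trapezoid(self, seed):
        from sklearn.metrics import roc_auc_score, roc_curve

        rng = np.random.default_rng(seed)
        y = rng.random(40) < 0.4
        if y.all() or not y.any():
            return
        s = rng.normal(size=40)
        # rank (Mann-Whitney) formulation
        from scipy.stats import rankdata

        r = rankdata(s)
        n1, n0 = y.sum(), (~y).sum()
        auc_rank = (r[y].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
        fpr, tpr, _ = roc_curve(y, s)
        auc_trap = np.trapezoid(tpr, fpr)
        assert auc_rank == pytest.approx(auc_trap, abs=1e-10)
        assert roc_auc_score(y, s) == pytest.approx(auc_rank, abs=1e-10)


class TestMisestimation:
    @pytest.mark.parametrize(
        "ref,est,flag",
        [
            (7.1, 30.0, "over"),  # 30 > 2*7.1 + 5 = 19.2
            (30.0, 14.0, "under"),  # 14 < 2/3*30 - 5 = 15
            (10.0, 10.0, "none"),
            (2.0, 10.0, "over"),  # 10 > 2*2 + 5 = 9
            (2.0, 0.0, "none"),  # below 5 can only be over-flagged
            (10.0, 2.0, "under"),  # 2 < 10/2 - 2.5 = 2.5
            (20.0, 38.0, "over"),  # 38 > 1.5*20 + 7.5 = 37.5
        ],
    )
    def test_flag_rules(self, ref, est, flag):
        assert wa.flag_misestimation(ref, est) == flag


class TestErrorRegression:
    def test_sparse_recovery(self):
        rng = np.random.default_rng(23)
        n = 200
        x = rng.normal(size=(n, 10))
        y = 2.0 * x[:, 0] + rng.normal(0, 0.5, n)
        res = wa.error_regression(x, y, seed=0)
        coefs = list(res["coefficients"].values())
        assert coefs[0] != 0.0
        assert sum(c == 0.0 for c in coefs[1:]) >= 7
        assert res["r2"] > 0.8

    def test_null_model_low_r2(self):
        rng = np.random.default_rng(24)
        x = rng.normal(size=(200, 8))
        y = rng.normal(size=200)
        res = wa.error_regression(x, y, seed=0)
        assert res["r2"] < 0.1

    def test_duplicate_predictors_do_not_fail(self):
        rng = np.random.default_rng(25)
        x1 = rng.normal(size=(100, 1))
        x = np.hstack([x1, x1, rng.normal(size=(100, 2))])
        y = x1[:, 0] + rng.normal(0, 0.3, 100)
        res = wa.error_regression(x, y, seed=0)
        assert np.isfinite(res["r2"])

    def test_too_few_recordings_fatal(self):
        with pytest.raises(ValueError):
            wa.error_regression(np.zeros((5, 2)), np.zeros(5))
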