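"""Cohort statistics against scipy oracles and hand-computed values."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from imprintscore.cohort_stats import (
    anova_oneway,
    classification_summary,
    coefficient_of_determination,
    demethylation_extent,
    group_tests,
    pearson_correlation,
    percent_positive,
    student_t,
    triad_correlation,
    welch_t,
)
from imprintscore.synthetic_data import SimulationConfig, simulate_triads


class TestPearson:
    def test_perfect_linear_relations(self):
        x = np.arange(1.0, 11.0)
        assert pearson_correlation(x, 2 * x) == pytest.approx((1.0, 1.0))
        r, r2 = pearson_correlation(x, -x)
        assert (r, r2) == pytest.approx((-1.0, 1.0))

    def test_matches_brute_force_covariance_ratio(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x, y = rng.normal(size=(2, 50))
            r, _ = pearson_correlation(x, y)
            brute = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
            assert r == pytest.approx(brute, abs=1e-12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=(2, 200))
        r, _ = pearson_correlation(x, y)
        assert r == pytest.approx(stats.pearsonr(x, y).statistic, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1, 2], [3, 4])
        with pytest.raises(ValueError):
            pearson_correlation([1, 1, 1], [1, 2, 3])

    def test_r_squared_of_printed_correlation(self):
        assert round(coefficient_of_determination(0.78), 2) == 0.61


class TestTTests:
    def test_hand_computed_pooled_t(self):
        res = student_t([1, 2, 3], [4, 5, 6])
        assert res.statistic == pytest.approx(-3.674, abs=1e-3)
        assert res.df[0] == 4

    def test_identical_groups_give_zero_statistic(self):
        x = [1.0, 2.0, 3.0]
        assert student_t(x, x).statistic == 0.0
        assert welch_t(x, x).p_value == 1.0

    def test_welch_matches_scipy(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 30)
        y = rng.normal(0.5, 2, 20)
        res = welch_t(x, y)
        ref = stats.ttest_ind(x, y, equal_var=False)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-6)

    def test_student_matches_scipy(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 15)
        y = rng.normal(1, 1, 25)
        res = student_t(x, y)
        ref = stats.ttest_ind(x, y, equal_var=True)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-6)


class TestAnova:
    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(10)
        groups = {g: rng.normal(i, 1, 12) for i, g in enumerate("abc")}
        res = anova_oneway(groups)
        ref = stats.f_oneway(*groups.values())
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-6)

    def test_two_group_f_equals_squared_pooled_t(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(size=(2, 20))
        f = anova_oneway({"x": x, "y": y}).statistic
        t = student_t(x, y).statistic
        assert f == pytest.approx(t ** 2, abs=1e-9)

    def test_group_tests_dispatches_on_group_count(self):
        rng = np.random.default_rng(12)
        two = {g: rng.normal(size=10) for g in "ab"}
        three = {g: rng.normal(size=10) for g in "abc"}
        assert group_tests(two).test == "welch_t"
        assert group_tests(two, method="student").test == "student_t"
        assert group_tests(three).test == "anova_oneway"
        with pytest.raises(ValueError):
            group_tests({"a": [1.0, 2.0]})


class TestDemethylation:
    @staticmethod
    def _table():
        rows = []
        for sid, g, v14, vl1 in [("n1", "normal", 50, 70), ("n2", "normal", 50, 70),
                                 ("t1", "early", 31, 65), ("t2", "early", 33, 66),
                                 ("t3", "early", 29, 64)]:
            for dmr in ("DMR-1", "DMR-2", "DMR-3"):
                rows.append({"sample_id": sid, "group": g, "locus": "14q32",
                             "dmr": dmr, "methylation_pct": float(v14)})
            rows.append({"sample_id": sid, "group": g, "locus": "LINE1",
                         "dmr": "LINE1", "methylation_pct": float(vl1)})
        return pd.DataFrame(rows)

    def test_deltas_are_normal_minus_sample(self):
        res = demethylation_extent(self._table(), {"14q32": 50.0, "LINE1": 70.0})
        d = res.deltas.set_index(["sample_id", "locus"])["delta"]
        assert d[("t1", "14q32")] == pytest.approx(19.0)
        assert d[("n1", "14q32")] == pytest.approx(0.0)
        assert d[("t3", "LINE1")] == pytest.approx(6.0)

    def test_swapping_normal_and_tumor_negates_delta(self):
        table = self._table()
        res = demethylation_extent(table, {"14q32": 31.0, "LINE1": 65.0})
        d = res.deltas.set_index(["sample_id", "locus"])["delta"]
        assert d[("n1", "14q32")] == pytest.approx(-19.0)

    def test_locus_contrast_is_significant_here(self):
        res = demethylation_extent(self._table(), {"14q32": 50.0, "LINE1": 70.0},
                                   group="early")
        assert res.test.p_value < 0.01

    def test_missing_normal_mean_is_an_error(self):
        with pytest.raises(ValueError, match="LINE1"):
            demethylation_extent(self._table(), {"14q32": 50.0})


class TestClassificationSummary:
    @pytest.mark.parametrize(
        "k,n,decimals,expected",
        [(20, 23, 0, 87.0), (5, 9, 0, 56.0), (13, 15, 1, 86.7),
         (11, 25, 0, 44.0), (16, 24, 1, 66.7), (8, 24, 1, 33.3), (0, 7, 0, 0.0)],
    )
    def test_count_to_percent_conversions(self, k, n, decimals, expected):
        assert percent_positive(k, n, decimals) == expected

    def test_rounding_error_bounded_by_half_width(self):
        for n in range(1, 40):
            for k in range(n + 1):
                assert abs(percent_positive(k, n, 0) - 100 * k / n) <= 0.5

    def test_summary_per_group(self):
        calls = pd.DataFrame({
            "group": ["early"] * 4 + ["late"] * 3,
            "call": ["positive", "positive", "positive", "negative",
                     "positive", "negative", "negative"],
        })
        out = {s.group: s for s in classification_summary(calls)}
        assert out["early"].n_positive == 3
        assert out["early"].percent_positive == 75.0
        assert out["late"].percent_positive == 33.0

    def test_unknown_call_labels_rejected(self):
        calls = pd.DataFrame({"group": ["a"], "call": ["maybe"]})
        with pytest.raises(ValueError):
            classification_summary(calls)


class TestTriads:
    def test_child_identical_to_father_gives_unit_correlation(self):
        rows = []
        rng = np.random.default_rng(20)
        values = rng.uniform(40, 80, 10)
        for i, v in enumerate(values):
            for member in ("child", "father", "mother"):
                rows.append({"triad_id": f"t{i}", "member": member, "dmr": "DMR-1",
                             "methylation_pct": v if member != "mother"
                             else rng.uniform(40, 80)})
        res = triad_correlation(pd.DataFrame(rows))
        father = res[(res.parent == "father")].iloc[0]
        assert father.r == pytest.approx(1.0)

    def test_simulated_triads_recover_targets(self):
        config = SimulationConfig(seed=21)
        res = triad_correlation(simulate_triads(5000, config)).set_index(["dmr", "parent"])
        assert res.loc[("DMR-1", "father"), "r"] == pytest.approx(0.5, abs=0.03)
        assert res.loc[("DMR-2", "mother"), "r"] == pytest.approx(0.63, abs=0.03)
        # the uncoupled parent is uncorrelated
        assert abs(res.loc[("DMR-1", "mother"), "r"]) < 0.05
        assert abs(res.loc[("DMR-2", "father"), "r"]) < 0.05

    def test_incomplete_triads_excluded_and_counted(self):
        rng = np.random.default_rng(22)
        rows = []
        for i in range(5):  # 5 complete triads
            for m in ("child", "mother", "father"):
                rows.append({"triad_id": f"t{i}", "member": m, "dmr": "DMR-1",
                             "methylation_pct": rng.uniform(40, 80)})
        for i in range(2):  # 2 triads missing the mother
            for m in ("child", "father"):
                rows.append({"triad_id": f"u{i}", "member": m, "dmr": "DMR-1",
                             "methylation_pct": rng.uniform(40, 80)})
        res = triad_correlation(pd.DataFrame(rows))
        assert (res["n"] == 5).all()
        assert (res["n_excluded"] == 2).all()
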