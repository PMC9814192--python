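"""Contrast estimation, rank tests, ranking tables, blot normalization."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mamsleep.errors import UndefinedMetricError
from mamsleep.stats import (
    BlotLane,
    compare_multi,
    compare_two,
    flag_above_max,
    normalize_blot,
    percent_change,
    rank_top_density,
)


class TestPercentChange:
    @pytest.mark.parametrize(
        "a, b, expected",
        [([2, 2, 2], [3, 3, 3], 50.0),
         ([1, 2, 3], [1, 2, 3], 0.0),
         ([1, 2, 3], [2, 3, 4], 50.0)],
    )
    def test_point_estimates(self, a, b, expected):
        pc, _ = percent_change(a, b, n_boot=100, seed=0)
        assert pc == pytest.approx(expected)

    def test_bootstrap_se_matches_large_resample_reference(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
        _, se = percent_change(a, b, n_boot=20_000, seed=1)
        _, se_ref = percent_change(a, b, n_boot=1_000_000, seed=99)
        assert se == pytest.approx(se_ref, rel=0.05)

    def test_zero_baseline_is_an_error(self):
        with pytest.raises(UndefinedMetricError):
            percent_change([-1, 0, 1], [1, 2, 3])

    def test_recovers_planted_multiplicative_effect(self):
        # degenerate groups: exact; noisy groups: within 2 bootstrap SEs
        a = np.full(30, 5.0)
        pc, _ = percent_change(a, a * 1.3, n_boot=100, seed=0)
        assert pc == pytest.approx(30.0)
        rng = np.random.default_rng(4)
        a = rng.normal(10, 1, 60)
        b = rng.normal(13, 1, 60)
        pc, se = percent_change(a, b, n_boot=5000, seed=0)
        assert abs(pc - 30.0) < 2 * se


class TestCompareTwo:
    def test_identical_groups_student_t(self):
        res = compare_two([1, 2, 3], [1, 2, 3], test="student_t", n_boot=0)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_mann_whitney_exact_separated_groups(self):
        # U = 0; two-sided exact p = 2 / C(8,4) = 2/70
        res = compare_two([1, 2, 3, 4], [10, 11, 12, 13], test="mann_whitney", n_boot=0)
        assert res.p_value == pytest.approx(2 / 70)

    def test_constant_identical_groups_mann_whitney(self):
        res = compare_two([5, 5, 5], [5, 5, 5], test="mann_whitney", n_boot=0)
        assert res.p_value == 1.0
        assert "zero-variance" in res.flags

    def test_welch_power_at_two_sigma_effect(self):
        """Welch t at n=6 vs 6 and a 2-sigma shift rejects at the rate the
        noncentral-t distribution predicts (~87 %)."""
        # closed-form oracle: power = P(|T'| > t_crit), T' ~ nct(df, ncp)
        ncp = 2.0 / math.sqrt(1 / 6 + 1 / 6)
        df = 10
        t_crit = sps.t.ppf(0.975, df)
        power = 1 - sps.nct.cdf(t_crit, df, ncp) + sps.nct.cdf(-t_crit, df, ncp)
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(1000):
            a = rng.normal(0, 1, 6)
            b = rng.normal(2, 1, 6)
            if compare_two(a, b, test="welch_t", n_boot=0).p_value < 0.05:
                hits += 1
        assert hits / 1000 == pytest.approx(power, abs=0.035)

    def test_welch_type_one_error_calibrated(self):
        """Null rejection rate at alpha=0.05 is 5 % +/- 0.7 % over 10 000
        seeded draws (two N(0,1) groups, n=6)."""
        rng = np.random.default_rng(12345)
        a = rng.normal(size=(10_000, 6))
        b = rng.normal(size=(10_000, 6))
        _, p = sps.ttest_ind(a, b, axis=1, equal_var=False)
        rate = (p < 0.05).mean()
        assert abs(rate - 0.05) <= 0.007
        # spot-check our wrapper agrees with the vectorized reference
        res = compare_two(a[0], b[0], test="welch_t", n_boot=0)
        assert res.p_value == pytest.approx(p[0])


class TestCompareMulti:
    def test_identical_groups_omnibus(self):
        groups = {"a": [1, 1, 2, 2], "b": [1, 1, 2, 2], "c": [1, 2, 1, 2]}
        res = compare_multi(groups, n_boot=0)
        assert res[0].test == "kruskal_wallis"
        assert res[0].p_value > 0.9

    def test_separated_groups_h_statistic_and_dunn(self):
        # ranks 1-5 / 6-10 / 11-15 -> H = 12.5 by the direct rank formula
        groups = {
            "a": list(range(1, 6)),
            "b": list(range(11, 16)),
            "c": list(range(21, 26)),
        }
        res = compare_multi(groups, n_boot=0)
        assert res[0].statistic == pytest.approx(12.5)
        dunn = [r for r in res if r.test == "dunn"]
        assert len(dunn) == 3
        extreme = [r for r in dunn if {r.group_a, r.group_b} == {"a", "c"}][0]
        assert extreme.p_value < 0.05

    def test_paired_wilcoxon_constant_shift_exact_p(self):
        # constant positive shift, n = 10 -> two-sided exact p = 2/2^10
        x = np.arange(10, dtype=float)
        res = compare_multi(
            {"g": x, "h": x + 100},  # omnibus groups (content irrelevant here)
            paired_followup="wilcoxon",
            paired={"g": (x, x + 3.0)},
            correction="none",
            n_boot=0,
        )
        wil = [r for r in res if r.test == "wilcoxon"][0]
        assert wil.p_value == pytest.approx(2 / 2**10)

    def test_bonferroni_never_rejects_more_than_uncorrected(self):
        rng = np.random.default_rng(3)
        groups = {k: rng.normal(i * 0.5, 1, 12) for i, k in enumerate("abcd")}
        corrected = compare_multi(groups, correction="bonferroni", n_boot=0)
        raw = compare_multi(groups, correction="none", n_boot=0)
        for rc, rr in zip(corrected, raw):
            if rc.test == "dunn":
                assert rc.p_value >= rr.p_value

    def test_small_group_is_an_error(self):
        with pytest.raises(ValueError, match="b"):
            compare_multi({"a": [1, 2, 3], "b": [1]}, n_boot=0)


def _records(values, prefix="c"):
    return pd.DataFrame({
        "cell_id": [f"{prefix}{i:03d}" for i in range(len(values))],
        "metric": values,
    })


class TestRanking:
    def test_top_20_of_1_to_30(self):
        a = _records(list(range(1, 31)))
        b = _records(list(range(1, 31)), prefix="d")
        out = rank_top_density(a, b, "metric", k=20)
        top_a = out[out.group == "A"]["metric"].tolist()
        assert top_a == list(range(30, 10, -1))

    def test_ties_broken_by_cell_id(self):
        a = _records([5, 5, 5, 1])
        b = _records([2, 2, 2, 2], prefix="d")
        out = rank_top_density(a, b, "metric", k=3)
        assert out[out.group == "A"]["cell_id"].tolist() == ["c000", "c001", "c002"]

    def test_k_shrinks_when_values_missing(self):
        a = _records([1.0, 2.0, float("nan")])
        b = _records([1.0, 2.0, 3.0], prefix="d")
        out = rank_top_density(a, b, "metric", k=3)
        assert out["k"].iloc[0] == 2

    def test_flag_above_max_is_strict(self):
        a = _records([1.0, 4.0])
        b = _records([3.9, 4.0, 4.1], prefix="d")
        n, ids = flag_above_max(a, b, "metric")
        assert n == 1 and ids == ["d002"]

    def test_flag_above_max_none(self):
        a = _records([1.0, 4.0])
        b = _records([0.5, 2.0], prefix="d")
        n, ids = flag_above_max(a, b, "metric")
        assert n == 0 and ids == []

    def test_flag_above_max_planted_outliers(self):
        rng = np.random.default_rng(6)
        a = _records(rng.normal(1.0, 0.05, 139))
        base_b = rng.normal(0.9, 0.03, 122)   # clearly inside the A-range
        outliers = rng.normal(3.0, 0.05, 10)  # clearly above it
        b = _records(np.concatenate([base_b, outliers]), prefix="d")
        n, ids = flag_above_max(a, b, "metric")
        assert n == 10
        assert set(ids) == {f"d{i:03d}" for i in range(122, 132)}


class TestNormalizeBlot:
    def test_printed_formula_substitution(self):
        lanes = [BlotLane("L1", "S", 5.0, 10.0), BlotLane("L2", "SD", 8.0, 20.0)]
        out = normalize_blot(lanes)
        assert out["norm_factor"].tolist() == [0.5, 1.0]
        assert out["normalized_signal"].tolist() == [10.0, 8.0]

    def test_single_lane_unchanged(self):
        out = normalize_blot([BlotLane("L1", "S", 7.0, 42.0)])
        assert out["normalized_signal"].iloc[0] == 7.0

    def test_equal_totals_identity(self):
        lanes = [BlotLane(f"L{i}", "S", float(i + 1), 30.0) for i in range(4)]
        out = normalize_blot(lanes)
        assert out["normalized_signal"].tolist() == out["signal"].tolist()

    def test_nonpositive_signal_rejected(self):
        with pytest.raises(ValueError):
            BlotLane("L1", "S", 0.0, 10.0)
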