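"""Population split at the CPM threshold and the statistical comparisons."""

import itertools
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wntflux.models import DetectionVolume
from wntflux.popsplit import (
    WindowedMeasurement, classify_cpm, compare_counts, compare_dslow,
    compare_rca_groups, cpm_histogram, fisher_exact_2x2, window_analyze,
)
from wntflux.pipeline import sample_window_curves


def fisher_two_sided_oracle(table):
    """Exhaustive hypergeometric enumeration, probability-mass criterion."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(x):
        if x < max(0, c1 - r2) or x > min(r1, c1):
            return 0.0
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = prob(a)
    return sum(p for x in range(0, min(r1, c1) + 1)
               if (p := prob(x)) <= p_obs * (1 + 1e-9))


def ranksum_two_sided_oracle(a, b):
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    pooled = sorted(a + b)
    n_a = len(a)
    obs = sum(sorted(pooled).index(v) + 1 for v in a)
    stats = [sum(idx + 1 for idx in combo)
             for combo in itertools.combinations(range(len(pooled)), n_a)]
    mean = np.mean(stats)
    extreme = sum(abs(s - mean) >= abs(obs - mean) - 1e-9 for s in stats)
    return extreme / len(stats)


class TestClassify:
    def test_boundary_inclusive_to_high(self):
        assert classify_cpm([7.0]) == ["high"]
        assert classify_cpm([6.999]) == ["low"]
        assert classify_cpm([]) == []

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 30, allow_nan=False), max_size=50))
    def test_partition_property(self, cpms):
        labels = classify_cpm(cpms)
        assert labels.count("high") + labels.count("low") == len(cpms)

    def test_histogram_bins_anchor_at_zero(self):
        hist = cpm_histogram([1.0, 3.4, 3.5, 8.0])
        assert set(hist) == {(0.0, 3.5), (3.5, 7.0), (7.0, 10.5)}
        assert len(hist[(0.0, 3.5)]) == 2  # 3.5 goes to the next bin


class TestRankSum:
    def test_identical_singletons(self):
        p, method = compare_dslow([1.0], [1.0])
        assert method == "asymptotic"  # tie -> normal approximation
        assert p == pytest.approx(1.0)

    def test_most_extreme_small_sample(self):
        p, method = compare_dslow([1, 2, 3], [4, 5, 6])
        assert method == "exact"
        assert p == pytest.approx(0.1)
        assert p == pytest.approx(ranksum_two_sided_oracle([1, 2, 3], [4, 5, 6]))

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        a = list(rng.normal(0, 1, 4).round(3))
        b = list(rng.normal(0.5, 1, 5).round(3))
        p, method = compare_dslow(a, b)
        assert method == "exact"
        assert p == pytest.approx(ranksum_two_sided_oracle(a, b), abs=1e-10)

    def test_large_shift_highly_significant(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 50)
        b = rng.normal(2, 1, 50)
        p, _ = compare_dslow(a, b)
        assert p < 1e-6

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_dslow([], [1.0])


class TestFisher:
    def test_balanced_table(self):
        p, degenerate = fisher_exact_2x2([[5, 5], [5, 5]])
        assert p == 1.0 and not degenerate

    def test_diagonal_table_value(self):
        p, _ = fisher_exact_2x2([[10, 0], [0, 10]])
        assert p == pytest.approx(fisher_two_sided_oracle([[10, 0], [0, 10]]),
                                  rel=1e-9)
        assert p == pytest.approx(2 / comb(20, 10), rel=1e-9)

    def test_zero_margin_degenerate(self):
        p, degenerate = fisher_exact_2x2([[0, 0], [3, 4]])
        assert degenerate and p == 1.0

    def test_exhaustive_agreement_small_tables(self):
        # every 2x2 table with total count <= 12 (hence all margins <= 12)
        for n in range(1, 13):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        t = [[a, b], [c, d]]
                        p, degenerate = fisher_exact_2x2(t)
                        if degenerate:
                            continue
                        assert p == pytest.approx(fisher_two_sided_oracle(t),
                                                  rel=1e-9), t

    def test_bonferroni_adjustment(self):
        tables = [[[8, 2], [2, 8]]] * 3
        res = compare_counts(tables)
        for raw, adj in zip(res["p_raw"], res["p_adjusted"]):
            assert adj == pytest.approx(min(1.0, 3 * raw))


class TestTukey:
    def test_two_groups_reduce_to_pooled_t(self):
        from scipy.stats import ttest_ind
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.8, 1, 10)
        res = compare_rca_groups({"a": a, "b": b})
        t_p = ttest_ind(a, b, equal_var=True).pvalue
        assert res["pairs"][("a", "b")]["p_adjusted"] == pytest.approx(t_p, rel=1e-6)

    def test_degenerate_constant_groups(self):
        res = compare_rca_groups({"a": [1.0, 1.0], "b": [1.0, 1.0]})
        assert res["degenerate"]
        assert np.isnan(res["pairs"][("a", "b")]["p_adjusted"])

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(3)
        groups = {
            "ctrl": rng.normal(0, 1, 15),
            "same": rng.normal(0, 1, 15),
            "shift": rng.normal(3, 1, 15),
        }
        res = compare_rca_groups(groups)
        assert res["pairs"][("ctrl", "shift")]["p_adjusted"] < 0.05
        assert res["pairs"][("same", "shift")]["p_adjusted"] < 0.05
        assert res["pairs"][("ctrl", "same")]["p_adjusted"] > 0.05


class TestWindowAnalyze:
    def test_curve_series_mode(self, volume):
        curves = sample_window_curves("embryo_two_component", 8, volume, seed=5)
        meas = window_analyze(curves, window_length=10.0, volume=volume)
        assert len(meas) == 8
        assert all(m.d_fast >= m.d_slow for m in meas)
        assert all(0 <= m.f_slow <= 1 for m in meas)
        assert sum(m.qc_pass for m in meas) >= 7

    def test_trace_mode_counts_and_drift_flagging(self):
        # stationary first half, 50% linear decay in the second half
        rng = np.random.default_rng(7)
        n = 40_000
        lam = np.full(n, 20.0)
        lam[n // 2:] *= 1.0 - 0.5 * np.arange(n // 2) / (n // 2 - 1)
        from wntflux.fluctsim import IntensityTrace
        tr = IntensityTrace(bin_width=1e-3, counts={"g": rng.poisson(lam)})
        meas = window_analyze(tr, window_length=10.0, n_components=1,
                              triplet=False, volume=DetectionVolume())
        assert len(meas) == 4
        assert meas[0].qc_pass and meas[1].qc_pass
        assert not (meas[2].qc_pass and meas[3].qc_pass)

    def test_end_to_end_population_shift(self, volume):
        # removing the bright assemblies (sFRP2 condition) must empty the
        # high-CPM class; Fisher + Bonferroni rejects decisively
        counts = {}
        for scen in ("embryo_two_component", "embryo_plus_sfrp2"):
            curves = sample_window_curves(scen, 40, volume, seed=11)
            meas = window_analyze(curves, volume=volume)
            labels = classify_cpm([m for m in meas if m.qc_pass])
            counts[scen] = (labels.count("high"), labels.count("low"))
        assert counts["embryo_two_component"][0] > counts["embryo_plus_sfrp2"][0]
        res = compare_counts([[list(counts["embryo_two_component"]),
                               list(counts["embryo_plus_sfrp2"])]])
        assert res["p_adjusted"][0] < 1e-3
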