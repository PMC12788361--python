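"""Descriptive statistics, symmetry indices and the Wilcoxon signed-rank
test against independent oracles."""

import dataclasses
import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slidegait import synthetic as syn
from slidegait.errors import DataError
from slidegait.metrics import (
    bilateral_report,
    cycle_metrics,
    descriptive_stats,
    paired_comparison,
    symmetry_index,
)

finite = st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False)


class TestDescriptiveStats:
    def test_small_example(self):
        s = descriptive_stats(np.array([1.0, 2.0, 3.0]))
        assert (s.minimum, s.maximum, s.value_range, s.mean, s.sd) == (1, 3, 2, 2, 1)

    def test_published_hip_flexion_range(self):
        # bilateral hip-flexion extrema reproduce the published ranges
        assert descriptive_stats(np.array([89.67, 122.09])).value_range == pytest.approx(32.42)
        assert descriptive_stats(np.array([80.73, 121.85])).value_range == pytest.approx(41.12)

    def test_constant_series(self):
        s = descriptive_stats(np.full(10, 7.0))
        assert s.sd == 0 and s.value_range == 0 and s.cv == 0

    def test_zero_mean_flags_cv_undefined(self):
        s = descriptive_stats(np.array([-1.0, 1.0]))
        assert not s.cv_defined and math.isnan(s.cv)

    def test_empty_series_rejected(self):
        with pytest.raises(DataError):
            descriptive_stats(np.array([]))

    def test_extremum_times(self):
        x = np.zeros(101)
        x[30], x[70] = 5.0, -5.0
        s = descriptive_stats(x, sampling_rate=100.0)
        assert s.t_peak == pytest.approx(0.30)
        assert s.t_min == pytest.approx(0.70)
        assert s.t_peak_frac == pytest.approx(0.30)


class TestSymmetryIndex:
    @pytest.mark.parametrize(
        "left,right,expected",
        [
            (298.94, 331.95, 10.46),  # peak pressure
            (127.66, 167.00, 26.70),  # mean pressure
            (109.11, 110.45, 1.22),  # mean hip flexion
            (95.85, 95.52, 0.34),  # knee peak
            (29.51, 29.94, 1.45),  # knee minimum
            (72.38, 69.92, 3.46),  # knee mean
        ],
    )
    def test_published_percent_values(self, left, right, expected):
        e = symmetry_index(left, right)
        assert e.mode == "percent"
        assert round(e.value, 2) == pytest.approx(expected)

    def test_sign_crossing_fallback(self):
        e = symmetry_index(-5.04, 3.89)
        assert e.mode == "absolute_difference"
        assert e.value == pytest.approx(8.93)

    def test_both_zero_is_perfectly_symmetric(self):
        e = symmetry_index(0.0, 0.0)
        assert e.mode == "percent" and e.value == 0.0

    def test_zero_denominator_flagged_not_raised(self):
        e = symmetry_index(-1.0, 1.0)  # opposite signs -> fallback, never undefined
        assert e.mode == "absolute_difference"
        e = symmetry_index(0.0, 0.0)
        assert e.defined

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(x=finite)
    def test_identity_gives_zero(self, x):
        assert symmetry_index(x, x).value == 0.0

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(l=st.floats(0.1, 1e5), r=st.floats(0.1, 1e5), c=st.floats(0.1, 1e3))
    def test_symmetric_and_scale_invariant(self, l, r, c):
        a, b = symmetry_index(l, r), symmetry_index(r, l)
        assert a.value == pytest.approx(b.value, rel=1e-12)
        scaled = symmetry_index(c * l, c * r)
        assert scaled.value == pytest.approx(a.value, rel=1e-9)


class TestBilateralReport:
    def test_symmetric_zero_noise_config_yields_zero_si(self, noiseless_cfg):
        mirrored = dataclasses.replace(noiseless_cfg, right_profiles=noiseless_cfg.left_profiles)
        left, _ = syn.generate_cycle(mirrored, "left")
        right, _ = syn.generate_cycle(mirrored, "right")
        entries = bilateral_report(cycle_metrics(left), cycle_metrics(right))
        for e in entries:
            assert e.value <= 1e-9, e.metric_name

    def test_metric_list_shape(self, noiseless_left, noiseless_right):
        entries = bilateral_report(
            cycle_metrics(noiseless_left[0]), cycle_metrics(noiseless_right[0])
        )
        # pressure peak/min/mean/T_peak + 4 joints x 6 metrics
        assert len(entries) == 4 + 4 * 6
        names = {e.metric_name for e in entries}
        assert "pressure_peak" in names and "hip_abd_t_min" in names

    def test_mismatched_metric_sets_rejected(self, noiseless_left):
        m = cycle_metrics(noiseless_left[0])
        other = cycle_metrics(noiseless_left[0])
        del other.channels["pressure_N"]
        with pytest.raises(DataError):
            bilateral_report(m, other)


def brute_force_wilcoxon_p(d):
    """Two-sided exact p by enumerating all 2^m sign assignments."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    m = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=m)
    ]
    ws = np.array(ws)
    total = len(ws)
    p = 2.0 * min((ws <= w_obs).sum(), (ws >= w_obs).sum()) / total
    return min(1.0, p)


class TestPairedComparison:
    def test_all_positive_n8_exact(self):
        left = np.zeros(8)
        right = np.arange(1.0, 9.0)
        res = paired_comparison(left, right)
        assert res.test_name == "wilcoxon-exact"
        assert res.p == pytest.approx(2.0 / 2**8)
        assert res.z > 0

    def test_identical_samples_degenerate(self):
        x = np.arange(10.0)
        res = paired_comparison(x, x)
        assert res.degenerate and res.p == 1.0 and res.z == 0.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(5)
        l, r = rng.normal(0, 1, 15), rng.normal(0.5, 1, 15)
        a, b = paired_comparison(l, r), paired_comparison(r, l)
        assert a.z == pytest.approx(-b.z)
        assert a.p == pytest.approx(b.p)

    @pytest.mark.parametrize("n", [5, 6, 8, 10, 12])
    def test_exact_p_matches_enumeration(self, n):
        rng = np.random.default_rng(100 + n)
        for _ in range(5):
            d = rng.normal(0.3, 1.0, n)
            d = np.where(d == 0, 0.1, d)
            res = paired_comparison(np.zeros(n), d)
            assert res.p == pytest.approx(brute_force_wilcoxon_p(d), abs=1e-12)

    def test_large_sample_normal_branch(self):
        rng = np.random.default_rng(2)
        l = rng.normal(0, 1, 40)
        r = l + rng.normal(0.5, 1, 40)
        res = paired_comparison(l, r)
        assert res.test_name == "wilcoxon-normal"
        assert 0 < res.p < 1

    def test_short_samples_rejected(self):
        with pytest.raises(DataError):
            paired_comparison(np.ones(3), np.zeros(3))
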