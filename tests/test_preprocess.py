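import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp

import isletca as ic
from isletca.errors import DegenerateTraceError
from isletca import preprocess as pre


class TestSmoothing:
    def test_constant_is_identity(self):
        np.testing.assert_allclose(ic.smooth_trace(np.full(30, 7.0), 5), 7.0)

    def test_shrinking_edge_average(self):
        # hand-computed centred means with truncated edge windows
        np.testing.assert_allclose(
            ic.smooth_trace([0, 3, 0, 3, 0], 3), [1.5, 1, 2, 1, 1.5]
        )

    def test_default_window_is_15(self):
        x = np.arange(40.0)
        np.testing.assert_allclose(ic.smooth_trace(x), ic.smooth_trace(x, 15))

    def test_window_below_one_rejected(self):
        with pytest.raises(ValueError):
            ic.smooth_trace(np.zeros(10), 0)

    def test_out_of_range_window_warns(self):
        with pytest.warns(UserWarning, match="3-15"):
            ic.smooth_trace(np.zeros(40), 21)

    @given(hnp.arrays(float, st.integers(16, 80),
                      elements=st.floats(-100, 100)),
           st.integers(3, 15))
    def test_mean_preserved_up_to_edge_effects(self, x, w):
        sm = ic.smooth_trace(x, w)
        bound = (w / x.size) * (np.abs(x).max() + 1e-9) + 1e-9
        assert abs(sm.mean() - x.mean()) <= bound


class TestFoldChangeGeneral:
    def test_examples(self):
        fc = ic.fold_change_general(np.array([100.0, 150.0, 100.0]), (0, 3))
        np.testing.assert_allclose(fc.values, [0.0, 0.5, 0.0])
        assert fc.values[fc.source_window[0]:fc.source_window[1]].min() == 0.0

    def test_constant_trace_gives_zeros(self):
        fc = ic.fold_change_general(np.full(10, 5.0), (0, 10))
        np.testing.assert_array_equal(fc.values, 0.0)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(DegenerateTraceError, match="offset"):
            ic.fold_change_general(np.array([0.0, 1.0, 2.0]), (0, 2))

    @given(st.floats(0.1, 1e4))
    def test_invariant_to_positive_gain(self, k):
        x = np.array([10.0, 14.0, 11.0, 20.0, 10.5])
        a = ic.fold_change_general(x, (0, 5)).values
        b = ic.fold_change_general(k * x, (0, 5)).values
        np.testing.assert_allclose(a, b, rtol=1e-9, atol=1e-12)


class TestMinMaxNormalize:
    def test_linear_trace(self):
        n = ic.minmax_normalize(np.array([2.0, 4.0, 6.0]), (0, 3))
        np.testing.assert_allclose(n.values, [0.0, 0.5, 1.0])

    def test_constant_trace_rejected(self):
        with pytest.raises(DegenerateTraceError):
            ic.minmax_normalize(np.full(5, 3.0), (0, 5))

    def test_separate_min_window(self):
        x = np.array([5.0, 4.0, 8.0, 12.0])
        n = ic.minmax_normalize(x, window=(2, 4), min_window=(0, 2))
        np.testing.assert_allclose(n.values, (x - 4.0) / 8.0)


def _brute_extrema(x):
    peaks, valleys = [], []
    i = 1
    n = len(x)
    while i < n - 1:
        j = i
        while j + 1 < n and x[j + 1] == x[j]:
            j += 1
        if j + 1 < n:
            if x[i - 1] < x[i] and x[j + 1] < x[j]:
                peaks.append(i)
            elif x[i - 1] > x[i] and x[j + 1] > x[j]:
                valleys.append(i)
        i = j + 1
    return np.array(peaks), np.array(valleys)


class TestExtrema:
    def test_monotone_ramp_has_none(self):
        p, v = ic.detect_local_extrema(np.arange(10.0))
        assert p.size == 0 and v.size == 0

    def test_triangle_pulse(self):
        p, v = ic.detect_local_extrema(np.array([0, 1, 2, 1, 0.0]))
        np.testing.assert_array_equal(p, [2])
        assert v.size == 0

    def test_two_pulses_one_dip(self):
        x = np.array([0, 2, 0.5, 2, 0.0])
        p, v = ic.detect_local_extrema(x)
        np.testing.assert_array_equal(p, [1, 3])
        np.testing.assert_array_equal(v, [2])

    def test_plateau_reports_first_frame(self):
        p, v = ic.detect_local_extrema(np.array([0, 1, 1, 1, 0.0]))
        np.testing.assert_array_equal(p, [1])

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            x = rng.normal(size=rng.integers(5, 60))
            p, v = ic.detect_local_extrema(x)
            bp, bv = _brute_extrema(x)
            np.testing.assert_array_equal(p, bp)
            np.testing.assert_array_equal(v, bv)


class TestFilterExtrema:
    def _trace(self, peak_val, valley_val):
        # peak at frame 10, valley 30 frames later (beyond the 25-frame rule)
        x = np.zeros(60)
        x[10] = peak_val
        x[40] = valley_val
        x[:10] = np.linspace(0, peak_val, 10, endpoint=False)
        x[11:40] = np.linspace(peak_val, valley_val, 29)
        x[41:] = peak_val
        return x

    def test_thirty_percent_drop_kept(self):
        x = self._trace(1.0, 0.69)
        kept = ic.filter_extrema(x, np.array([10]), np.array([40]))
        np.testing.assert_array_equal(kept, [40])

    def test_small_drop_removed(self):
        x = self._trace(1.0, 0.75)
        kept = ic.filter_extrema(x, np.array([10]), np.array([40]))
        assert kept.size == 0

    def test_close_peak_discarded_from_pairing(self):
        # valley only 10 frames after its peak: the peak cannot be its
        # reference, so the valley is retained as an anchor
        x = np.zeros(30)
        x[10], x[20] = 1.0, 0.9
        kept = ic.filter_extrema(x, np.array([10]), np.array([20]))
        np.testing.assert_array_equal(kept, [20])

    def test_valley_before_first_peak_retained(self):
        x = np.zeros(60)
        x[5], x[40] = -0.5, 1.0
        kept = ic.filter_extrema(x, np.array([40]), np.array([5]))
        np.testing.assert_array_equal(kept, [5])

    @given(st.integers(0, 2**31 - 1))
    def test_output_subset_and_ordered(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=120).cumsum()
        p, v = ic.detect_local_extrema(x)
        kept = ic.filter_extrema(x, p, v)
        assert set(kept) <= set(v)
        assert np.all(np.diff(kept) > 0)


class TestAdaptiveBaseline:
    def test_line_between_two_anchors(self):
        x = np.zeros(101)
        x[100] = 10.0
        bl = ic.build_adaptive_baseline(x, np.array([0, 100]))
        assert bl.baseline[50] == pytest.approx(5.0)

    def test_single_valley_constant(self):
        x = np.arange(50.0)
        bl = ic.build_adaptive_baseline(x, np.array([20]))
        np.testing.assert_allclose(bl.baseline, 20.0)

    def test_no_valleys_falls_back_to_minimum(self):
        x = np.array([3.0, 1.0, 2.0])
        bl = ic.build_adaptive_baseline(x, np.array([], dtype=int))
        np.testing.assert_allclose(bl.baseline, 1.0)

    def test_tracks_linear_drift_under_square_waves(self):
        # square waves riding on a linear drift: between anchors the fitted
        # baseline slope must match the drift slope within 10%
        rng = np.random.default_rng(3)
        n, slope = 2000, 0.4 / 2000
        t = np.arange(n)
        x = slope * t + 0.002 * rng.normal(size=n)
        for start in range(100, n - 120, 200):
            x[start:start + 40] += 0.5
        sm = ic.smooth_trace(x + 1.0, 15) - 1.0
        p, v = ic.detect_local_extrema(sm)
        kept = ic.filter_extrema(sm, p, v)
        bl = ic.build_adaptive_baseline(sm, kept).baseline
        inner = slice(int(kept[0]), int(kept[-1]) + 1)
        fitted = np.polyfit(t[inner], bl[inner], 1)[0]
        assert fitted == pytest.approx(slope, rel=0.10)

    def test_idempotent_on_detrended_trace(self):
        rng = np.random.default_rng(5)
        raw = np.ones(2000) + 0.01 * rng.normal(size=2000)
        for start in range(100, 1900, 200):
            raw[start:start + 40] += 0.5
        sf, _ = ic.adaptive_fold_change(ic.smooth_trace(raw, 15))
        # re-detrending the detrended trace: baseline stays within noise of 0
        sf2 = ic.fold_change_adaptive(sf.values, np.zeros_like(sf.values),
                                      ratio_shift=1.0)
        p, v = ic.detect_local_extrema(sf.values)
        kept = ic.filter_extrema(sf.values, p, v)
        bl2 = ic.build_adaptive_baseline(sf.values, kept).baseline
        assert np.abs(bl2).max() < 0.03


class TestFoldChangeAdaptive:
    def test_trace_equal_to_baseline_is_zero(self):
        x = np.linspace(10, 20, 30)
        fc = ic.fold_change_adaptive(x, x)
        np.testing.assert_allclose(fc.values, 0.0, atol=1e-12)

    def test_ten_percent_above(self):
        fc = ic.fold_change_adaptive(np.full(5, 110.0), np.full(5, 100.0))
        np.testing.assert_allclose(fc.values, 0.1)

    def test_nonpositive_baseline_names_frame(self):
        with pytest.raises(DegenerateTraceError, match="frame 2"):
            ic.fold_change_adaptive(np.ones(4), np.array([1.0, 1.0, 0.0, 1.0]))

    def test_shifted_ratio_matches_raw_formula(self):
        # SF on fold-change traces with shift 1 == direct formula on raws
        rng = np.random.default_rng(11)
        raw = rng.uniform(50, 150, 100)
        bl_raw = rng.uniform(40, 60, 100)
        f0 = 50.0
        fc = raw / f0 - 1.0
        bl_fc = bl_raw / f0 - 1.0
        direct = ic.fold_change_adaptive(raw, bl_raw).values
        shifted = ic.fold_change_adaptive(fc, bl_fc, ratio_shift=1.0).values
        np.testing.assert_allclose(shifted, direct, rtol=1e-10)

    def test_adaptive_recovers_waves_general_misses(self):
        # drifting baseline: detection after adaptive detrending finds at
        # least as many waves as detection on the section fold change
        params = ic.preset("drifting", rng_seed=2)
        traces, _, tl, truth = ic.simulate_islet(params)
        islet = ic.smooth_trace(traces.islet_trace(), 15)
        s, e = tl.second_phase_window
        sf, _ = ic.adaptive_fold_change(islet[s:e])
        n_adaptive = len(ic.detect_waves(sf.values, frame_interval_s=0.5))
        fc = ic.fold_change_general(islet[s:e], (0, e - s)).values
        n_general = len(ic.detect_waves(fc, frame_interval_s=0.5))
        assert n_adaptive >= n_general
        assert n_adaptive == truth.n_waves
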