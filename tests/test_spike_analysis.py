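"""Evoked-response reduction: counts, PSTHs, thresholds, dynamic range."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stimlimit as sl
from stimlimit.errors import BaselineError, InputError, ResolutionError
from stimlimit.spike_analysis import latency_split, responded


def trial(times, baseline=2.0):
    return sl.TrialResponse(spike_times_s=np.array(times), baseline_span_s=baseline)


class TestCountEvoked:
    def test_baseline_subtraction(self):
        # 7 post spikes, 4 baseline spikes in 2 s (2 Hz) -> 7 - 1 = 6
        t = trial([-1.9, -1.2, -0.7, -0.1, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.45])
        assert sl.count_evoked(t) == pytest.approx(6.0)

    def test_empty_trial(self):
        assert sl.count_evoked(trial([])) == 0.0

    def test_suppression_preserved(self):
        t = trial(np.linspace(-1.95, -0.05, 8))
        assert sl.count_evoked(t) == pytest.approx(-2.0)

    def test_missing_baseline_rejected(self):
        with pytest.raises(BaselineError):
            sl.count_evoked(trial([0.1], baseline=0.5))


class TestBuildPSTH:
    def test_no_spikes_all_zero(self):
        psth = sl.build_psth([trial([]), trial([])])
        assert np.all(psth.rate_hz == 0.0)

    def test_single_bin_rate(self):
        # 5 trials, one spike at 10 ms each, 10 ms bins -> 100 spikes/s
        psth = sl.build_psth([trial([0.012])] * 5, bin_width_s=0.01)
        k = np.searchsorted(psth.bin_edges_s, 0.012) - 1
        assert psth.rate_hz[k] == pytest.approx(100.0)
        assert np.sum(psth.rate_hz > 0) == 1

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            sl.build_psth([])

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_conservation(self, seed):
        """Σ rate·Δt over post-stimulus bins equals the mean post count."""
        rng = np.random.default_rng(seed)
        trials = [
            trial(rng.uniform(-0.05, 0.5, size=rng.integers(0, 40)))
            for _ in range(rng.integers(1, 8))
        ]
        psth = sl.build_psth(trials)
        mean_post = np.mean(
            [np.sum((t.spike_times_s >= 0) & (t.spike_times_s < 0.5)) for t in trials]
        )
        assert psth.post_stimulus_count() == pytest.approx(mean_post, rel=1e-12, abs=1e-12)


class TestResponseCurve:
    def test_probability_fractions(self):
        levels = {
            1.0: [trial([0.1]), trial([0.2]), trial([0.3]), trial([]), trial([])],
            2.0: [trial([0.1])] * 5,
        }
        curve = sl.response_curve(levels, cic_limit_nC=10.0)
        assert curve.table["response_probability"].tolist() == [0.6, 1.0]

    def test_levels_above_cic_flagged(self):
        levels = {1.0: [trial([])] * 2, 2.0: [trial([])] * 2, 5.0: [trial([0.1])] * 2}
        curve = sl.response_curve(levels, cic_limit_nC=3.0)
        assert curve.table["in_cic"].tolist() == [True, True, False]
        assert len(curve.within_cic()) == 2

    def test_single_level_rejected(self):
        with pytest.raises(InputError):
            sl.response_curve({1.0: [trial([])]}, cic_limit_nC=10.0)


class TestEstimateThreshold:
    def test_linear_interpolation(self, curve_factory):
        curve = curve_factory([1.0, 2.0], [0.2, 0.8], [1.0, 2.0])
        thr, status = sl.estimate_threshold(curve)
        assert (thr, status) == (pytest.approx(1.5), "ok")

    def test_exact_half_level(self, curve_factory):
        curve = curve_factory([1.0, 2.0, 3.0], [0.0, 0.5, 1.0], [0, 1, 2])
        thr, _ = sl.estimate_threshold(curve)
        assert thr == pytest.approx(2.0)

    def test_left_censored(self, curve_factory):
        curve = curve_factory([1.0, 2.0], [0.6, 1.0], [1, 2])
        thr, status = sl.estimate_threshold(curve)
        assert (thr, status) == (1.0, "left-censored")

    def test_never_responds(self, curve_factory):
        curve = curve_factory([1.0, 2.0, 3.0], [0.0, 0.0, 0.0], [0, 0, 0])
        thr, status = sl.estimate_threshold(curve)
        assert status == "no-threshold"
        assert np.isnan(thr)

    def test_lowest_crossing_wins_on_non_monotone(self, curve_factory):
        curve = curve_factory([1, 2, 3, 4], [0.2, 0.6, 0.4, 0.8], [1, 1, 1, 1])
        thr, _ = sl.estimate_threshold(curve)
        assert thr == pytest.approx(1.75)

    def test_invariant_to_levels_above_crossing(self, curve_factory):
        c1 = curve_factory([1.0, 2.0], [0.2, 0.8], [1, 2])
        c2 = curve_factory([1.0, 2.0, 3.0, 4.0], [0.2, 0.8, 0.9, 1.0], [1, 2, 3, 4])
        assert sl.estimate_threshold(c1)[0] == sl.estimate_threshold(c2)[0]

    def test_crossing_above_cic_does_not_count(self, curve_factory):
        curve = curve_factory([1.0, 2.0, 5.0], [0.1, 0.3, 0.9], [0, 1, 4], cic=3.0)
        _, status = sl.estimate_threshold(curve)
        assert status == "no-threshold"


class TestEstimateHalfMax:
    def test_interpolated_half_max(self, curve_factory):
        curve = curve_factory([1.0, 2.0, 3.0], [0.2, 0.6, 1.0], [0.0, 4.0, 8.0])
        hm, status = sl.estimate_half_max(curve)
        assert (hm, status) == (pytest.approx(2.0), "ok")

    def test_flat_nonzero_curve_returns_first_level(self, curve_factory):
        curve = curve_factory([1.0, 2.0, 3.0], [1, 1, 1], [3.0, 3.0, 3.0])
        hm, _ = sl.estimate_half_max(curve)
        assert hm == 1.0

    def test_all_zero_counts_undefined(self, curve_factory):
        curve = curve_factory([1.0, 2.0], [0, 0], [0.0, 0.0])
        assert sl.estimate_half_max(curve)[1] == "undefined"


class TestDynamicRange:
    def test_zero_db_when_max_equals_threshold_count(self, curve_factory):
        curve = curve_factory([1.0, 2.0, 3.0], [0.2, 0.8, 1.0], [3.0, 3.0, 3.0])
        dr, status = sl.dynamic_range(curve)
        assert (dr, status) == (pytest.approx(0.0, abs=1e-12), "ok")

    def test_ten_db_for_tenfold_ratio(self, curve_factory):
        curve = curve_factory([1.0, 2.0, 3.0], [0.0, 1.0, 1.0], [0.5, 1.0, 10.0])
        # threshold at 1.5 nC -> interpolated count 0.75; max 10 -> not 10 dB
        curve2 = curve_factory([1.0, 2.0, 3.0], [0.0, 1.0, 1.0], [1.0, 1.0, 10.0])
        dr, _ = sl.dynamic_range(curve2)
        assert dr == pytest.approx(10.0)
        dr1, _ = sl.dynamic_range(curve)
        assert dr1 == pytest.approx(10 * np.log10(10 / 0.75))

    def test_scale_invariance(self, curve_factory):
        c1 = curve_factory([1, 2, 3], [0.2, 0.8, 1.0], [1.0, 2.0, 6.0])
        c2 = curve_factory([1, 2, 3], [0.2, 0.8, 1.0], [7.0, 14.0, 42.0])
        assert sl.dynamic_range(c1)[0] == pytest.approx(sl.dynamic_range(c2)[0], rel=1e-12)

    def test_nonpositive_threshold_count_undefined(self, curve_factory):
        curve = curve_factory([1.0, 2.0], [0.2, 0.8], [-0.5, 0.0])
        assert sl.dynamic_range(curve)[1] == "undefined"

    def test_nearest_mode(self, curve_factory):
        # threshold interpolates to 1.75 nC -> nearest tested level is 2.0
        curve = curve_factory([1.0, 2.0], [0.2, 0.6], [1.0, 4.0])
        dr_near, _ = sl.dynamic_range(curve, mode="nearest")
        assert dr_near == pytest.approx(0.0, abs=1e-12)
        dr_interp, _ = sl.dynamic_range(curve)
        assert dr_interp == pytest.approx(10 * np.log10(4.0 / 3.25))


class TestPopulationSummary:
    def test_single_cell_degenerate(self):
        m = sl.CellMetrics("c0", 10.0, "p", 1.5, "ok", 1.8, "ok", 3.0, "ok")
        s = sl.population_summary([m])
        assert s["threshold_nC_mean"].iloc[0] == s["threshold_nC_median"].iloc[0] == 1.5

    def test_order_statistics(self):
        ms = [
            sl.CellMetrics(f"c{i}", 10.0, "p", float(q), "ok", q, "ok", 1.0, "ok")
            for i, q in enumerate([1, 2, 3, 4, 5])
        ]
        s = sl.population_summary(ms)
        assert s["threshold_nC_median"].iloc[0] == 3.0
        assert s["threshold_nC_q25"].iloc[0] == 2.0
        assert s["threshold_nC_q75"].iloc[0] == 4.0

    def test_responsive_fraction_counts_no_threshold(self):
        ms = [
            sl.CellMetrics("a", 10.0, "p", 1.0, "ok", 1.0, "ok", 1.0, "ok"),
            sl.CellMetrics("b", 10.0, "p", float("nan"), "no-threshold", float("nan"),
                           "undefined", float("nan"), "no-threshold"),
        ]
        s = sl.population_summary(ms)
        assert s["responsive_fraction"].iloc[0] == 0.5

    def test_charge_density_threshold_units(self):
        m = sl.CellMetrics("c0", 10.0, "p", 2.5918, "ok", 1.0, "ok", 1.0, "ok")
        s = sl.population_summary([m])
        # 2.5918 nC on a 10 μm disk is exactly the 3.3 mC/cm² density
        assert s["threshold_density_mC_cm2_median"].iloc[0] == pytest.approx(3.3, rel=1e-3)


class TestDetectSpikes:
    FS = 20e3

    def _template(self, n):
        t = np.arange(n) / self.FS
        return np.sin(2 * np.pi * 1000 * t) * np.hanning(n)

    def test_flat_trace_no_spikes(self):
        assert sl.detect_spikes(np.zeros(4000), self.FS).size == 0

    def test_recovers_injected_templates(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1.0, 40000)
        tpl = 10.0 * self._template(20)  # SNR 10
        starts = [0.30, 0.85, 1.40]
        peak_offset = np.argmax(np.abs(tpl)) / self.FS
        for t0 in starts:
            k = int(t0 * self.FS)
            x[k : k + 20] += tpl
        times = sl.detect_spikes(x, self.FS, baseline_end_s=0.25)
        truth = np.array(starts) + peak_offset
        assert len(times) == 3
        assert np.all(np.abs(times - truth) < 0.2e-3)

    def test_refractory_merge(self):
        x = np.zeros(12000)
        rng = np.random.default_rng(1)
        x += rng.normal(0, 0.05, x.size)
        tpl = self._template(20)
        for t0 in (0.300, 0.3005):  # 0.5 ms apart
            k = int(t0 * self.FS)
            x[k : k + 20] += tpl
        times = sl.detect_spikes(x, self.FS, baseline_end_s=0.2)
        assert len(times) == 1

    def test_artifact_blanking(self):
        x = np.zeros(8000)
        rng = np.random.default_rng(2)
        x += rng.normal(0, 0.05, x.size)
        k = int(0.2 * self.FS)
        x[k : k + 20] += self._template(20)
        times = sl.detect_spikes(
            x, self.FS, baseline_end_s=0.15, blank_windows_s=[(0.199, 0.202)]
        )
        assert times.size == 0

    def test_low_sampling_rejected(self):
        with pytest.raises(ResolutionError):
            sl.detect_spikes(np.zeros(100), 5e3)


class TestLatencySplit:
    def test_split_at_100ms(self):
        trials = [trial([0.01, 0.05, 0.2, 0.3]), trial([0.02, 0.15])]
        out = latency_split(trials)
        assert out["short_per_trial"] == pytest.approx(1.5)
        assert out["long_per_trial"] == pytest.approx(1.5)
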