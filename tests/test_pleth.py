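"""Signal path: integration, calibration, segmentation, windows, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from breathomics.pleth import (
    AnalysisWindows,
    CalibrationError,
    InputError,
    PressureTrace,
    calibrate,
    integrate_flow,
    segment_breaths,
    select_windows,
    ventilation_summary,
)
from conftest import flat_trace


def _trace(samples, fs=1000.0, **kw):
    return PressureTrace(samples=np.asarray(samples, dtype=float), sampling_rate_hz=fs, **kw)


class TestIntegrateFlow:
    def test_zero_flow_zero_volume(self):
        vol = integrate_flow(_trace(np.zeros(5000)), drift_correction="none")
        assert np.all(vol.samples == 0.0)

    def test_rectangular_pulse_terminal_volume(self):
        # 1 mV for 1 s at 1 kHz -> 1.0 mV·s.
        x = np.zeros(3000)
        x[1000:2000] = 1.0
        vol = integrate_flow(_trace(x), drift_correction="none")
        assert vol.samples[-1] == pytest.approx(1.0, abs=1e-6)

    def test_sine_closed_form(self):
        # ∫ sin(2πt) dt peaks at 1/π at t = 0.5 s.
        t = np.arange(1000) / 1000.0
        vol = integrate_flow(_trace(np.sin(2 * np.pi * t)), drift_correction="none")
        assert vol.samples.max() == pytest.approx(1.0 / np.pi, abs=1e-4)
        assert vol.times_s[np.argmax(vol.samples)] == pytest.approx(0.5, abs=2e-3)

    def test_empty_trace_rejected(self):
        with pytest.raises(InputError):
            integrate_flow(_trace([]))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        a=st.floats(-5, 5, allow_nan=False),
        b=st.floats(-5, 5, allow_nan=False),
        seed=st.integers(0, 100),
    )
    def test_linearity(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=500), rng.normal(size=500)
        lhs = integrate_flow(_trace(a * x + b * y), drift_correction="none").samples
        rhs = a * integrate_flow(_trace(x), drift_correction="none").samples
        rhs = rhs + b * integrate_flow(_trace(y), drift_correction="none").samples
        assert np.allclose(lhs, rhs, atol=1e-9)


def _injection_train(peak_heights_mv, fs=1000.0, rate_hz=3.0, pulse_s=0.15):
    """Flow whose integral is a train of raised-sine pulses of given heights."""
    dur = 0.5 + len(peak_heights_mv) / rate_hz
    n = int(dur * fs)
    t = np.arange(n) / fs
    flow = np.zeros(n)
    for k, h in enumerate(peak_heights_mv):
        onset = 0.2 + k / rate_hz
        m = (t >= onset) & (t < onset + pulse_s)
        flow[m] += h * (np.pi / pulse_s) * np.sin(2 * np.pi * (t[m] - onset) / pulse_s)
    return _trace(flow, fs)


class TestCalibrate:
    def test_six_pulses_of_2mv_give_10ul_per_mv(self):
        cal = calibrate(_injection_train([2.0] * 6), injection_volume_ul=20.0)
        assert cal.ul_per_mv == pytest.approx(10.0, rel=1e-3)
        assert cal.n_injections == 6

    def test_mean_of_unequal_heights(self):
        cal = calibrate(_injection_train([1.9, 2.0, 2.1]), injection_volume_ul=20.0)
        assert cal.ul_per_mv == pytest.approx(10.0, rel=1e-3)

    def test_generator_roundtrip_within_2pct(self):
        from breathomics.synthgen import BreathSimParams, gen_breath_trace

        for f in (0.5, 1.0, 2.0):
            _, cal_trace, _ = gen_breath_trace(
                BreathSimParams(duration_s=5, cal_factor_ul_per_mv=f, seed=1)
            )
            cal = calibrate(cal_trace)
            assert cal.ul_per_mv == pytest.approx(f, rel=0.02)

    def test_too_few_pulses_error(self):
        with pytest.raises(CalibrationError):
            calibrate(_injection_train([2.0, 2.0]))

    def test_flat_trace_error(self):
        with pytest.raises(CalibrationError):
            calibrate(flat_trace(5.0))


class TestSegmentBreaths:
    def test_flatline_gives_zero_breaths(self):
        series = segment_breaths(integrate_flow(flat_trace(20.0)))
        assert len(series) == 0

    def test_noiseless_periodic_counts_and_ibis(self, clean_periodic_trace):
        trace, _, truth = clean_periodic_trace
        # A noiseless trace needs no drift correction; IBIs are exact to
        # one sample period.
        series = segment_breaths(integrate_flow(trace, drift_correction="none"))
        assert len(series) == 30
        dt = 1.0 / trace.sampling_rate_hz
        assert np.all(np.abs(series.ibis_s - 1.0 / 3.0) <= dt + 1e-12)

    def test_snr10_recovery_benchmark(self, breath_study):
        """At SNR 10, ≥99% of true onsets matched within ±25 ms, ≤1% spurious."""
        _, _, series, truth = breath_study
        det, gt = series.onsets_s, truth.breath_onsets_s
        d = np.abs(det[:, None] - gt[None, :])
        matched_gt = (d.min(axis=0) <= 0.025).mean()
        spurious = (d.min(axis=1) > 0.025).mean()
        assert matched_gt >= 0.99
        assert spurious <= 0.01

    def test_gain_invariance(self, clean_periodic_trace):
        trace, _, _ = clean_periodic_trace
        vol = integrate_flow(trace, drift_correction="none")
        ref = segment_breaths(vol)
        for c in (0.1, 3.0, 250.0):
            scaled = type(vol)(vol.samples * c, vol.sampling_rate_hz)
            got = segment_breaths(scaled)
            assert len(got) == len(ref)
            assert np.allclose(got.ibis_s, ref.ibis_s)

    def test_too_short_waveform_rejected(self):
        with pytest.raises(InputError):
            segment_breaths(integrate_flow(_trace(np.zeros(50))), refractory_s=0.1)


class TestSelectWindows:
    def test_clean_epoch_gives_full_tail(self):
        trace = flat_trace(600.0)
        w = select_windows(trace, "room_air", "ventilation")
        assert w.segments == [(300.0, 600.0)]
        assert w.cumulative_s == 300.0
        assert not w.insufficient

    def test_short_runs_flag_insufficient(self):
        # Artifact gaps leave only 8 s and 9 s clean runs in the tail.
        mask = [(0.0, 283.0), (291.0, 291.5), (300.5, 600.0)]
        trace = flat_trace(600.0)
        trace.artifact_mask = mask
        w = select_windows(trace, "room_air", "ventilation")
        assert w.segments == []
        assert w.insufficient

    def test_cumulative_65s_accepted(self):
        # Clean runs of 30, 20, 15 s in the last 5 min: 65 s >= 60 s.
        trace = flat_trace(600.0)
        trace.artifact_mask = [
            (300.0, 330.0),
            (360.0, 380.0),
            (400.0, 420.0),
            (435.0, 600.0),
        ]
        w = select_windows(trace, "room_air", "ventilation")
        assert [round(e - s) for s, e in w.segments] == [30, 20, 15]
        assert w.cumulative_s == pytest.approx(65.0)
        assert not w.insufficient

    def test_pattern_policy_caps_at_600s(self):
        trace = flat_trace(900.0)
        w = select_windows(trace, "room_air", "pattern")
        assert w.cumulative_s == pytest.approx(600.0)

    def test_unknown_epoch_rejected(self):
        with pytest.raises(InputError):
            select_windows(flat_trace(60.0), "hypoxia")


class TestVentilationSummary:
    def test_rate_and_volume_arithmetic(self, clean_periodic_trace):
        trace, cal_trace, truth = clean_periodic_trace
        series = segment_breaths(integrate_flow(trace, drift_correction="none"))
        cal = calibrate(cal_trace)
        w = AnalysisWindows([(0.0, 10.0)], "ventilation")
        s = ventilation_summary(series, cal, w)
        assert s.vf == pytest.approx(180.0, rel=1e-6)  # 30 breaths / 10 s
        assert s.vt == pytest.approx(10.0, rel=0.02)
        assert s.ve == pytest.approx(s.vf * s.vt, rel=1e-12)

    def test_planted_recovery_noise_free(self):
        """With zero jitter and noise, V_f and V_T match planted values."""
        from breathomics.synthgen import BreathSimParams, gen_breath_trace

        trace, cal_trace, truth = gen_breath_trace(
            BreathSimParams(
                duration_s=60, ibi_cv=0, amp_cv=0, noise_sd=0, p_apnea=0, seed=2
            )
        )
        series = segment_breaths(integrate_flow(trace))
        cal = calibrate(cal_trace)
        w = select_windows(trace, "room_air", "ventilation", min_total_s=50)
        s = ventilation_summary(series, cal, w)
        gt_in = [o for o in truth.breath_onsets_s if any(a <= o < b for a, b in w.segments)]
        vf_true = 60.0 * len(gt_in) / w.cumulative_s
        assert s.vf == pytest.approx(vf_true, rel=0.01)
        assert s.vt == pytest.approx(truth.true_vt, rel=0.02)

    def test_insufficient_windows_rejected(self, clean_periodic_trace):
        trace, cal_trace, _ = clean_periodic_trace
        series = segment_breaths(integrate_flow(trace))
        cal = calibrate(cal_trace)
        w = AnalysisWindows([], "ventilation", insufficient=True)
        with pytest.raises(InputError):
            ventilation_summary(series, cal, w)
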