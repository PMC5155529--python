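"""Pneumotachograph signal processing.

A head-out pneumotachograph reports airflow as a pressure signal (mV).
Integrating that flow over time yields a relative volume waveform whose
per-breath peak height, scaled by a calibration factor obtained from
known-volume injections, gives tidal volume. This module turns a raw
trace into calibrated per-breath measurements and ventilation summaries:

* :func:`integrate_flow` — cumulative trapezoidal integration with
  optional drift correction of the *integrated* waveform only; the raw
  pressure trace is never filtered or smoothed.
* :func:`calibrate` — derive the µl/mV factor from a train of
  known-volume injection pulses (20 µl at 3 Hz by convention).
* :func:`segment_breaths` — hysteresis breath detection on the volume
  waveform.
* :func:`select_windows` — pick artifact-free analysis windows under the
  ventilation rule (≥10 s runs from the last 5 min, ≥1 min cumulative)
  or the pattern rule (up to 10 min of artifact-free trace).
* :func:`ventilation_summary` — respiratory rate V_f, tidal volume V_T
  and minute ventilation V_E = V_f · V_T over the selected windows.

Time is measured in seconds from trace start; all intervals are
half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.signal import find_peaks

__all__ = [
    "PressureTrace",
    "VolumeWaveform",
    "CalibrationFactor",
    "Breath",
    "BreathSeries",
    "AnalysisWindows",
    "RespiratorySummary",
    "integrate_flow",
    "calibrate",
    "segment_breaths",
    "select_windows",
    "ventilation_summary",
]

EPOCH_LABELS = ("acclimation", "room_air", "hypoxia", "hypercapnia", "recovery")


class InputError(ValueError):
    """Raised for invalid or degenerate inputs."""


class CalibrationError(RuntimeError):
    """Raised when too few calibration injection pulses are detectable."""


@dataclass
class PressureTrace:
    """Raw pneumotachograph flow signal with condition epochs and artifact mask.

    Parameters
    ----------
    samples
        Flow signal in mV, one value per sample.
    sampling_rate_hz
        Sampling frequency in Hz.
    epochs
        Ordered, non-overlapping ``(label, start_s, end_s)`` condition
        annotations; labels are drawn from ``EPOCH_LABELS``.
    artifact_mask
        ``(start_s, end_s)`` intervals contaminated by movement artifacts.
    temperature_c
        Optional chamber temperature channel (same length as ``samples``).
    """

    samples: np.ndarray
    sampling_rate_hz: float
    epochs: list[tuple[str, float, float]] = field(default_factory=list)
    artifact_mask: list[tuple[float, float]] = field(default_factory=list)
    temperature_c: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate_hz <= 0:
            raise InputError("sampling_rate_hz must be positive")
        dur = self.duration_s
        prev_end = 0.0
        for label, start, end in self.epochs:
            if label not in EPOCH_LABELS:
                raise InputError(f"unknown epoch label {label!r}")
            if not (0.0 <= start < end <= dur + 1e-9):
                raise InputError(f"epoch [{start}, {end}) outside trace [0, {dur})")
            if start < prev_end - 1e-9:
                raise InputError("epochs must be ordered and non-overlapping")
            prev_end = end
        for start, end in self.artifact_mask:
            if not (0.0 <= start < end <= dur + 1e-9):
                raise InputError(f"mask interval [{start}, {end}) outside trace")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sampling_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sampling_rate_hz

    def epoch_interval(self, label: str) -> tuple[float, float]:
        for lab, start, end in self.epochs:
            if lab == label:
                return start, end
        raise InputError(f"epoch {label!r} not present in trace")


@dataclass
class VolumeWaveform:
    """Relative volume waveform (mV·s of integrated flow, reported in mV units)."""

    samples: np.ndarray
    sampling_rate_hz: float
    drift_corrected: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sampling_rate_hz


@dataclass
class CalibrationFactor:
    """Volume calibration: µl per mV of volume-waveform peak height."""

    ul_per_mv: float
    n_injections: int
    injection_volume_ul: float = 20.0

    def __post_init__(self) -> None:
        if self.ul_per_mv <= 0:
            raise InputError("ul_per_mv must be positive")
        if self.n_injections < 3:
            raise InputError("calibration requires at least 3 injections")


@dataclass
class Breath:
    onset_s: float
    peak_s: float
    amplitude_mv: float
    volume_ul: float | None = None

    def __post_init__(self) -> None:
        if not self.onset_s < self.peak_s:
            raise InputError("breath onset must precede its peak")
        if self.amplitude_mv <= 0:
            raise InputError("breath amplitude must be positive")


@dataclass
class BreathSeries:
    """Ordered breaths with onset-to-onset interbreath intervals (IBIs)."""

    breaths: list[Breath]

    def __post_init__(self) -> None:
        onsets = self.onsets_s
        if len(onsets) > 1 and not np.all(np.diff(onsets) > 0):
            raise InputError("breath onsets must be strictly increasing")

    @property
    def onsets_s(self) -> np.ndarray:
        return np.array([b.onset_s for b in self.breaths], dtype=float)

    @property
    def amplitudes_mv(self) -> np.ndarray:
        return np.array([b.amplitude_mv for b in self.breaths], dtype=float)

    @property
    def ibis_s(self) -> np.ndarray:
        return np.diff(self.onsets_s)

    def __len__(self) -> int:
        return len(self.breaths)

    def calibrated(self, cal: CalibrationFactor) -> "BreathSeries":
        """Return a copy with per-breath volumes filled in (µl)."""
        out = [
            Breath(b.onset_s, b.peak_s, b.amplitude_mv, b.amplitude_mv * cal.ul_per_mv)
            for b in self.breaths
        ]
        return BreathSeries(out)

    def restrict(self, windows: "AnalysisWindows") -> "BreathSeries":
        """Breaths whose onset falls inside one of the analysis windows."""
        kept = [
            b
            for b in self.breaths
            if any(s <= b.onset_s < e for s, e in windows.segments)
        ]
        return BreathSeries(kept)

    def ibis_within(self, windows: "AnalysisWindows") -> np.ndarray:
        """IBIs whose both endpoints lie inside the same window.

        An IBI spanning a window boundary is excluded: it mixes time from
        different artifact-free stretches and cannot be attributed to either.
        """
        out: list[float] = []
        onsets = self.onsets_s
        for a, b in zip(onsets[:-1], onsets[1:]):
            if any(s <= a and b < e for s, e in windows.segments):
                out.append(b - a)
        return np.asarray(out, dtype=float)


@dataclass
class AnalysisWindows:
    segments: list[tuple[float, float]]
    policy: str = "ventilation"
    insufficient: bool = False

    @property
    def cumulative_s(self) -> float:
        return float(sum(e - s for s, e in self.segments))


@dataclass
class RespiratorySummary:
    """Ventilation and pattern metrics for one animal × condition."""

    vf: float  # breaths/min
    vt: float  # µl
    ve: float  # µl/min
    apnea_count: int = 0
    apnea_mean_length_s: float | None = None
    cv_ibi: float | None = None
    cv_amplitude: float | None = None
    condition: str | None = None

    def __post_init__(self) -> None:
        if self.vf < 0 or self.vt < 0 or self.ve < 0:
            raise InputError("ventilation quantities must be non-negative")
        if abs(self.ve - self.vf * self.vt) > 1e-9 * max(1.0, abs(self.ve)):
            raise InputError("ve must equal vf * vt")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def integrate_flow(
    trace: PressureTrace,
    drift_correction: str = "rolling_median",
    drift_window_s: float = 10.0,
) -> VolumeWaveform:
    """Integrate the flow channel into a relative volume waveform.

    The cumulative trapezoidal integral of the pressure (flow) signal is
    the respiratory volume waveform. Integration accumulates any DC
    offset or sensor drift into a slow baseline wander, so an optional
    drift correction — ``"none"``, ``"linear"`` (subtract least-squares
    line) or ``"rolling_median"`` (subtract a centered rolling median)
    — is applied to the integrated waveform. The raw pressure trace
    itself is never modified. The default 10 s median window is long
    against both the breath cycle and apneic pauses, so the breath
    pulses themselves barely deflect the estimated baseline, yet it
    still tracks integration drift on the tens-of-seconds scale.
    """
    if len(trace.samples) == 0:
        raise InputError("cannot integrate an empty trace")
    dt = 1.0 / trace.sampling_rate_hz
    vol = cumulative_trapezoid(trace.samples, dx=dt, initial=0.0)
    if drift_correction == "none":
        return VolumeWaveform(vol, trace.sampling_rate_hz, drift_corrected=False)
    if drift_correction == "linear":
        t = trace.times_s
        coef = np.polyfit(t, vol, 1)
        vol = vol - np.polyval(coef, t)
    elif drift_correction == "rolling_median":
        win = max(3, int(round(drift_window_s * trace.sampling_rate_hz)))
        win = min(win, len(vol))
        # Reflect-pad so the window never truncates at the trace edges.
        pad = win // 2
        padded = np.concatenate([vol[pad:0:-1], vol, vol[-2 : -pad - 2 : -1]])
        baseline = (
            pd.Series(padded)
            .rolling(win, center=True, min_periods=1)
            .median()
            .to_numpy()[pad : pad + len(vol)]
        )
        vol = vol - baseline
    else:
        raise InputError(f"unknown drift correction {drift_correction!r}")
    return VolumeWaveform(vol, trace.sampling_rate_hz, drift_corrected=True)


def calibrate(
    cal_trace: PressureTrace,
    injection_volume_ul: float = 20.0,
    drift_correction: str = "rolling_median",
) -> CalibrationFactor:
    """Derive the µl/mV factor from a known-volume injection train.

    The calibration trace (a series of fixed-volume pipette injections,
    20 µl at 3 Hz by convention) is integrated like an experimental
    trace; injection peaks are detected by prominence and the factor is
    ``injection_volume_ul / mean(peak heights)``.
    """
    vol = integrate_flow(cal_trace, drift_correction=drift_correction)
    v = vol.samples
    span = float(np.max(v) - np.min(v)) if len(v) else 0.0
    if span <= 0:
        raise CalibrationError("calibration trace is flat; no injection pulses found")
    # Injections are well-separated stereotyped pulses: half-span prominence.
    min_dist = max(1, int(0.1 * cal_trace.sampling_rate_hz))
    peaks, _ = find_peaks(v, prominence=0.5 * span, distance=min_dist)
    if len(peaks) < 3:
        raise CalibrationError(
            f"only {len(peaks)} injection pulses detected; need at least 3"
        )
    baseline = float(np.median(v))
    heights = v[peaks] - baseline
    mean_h = float(np.mean(heights))
    if mean_h <= 0:
        raise CalibrationError("non-positive mean injection peak height")
    return CalibrationFactor(
        ul_per_mv=injection_volume_ul / mean_h,
        n_injections=int(len(peaks)),
        injection_volume_ul=injection_volume_ul,
    )


def _running_scale(v: np.ndarray, fs: float, window_s: float) -> tuple[np.ndarray, np.ndarray]:
    """Rolling amplitude scale (max − min) and rolling floor over ``window_s``."""
    win = max(3, int(round(window_s * fs)))
    s = pd.Series(v)
    roll = s.rolling(win, center=True, min_periods=1)
    lo = roll.min().to_numpy()
    hi = roll.max().to_numpy()
    return hi - lo, lo


def segment_breaths(
    volume: VolumeWaveform,
    hi_frac: float = 0.5,
    lo_frac: float = 0.25,
    refractory_s: float = 0.1,
    scale_window_s: float = 10.0,
    onset_frac: float = 0.02,
) -> BreathSeries:
    """Segment a volume waveform into breaths by hysteresis peak detection.

    A breath is triggered when the waveform rises above
    ``hi_frac × scale`` (scale = running max−min amplitude over
    ``scale_window_s``) after having been below ``lo_frac × scale``; one
    breath is counted per excursion, the peak is the excursion maximum
    (earliest sample on ties), and the amplitude is peak minus the
    preceding trough. Detected onsets are then refined by backtracking
    from the peak to the last sample at or below
    ``trough + onset_frac × amplitude``, which tracks the true start of
    the inspiratory upstroke far more closely than the hi-threshold
    crossing does. Onsets closer than ``refractory_s`` to the previous
    one are suppressed.
    """
    v = volume.samples
    fs = volume.sampling_rate_hz
    n = len(v)
    if n < int(refractory_s * fs) + 2:
        raise InputError("waveform shorter than the refractory period")
    scale, floor = _running_scale(v, fs, scale_window_s)
    if float(np.max(scale)) <= 0:
        return BreathSeries([])
    hi_t = floor + hi_frac * scale
    lo_t = floor + lo_frac * scale

    above_hi = v > hi_t
    below_lo = v < lo_t
    # Upward hi crossings, gated by having visited the lo band since the
    # previous excursion (classic hysteresis).
    cross_idx = np.flatnonzero(above_hi[1:] & ~above_hi[:-1]) + 1

    breaths: list[Breath] = []
    refractory = int(round(refractory_s * fs))
    last_onset_i = -n
    last_excursion_end = 0
    armed = True
    lo_idx = np.flatnonzero(below_lo)
    for c in cross_idx:
        if not armed:
            # Armed again once the signal has dipped below lo since the
            # end of the previous excursion.
            j = np.searchsorted(lo_idx, last_excursion_end)
            if j < len(lo_idx) and lo_idx[j] <= c:
                armed = True
            else:
                continue
        # Excursion extends until the signal drops back below lo.
        j = np.searchsorted(lo_idx, c)
        end = int(lo_idx[j]) if j < len(lo_idx) else n
        seg = v[c:end] if end > c else v[c : c + 1]
        peak_i = c + int(np.argmax(seg))
        # Preceding trough: minimum since the previous excursion ended.
        t0 = max(last_excursion_end, 0)
        trough_seg = v[t0:c + 1]
        trough_i = t0 + int(np.argmin(trough_seg))
        trough = float(v[trough_i])
        amp = float(v[peak_i]) - trough
        if amp <= 0:
            continue
        # Backtrack to the onset of the upstroke.
        thresh = trough + onset_frac * amp
        k = peak_i
        while k > trough_i and v[k - 1] > thresh:
            k -= 1
        onset_i = k
        if onset_i - last_onset_i < refractory:
            last_excursion_end = end
            armed = False
            continue
        breaths.append(
            Breath(
                onset_s=onset_i / fs,
                peak_s=peak_i / fs,
                amplitude_mv=amp,
            )
        )
        last_onset_i = onset_i
        last_excursion_end = end
        armed = False
    return BreathSeries(breaths)


def _artifact_free_runs(
    interval: tuple[float, float], mask: Sequence[tuple[float, float]]
) -> list[tuple[float, float]]:
    """Maximal sub-intervals of ``interval`` not covered by any mask interval."""
    start, end = interval
    events = sorted((max(s, start), min(e, end)) for s, e in mask if e > start and s < end)
    runs: list[tuple[float, float]] = []
    cursor = start
    for s, e in events:
        if s > cursor:
            runs.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < end:
        runs.append((cursor, end))
    return runs


def select_windows(
    trace: PressureTrace,
    epoch_label: str,
    policy: str = "ventilation",
    min_segment_s: float = 10.0,
    min_total_s: float = 60.0,
    tail_s: float = 300.0,
    pattern_total_s: float = 600.0,
) -> AnalysisWindows:
    """Select artifact-free analysis windows for an epoch.

    ``ventilation`` policy: within the last ``tail_s`` (5 min) of the
    epoch, keep maximal artifact-free runs of at least ``min_segment_s``
    (10 s); the selection is flagged insufficient if the cumulative
    length falls short of ``min_total_s`` (1 min).

    ``pattern`` policy: artifact-free runs of at least ``min_segment_s``
    anywhere in the epoch, accumulated chronologically up to
    ``pattern_total_s`` (10 min); used for apnea counts, IBI/amplitude
    variability and Poincaré pairs.
    """
    start, end = trace.epoch_interval(epoch_label)
    if policy == "ventilation":
        lo = max(start, end - tail_s)
        runs = _artifact_free_runs((lo, end), trace.artifact_mask)
        segs = [(s, e) for s, e in runs if e - s >= min_segment_s]
        cum = sum(e - s for s, e in segs)
        return AnalysisWindows(segs, policy, insufficient=cum < min_total_s)
    if policy == "pattern":
        runs = _artifact_free_runs((start, end), trace.artifact_mask)
        segs: list[tuple[float, float]] = []
        cum = 0.0
        for s, e in runs:
            if e - s < min_segment_s:
                continue
            take = min(e - s, pattern_total_s - cum)
            if take <= 0:
                break
            segs.append((s, s + take))
            cum += take
        return AnalysisWindows(segs, policy, insufficient=len(segs) == 0)
    raise InputError(f"unknown window policy {policy!r}")


def ventilation_summary(
    series: BreathSeries,
    cal: CalibrationFactor,
    windows: AnalysisWindows,
    condition: str | None = None,
) -> RespiratorySummary:
    """V_f, V_T and V_E over the selected windows.

    V_f = 60 × n_breaths / cumulative window time (breaths/min);
    V_T = mean calibrated breath volume (µl); V_E = V_f × V_T (µl/min).
    """
    if windows.insufficient:
        raise InputError("analysis windows flagged insufficient")
    sel = series.restrict(windows).calibrated(cal)
    if len(sel) == 0:
        raise InputError("no breaths inside the analysis windows")
    vf = 60.0 * len(sel) / windows.cumulative_s
    vt = float(np.mean([b.volume_ul for b in sel.breaths]))
    return RespiratorySummary(vf=vf, vt=vt, ve=vf * vt, condition=condition)
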