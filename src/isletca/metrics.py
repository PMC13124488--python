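"""Islet-level Ca2+ dynamics: wave detection, AUC, phase metrics.

The biphasic response of an islet to a glucose ramp is summarised by:

* area under the fold-change curve (a simple per-frame sum ``AUC_app`` and
  the trapezoid-rule integral), per phase;
* first-phase activation time (FP-T20, first crossing of the activity
  threshold after 11 mM glucose), amplitude and width;
* second-phase oscillations: individual Ca2+ waves detected on the
  adaptive-baseline fold change with a double threshold (amplitude > 0.2
  fold change, sustained >= 2 s), from which frequency, mean peak amplitude
  and mean peak width follow.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .io import ExperimentTimeline

__all__ = [
    "WaveEvent",
    "GlobalMetrics",
    "FirstPhaseMetrics",
    "SecondPhaseMetrics",
    "detect_waves",
    "auc_app",
    "auc_trapezoid",
    "first_phase_metrics",
    "second_phase_metrics",
]

#: Activity threshold on fold change: >0.2 (20% above baseline) counts as
#: active with GCaMP6-class sensors.
DEFAULT_ACTIVITY_THRESHOLD = 0.2
#: Minimum sustained activity for a deflection to count as a Ca2+ wave.
DEFAULT_MIN_WAVE_DURATION_S = 2.0


@dataclass
class WaveEvent:
    """One detected Ca2+ wave on a fold-change trace.

    ``activation_frame`` is the first frame strictly above the threshold
    (the SP-T20 crossing for that wave); ``deactivation_frame`` the first
    subsequent frame strictly below it (exclusive end of the active span).
    Frames are indices into the trace that was passed to
    :func:`detect_waves`, i.e. section-relative.
    """

    activation_frame: int
    deactivation_frame: int
    peak_amplitude: float
    width_s: float
    truncated: bool = False


@dataclass
class FirstPhaseMetrics:
    fp_t20_s: float | None  # None = never activated in the window
    fp_amplitude: float
    fp_width_s: float | None


@dataclass
class SecondPhaseMetrics:
    frequency_per_min: float
    mean_amplitude: float | None  # None when no waves
    mean_width_s: float | None
    n_waves: int


@dataclass
class GlobalMetrics:
    """Bundle of the islet-level summary statistics written to
    ``global_metrics.json``."""

    auc_app_first: float
    auc_app_second: float
    auc_trap_first: float
    auc_trap_second: float
    fp_t20_s: float | None
    fp_amplitude: float
    fp_width_s: float | None
    sp_frequency_per_min: float
    sp_mean_amplitude: float | None
    sp_mean_width_s: float | None
    n_waves: int

    def to_dict(self) -> dict:
        return asdict(self)


def detect_waves(
    sf_fold_change: np.ndarray,
    threshold: float = DEFAULT_ACTIVITY_THRESHOLD,
    min_duration_s: float = DEFAULT_MIN_WAVE_DURATION_S,
    frame_interval_s: float = 0.5,
) -> list[WaveEvent]:
    """Detect Ca2+ waves with the double threshold.

    An event opens at the first frame with value strictly above
    ``threshold`` and closes at the first later frame strictly below it;
    values exactly at the threshold toggle nothing.  Events sustained for
    less than ``min_duration_s`` are discarded.  An event still open at the
    end of the trace closes at the last frame and is flagged ``truncated``.
    """
    x = np.asarray(sf_fold_change, dtype=float)
    events: list[WaveEvent] = []
    open_at: int | None = None
    for i, v in enumerate(x):
        if open_at is None:
            if v > threshold:
                open_at = i
        elif v < threshold:
            events.append(_close_event(x, open_at, i, frame_interval_s))
            open_at = None
    if open_at is not None:
        ev = _close_event(x, open_at, x.size, frame_interval_s)
        ev.truncated = True
        events.append(ev)
    return [e for e in events if e.width_s >= min_duration_s]


def _close_event(x: np.ndarray, start: int, end: int, dt: float) -> WaveEvent:
    return WaveEvent(
        activation_frame=int(start),
        deactivation_frame=int(end),
        peak_amplitude=float(x[start:end].max()),
        width_s=(end - start) * dt,
    )


def auc_app(fold_change: np.ndarray, window: tuple[int, int]) -> float:
    """Apparent area under the curve: the plain sum of fold-change values
    over the half-open frame window (unitless; no time scaling)."""
    x = np.asarray(fold_change, dtype=float)
    s, e = window
    return float(x[s:e].sum())


def auc_trapezoid(
    fold_change: np.ndarray, window: tuple[int, int], frame_interval_s: float
) -> float:
    """Trapezoid-rule area under the fold-change curve over the window,
    in fold-change x seconds: sum of ``(F_i + F_{i+1}) / 2 * dt``.

    The half-open frame window ``[s, e)`` covers the time span
    ``[s*dt, e*dt]``, so the closing sample at frame ``e`` enters the last
    trapezoid when the trace extends that far; this keeps areas additive
    over adjacent windows.
    """
    x = np.asarray(fold_change, dtype=float)
    s, e = window
    seg = x[s:min(e + 1, x.size)]
    if seg.size < 2:
        return 0.0
    return float(np.trapezoid(seg, dx=frame_interval_s))


def first_phase_metrics(
    fold_change: np.ndarray,
    timeline: ExperimentTimeline,
    threshold: float = DEFAULT_ACTIVITY_THRESHOLD,
) -> FirstPhaseMetrics:
    """First-phase activation time, amplitude and width on the general
    fold-change trace.

    The window is ``[frame_g11, first_phase_end_frame)``.  FP-T20 is the
    time from glucose elevation to the first frame strictly above the
    threshold; the width runs from that crossing until the trace first
    falls strictly below the threshold again (operationalising "the next
    significant activity decrease"); the amplitude is the window maximum.
    """
    x = np.asarray(fold_change, dtype=float)
    s, e = timeline.first_phase_window
    dt = timeline.frame_interval_s
    win = x[s:e]
    if win.size == 0:
        raise ValueError("empty first-phase window")
    amplitude = float(win.max())
    above = np.nonzero(win > threshold)[0]
    if above.size == 0:
        return FirstPhaseMetrics(fp_t20_s=None, fp_amplitude=amplitude, fp_width_s=None)
    t20_idx = int(above[0])
    below_after = np.nonzero(win[t20_idx:] < threshold)[0]
    width = float(below_after[0]) * dt if below_after.size else (win.size - t20_idx) * dt
    return FirstPhaseMetrics(
        fp_t20_s=t20_idx * dt,
        fp_amplitude=amplitude,
        fp_width_s=width,
    )


def second_phase_metrics(
    waves: list[WaveEvent],
    window: tuple[int, int],
    frame_interval_s: float,
) -> SecondPhaseMetrics:
    """Oscillation frequency and mean wave amplitude/width over a window.

    Frequency is the number of waves divided by the window length in
    minutes (15 waves in a 1,200 s window -> 0.75 waves/min).  With zero
    waves the frequency is 0 and the means are undefined (None).
    """
    s, e = window
    if e <= s:
        raise ValueError(f"empty second-phase window {window}")
    minutes = (e - s) * frame_interval_s / 60.0
    n = len(waves)
    if n == 0:
        return SecondPhaseMetrics(0.0, None, None, 0)
    return SecondPhaseMetrics(
        frequency_per_min=n / minutes,
        mean_amplitude=float(np.mean([w.peak_amplitude for w in waves])),
        mean_width_s=float(np.mean([w.width_s for w in waves])),
        n_waves=n,
    )
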