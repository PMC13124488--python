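"""Seeded generator of synthetic islet recordings with planted ground truth.

The generator emulates what a glucose-ramp Ca2+ imaging session produces —
a Multi-Measure trace table, centroids and a timeline — for an islet whose
behaviour is fully known: which cells respond early in the first phase,
which lead the second-phase waves, which participate in (almost) every
wave, and which are dead to KCl.  The signal model is deliberately
phenomenological: per-cell fluorescence is a baseline with optional drift,
plus a smoothed-step first-phase response, a square-wave train during the
second phase, a terminal KCl step, and Gaussian noise.  It reproduces the
statistics the analysis pipeline consumes, not the underlying
electrophysiology, so every planted quantity has a closed form and can
serve as an oracle for the detection and classification stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ConfigError
from .io import (
    CellCentroids,
    ExperimentTimeline,
    PROTOCOL_DEFAULTS,
    TraceMatrix,
    write_multimeasure_csv,
)
from .metrics import WaveEvent

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "simulate_islet",
    "preset",
    "n_planted_waves",
    "count_recovered_waves",
    "write_simulation",
]


@dataclass
class SimulationParams:
    """Everything that defines a synthetic recording.

    Amplitudes are fractions of the resting fluorescence ``baseline_f0``;
    the planted sets are cell indices and must be disjoint from
    ``dead_cells``.
    """

    n_cells: int = 50
    frame_interval_s: float = 0.5
    timeline: ExperimentTimeline = field(
        default_factory=lambda: ExperimentTimeline(**PROTOCOL_DEFAULTS)
    )
    baseline_f0: float = 1000.0
    noise_sd: float = 0.02              # Gaussian noise, fraction of f0
    drift_slope: float = 0.0            # total linear drift over the recording
    drift_sin_amp: float = 0.0          # slow sinusoidal drift amplitude
    drift_sin_period_s: float = 900.0
    # first phase: smoothed step per cell at its onset latency after g11
    fp_amplitude: float = 1.0
    fp_onset_mean_s: float = 180.0
    fp_onset_sd_s: float = 40.0
    fp_duration_s: float = 330.0
    fp_rise_s: float = 5.0
    fp_decay_s: float = 60.0
    fast_cells: tuple[int, ...] = ()
    fast_onset_mean_s: float = 60.0
    fast_onset_sd_s: float = 10.0
    # second phase: square-wave train with per-cell participation and lag
    wave_period_s: float = 44.0
    wave_width_s: float = 12.0
    wave_amplitude: float = 0.6
    wave_delay_s: float = 60.0
    leader_cells: tuple[int, ...] = ()
    leader_lead_s: float = 1.5          # followers lag behind wave start by this
    lag_jitter_sd_s: float = 0.3
    high_participation_cells: tuple[int, ...] = ()
    participation_p: float = 0.78       # per-wave participation of ordinary cells
    # terminal depolarisation
    dead_cells: tuple[int, ...] = ()
    kcl_amplitude: float = 1.5
    kcl_rise_s: float = 5.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ConfigError("n_cells must be >= 1")
        if not 0.0 <= self.participation_p <= 1.0:
            raise ConfigError("participation_p must be in [0, 1]")
        planted = set(self.fast_cells) | set(self.leader_cells) | set(
            self.high_participation_cells
        )
        if planted & set(self.dead_cells):
            raise ConfigError("planted functional cells cannot also be dead")
        for group in (self.fast_cells, self.leader_cells,
                      self.high_participation_cells, self.dead_cells):
            if any(i < 0 or i >= self.n_cells for i in group):
                raise ConfigError("planted cell index out of range")
        if self.wave_amplitude <= 0.3:
            raise ConfigError(
                "wave_amplitude must clear the 0.2 detection threshold with "
                "margin; got "
                f"{self.wave_amplitude}"
            )


@dataclass
class GroundTruth:
    """Planted truth for a simulated recording, used as the test oracle."""

    first_responders: np.ndarray        # cell indices with early FP onset
    leaders: np.ndarray                 # cells that lead every wave
    high_participation: np.ndarray      # cells participating in every wave
    dead_cells: np.ndarray              # no KCl (or any) response
    fp_onset_s: np.ndarray              # per-cell first-phase onset after g11
    wave_start_frames: np.ndarray       # islet wave starts (absolute frames)
    wave_end_frames: np.ndarray
    activation_frames: np.ndarray       # (n_cells, n_waves), NaN = sat out

    @property
    def n_waves(self) -> int:
        return self.wave_start_frames.size


def n_planted_waves(params: SimulationParams) -> int:
    """Number of second-phase waves the parameters plant (closed form)."""
    tl = params.timeline
    section_s = (tl.frame_kcl - tl.frame_g25) * tl.frame_interval_s
    usable = section_s - params.wave_delay_s - params.wave_width_s
    if usable < 0:
        return 0
    return int(usable // params.wave_period_s) + 1


def _add_pulse(row: np.ndarray, dt: float, t_on: float, t_off: float,
               amp: float, rise_s: float, decay_s: float = 0.0) -> None:
    """Add a trapezoidal pulse (linear rise/decay) to one trace, in place."""
    n = row.size
    t = np.arange(n) * dt
    up = np.clip((t - t_on) / max(rise_s, dt), 0.0, 1.0)
    if decay_s > 0:
        down = np.clip(1.0 - (t - t_off) / decay_s, 0.0, 1.0)
    else:
        down = (t < t_off).astype(float)
    row += amp * up * down


def simulate_islet(
    params: SimulationParams,
) -> tuple[TraceMatrix, CellCentroids, ExperimentTimeline, GroundTruth]:
    """Generate one synthetic recording; deterministic for a given seed."""
    tl = params.timeline
    dt = params.frame_interval_s
    n, nf = params.n_cells, tl.n_frames
    rng = np.random.default_rng(params.rng_seed)

    dead = np.asarray(sorted(params.dead_cells), dtype=int)
    alive = np.setdiff1d(np.arange(n), dead)
    signal = np.zeros((n, nf))

    # --- first phase: per-cell onset latency after the 11 mM rise
    onset = rng.normal(params.fp_onset_mean_s, params.fp_onset_sd_s, size=n)
    fast = np.asarray(sorted(params.fast_cells), dtype=int)
    if fast.size:
        onset[fast] = rng.normal(
            params.fast_onset_mean_s, params.fast_onset_sd_s, size=fast.size
        )
    fp_win_s = (tl.first_phase_window[1] - tl.first_phase_window[0]) * dt
    onset = np.clip(onset, 2.0, fp_win_s - params.fp_duration_s - params.fp_decay_s)
    g11_s = tl.frame_g11 * dt
    for i in alive:
        t_on = g11_s + onset[i]
        _add_pulse(signal[i], dt, t_on, t_on + params.fp_duration_s,
                   params.fp_amplitude, params.fp_rise_s, params.fp_decay_s)

    # --- second phase: square-wave train with participation and lags
    leaders = np.asarray(sorted(params.leader_cells), dtype=int)
    hubs = np.asarray(sorted(params.high_participation_cells), dtype=int)
    p_vec = np.full(n, params.participation_p)
    p_vec[leaders] = 1.0
    p_vec[hubs] = 1.0
    p_vec[dead] = 0.0
    is_leader = np.zeros(n, dtype=bool)
    is_leader[leaders] = True

    g25_s = tl.frame_g25 * dt
    n_waves = n_planted_waves(params)
    wave_starts = np.array([
        g25_s + params.wave_delay_s + k * params.wave_period_s
        for k in range(n_waves)
    ])
    activation = np.full((n, n_waves), np.nan)
    for k, t0 in enumerate(wave_starts):
        take = rng.random(n) < p_vec
        lag = np.where(
            is_leader, 0.0,
            params.leader_lead_s + rng.normal(0.0, params.lag_jitter_sd_s, n),
        )
        lag = np.clip(lag, 0.0, params.wave_width_s / 2)
        t_end = t0 + params.wave_width_s
        for i in np.nonzero(take)[0]:
            a = int(round((t0 + lag[i]) / dt))
            b = int(round(t_end / dt))
            signal[i, a:b] += params.wave_amplitude
            activation[i, k] = a

    # --- terminal KCl depolarisation (all live cells)
    kcl_s = tl.frame_kcl * dt
    for i in alive:
        _add_pulse(signal[i], dt, kcl_s, nf * dt, params.kcl_amplitude,
                   params.kcl_rise_s)

    # --- baseline, drift, noise
    frames = np.arange(nf)
    drift = params.drift_slope * frames / nf
    if params.drift_sin_amp:
        drift = drift + params.drift_sin_amp * np.sin(
            2 * np.pi * frames * dt / params.drift_sin_period_s
        )
    f0 = params.baseline_f0
    fluor = f0 * (1.0 + drift[None, :] + signal)
    fluor += rng.normal(0.0, params.noise_sd * f0, size=fluor.shape)
    fluor = np.clip(fluor, 0.0, None)

    # --- centroids uniform in a disc (imaging field 256 x 256 px)
    theta = rng.uniform(0, 2 * np.pi, n)
    radius = 100.0 * np.sqrt(rng.uniform(0, 1, n))
    cent = CellCentroids(
        cell_ids=[f"Cell_{i + 1}" for i in range(n)],
        x_px=128.0 + radius * np.cos(theta),
        y_px=128.0 + radius * np.sin(theta),
    )
    traces = TraceMatrix(
        cell_ids=list(cent.cell_ids),
        fluorescence=fluor,
        frame_interval_s=dt,
        includes_islet_roi=False,
    )
    truth = GroundTruth(
        first_responders=fast,
        leaders=leaders,
        high_participation=hubs,
        dead_cells=dead,
        fp_onset_s=onset,
        wave_start_frames=np.round(wave_starts / dt).astype(int),
        wave_end_frames=np.round((wave_starts + params.wave_width_s) / dt).astype(int),
        activation_frames=activation,
    )
    return traces, cent, tl, truth


_PRESETS = {
    "clean": dict(
        n_cells=50,
        noise_sd=0.02,
        fast_cells=tuple(range(0, 5)),
        leader_cells=tuple(range(5, 10)),
        high_participation_cells=tuple(range(10, 15)),
        dead_cells=(47, 48, 49),
    ),
    "noisy": dict(
        n_cells=50,
        noise_sd=0.08,
        fast_cells=tuple(range(0, 5)),
        leader_cells=tuple(range(5, 10)),
        high_participation_cells=tuple(range(10, 15)),
        dead_cells=(47, 48, 49),
    ),
    "drifting": dict(
        n_cells=10,
        noise_sd=0.02,
        drift_slope=1.5,
        drift_sin_amp=0.05,
        participation_p=1.0,
    ),
    "no_heterogeneity": dict(
        n_cells=30,
        noise_sd=0.02,
        participation_p=0.85,
    ),
}


def preset(name: str, rng_seed: int = 0, **overrides) -> SimulationParams:
    """Named parameter bundles.

    ``clean``: 50 cells, low noise, 5 planted first-responders, 5 leaders,
    5 all-wave participants and 3 KCl-dead cells — the reference condition
    for recovery tests.  ``noisy``: the same islet at four times the noise.
    ``drifting``: a strong upward baseline drift that defeats wave counting
    against the fixed section baseline but not against the adaptive one.
    ``no_heterogeneity``: exchangeable cells, for label-bias checks.
    """
    if name not in _PRESETS:
        raise ConfigError(
            f"unknown preset {name!r}; choose from {sorted(_PRESETS)}"
        )
    kwargs = dict(_PRESETS[name])
    kwargs.update(overrides)
    return SimulationParams(rng_seed=rng_seed, **kwargs)


def count_recovered_waves(
    events: list[WaveEvent],
    truth: GroundTruth,
    section_start_frame: int,
    slack_frames: int = 20,
) -> int:
    """One-to-one matching of detected waves against planted ones.

    A planted wave is recovered when some detected event activates within
    ``[start - slack, end]`` of it (frames); each event matches at most one
    planted wave, so a single merged detection cannot claim a whole train.
    """
    starts = truth.wave_start_frames - section_start_frame
    ends = truth.wave_end_frames - section_start_frame
    used = np.zeros(len(events), dtype=bool)
    recovered = 0
    for s, e in zip(starts, ends):
        for k, ev in enumerate(events):
            if used[k]:
                continue
            if s - slack_frames <= ev.activation_frame <= e:
                used[k] = True
                recovered += 1
                break
    return recovered


def write_simulation(
    outdir: str | Path,
    traces: TraceMatrix,
    centroids: CellCentroids,
    timeline: ExperimentTimeline,
    truth: GroundTruth | None = None,
) -> None:
    """Write a simulated recording in the exact formats the loaders read
    (traces.csv, centroids.csv, timeline.json, plus ground_truth.json)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_multimeasure_csv(outdir / "traces.csv", traces)
    import pandas as pd

    pd.DataFrame({
        "Label": centroids.cell_ids,
        "X": centroids.x_px,
        "Y": centroids.y_px,
    }).to_csv(outdir / "centroids.csv", index=False, float_format="%.12g")
    (outdir / "timeline.json").write_text(
        json.dumps(timeline.to_dict(), indent=2) + "\n"
    )
    if truth is not None:
        payload = {
            "first_responders": truth.first_responders.tolist(),
            "leaders": truth.leaders.tolist(),
            "high_participation": truth.high_participation.tolist(),
            "dead_cells": truth.dead_cells.tolist(),
            "fp_onset_s": truth.fp_onset_s.tolist(),
            "wave_start_frames": truth.wave_start_frames.tolist(),
            "wave_end_frames": truth.wave_end_frames.tolist(),
        }
        (outdir / "ground_truth.json").write_text(
            json.dumps(payload, indent=2) + "\n"
        )
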