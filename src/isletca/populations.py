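"""Per-cell functional classification: first-responders and leaders.

*First-responders* are the 10% of KCl-responsive beta-cells with the
fastest first-phase activation (FR-T20, measured on the min-max normalised
single-cell trace from the moment glucose rises to 11 mM).

*Leaders* are called during the second phase: within each islet-level
Ca2+ wave window the cell trace is rescaled to [0, 1] and its per-wave
activation latency (SCSP-T20-i) measured from the window start; cells whose
mean latency over the waves they participate in is at or below the 10th
percentile are leaders.

Cells that show no Ca2+ rise after KCl depolarisation cannot be quantified
reliably and are excluded up front.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateTraceError
from .io import ExperimentTimeline
from .metrics import DEFAULT_ACTIVITY_THRESHOLD, WaveEvent
from .preprocess import fold_change_general, minmax_normalize

__all__ = [
    "CellPhenotype",
    "kcl_filter",
    "activation_time_t20",
    "first_responder_latencies",
    "identify_first_responders",
    "wave_windows",
    "leader_latencies",
    "identify_leaders",
]

log = logging.getLogger(__name__)


@dataclass
class CellPhenotype:
    """Per-cell summary row written to ``cell_labels.csv``."""

    cell_id: str
    included: bool
    fr_t20_s: float | None = None
    mean_scsp_t20_s: float | None = None
    is_first_responder: bool = False
    is_leader: bool = False
    is_hub_criterion: bool = False
    is_hub_top10: bool = False


def kcl_filter(
    cell_traces: np.ndarray,
    timeline: ExperimentTimeline,
    threshold: float = DEFAULT_ACTIVITY_THRESHOLD,
) -> np.ndarray:
    """Boolean mask of cells responsive to terminal KCl depolarisation.

    A cell is included iff its general fold change (3 mM baseline) exceeds
    the threshold at any frame of the KCl window.  An empty KCl window
    includes every cell, with a warning.
    """
    traces = np.atleast_2d(np.asarray(cell_traces, dtype=float))
    s, e = timeline.kcl_window
    if e <= s:
        log.warning("empty KCl window; including all cells unfiltered")
        return np.ones(traces.shape[0], dtype=bool)
    bs, be = timeline.baseline_window
    included = np.zeros(traces.shape[0], dtype=bool)
    for i, row in enumerate(traces):
        try:
            fc = fold_change_general(row, (bs, be)).values
        except DegenerateTraceError:
            included[i] = False
            continue
        included[i] = bool(np.any(fc[s:e] > threshold))
    return included


def activation_time_t20(
    normalized_values: np.ndarray,
    window: tuple[int, int],
    threshold: float = 0.20,
    frame_interval_s: float = 0.5,
) -> float | None:
    """Latency from window start to the first frame at or above the
    threshold on a min-max normalised trace, in seconds; None if the trace
    never reaches it within the window."""
    x = np.asarray(normalized_values, dtype=float)
    s, e = window
    hits = np.nonzero(x[s:e] >= threshold)[0]
    if hits.size == 0:
        return None
    return float(hits[0]) * frame_interval_s


def first_responder_latencies(
    cell_traces: np.ndarray,
    timeline: ExperimentTimeline,
    threshold: float = 0.20,
) -> np.ndarray:
    """FR-T20 per cell in seconds from the 11 mM glucose rise (NaN when a
    cell never activates or is constant).

    Each cell is min-max normalised with ``F_min`` taken before the initial
    glucose response (the 3 mM window) and ``F_max`` over the first-phase
    analysis window, then the T20 crossing is located inside
    ``[frame_g11, first_phase_end_frame)``.
    """
    traces = np.atleast_2d(np.asarray(cell_traces, dtype=float))
    fp = timeline.first_phase_window
    out = np.full(traces.shape[0], np.nan)
    for i, row in enumerate(traces):
        try:
            norm = minmax_normalize(
                row, window=(0, fp[1]), min_window=timeline.baseline_window
            )
        except DegenerateTraceError:
            log.warning("cell %d constant over the first phase; no FR-T20", i)
            continue
        t = activation_time_t20(
            norm.values, fp, threshold=threshold,
            frame_interval_s=timeline.frame_interval_s,
        )
        if t is not None:
            out[i] = t
    return out


def identify_first_responders(
    latencies_s: np.ndarray,
    included: np.ndarray | None = None,
    fraction: float = 0.10,
) -> np.ndarray:
    """Label the fastest ``ceil(fraction * n_included)`` cells.

    Cells with no latency (NaN) rank last and are never labelled; ties at
    the cutoff resolve by earlier latency then by cell order (stable sort).
    """
    lat = np.asarray(latencies_s, dtype=float)
    n = lat.size
    if included is None:
        included = np.ones(n, dtype=bool)
    included = np.asarray(included, dtype=bool)
    n_incl = int(included.sum())
    labels = np.zeros(n, dtype=bool)
    if n_incl == 0:
        log.warning("no included cells; no first-responders labelled")
        return labels
    if n_incl < 10:
        log.warning("only %d included cells; first-responder call is coarse", n_incl)
    k = math.ceil(fraction * n_incl)
    eligible = included & np.isfinite(lat)
    order = np.argsort(lat[eligible], kind="stable")
    chosen = np.nonzero(eligible)[0][order][:k]
    labels[chosen] = True
    return labels


def wave_windows(
    islet_waves: list[WaveEvent],
    valley_frames: np.ndarray,
    section: tuple[int, int],
) -> list[tuple[int, int]]:
    """Per-wave analysis windows from the islet waves and baseline anchors.

    Window ``i`` runs from the valley anchor preceding wave ``i``'s
    activation to the anchor following its deactivation, clipped to the
    section; waves without a separating anchor split at the midpoint of the
    gap between them.  Windows are half-open, ordered and non-overlapping.
    All frames are section-relative.
    """
    lo, hi = 0, section[1] - section[0]
    anchors = np.asarray(valley_frames, dtype=int)
    windows: list[tuple[int, int]] = []
    prev_end = lo
    for i, w in enumerate(islet_waves):
        before = anchors[anchors <= w.activation_frame]
        start = int(before[-1]) if before.size else lo
        after = anchors[anchors >= w.deactivation_frame]
        end = int(after[0]) if after.size else hi
        start = max(start, prev_end, lo)
        end = min(end, hi)
        if i + 1 < len(islet_waves):
            nxt = islet_waves[i + 1].activation_frame
            if end > nxt:  # no anchor between consecutive waves
                end = (w.deactivation_frame + nxt) // 2
        if start >= end:
            log.warning("degenerate window for wave %d; skipped", i)
            continue
        windows.append((start, end))
        prev_end = end
    return windows


def leader_latencies(
    cell_sf: np.ndarray,
    windows: list[tuple[int, int]],
    frame_interval_s: float,
    threshold: float = DEFAULT_ACTIVITY_THRESHOLD,
    min_participation: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean per-wave activation latency (SCSP-T20) per cell, in seconds.

    ``cell_sf`` holds each cell's adaptive-baseline fold change over the
    section the windows refer to.  A cell participates in a wave when its
    fold change exceeds the activity threshold inside the window; for
    participating cells the trace is min-max rescaled within the window and
    the T20 crossing timed from the window start.  Cells participating in
    fewer than ``min_participation`` of the waves get NaN (their mean would
    be unstable) and are logged.

    Returns ``(mean_latency_s, participation_fraction)`` per cell.
    """
    sf = np.atleast_2d(np.asarray(cell_sf, dtype=float))
    n_cells = sf.shape[0]
    n_waves = len(windows)
    if n_waves == 0:
        log.warning("no wave windows; leader latencies undefined")
        return np.full(n_cells, np.nan), np.zeros(n_cells)
    lat_sum = np.zeros(n_cells)
    lat_cnt = np.zeros(n_cells, dtype=int)
    for (s, e) in windows:
        seg = sf[:, s:e]
        for i in range(n_cells):
            row = seg[i]
            if not np.any(row > threshold):
                continue  # cell sat this wave out
            rng_ = row.max() - row.min()
            if rng_ <= 0:
                continue
            rescaled = (row - row.min()) / rng_
            hits = np.nonzero(rescaled >= 0.20)[0]
            if hits.size == 0:
                continue
            lat_sum[i] += hits[0] * frame_interval_s
            lat_cnt[i] += 1
    participation = lat_cnt / n_waves
    means = np.full(n_cells, np.nan)
    active = lat_cnt > 0
    means[active] = lat_sum[active] / lat_cnt[active]
    low = active & (participation < min_participation)
    if np.any(low):
        log.info(
            "%d cells active in < %.0f%% of waves excluded from leader "
            "eligibility", int(low.sum()), 100 * min_participation,
        )
    means[participation < min_participation] = np.nan
    return means, participation


def identify_leaders(
    mean_latencies_s: np.ndarray,
    included: np.ndarray | None = None,
    percentile: float = 10.0,
) -> np.ndarray:
    """Label cells whose mean per-wave latency is at or below the given
    percentile of the included, eligible cells (inclusive "linear"
    percentile definition)."""
    lat = np.asarray(mean_latencies_s, dtype=float)
    n = lat.size
    if included is None:
        included = np.ones(n, dtype=bool)
    eligible = np.asarray(included, dtype=bool) & np.isfinite(lat)
    labels = np.zeros(n, dtype=bool)
    if not np.any(eligible):
        log.warning("no eligible cells; no leaders labelled")
        return labels
    cutoff = np.percentile(lat[eligible], percentile, method="linear")
    labels[eligible] = lat[eligible] <= cutoff
    return labels
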