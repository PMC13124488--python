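"""Signal conditioning shared by islet-level and single-cell analyses.

The stages mirror the standard workflow for GCaMP islet recordings:

1. moving-average smoothing (3-15 frame window) to suppress shot noise and
   small focal-plane movements;
2. expression as *fold change* ``(F - F_min) / F_min`` against the minimum
   recorded at 3 mM glucose (the "general" baseline);
3. for oscillation analysis, an *adaptive baseline*: a piecewise-linear
   curve through filtered signal valleys that detrends slow drifts of the
   Ca2+ baseline, so that individual waves can be thresholded reliably.

All functions operate on 1-D numpy arrays indexed by frame.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .errors import DegenerateTraceError

__all__ = [
    "FoldChangeTrace",
    "NormalizedTrace",
    "AdaptiveBaseline",
    "smooth_trace",
    "fold_change_general",
    "minmax_normalize",
    "detect_local_extrema",
    "filter_extrema",
    "build_adaptive_baseline",
    "fold_change_adaptive",
    "adaptive_fold_change",
]

log = logging.getLogger(__name__)

#: Default moving-average window (frames); the recommended filter size.
DEFAULT_SMOOTH_WINDOW = 15
#: Minimum peak-to-valley separation for baseline anchoring, in seconds:
#: a Ca2+ wave typically returns to baseline within ~12.5 s, so peaks closer
#: than this to a valley belong to the wave itself, not to the baseline.
DEFAULT_VALLEY_SEPARATION_S = 12.5
#: A valley must sit at least 30% below its reference peak to anchor the
#: adaptive baseline.
DEFAULT_MIN_DROP_FRAC = 0.30


@dataclass
class FoldChangeTrace:
    """Unitless fold-change trace ``(F - baseline) / baseline``."""

    values: np.ndarray
    baseline_kind: str  # "general" | "adaptive" | "per_wave"
    source_window: tuple[int, int] | None = None


@dataclass
class NormalizedTrace:
    """Min-max normalised trace, forced into [0, 1] over its window."""

    values: np.ndarray
    window: tuple[int, int]


@dataclass
class AdaptiveBaseline:
    """Piecewise-linear baseline through retained valley anchors.

    Outside the first/last anchor the baseline extends flat at the nearest
    anchor value.  ``removed_peaks``/``removed_valleys`` record the extrema
    the filtering stage rejected, with the reason, for auditing.
    """

    baseline: np.ndarray
    valley_frames: np.ndarray
    removed_peaks: list[tuple[int, str]] = field(default_factory=list)
    removed_valleys: list[tuple[int, str]] = field(default_factory=list)


def smooth_trace(values: np.ndarray, window_frames: int = DEFAULT_SMOOTH_WINDOW) -> np.ndarray:
    """Centred moving average; edges average over the frames available.

    ``window_frames`` outside 3-15 triggers a warning (over-smoothing can
    mask small Ca2+ peaks; under-smoothing leaves noise extrema that disturb
    valley detection).
    """
    values = np.asarray(values, dtype=float)
    w = int(window_frames)
    if w < 1:
        raise ValueError(f"window_frames must be >= 1, got {window_frames}")
    if not (3 <= w <= 15):
        warnings.warn(
            f"smoothing window {w} outside the recommended 3-15 frame range",
            stacklevel=2,
        )
    n = values.size
    if w > n:
        raise ValueError(f"window_frames={w} exceeds trace length {n}")
    left = (w - 1) // 2
    right = w // 2
    idx = np.arange(n)
    starts = np.clip(idx - left, 0, n)
    ends = np.clip(idx + right + 1, 0, n)
    cs = np.concatenate(([0.0], np.cumsum(values)))
    return (cs[ends] - cs[starts]) / (ends - starts)


def fold_change_general(
    values: np.ndarray, baseline_window: tuple[int, int]
) -> FoldChangeTrace:
    """Express a raw trace as fold change over the general baseline.

    ``F_min`` is the minimum over ``baseline_window`` (the 3 mM-glucose
    segment in the standard protocol); the result is
    ``(F_i - F_min) / F_min`` and is exactly 0 at the window minimum.
    """
    values = np.asarray(values, dtype=float)
    s, e = baseline_window
    window_vals = values[s:e]
    if window_vals.size == 0:
        raise ValueError(f"empty baseline window {baseline_window}")
    f_min = float(window_vals.min())
    if f_min <= 0:
        raise DegenerateTraceError(
            f"baseline minimum {f_min} is not positive; fluorescence must be "
            "positive — apply an offset correction before fold change"
        )
    return FoldChangeTrace(
        values=(values - f_min) / f_min,
        baseline_kind="general",
        source_window=(int(s), int(e)),
    )


def minmax_normalize(
    values: np.ndarray,
    window: tuple[int, int],
    min_window: tuple[int, int] | None = None,
) -> NormalizedTrace:
    """Rescale a trace to [0, 1]: ``(F_i - F_min) / (F_max - F_min)``.

    ``F_max`` is taken over ``window``; ``F_min`` too, unless ``min_window``
    is given (single-cell activation times take ``F_min`` from before the
    glucose response but ``F_max`` from the response window).
    """
    values = np.asarray(values, dtype=float)
    s, e = window
    f_max = float(values[s:e].max())
    ms, me = min_window if min_window is not None else window
    f_min = float(values[ms:me].min())
    if f_max <= f_min:
        raise DegenerateTraceError(
            f"constant trace over frames [{s}, {e}): min-max normalisation "
            "is undefined; flag the cell as unanalysable"
        )
    return NormalizedTrace(values=(values - f_min) / (f_max - f_min), window=(int(s), int(e)))


def detect_local_extrema(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Strict local maxima and minima of a trace.

    Plateaus report their first frame; the first and last frames of the
    trace are never extrema.  Returns ``(peak_frames, valley_frames)``.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 frames to define interior extrema")
    peaks, props = find_peaks(values, plateau_size=1)
    peak_frames = props["left_edges"]
    valleys, vprops = find_peaks(-values, plateau_size=1)
    valley_frames = vprops["left_edges"]
    return peak_frames.astype(int), valley_frames.astype(int)


def filter_extrema(
    values: np.ndarray,
    peaks: np.ndarray,
    valleys: np.ndarray,
    min_separation_frames: int = 25,
    min_drop_frac: float = DEFAULT_MIN_DROP_FRAC,
    return_audit: bool = False,
):
    """Select the valleys that anchor the adaptive baseline.

    For each valley the reference peak is the immediately preceding peak at
    least ``min_separation_frames`` before it — peaks closer than that are
    part of the deactivating wave and are discarded from the pairing.  The
    valley is kept only when it sits at least ``min_drop_frac`` below the
    reference: ``(peak - valley) / peak >= min_drop_frac``.  Valleys with no
    (surviving) preceding peak are retained as anchors, which keeps the
    pre-activation segment of a section anchored at baseline level.

    Returns the kept valley frames (a subset of ``valleys``, order
    preserved); with ``return_audit=True`` also returns the removed peaks
    and valleys with the reason for each.
    """
    values = np.asarray(values, dtype=float)
    peaks = np.asarray(peaks, dtype=int)
    valleys = np.asarray(valleys, dtype=int)
    kept: list[int] = []
    removed_valleys: list[tuple[int, str]] = []
    paired_peaks: set[int] = set()
    for v in valleys:
        preceding = peaks[peaks < v]
        if preceding.size == 0:
            kept.append(int(v))
            continue
        qualifying = preceding[(v - preceding) >= min_separation_frames]
        if qualifying.size == 0:
            # every preceding peak is within the wave-deactivation distance
            kept.append(int(v))
            continue
        ref = int(qualifying[-1])
        paired_peaks.add(ref)
        pk, vl = values[ref], values[v]
        if pk > 0 and (pk - vl) / pk >= min_drop_frac:
            kept.append(int(v))
        else:
            removed_valleys.append(
                (int(v), f"drop below reference peak at frame {ref} is < "
                         f"{min_drop_frac:.0%}")
            )
    removed_peaks = [
        (int(p), "within min separation of a valley")
        for p in peaks
        if p not in paired_peaks
        and np.any(np.abs(valleys - p) < min_separation_frames)
    ]
    kept_arr = np.asarray(kept, dtype=int)
    if return_audit:
        return kept_arr, removed_peaks, removed_valleys
    return kept_arr


def build_adaptive_baseline(
    values: np.ndarray, valleys_kept: np.ndarray
) -> AdaptiveBaseline:
    """Connect the retained valleys with straight lines (``y = m x + b``
    between consecutive anchors) to form the adaptive baseline.

    Beyond the first/last anchor the baseline extends flat.  With no valleys
    at all the baseline falls back to a constant at the trace minimum.
    """
    values = np.asarray(values, dtype=float)
    valleys_kept = np.asarray(valleys_kept, dtype=int)
    frames = np.arange(values.size)
    if valleys_kept.size == 0:
        log.warning(
            "no valley anchors retained; falling back to a constant baseline "
            "at the trace minimum"
        )
        baseline = np.full(values.size, float(values.min()))
    else:
        baseline = np.interp(frames, valleys_kept, values[valleys_kept])
    return AdaptiveBaseline(baseline=baseline, valley_frames=valleys_kept)


def fold_change_adaptive(
    values: np.ndarray,
    baseline: np.ndarray | AdaptiveBaseline,
    ratio_shift: float = 0.0,
) -> FoldChangeTrace:
    """Fold change against a per-frame baseline:
    ``(F_i - BL_i) / BL_i`` evaluated with an optional common shift.

    On raw intensities use ``ratio_shift=0`` (the direct formula).  When the
    input is already a section fold-change trace, its baseline can touch 0,
    so the ratio is taken in intensity space by shifting both sides by +1
    (``ratio_shift=1``): ``SF = (1 + F) / (1 + BL) - 1``, which reduces to
    the direct formula on raw intensities and keeps the divisor positive.
    """
    values = np.asarray(values, dtype=float)
    bl = baseline.baseline if isinstance(baseline, AdaptiveBaseline) else np.asarray(baseline, dtype=float)
    if bl.shape != values.shape:
        raise ValueError("baseline and trace must have the same length")
    denom = bl + ratio_shift
    bad = np.nonzero(denom <= 0)[0]
    if bad.size:
        raise DegenerateTraceError(
            f"adaptive baseline not positive at frame {int(bad[0])}; cannot "
            "express fold change"
        )
    return FoldChangeTrace(
        values=(values + ratio_shift) / denom - 1.0,
        baseline_kind="adaptive",
    )


def adaptive_fold_change(
    section_raw: np.ndarray,
    min_separation_frames: int = 25,
    min_drop_frac: float = DEFAULT_MIN_DROP_FRAC,
) -> tuple[FoldChangeTrace, AdaptiveBaseline]:
    """Full adaptive detrending of one analysis section.

    The (smoothed) raw section is first expressed as section fold change
    against its own minimum, valleys are detected and filtered on that
    trace, the baseline is built through them, and the section fold change
    is re-expressed relative to the baseline (shift-by-one ratio, see
    :func:`fold_change_adaptive`).  Returns the detrended fold-change trace
    and the baseline object (anchors + audit trail).
    """
    section_raw = np.asarray(section_raw, dtype=float)
    section_fc = fold_change_general(section_raw, (0, section_raw.size))
    peaks, valleys = detect_local_extrema(section_fc.values)
    kept, removed_peaks, removed_valleys = filter_extrema(
        section_fc.values,
        peaks,
        valleys,
        min_separation_frames=min_separation_frames,
        min_drop_frac=min_drop_frac,
        return_audit=True,
    )
    bl = build_adaptive_baseline(section_fc.values, kept)
    bl.removed_peaks = removed_peaks
    bl.removed_valleys = removed_valleys
    sf = fold_change_adaptive(section_fc.values, bl.baseline, ratio_shift=1.0)
    return sf, bl
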