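"""Reading and writing the pipeline's input and output artifacts.

Inputs are the three files an imaging session produces once ROIs have been
drawn: the ImageJ "Multi Measure" trace table (one row per frame, one column
per ROI), the ROI centroid table, and a small JSON file describing the
stimulation timeline (frame interval and the frames at which 11 mM glucose,
25 mM glucose, and KCl were added).  Outputs are plain CSV/JSON tables so
that two runs of the same analysis are diffable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, InputFormatError

__all__ = [
    "TraceMatrix",
    "CellCentroids",
    "ExperimentTimeline",
    "PROTOCOL_DEFAULTS",
    "read_multimeasure_csv",
    "write_multimeasure_csv",
    "read_centroids_csv",
    "read_timeline_config",
    "write_results",
]

#: Stimulation protocol defaults: 2 frames/s for 42 min (5,040 frames),
#: 11 mM glucose at frame 360 (3 min), 25 mM at frame 2,160, KCl near the end.
PROTOCOL_DEFAULTS = {
    "frame_interval_s": 0.5,
    "n_frames": 5040,
    "frame_g11": 360,
    "frame_g25": 2160,
    "frame_kcl": 4800,
}

# Numeric formatting used for every CSV we emit; 12 significant digits keeps
# float64 round-trips byte-stable across runs.
_FLOAT_FMT = "%.12g"


@dataclass
class TraceMatrix:
    """Raw fluorescence, cells x frames, with ROI identities and a time axis.

    ``fluorescence[i, t]`` is the integrated density of ROI ``i`` at frame
    ``t`` (arbitrary units).  When ``includes_islet_roi`` is true, row 0 is
    the whole-islet polygon trace and rows 1.. are single cells.
    """

    cell_ids: list[str]
    fluorescence: np.ndarray
    frame_interval_s: float
    includes_islet_roi: bool = False

    def __post_init__(self) -> None:
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.fluorescence.ndim != 2:
            raise InputFormatError("fluorescence must be a 2-D cells x frames array")
        if self.fluorescence.shape[0] != len(self.cell_ids):
            raise InputFormatError(
                f"{len(self.cell_ids)} cell ids but "
                f"{self.fluorescence.shape[0]} trace rows"
            )
        if self.fluorescence.shape[1] < 2:
            raise InputFormatError("a recording needs at least 2 frames")
        if self.frame_interval_s <= 0:
            raise ConfigError("frame_interval_s must be positive")
        if not np.all(np.isfinite(self.fluorescence)):
            raise InputFormatError("fluorescence contains non-finite values")
        if np.any(self.fluorescence < 0):
            raise InputFormatError("fluorescence intensities must be >= 0")

    @property
    def n_rois(self) -> int:
        return self.fluorescence.shape[0]

    @property
    def n_frames(self) -> int:
        return self.fluorescence.shape[1]

    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s

    def cell_traces(self) -> np.ndarray:
        """Single-cell rows (drops the islet polygon row when present)."""
        return self.fluorescence[1:] if self.includes_islet_roi else self.fluorescence

    def cell_trace_ids(self) -> list[str]:
        return self.cell_ids[1:] if self.includes_islet_roi else self.cell_ids

    def islet_trace(self) -> np.ndarray:
        """Whole-islet trace: the polygon ROI when recorded, otherwise the
        mean of the single-cell traces."""
        if self.includes_islet_roi:
            return self.fluorescence[0]
        return self.fluorescence.mean(axis=0)


@dataclass
class CellCentroids:
    """ROI centroid coordinates in image pixels, in ROI order."""

    cell_ids: list[str]
    x_px: np.ndarray
    y_px: np.ndarray

    def __post_init__(self) -> None:
        self.x_px = np.asarray(self.x_px, dtype=float)
        self.y_px = np.asarray(self.y_px, dtype=float)
        n = len(self.cell_ids)
        if self.x_px.shape != (n,) or self.y_px.shape != (n,):
            raise InputFormatError("centroid arrays must match cell_ids length")
        if not (np.all(np.isfinite(self.x_px)) and np.all(np.isfinite(self.y_px))):
            raise InputFormatError("centroid coordinates must be finite")

    def __len__(self) -> int:
        return len(self.cell_ids)


@dataclass
class ExperimentTimeline:
    """Frame-indexed stimulation timeline.

    All frames are 0-based and windows are half-open ``[start, end)``:
    3 mM baseline ``[0, frame_g11)``, first phase
    ``[frame_g11, first_phase_end_frame)``, second phase
    ``[frame_g25, frame_kcl)``, KCl ``[frame_kcl, n_frames)``.
    """

    frame_interval_s: float
    n_frames: int
    frame_g11: int
    frame_g25: int
    frame_kcl: int
    first_phase_end_frame: int | None = None

    def __post_init__(self) -> None:
        if self.first_phase_end_frame is None:
            self.first_phase_end_frame = self.frame_g25
        if self.frame_interval_s <= 0:
            raise ConfigError("frame_interval_s must be positive")
        if not (0 < self.frame_g11 < self.frame_g25 < self.frame_kcl <= self.n_frames):
            raise ConfigError(
                "stimulus frames must satisfy 0 < g11 < g25 < kcl <= n_frames, got "
                f"g11={self.frame_g11}, g25={self.frame_g25}, "
                f"kcl={self.frame_kcl}, n_frames={self.n_frames}"
            )
        if not (self.frame_g11 < self.first_phase_end_frame <= self.frame_g25):
            raise ConfigError(
                "first_phase_end_frame must lie in (frame_g11, frame_g25], got "
                f"{self.first_phase_end_frame}"
            )

    # window helpers (frame ranges, half-open)
    @property
    def baseline_window(self) -> tuple[int, int]:
        return (0, self.frame_g11)

    @property
    def first_phase_window(self) -> tuple[int, int]:
        return (self.frame_g11, int(self.first_phase_end_frame))

    @property
    def second_phase_window(self) -> tuple[int, int]:
        return (self.frame_g25, self.frame_kcl)

    @property
    def kcl_window(self) -> tuple[int, int]:
        return (self.frame_kcl, self.n_frames)

    def to_dict(self) -> dict:
        return asdict(self)


def _detect_index_column(df: pd.DataFrame) -> bool:
    """Heuristic for the leading ImageJ row-index column: either an unnamed
    header or consecutive integers 1..N (ImageJ numbers frames from 1)."""
    first = df.columns[0]
    name = str(first).strip().lower()
    if name == "" or name.startswith("unnamed"):
        return True
    col = df.iloc[:, 0]
    try:
        vals = pd.to_numeric(col, errors="raise").to_numpy()
    except (ValueError, TypeError):
        return False
    if not np.allclose(vals, np.round(vals)):
        return False
    n = len(vals)
    return bool(np.array_equal(vals, np.arange(1, n + 1)))


def read_multimeasure_csv(
    path: str | Path,
    frame_interval_s: float,
    islet_roi_first: bool = False,
) -> TraceMatrix:
    """Read an ImageJ "Multi Measure" export: one row per frame, one column
    per ROI; a leading row-index column (1..N) is recognised and dropped.

    Parameters
    ----------
    path
        CSV file as saved from the ImageJ ROI manager.
    frame_interval_s
        Seconds per frame (not stored in the ImageJ export).
    islet_roi_first
        Set when the first ROI column is the whole-islet polygon rather
        than a single cell.
    """
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"trace file not found: {path}")
    try:
        df = pd.read_csv(path, keep_default_na=False, na_values=[])
    except pd.errors.ParserError as exc:
        raise InputFormatError(f"malformed trace CSV {path}: {exc}") from exc
    if df.shape[0] < 2:
        raise InputFormatError(f"{path}: a recording needs at least 2 data rows")

    if _detect_index_column(df):
        df = df.iloc[:, 1:]
    if df.shape[1] < 1:
        raise InputFormatError(f"{path}: no ROI columns after the index column")

    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() | ~np.isfinite(numeric.to_numpy(dtype=float, na_value=np.nan))
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise InputFormatError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at data row {r + 1}, "
            f"column {df.columns[c]!r}"
        )
    return TraceMatrix(
        cell_ids=[str(c) for c in df.columns],
        fluorescence=numeric.to_numpy(dtype=float).T,
        frame_interval_s=frame_interval_s,
        includes_islet_roi=islet_roi_first,
    )


def write_multimeasure_csv(path: str | Path, traces: TraceMatrix) -> None:
    """Write a TraceMatrix in the same layout ImageJ produces (row index
    column 1..N, one ROI per column)."""
    df = pd.DataFrame(traces.fluorescence.T, columns=traces.cell_ids)
    df.insert(0, " ", np.arange(1, traces.n_frames + 1))
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_centroids_csv(
    path: str | Path, expected_n: int | None = None
) -> CellCentroids:
    """Read the ImageJ centroid measurement table (needs X and Y columns,
    case-insensitive); ROI order is preserved."""
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"centroid file not found: {path}")
    df = pd.read_csv(path)
    cols = {str(c).strip().lower(): c for c in df.columns}
    if "x" not in cols or "y" not in cols:
        raise InputFormatError(
            f"{path}: centroid table must have X and Y columns, found "
            f"{list(df.columns)}"
        )
    label_col = next((cols[k] for k in ("label", "cell", "id", "roi") if k in cols), None)
    if label_col is not None:
        ids = [str(v) for v in df[label_col]]
    else:
        ids = [f"ROI_{i + 1}" for i in range(len(df))]
    cent = CellCentroids(
        cell_ids=ids,
        x_px=pd.to_numeric(df[cols["x"]]).to_numpy(),
        y_px=pd.to_numeric(df[cols["y"]]).to_numpy(),
    )
    if expected_n is not None and len(cent) != expected_n:
        raise InputFormatError(
            f"{path}: {len(cent)} centroids but {expected_n} ROIs expected"
        )
    return cent


def read_timeline_config(path: str | Path) -> ExperimentTimeline:
    """Read the flat-JSON experiment timeline.

    Keys: ``frame_interval_s``, ``n_frames``, ``frame_g11``, ``frame_g25``,
    ``frame_kcl``, optional ``first_phase_end_frame``.  With
    ``"use_protocol_defaults": true`` any missing key falls back to the
    standard 42-min, 2 frames/s glucose-ramp protocol.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"timeline config not found: {path}")
    with open(path) as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"timeline config {path} is not valid JSON: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"timeline config {path} must be a JSON object")
    use_defaults = bool(raw.pop("use_protocol_defaults", False))
    fields = dict(PROTOCOL_DEFAULTS) if use_defaults else {}
    known = set(PROTOCOL_DEFAULTS) | {"first_phase_end_frame"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown timeline keys: {sorted(unknown)}")
    fields.update(raw)
    missing = set(PROTOCOL_DEFAULTS) - set(fields)
    if missing:
        raise ConfigError(
            f"timeline config missing {sorted(missing)} "
            "(set use_protocol_defaults to fall back to the standard protocol)"
        )
    return ExperimentTimeline(**fields)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_results(
    outdir: str | Path,
    global_metrics: dict | None = None,
    waves: pd.DataFrame | None = None,
    coactivity=None,
    cell_labels: pd.DataFrame | None = None,
    edges: pd.DataFrame | None = None,
) -> list[Path]:
    """Write the standard result file set into ``outdir``.

    Produces ``global_metrics.json``, ``waves.csv``, ``coactivity_matrix.csv``,
    ``significance_mask.csv``, ``cell_labels.csv`` and ``edges.csv`` (only the
    ones whose inputs are given).  Formatting is fixed so reruns with the same
    configuration and seed are byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _emit(name: str, writer) -> None:
        p = outdir / name
        writer(p)
        written.append(p)

    if global_metrics is not None:
        _emit(
            "global_metrics.json",
            lambda p: p.write_text(
                json.dumps(global_metrics, indent=2, sort_keys=True,
                           default=_json_default)
                + "\n"
            ),
        )
    if waves is not None:
        _emit("waves.csv",
              lambda p: waves.to_csv(p, index=False, float_format=_FLOAT_FMT))
    if coactivity is not None:
        ids = getattr(coactivity, "cell_ids", None)
        if ids is None:
            ids = [str(i) for i in range(coactivity.C.shape[0])]
        cmat = pd.DataFrame(coactivity.C, index=ids, columns=ids)
        _emit("coactivity_matrix.csv",
              lambda p: cmat.to_csv(p, float_format=_FLOAT_FMT))
        sig = pd.DataFrame(coactivity.significant.astype(int), index=ids, columns=ids)
        _emit("significance_mask.csv", lambda p: sig.to_csv(p))
    if cell_labels is not None:
        _emit("cell_labels.csv",
              lambda p: cell_labels.to_csv(p, index=False, float_format=_FLOAT_FMT))
    if edges is not None:
        _emit("edges.csv",
              lambda p: edges.to_csv(p, index=False, float_format=_FLOAT_FMT))
    return written
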