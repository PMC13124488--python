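"""End-to-end analysis: load -> condition -> global metrics -> subpopulations.

:func:`run_full_analysis` executes the whole workflow on one recording:

1. load the trace/centroid/timeline artifacts (or take them in memory);
2. smooth every trace and express the islet trace as general fold change;
3. first-phase metrics and AUCs against the 3 mM baseline;
4. adaptive-baseline detrending of the oscillatory section, islet wave
   detection and second-phase metrics;
5. KCl-responsiveness filtering, first-responder calls;
6. per-cell detrending, binarisation, coactivity + shuffle null, hub and
   leader calls;
7. deterministic result files plus the resolved configuration.

Every tunable surfaces in :class:`RunConfig`, whose defaults are the
standard GCaMP6 thresholds (activity > 0.2 fold change sustained >= 2 s,
12.5 s valley separation, 30% valley drop, 10% subpopulation fractions,
10,000 shuffles).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as iio
from . import metrics as gm
from . import network as net
from . import populations as pop
from . import preprocess as pre
from .errors import ConfigError, IsletError

__all__ = ["RunConfig", "AnalysisResult", "run_full_analysis"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run (all thresholds explicit)."""

    traces_path: str | None = None
    centroids_path: str | None = None
    timeline_path: str | None = None
    outdir: str | None = None
    islet_roi_first: bool = False
    smoothing_window: int = pre.DEFAULT_SMOOTH_WINDOW
    activation_threshold: float = gm.DEFAULT_ACTIVITY_THRESHOLD
    min_wave_s: float = gm.DEFAULT_MIN_WAVE_DURATION_S
    valley_min_drop: float = pre.DEFAULT_MIN_DROP_FRAC
    valley_sep_s: float = pre.DEFAULT_VALLEY_SEPARATION_S
    binarize_threshold: float = net.DEFAULT_BINARIZE_THRESHOLD
    n_shuffles: int = net.DEFAULT_N_SHUFFLES
    leader_percentile: float = 10.0
    fr_fraction: float = 0.10
    hub_rule: str = "both"              # criterion | top10 | both
    analysis_section: str = "second"    # second (25 mM) or first (11 mM)
    shuffle_mode: str = "rotate"
    cislet_significant_only: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.hub_rule not in ("criterion", "top10", "both"):
            raise ConfigError(f"hub_rule must be criterion|top10|both, got {self.hub_rule!r}")
        if self.analysis_section not in ("first", "second"):
            raise ConfigError(f"analysis_section must be first|second, got {self.analysis_section!r}")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))


@dataclass
class AnalysisResult:
    """Everything one run computed, in memory."""

    config: RunConfig
    timeline: iio.ExperimentTimeline
    global_metrics: gm.GlobalMetrics
    waves: list[gm.WaveEvent]
    islet_sf: np.ndarray
    islet_baseline: pre.AdaptiveBaseline
    section: tuple[int, int]
    included: np.ndarray
    fr_latencies_s: np.ndarray
    leader_latencies_s: np.ndarray
    first_responders: np.ndarray
    leaders: np.ndarray
    hubs_criterion: np.ndarray
    hubs_top10: np.ndarray
    coactivity: net.CoactivityResult | None
    cell_labels: pd.DataFrame
    written: list[Path] = field(default_factory=list)


class _Stage:
    """Context that prefixes any error with the pipeline stage name."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        log.info("stage: %s", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and isinstance(exc, Exception):
            kind = type(exc) if isinstance(exc, IsletError) else IsletError
            raise kind(f"stage '{self.name}' failed: {exc}") from exc
        return False


def _section_window(cfg: RunConfig, tl: iio.ExperimentTimeline) -> tuple[int, int]:
    if cfg.analysis_section == "second":
        return tl.second_phase_window
    return tl.first_phase_window


def run_full_analysis(
    config: RunConfig,
    traces: iio.TraceMatrix | None = None,
    centroids: iio.CellCentroids | None = None,
    timeline: iio.ExperimentTimeline | None = None,
) -> AnalysisResult:
    """Run the complete analysis; inputs come from ``config`` paths unless
    given in memory.  Deterministic for a fixed config (incl. seed)."""
    cfg = config

    with _Stage("load inputs"):
        if traces is None:
            if cfg.traces_path is None or cfg.timeline_path is None:
                raise ConfigError("traces_path and timeline_path (or in-memory objects) required")
            timeline = iio.read_timeline_config(cfg.timeline_path)
            traces = iio.read_multimeasure_csv(
                cfg.traces_path, timeline.frame_interval_s, cfg.islet_roi_first
            )
        if timeline is None:
            raise ConfigError("timeline required")
        if centroids is None and cfg.centroids_path is not None:
            try:
                centroids = iio.read_centroids_csv(cfg.centroids_path)
            except IsletError as exc:
                log.warning("centroids unavailable (%s); network export degraded", exc)

    tl = timeline
    dt = tl.frame_interval_s
    sep_frames = max(1, int(round(cfg.valley_sep_s / dt)))

    with _Stage("smoothing"):
        cells_raw = traces.cell_traces()
        cell_ids = traces.cell_trace_ids()
        cells = np.vstack([
            pre.smooth_trace(row, cfg.smoothing_window) for row in cells_raw
        ])
        islet = pre.smooth_trace(traces.islet_trace(), cfg.smoothing_window)

    with _Stage("general fold change / first phase / AUC"):
        islet_fc = pre.fold_change_general(islet, tl.baseline_window).values
        fp = gm.first_phase_metrics(islet_fc, tl, cfg.activation_threshold)
        auc_app_first = gm.auc_app(islet_fc, tl.first_phase_window)
        auc_app_second = gm.auc_app(islet_fc, tl.second_phase_window)
        auc_trap_first = gm.auc_trapezoid(islet_fc, tl.first_phase_window, dt)
        auc_trap_second = gm.auc_trapezoid(islet_fc, tl.second_phase_window, dt)

    with _Stage("adaptive baseline / wave detection"):
        sec = _section_window(cfg, tl)
        islet_sf, islet_bl = pre.adaptive_fold_change(
            islet[sec[0]:sec[1]],
            min_separation_frames=sep_frames,
            min_drop_frac=cfg.valley_min_drop,
        )
        waves = gm.detect_waves(
            islet_sf.values, cfg.activation_threshold, cfg.min_wave_s, dt
        )
        sp = gm.second_phase_metrics(waves, sec, dt)

    metrics = gm.GlobalMetrics(
        auc_app_first=auc_app_first,
        auc_app_second=auc_app_second,
        auc_trap_first=auc_trap_first,
        auc_trap_second=auc_trap_second,
        fp_t20_s=fp.fp_t20_s,
        fp_amplitude=fp.fp_amplitude,
        fp_width_s=fp.fp_width_s,
        sp_frequency_per_min=sp.frequency_per_min,
        sp_mean_amplitude=sp.mean_amplitude,
        sp_mean_width_s=sp.mean_width_s,
        n_waves=sp.n_waves,
    )

    with _Stage("KCl filter"):
        included = pop.kcl_filter(cells, tl, cfg.activation_threshold)
        for i in np.nonzero(~included)[0]:
            log.info("cell %s excluded: no KCl response", cell_ids[i])

    with _Stage("first-responders"):
        fr_lat = pop.first_responder_latencies(cells, tl, threshold=0.20)
        fr_labels = pop.identify_first_responders(fr_lat, included, cfg.fr_fraction)

    n_cells = cells.shape[0]
    with _Stage("per-cell detrending / binarisation"):
        sf_rows = np.zeros((n_cells, sec[1] - sec[0]))
        analyzable = included.copy()
        for i in range(n_cells):
            if not included[i]:
                continue
            try:
                sf_i, _ = pre.adaptive_fold_change(
                    cells[i, sec[0]:sec[1]],
                    min_separation_frames=sep_frames,
                    min_drop_frac=cfg.valley_min_drop,
                )
                sf_rows[i] = sf_i.values
            except IsletError as exc:
                log.warning("cell %s not analysable in section: %s", cell_ids[i], exc)
                analyzable[i] = False
        idx = np.nonzero(analyzable)[0]

    coactivity = None
    hubs_criterion = np.zeros(n_cells, dtype=bool)
    hubs_top10 = np.zeros(n_cells, dtype=bool)
    if idx.size >= 2:
        with _Stage("coactivity / hubs"):
            binar = net.binarize(sf_rows[idx], cfg.binarize_threshold, sec)
            coactivity = net.coactivity_matrix(
                binar,
                n_shuffles=cfg.n_shuffles,
                rng=cfg.rng_seed,
                cell_ids=[cell_ids[i] for i in idx],
                shuffle_mode=cfg.shuffle_mode,
                cislet_significant_only=cfg.cislet_significant_only,
            )
            if cfg.hub_rule in ("criterion", "both"):
                hubs_criterion[idx] = net.identify_hubs_criterion(coactivity)
            if cfg.hub_rule in ("top10", "both"):
                hubs_top10[idx] = net.identify_hubs_top10(coactivity)
    else:
        log.warning("fewer than 2 analysable cells; connectivity skipped")

    with _Stage("leaders"):
        windows = pop.wave_windows(waves, islet_bl.valley_frames, sec)
        leader_lat, participation = pop.leader_latencies(
            sf_rows, windows, dt, threshold=cfg.activation_threshold
        )
        leader_lat[~analyzable] = np.nan
        leader_labels = pop.identify_leaders(
            leader_lat, analyzable, cfg.leader_percentile
        )

    with _Stage("assemble / export"):
        labels_df = pd.DataFrame({
            "cell_id": cell_ids,
            "included": included,
            "fr_t20_s": fr_lat,
            "mean_scsp_t20_s": leader_lat,
            "is_first_responder": fr_labels,
            "is_leader": leader_labels,
            "is_hub_criterion": hubs_criterion,
            "is_hub_top10": hubs_top10,
        })
        if centroids is not None and len(centroids) == n_cells:
            labels_df["x_px"] = centroids.x_px
            labels_df["y_px"] = centroids.y_px
        waves_df = pd.DataFrame([
            {
                "wave_id": k,
                "activation_frame": w.activation_frame + sec[0],
                "deactivation_frame": w.deactivation_frame + sec[0],
                "activation_s": (w.activation_frame + sec[0]) * dt,
                "width_s": w.width_s,
                "peak_amplitude": w.peak_amplitude,
                "truncated": w.truncated,
            }
            for k, w in enumerate(waves)
        ], columns=["wave_id", "activation_frame", "deactivation_frame",
                    "activation_s", "width_s", "peak_amplitude", "truncated"])
        written: list[Path] = []
        if cfg.outdir is not None:
            gdict = metrics.to_dict()
            gdict["c_islet"] = coactivity.c_islet if coactivity else None
            gdict["connectivity_class"] = (
                coactivity.connectivity_class if coactivity else None
            )
            edges = None
            if coactivity is not None:
                _, edges = net.export_network(coactivity, centroids)
            written = iio.write_results(
                cfg.outdir,
                global_metrics=gdict,
                waves=waves_df,
                coactivity=coactivity,
                cell_labels=labels_df,
                edges=edges,
            )
            cfg_path = Path(cfg.outdir) / "resolved_config.json"
            cfg_path.write_text(cfg.to_json() + "\n")
            written.append(cfg_path)

    return AnalysisResult(
        config=cfg,
        timeline=tl,
        global_metrics=metrics,
        waves=waves,
        islet_sf=islet_sf.values,
        islet_baseline=islet_bl,
        section=sec,
        included=included,
        fr_latencies_s=fr_lat,
        leader_latencies_s=leader_lat,
        first_responders=fr_labels,
        leaders=leader_labels,
        hubs_criterion=hubs_criterion,
        hubs_top10=hubs_top10,
        coactivity=coactivity,
        cell_labels=labels_df,
        written=written,
    )
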