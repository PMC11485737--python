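"""The real-time loop: per-frame processing plus multi-timescale analysis.

Headless equivalent of a closed-loop acquisition GUI.  Per frame: register
against the template, extract soma/neuropil fluorescence, neuropil-correct,
baseline, dF/F0.  On slower cadences (all measured in *stream time*, frame
index over frame rate, so replay and live runs are bit-identical): a 2 Hz
indicator summary, a 1 Hz functional-network update with degree ranking and
automatic top-5 target selection, a 30 s synchrony report, and per-trial
receptive-field updates when a tone schedule is attached.  Every completed
computation is appended to a JSONL event log — the analogue of the GUI
panels.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from castream import holography, network, rois, stream_io, synchrony, traces, tuning
from castream.registration import Shift, apply_shift, build_template, estimate_shift

__all__ = ["PipelineConfig", "EventLog", "PipelineResult", "run_pipeline", "select_auto_cells"]

log = logging.getLogger(__name__)


class EventLog:
    """Append-only JSONL record stream, one record per completed computation."""

    def __init__(self, path: str | Path | None = None):
        self.path = Path(path) if path is not None else None
        self.records: list[dict] = []
        self._fh = open(self.path, "w") if self.path is not None else None

    def append(self, time_s: float, kind: str, payload: dict) -> None:
        if self.records and time_s < self.records[-1]["time_s"] - 1e-9:
            raise ValueError("event timestamps must be non-decreasing")
        record = {"time_s": float(time_s), "kind": kind, "payload": payload}
        self.records.append(record)
        if self._fh is not None:
            self._fh.write(json.dumps(record) + "\n")
            self._fh.flush()

    def by_kind(self, kind: str) -> list[dict]:
        return [r for r in self.records if r["kind"] == kind]

    def close(self) -> None:
        if self._fh is not None:
            self._fh.close()
            self._fh = None


@dataclass
class PipelineConfig:
    stream: stream_io.StreamConfig
    centers_path: str | Path
    out_dir: str | Path | None = None
    # ROI geometry
    roi_geometry: rois.RoiGeometry = field(default_factory=rois.RoiGeometry)
    # traces
    alpha: float = traces.DEFAULT_ALPHA
    baseline_window_s: float = traces.DEFAULT_WINDOW_S
    # registration
    template_frames: int = 30
    register: bool = True
    upsample: int = 10
    max_shift: float = 20.0
    # network
    network_method: str = "mst"  # "mst" | "threshold"
    theta: float = 0.5
    analysis_window_s: float | None = None  # None -> cumulative
    min_corr_samples: int = network.DEFAULT_MIN_SAMPLES
    # cadences, stream-time seconds
    indicator_period_s: float = 0.5  # 2 Hz
    network_period_s: float = 1.0  # 1 Hz
    synchrony_period_s: float = 30.0
    # synchrony
    n_surrogates: int = synchrony.DEFAULT_N_SURROGATES
    synchrony_alpha: float = synchrony.DEFAULT_ALPHA
    decay_s: float = synchrony.DEFAULT_DECAY_S
    # tuning
    tuning_enabled: bool = False
    schedule_path: str | Path | None = None
    # stimulation trigger
    trigger_mode: str = "manual"  # "manual" | "top5" | "watch"
    watch_cells: tuple[int, ...] = ()
    watch_dff_threshold: float = 0.5
    refractory_s: float = 3.0
    stim_duration_ms: float = 30.0
    stim_period_s: float = 3.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["stream"] = stream_io.StreamConfig(**raw["stream"])
        if "roi_geometry" in raw:
            raw["roi_geometry"] = rois.RoiGeometry(**raw["roi_geometry"])
        for key in ("watch_cells",):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class PipelineResult:
    store: traces.TraceStore
    roiset: rois.ROISet
    events: EventLog
    rankings: list[list[int]]
    receptive_fields: dict[int, tuning.ReceptiveField] | None = None


def select_auto_cells(ranking: list[int], n: int = 5) -> list[int]:
    """Top-n ranked cells (all of them when the session has fewer)."""
    return list(ranking[:n])


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full loop over the configured stream; see module docstring.

    Per-stage failures inside the loop are logged as warning events and the
    loop continues: a failed network update must never kill trace
    extraction.
    """
    cfg = config
    out_dir = Path(cfg.out_dir) if cfg.out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    events = EventLog(out_dir / "events.jsonl" if out_dir is not None else None)

    frame_rate = cfg.stream.frame_rate
    frame_shape = (cfg.stream.height, cfg.stream.width)
    centers = rois.load_centers(cfg.centers_path, frame_shape)
    roiset = rois.build_roiset(centers, frame_shape, cfg.roi_geometry)
    store = traces.TraceStore(
        cell_ids=roiset.cell_ids,
        frame_rate=frame_rate,
        alpha=cfg.alpha,
        window_s=cfg.baseline_window_s,
    )

    schedule = None
    rfs: dict[int, tuning.ReceptiveField] | None = None
    if cfg.tuning_enabled and cfg.schedule_path is not None:
        schedule = tuning.StimulusSchedule.from_csv(cfg.schedule_path)
        rfs = {
            cid: tuning.ReceptiveField(
                cid, list(schedule.frequencies_hz), list(schedule.levels_db)
            )
            for cid in roiset.cell_ids
        }
    # precompute trial windows (sorted by onset); consume with a cursor
    trial_windows: list[tuple[tuning.StimulusEvent, np.ndarray]] = []
    if schedule is not None:
        trial_windows = tuning.assign_trials(schedule, frame_rate, 10**12)
    trial_cursor = 0
    cell_pos = {c: i for i, c in enumerate(roiset.cell_ids)}

    rankings: list[list[int]] = []
    template = None
    template_buf: list[np.ndarray] = []
    pending_frames: list = []  # frames buffered until the template exists
    last_stim_time = -np.inf
    synchrony_rng = np.random.default_rng(cfg.seed)

    def indicator_frames() -> int:
        return max(1, int(round(cfg.indicator_period_s * frame_rate)))

    def process_frame(frame) -> None:
        nonlocal last_stim_time
        if cfg.register and template is not None:
            shift = estimate_shift(frame, template, cfg.upsample, cfg.max_shift)
            if not shift.degenerate:
                frame = apply_shift(frame, shift)
            events.append(
                frame.time_s,
                "shift",
                {"frame": frame.index, "dy": shift.dy, "dx": shift.dx,
                 "error": shift.registration_error, "degenerate": shift.degenerate,
                 "clamped": shift.clamped},
            )
        f_soma, f_np = traces.extract_fluorescence(frame, roiset)
        dff = store.append_frame(f_soma, f_np)
        t = frame.time_s
        idx = frame.index

        if (idx + 1) % indicator_frames() == 0:
            top = rankings[-1][:5] if rankings else roiset.cell_ids[:5]
            events.append(
                t, "traces",
                {"frame": idx,
                 "cells": top,
                 "dff": [None if not np.isfinite(dff[cell_pos[c]]) else round(float(dff[cell_pos[c]]), 6)
                         for c in top]},
            )

        # 1 Hz network / ranking update
        if (idx + 1) % max(1, int(round(cfg.network_period_s * frame_rate))) == 0:
            _network_update(t, idx)

        # 30 s synchrony update
        if (idx + 1) % max(1, int(round(cfg.synchrony_period_s * frame_rate))) == 0:
            _synchrony_update(t, idx)

        # tuning: fold in every newly completed trial
        if rfs is not None:
            _tuning_update(t, idx)

        # stimulation trigger
        if cfg.trigger_mode == "manual" and out_dir is not None:
            req_path = out_dir / "control" / "stim_request.json"
            if req_path.exists():
                req = json.loads(req_path.read_text())
                req_path.unlink()
                targets = [
                    holography.TargetSpec(c, (roiset.centers[c].x, roiset.centers[c].y))
                    for c in req.get("cell_ids", []) if c in cell_pos
                ]
                if targets:
                    holography.stimulate(
                        events, targets, t,
                        duration_ms=req.get("duration_ms", cfg.stim_duration_ms),
                        period_s=req.get("period_s", cfg.stim_period_s),
                    )
        if cfg.trigger_mode == "watch" and cfg.watch_cells:
            vals = [dff[cell_pos[c]] for c in cfg.watch_cells if c in cell_pos]
            vals = [v for v in vals if np.isfinite(v)]
            if vals and np.mean(vals) > cfg.watch_dff_threshold:
                if t - last_stim_time >= cfg.refractory_s:
                    last_stim_time = t
                    targets = [
                        holography.TargetSpec(c, (roiset.centers[c].x, roiset.centers[c].y))
                        for c in cfg.watch_cells if c in cell_pos
                    ]
                    holography.stimulate(
                        events, targets, t,
                        duration_ms=cfg.stim_duration_ms, period_s=cfg.stim_period_s,
                    )

    def _window_start(idx: int) -> int:
        if cfg.analysis_window_s is None:
            return 0
        return max(0, idx + 1 - int(round(cfg.analysis_window_s * frame_rate)))

    def _network_update(t: float, idx: int) -> None:
        nonlocal last_stim_time
        start = _window_start(idx)
        try:
            corr = network.pairwise_correlations(
                store.dff[start : idx + 1],
                cell_ids=roiset.cell_ids,
                min_samples=cfg.min_corr_samples,
                window=(start, idx + 1),
            )
        except network.WindowTooShortError as exc:
            events.append(t, "warning", {"stage": "network", "message": str(exc)})
            return
        try:
            if cfg.network_method == "mst":
                graph = network.mst_network(corr)
            else:
                graph = network.threshold_network(corr, cfg.theta)
            ranking = network.rank_by_degree(graph)
            rankings.append(ranking)
            events.append(
                t, "network",
                {"frame": idx, "method": graph.method, "n_edges": graph.n_edges,
                 "window": list(corr.window)},
            )
            events.append(
                t, "ranking",
                {"frame": idx, "method": graph.method, "ranking": ranking,
                 "degrees": {str(c): graph.degree[c] for c in graph.cell_ids},
                 "top5": select_auto_cells(ranking)},
            )
            if cfg.trigger_mode == "top5" and t - last_stim_time >= cfg.stim_period_s:
                last_stim_time = t
                targets = [
                    holography.TargetSpec(c, (roiset.centers[c].x, roiset.centers[c].y))
                    for c in select_auto_cells(ranking)
                ]
                holography.stimulate(
                    events, targets, t,
                    duration_ms=cfg.stim_duration_ms, period_s=cfg.stim_period_s,
                )
        except Exception as exc:  # per-stage isolation
            log.exception("network update failed at frame %d", idx)
            events.append(t, "warning", {"stage": "network", "message": str(exc)})

    def _synchrony_update(t: float, idx: int) -> None:
        try:
            dff = store.dff[: idx + 1]
            spikes = synchrony.spike_matrix_from_dff(
                dff, roiset.cell_ids, frame_rate, cfg.decay_s
            )
            report = synchrony.synchrony_report(
                spikes, t, (0, idx + 1),
                n_surrogates=cfg.n_surrogates,
                seed=synchrony_rng,
                alpha=cfg.synchrony_alpha,
            )
            events.append(
                t, "synchrony",
                {"frame": idx,
                 "orders": {
                     str(k): {"observed": r.observed,
                              "surrogate_mean": round(r.surrogate_mean, 3),
                              "z": round(r.z, 3), "verdict": r.verdict}
                     for k, r in report.orders.items()}},
            )
        except Exception as exc:
            log.exception("synchrony update failed at frame %d", idx)
            events.append(t, "warning", {"stage": "synchrony", "message": str(exc)})

    def _tuning_update(t: float, idx: int) -> None:
        nonlocal trial_cursor
        while trial_cursor < len(trial_windows):
            ev, frames = trial_windows[trial_cursor]
            if frames[-1] > idx:  # window not fully acquired yet
                break
            dff = store.dff
            for cid, rf in rfs.items():
                tuning.update_receptive_field(rf, dff[:, cell_pos[cid]], ev, frames)
            events.append(
                t, "rf_update",
                {"frame": idx, "onset_s": ev.onset_s,
                 "frequency_hz": ev.frequency_hz, "level_db": ev.level_db},
            )
            trial_cursor += 1

    # ---- main loop -------------------------------------------------------
    stream = stream_io.open_stream(cfg.stream)
    for frame in stream:
        if template is None:
            template_buf.append(frame)
            pending_frames.append(frame)
            if len(template_buf) >= cfg.template_frames:
                template = build_template(template_buf)
                for f in pending_frames:
                    process_frame(f)
                pending_frames.clear()
                template_buf.clear()
            continue
        process_frame(frame)

    if template is None and pending_frames:
        # short session: build the template from whatever arrived
        template = build_template(template_buf)
        for f in pending_frames:
            process_frame(f)
        pending_frames.clear()

    if out_dir is not None:
        store.to_csv(out_dir / "traces.csv")
        store.to_hdf5(out_dir / "traces.h5")
        if rfs is not None:
            rf_summary = []
            for cid, rf in rfs.items():
                rf.to_dataframe().to_csv(out_dir / f"rf_cell_{cid}.csv")
                bf = tuning.best_frequency(rf)
                rf_summary.append(
                    {"cell_id": cid, "best_frequency_hz": bf,
                     "n_trials_total": int(rf.n_trials.sum())}
                )
            with open(out_dir / "best_frequencies.json", "w") as fh:
                json.dump(rf_summary, fh)
    events.close()
    return PipelineResult(
        store=store, roiset=roiset, events=events, rankings=rankings,
        receptive_fields=rfs,
    )
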