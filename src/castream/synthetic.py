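"""Ground-truth synthetic calcium-imaging sessions.

Generates everything the pipeline consumes — a raw/TIF movie with
ring-shaped somata over a diffuse neuropil background, a cell-centers CSV,
a tone schedule, and a ground-truth JSON — from a config and a seed, fully
deterministically.  Spike trains combine a Poisson background, shared
latent events within correlation groups (so the network module has
structure to recover), and tone-locked tuned responses (so the tuning
module has best frequencies to recover); traces are spike trains convolved
with a difference-of-exponentials calcium kernel; the movie adds slow x-y
drift and Gaussian noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tifffile

from castream import registration, tuning
from castream.stream_io import write_raw_movie

__all__ = ["SyntheticConfig", "GroundTruth", "generate_ground_truth", "render_movie", "write_fixture_bundle"]


@dataclass
class SyntheticConfig:
    """Study conditions for a synthetic session (demo scale by default)."""

    height: int = 256
    width: int = 256
    n_cells: int = 60
    frame_rate: float = 30.0
    duration_s: float = 120.0
    # kinetics: GCaMP-like indicator
    kernel_rise_s: float = 0.05
    kernel_decay_s: float = 1.5
    # activity
    background_rate_hz: float = 0.12
    group_cells: tuple[int, ...] = (0, 1, 2, 3, 4)
    group_coupling: float = 0.8
    group_event_rate_hz: float = 1.2
    # weak recruitment of the rest of the population on each latent event
    # (population-wide up-states); this is what makes the driven group the
    # cells "most correlated to the rest of the population"
    global_coupling: float = 0.25
    # imaging
    baseline_intensity: float = 1000.0
    soma_gain: float = 800.0
    neuropil_dilution: float = 0.3
    noise_sd_frac: float = 0.02  # Gaussian noise sd as fraction of baseline
    drift_max_px: float = 0.0
    # ROI geometry used for rendering (matches the default extraction rings)
    r_inner: float = 2.0
    r_outer: float = 6.0
    min_center_spacing_px: float = 22.0
    # tuning
    tuning_enabled: bool = False
    tone_f_start_hz: float = 4000.0
    tone_n_steps: int = 8
    tone_levels_db: tuple[float, ...] = (50.0, 60.0, 70.0)
    tone_n_repeats: int = 10
    tone_response_prob_max: float = 0.9
    tuning_width_octaves: float = 0.5
    tuned_cells: tuple[int, ...] = ()  # empty + tuning_enabled -> all cells

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate))


@dataclass
class GroundTruth:
    config: SyntheticConfig
    seed: int
    centers: np.ndarray  # (n_cells, 2) as (x, y)
    spikes: np.ndarray  # (frames, cells) int8
    best_frequency_hz: np.ndarray  # NaN for untuned cells
    drift: np.ndarray  # (frames, 2) as (dy, dx)
    schedule: tuning.StimulusSchedule | None = None

    def to_json(self, path) -> None:
        payload = {
            "config": asdict(self.config),
            "seed": self.seed,
            "centers": self.centers.tolist(),
            "spike_frames": [
                np.flatnonzero(self.spikes[:, j]).tolist()
                for j in range(self.spikes.shape[1])
            ],
            "best_frequency_hz": [
                None if not np.isfinite(b) else b for b in self.best_frequency_hz
            ],
            "drift": self.drift.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _place_centers(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample cell centers with a minimum spacing, away from edges."""
    margin = cfg.r_outer + 12.0
    centers: list[tuple[float, float]] = []
    for _ in range(200000):
        if len(centers) == cfg.n_cells:
            break
        x = rng.uniform(margin, cfg.width - margin)
        y = rng.uniform(margin, cfg.height - margin)
        if all(np.hypot(x - cx, y - cy) >= cfg.min_center_spacing_px for cx, cy in centers):
            centers.append((x, y))
    if len(centers) < cfg.n_cells:
        raise ValueError("could not place all cells; lower n_cells or spacing")
    return np.asarray(centers)


def _tone_schedule(cfg: SyntheticConfig, rng: np.random.Generator) -> tuning.StimulusSchedule:
    freqs = tuning.half_octave_ladder(cfg.tone_f_start_hz, cfg.tone_n_steps)
    return tuning.build_tone_schedule(
        list(freqs),
        levels_db=cfg.tone_levels_db,
        n_repeats=cfg.tone_n_repeats,
        seed=int(rng.integers(2**31)),
    )


def generate_ground_truth(config: SyntheticConfig, seed: int) -> GroundTruth:
    """Sample centers, spike trains, tuning, and drift for one session.

    Spikes are the union of (a) an independent Poisson background,
    (b) shared latent events: each correlation-group event recruits each
    group member with probability ``group_coupling``, and (c) for tuned
    cells, tone-locked responses whose probability falls off as a Gaussian
    in log2 frequency distance from the cell's best frequency and scales
    with sound level.
    """
    cfg = config
    rng = np.random.default_rng(seed)
    centers = _place_centers(cfg, rng)
    T, n = cfg.n_frames, cfg.n_cells
    dt = 1.0 / cfg.frame_rate

    spikes = (rng.random((T, n)) < cfg.background_rate_hz * dt).astype(np.int8)

    # shared latent drive: group members recruited strongly, the rest of
    # the population weakly, on each latent event
    group = [c for c in cfg.group_cells if c < n]
    if group and cfg.group_event_rate_hz > 0:
        in_group = np.zeros(n, dtype=bool)
        in_group[group] = True
        p_recruit = np.where(in_group, cfg.group_coupling, cfg.global_coupling)
        events = np.flatnonzero(rng.random(T) < cfg.group_event_rate_hz * dt)
        for t in events:
            recruited = rng.random(n) < p_recruit
            spikes[t, recruited] = 1

    best_f = np.full(n, np.nan)
    schedule = None
    if cfg.tuning_enabled:
        schedule = _tone_schedule(cfg, rng)
        freqs = np.asarray(schedule.frequencies_hz)
        levels = np.asarray(schedule.levels_db)
        tuned = list(cfg.tuned_cells) if cfg.tuned_cells else list(range(n))
        best_f[tuned] = rng.choice(freqs, size=len(tuned))
        level_gain = {
            lv: 0.6 + 0.4 * i / max(1, len(levels) - 1) for i, lv in enumerate(levels)
        }
        for ev in schedule.events:
            onset = int(round(ev.onset_s * cfg.frame_rate))
            if onset >= T:
                continue
            for j in tuned:
                d_oct = np.log2(ev.frequency_hz / best_f[j])
                p = (
                    cfg.tone_response_prob_max
                    * np.exp(-0.5 * (d_oct / cfg.tuning_width_octaves) ** 2)
                    * level_gain[ev.level_db]
                )
                if rng.random() < p:
                    # response onset jitter of 0-2 frames
                    t = min(T - 1, onset + rng.integers(0, 3))
                    spikes[t, j] = 1

    if cfg.drift_max_px > 0:
        # slow smooth drift: low-frequency random walk scaled to max amplitude
        walk = np.cumsum(rng.normal(size=(T, 2)), axis=0)
        walk -= walk[0]
        scale = np.abs(walk).max()
        drift = walk / scale * cfg.drift_max_px if scale > 0 else walk
    else:
        drift = np.zeros((T, 2))

    return GroundTruth(
        config=cfg,
        seed=seed,
        centers=centers,
        spikes=spikes,
        best_frequency_hz=best_f,
        drift=drift,
        schedule=schedule,
    )


def calcium_kernel(cfg: SyntheticConfig) -> np.ndarray:
    """Difference-of-exponentials kernel, unit peak, truncated at 5 decay taus."""
    t = np.arange(0, 5.0 * cfg.kernel_decay_s, 1.0 / cfg.frame_rate)
    k = np.exp(-t / cfg.kernel_decay_s) - np.exp(-t / cfg.kernel_rise_s)
    return k / k.max()


def ground_truth_traces(gt: GroundTruth) -> np.ndarray:
    """(frames, cells) noiseless activity traces: spikes (*) calcium kernel."""
    k = calcium_kernel(gt.config)
    T, n = gt.spikes.shape
    out = np.empty((T, n))
    for j in range(n):
        out[:, j] = np.convolve(gt.spikes[:, j].astype(np.float64), k)[:T]
    return out


def render_movie(
    gt: GroundTruth,
    out_path: str | Path | None = None,
    fmt: str = "raw_u16",
) -> np.ndarray:
    """Render the session to a (T, H, W) uint16 movie (and optionally disk).

    Somata are bright rings modulated by (1 + trace); the neuropil is a
    smooth background carrying a diluted mixture of all traces; per-frame
    drift translates the scene; Gaussian noise is added and the result is
    clipped to the unsigned 16-bit range.
    """
    cfg = gt.config
    rng = np.random.default_rng(gt.seed + 1)  # noise stream, distinct from GT
    traces = ground_truth_traces(gt)
    T = cfg.n_frames
    h, w = cfg.height, cfg.width
    yy, xx = np.mgrid[0:h, 0:w]

    soma_idx = []
    soma_static = np.zeros(h * w)
    for cx, cy in gt.centers:
        r = np.hypot(yy - cy, xx - cx)
        idx = np.flatnonzero((r >= cfg.r_inner) & (r <= cfg.r_outer))
        soma_idx.append(idx)
        soma_static[idx] += cfg.soma_gain * 0.5

    # smooth neuropil field: sum of broad Gaussian aprons around the cells
    apron = np.zeros((h, w))
    for cx, cy in gt.centers:
        r2 = (yy - cy) ** 2 + (xx - cx) ** 2
        apron += np.exp(-r2 / (2 * 30.0**2))
    apron = apron / apron.max()
    npil_base = (cfg.baseline_intensity * (0.5 + 0.5 * apron)).ravel()

    base = cfg.baseline_intensity
    movie = np.empty((T, h, w), dtype=np.uint16)
    mixture = traces.mean(axis=1)  # diluted mixture of all traces
    for t in range(T):
        frame = npil_base * (1.0 + cfg.neuropil_dilution * mixture[t]) + soma_static
        for j, idx in enumerate(soma_idx):
            frame[idx] += cfg.soma_gain * traces[t, j]
        frame = frame.reshape(h, w)
        dy, dx = gt.drift[t]
        if dy != 0.0 or dx != 0.0:
            frame = registration.translate(frame, dy, dx, fill=float(np.median(frame)))
        frame = frame + rng.normal(0.0, cfg.noise_sd_frac * base, size=(h, w))
        movie[t] = np.clip(frame, 0, 65535).astype(np.uint16)

    if out_path is not None:
        if fmt == "raw_u16":
            write_raw_movie(out_path, movie)
        elif fmt == "tif":
            tifffile.imwrite(out_path, movie)
        else:
            raise ValueError(f"unknown movie format {fmt!r}")
    return movie


def write_fixture_bundle(
    config: SyntheticConfig, seed: int, out_dir: str | Path, fmt: str = "raw_u16"
) -> dict[str, Path]:
    """Write movie + centers CSV + stimulus CSV + ground-truth JSON.

    The canonical self-contained demo session: every file is in a format
    the pipeline consumes directly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gt = generate_ground_truth(config, seed)
    ext = "raw" if fmt == "raw_u16" else "tif"
    paths = {
        "movie": out_dir / f"movie.{ext}",
        "centers": out_dir / "centers.csv",
        "ground_truth": out_dir / "ground_truth.json",
    }
    render_movie(gt, paths["movie"], fmt=fmt)
    with open(paths["centers"], "w") as fh:
        fh.write("cell_id,x,y\n")
        for j, (x, y) in enumerate(gt.centers):
            fh.write(f"{j},{x:.2f},{y:.2f}\n")
    gt.to_json(paths["ground_truth"])
    if gt.schedule is not None:
        paths["schedule"] = out_dir / "schedule.csv"
        gt.schedule.to_csv(paths["schedule"])
    return paths
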