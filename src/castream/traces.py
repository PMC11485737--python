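"""Fluorescence extraction, neuropil correction, baselining, dF/F0.

Per frame and cell: F_soma and F_NP are mask-pixel means; the corrected
fluorescence is F = F_soma - alpha * F_NP (alpha default 0.7); the baseline
F0 is the mean of samples strictly below the 50th percentile within the
trailing window (default 10 s) of the corrected series; dF/F0 = (F-F0)/F0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from castream.rois import ROISet
from castream.stream_io import Frame

__all__ = [
    "TraceStore",
    "extract_fluorescence",
    "neuropil_correct",
    "update_baseline",
    "compute_dff",
]

DEFAULT_ALPHA = 0.7
DEFAULT_WINDOW_S = 10.0


def extract_fluorescence(
    frame: Frame | np.ndarray, roiset: ROISet
) -> tuple[np.ndarray, np.ndarray]:
    """Mean soma and neuropil intensity per cell, NaN for empty masks."""
    pixels = frame.pixels if isinstance(frame, Frame) else np.asarray(frame)
    flat = pixels.ravel().astype(np.float64)
    n = roiset.n_cells
    f_soma = np.full(n, np.nan)
    f_np = np.full(n, np.nan)
    for i, cid in enumerate(roiset.cell_ids):
        soma = roiset.soma[cid]
        if soma.size:
            f_soma[i] = flat[soma].mean()
        npil = roiset.neuropil.get(cid)
        if npil is not None and npil.size:
            f_np[i] = flat[npil].mean()
    return f_soma, f_np


def neuropil_correct(f_soma, f_np, alpha: float = DEFAULT_ALPHA):
    """F = F_soma - alpha * F_NP, elementwise; alpha in [0, 1]."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    return f_soma - alpha * np.asarray(f_np)


def update_baseline(
    f_history: np.ndarray,
    now_index: int,
    window_s: float = DEFAULT_WINDOW_S,
    frame_rate: float = 30.0,
) -> float:
    """Sliding-window baseline at one time point of one cell's F series.

    The window is the trailing ``window_s`` seconds ending at (and
    including) ``now_index``; early in a session all available samples are
    used.  F0 is the mean of window samples strictly below the window's
    50th percentile; if no sample is strictly below it (constant window),
    F0 falls back to the window median.  NaN samples (failed registration,
    empty masks) are ignored.
    """
    f_history = np.asarray(f_history, dtype=np.float64)
    n_window = max(1, int(round(window_s * frame_rate)))
    start = max(0, now_index + 1 - n_window)
    window = f_history[start : now_index + 1]
    window = window[np.isfinite(window)]
    if window.size == 0:
        return np.nan
    med = np.percentile(window, 50)
    below = window[window < med]
    if below.size == 0:
        return float(med)
    return float(below.mean())


def _baseline_vector(
    f_matrix: np.ndarray, now_index: int, window_s: float, frame_rate: float
) -> np.ndarray:
    """update_baseline for all cells at once; f_matrix is (frames, cells)."""
    n_window = max(1, int(round(window_s * frame_rate)))
    start = max(0, now_index + 1 - n_window)
    window = f_matrix[start : now_index + 1]
    out = np.empty(window.shape[1])
    med = np.nanpercentile(window, 50, axis=0)
    for j in range(window.shape[1]):
        col = window[:, j]
        col = col[np.isfinite(col)]
        if col.size == 0:
            out[j] = np.nan
            continue
        below = col[col < med[j]]
        out[j] = below.mean() if below.size else med[j]
    return out


def compute_dff(f, f0):
    """(F - F0) / F0; non-positive or missing baselines give NaN."""
    f = np.asarray(f, dtype=np.float64)
    f0 = np.asarray(f0, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        dff = (f - f0) / f0
    return np.where(np.isfinite(dff) & (f0 > 0), dff, np.nan)


@dataclass
class TraceStore:
    """Append-only per-cell fluorescence series for a session.

    Rows are frames, columns are cells (ordered as ``cell_ids``).
    """

    cell_ids: list[int]
    frame_rate: float = 30.0
    alpha: float = DEFAULT_ALPHA
    window_s: float = DEFAULT_WINDOW_S
    _f_soma: list[np.ndarray] = field(default_factory=list, repr=False)
    _f_np: list[np.ndarray] = field(default_factory=list, repr=False)
    _f: list[np.ndarray] = field(default_factory=list, repr=False)
    _f0: list[np.ndarray] = field(default_factory=list, repr=False)
    _dff: list[np.ndarray] = field(default_factory=list, repr=False)

    @property
    def n_frames(self) -> int:
        return len(self._f)

    def append_frame(self, f_soma: np.ndarray, f_np: np.ndarray) -> np.ndarray:
        """Ingest one frame's raw means; returns the frame's dF/F0 vector.

        The first frame bootstraps F0 := F (dF/F0 = 0): real-time operation
        cannot wait for a full baseline window.
        """
        f = neuropil_correct(f_soma, f_np, self.alpha)
        self._f_soma.append(np.asarray(f_soma, dtype=np.float64))
        self._f_np.append(np.asarray(f_np, dtype=np.float64))
        self._f.append(np.asarray(f, dtype=np.float64))
        now = len(self._f) - 1
        if now == 0:
            f0 = np.asarray(f, dtype=np.float64).copy()
        else:
            # materialize only the trailing window, not the whole session
            n_window = max(1, int(round(self.window_s * self.frame_rate)))
            start = max(0, now + 1 - n_window)
            window = np.asarray(self._f[start : now + 1])
            f0 = _baseline_vector(window, window.shape[0] - 1, self.window_s, self.frame_rate)
        self._f0.append(f0)
        dff = compute_dff(f, f0)
        self._dff.append(dff)
        return dff

    @property
    def f_soma(self) -> np.ndarray:
        return np.asarray(self._f_soma)

    @property
    def f_np(self) -> np.ndarray:
        return np.asarray(self._f_np)

    @property
    def f(self) -> np.ndarray:
        return np.asarray(self._f)

    @property
    def f0(self) -> np.ndarray:
        return np.asarray(self._f0)

    @property
    def dff(self) -> np.ndarray:
        return np.asarray(self._dff)

    def dff_window(self, start_frame: int, end_frame: int) -> np.ndarray:
        """dF/F0 rows for frames [start_frame, end_frame)."""
        return self.dff[start_frame:end_frame]

    def to_csv(self, path) -> None:
        """Wide CSV: frame, time_s, then one dF/F0 column per cell."""
        dff = self.dff
        idx = np.arange(dff.shape[0])
        df = pd.DataFrame(dff, columns=[f"cell_{c}" for c in self.cell_ids])
        df.insert(0, "time_s", idx / self.frame_rate)
        df.insert(0, "frame", idx)
        df.to_csv(path, index=False)

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as fh:
            fh.attrs["frame_rate"] = self.frame_rate
            fh.attrs["alpha"] = self.alpha
            fh.attrs["window_s"] = self.window_s
            fh.create_dataset("cell_ids", data=np.asarray(self.cell_ids))
            for name in ("f_soma", "f_np", "f", "f0", "dff"):
                fh.create_dataset(name, data=getattr(self, name))
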