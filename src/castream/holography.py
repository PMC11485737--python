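"""Gerchberg-Saxton hologram computation for multi-spot photostimulation.

A phase-only spatial light modulator (SLM) in the Fourier plane of the
objective shapes the stimulation laser into beamlets focused on selected
cells.  The SLM and focal planes are related by a single-lens far-field
(discrete Fourier) transform; given a desired focal amplitude pattern —
superposed disk or optical-vortex beamlets centered on the targets — the
Gerchberg-Saxton algorithm iterates between the two planes, imposing unit
amplitude on the SLM side and the target amplitude on the focal side,
until the phase mask reproduces the pattern.

All of this runs against a *virtual* SLM: masks and simulated focal
intensities are computed and written to disk; no hardware I/O occurs.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "TargetSpec",
    "PhaseMask",
    "IntensityPattern",
    "CalibrationMap",
    "build_target_field",
    "gs_phase_mask",
    "simulate_intensity",
    "target_efficiency",
    "sequence_masks",
    "stimulate",
    "save_phase_mask",
]

DEFAULT_SLM_SHAPE = (512, 512)  # desk-scale; hardware-scale 1536x1536 via config
FULL_SLM_SHAPE = (1536, 1536)
DEFAULT_GS_ITERATIONS = 30
DEFAULT_VORTEX_RING_R0 = 3.0  # ring radius = r0 * sqrt(|L|), px


@dataclass(frozen=True)
class TargetSpec:
    """One photostimulation target in imaging-FOV pixel coordinates."""

    cell_id: int
    fov_xy: tuple[float, float]  # (x, y)
    shape: str = "disk"  # "disk" | "vortex"
    disk_radius_px: float = 3.0
    vortex_mode: int = 5  # L; sign sets handedness

    def __post_init__(self) -> None:
        if self.shape not in ("disk", "vortex"):
            raise ValueError(f"unknown beamlet shape {self.shape!r}")
        if self.shape == "vortex" and self.vortex_mode == 0:
            raise ValueError("vortex mode L must be nonzero")


@dataclass(frozen=True)
class PhaseMask:
    """Phase pattern on the (virtual) SLM plane, values in [0, 2*pi)."""

    phase: np.ndarray

    def __post_init__(self) -> None:
        if self.phase.ndim != 2:
            raise ValueError("phase mask must be 2-D")

    @property
    def slm_shape(self) -> tuple[int, int]:
        return self.phase.shape


@dataclass(frozen=True)
class IntensityPattern:
    """Simulated focal-plane intensity, normalized to total 1."""

    intensity: np.ndarray


@dataclass(frozen=True)
class CalibrationMap:
    """Affine map from imaging-FOV pixels to focal-grid coordinates."""

    matrix: np.ndarray = field(default_factory=lambda: np.eye(2))
    offset: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("calibration matrix must be invertible")

    def apply(self, xy: tuple[float, float]) -> tuple[float, float]:
        out = self.matrix @ np.asarray(xy, dtype=np.float64) + self.offset
        return float(out[0]), float(out[1])

    @classmethod
    def from_correspondences(cls, fov_pts: np.ndarray, slm_pts: np.ndarray) -> "CalibrationMap":
        """Least-squares affine fit from >= 3 (FOV, focal) point pairs."""
        fov_pts = np.asarray(fov_pts, dtype=np.float64)
        slm_pts = np.asarray(slm_pts, dtype=np.float64)
        if fov_pts.shape[0] < 3:
            raise ValueError("need at least 3 correspondence pairs")
        A = np.hstack([fov_pts, np.ones((fov_pts.shape[0], 1))])
        coef, *_ = np.linalg.lstsq(A, slm_pts, rcond=None)
        return cls(matrix=coef[:2].T.copy(), offset=coef[2].copy())

    @classmethod
    def from_csv(cls, path) -> "CalibrationMap":
        pts = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls.from_correspondences(pts[:, :2], pts[:, 2:4])


def _fft2c(field: np.ndarray) -> np.ndarray:
    """Centered unitary 2-D DFT (SLM plane -> focal plane)."""
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(field), norm="ortho"))


def _ifft2c(field: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(field), norm="ortho"))


def build_target_field(
    targets: list[TargetSpec],
    calib: CalibrationMap | None = None,
    grid_shape: tuple[int, int] = DEFAULT_SLM_SHAPE,
    vortex_ring_r0: float = DEFAULT_VORTEX_RING_R0,
) -> np.ndarray:
    """Superpose beamlet templates into a complex focal-plane amplitude.

    Disk targets contribute a uniform-amplitude disk of ``disk_radius_px``;
    vortex targets contribute a thin ring of radius r0*sqrt(|L|) carrying
    spiral phase exp(i*L*theta) about the target center (the central phase
    singularity forces an on-axis intensity null).
    """
    if not targets:
        raise ValueError("need at least one target")
    calib = calib or CalibrationMap()
    h, w = grid_shape
    yy, xx = np.mgrid[0:h, 0:w]
    out = np.zeros(grid_shape, dtype=np.complex128)
    for t in targets:
        cx, cy = calib.apply(t.fov_xy)
        if not (0 <= cx < w and 0 <= cy < h):
            raise ValueError(
                f"cell {t.cell_id} maps to ({cx:.1f}, {cy:.1f}), outside the "
                f"{h}x{w} grid"
            )
        dy, dx = yy - cy, xx - cx
        r = np.hypot(dy, dx)
        if t.shape == "disk":
            out[r <= t.disk_radius_px] += 1.0
        else:
            ring_r = vortex_ring_r0 * np.sqrt(abs(t.vortex_mode))
            ring = (r >= ring_r - 1.0) & (r <= ring_r + 1.0)
            theta = np.arctan2(dy, dx)
            out[ring] += np.exp(1j * t.vortex_mode * theta[ring])
    if not np.any(out):
        raise ValueError("target field is empty (zero-radius templates off-grid?)")
    return out


def gs_phase_mask(
    target_field: np.ndarray,
    n_iterations: int = DEFAULT_GS_ITERATIONS,
    seed: int = 0,
) -> tuple[PhaseMask, list[float]]:
    """Gerchberg-Saxton phase retrieval for a desired focal amplitude.

    Initialization is the random-superposition scheme: a seeded random
    diffuser phase is applied to the target amplitude in the focal plane
    and back-propagated, so the starting field already concentrates energy
    on the targets (a fully random SLM phase leaves speckle lobes next to
    point targets that the projections cannot remove).  Each iteration then
    imposes unit amplitude on the SLM plane and the target amplitude on the
    focal plane, keeping the phases.  Returns the final SLM phase and the
    per-iteration focal-amplitude error (root-mean-square difference
    between achieved and target amplitude, both unit-normalized), which is
    non-increasing in practice.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    target_field = np.asarray(target_field, dtype=np.complex128)
    target_amp = np.abs(target_field)
    if not target_amp.any():
        raise ValueError("all-zero target field")
    target_amp = target_amp / np.linalg.norm(target_amp)
    rng = np.random.default_rng(seed)
    diffuser = rng.uniform(0.0, 2.0 * np.pi, size=target_amp.shape)
    init = _ifft2c(target_amp * np.exp(1j * (np.angle(target_field) + diffuser)))
    phase = np.mod(np.angle(init), 2.0 * np.pi)
    errors: list[float] = []
    for _ in range(n_iterations):
        focal = _fft2c(np.exp(1j * phase))
        achieved = np.abs(focal)
        achieved = achieved / np.linalg.norm(achieved)
        errors.append(float(np.linalg.norm(achieved - target_amp)))
        slm = _ifft2c(target_amp * np.exp(1j * np.angle(focal)))
        phase = np.mod(np.angle(slm), 2.0 * np.pi)
    return PhaseMask(phase=phase), errors


def simulate_intensity(mask: PhaseMask) -> IntensityPattern:
    """Focal intensity |DFT of unit-amplitude field with given phase|^2.

    The unitary transform conserves energy exactly; the returned pattern is
    normalized to total 1.
    """
    focal = _fft2c(np.exp(1j * mask.phase))
    intensity = np.abs(focal) ** 2
    return IntensityPattern(intensity=intensity / intensity.sum())


def target_efficiency(
    pattern: IntensityPattern,
    targets: list[TargetSpec],
    capture_radius_px: float = 5.0,
    calib: CalibrationMap | None = None,
) -> float:
    """Fraction of total focal intensity landing within the capture disks."""
    calib = calib or CalibrationMap()
    h, w = pattern.intensity.shape
    yy, xx = np.mgrid[0:h, 0:w]
    captured = np.zeros((h, w), dtype=bool)
    for t in targets:
        cx, cy = calib.apply(t.fov_xy)
        if not (0 <= cx < w and 0 <= cy < h):
            raise ValueError(f"cell {t.cell_id} maps outside the grid")
        captured |= np.hypot(yy - cy, xx - cx) <= capture_radius_px
    return float(pattern.intensity[captured].sum())


def sequence_masks(
    targets: list[TargetSpec],
    rate_hz: float,
    grid_shape: tuple[int, int] = DEFAULT_SLM_SHAPE,
    calib: CalibrationMap | None = None,
    n_iterations: int = DEFAULT_GS_ITERATIONS,
    seed: int = 0,
) -> list[tuple[PhaseMask, float]]:
    """Precompute one mask per target for sequential stimulation.

    All masks are computed up front ("predownloaded"); during stimulation
    the virtual SLM driver would cycle through them at ``rate_hz``, so each
    mask dwells 1/rate_hz seconds.  Same targets and seed give bit-identical
    masks.
    """
    if rate_hz <= 0:
        raise ValueError("rate_hz must be positive")
    dwell = 1.0 / rate_hz
    out = []
    for t in targets:
        field_ = build_target_field([t], calib=calib, grid_shape=grid_shape)
        mask, _ = gs_phase_mask(field_, n_iterations=n_iterations, seed=seed)
        out.append((mask, dwell))
    return out


def save_phase_mask(mask: PhaseMask, png_path, npy_path=None) -> None:
    """Write the mask as 8-bit grayscale ([0, 2*pi) -> [0, 255]) plus raw floats."""
    import imageio.v3 as iio

    quantized = np.round(mask.phase / (2.0 * np.pi) * 255.0).astype(np.uint8)
    iio.imwrite(png_path, quantized)
    if npy_path is not None:
        np.save(npy_path, mask.phase)


def stimulate(
    event_log,
    targets: list[TargetSpec],
    time_s: float,
    duration_ms: float = 30.0,
    period_s: float = 3.0,
    mask_refs: list[str] | None = None,
    power_mw_per_cell: float | None = None,
) -> dict:
    """Record a (virtual) stimulation event; no hardware I/O is performed.

    Default timing mirrors a typical optogenetics protocol: a 30 ms pulse
    every 3 s.  Laser-power values are metadata echoed in the record, never
    used in any computation.
    """
    record = {
        "time_s": float(time_s),
        "kind": "stimulation",
        "payload": {
            "cell_ids": [t.cell_id for t in targets],
            "shape": targets[0].shape if targets else None,
            "params": [
                {"L": t.vortex_mode} if t.shape == "vortex" else {"radius_px": t.disk_radius_px}
                for t in targets
            ],
            "duration_ms": float(duration_ms),
            "period_s": float(period_s),
            "mask_refs": mask_refs or [],
            "power_mw_per_cell": power_mw_per_cell,
        },
    }
    if event_log is not None:
        event_log.append(record["time_s"], "stimulation", record["payload"])
    return record
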