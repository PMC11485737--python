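"""Rigid x-y drift correction by subpixel DFT cross-correlation.

Each incoming frame is registered against a fixed template (the pixelwise
mean of a short initial batch) using the single-step upsampled-DFT
cross-correlation method; the estimated drift is undone with a Fourier
phase-shift translation.

Sign convention: `estimate_shift` returns the drift of the frame *relative
to* the template — a frame whose content moved down by ``dy`` rows and
right by ``dx`` columns yields ``Shift(dy, dx)``.  `apply_shift` translates
by ``-(dy, dx)``, undoing the drift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import fourier_shift
from skimage.registration import phase_cross_correlation

from castream.stream_io import Frame

__all__ = ["Template", "Shift", "build_template", "estimate_shift", "apply_shift", "translate"]

DEFAULT_MAX_SHIFT = 20.0
DEFAULT_UPSAMPLE = 10


@dataclass(frozen=True)
class Template:
    pixels: np.ndarray  # float mean image, (H, W)
    n_frames_averaged: int


@dataclass(frozen=True)
class Shift:
    dy: float
    dx: float
    registration_error: float = 0.0
    degenerate: bool = False
    clamped: bool = False


def build_template(frames: list[Frame]) -> Template:
    """Pixelwise arithmetic mean of an initial batch of frames."""
    if not frames:
        raise ValueError("cannot build a template from zero frames")
    shape = frames[0].pixels.shape
    acc = np.zeros(shape, dtype=np.float64)
    for f in frames:
        if f.pixels.shape != shape:
            raise ValueError("all template frames must share one shape")
        acc += f.pixels
    return Template(pixels=acc / len(frames), n_frames_averaged=len(frames))


def estimate_shift(
    frame: Frame | np.ndarray,
    template: Template,
    upsample: int = DEFAULT_UPSAMPLE,
    max_shift: float = DEFAULT_MAX_SHIFT,
) -> Shift:
    """Estimate the frame's drift relative to the template.

    Returns the (dy, dx) maximizing the upsampled cross-correlation, to
    1/upsample pixel precision.  A flat (zero-variance) frame cannot be
    registered: the shift is zero and flagged degenerate.  Estimates larger
    than ``max_shift`` are clamped and flagged so a failed registration
    cannot corrupt downstream traces.
    """
    pixels = frame.pixels if isinstance(frame, Frame) else np.asarray(frame)
    if pixels.shape != template.pixels.shape:
        raise ValueError("frame and template shapes differ")
    if upsample < 1:
        raise ValueError("upsample must be >= 1")
    if np.ptp(pixels) == 0 or np.ptp(template.pixels) == 0:
        return Shift(0.0, 0.0, registration_error=1.0, degenerate=True)
    # phase_cross_correlation returns the shift to apply to `moving` to
    # align it with `reference`; the drift is its negation
    shift, error, _ = phase_cross_correlation(
        template.pixels, pixels.astype(np.float64), upsample_factor=upsample,
        normalization=None,
    )
    dy, dx = -float(shift[0]), -float(shift[1])
    clamped = False
    if abs(dy) > max_shift or abs(dx) > max_shift:
        dy = float(np.clip(dy, -max_shift, max_shift))
        dx = float(np.clip(dx, -max_shift, max_shift))
        clamped = True
    return Shift(dy, dx, registration_error=float(error), clamped=clamped)


def _fourier_translate(pixels: np.ndarray, dy: float, dx: float, fill: float) -> np.ndarray:
    """Translate content by (+dy, +dx) via a Fourier phase ramp.

    The Fourier translation wraps circularly; the wrapped-in border is
    overwritten with ``fill`` so out-of-view pixels stay neutral.
    """
    out = np.fft.ifftn(fourier_shift(np.fft.fftn(pixels.astype(np.float64)), (dy, dx))).real
    iy, ix = int(np.ceil(abs(dy))), int(np.ceil(abs(dx)))
    if iy:
        if dy > 0:
            out[:iy, :] = fill
        else:
            out[-iy:, :] = fill
    if ix:
        if dx > 0:
            out[:, :ix] = fill
        else:
            out[:, -ix:] = fill
    return out


def translate(pixels: np.ndarray, dy: float, dx: float, fill: float | None = None) -> np.ndarray:
    """Shift image content by (+dy, +dx) via a Fourier phase ramp.

    Fixture helper for drift synthesis.  With ``fill=None`` the translation
    is purely spectral (periodic wrap, exactly invertible and compositional);
    passing a fill value overwrites the wrapped-in border, as a real drifting
    field of view would.
    """
    pixels = np.asarray(pixels)
    if fill is None:
        spec = np.fft.fftn(pixels.astype(np.float64))
        # the Nyquist bins' phase is ambiguous under fractional shifts;
        # zeroing them makes the operator exactly compositional
        h, w = pixels.shape
        if h % 2 == 0:
            spec[h // 2, :] = 0.0
        if w % 2 == 0:
            spec[:, w // 2] = 0.0
        return np.fft.ifftn(fourier_shift(spec, (dy, dx))).real
    return _fourier_translate(pixels, dy, dx, fill=fill)


def apply_shift(frame: Frame, shift: Shift) -> Frame:
    """Undo the estimated drift: translate the frame by -(dy, dx).

    Out-of-view pixels are filled with the frame median, which is neutral
    with respect to dF/F0 baselines.  Returns a float-valued frame (clipped
    to the unsigned range) with the same index and time.
    """
    if shift.dy == 0.0 and shift.dx == 0.0:
        return frame
    fill = float(np.median(frame.pixels))
    out = _fourier_translate(frame.pixels, -shift.dy, -shift.dx, fill)
    out = np.clip(out, 0.0, 65535.0)
    return Frame(pixels=out, index=frame.index, time_s=frame.time_s)
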