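"""Frame sources: headerless raw-binary streams and TIF stacks.

A frame stream is either *live* (the acquisition software is appending to a
raw-binary file and we poll for complete frames, never yielding a partially
written one) or a *replay* of a finished file.  Raw binary is headerless,
frame-major, row-major, little-endian 16-bit; two dialects exist in the
wild: unsigned 16-bit and signed 16-bit that must be converted to unsigned.
"""

from __future__ import annotations

import os
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import tifffile
import yaml

__all__ = [
    "Frame",
    "StreamConfig",
    "StreamError",
    "open_stream",
    "convert_signed",
    "read_tif_stack",
    "write_raw_movie",
]

BYTES_PER_PIXEL = 2


class StreamError(RuntimeError):
    """Fatal error on a frame source (unreadable file, bad format)."""


@dataclass(frozen=True)
class Frame:
    """One acquired image with its ordinal and stream time."""

    pixels: np.ndarray  # (H, W) uint16
    index: int
    time_s: float

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2:
            raise ValueError("Frame pixels must be 2-D")


@dataclass
class StreamConfig:
    """Where frames come from and how to interpret the bytes."""

    source_path: str | Path
    dialect: str = "raw_u16"  # raw_u16 | raw_s16 | tif
    height: int = 512
    width: int = 512
    frame_rate: float = 30.0
    poll_interval_s: float = 0.01
    replay: bool = True
    n_frames: int | None = None  # live mode: stop after this many frames
    idle_timeout_s: float = 5.0  # live mode: stop if the file stops growing
    paced: bool = False  # replay mode: sleep to emulate acquisition pace

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("height and width must be positive")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.dialect not in ("raw_u16", "raw_s16", "tif"):
            raise ValueError(f"unknown dialect {self.dialect!r}")

    @property
    def frame_bytes(self) -> int:
        return self.height * self.width * BYTES_PER_PIXEL

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StreamConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def convert_signed(raw: np.ndarray) -> np.ndarray:
    """Map signed 16-bit samples to the unsigned range by clamping at zero.

    PMT offsets below zero carry no signal, so negatives clamp to 0; the
    mapping is monotone and leaves non-negative values untouched.
    """
    return np.clip(raw, 0, None).astype(np.uint16)


def _read_raw_frame(fh, config: StreamConfig, index: int) -> Frame:
    fh.seek(index * config.frame_bytes)
    buf = fh.read(config.frame_bytes)
    dtype = "<i2" if config.dialect == "raw_s16" else "<u2"
    pixels = np.frombuffer(buf, dtype=dtype).reshape(config.height, config.width)
    if config.dialect == "raw_s16":
        pixels = convert_signed(pixels)
    else:
        pixels = np.ascontiguousarray(pixels)
    return Frame(pixels=pixels, index=index, time_s=index / config.frame_rate)


def _raw_stream(config: StreamConfig) -> Iterator[Frame]:
    path = Path(config.source_path)
    if config.replay and not path.exists():
        raise StreamError(f"stream source not found: {path}")
    # live mode: wait for the file to appear
    deadline = time.monotonic() + config.idle_timeout_s
    while not path.exists():
        if config.replay or time.monotonic() > deadline:
            raise StreamError(f"stream source not found: {path}")
        time.sleep(config.poll_interval_s)

    index = 0
    with open(path, "rb") as fh:
        last_growth = time.monotonic()
        last_size = -1
        while True:
            if config.n_frames is not None and index >= config.n_frames:
                return
            size = os.path.getsize(path)
            if size != last_size:
                last_size = size
                last_growth = time.monotonic()
            # frame completeness: all of this frame's bytes are on disk
            if size >= (index + 1) * config.frame_bytes:
                frame = _read_raw_frame(fh, config, index)
                index += 1
                if config.paced and config.replay:
                    time.sleep(1.0 / config.frame_rate)
                yield frame
                continue
            if config.replay:
                return  # truncated final frame: end cleanly before it
            if time.monotonic() - last_growth > config.idle_timeout_s:
                return
            time.sleep(config.poll_interval_s)


def read_tif_stack(path: str | Path, frame_rate: float = 30.0) -> Iterator[Frame]:
    """Yield the pages of a grayscale TIF stack as Frames.

    8-bit input is upcast to uint16 without rescaling; color pages are a
    fatal format error.
    """
    path = Path(path)
    if not path.exists():
        raise StreamError(f"stream source not found: {path}")
    with tifffile.TiffFile(path) as tif:
        for index, page in enumerate(tif.pages):
            pixels = page.asarray()
            if pixels.ndim != 2:
                raise StreamError(
                    f"page {index} of {path} is not single-channel grayscale"
                )
            if pixels.dtype == np.int16:
                pixels = convert_signed(pixels)
            else:
                pixels = pixels.astype(np.uint16)
            yield Frame(pixels=pixels, index=index, time_s=index / frame_rate)


def open_stream(config: StreamConfig) -> Iterator[Frame]:
    """Open the configured source and yield Frames in acquisition order.

    In live mode this blocks/polls until the next complete frame's bytes
    exist on disk; a partially written trailing frame is never yielded.
    """
    if config.dialect == "tif":
        frames = read_tif_stack(config.source_path, config.frame_rate)
        if config.n_frames is None:
            return frames
        import itertools

        return itertools.islice(frames, config.n_frames)
    return _raw_stream(config)


def write_raw_movie(path: str | Path, movie: np.ndarray) -> None:
    """Write an (T, H, W) uint16 movie as headerless little-endian raw binary."""
    movie = np.asarray(movie)
    if movie.dtype != np.uint16:
        raise ValueError("raw movies are written as uint16")
    with open(path, "wb") as fh:
        fh.write(movie.astype("<u2").tobytes())
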