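"""Ring-shaped somatic ROIs and neuropil annuli from cell-center coordinates.

Each selected neuron gets a ring ("donut") of pixels over its soma —
membrane-proximal pixels carry most of the somatic signal — and a wider
neuropil annulus starting one pixel beyond the soma's outer boundary and
extending a fixed physical distance (default 15 um).  Pixels claimed by
two somata are excluded from both; neuropil annuli exclude every cell's
soma pixels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CellCenter",
    "RoiGeometry",
    "ROISet",
    "load_centers",
    "build_soma_masks",
    "resolve_overlaps",
    "build_neuropil_masks",
    "build_roiset",
]

log = logging.getLogger(__name__)

# FOV scale: ~370 um across 512 px
DEFAULT_PIXEL_SIZE_UM = 370.0 / 512.0


@dataclass(frozen=True)
class CellCenter:
    cell_id: int
    x: float  # column, 0-based
    y: float  # row, 0-based


@dataclass(frozen=True)
class RoiGeometry:
    """Ring and annulus parameters, pixels unless noted."""

    r_inner: float = 2.0
    r_outer: float = 6.0
    neuropil_extent_um: float = 15.0
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    @property
    def neuropil_outer_px(self) -> float:
        return self.r_outer + self.neuropil_extent_um / self.pixel_size_um


@dataclass
class ROISet:
    """Per-cell soma and neuropil masks as flat pixel-index arrays."""

    frame_shape: tuple[int, int]
    geometry: RoiGeometry
    cell_ids: list[int]
    centers: dict[int, CellCenter]
    soma: dict[int, np.ndarray] = field(default_factory=dict)
    neuropil: dict[int, np.ndarray] = field(default_factory=dict)
    inactive: set[int] = field(default_factory=set)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def label_image(self) -> np.ndarray:
        """uint16 label image: 0 background, cell_id+1 soma, 32768+cell_id+1 neuropil."""
        img = np.zeros(self.frame_shape, dtype=np.uint16)
        for cid, idx in self.neuropil.items():
            img.flat[idx] = 32768 + cid + 1
        for cid, idx in self.soma.items():
            img.flat[idx] = cid + 1
        return img


def load_centers(path, frame_shape: tuple[int, int]) -> list[CellCenter]:
    """Read a cell_id,x,y CSV (0-based pixels), dropping out-of-bounds rows."""
    df = pd.read_csv(path)
    required = {"cell_id", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"centers file must have columns {sorted(required)}")
    if len(df) == 0:
        raise ValueError("no cells in centers file")
    if df["cell_id"].duplicated().any():
        dupes = df.loc[df["cell_id"].duplicated(), "cell_id"].tolist()
        raise ValueError(f"duplicate cell ids: {dupes}")
    h, w = frame_shape
    centers = []
    for row in df.itertuples(index=False):
        if not (0 <= row.x < w and 0 <= row.y < h):
            warnings.warn(
                f"cell {row.cell_id} at ({row.x}, {row.y}) is outside the "
                f"{h}x{w} frame; dropped",
                stacklevel=2,
            )
            continue
        centers.append(CellCenter(int(row.cell_id), float(row.x), float(row.y)))
    if not centers:
        raise ValueError("no cells within frame bounds")
    return centers


def _annulus_indices(
    center: CellCenter, r_lo: float, r_hi: float, frame_shape: tuple[int, int]
) -> np.ndarray:
    """Flat indices of pixels with r_lo <= euclidean distance <= r_hi, clipped to bounds."""
    h, w = frame_shape
    y0 = max(0, int(np.floor(center.y - r_hi)))
    y1 = min(h, int(np.ceil(center.y + r_hi)) + 1)
    x0 = max(0, int(np.floor(center.x - r_hi)))
    x1 = min(w, int(np.ceil(center.x + r_hi)) + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.hypot(yy - center.y, xx - center.x)
    sel = (d >= r_lo) & (d <= r_hi)
    return (yy[sel] * w + xx[sel]).astype(np.intp)


def build_soma_masks(
    centers: list[CellCenter],
    geometry: RoiGeometry,
    frame_shape: tuple[int, int],
) -> ROISet:
    """Draw each soma ring: pixels with r_inner <= dist(center) <= r_outer."""
    roiset = ROISet(
        frame_shape=frame_shape,
        geometry=geometry,
        cell_ids=[c.cell_id for c in centers],
        centers={c.cell_id: c for c in centers},
    )
    for c in centers:
        roiset.soma[c.cell_id] = _annulus_indices(
            c, geometry.r_inner, geometry.r_outer, frame_shape
        )
    return roiset


def resolve_overlaps(roiset: ROISet) -> ROISet:
    """Remove every pixel claimed by two or more somata from all of them.

    A cell whose ring becomes empty is flagged inactive and excluded from
    trace extraction downstream.
    """
    counts = np.zeros(roiset.frame_shape[0] * roiset.frame_shape[1], dtype=np.int32)
    for idx in roiset.soma.values():
        counts[idx] += 1
    for cid in roiset.cell_ids:
        idx = roiset.soma[cid]
        kept = idx[counts[idx] == 1]
        roiset.soma[cid] = kept
        if kept.size == 0:
            roiset.inactive.add(cid)
            log.warning("cell %d lost all soma pixels to overlaps; flagged inactive", cid)
    return roiset


def build_neuropil_masks(roiset: ROISet) -> ROISet:
    """Draw neuropil annuli: r_outer + 1 px out to r_outer + extent_um/pixel_size.

    Pixels assigned to ANY cell's soma (neighbors and self alike) are
    excluded from each annulus.
    """
    geom = roiset.geometry
    all_soma = np.zeros(roiset.frame_shape[0] * roiset.frame_shape[1], dtype=bool)
    for idx in roiset.soma.values():
        all_soma[idx] = True
    for cid in roiset.cell_ids:
        idx = _annulus_indices(
            roiset.centers[cid],
            geom.r_outer + 1.0,
            geom.neuropil_outer_px,
            roiset.frame_shape,
        )
        roiset.neuropil[cid] = idx[~all_soma[idx]]
    return roiset


def build_roiset(
    centers: list[CellCenter],
    frame_shape: tuple[int, int],
    geometry: RoiGeometry | None = None,
) -> ROISet:
    """Full build sequence: soma rings -> overlap exclusion -> neuropil annuli."""
    geometry = geometry or RoiGeometry()
    roiset = build_soma_masks(centers, geometry, frame_shape)
    roiset = resolve_overlaps(roiset)
    return build_neuropil_masks(roiset)
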