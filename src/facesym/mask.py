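"""Binary analysis mask: padded rectangle + half-ellipse, brow removal, midline.

The mask is built from 9 face-mesh landmarks — eye corners 33/133 and
362/263, nose bridge 1 and tip 0, lip centers 13/14, chin 152. Its upper
half is an axis-aligned rectangle spanning the padded eye-corner extent,
from the eyebrow cut line down to the midpoint between the eye line and
the padded chin; the lower half is the matching half-ellipse reaching the
padded chin. Everything above the eyebrows is removed so hair movement
cannot leak into the score. Pixels are foreground when their center
(col + 0.5, row + 0.5) lies inside the analytic shape.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import DegenerateGeometryError
from .landmarks import (
    CHIN,
    EYE_CORNER_LANDMARKS,
    EYEBROW_LANDMARKS,
    MIDLINE_LANDMARKS,
    LandmarkSet,
)


@dataclasses.dataclass
class FaceMask:
    """Binary analysis region plus the mirror midline column."""

    raster: np.ndarray  # (H, W) bool
    midline_x: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.raster)
        if arr.ndim != 2 or arr.dtype != np.bool_:
            raise ValueError("mask raster must be 2-D boolean")
        self.raster = arr

    @property
    def dims(self) -> tuple[int, int]:
        return (self.raster.shape[1], self.raster.shape[0])

    @property
    def n_foreground(self) -> int:
        return int(self.raster.sum())

    def to_png(self, path: str | Path) -> None:
        Image.fromarray(self.raster.astype(np.uint8) * 255).save(path)


def eyebrow_cut_y(lms: LandmarkSet) -> float:
    """Lowest (largest y) eyebrow landmark: the horizontal brow cut line."""
    return float(lms.points[list(EYEBROW_LANDMARKS), 1].max())


def mask_midline(lms: LandmarkSet) -> float:
    """Mirror-axis column: mean x of the facial-midline landmarks.

    Uses nose bridge/tip, lip centers and chin rather than the mask
    bounding box, so a palsy-asymmetric mask extent does not shift the
    mirror axis.
    """
    return float(lms.points[list(MIDLINE_LANDMARKS), 0].mean())


def build_mask(
    lms: LandmarkSet, dims: tuple[int, int], padding_frac: float = 0.10
) -> FaceMask:
    """Rasterize the rectangle-plus-half-ellipse analysis region.

    Raises DegenerateGeometryError when the defining landmarks have no
    horizontal or vertical extent.
    """
    w, h = dims
    pts = lms.points
    eye_x = pts[list(EYE_CORNER_LANDMARKS), 0]
    eye_y = float(pts[list(EYE_CORNER_LANDMARKS), 1].mean())
    chin_y = float(pts[CHIN, 1])

    x_min, x_max = float(eye_x.min()), float(eye_x.max())
    width = x_max - x_min
    height = chin_y - eye_y
    if width < 1e-9 or height < 1e-9:
        raise DegenerateGeometryError("mask landmarks have no extent")

    rx0 = x_min - padding_frac * width
    rx1 = x_max + padding_frac * width
    chin_pad = chin_y + padding_frac * height
    y_top = eyebrow_cut_y(lms)
    y_mid = (eye_y + chin_pad) / 2.0

    cx = (rx0 + rx1) / 2.0
    semi_x = (rx1 - rx0) / 2.0
    semi_y = chin_pad - y_mid

    xs = np.arange(w) + 0.5
    ys = np.arange(h) + 0.5
    xg, yg = np.meshgrid(xs, ys)

    rect = (xg >= rx0) & (xg <= rx1) & (yg >= y_top) & (yg <= y_mid)
    ellipse = (
        (yg >= y_mid)
        & (((xg - cx) / semi_x) ** 2 + ((yg - y_mid) / semi_y) ** 2 <= 1.0)
    )
    return FaceMask(raster=rect | ellipse, midline_x=mask_midline(lms))


def remove_brow_region(mask: FaceMask, lms: LandmarkSet) -> FaceMask:
    """Zero out every mask row above the eyebrow cut line.

    A single horizontal cut at the lowest eyebrow landmark; rows whose
    pixel centers lie above it are cleared.
    """
    y_cut = eyebrow_cut_y(lms)
    out = mask.raster.copy()
    ys = np.arange(out.shape[0]) + 0.5
    out[ys < y_cut, :] = False
    return FaceMask(raster=out, midline_x=mask.midline_x)
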