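"""Processed difference image: pre-blur, |ref - expr|, smooth, amplify, heatmap.

A 5x5 Gaussian pre-blur suppresses high-frequency texture (facial hair,
skin) on both the reference and the aligned expression image; their
masked absolute difference is converted to grayscale, smoothed with a
111x111 Gaussian and multiplied by 5 with saturation at 255. The result
drives both the rainbow heatmap (blue = no change, red = saturated, i.e.
a smoothed difference of 51 or more) and the symmetry score.

Gaussian sigma follows the kernel-size convention
sigma = 0.3 * ((k - 1)/2 - 1) + 0.8 with reflect border padding, so a
constant image stays constant and edges pick up no dark halo.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .errors import ConfigError, ZeroValidPairsError
from .landmarks import FaceImage
from .mask import FaceMask

LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclasses.dataclass
class DiffMap:
    """Smoothed, amplified, clipped single-channel difference image."""

    raster: np.ndarray  # (H, W) uint8
    amplification: int = 5
    smooth_kernel: int = 111

    def __post_init__(self) -> None:
        arr = np.asarray(self.raster)
        if arr.ndim != 2 or arr.dtype != np.uint8:
            raise ValueError("DiffMap raster must be 2-D uint8")
        self.raster = arr

    @property
    def dims(self) -> tuple[int, int]:
        return (self.raster.shape[1], self.raster.shape[0])

    def to_png(self, path: str | Path) -> None:
        Image.fromarray(self.raster).save(path)


def kernel_sigma(kernel: int) -> float:
    return 0.3 * ((kernel - 1) / 2.0 - 1.0) + 0.8


def _blur(arr: np.ndarray, kernel: int) -> np.ndarray:
    """Finite-support Gaussian blur (radius (k-1)/2, reflect border)."""
    if kernel <= 0 or kernel % 2 == 0:
        raise ConfigError(f"blur kernel must be odd and positive, got {kernel}")
    if kernel == 1:
        return arr.astype(np.float64)
    sigma = kernel_sigma(kernel)
    radius = (kernel - 1) // 2
    out = np.empty(arr.shape, dtype=np.float64)
    if arr.ndim == 2:
        gaussian_filter(
            arr.astype(np.float64), sigma, mode="reflect", radius=radius, output=out
        )
    else:
        for c in range(arr.shape[2]):
            gaussian_filter(
                arr[..., c].astype(np.float64),
                sigma,
                mode="reflect",
                radius=radius,
                output=out[..., c],
            )
    return out


def preblur(image: FaceImage, kernel: int = 5) -> FaceImage:
    """Slight Gaussian blur applied before differencing (default 5x5)."""
    blurred = np.clip(np.rint(_blur(image.raster, kernel)), 0, 255).astype(np.uint8)
    return FaceImage(blurred, image.expression_index, image.visit_date)


def abs_diff_gray(
    ref: FaceImage, expr_aligned: FaceImage, mask: FaceMask
) -> np.ndarray:
    """Masked per-channel absolute difference, collapsed to grayscale.

    Both images are masked first, so outside-mask pixels are exactly 0
    in the output. Returns a float64 raster on the 0-255 scale.
    """
    if ref.dims != expr_aligned.dims or ref.dims != mask.dims:
        raise ValueError(
            f"dimension mismatch: ref {ref.dims}, expr {expr_aligned.dims}, "
            f"mask {mask.dims}"
        )
    m = mask.raster[..., None]
    a = ref.raster.astype(np.float64) * m
    b = expr_aligned.raster.astype(np.float64) * m
    return np.abs(a - b) @ LUMA_WEIGHTS


def amplify_clip(values: np.ndarray, factor: int) -> np.ndarray:
    """Multiply by the amplification factor, saturating at 255."""
    return np.clip(np.asarray(values, dtype=np.float64) * factor, 0.0, 255.0)


def smooth_amplify(raw: np.ndarray, kernel: int = 111, factor: int = 5) -> DiffMap:
    """Blur the raw difference, amplify with 8-bit saturation.

    With the default factor 5, any smoothed difference of 51 or more
    saturates (51 * 5 = 255).
    """
    if factor <= 0:
        raise ConfigError(f"amplification factor must be positive, got {factor}")
    smoothed = _blur(np.asarray(raw, dtype=np.float64), kernel)
    out = np.rint(amplify_clip(smoothed, factor)).astype(np.uint8)
    return DiffMap(raster=out, amplification=factor, smooth_kernel=kernel)


# ---------------------------------------------------------------------------
# Heatmap rendering
# ---------------------------------------------------------------------------

def _blue_red_lut() -> np.ndarray:
    """256-entry rainbow LUT: HSV hue 240 deg (blue) down to 0 deg (red).

    Red is non-decreasing and blue non-increasing along the ramp, unlike
    matplotlib's jet whose red channel falls off at the top end.
    """
    from matplotlib.colors import hsv_to_rgb

    hues = np.linspace(240.0, 0.0, 256) / 360.0
    hsv = np.stack([hues, np.ones(256), np.ones(256)], axis=1)
    return np.clip(np.rint(hsv_to_rgb(hsv) * 255), 0, 255).astype(np.uint8)


def render_heatmap(d: DiffMap, colormap: str = "blue-red") -> FaceImage:
    """Colorize the difference map, value 0 -> blue end, 255 -> red end."""
    if colormap == "blue-red":
        lut = _blue_red_lut()
    else:
        import matplotlib.pyplot as plt

        cmap = plt.get_cmap(colormap)
        lut = np.clip(
            np.rint(cmap(np.linspace(0, 1, 256))[:, :3] * 255), 0, 255
        ).astype(np.uint8)
    return FaceImage(lut[d.raster])


def movement_intensity(d: DiffMap, mask: FaceMask) -> float:
    """Mean processed-difference value inside the mask.

    A low value signals a hesitantly performed expression whose high
    symmetry score may not be clinically meaningful.
    """
    if d.dims != mask.dims:
        raise ValueError("DiffMap and mask dimensions differ")
    if mask.n_foreground == 0:
        raise ZeroValidPairsError("mask has no foreground pixels")
    return float(d.raster[mask.raster].mean())
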