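"""Variance-weighted left/right symmetry score.

The right half of the masked difference image is mirrored about the
facial midline onto the left half; only pixel pairs where both mirror
positions are inside the mask enter the comparison. The base score

    S_mean = 1 - (1/N) * sum_i |L_i - R_i| / 255

is the inverse of the mean absolute half-difference, normalized to the
8-bit range so it lies in [0, 1]. To penalize spatially irregular
asymmetries it is weighted by the population variance sigma^2 of the
signed differences (on the raw 0-255 scale):

    S = S_mean * (1 - min(sigma^2 / sigma2_max, 1)),   sigma2_max = 5000.

S ranges from 0 (low symmetry) to 1 (perfectly uniform movement).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .diffmap import DiffMap
from .errors import ZeroValidPairsError
from .mask import FaceMask


@dataclasses.dataclass
class ScoreConfig:
    """Score normalizers: sigma2_max (variance ceiling) and the 8-bit scale."""

    sigma2_max: float = 5000.0
    intensity_scale: float = 255.0

    def __post_init__(self) -> None:
        if self.sigma2_max <= 0:
            raise ValueError("sigma2_max must be positive")
        if self.intensity_scale <= 0:
            raise ValueError("intensity_scale must be positive")


@dataclasses.dataclass
class SymmetryResult:
    """Score components for one expression image."""

    s_mean: float
    variance: float
    score: float
    n_valid: int
    expression_index: int | None = None


def paired_half_pixels(
    d: DiffMap | np.ndarray, mask: FaceMask
) -> tuple[np.ndarray, np.ndarray]:
    """Collect (left, mirrored-right) value pairs inside the mask.

    A pixel column j is "left" when its center j + 0.5 lies strictly
    left of the midline; its mirror column is the one containing the
    reflected center 2 * midline_x - (j + 0.5). A pair is valid when
    both pixels are mask-foreground and the mirror center is strictly
    right of the midline — this drops the column straddling the midline
    and makes self-pairing impossible.
    """
    raster = d.raster if isinstance(d, DiffMap) else np.asarray(d)
    m = mask.raster
    if raster.shape != m.shape:
        raise ValueError("DiffMap and mask dimensions differ")
    h, w = m.shape
    mid = mask.midline_x

    cols = np.arange(w)
    centers = cols + 0.5
    mirror = np.floor(2.0 * mid - centers).astype(int)  # floor(2*mid - j - 0.5)
    valid_col = (
        (centers < mid)
        & (mirror >= 0)
        & (mirror < w)
        & (np.clip(mirror, 0, w - 1) + 0.5 > mid)
    )
    left_cols = cols[valid_col]
    if left_cols.size == 0:
        raise ZeroValidPairsError("no mirrored pixel pairs inside the mask")

    pair_mask = m[:, left_cols] & m[:, mirror[valid_col]]
    if not pair_mask.any():
        raise ZeroValidPairsError("no mirrored pixel pairs inside the mask")
    left_vals = raster[:, left_cols].astype(np.float64)[pair_mask]
    right_vals = raster[:, mirror[valid_col]].astype(np.float64)[pair_mask]
    return left_vals, right_vals


def compute_s_mean(
    left: np.ndarray, right: np.ndarray, cfg: ScoreConfig | None = None
) -> float:
    """Base score: 1 minus the normalized mean absolute half-difference."""
    cfg = cfg or ScoreConfig()
    diffs = np.abs(np.asarray(left, dtype=np.float64) - np.asarray(right))
    if diffs.size == 0:
        raise ZeroValidPairsError("no pairs to score")
    return float(1.0 - diffs.mean() / cfg.intensity_scale)


def variance_weight(differences: np.ndarray, cfg: ScoreConfig | None = None) -> float:
    """Weight 1 - min(sigma^2 / sigma2_max, 1) from the signed differences."""
    cfg = cfg or ScoreConfig()
    diffs = np.asarray(differences, dtype=np.float64)
    if diffs.size == 0:
        raise ZeroValidPairsError("no pairs to weight")
    var = float(np.var(diffs))  # population variance
    return 1.0 - min(var / cfg.sigma2_max, 1.0)


def symmetry_score(
    d: DiffMap | np.ndarray,
    mask: FaceMask,
    cfg: ScoreConfig | None = None,
    expression_index: int | None = None,
) -> SymmetryResult:
    """Full variance-weighted symmetry score for one difference map."""
    cfg = cfg or ScoreConfig()
    left, right = paired_half_pixels(d, mask)
    signed = left - right
    s_mean = compute_s_mean(left, right, cfg)
    var = float(np.var(signed))
    weight = variance_weight(signed, cfg)
    score = s_mean * weight
    assert 0.0 <= score <= s_mean <= 1.0 or math.isclose(score, s_mean)
    return SymmetryResult(
        s_mean=s_mean,
        variance=var,
        score=score,
        n_valid=int(left.size),
        expression_index=expression_index,
    )
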