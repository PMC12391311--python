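"""Run configuration: every tunable processing parameter in one place.

Defaults are the published pipeline constants: 5x5 pre-blur, 111x111
difference smoothing, x5 amplification with 8-bit saturation, maximum
variance 5000 for the score weighting, 10% mask padding, +/-0.001
trend threshold and a window-3 rolling median for longitudinal series.
"""

from __future__ import annotations

import dataclasses
import tomllib
from pathlib import Path
from typing import Any

from .errors import ConfigError


@dataclasses.dataclass
class RunConfig:
    """All pipeline parameters, overridable from a TOML file or CLI flags.

    Attributes
    ----------
    preblur_kernel
        Side length of the Gaussian pre-blur applied to reference and
        aligned expression image before differencing (odd, pixels).
    smooth_kernel
        Side length of the Gaussian blur applied to the raw difference
        image (odd, pixels).
    amplification
        Integer factor multiplying the smoothed difference, saturating
        at 255.
    sigma2_max
        Maximum variance normalizer of the score weighting; at or above
        this variance of the left-minus-mirrored-right differences the
        score is 0.
    intensity_scale
        Normalizer dividing the mean absolute half-difference so the
        base score lies in [0, 1]; 255 for 8-bit images.
    padding_frac
        Fractional padding per side applied to the face-mask rectangle
        and ellipse extents.
    trend_threshold
        Slope magnitude below which a longitudinal trend counts as no
        significant change (score units per examination).
    rolling_window
        Window of the rolling median applied to score series with at
        least that many points.
    movement_intensity_min
        Mean processed-difference value (0-255) below which an
        expression is flagged as hesitantly performed.
    variance_on_amplified
        Whether the weighting variance is computed on the amplified,
        clipped difference map (default) or would require the
        pre-amplification map.
    alignment_dof
        "similarity" (translation + rotation + isotropic scale) or
        "affine" (full 6-DOF) landmark alignment.
    aggregate
        Per-visit aggregate over expression scores: "mean", "median",
        or an expression index 2-9 as a string.
    time_axis
        "index" (examination number 0,1,2,...) or "days" (days since
        first visit) as the abscissa for trend slopes.
    colormap
        Heatmap palette; "blue-red" is the built-in monotone rainbow,
        any matplotlib colormap name is accepted.
    provider
        Landmark provider selection: "replay" (stored coordinates next
        to each image) or "mediapipe" (external face-mesh model).
    amplification_overrides
        Optional per-expression amplification factors, keyed by
        expression index; empty by default (uniform amplification).
    """

    preblur_kernel: int = 5
    smooth_kernel: int = 111
    amplification: int = 5
    sigma2_max: float = 5000.0
    intensity_scale: float = 255.0
    padding_frac: float = 0.10
    trend_threshold: float = 0.001
    rolling_window: int = 3
    movement_intensity_min: float = 5.0
    variance_on_amplified: bool = True
    alignment_dof: str = "similarity"
    aggregate: str = "mean"
    time_axis: str = "index"
    colormap: str = "blue-red"
    provider: str = "replay"
    output_dir: str = "facesym_out"
    amplification_overrides: dict[int, int] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("preblur_kernel", "smooth_kernel"):
            k = getattr(self, name)
            if k <= 0 or k % 2 == 0:
                raise ConfigError(f"{name} must be odd and positive, got {k}")
        if self.amplification <= 0:
            raise ConfigError("amplification must be positive")
        if self.sigma2_max <= 0:
            raise ConfigError("sigma2_max must be positive")
        for name in ("trend_threshold", "movement_intensity_min", "padding_frac"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.rolling_window < 1:
            raise ConfigError("rolling_window must be >= 1")
        if self.alignment_dof not in ("similarity", "affine"):
            raise ConfigError("alignment_dof must be 'similarity' or 'affine'")
        if self.time_axis not in ("index", "days"):
            raise ConfigError("time_axis must be 'index' or 'days'")

    @classmethod
    def from_toml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        """Load a flat key-value TOML file; keyword overrides win."""
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "amplification_overrides" in data:
            data["amplification_overrides"] = {
                int(k): int(v) for k, v in data["amplification_overrides"].items()
            }
        return cls(**data)

    def replace(self, **changes: Any) -> "RunConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)
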