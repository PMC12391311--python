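"""Landmark acquisition, interocular scaling, canvas centering and alignment.

The geometric backbone of the pipeline: every image carries a 478-point
face-mesh landmark set in pixel coordinates (origin top-left, x right,
y down, 0-based; point (x, y) addresses pixel (floor(x), floor(y))).
Faces are normalized so the outer eye corners are 200 px apart, centered
on the reference canvas, and registered to the neutral reference with a
least-squares similarity transform estimated from all 478 landmarks.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np
from PIL import Image

from .errors import (
    DegenerateGeometryError,
    NoFaceDetectedError,
    ProviderContractError,
)

N_LANDMARKS = 478

# Face-mesh indices of the named anatomical points used by the pipeline.
LEFT_EYE_OUTER = 33     # image-left outer (temporal) eye corner
LEFT_EYE_INNER = 133
RIGHT_EYE_INNER = 362
RIGHT_EYE_OUTER = 263   # image-right outer (temporal) eye corner
NOSE_BRIDGE = 1
NOSE_TIP = 0
UPPER_LIP = 13
LOWER_LIP = 14
CHIN = 152

EYE_CORNER_LANDMARKS = (LEFT_EYE_OUTER, LEFT_EYE_INNER, RIGHT_EYE_INNER, RIGHT_EYE_OUTER)
MASK_LANDMARKS = (33, 133, 362, 263, 1, 0, 13, 14, 152)
MIDLINE_LANDMARKS = (NOSE_BRIDGE, NOSE_TIP, UPPER_LIP, LOWER_LIP, CHIN)
EYEBROW_LANDMARKS = (70, 63, 105, 66, 107, 336, 296, 334, 293, 300)

INTEROCULAR_TARGET = 200.0  # px between outer eye corners after scaling


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class LandmarkSet:
    """478 facial landmarks in pixel coordinates of a specific image."""

    points: np.ndarray  # (478, 2) float64, columns (x, y)
    source_dims: tuple[int, int]  # (width, height) of the image

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.shape != (N_LANDMARKS, 2):
            raise ProviderContractError(
                f"expected {N_LANDMARKS} landmarks, got shape {pts.shape}"
            )
        if not np.all(np.isfinite(pts)):
            raise ProviderContractError("landmark coordinates must be finite")
        self.points = pts

    @classmethod
    def from_normalized(
        cls, normalized: np.ndarray, dims: tuple[int, int]
    ) -> "LandmarkSet":
        """Convert [0, 1]-normalized provider output to pixel coordinates."""
        pts = np.asarray(normalized, dtype=np.float64)[:, :2].copy()
        pts[:, 0] *= dims[0]
        pts[:, 1] *= dims[1]
        return cls(points=pts, source_dims=dims)

    def interocular_distance(self) -> float:
        return float(
            np.linalg.norm(self.points[LEFT_EYE_OUTER] - self.points[RIGHT_EYE_OUTER])
        )

    # -- serialization ------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("index,x,y\n")
            for i, (x, y) in enumerate(self.points):
                fh.write(f"{i},{float(x)!r},{float(y)!r}\n")

    @classmethod
    def from_csv(cls, path: str | Path, dims: tuple[int, int]) -> "LandmarkSet":
        rows = np.loadtxt(path, delimiter=",", skiprows=1, dtype=np.float64)
        order = np.argsort(rows[:, 0])
        return cls(points=rows[order, 1:3], source_dims=dims)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "source_dims": list(self.source_dims),
            "points": self.points.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "LandmarkSet":
        payload = json.loads(Path(path).read_text())
        return cls(
            points=np.asarray(payload["points"], dtype=np.float64),
            source_dims=tuple(payload["source_dims"]),
        )


@dataclasses.dataclass
class FaceImage:
    """An 8-bit RGB photograph with its role in the nine-image series.

    Expression index 1 is the neutral reference; 2-9 are the
    standardized expressions (eyes gently/tightly closed, frowning,
    nose wrinkling, closed-mouth stretch, mouth stretch with teeth,
    lip pursing, mouth corners down).
    """

    raster: np.ndarray  # (H, W, 3) uint8
    expression_index: int = 1
    visit_date: datetime.date | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.raster)
        if arr.ndim != 3 or arr.shape[2] != 3 or arr.dtype != np.uint8:
            raise ValueError("raster must be (H, W, 3) uint8")
        if not 1 <= self.expression_index <= 9:
            raise ValueError("expression_index must be in 1..9")
        self.raster = arr

    @property
    def dims(self) -> tuple[int, int]:
        """(width, height) in pixels."""
        return (self.raster.shape[1], self.raster.shape[0])

    @classmethod
    def from_file(
        cls,
        path: str | Path,
        expression_index: int = 1,
        visit_date: datetime.date | None = None,
    ) -> "FaceImage":
        with Image.open(path) as img:
            arr = np.asarray(img.convert("RGB"), dtype=np.uint8)
        return cls(arr, expression_index, visit_date)

    def to_file(self, path: str | Path) -> None:
        Image.fromarray(self.raster).save(path)


@dataclasses.dataclass
class SimilarityTransform:
    """4-DOF similarity: x' = s * R(theta) @ x + t."""

    scale: float = 1.0
    rotation: float = 0.0  # radians, positive = image-clockwise (y down)
    translation: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def matrix(self) -> np.ndarray:
        """Homogeneous 3x3 matrix acting on (x, y, 1) column vectors."""
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        m = np.array(
            [
                [self.scale * c, -self.scale * s, self.translation[0]],
                [self.scale * s, self.scale * c, self.translation[1]],
                [0.0, 0.0, 1.0],
            ]
        )
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64)
        return pts @ self.matrix[:2, :2].T + np.asarray(self.translation)

    def inverse(self) -> "SimilarityTransform":
        inv_scale = 1.0 / self.scale
        c, s = np.cos(-self.rotation), np.sin(-self.rotation)
        tx, ty = self.translation
        return SimilarityTransform(
            scale=inv_scale,
            rotation=-self.rotation,
            translation=(
                -inv_scale * (c * tx - s * ty),
                -inv_scale * (s * tx + c * ty),
            ),
        )

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """Return the transform applying `other` first, then self."""
        m = self.matrix @ other.matrix
        scale = float(np.hypot(m[0, 0], m[1, 0]))
        return SimilarityTransform(
            scale=scale,
            rotation=float(np.arctan2(m[1, 0], m[0, 0])),
            translation=(float(m[0, 2]), float(m[1, 2])),
        )

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls()


@dataclasses.dataclass
class AffineTransform:
    """Full 6-DOF affine alignment, selectable via config."""

    matrix: np.ndarray  # 3x3 homogeneous

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64)
        return pts @ self.matrix[:2, :2].T + self.matrix[:2, 2]


# ---------------------------------------------------------------------------
# Landmark providers
# ---------------------------------------------------------------------------

@runtime_checkable
class LandmarkProvider(Protocol):
    """Pluggable source of 478-point face-mesh landmarks."""

    def detect(self, image: FaceImage) -> LandmarkSet | None:
        """Return landmarks in pixel coordinates, or None if no face."""
        ...


class ReplayProvider:
    """Serves pre-computed landmark sets, keyed by image identity.

    Used for synthetic fixtures (the analytic template coordinates) and
    for replaying stored detections without the external model. Keys are
    arbitrary hashables; `detect` resolves the key via `key_fn`.
    """

    def __init__(self, landmark_map, key_fn=None):
        self._map = dict(landmark_map)
        self._key_fn = key_fn or (lambda img: id(img))

    def detect(self, image: FaceImage) -> LandmarkSet | None:
        return self._map.get(self._key_fn(image))


class MediaPipeProvider:
    """Wraps the external MediaPipe face-mesh model (refined landmarks).

    The model is an optional runtime dependency; importing it is
    deferred so the rest of the package works without it.
    """

    def __init__(self) -> None:
        try:
            import mediapipe  # type: ignore
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "MediaPipeProvider requires the 'mediapipe' package; "
                "install it or use the replay provider"
            ) from exc
        self._mp = mediapipe

    def detect(self, image: FaceImage) -> LandmarkSet | None:  # pragma: no cover
        mp = self._mp
        with mp.solutions.face_mesh.FaceMesh(
            static_image_mode=True, refine_landmarks=True, max_num_faces=1
        ) as mesh:
            result = mesh.process(image.raster)
        if not result.multi_face_landmarks:
            return None
        face = result.multi_face_landmarks[0]
        normalized = np.array([[p.x, p.y] for p in face.landmark])
        return LandmarkSet.from_normalized(normalized, image.dims)


def detect_landmarks(image: FaceImage, provider: LandmarkProvider) -> LandmarkSet:
    """Run the provider and enforce the 478-point contract."""
    result = provider.detect(image)
    if result is None:
        raise NoFaceDetectedError(
            f"no face detected in expression-{image.expression_index} image"
        )
    if not isinstance(result, LandmarkSet):
        result = LandmarkSet(
            points=np.asarray(result, dtype=np.float64), source_dims=image.dims
        )
    if result.points.shape[0] != N_LANDMARKS:
        raise ProviderContractError(
            f"provider returned {result.points.shape[0]} points, "
            f"contract requires {N_LANDMARKS}"
        )
    return result


# ---------------------------------------------------------------------------
# Interocular scaling and canvas centering
# ---------------------------------------------------------------------------

def interocular_scale(
    image: FaceImage, lms: LandmarkSet, target: float = INTEROCULAR_TARGET
) -> tuple[FaceImage, LandmarkSet, float]:
    """Uniformly rescale so the outer eye corners are `target` px apart.

    Returns the resampled image, the rescaled landmarks and the scale
    factor applied. Landmark coordinates are multiplied exactly by the
    factor; the raster is resampled bilinearly to the rounded new size.
    """
    dist = lms.interocular_distance()
    if dist < 1e-9:
        raise DegenerateGeometryError("outer eye corners coincide")
    factor = target / dist
    w, h = image.dims
    new_w = max(1, round(w * factor))
    new_h = max(1, round(h * factor))
    if (new_w, new_h) == (w, h) and abs(factor - 1.0) < 1e-12:
        out_img = image
    else:
        resized = Image.fromarray(image.raster).resize(
            (new_w, new_h), Image.BILINEAR
        )
        out_img = FaceImage(
            np.asarray(resized, dtype=np.uint8),
            image.expression_index,
            image.visit_date,
        )
    out_lms = LandmarkSet(points=lms.points * factor, source_dims=(new_w, new_h))
    return out_img, out_lms, factor


def center_on_canvas(
    image: FaceImage, lms: LandmarkSet, ref_dims: tuple[int, int]
) -> tuple[FaceImage, LandmarkSet]:
    """Center the image on a canvas of the reference dimensions.

    Smaller images are zero-padded symmetrically; larger ones are
    center-cropped. The offset per axis is floor((ref - src) / 2), so
    ties break toward the top-left. Landmarks are shifted by the same
    offset and may leave the canvas after a crop.
    """
    ref_w, ref_h = ref_dims
    if ref_w <= 0 or ref_h <= 0:
        raise ValueError("ref_dims must be positive")
    src_h, src_w = image.raster.shape[:2]
    off_x = (ref_w - src_w) // 2
    off_y = (ref_h - src_h) // 2

    canvas = np.zeros((ref_h, ref_w, 3), dtype=np.uint8)
    dst_x0, src_x0 = (off_x, 0) if off_x >= 0 else (0, -off_x)
    dst_y0, src_y0 = (off_y, 0) if off_y >= 0 else (0, -off_y)
    cw = min(src_w - src_x0, ref_w - dst_x0)
    ch = min(src_h - src_y0, ref_h - dst_y0)
    canvas[dst_y0 : dst_y0 + ch, dst_x0 : dst_x0 + cw] = image.raster[
        src_y0 : src_y0 + ch, src_x0 : src_x0 + cw
    ]

    out_lms = LandmarkSet(
        points=lms.points + np.array([off_x, off_y], dtype=np.float64),
        source_dims=(ref_w, ref_h),
    )
    return (
        FaceImage(canvas, image.expression_index, image.visit_date),
        out_lms,
    )


# ---------------------------------------------------------------------------
# Alignment estimation and warping
# ---------------------------------------------------------------------------

def estimate_alignment(src: LandmarkSet, dst: LandmarkSet) -> SimilarityTransform:
    """Least-squares similarity registration over all 478 landmarks.

    Closed-form solution (orthogonal Procrustes with isotropic scale):
    minimizes sum ||s R x_i + t - y_i||^2 over rotation R, scale s > 0
    and translation t.
    """
    x = src.points
    y = dst.points
    mu_x = x.mean(axis=0)
    mu_y = y.mean(axis=0)
    xc = x - mu_x
    yc = y - mu_y
    var_x = float((xc**2).sum() / len(x))
    if var_x < 1e-18:
        raise DegenerateGeometryError("source landmarks are all coincident")

    cov = yc.T @ xc / len(x)
    u, d, vt = np.linalg.svd(cov)
    sign = np.sign(np.linalg.det(u @ vt))
    correction = np.array([1.0, sign])
    rot = u @ np.diag(correction) @ vt
    scale = float((d * correction).sum() / var_x)
    trans = mu_y - scale * rot @ mu_x
    return SimilarityTransform(
        scale=scale,
        rotation=float(np.arctan2(rot[1, 0], rot[0, 0])),
        translation=(float(trans[0]), float(trans[1])),
    )


def estimate_affine(src: LandmarkSet, dst: LandmarkSet) -> AffineTransform:
    """Full 6-DOF least-squares affine registration (config option)."""
    x = src.points
    if float(((x - x.mean(axis=0)) ** 2).sum()) < 1e-18:
        raise DegenerateGeometryError("source landmarks are all coincident")
    design = np.hstack([x, np.ones((len(x), 1))])
    coef, *_ = np.linalg.lstsq(design, dst.points, rcond=None)
    m = np.eye(3)
    m[:2, :2] = coef[:2].T
    m[:2, 2] = coef[2]
    return AffineTransform(matrix=m)


def warp_image(
    image: FaceImage,
    transform: SimilarityTransform | AffineTransform,
    out_dims: tuple[int, int],
) -> FaceImage:
    """Resample the image into the reference frame of the transform.

    `transform` maps source pixel coordinates to reference coordinates;
    the output raster has `out_dims` (width, height). Bilinear
    interpolation, out-of-source pixels filled with 0.
    """
    from skimage.transform import AffineTransform as SkAffine
    from skimage.transform import warp

    out_w, out_h = out_dims
    inv = np.linalg.inv(transform.matrix)
    warped = warp(
        image.raster,
        inverse_map=SkAffine(matrix=inv),
        output_shape=(out_h, out_w),
        order=1,
        mode="constant",
        cval=0.0,
        preserve_range=True,
    )
    return FaceImage(
        np.clip(np.rint(warped), 0, 255).astype(np.uint8),
        image.expression_index,
        image.visit_date,
    )
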