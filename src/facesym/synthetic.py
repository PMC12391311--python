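"""Procedural face fixtures with known ground truth.

Faces are flat-shaded geometric primitives (face ellipse, eye and mouth
ellipses, brow bars, nose band, nostril disks) plus mild seeded texture
noise, drawn analytically on pixel centers so a zero-asymmetry pair is
exactly mirror-symmetric about the canvas midline. Each of the eight
standardized expressions displaces one feature group; the asymmetry
parameter a in [0, 1] attenuates the displacement on the image-right
side by (1 - a): a = 0 moves both sides identically, a = 1 freezes the
right side entirely, emulating complete unilateral palsy.

The matching 478-point landmark set places the pipeline's named indices
(outer/inner eye corners 33/133/362/263, nose bridge 1 and tip 0, lip
centers 13/14, chin 152, the ten eyebrow points) at their analytic
positions and distributes the remaining indices along the face outline,
so "all landmarks" alignment is exercised. A replay provider serves
these template coordinates in place of a live face-mesh model.

These fixtures deliberately lack photographic realism: no shading
gradients, pose variation, occlusion or detector noise. They validate
the geometry and arithmetic of the pipeline, not detector robustness.
"""

from __future__ import annotations

import dataclasses
import datetime
from pathlib import Path

import numpy as np

from .landmarks import (
    CHIN,
    EYEBROW_LANDMARKS,
    LEFT_EYE_INNER,
    LEFT_EYE_OUTER,
    LOWER_LIP,
    N_LANDMARKS,
    NOSE_BRIDGE,
    NOSE_TIP,
    RIGHT_EYE_INNER,
    RIGHT_EYE_OUTER,
    UPPER_LIP,
    FaceImage,
    LandmarkSet,
)
from .longitudinal import ScoreSeries, VisitScores

EXPRESSION_NAMES = {
    2: "eyes gently closed",
    3: "eyes tightly closed",
    4: "frowning / forehead wrinkling",
    5: "nose wrinkling",
    6: "closed-mouth stretch",
    7: "mouth stretch with teeth showing",
    8: "lip pursing",
    9: "mouth corners down",
}


@dataclasses.dataclass
class SyntheticFaceSpec:
    """Parameters of one neutral/expression fixture pair."""

    width: int = 360          # canvas width, even so the midline falls on a
    height: int = 480         # pixel boundary and mirror pairing is exact
    expression_index: int = 7
    asymmetry: float = 0.0    # a in [0, 1]; right-side displacement x(1 - a)
    displacement: float = 1.0  # global multiplier on expression movement
    noise_sd: float = 3.0     # texture noise, shared by both images
    seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= self.expression_index <= 9:
            raise ValueError("expression_index must be in 2..9")
        if not 0.0 <= self.asymmetry <= 1.0:
            raise ValueError("asymmetry must lie in [0, 1]")
        if self.width % 2 != 0:
            raise ValueError("width must be even")


@dataclasses.dataclass
class _FaceParams:
    """Per-side feature geometry, all in pixels."""

    cx: float
    cy: float
    fa: float               # face ellipse half-axes
    fb: float
    eye_dx: float           # eye center offset from midline
    eye_y: float
    ew: float               # eye half-width
    eh: tuple[float, float]  # eye half-height (left, right)
    brow_y: tuple[float, float]
    brow_w: float
    nostril_r: tuple[float, float]
    nostril_dy: tuple[float, float]
    mouth_y: float
    mouth_w: tuple[float, float]   # mouth half-width per side
    mouth_h: tuple[float, float]   # mouth half-height per side
    teeth: bool
    corner_drop: tuple[float, float]
    chin_y: float
    bridge_y: float
    nose_tip_y: float


def _face_params(spec: SyntheticFaceSpec, neutral: bool) -> _FaceParams:
    w, h = float(spec.width), float(spec.height)
    cx, cy = w / 2.0, h * 0.52
    fa, fb = 0.36 * w, 0.42 * h
    eye_y = cy - 0.35 * fb
    eye_dx = 0.45 * fa
    ew = 0.07 * w
    eh0 = 0.025 * h
    brow_y0 = eye_y - 0.06 * h
    mouth_y = cy + 0.55 * fb
    chin_y = cy + fb

    # side displacement factors: (image-left, image-right)
    d = 0.0 if neutral else spec.displacement
    f = (d, d * (1.0 - spec.asymmetry))

    eh = (eh0, eh0)
    brow_y = (brow_y0, brow_y0)
    nostril_r = (5.0, 5.0)
    nostril_dy = (0.0, 0.0)
    mouth_w = (0.12 * w, 0.12 * w)
    mouth_h = (6.0, 6.0)
    teeth = False
    corner_drop = (0.0, 0.0)

    e = spec.expression_index
    if e == 2:  # eyes gently closed
        eh = tuple(eh0 * (1.0 - 0.6 * fi) for fi in f)
    elif e == 3:  # eyes tightly closed
        eh = tuple(eh0 * (1.0 - 0.85 * fi) for fi in f)
    elif e == 4:  # frowning / forehead wrinkling: brows rise
        brow_y = tuple(brow_y0 - 14.0 * fi for fi in f)
    elif e == 5:  # nose wrinkling: nostrils flare and rise
        nostril_r = tuple(5.0 + 6.0 * fi for fi in f)
        nostril_dy = tuple(-6.0 * fi for fi in f)
    elif e == 6:  # closed-mouth stretch
        mouth_w = tuple(0.12 * w + 22.0 * fi for fi in f)
    elif e == 7:  # mouth stretch with teeth showing
        mouth_w = tuple(0.12 * w + 26.0 * fi for fi in f)
        mouth_h = tuple(6.0 + 9.0 * fi for fi in f)
        teeth = not neutral
    elif e == 8:  # lip pursing
        mouth_w = tuple(0.12 * w - 18.0 * fi for fi in f)
        mouth_h = tuple(6.0 + 7.0 * fi for fi in f)
    elif e == 9:  # mouth corners down
        corner_drop = tuple(16.0 * fi for fi in f)

    return _FaceParams(
        cx=cx, cy=cy, fa=fa, fb=fb,
        eye_dx=eye_dx, eye_y=eye_y, ew=ew, eh=eh,
        brow_y=brow_y, brow_w=1.1 * ew,
        nostril_r=nostril_r, nostril_dy=nostril_dy,
        mouth_y=mouth_y, mouth_w=mouth_w, mouth_h=mouth_h,
        teeth=teeth, corner_drop=corner_drop,
        chin_y=chin_y, bridge_y=eye_y + 8.0, nose_tip_y=cy + 10.0,
    )


def _render(p: _FaceParams, dims: tuple[int, int], noise: np.ndarray) -> np.ndarray:
    w, h = dims
    xg, yg = np.meshgrid(np.arange(w) + 0.5, np.arange(h) + 0.5)
    img = np.full((h, w), 70.0)

    face = ((xg - p.cx) / p.fa) ** 2 + ((yg - p.cy) / p.fb) ** 2 <= 1.0
    img[face] = 175.0

    for side, sign in ((0, -1.0), (1, 1.0)):
        ex = p.cx + sign * p.eye_dx
        # brow bar
        brow = (np.abs(xg - ex) <= p.brow_w) & (np.abs(yg - p.brow_y[side]) <= 5.0)
        img[brow] = 60.0
        # eye ellipse (degenerates gracefully as the lid closes)
        eh = max(p.eh[side], 1.0)
        eye = ((xg - ex) / p.ew) ** 2 + ((yg - p.eye_y) / eh) ** 2 <= 1.0
        img[eye] = 45.0
        # nostril
        ny = p.nose_tip_y + p.nostril_dy[side]
        nostril = (xg - (p.cx + sign * 14.0)) ** 2 + (yg - ny) ** 2 <= p.nostril_r[
            side
        ] ** 2
        img[nostril] = 90.0

    # nose band (midline feature, expression-invariant)
    band = (np.abs(xg - p.cx) <= 4.0) & (yg >= p.bridge_y) & (yg <= p.nose_tip_y)
    img[band] = 120.0

    # mouth, drawn per half so each side stretches independently
    for side, half in ((0, xg <= p.cx), (1, xg > p.cx)):
        mw = max(p.mouth_w[side], 4.0)
        mh = max(p.mouth_h[side], 1.5)
        lips = half & (
            ((xg - p.cx) / mw) ** 2 + ((yg - p.mouth_y) / mh) ** 2 <= 1.0
        )
        img[lips] = 85.0
        if p.teeth:
            inner = half & (
                ((xg - p.cx) / (0.8 * mw)) ** 2
                + ((yg - p.mouth_y) / (0.55 * mh)) ** 2
                <= 1.0
            )
            img[inner] = 225.0
        if p.corner_drop[side] > 0.0:
            sign = -1.0 if side == 0 else 1.0
            corner = (xg - (p.cx + sign * mw)) ** 2 + (
                yg - (p.mouth_y + p.corner_drop[side])
            ) ** 2 <= 49.0
            img[corner] = 85.0

    out = np.clip(np.rint(img + noise), 0, 255).astype(np.uint8)
    return np.repeat(out[:, :, None], 3, axis=2)


def _landmarks(p: _FaceParams, dims: tuple[int, int]) -> LandmarkSet:
    pts = np.zeros((N_LANDMARKS, 2))
    named: dict[int, tuple[float, float]] = {
        LEFT_EYE_OUTER: (p.cx - p.eye_dx - p.ew, p.eye_y),
        LEFT_EYE_INNER: (p.cx - p.eye_dx + p.ew, p.eye_y),
        RIGHT_EYE_INNER: (p.cx + p.eye_dx - p.ew, p.eye_y),
        RIGHT_EYE_OUTER: (p.cx + p.eye_dx + p.ew, p.eye_y),
        NOSE_BRIDGE: (p.cx, p.bridge_y),
        NOSE_TIP: (p.cx, p.nose_tip_y),
        UPPER_LIP: (p.cx, p.mouth_y - (p.mouth_h[0] + p.mouth_h[1]) / 2.0),
        LOWER_LIP: (p.cx, p.mouth_y + (p.mouth_h[0] + p.mouth_h[1]) / 2.0),
        CHIN: (p.cx, p.chin_y),
    }
    offsets = np.linspace(-p.brow_w, p.brow_w, 5)
    for k, off in zip(EYEBROW_LANDMARKS[:5], offsets):
        named[k] = (p.cx - p.eye_dx + off, p.brow_y[0])
    for k, off in zip(EYEBROW_LANDMARKS[5:], offsets):
        named[k] = (p.cx + p.eye_dx + off, p.brow_y[1])

    free = [i for i in range(N_LANDMARKS) if i not in named]
    angles = 2.0 * np.pi * np.arange(len(free)) / len(free)
    for i, ang in zip(free, angles):
        pts[i] = (p.cx + p.fa * np.cos(ang), p.cy + p.fb * np.sin(ang))
    for i, xy in named.items():
        pts[i] = xy
    return LandmarkSet(points=pts, source_dims=dims)


def generate_face_pair(
    spec: SyntheticFaceSpec,
) -> tuple[FaceImage, FaceImage, LandmarkSet, LandmarkSet]:
    """Neutral/expression image pair plus their landmark templates.

    Deterministic in the spec (including seed); the same texture-noise
    field is applied to both images so every pixel difference is
    structural.
    """
    dims = (spec.width, spec.height)
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sd, (spec.height, spec.width))

    p_neutral = _face_params(spec, neutral=True)
    p_expr = _face_params(spec, neutral=False)
    neutral = FaceImage(_render(p_neutral, dims, noise), expression_index=1)
    expr = FaceImage(
        _render(p_expr, dims, noise), expression_index=spec.expression_index
    )
    return neutral, expr, _landmarks(p_neutral, dims), _landmarks(p_expr, dims)


def generate_score_series(
    true_slope: float,
    noise_sd: float,
    n: int,
    seed: int,
    base: float = 0.6,
    patient_id: str = "synthetic",
    start_date: datetime.date = datetime.date(2020, 1, 1),
) -> ScoreSeries:
    """Linear-trend score series: clip(base + slope * i + noise, 0, 1)."""
    if n < 2:
        raise ValueError("need at least 2 visits")
    rng = np.random.default_rng(seed)
    values = np.clip(
        base + true_slope * np.arange(n) + rng.normal(0.0, noise_sd, n), 0.0, 1.0
    )
    entries = [
        VisitScores(
            date=start_date + datetime.timedelta(days=30 * i),
            scores={2: float(v)},
        )
        for i, v in enumerate(values)
    ]
    return ScoreSeries(patient_id=patient_id, entries=entries)


def write_visit(
    visit_dir: str | Path,
    asymmetry: float,
    seed: int,
    expressions: tuple[int, ...] = tuple(range(2, 10)),
    dims: tuple[int, int] = (360, 480),
) -> None:
    """Write one synthetic visit in the pipeline's dataset layout.

    Creates expr_<n>.png for the neutral image (n = 1) and each
    requested expression, each with a sidecar expr_<n>.landmarks.json
    consumed by the replay provider.
    """
    visit_dir = Path(visit_dir)
    visit_dir.mkdir(parents=True, exist_ok=True)
    wrote_neutral = False
    for e in expressions:
        spec = SyntheticFaceSpec(
            width=dims[0],
            height=dims[1],
            expression_index=e,
            asymmetry=asymmetry,
            seed=seed,
        )
        neutral, expr, lms_n, lms_e = generate_face_pair(spec)
        if not wrote_neutral:
            neutral.to_file(visit_dir / "expr_1.png")
            lms_n.to_json(visit_dir / "expr_1.landmarks.json")
            wrote_neutral = True
        expr.to_file(visit_dir / f"expr_{e}.png")
        lms_e.to_json(visit_dir / f"expr_{e}.landmarks.json")


def write_dataset(
    root: str | Path,
    patients: dict[str, list[tuple[str, float]]],
    seed: int = 0,
    expressions: tuple[int, ...] = tuple(range(2, 10)),
    dims: tuple[int, int] = (360, 480),
) -> None:
    """Write a cohort tree patient_id/visit_date/expr_<n>.png.

    `patients` maps patient id to a list of (ISO date, asymmetry)
    visits; asymmetry decreasing over visits emulates recovery.
    """
    root = Path(root)
    for pid, visits in patients.items():
        for date, asym in visits:
            write_visit(
                root / pid / date, asymmetry=asym, seed=seed,
                expressions=expressions, dims=dims,
            )
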