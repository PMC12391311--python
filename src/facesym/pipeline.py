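"""End-to-end orchestration: visit processing, cohort runs, reporting.

For every visit directory (expr_1.png = neutral reference, expr_2..9.png
= expressions) the pipeline scales each face to a 200 px interocular
distance, centers the expression on the reference canvas, aligns it with
a similarity transform estimated from all 478 landmarks, builds the
masked difference map, renders the heatmap and computes the
variance-weighted symmetry score plus the movement-intensity flag.
Cohort runs add per-patient robust trends and clinical-grade
correlations.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from pathlib import Path

import pandas as pd

from .config import RunConfig
from .diffmap import (
    DiffMap,
    abs_diff_gray,
    movement_intensity,
    preblur,
    render_heatmap,
    smooth_amplify,
)
from .errors import FaceSymError
from .landmarks import (
    FaceImage,
    LandmarkSet,
    MediaPipeProvider,
    estimate_affine,
    estimate_alignment,
    center_on_canvas,
    detect_landmarks,
    interocular_scale,
    warp_image,
)
from .mask import FaceMask, build_mask, remove_brow_region
from .score import ScoreConfig, SymmetryResult, symmetry_score

logger = logging.getLogger("facesym")

RESULT_COLUMNS = [
    "patient_id",
    "visit_date",
    "expression_index",
    "s_mean",
    "variance",
    "score",
    "n_valid",
    "movement_intensity",
    "low_movement",
]


@dataclasses.dataclass
class PairResult:
    """Everything the pipeline derives from one neutral/expression pair."""

    result: SymmetryResult
    diffmap: DiffMap
    mask: FaceMask
    heatmap: FaceImage
    aligned: FaceImage
    movement_intensity: float
    low_movement: bool


def process_pair(
    ref: FaceImage,
    ref_lms: LandmarkSet,
    expr: FaceImage,
    expr_lms: LandmarkSet,
    cfg: RunConfig | None = None,
) -> PairResult:
    """Run the full processing chain for one expression image."""
    cfg = cfg or RunConfig()

    ref_s, ref_lms_s, _ = interocular_scale(ref, ref_lms)
    expr_s, expr_lms_s, _ = interocular_scale(expr, expr_lms)
    expr_c, expr_lms_c = center_on_canvas(expr_s, expr_lms_s, ref_s.dims)

    if cfg.alignment_dof == "affine":
        transform = estimate_affine(expr_lms_c, ref_lms_s)
    else:
        transform = estimate_alignment(expr_lms_c, ref_lms_s)
    expr_a = warp_image(expr_c, transform, ref_s.dims)

    mask = build_mask(ref_lms_s, ref_s.dims, cfg.padding_frac)
    mask = remove_brow_region(mask, ref_lms_s)

    ref_b = preblur(ref_s, cfg.preblur_kernel)
    expr_b = preblur(expr_a, cfg.preblur_kernel)
    raw = abs_diff_gray(ref_b, expr_b, mask)
    amp = cfg.amplification_overrides.get(expr.expression_index, cfg.amplification)
    dm = smooth_amplify(raw, cfg.smooth_kernel, amp)

    score_cfg = ScoreConfig(
        sigma2_max=cfg.sigma2_max, intensity_scale=cfg.intensity_scale
    )
    if cfg.variance_on_amplified:
        result = symmetry_score(dm, mask, score_cfg, expr.expression_index)
    else:
        # score the smoothed map before amplification (config alternative)
        import numpy as np

        from .diffmap import _blur

        smoothed = np.clip(np.rint(_blur(raw, cfg.smooth_kernel)), 0, 255).astype(
            np.uint8
        )
        result = symmetry_score(smoothed, mask, score_cfg, expr.expression_index)

    mi = movement_intensity(dm, mask)
    return PairResult(
        result=result,
        diffmap=dm,
        mask=mask,
        heatmap=render_heatmap(dm, cfg.colormap),
        aligned=expr_a,
        movement_intensity=mi,
        low_movement=bool(mi < cfg.movement_intensity_min),
    )


def flag_insufficient_movement(
    results: list[dict], cfg: RunConfig | None = None
) -> list[bool]:
    """Flag expressions whose movement intensity falls below the threshold.

    Flagged rows are annotated, never dropped: a hesitant expression can
    earn a deceptively high symmetry score, so the flag is interpretive
    context, not an exclusion rule.
    """
    cfg = cfg or RunConfig()
    return [r["movement_intensity"] < cfg.movement_intensity_min for r in results]


# ---------------------------------------------------------------------------
# Dataset traversal
# ---------------------------------------------------------------------------

def _load_landmarks(
    image_path: Path, image: FaceImage, cfg: RunConfig
) -> LandmarkSet:
    if cfg.provider == "replay":
        sidecar = image_path.parent / (image_path.stem + ".landmarks.json")
        if not sidecar.exists():
            raise FaceSymError(f"replay provider: no landmark sidecar for {image_path}")
        return LandmarkSet.from_json(sidecar)
    if cfg.provider == "mediapipe":
        return detect_landmarks(image, MediaPipeProvider())
    raise FaceSymError(f"unknown provider {cfg.provider!r}")


def _parse_date(name: str) -> datetime.date | None:
    try:
        return datetime.date.fromisoformat(name)
    except ValueError:
        return None


def process_visit(
    visit_dir: str | Path,
    cfg: RunConfig | None = None,
    patient_id: str = "",
    visit_date: str = "",
    out_dir: str | Path | None = None,
) -> list[dict]:
    """Score every expression image of one visit directory.

    Returns one result row per processed expression; writes aligned
    image, difference map and heatmap PNGs when `out_dir` is given.
    Missing neutral image skips the visit; a landmark failure skips only
    that expression. Both are logged.
    """
    cfg = cfg or RunConfig()
    visit_dir = Path(visit_dir)
    ref_path = visit_dir / "expr_1.png"
    if not ref_path.exists():
        logger.error("visit %s: missing neutral reference expr_1.png", visit_dir)
        return []
    ref = FaceImage.from_file(ref_path, expression_index=1)
    try:
        ref_lms = _load_landmarks(ref_path, ref, cfg)
    except FaceSymError as exc:
        logger.error("visit %s: reference landmarks failed: %s", visit_dir, exc)
        return []

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)

    rows: list[dict] = []
    for e in range(2, 10):
        img_path = visit_dir / f"expr_{e}.png"
        if not img_path.exists():
            img_path = visit_dir / f"expr_{e}.jpg"
            if not img_path.exists():
                continue
        try:
            expr = FaceImage.from_file(img_path, expression_index=e)
            expr_lms = _load_landmarks(img_path, expr, cfg)
            pair = process_pair(ref, ref_lms, expr, expr_lms, cfg)
        except FaceSymError as exc:
            logger.error("expression %d in %s skipped: %s", e, visit_dir, exc)
            continue
        rows.append(
            {
                "patient_id": patient_id,
                "visit_date": visit_date,
                "expression_index": e,
                "s_mean": pair.result.s_mean,
                "variance": pair.result.variance,
                "score": pair.result.score,
                "n_valid": pair.result.n_valid,
                "movement_intensity": pair.movement_intensity,
                "low_movement": pair.low_movement,
            }
        )
        if out_dir is not None:
            stem = f"expr_{e}"
            pair.aligned.to_file(out_dir / f"{stem}_aligned.png")
            pair.diffmap.to_png(out_dir / f"{stem}_diff.png")
            pair.heatmap.to_file(out_dir / f"{stem}_heatmap.png")
    return rows


def run_dataset(input_dir: str | Path, cfg: RunConfig | None = None) -> dict:
    """Process a cohort tree patient_id/visit_date/expr_<n>.png.

    Writes scores.csv, per-patient trends and a cohort summary JSON to
    the configured output directory and returns the report dict.
    """
    from .longitudinal import ScoreSeries, VisitScores, cohort_summary

    cfg = cfg or RunConfig()
    input_dir = Path(input_dir)
    out_root = Path(cfg.output_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    logger.info("run config: %s", json.dumps(cfg.to_dict(), default=str))

    all_rows: list[dict] = []
    for patient_dir in sorted(p for p in input_dir.iterdir() if p.is_dir()):
        for visit_dir in sorted(v for v in patient_dir.iterdir() if v.is_dir()):
            rows = process_visit(
                visit_dir,
                cfg,
                patient_id=patient_dir.name,
                visit_date=visit_dir.name,
                out_dir=out_root / patient_dir.name / visit_dir.name,
            )
            all_rows.extend(rows)

    df = pd.DataFrame(all_rows, columns=RESULT_COLUMNS)
    df.to_csv(out_root / "scores.csv", index=False)

    series_list = []
    for pid, grp in df.groupby("patient_id", sort=True):
        entries = []
        for date_str, visit in grp.groupby("visit_date", sort=True):
            date = _parse_date(str(date_str))
            if date is None:
                continue
            entries.append(
                VisitScores(
                    date=date,
                    scores={
                        int(r.expression_index): float(r.score)
                        for r in visit.itertuples()
                    },
                )
            )
        if entries:
            series_list.append(ScoreSeries(patient_id=str(pid), entries=entries))

    summary = cohort_summary(
        series_list,
        aggregate=cfg.aggregate,
        window=cfg.rolling_window,
        threshold=cfg.trend_threshold,
        time_axis=cfg.time_axis,
    )
    summary["n_result_rows"] = len(df)
    summary["n_low_movement_flags"] = int(df["low_movement"].sum()) if len(df) else 0
    (out_root / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True)
    )
    return summary
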