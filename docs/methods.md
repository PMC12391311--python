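# Methods

## Processing model

Each dataset is one visit: a neutral-reference photograph (index 1) and
up to eight standardized expression photographs (indices 2–9). All
geometry is in 0-based pixel coordinates, origin top-left, x rightward,
y downward; a point (x, y) addresses pixel (floor(x), floor(y)), and a
pixel's center is (col + 0.5, row + 0.5).

1. **Landmarks.** A provider conforming to the 478-point face-mesh
   contract supplies landmarks per image. Providers returning
   normalized [0, 1] coordinates are converted to pixels by
   multiplying by image width/height. A provider returning no face is
   an explicit per-image failure; returning ≠ 478 points is a contract
   violation. The z coordinate, if emitted, is discarded.
2. **Interocular scaling.** Faces are uniformly rescaled until the
   outer eye corners (face-mesh indices 33 and 263, the temporal-most
   eye points) are 200 px apart. Landmark coordinates are multiplied
   exactly by the factor; the raster is resampled bilinearly to the
   rounded size, so the rasterized distance is exact to well under
   half a pixel.
3. **Canvas centering.** The expression image is centered on a canvas
   with the reference's dimensions. The per-axis offset is
   floor((ref − src)/2) (ties toward top-left); oversized images are
   center-cropped and landmarks shifted by the same offset, possibly
   off-canvas.
4. **Alignment.** A least-squares similarity transform (translation,
   rotation, isotropic scale — 4 DOF) is estimated from all 478
   correspondences via the closed-form orthogonal-Procrustes solution
   and applied with bilinear interpolation, border fill 0. The
   4-DOF model matches the enumeration "translation, rotation,
   scaling"; a full 6-DOF affine is available via
   `alignment_dof = "affine"` but off by default. Centering precedes
   alignment estimation, following the listed processing order. The
   downstream 111×111 blur makes the interpolation choice immaterial;
   bilinear is the cheapest smooth option.
5. **Mask.** From 9 landmarks (eye corners 33/133/362/263, nose bridge
   1, nose tip 0, lip centers 13/14, chin 152): an axis-aligned
   rectangle spanning the eye-corner x-extent padded by
   `padding_frac` (default 0.10 per side) of the unpadded width,
   running from the eyebrow cut line to the vertical midpoint between
   the eye line and the padded chin; below that midpoint, a
   half-ellipse whose vertical semi-axis reaches the padded chin. The
   eyebrow cut is a single horizontal line at the lowest of the ten
   face-mesh brow landmarks {70, 63, 105, 66, 107, 336, 296, 334, 293,
   300}; everything above it is removed so hair movement cannot enter
   the score. A pixel is foreground when its center lies inside the
   analytic shape, which makes the mask exactly equivariant under
   integer landmark translations. The mirror midline is the mean x of
   the midline landmarks {1, 0, 13, 14, 152} — robust to asymmetric
   mask extents caused by palsy, unlike a bounding-box center.
6. **Difference image.** Both masked images receive a 5×5 Gaussian
   pre-blur (suppressing facial-hair/skin texture); the absolute
   per-channel difference is collapsed to grayscale with luma weights
   0.299/0.587/0.114, smoothed with a 111×111 Gaussian, multiplied by
   5 and clipped at 255. Gaussian σ follows the kernel-size convention
   σ = 0.3·((k−1)/2 − 1) + 0.8 with an explicit radius of (k−1)/2 and
   reflect border padding (zero padding would inject dark halos at the
   frame edge into the score). Clipping happens at the amplification
   step, so a smoothed difference of 51 is the saturation onset
   (51 × 5 = 255). The heatmap maps 0 → blue, 255 → red through an
   HSV hue ramp (240°→0°) whose red channel is non-decreasing and blue
   non-increasing; any matplotlib colormap can be selected instead.
7. **Score.** See README for the equations. Normalization choices the
   equations leave open: the mean absolute difference is divided by
   255 so S_mean ∈ [0, 1], while σ² stays on the raw 0–255 scale where
   the default ceiling σ²_max = 5000 is meaningful; both constants are
   config fields. The variance is the population variance (divide by
   N). The score is computed on the amplified, clipped map by default
   (`variance_on_amplified = false` scores the smoothed map before
   amplification instead). Pairing: a pixel is "left" when its center
   is strictly left of the midline; its partner is the pixel containing
   the mirrored center, required to be mask-foreground and strictly
   right of the midline. This excludes the column straddling the
   midline (no self-pairing) yet degenerates to clean full pairing when
   the midline falls on a pixel boundary. "Left" means image-left;
   clinical laterality is metadata only.
8. **Movement intensity.** The mean amplified difference inside the
   mask. Expressions with intensity below `movement_intensity_min`
   (default 5.0 of 255, a pragmatic floor an order of magnitude below
   typical well-performed expressions on the synthetic fixtures) are
   flagged as possibly hesitant — annotated, never excluded, since a
   low-movement expression can earn a deceptively high score and should
   be read alongside its heatmap.
9. **Trends.** The per-visit aggregate is the mean over available
   expression scores (config: median, or a single expression). Series
   with ≥ 3 visits pass through a centered window-3 rolling median
   (shrunken asymmetric windows at the ends keep the length); shorter
   series are used unfiltered. The Theil–Sen slope is taken over the
   examination index 0, 1, 2, … by default — the ±0.001 threshold is
   unitless per examination step — with days-since-baseline as a
   config option. Threshold comparisons are strict, so boundary slopes
   fall to "no significant change". Grade validation uses Spearman's
   rank correlation with average-rank ties and the t-approximation
   p-value (standard at the cohort sizes involved; exact inference
   would matter only below ~10 pairs).

## Synthetic fixtures

The generator draws faces as flat-shaded analytic primitives (face
ellipse, eye/mouth ellipses, brow bars, nose band, nostril disks) with
mild seeded texture noise shared between the neutral and expression
images, so every pixel difference is structural. Each expression index
displaces exactly its feature group; the asymmetry parameter a ∈ [0, 1]
attenuates the image-right displacement by (1 − a), emulating
unilateral palsy with a known severity: a = 0 yields an exactly
mirror-symmetric difference (the canvas width is even so pixel centers
mirror onto pixel centers), a = 1 freezes the right side bit-exactly.
The 478-point template pins the named indices to their analytic
positions and distributes the rest along the face outline so
whole-set alignment is exercised. Default canvas 360×480 px with a
template interocular distance of ≈167 px, i.e. the scaling step is a
non-trivial ≈1.2× resample; displacement magnitudes are set so a
well-performed expression drives the smoothed difference into the
heatmap's saturating range, as real expressions do.

What the fixtures deliberately lack: photographic texture, shading,
pose and illumination variation, detector noise, occlusion, and any
interaction between the landmark model and palsy. Passing tests
therefore validate the pipeline's geometry and arithmetic and its
monotone response to controlled asymmetry — not detector robustness on
clinical photographs.

## Numerical choices and degenerate inputs

- All blurs use float64 internally; rasters are rounded back to uint8
  at stage boundaries, so constant images are exactly preserved.
- Coincident eye corners, all-coincident landmark sets and
  zero-extent mask landmarks raise `DegenerateGeometryError`; an empty
  pairing (mask entirely on one side) raises `ZeroValidPairsError`
  rather than returning a default score.
- Even blur kernels and non-positive normalizers are rejected at
  configuration time.
- Test problem sizes: score-oracle cross-checks run on ≤16×16 rasters
  (1000 random instances), alignment recovery on 100 random transforms,
  end-to-end monotonicity on the 8 expressions × 5 asymmetry levels of
  the default 360×480 fixture, and slope recovery on 1000 simulated
  series of 8 visits.

## Known limitations

- The score inherits alignment quality: gross head-pose differences
  between reference and expression show up as inflated differences.
- A hesitant expression yields high symmetry with low movement; the
  intensity flag marks, but cannot correct, such visits.
- Baseline (resting) asymmetry is invisible by design — the method
  measures dynamic change from the patient's own neutral state.
- The replay provider trusts its stored coordinates; only the external
  face-mesh model path performs actual detection, and it is exercised
  only when that optional dependency is installed.
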