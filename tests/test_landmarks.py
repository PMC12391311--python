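"""Landmark geometry: scaling, centering, alignment estimation, warping."""

import numpy as np
import pytest

from facesym import (
    DegenerateGeometryError,
    FaceImage,
    LandmarkSet,
    NoFaceDetectedError,
    ProviderContractError,
    ReplayProvider,
    SimilarityTransform,
    center_on_canvas,
    detect_landmarks,
    estimate_alignment,
    interocular_scale,
    warp_image,
)
from facesym.landmarks import LEFT_EYE_OUTER, N_LANDMARKS, RIGHT_EYE_OUTER


def _image(w=64, h=64, value=128):
    return FaceImage(np.full((h, w, 3), value, dtype=np.uint8))


def _similarity_points(points, scale, rot, trans):
    c, s = np.cos(rot), np.sin(rot)
    r = np.array([[c, -s], [s, c]])
    return scale * points @ r.T + np.asarray(trans)


class TestProviders:
    def test_replay_provider_returns_stored_template_verbatim(self, template_landmarks):
        img = _image()
        provider = ReplayProvider({id(img): template_landmarks})
        got = detect_landmarks(img, provider)
        np.testing.assert_array_equal(got.points, template_landmarks.points)
        assert got.points.shape == (N_LANDMARKS, 2)

    def test_no_face_raises_named_error(self):
        img = _image()
        with pytest.raises(NoFaceDetectedError):
            detect_landmarks(img, ReplayProvider({}))

    def test_wrong_point_count_is_contract_violation(self):
        with pytest.raises(ProviderContractError):
            LandmarkSet(points=np.zeros((68, 2)), source_dims=(64, 64))

    def test_normalized_coordinates_scale_by_image_dims(self):
        norm = np.full((N_LANDMARKS, 2), 0.5)
        lms = LandmarkSet.from_normalized(norm, (200, 100))
        np.testing.assert_allclose(lms.points, [[100.0, 50.0]] * N_LANDMARKS)

    def test_csv_json_round_trip(self, template_landmarks, tmp_path):
        template_landmarks.to_csv(tmp_path / "lms.csv")
        back = LandmarkSet.from_csv(tmp_path / "lms.csv", template_landmarks.source_dims)
        np.testing.assert_array_equal(back.points, template_landmarks.points)
        template_landmarks.to_json(tmp_path / "lms.json")
        back = LandmarkSet.from_json(tmp_path / "lms.json")
        np.testing.assert_array_equal(back.points, template_landmarks.points)
        assert back.source_dims == template_landmarks.source_dims


class TestInterocularScale:
    @pytest.mark.parametrize("distance", [50.0, 100.0, 137.0, 400.0])
    def test_post_scaling_distance_is_200(self, template_landmarks, distance):
        base = template_landmarks
        factor0 = distance / base.interocular_distance()
        pts = base.points * factor0
        w = max(64, int(base.source_dims[0] * factor0) + 1)
        h = max(64, int(base.source_dims[1] * factor0) + 1)
        lms = LandmarkSet(points=pts, source_dims=(w, h))
        assert lms.interocular_distance() == pytest.approx(distance)
        img = _image(w, h)
        _, out_lms, factor = interocular_scale(img, lms)
        assert out_lms.interocular_distance() == pytest.approx(200.0, abs=1e-9)
        assert factor == pytest.approx(200.0 / distance)

    def test_distance_100_gives_factor_2(self, template_landmarks):
        factor0 = 100.0 / template_landmarks.interocular_distance()
        lms = LandmarkSet(points=template_landmarks.points * factor0, source_dims=(256, 256))
        img = _image(256, 256)
        out_img, out_lms, factor = interocular_scale(img, lms)
        assert factor == pytest.approx(2.0)
        assert out_img.dims == (512, 512)

    def test_exact_200_is_identity(self, template_landmarks):
        factor0 = 200.0 / template_landmarks.interocular_distance()
        lms = LandmarkSet(points=template_landmarks.points * factor0, source_dims=(600, 600))
        img = _image(600, 600)
        out_img, _, factor = interocular_scale(img, lms)
        assert factor == pytest.approx(1.0)
        np.testing.assert_array_equal(out_img.raster, img.raster)

    def test_idempotent(self, template_landmarks):
        img = _image(*template_landmarks.source_dims)
        img1, lms1, _ = interocular_scale(img, template_landmarks)
        _, lms2, factor2 = interocular_scale(img1, lms1)
        assert factor2 == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(lms2.points, lms1.points, atol=1e-9)

    def test_coincident_eye_corners_raise(self):
        pts = np.ones((N_LANDMARKS, 2))
        lms = LandmarkSet(points=pts, source_dims=(64, 64))
        with pytest.raises(DegenerateGeometryError):
            interocular_scale(_image(), lms)


class TestCenterOnCanvas:
    def test_same_dims_is_identity(self, template_landmarks):
        img = _image(*template_landmarks.source_dims)
        out_img, out_lms = center_on_canvas(img, template_landmarks, img.dims)
        np.testing.assert_array_equal(out_img.raster, img.raster)
        np.testing.assert_array_equal(out_lms.points, template_landmarks.points)

    def test_pad_offset_is_floor_half_difference(self):
        rng = np.random.default_rng(0)
        raster = rng.integers(0, 256, (100, 100, 3), dtype=np.uint8)
        img = FaceImage(raster)
        lms = LandmarkSet(points=rng.uniform(0, 100, (N_LANDMARKS, 2)), source_dims=(100, 100))
        out_img, out_lms = center_on_canvas(img, lms, (200, 200))
        assert out_img.dims == (200, 200)
        np.testing.assert_allclose(out_lms.points, lms.points + 50.0)
        np.testing.assert_array_equal(out_img.raster[50:150, 50:150], raster)

    def test_crop_keeps_central_block(self):
        rng = np.random.default_rng(1)
        raster = rng.integers(0, 256, (300, 300, 3), dtype=np.uint8)
        img = FaceImage(raster)
        lms = LandmarkSet(points=rng.uniform(0, 300, (N_LANDMARKS, 2)), source_dims=(300, 300))
        out_img, out_lms = center_on_canvas(img, lms, (200, 200))
        np.testing.assert_array_equal(out_img.raster, raster[50:250, 50:250])
        np.testing.assert_allclose(out_lms.points, lms.points - 50.0)

    def test_relative_geometry_preserved(self, template_landmarks):
        img = _image(*template_landmarks.source_dims)
        _, out_lms = center_on_canvas(img, template_landmarks, (500, 700))
        d_before = np.linalg.norm(
            template_landmarks.points[None] - template_landmarks.points[:, None], axis=-1
        )
        d_after = np.linalg.norm(out_lms.points[None] - out_lms.points[:, None], axis=-1)
        np.testing.assert_allclose(d_after, d_before, atol=1e-9)


class TestEstimateAlignment:
    def test_identity_on_equal_sets(self, template_landmarks):
        t = estimate_alignment(template_landmarks, template_landmarks)
        assert t.scale == pytest.approx(1.0, abs=1e-9)
        assert t.rotation == pytest.approx(0.0, abs=1e-9)
        assert t.translation == pytest.approx((0.0, 0.0), abs=1e-9)

    def test_recovers_rotation_about_centroid_plus_translation(self, template_landmarks):
        src = template_landmarks
        rot = np.deg2rad(10.0)
        centroid = src.points.mean(axis=0)
        dst_pts = _similarity_points(src.points - centroid, 1.0, rot, centroid + [5.0, -3.0])
        dst = LandmarkSet(points=dst_pts, source_dims=src.source_dims)
        t = estimate_alignment(src, dst)
        assert t.rotation == pytest.approx(rot, abs=1e-6)
        assert t.scale == pytest.approx(1.0, abs=1e-6)
        np.testing.assert_allclose(t.apply(src.points), dst_pts, atol=1e-6)
        # the centroid displacement equals the injected (5, -3) translation
        np.testing.assert_allclose(dst_pts.mean(axis=0) - centroid, [5.0, -3.0], atol=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_exact_recovery_against_procrustes_oracle(self, template_landmarks, seed):
        """Noiseless recovery matches the independent least-squares solution."""
        from skimage.transform import SimilarityTransform as SkSimilarity

        rng = np.random.default_rng(seed)
        scale = rng.uniform(0.5, 2.0)
        rot = np.deg2rad(rng.uniform(-30.0, 30.0))
        trans = rng.uniform(-40.0, 40.0, 2)
        src = template_landmarks
        dst_pts = _similarity_points(src.points, scale, rot, trans)
        t = estimate_alignment(src, LandmarkSet(points=dst_pts, source_dims=src.source_dims))
        assert t.scale == pytest.approx(scale, abs=1e-6)
        assert t.rotation == pytest.approx(rot, abs=1e-6)
        np.testing.assert_allclose(t.translation, trans, atol=1e-6)

        if hasattr(SkSimilarity, "from_estimate"):
            oracle = SkSimilarity.from_estimate(src.points, dst_pts)
        else:  # older scikit-image
            oracle = SkSimilarity()
            assert oracle.estimate(src.points, dst_pts)
        np.testing.assert_allclose(t.matrix, oracle.params, atol=1e-6)

    def test_noisy_recovery_within_three_sigma(self, template_landmarks):
        """Monte-Carlo: jitter sigma=0.5 px recovers translation to 3*sigma/sqrt(478)."""
        src = template_landmarks
        centroid = src.points.mean(axis=0)
        tol = 3.0 * 0.5 / np.sqrt(N_LANDMARKS)
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            scale = rng.uniform(0.8, 1.25)
            rot = np.deg2rad(rng.uniform(-15.0, 15.0))
            trans = rng.uniform(-20.0, 20.0, 2)
            dst_pts = _similarity_points(
                src.points - centroid, scale, rot, centroid + trans
            )
            dst_pts = dst_pts + rng.normal(0.0, 0.5, dst_pts.shape)
            t = estimate_alignment(src, LandmarkSet(points=dst_pts, source_dims=src.source_dims))
            est_trans = t.apply(centroid[None])[0] - centroid
            if (
                abs(est_trans[0] - trans[0]) <= tol
                and abs(est_trans[1] - trans[1]) <= tol
                and abs(t.rotation - rot) <= tol
                and abs(t.scale - scale) <= tol
            ):
                hits += 1
        assert hits >= 0.95 * n_seeds

    def test_degenerate_source_raises(self):
        pts = np.full((N_LANDMARKS, 2), 7.0)
        lms = LandmarkSet(points=pts, source_dims=(64, 64))
        with pytest.raises(DegenerateGeometryError):
            estimate_alignment(lms, lms)

    def test_transform_inverse_round_trip(self):
        t = SimilarityTransform(scale=1.7, rotation=0.4, translation=(12.0, -8.0))
        pts = np.random.default_rng(3).uniform(-50, 50, (100, 2))
        np.testing.assert_allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-9)
        np.testing.assert_allclose(
            t.compose(t.inverse()).matrix, np.eye(3), atol=1e-9
        )


class TestWarpImage:
    def test_identity_is_bit_exact(self):
        rng = np.random.default_rng(5)
        img = FaceImage(rng.integers(0, 256, (40, 60, 3), dtype=np.uint8))
        out = warp_image(img, SimilarityTransform.identity(), img.dims)
        np.testing.assert_array_equal(out.raster, img.raster)

    def test_integer_translation_shifts_pixels(self):
        rng = np.random.default_rng(6)
        img = FaceImage(rng.integers(0, 256, (40, 60, 3), dtype=np.uint8))
        t = SimilarityTransform(translation=(10.0, 0.0))
        out = warp_image(img, t, img.dims)
        np.testing.assert_array_equal(out.raster[:, 10:], img.raster[:, :-10])
        assert np.all(out.raster[:, :10] == 0)

    def test_rotation_round_trip_recovers_interior(self):
        rng = np.random.default_rng(7)
        base = np.zeros((80, 80, 3), dtype=np.uint8)
        base[20:60, 20:60] = rng.integers(0, 256, (40, 40, 3), dtype=np.uint8)
        img = FaceImage(base)
        # rotate 90 degrees about the image center
        c = 40.0
        rot = np.pi / 2.0
        t = SimilarityTransform(
            rotation=rot,
            translation=(
                c - c * np.cos(rot) + c * np.sin(rot),
                c - c * np.sin(rot) - c * np.cos(rot),
            ),
        )
        rotated = warp_image(img, t, img.dims)
        assert not np.array_equal(rotated.raster, img.raster)
        back = warp_image(rotated, t.inverse(), img.dims)
        interior = (slice(25, 55), slice(25, 55))
        diff = np.abs(
            back.raster[interior].astype(int) - img.raster[interior].astype(int)
        )
        assert diff.max() <= 2
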