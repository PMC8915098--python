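import numpy as np
import pytest

from fundusmosaic.geometry import Circle, Frame, Homography
from fundusmosaic.mosaic import (
    BlendField,
    InsufficientMatchesError,
    KeypointSet,
    MatchSet,
    blend,
    compute_blend_weights,
    detect_and_describe,
    estimate_homography,
    match_descriptors,
    mosaic_sequence,
    warp_to_reference,
)
from fundusmosaic.synthetic import make_fundus_frame, make_sequence


def unit_descriptors(rng, n):
    d = rng.normal(size=(n, 128))
    return d / np.linalg.norm(d, axis=1, keepdims=True)


class TestDetectAndDescribe:
    def test_constant_image_no_keypoints(self):
        kp = detect_and_describe(np.full((64, 64, 3), 120, dtype=np.uint8))
        assert len(kp) == 0

    def test_descriptors_unit_l2(self, small_scene):
        kp = detect_and_describe(small_scene.image)
        assert len(kp) > 20
        norms = np.linalg.norm(kp.descriptors, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-6)

    def test_rotated_copy_matches(self, small_scene):
        img = small_scene.image[:320, :320]  # square so rot90 keeps the shape
        rot = np.rot90(img).copy()
        kp_a = detect_and_describe(img)
        kp_b = detect_and_describe(rot)
        matches = match_descriptors(kp_a, kp_b, ratio=0.8)
        assert len(matches) >= 10
        dists = np.array([d for _, _, d in matches.pairs])
        assert np.median(dists) < 0.3
        # rot90 CCW maps (x, y) -> (y, W-1-x); verify matched locations agree
        w = img.shape[1]
        good = 0
        for i, j, _ in matches.pairs:
            x, y = kp_a.locations[i]
            ex, ey = y, w - 1 - x
            if np.hypot(*(kp_b.locations[j] - (ex, ey))) < 2.0:
                good += 1
        assert good / len(matches) > 0.8


class TestMatchDescriptors:
    def test_identical_sets_self_matched(self):
        rng = np.random.default_rng(1)
        desc = unit_descriptors(rng, 20)
        locs = rng.uniform(0, 100, size=(20, 2))
        kp = KeypointSet(locs, desc)
        matches = match_descriptors(kp, kp, ratio=0.8)
        assert len(matches) == 20
        assert all(i == j for i, j, _ in matches.pairs)

    def test_disjoint_random_sets_near_empty(self):
        rng = np.random.default_rng(2)
        a = KeypointSet(rng.uniform(0, 10, (40, 2)), unit_descriptors(rng, 40))
        b = KeypointSet(rng.uniform(0, 10, (40, 2)), unit_descriptors(rng, 40))
        matches = match_descriptors(a, b, ratio=0.8)
        assert len(matches) <= 4  # ratio test rejects near-orthogonal noise

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        a = KeypointSet(rng.uniform(0, 10, (5, 2)), unit_descriptors(rng, 5))
        b = KeypointSet(rng.uniform(0, 10, (5, 2)), unit_descriptors(rng, 5))
        ratio = 0.9

        # oracle: full distance table, ratio test, per-following uniqueness
        table = np.sqrt(
            ((a.descriptors[:, None, :] - b.descriptors[None, :, :]) ** 2).sum(-1)
        )
        expected = {}
        for i in range(5):
            order = np.argsort(table[i])
            if table[i, order[0]] / table[i, order[1]] < ratio:
                j = int(order[0])
                if j not in expected or table[i, j] < expected[j][1]:
                    expected[j] = (i, table[i, j])
        expected_pairs = sorted((i, j) for j, (i, _) in expected.items())

        got = match_descriptors(a, b, ratio=ratio)
        assert sorted((i, j) for i, j, _ in got.pairs) == expected_pairs

    def test_each_following_keypoint_at_most_once(self, small_scene):
        kp = detect_and_describe(small_scene.image)
        matches = match_descriptors(kp, kp, ratio=1.0)
        followings = [j for _, j, _ in matches.pairs]
        assert len(followings) == len(set(followings))

    def test_bad_ratio_rejected(self):
        kp = KeypointSet.empty()
        with pytest.raises(ValueError):
            match_descriptors(kp, kp, ratio=0.0)


class TestEstimateHomography:
    def test_identical_pair_identity(self, small_scene):
        kp = detect_and_describe(small_scene.image)
        matches = match_descriptors(kp, kp, ratio=0.99)
        est = estimate_homography(matches, kp, kp)
        np.testing.assert_allclose(est.homography.h, np.eye(3), atol=1e-3)

    def test_known_warp_recovered(self):
        scene = make_fundus_frame(400, 400, Circle(200, 200, 170), n_vessels=8, seed=4)
        seq = make_sequence(scene, 2, max_shift=12, max_rot_deg=3, seed=5)
        kp0 = detect_and_describe(seq.frames[0].pixels)
        kp1 = detect_and_describe(seq.frames[1].pixels)
        matches = match_descriptors(kp0, kp1)
        est = estimate_homography(matches, kp0, kp1)
        corners = np.array([[0, 0], [400, 0], [400, 400], [0, 400]], float)
        gt = seq.gt_homographies[1]
        err = np.linalg.norm(est.homography.apply(corners) - gt.apply(corners), axis=1)
        assert err.max() < 1.0

    def test_three_matches_rejected(self):
        rng = np.random.default_rng(6)
        kp = KeypointSet(rng.uniform(0, 10, (5, 2)), unit_descriptors(rng, 5))
        m = MatchSet([(0, 0, 0.1), (1, 1, 0.1), (2, 2, 0.1)])
        with pytest.raises(InsufficientMatchesError):
            estimate_homography(m, kp, kp)


class TestWarpToReference:
    def test_identity_unchanged(self, small_scene):
        img = small_scene.image
        out, mask = warp_to_reference(img, Homography.identity(), 420, 320)
        np.testing.assert_array_equal(out, img)
        assert np.all(mask == 1)

    def test_translation_shifts_content(self, small_scene):
        img = small_scene.image
        t = np.eye(3)
        t[0, 2], t[1, 2] = 10, 5
        out, mask = warp_to_reference(img, Homography(t), 440, 340)
        np.testing.assert_array_equal(out[5:325, 10:430], img)
        assert mask.sum() == 320 * 420  # area preserved, no clipping here

    def test_roundtrip_interpolation_tolerance(self, small_scene):
        img = small_scene.image
        t = np.array([[0.999, 0.02, 7.3], [-0.02, 0.999, -4.1], [0, 0, 1.0]])
        h = Homography(t)
        fwd, _ = warp_to_reference(img, h, 460, 360)
        back, mask = warp_to_reference(fwd, h.inverse(), 420, 320)
        interior = np.zeros((320, 420), dtype=bool)
        interior[20:300, 20:400] = True
        interior &= mask.astype(bool)
        diff = np.abs(back.astype(float) - img.astype(float))[interior]
        assert diff.mean() < 2.0


class TestBlendWeights:
    def test_one_dimensional_toy(self):
        m1 = np.zeros((1, 9), dtype=np.uint8)
        m2 = np.zeros((1, 9), dtype=np.uint8)
        m1[0, 0:6] = 1  # columns 0-5
        m2[0, 3:9] = 1  # columns 3-8; overlap 3-5
        f = compute_blend_weights(m1, m2)
        np.testing.assert_array_equal(f.R[0], [0, 0, 0, 1, 1, 1, 0, 0, 0])
        # column 4: d1 = 2 (to col 2), d2 = 2 (to col 6)
        assert f.d1[0, 4] == 2 and f.d2[0, 4] == 2
        assert f.w1[0, 4] == pytest.approx(0.5)
        # column 3: d1 = 1, d2 = 3
        assert f.w1[0, 3] == pytest.approx(0.75)
        assert f.w2[0, 3] == pytest.approx(0.25)

    def test_exclusive_regions_weight_one(self):
        m1 = np.zeros((1, 9), dtype=np.uint8)
        m2 = np.zeros((1, 9), dtype=np.uint8)
        m1[0, 0:6] = 1
        m2[0, 3:9] = 1
        f = compute_blend_weights(m1, m2)
        assert np.all(f.w1[0, 0:3] == 1.0) and np.all(f.w2[0, 0:3] == 0.0)
        assert np.all(f.w2[0, 6:9] == 1.0) and np.all(f.w1[0, 6:9] == 0.0)

    def test_partition_of_unity_random_geometries(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            h, w = rng.integers(8, 40, size=2)
            m1 = np.zeros((h, w), dtype=np.uint8)
            m2 = np.zeros((h, w), dtype=np.uint8)
            y0, x0 = rng.integers(0, h // 2), rng.integers(0, w // 2)
            m1[y0 : y0 + h // 2 + 1, x0 : x0 + w // 2 + 1] = 1
            y1, x1 = rng.integers(0, h // 2), rng.integers(0, w // 2)
            m2[y1 : y1 + h // 2 + 1, x1 : x1 + w // 2 + 1] = 1
            f = compute_blend_weights(m1, m2)
            R = f.R.astype(bool)
            if R.any():
                assert np.abs(f.w1[R] + f.w2[R] - 1.0).max() < 1e-6
            assert np.all(f.w1[f.m1 == 0] == 0)
            assert np.all(f.w2[f.m2 == 0] == 0)

    def test_fully_contained_image_uniform_half(self, caplog):
        m1 = np.ones((10, 10), dtype=np.uint8)
        m2 = np.zeros((10, 10), dtype=np.uint8)
        m2[2:6, 2:6] = 1  # m2 entirely inside the overlap
        f = compute_blend_weights(m1, m2)
        R = f.R.astype(bool)
        assert np.all(f.w1[R] == 0.5) and np.all(f.w2[R] == 0.5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_blend_weights(np.ones((3, 3)), np.ones((4, 4)))


class TestBlend:
    def _field(self, w1, w2, m1=None, m2=None):
        shape = w1.shape
        one = np.ones(shape, dtype=np.uint8)
        return BlendField(
            m1 if m1 is not None else one,
            m2 if m2 is not None else one,
            one, np.zeros(shape), np.zeros(shape), w1, w2,
        )

    def test_identical_images_identity(self):
        rng = np.random.default_rng(8)
        img = rng.integers(0, 256, size=(6, 6, 3), dtype=np.uint8)
        w1 = np.full((6, 6), 0.37)
        f = self._field(w1, 1.0 - w1)
        np.testing.assert_array_equal(blend(img, img, f), img)

    def test_weighted_sum_arithmetic(self):
        I1 = np.full((1, 1, 3), 200, dtype=np.uint8)
        I2 = np.full((1, 1, 3), 100, dtype=np.uint8)
        f = self._field(np.array([[0.75]]), np.array([[0.25]]))
        assert np.all(blend(I1, I2, f) == 175)

    def test_outside_both_masks_zero(self):
        I1 = np.full((2, 2, 3), 200, dtype=np.uint8)
        f = self._field(np.zeros((2, 2)), np.zeros((2, 2)))
        assert np.all(blend(I1, I1, f) == 0)

    def test_shape_mismatch_rejected(self):
        f = self._field(np.ones((2, 2)), np.zeros((2, 2)))
        with pytest.raises(ValueError):
            blend(np.zeros((2, 2, 3)), np.zeros((3, 3, 3)), f)


class TestMosaicSequence:
    def test_same_image_twice_identity(self, small_frame):
        res = mosaic_sequence([small_frame, small_frame])
        assert res.canvas.shape == small_frame.pixels.shape
        np.testing.assert_array_equal(res.canvas, small_frame.pixels)
        assert res.homographies[0] is not None
        np.testing.assert_allclose(res.homographies[1].h, np.eye(3), atol=1e-2)

    def test_sequence_geometry_and_growth(self):
        scene = make_fundus_frame(400, 400, Circle(200, 200, 160), n_vessels=8, seed=9)
        seq = make_sequence(scene, 3, max_shift=25, max_rot_deg=4, seed=10)
        res = mosaic_sequence(seq.frames)
        # landmarks inside the retina reproject within 2 px of ground truth
        rng = np.random.default_rng(11)
        ang = rng.uniform(0, 2 * np.pi, 15)
        rad = rng.uniform(0, 0.8 * 160, 15)
        pts = np.stack([200 + rad * np.cos(ang), 200 + rad * np.sin(ang)], axis=1)
        for i in range(1, 3):
            est, gt = res.homographies[i], seq.gt_homographies[i]
            assert est is not None
            p_i = gt.inverse().apply(pts)
            assert np.abs(est.apply(p_i) - gt.apply(p_i)).max() < 2.0
        # mosaic valid area at least any single input's
        assert res.valid_mask.sum() >= 400 * 400

    def test_black_frame_skipped_ablation_equality(self, small_frame):
        scene = make_fundus_frame(400, 400, Circle(200, 200, 160), n_vessels=8, seed=12)
        seq = make_sequence(scene, 2, max_shift=15, max_rot_deg=3, seed=13)
        black = Frame(np.zeros((400, 400, 3), dtype=np.uint8), index=99)
        with_black = mosaic_sequence([seq.frames[0], black, seq.frames[1]])
        without = mosaic_sequence(seq.frames)
        assert with_black.homographies[1] is None
        np.testing.assert_array_equal(with_black.canvas, without.canvas)

    def test_single_image_rejected(self, small_frame):
        with pytest.raises(ValueError):
            mosaic_sequence([small_frame])
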