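"""Registration, rolling-ball background, and autofluorescence removal."""

import numpy as np
import pytest
from scipy import ndimage

from hifi.align import (
    PlanarTransform,
    align_experiment,
    apply_transform,
    estimate_transform,
    rolling_ball_subtract,
    subtract_autofluorescence,
    _warp,
)
from hifi.stack import ChannelImage
from hifi.synthetic import FixtureSpec, make_cyclic_rounds


def _nuclei_image(shape=(512, 512), seed=0, n=150, pixel_size=0.5):
    r = np.random.default_rng(seed)
    img = np.zeros(shape, np.float32)
    ys = r.uniform(30, shape[0] - 30, n)
    xs = r.uniform(30, shape[1] - 30, n)
    for y, x in zip(ys, xs):
        yi, xi = int(y), int(x)
        sl = np.s_[max(0, yi - 12) : yi + 13, max(0, xi - 12) : xi + 13]
        py, px = np.mgrid[sl]
        img[sl] += 3000 * np.exp(-((py - y) ** 2 + (px - x) ** 2) / (2 * 3.5**2))
    img += r.poisson(40, shape)
    return ChannelImage(img, pixel_size, "DAPI"), np.column_stack([ys, xs])


class TestRollingBall:
    def test_constant_image_maps_to_zero(self):
        img = ChannelImage(np.full((128, 128), 500.0), 1.0)
        assert np.all(rolling_ball_subtract(img, 75).pixels == 0)

    def test_isolated_spot_preserved(self):
        im = np.zeros((256, 256))
        im[100:103, 100:103] = 2000.0
        out = rolling_ball_subtract(ChannelImage(im, 1.0), 75)
        np.testing.assert_allclose(out.pixels[100:103, 100:103], 2000.0, rtol=0.01)

    def test_gradient_removed_spots_recovered(self):
        yy, xx = np.mgrid[0:256, 0:256]
        grad = 0.4 * yy + 0.2 * xx
        spots = np.zeros((256, 256))
        for y, x in [(60, 70), (180, 120), (120, 200)]:
            spots[y : y + 3, x : x + 3] = 3000.0
        out = rolling_ball_subtract(ChannelImage(grad + spots, 1.0), 75)
        assert np.abs(out.pixels - spots).max() < 0.02 * 3000

    def test_matches_direct_morphological_oracle(self):
        # small ball: implementation takes the direct path and must equal
        # the reference rolling-ball filter exactly
        from skimage.restoration import rolling_ball as sk_ball

        r = np.random.default_rng(3)
        im = ndimage.gaussian_filter(r.uniform(0, 1000, (96, 96)), 3)
        out = rolling_ball_subtract(ChannelImage(im, 1.0), 20)
        expected = np.clip(im - sk_ball(im, radius=10), 0, None)
        np.testing.assert_allclose(out.pixels, expected, atol=1e-6)

    def test_ball_below_two_pixels_rejected(self):
        with pytest.raises(ValueError):
            rolling_ball_subtract(ChannelImage(np.zeros((8, 8)), pixel_size=10.0), 15)


class TestEstimateTransform:
    def test_self_alignment_is_identity(self):
        ref, _ = _nuclei_image(seed=1)
        t = estimate_transform(ref, ref, "rigid")
        np.testing.assert_allclose(t.linear, np.eye(2), atol=1e-3)
        np.testing.assert_allclose(t.translation, 0, atol=1e-3)

    def test_known_translation_recovered(self):
        ref, pts = _nuclei_image(seed=2)
        true = PlanarTransform.rigid(0.0, (17.3, -8.6))
        inv = true.inverse()
        mov = ref.with_pixels(np.clip(_warp(ref.pixels, inv.linear, inv.translation), 0, None))
        est = estimate_transform(ref, mov, "rigid")
        np.testing.assert_allclose(est.translation, [17.3, -8.6], atol=0.25)

    def test_known_rotation_recovered(self):
        ref, _ = _nuclei_image(seed=3)
        c = ((ref.shape[0] - 1) / 2, (ref.shape[1] - 1) / 2)
        true = PlanarTransform.rigid(1.5, (0, 0), c)
        inv = true.inverse()
        mov = ref.with_pixels(np.clip(_warp(ref.pixels, inv.linear, inv.translation), 0, None))
        est = estimate_transform(ref, mov, "rigid")
        angle = np.degrees(np.arctan2(est.linear[1, 0], est.linear[0, 0]))
        assert angle == pytest.approx(1.5, abs=0.05)

    def test_affine_mode_recovers_rigid_motion(self):
        ref, pts = _nuclei_image(seed=8)
        c = ((ref.shape[0] - 1) / 2, (ref.shape[1] - 1) / 2)
        true = PlanarTransform.rigid(1.0, (5.0, -3.0), c)
        inv = true.inverse()
        mov = ref.with_pixels(np.clip(_warp(ref.pixels, inv.linear, inv.translation), 0, None))
        est = estimate_transform(ref, mov, "affine")
        rec = est.apply_points(inv.apply_points(pts))
        assert np.sqrt(np.mean(np.sum((rec - pts) ** 2, axis=1))) < 0.5

    def test_constant_image_rejected(self):
        flat = ChannelImage(np.full((128, 128), 5.0), 1.0)
        with pytest.raises(ValueError, match="constant"):
            estimate_transform(flat, flat)

    def test_registered_residual_not_worse_than_unregistered(self):
        ref, _ = _nuclei_image(seed=5)
        true = PlanarTransform.rigid(1.0, (10.0, -6.0))
        inv = true.inverse()
        mov = np.clip(_warp(ref.pixels, inv.linear, inv.translation), 0, None)
        est = estimate_transform(ref, ref.with_pixels(mov), "rigid")
        unregistered = float(np.mean((mov - ref.pixels) ** 2))
        assert est.residual <= unregistered


class TestApplyTransform:
    def test_identity_unchanged(self):
        ref, _ = _nuclei_image(seed=6, shape=(128, 128), n=20)
        out = apply_transform(ref, PlanarTransform.identity())
        np.testing.assert_allclose(out.pixels, ref.pixels, atol=1e-3)

    def test_integer_shift_exact(self):
        ref, _ = _nuclei_image(seed=7, shape=(128, 128), n=20)
        t = PlanarTransform.rigid(0.0, (5.0, 0.0))
        out = apply_transform(ref, t)
        np.testing.assert_allclose(out.pixels[5:, :], ref.pixels[:-5, :], atol=1e-3)

    def test_inverse_restores_smooth_image(self):
        r = np.random.default_rng(9)
        smooth = ndimage.gaussian_filter(r.uniform(0, 1000, (256, 256)), 8)
        img = ChannelImage(smooth, 1.0)
        t = PlanarTransform.rigid(1.0, (4.2, -3.7), (127.5, 127.5))
        roundtrip = apply_transform(apply_transform(img, t), t.inverse())
        interior = np.s_[40:-40, 40:-40]
        err = np.abs(roundtrip.pixels[interior] - smooth[interior]).mean()
        assert err < 0.01 * (smooth.max() - smooth.min())

    def test_rigid_matrix_orthonormality_enforced(self):
        with pytest.raises(ValueError):
            PlanarTransform("rigid", np.array([[2.0, 0, 0], [0, 2.0, 0]]))


class TestSubtractAutofluorescence:
    def test_self_subtraction_zeroes(self):
        r = np.random.default_rng(1)
        img = ChannelImage(r.uniform(0, 1000, (64, 64)), 1.0)
        out = subtract_autofluorescence(img, img)
        assert np.all(out.pixels == 0)

    def test_zero_af_noop(self):
        r = np.random.default_rng(2)
        img = ChannelImage(r.uniform(0, 1000, (64, 64)), 1.0)
        out = subtract_autofluorescence(img, img.with_pixels(np.zeros((64, 64))))
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_constructed_sum_recovers_marker(self):
        r = np.random.default_rng(3)
        marker = r.uniform(0, 500, (64, 64))
        af = ndimage.gaussian_filter(r.uniform(0, 400, (64, 64)), 6)
        total = ChannelImage(marker + af, 1.0)
        out = subtract_autofluorescence(total, total.with_pixels(af))
        np.testing.assert_allclose(out.pixels, marker, atol=1e-9)

    def test_never_negative(self):
        img = ChannelImage(np.full((8, 8), 10.0), 1.0)
        af = ChannelImage(np.full((8, 8), 100.0), 1.0)
        assert subtract_autofluorescence(img, af).pixels.min() == 0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            subtract_autofluorescence(
                ChannelImage(np.zeros((8, 8)), 1.0), ChannelImage(np.zeros((9, 8)), 1.0)
            )


@pytest.fixture(scope="module")
def experiment():
    spec = FixtureSpec(seed=11, shape=(512, 512), n_rounds=3, channels_per_round=3, n_nuclei=120)
    return make_cyclic_rounds(spec)


class TestAlignExperiment:
    def test_landmarks_agree_after_alignment(self, experiment):
        rounds, _, gt = experiment
        result = align_experiment(rounds)
        for k in (1, 2):
            rec = result.transforms[k].apply_points(gt["landmarks"][k])
            rms = np.sqrt(np.mean(np.sum((rec - gt["landmarks_reference"]) ** 2, axis=1)))
            assert rms < 0.5

    def test_single_round_identity(self, experiment):
        rounds, _, _ = experiment
        result = align_experiment([rounds[0]])
        assert len(result.stack) == len(rounds[0])
        np.testing.assert_array_equal(
            result.stack.channels[1].pixels, rounds[0].channels[1].pixels
        )

    def test_skip_af_channel_untouched_beyond_warp(self, experiment):
        rounds, af_round, _ = experiment
        af_map = {
            c.channel_name: f"AF_{i}"
            for rnd in rounds
            for i, c in enumerate(rnd.channels)
            if i > 0
        }
        res_skip = align_experiment(
            rounds, af_round=af_round, af_map=af_map, skip_af_channels={"M2_1"}
        )
        res_plain = align_experiment(rounds)
        skip_img = res_skip.stack.channel("M2_1").pixels
        warped_only = res_plain.stack.channel("M2_1").pixels
        np.testing.assert_array_equal(skip_img, warped_only)
        # a non-exempt channel of the same round was reduced by subtraction
        assert (
            res_skip.stack.channel("M2_2").pixels.sum()
            < res_plain.stack.channel("M2_2").pixels.sum()
        )

    def test_af_map_must_cover_channels(self, experiment):
        rounds, af_round, _ = experiment
        with pytest.raises(ValueError, match="af_map"):
            align_experiment(rounds, af_round=af_round, af_map={})

    def test_dapi_kept_once_by_default(self, experiment):
        rounds, _, _ = experiment
        result = align_experiment(rounds)
        assert sum(n == "DAPI" for n in result.stack.marker_names) == 1
        all_dapi = align_experiment(rounds, keep_dapi="all")
        assert sum(n.startswith("DAPI") for n in all_dapi.stack.marker_names) == 3
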