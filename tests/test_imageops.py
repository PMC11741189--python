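import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from adipoquant import (
    BinaryMask,
    ImagePlane,
    apply_threshold,
    connected_particles,
    gaussian_blur,
    subtract_constant,
    subtract_images,
    subtract_rolling_ball,
)
from conftest import plane
from oracles import brute_force_opening, flood_fill_components


class TestImagePlane:
    def test_rejects_out_of_range_for_integer_depths(self):
        with pytest.raises(ValueError):
            ImagePlane(np.full((4, 4), 300.0), bit_depth=8)
        with pytest.raises(ValueError):
            ImagePlane(np.full((4, 4), -1.0), bit_depth=16)

    def test_float_plane_may_be_negative(self):
        p = ImagePlane(np.array([[-5.0, 3.0]]), bit_depth=32)
        assert p.pixels.min() == -5.0

    def test_rejects_bad_calibration_and_shape(self):
        with pytest.raises(ValueError):
            ImagePlane(np.zeros((4, 4)), pixel_size=0.0)
        with pytest.raises(ValueError):
            ImagePlane(np.zeros(4))


class TestSubtractConstant:
    def test_elementwise_with_clamp(self):
        img = plane([[0, 30], [70, 200]])
        out = subtract_constant(img, 50)
        assert out.pixels.tolist() == [[0, 0], [20, 150]]

    def test_exact_cancellation_and_identity(self):
        img = plane(np.full((8, 8), 50.0))
        assert not subtract_constant(img, 50).pixels.any()
        assert np.array_equal(subtract_constant(img, 0).pixels, img.pixels)

    def test_negative_offset_rejected(self):
        with pytest.raises(ValueError):
            subtract_constant(plane(np.zeros((2, 2))), -1)


class TestRollingBall:
    def test_flat_image_maps_to_zero(self):
        img = plane(np.full((64, 64), 117.0))
        assert not subtract_rolling_ball(img, 50).pixels.any()

    def test_small_spot_survives_large_radius(self):
        # a feature much narrower than the ball is signal, not background
        img = np.zeros((64, 64))
        img[30, 30:33] = 100.0
        out = subtract_rolling_ball(plane(img), 50)
        assert out.pixels[30, 30:33].tolist() == [100.0] * 3
        np.testing.assert_allclose(out.pixels, img - brute_force_opening(img, 50), atol=1e-9)

    def test_ramp_plus_spot_matches_brute_force_oracle(self):
        ramp = np.tile(np.linspace(0, 30, 64), (64, 1))
        ramp[20, 40:43] += 80.0
        out = subtract_rolling_ball(plane(ramp), 10)
        oracle = ramp - brute_force_opening(ramp, 10)
        assert np.abs(out.pixels - oracle).max() <= 1.0

    def test_bounded_and_idempotent(self, rng):
        img = rng.uniform(0, 500, (96, 96))
        once = subtract_rolling_ball(plane(img), 15)
        assert once.pixels.min() >= 0
        assert (once.pixels <= img + 1e-9).all()
        twice = subtract_rolling_ball(once, 15)
        assert np.abs(twice.pixels - once.pixels).max() < 1.0

    def test_radius_below_one_rejected(self):
        with pytest.raises(ValueError):
            subtract_rolling_ball(plane(np.zeros((4, 4))), 0)


class TestGaussianBlur:
    def test_constant_preserved(self):
        img = plane(np.full((32, 32), 7.0))
        np.testing.assert_allclose(gaussian_blur(img, 4).pixels, 7.0)

    def test_impulse_peak_matches_closed_form(self):
        img = np.zeros((129, 129))
        img[64, 64] = 1.0
        out = gaussian_blur(ImagePlane(img, 32, 1.0), 4.0)
        peak = 1.0 / (2 * np.pi * 16)
        assert abs(out.pixels[64, 64] - peak) / peak < 0.02

    def test_interior_impulse_conserves_total_intensity(self):
        img = np.zeros((129, 129))
        img[64, 64] = 1.0
        out = gaussian_blur(ImagePlane(img, 32, 1.0), 4.0)
        assert abs(out.pixels.sum() - 1.0) < 1e-6

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_blur(plane(np.zeros((4, 4))), 0.0)


class TestSubtractImages:
    def test_elementwise_signed(self):
        out = subtract_images(plane([[10.0, 5.0]]), plane([[3.0, 8.0]]))
        assert out.pixels.tolist() == [[7.0, -3.0]]
        assert out.bit_depth == 32

    def test_self_difference_is_zero(self, rng):
        a = plane(rng.uniform(0, 100, (16, 16)))
        assert not subtract_images(a, a).pixels.any()

    def test_impulse_minus_blur_gives_dog_center(self):
        img = np.zeros((129, 129))
        img[64, 64] = 1.0
        a = ImagePlane(img, 32, 1.0)
        d = subtract_images(a, gaussian_blur(a, 4.0))
        expected = 1.0 - 1.0 / (2 * np.pi * 16)
        assert abs(d.pixels[64, 64] - expected) < 1e-3

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            subtract_images(plane(np.zeros((4, 4))), plane(np.zeros((4, 5))))


class TestThreshold:
    def test_lower_bound_is_foreground(self):
        mask = apply_threshold(plane([[0.0, 2.9, 3.0, 7.0]], bit_depth=32), 3.0)
        assert mask.pixels.tolist() == [[False, False, True, True]]

    def test_minus_infinity_selects_everything(self):
        mask = apply_threshold(plane(np.zeros((4, 4))), -np.inf)
        assert mask.pixels.all()

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        img=arrays(np.float64, (12, 12), elements=st.floats(-50, 50)),
        t1=st.floats(-40, 40),
        dt=st.floats(0.1, 40),
    )
    def test_foreground_shrinks_monotonically(self, img, t1, dt):
        p = ImagePlane(img, 32, 1.0)
        lo = apply_threshold(p, t1).pixels
        hi = apply_threshold(p, t1 + dt).pixels
        assert (hi <= lo).all()


class TestConnectedParticles:
    def test_empty_mask_yields_empty_table(self):
        table = connected_particles(BinaryMask(np.zeros((8, 8), bool)))
        assert len(table) == 0

    def test_diagonal_pixels_depend_on_connectivity(self):
        mask = np.zeros((4, 4), bool)
        mask[1, 1] = mask[2, 2] = True
        assert len(connected_particles(BinaryMask(mask), 8)) == 1
        assert len(connected_particles(BinaryMask(mask), 4)) == 2

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle_on_random_masks(self, rng, connectivity):
        for _ in range(60):
            mask = rng.random((32, 32)) < rng.uniform(0.05, 0.6)
            table = connected_particles(BinaryMask(mask), connectivity)
            assert sorted(table.areas_px.tolist()) == flood_fill_components(mask, connectivity)
            assert table.areas_px.sum() <= mask.size

    def test_labels_contiguous_from_one(self, rng):
        mask = rng.random((32, 32)) < 0.3
        table = connected_particles(BinaryMask(mask))
        assert [p.label for p in table] == list(range(1, len(table) + 1))

    def test_disk_is_round_and_line_is_not(self):
        from skimage.draw import disk as skdisk

        m = np.zeros((64, 64), bool)
        rr, cc = skdisk((32, 32), 8)
        m[rr, cc] = True
        assert connected_particles(BinaryMask(m)).particles[0].circularity >= 0.85
        m2 = np.zeros((64, 64), bool)
        m2[30, 10:30] = True
        assert connected_particles(BinaryMask(m2)).particles[0].circularity < 0.3

    def test_area_calibration(self):
        mask = np.zeros((8, 8), bool)
        mask[2:4, 2:4] = True
        table = connected_particles(BinaryMask(mask, pixel_size=0.5))
        p = table.particles[0]
        assert p.area_px == 4
        assert p.area_um2 == pytest.approx(1.0)
        assert p.equivalent_diameter_um == pytest.approx(2 * np.sqrt(1.0 / np.pi))
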