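import numpy as np
import pytest

from medifuse.exceptions import (
    DegenerateInputError,
    FormatError,
    ParameterError,
    ValidationError,
)
from medifuse.image import (
    ImagePlane,
    SearchBounds,
    anisodiffuse,
    apply_rigid,
    hist_equalize,
    mi_cost,
    read_image,
    register_rigid,
    ssd_cost,
    write_image,
)


class TestImagePlane:
    def test_rejects_too_small_and_out_of_range(self):
        with pytest.raises(ValidationError):
            ImagePlane(np.zeros((8, 32)))
        with pytest.raises(ValidationError):
            ImagePlane(np.full((32, 32), 1.5))

    def test_accepts_unit_range(self, rng):
        p = ImagePlane(rng.random((20, 24)))
        assert p.height == 20 and p.width == 24


class TestReadWrite:
    def test_full_scale_and_midtone_normalization(self, tmp_path):
        arr = np.full((16, 16), 255, dtype=np.uint8)
        arr[0, 0] = 128
        import imageio.v3 as iio
        iio.imwrite(tmp_path / "a.png", arr)
        plane = read_image(tmp_path / "a.png")
        assert plane.pixels[1, 1] == 1.0
        assert plane.pixels[0, 0] == pytest.approx(128 / 255)
        assert plane.source_bit_depth == 8

    def test_rgb_reduces_to_rec601_luminance(self, tmp_path):
        rgb = np.zeros((16, 16, 3), dtype=np.uint8)
        rgb[..., 0] = 255  # pure red
        import imageio.v3 as iio
        iio.imwrite(tmp_path / "red.png", rgb)
        plane = read_image(tmp_path / "red.png")
        assert plane.pixels[3, 3] == pytest.approx(0.299, abs=1e-6)
        assert "color" in plane.meta

    def test_roundtrip_within_one_level(self, tmp_path, rng):
        plane = ImagePlane(rng.random((32, 32)))
        write_image(tmp_path / "r.png", plane)
        back = read_image(tmp_path / "r.png")
        assert np.max(np.abs(back.pixels - plane.pixels)) <= 1 / 255 + 1e-12

    def test_unreadable_file_names_path(self, tmp_path):
        bad = tmp_path / "not_an_image.png"
        bad.write_text("hello")
        with pytest.raises(FormatError, match="not_an_image"):
            read_image(bad)


class TestRegistration:
    def test_identity_transform_is_bit_exact(self, rng):
        img = rng.random((32, 32))
        assert np.array_equal(apply_rigid(img, 0, 0, 0), img)

    def test_ssd_single_pixel_difference(self):
        a = np.zeros((16, 16))
        b = a.copy()
        b[4, 5] = 0.5
        assert ssd_cost(a, b) == pytest.approx(0.25)

    def test_identical_images_give_identity_and_zero_cost(self, synthetic_pair):
        fixed = synthetic_pair.composite
        out, tf = register_rigid(fixed, fixed, cost="ssd",
                                 search=SearchBounds(max_shift=2))
        assert abs(tf.dx) < 0.2 and abs(tf.dy) < 0.2 and abs(tf.theta) < 0.2
        assert tf.cost_value < 1e-6

    @pytest.mark.parametrize("shift", [(3, -2), (-4, 1), (0, 5)])
    def test_known_shift_recovered(self, shift, synthetic_pair):
        fixed = synthetic_pair.composite.pixels
        moving = apply_rigid(fixed, *shift, 0.0)
        _, tf = register_rigid(moving, fixed, cost="ssd",
                               search=SearchBounds(max_shift=5))
        assert abs(tf.dx + shift[0]) <= 0.5
        assert abs(tf.dy + shift[1]) <= 0.5

    def test_mi_cost_recovers_shift_too(self, synthetic_pair):
        fixed = synthetic_pair.composite.pixels
        moving = apply_rigid(fixed, 2, -3, 0.0)
        _, tf = register_rigid(moving, fixed, cost="mi",
                               search=SearchBounds(max_shift=4))
        assert abs(tf.dx + 2) <= 0.5 and abs(tf.dy - 3) <= 0.5

    def test_constant_fixed_under_mi_is_degenerate(self, rng):
        with pytest.raises(DegenerateInputError):
            register_rigid(rng.random((20, 20)), np.full((20, 20), 0.5),
                           cost="mi")

    def test_mi_is_nonnegative_and_symmetricish(self, rng):
        a, b = rng.random((32, 32)), rng.random((32, 32))
        assert mi_cost(a, b) == pytest.approx(mi_cost(b, a), abs=1e-9)


class TestDiffusion:
    def test_constant_image_unchanged(self):
        c = np.full((20, 20), 0.4)
        out = anisodiffuse(c, iterations=15, kappa=0.1, dt=0.2)
        assert np.allclose(out, c)

    def test_zero_iterations_is_identity(self, rng):
        img = rng.random((20, 20))
        assert np.array_equal(anisodiffuse(img, iterations=0), img)

    def test_step_edge_location_preserved(self):
        img = np.zeros((24, 24))
        img[:, 12:] = 0.8
        out = anisodiffuse(img, iterations=10, kappa=0.05, dt=0.2)
        grad = np.abs(np.diff(out[12]))
        assert np.argmax(grad) == 11  # edge stays between cols 11 and 12

    def test_impulse_decays_monotonically_for_large_kappa(self):
        img = np.zeros((21, 21))
        img[10, 10] = 1.0
        prev = 1.0
        cur = img
        for _ in range(8):
            cur = anisodiffuse(cur, iterations=1, kappa=50.0, dt=0.2)
            peak = cur[10, 10]
            assert peak < prev
            prev = peak

    def test_parameter_validation(self, rng):
        img = rng.random((20, 20))
        with pytest.raises(ParameterError):
            anisodiffuse(img, kappa=-1.0)
        with pytest.raises(ParameterError):
            anisodiffuse(img, dt=0.5)


class TestHistEqualize:
    def test_two_level_image_maps_to_cdf_values(self):
        img = np.full((20, 20), 0.2)
        img[:5] = 0.8  # 25% bright, 75% dark
        out = hist_equalize(img)
        assert np.allclose(out[10], 0.75)
        assert np.allclose(out[0], 1.0)

    def test_constant_image_unchanged(self):
        c = np.full((20, 20), 0.3)
        assert np.array_equal(hist_equalize(c), c)

    def test_uniform_histogram_nearly_fixed_point(self):
        img = (np.arange(256).reshape(16, 16) / 255.0)
        out = hist_equalize(img)
        assert np.max(np.abs(out - img)) <= 1 / 255 + 1e-12

    def test_output_in_unit_interval(self, rng):
        out = hist_equalize(rng.random((30, 30)))
        assert out.min() >= 0 and out.max() <= 1
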