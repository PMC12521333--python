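"""Intensity and size normalization: reference pinning, gain invariance,
scale pinning, canvas placement, idempotence."""

from dataclasses import replace

import numpy as np
import pytest

from cxraer.datatypes import RawRadiograph, ScaleBar
from cxraer.normalize import (
    NormalizationError,
    NormalizeConfig,
    compute_size_factor,
    find_reference_intensity,
    normalize_intensity,
    normalize_radiograph,
    place_on_canvas,
    resample,
)
from cxraer.phantom import PhantomSpec, generate_phantom
from cxraer.segments import measure_image


def _image_with(values: dict[tuple[int, int], float]) -> np.ndarray:
    img = np.zeros((64, 64))
    for (y, x), v in values.items():
        img[y, x] = v
    return img


class TestReferenceIntensity:
    def test_maximum_of_region(self):
        img = _image_with({(5, 5): 10, (5, 6): 250, (5, 7): 100})
        poly = np.array([[4.6, 4.6], [7.4, 4.6], [7.4, 5.4], [4.6, 5.4]])
        assert find_reference_intensity(img, poly) == 250

    def test_uniform_plateau(self):
        img = np.full((64, 64), 37.5)
        poly = np.array([[10, 10], [20, 10], [20, 20], [10, 20]])
        assert find_reference_intensity(img, poly) == 37.5

    def test_zero_reference_rejected(self):
        img = np.zeros((64, 64))
        poly = np.array([[10, 10], [20, 10], [20, 20], [10, 20]])
        with pytest.raises(NormalizationError):
            find_reference_intensity(img, poly)

    def test_phantom_liver_reference_includes_gain(self, default_spec):
        b = generate_phantom(replace(default_spec, exposure_gain=1.3), seed=2)
        ref = find_reference_intensity(b.image, b.annotations.liver_region)
        assert ref == pytest.approx(255.0 * 1.3, rel=1e-12)


class TestIntensityScaling:
    def test_linear_scaling(self):
        out = normalize_intensity(np.array([[50.0]]), reference=200, target_level=100)
        assert out[0, 0] == 25.0

    def test_reference_equal_target_is_identity(self):
        img = np.random.default_rng(0).uniform(0, 200, (16, 16))
        assert np.array_equal(normalize_intensity(img, 123.0, 123.0), img)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(NormalizationError):
            normalize_intensity(np.ones((4, 4)), 0.0)

    def test_exposure_gain_cancels(self, default_spec):
        b1 = generate_phantom(default_spec, seed=4)
        b2 = generate_phantom(replace(default_spec, exposure_gain=1.6), seed=4)
        n1 = normalize_intensity(
            b1.image.pixels, find_reference_intensity(b1.image, b1.annotations.liver_region)
        )
        n2 = normalize_intensity(
            b2.image.pixels, find_reference_intensity(b2.image, b2.annotations.liver_region)
        )
        assert np.allclose(n1, n2, rtol=1e-9, atol=1e-9)


@pytest.mark.parametrize(
    "mm,px,expected",
    [(10.0, 100.0, 0.5), (10.0, 50.0, 1.0), (20.0, 80.0, 1.25)],
)
def test_size_factor(mm, px, expected):
    bar = ScaleBar(p1=(0, 0), p2=(px, 0), mm=mm)
    assert compute_size_factor(bar) == pytest.approx(expected, rel=1e-12)


def test_coincident_scale_bar_endpoints_rejected():
    with pytest.raises(NormalizationError):
        compute_size_factor(ScaleBar(p1=(5, 5), p2=(5, 5), mm=10))


class TestResample:
    def test_factor_one_is_identity(self):
        img = np.random.default_rng(1).uniform(0, 255, (40, 30))
        assert np.array_equal(resample(img, 1.0), img)

    def test_constant_image_stays_constant(self):
        out = resample(np.full((100, 100), 42.0), 0.5)
        assert out.shape == (50, 50)
        assert np.allclose(out, 42.0)

    def test_too_small_output_rejected(self):
        with pytest.raises(NormalizationError):
            resample(np.ones((40, 40)), 0.1)

    def test_mpi_stable_under_halving(self, default_spec):
        """Bilinear halving shifts segment MPI by < 0.5 intensity units."""
        canonical = generate_phantom(default_spec, seed=6)
        drawn_double = generate_phantom(replace(default_spec, scale_bar_px=100.0), seed=6)
        m1 = measure_image(normalize_radiograph(canonical.image, canonical.annotations))
        m2 = measure_image(normalize_radiograph(drawn_double.image, drawn_double.annotations))
        for a, b in zip(m1, m2):
            assert abs(a.mpi - b.mpi) < 0.5


class TestCanvas:
    def test_exact_fit_unchanged(self):
        img = np.random.default_rng(2).uniform(size=(1170, 2075))
        canvas, (ox, oy) = place_on_canvas(img)
        assert (ox, oy) == (0, 0)
        assert np.array_equal(canvas, img)

    def test_centered_offsets_and_pixel_lookup(self):
        img = np.random.default_rng(3).uniform(size=(800, 1000))
        canvas, (ox, oy) = place_on_canvas(img)
        assert (ox, oy) == ((2075 - 1000) // 2, (1170 - 800) // 2)
        assert canvas[oy, ox] == img[0, 0]
        assert canvas.shape == (1170, 2075)

    def test_oversized_image_rejected(self):
        with pytest.raises(NormalizationError, match="scale"):
            place_on_canvas(np.ones((1200, 2100)))


class TestFullNormalization:
    def test_canvas_width_is_canonical(self, default_spec):
        b = generate_phantom(default_spec, seed=8)
        norm = normalize_radiograph(b.image, b.annotations)
        assert norm.pixels.shape == (1170, 2075)

    def test_end_to_end_gain_invariance(self, default_spec):
        spec = replace(default_spec, scale_bar_px=100.0)  # exercises resampling
        b1 = generate_phantom(spec, seed=9)
        b2 = generate_phantom(replace(spec, exposure_gain=2.0), seed=9)
        n1 = normalize_radiograph(b1.image, b1.annotations)
        n2 = normalize_radiograph(b2.image, b2.annotations)
        assert np.allclose(n1.pixels, n2.pixels, rtol=1e-9, atol=1e-9)

    def test_missing_roi_error_names_the_gap(self, default_spec):
        b = generate_phantom(default_spec, seed=10)
        b.annotations.rois = [r for r in b.annotations.rois if r.key != ("left", 4)]
        with pytest.raises(Exception, match=r"left.*4"):
            normalize_radiograph(b.image, b.annotations)

    def test_normalization_is_idempotent(self, default_spec):
        b = generate_phantom(default_spec, seed=12)
        n1 = normalize_radiograph(b.image, b.annotations)
        again = RawRadiograph(image_id=n1.image_id, pixels=n1.pixels, bit_depth=16)
        n2 = normalize_radiograph(again, n1.annotations)
        assert np.allclose(n1.pixels, n2.pixels, rtol=1e-9, atol=1e-9)
        assert n2.size_factor == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("drawn_px", [40.0, 80.0, 173.0, 300.0])
    def test_scale_bar_pinned_to_50px(self, default_spec, drawn_px):
        b = generate_phantom(replace(default_spec, scale_bar_px=drawn_px), seed=13)
        norm = normalize_radiograph(b.image, b.annotations)
        assert norm.annotations.scale_bar.pixel_length == pytest.approx(50.0, abs=0.5)

    def test_liver_reference_pinned_to_target(self, default_spec):
        b = generate_phantom(replace(default_spec, exposure_gain=1.2), seed=14)
        norm = normalize_radiograph(b.image, b.annotations)
        from cxraer.segments import rasterize_roi

        mask = rasterize_roi(norm.annotations.liver_region, norm.pixels.shape)
        assert norm.pixels[mask].max() == pytest.approx(255.0, abs=0.5)
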