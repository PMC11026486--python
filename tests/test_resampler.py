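"""Retinal sampling layer: weight structure, conservation, geometry."""

import math

import numpy as np
import pytest

from retinal_sampling.prf import fit_exponential_decay
from retinal_sampling.rgc import cumulative_radius, inverse_radius
from retinal_sampling.resampler import (
    SamplingSpec,
    build_weights,
    inverse_resample,
    resample,
    unit_eccentricity,
    unit_position_linear,
)
from retinal_sampling.stimuli import GratingSpec, make_grating


class TestBuildWeights:
    def test_rows_sum_to_one_with_at_most_four_sources(self, small_spec):
        w = build_weights(small_spec)
        sums = np.asarray(w.matrix.sum(axis=1)).ravel()
        covered = w.covered.ravel()
        assert np.allclose(sums[covered], 1.0)
        assert np.all(sums[~covered] == 0.0)
        nnz = np.diff(w.matrix.indptr)
        assert nnz.max() <= 4
        assert w.matrix.data.min() >= 0.0

    def test_center_is_fixed_point(self, small_spec):
        w = build_weights(small_spec)
        w_o, w_i = small_spec.output_width, small_spec.input_width
        center_out = (w_o // 2) * w_o + w_o // 2
        row = w.matrix.getrow(center_out)
        assert row.nnz == 1
        assert row.indices[0] == (w_i // 2) * w_i + w_i // 2
        assert row.data[0] == pytest.approx(1.0)

    def test_half_radius_pixel_sources_at_closed_form_radius(self, small_spec):
        # output pixel on the +x axis at half the output radius: its source
        # must sit at inverse_radius(0.5 * r_gc(fov/2)) * w_i / fov px
        w = build_weights(small_spec)
        w_o, w_i = small_spec.output_width, small_spec.input_width
        c_o, c_i = w_o // 2, w_i // 2
        col = c_o + w_o // 4
        row = w.matrix.getrow(c_o * w_o + col)
        src_r = row.indices // w_i
        src_c = row.indices % w_i
        src_x = (row.data * (src_c - c_i)).sum()
        src_y = (row.data * (src_r - c_i)).sum()
        expected = (
            inverse_radius(0.5 * cumulative_radius(small_spec.fov / 2))
            * w_i
            / small_spec.fov
        )
        assert src_y == pytest.approx(0.0, abs=1e-9)
        assert src_x == pytest.approx(expected, abs=1.0)  # bilinear quantization

    def test_corner_pixels_uncovered(self, small_spec):
        w = build_weights(small_spec)
        assert w.matrix.getrow(0).nnz == 0
        assert not w.covered[0, 0]

    def test_radial_map_order_preserving(self, small_spec):
        # r_o monotone in r_i along the +x axis
        w_o = small_spec.output_width
        r_o = np.arange(1, w_o // 2)
        r_gc = r_o * small_spec.total_cell_radius / (w_o / 2)
        r_i = inverse_radius(r_gc) * small_spec.input_width / small_spec.fov
        assert np.all(np.diff(r_i) > 0)

    def test_alpha_not_one_rejected(self):
        from retinal_sampling.rgc import RGCDensityParams

        spec = SamplingSpec(64, 32, 20.0, RGCDensityParams(alpha=0.99))
        with pytest.raises(ValueError):
            build_weights(spec)


class TestResample:
    def test_uniform_image_conserved(self, small_spec):
        w = build_weights(small_spec)
        img = np.full((129, 129, 3), 0.37)
        out = resample(img, w)
        assert np.allclose(out[w.covered], 0.37)
        assert np.allclose(out[~w.covered], 0.0)

    def test_linear_in_image(self, small_spec, rng):
        w = build_weights(small_spec)
        a = rng.random((129, 129, 3))
        b = rng.random((129, 129, 3))
        assert np.allclose(resample(a + b, w), resample(a, w) + resample(b, w))
        assert np.allclose(resample(2.5 * a, w), 2.5 * resample(a, w))

    def test_foveal_disk_magnification(self, small_spec):
        # a 2-deg disk covers the closed-form predicted output radius
        w = build_weights(small_spec)
        size = small_spec.input_width
        c = (size - 1) / 2
        x, y = np.mgrid[0:size, 0:size]
        r_deg = np.hypot(x - c, y - c) * small_spec.fov / size
        disk = (r_deg <= 2.0).astype(float)
        out = resample(disk, w)
        predicted = (
            (small_spec.output_width / 2)
            * cumulative_radius(2.0)
            / cumulative_radius(small_spec.fov / 2)
        )
        empirical = math.sqrt((out > 1e-6).sum() / math.pi)
        assert empirical == pytest.approx(predicted, abs=1.0)

    def test_shape_mismatch_rejected(self, small_spec):
        w = build_weights(small_spec)
        with pytest.raises(ValueError):
            resample(np.zeros((64, 64, 3)), w)


class TestInverseResample:
    def test_uniform_and_zero_images(self, small_spec):
        w = build_weights(small_spec)
        uniform = np.full((65, 65, 3), 0.8)
        rendered = inverse_resample(uniform, small_spec)
        size = small_spec.input_width
        c = (size - 1) / 2
        x, y = np.mgrid[0:size, 0:size]
        inside = np.hypot(x - c, y - c) * small_spec.fov / size <= small_spec.fov / 2
        assert np.allclose(rendered[inside], 0.8)
        assert np.allclose(inverse_resample(np.zeros((65, 65, 3)), small_spec), 0.0)

    def test_round_trip_accurate_in_central_field(self, small_spec):
        w = build_weights(small_spec)
        g = make_grating(
            GratingSpec(45.0, 0.2, size=small_spec.input_width, fov=small_spec.fov),
            rgb=False,
        )
        rt = inverse_resample(resample(g, w), small_spec)
        size = small_spec.input_width
        c = (size - 1) / 2
        x, y = np.mgrid[0:size, 0:size]
        central = np.hypot(x - c, y - c) * small_spec.fov / size <= 2.0
        assert np.abs(rt[central] - g[central]).mean() < 0.01

    def test_shape_mismatch_rejected(self, small_spec):
        with pytest.raises(ValueError):
            inverse_resample(np.zeros((64, 64, 3)), small_spec)


class TestUnitEccentricity:
    def test_central_unit_near_zero(self, small_spec):
        ecc, _ = unit_eccentricity(32.0, 32.0, 1.0, small_spec, offset=0.0)
        assert ecc == pytest.approx(0.0, abs=1e-9)

    def test_boundary_unit_at_half_fov(self, small_spec):
        # ganglion radius w_o/2 (the raster boundary, between pixel centers)
        ecc, ang = unit_eccentricity(32.0, 32.0 + 32.5, 1.0, small_spec, offset=0.0)
        assert ecc == pytest.approx(small_spec.fov / 2, abs=1e-9)
        assert ang == pytest.approx(0.0)

    def test_half_radius_closed_form(self, small_spec):
        ecc, _ = unit_eccentricity(32.0, 32.0 + 16.25, 1.0, small_spec, offset=0.0)
        expected = inverse_radius(0.5 * cumulative_radius(small_spec.fov / 2))
        assert ecc == pytest.approx(expected, abs=1e-9)

    def test_out_of_map_rejected(self, small_spec):
        with pytest.raises(IndexError):
            unit_eccentricity(-1.0, 0.0, 1.0, small_spec)

    def test_linear_counterpart(self):
        ecc, ang = unit_position_linear(32.0, 64.0, 1.0, 65, 20.0, offset=0.0)
        assert ecc == pytest.approx(32 * 20.0 / 65)
        assert ang == pytest.approx(0.0)


class TestGeometricMagnification:
    def test_pixel_counts_decrease_and_decay_exponentially(self, small_spec):
        # counting ganglion pixels per 1-deg bin is the geometric core of
        # cortical magnification: strictly decreasing, exponential beats line
        spec = SamplingSpec(256, 128, 20.0)
        w_o = spec.output_width
        rows, cols = np.mgrid[0:w_o, 0:w_o]
        ecc, _ = unit_eccentricity(
            rows.ravel().astype(float), cols.ravel().astype(float), 1.0, spec,
            offset=0.0,
        )
        counts, edges = np.histogram(ecc[np.isfinite(ecc)], bins=np.arange(0, 11))
        assert np.all(np.diff(counts) < 0)
        centers = (edges[:-1] + edges[1:]) / 2
        lin = np.polyfit(centers, counts, 1)
        lin_res = np.sum((counts - np.polyval(lin, centers)) ** 2)
        lin_r2 = 1 - lin_res / np.sum((counts - counts.mean()) ** 2)
        _, exp_r2 = fit_exponential_decay(centers, counts.astype(float))
        assert exp_r2 > lin_r2
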