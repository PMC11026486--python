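"""Polar binning, bias ratios, sensitivity, frequency maps, curvature."""

import math

import numpy as np
import pytest

from retinal_sampling.resampler import SamplingSpec, unit_eccentricity
from retinal_sampling.stimuli import (
    GratingSpec,
    make_curved_line_set,
    make_gabor_bank,
    make_grating,
)
from retinal_sampling.tuning import (
    FrequencyMap,
    SensitivityCurve,
    build_gabor_pyramid,
    curvature_similarity,
    dominant_frequency_map,
    polar_bin_profile,
    predicted_response_map,
    radial_bias_ratio,
    sensitivity_curve,
    sf_tuning,
)

SPEC = SamplingSpec(128, 64, 20.0)


def _unit_angles(shape):
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    _, ang = unit_eccentricity(
        rows.ravel().astype(float), cols.ravel().astype(float), 1.0, SPEC, offset=0.0
    )
    return ang.reshape(shape)


class TestPolarBins:
    def test_uniform_map_normalizes_to_all_ones(self):
        prof = polar_bin_profile(np.ones((64, 64)), SPEC, 1.0, 0.0)
        assert np.allclose(prof.normalized, 1.0)
        assert np.allclose(prof.means, prof.means[0])

    def test_wedge_map_peaks_at_its_bin(self):
        ang = _unit_angles((64, 64))
        wedge = ((ang <= 22.5) | (ang >= 337.5)).astype(float)
        prof = polar_bin_profile(wedge, SPEC, 1.0, 0.0)
        assert prof.normalized[0] == 1.0
        assert prof.means[8] == 0.0  # opposite bin (180 deg)

    def test_rotation_shifts_profile_by_one_bin(self):
        ang = _unit_angles((64, 64))
        base = np.cos(np.radians(ang))
        rot = np.cos(np.radians(ang - 22.5))
        p0 = polar_bin_profile(np.exp(base), SPEC, 1.0, 0.0)
        p1 = polar_bin_profile(np.exp(rot), SPEC, 1.0, 0.0)
        assert np.allclose(np.roll(p0.means, 1), p1.means, rtol=0.02)

    def test_outer_exclusion_drops_far_units(self):
        prof = polar_bin_profile(np.ones((64, 64)), SPEC, 1.0, 0.0, outer_margin=1.2)
        full = polar_bin_profile(np.ones((64, 64)), SPEC, 1.0, 0.0, outer_margin=0.0)
        assert prof.n_units.sum() < full.n_units.sum()


class TestBiasRatio:
    def _profile(self, means):
        from retinal_sampling.tuning import PolarBinProfile

        means = np.asarray(means, dtype=float)
        return PolarBinProfile(
            bin_centers=np.arange(16) * 22.5,
            means=means,
            normalized=means / means.max(),
            n_units=np.ones(16, dtype=int),
        )

    def test_uniform_profile_gives_unity(self):
        assert radial_bias_ratio(self._profile(np.ones(16)), 45.0) == 1.0

    def test_constructed_two_to_one_ratio(self):
        means = np.ones(16) * 0.5
        means[0] = means[8] = 1.0  # 0 and 180 deg bins
        assert radial_bias_ratio(self._profile(means), 0.0) == pytest.approx(2.0)

    def test_scale_invariance(self):
        means = np.linspace(1.0, 2.5, 16)
        r1 = radial_bias_ratio(self._profile(means), 90.0)
        r2 = radial_bias_ratio(self._profile(10.0 * means), 90.0)
        assert r1 == pytest.approx(r2)

    def test_misaligned_orientation_rejected(self):
        with pytest.raises(ValueError):
            radial_bias_ratio(self._profile(np.ones(16)), 30.0)

    def test_zero_denominator_flagged(self):
        means = np.zeros(16)
        means[0] = means[8] = 1.0
        with pytest.warns(UserWarning):
            assert radial_bias_ratio(self._profile(means), 0.0) == math.inf


class TestSensitivityCurve:
    def test_peak_near_preferred_frequency(self):
        # wavelength 2*pi px on an 11-px patch peaks near 11/(2*pi) ~ 1.75 cpi
        bank = make_gabor_bank(size=11, wavelength=2 * math.pi, n_orientations=8)
        curve = sensitivity_curve(bank, n_orientations=4, n_phases=6)
        peak = curve.frequencies_cpi[np.argmax(curve.values)]
        assert abs(peak - 11 / (2 * math.pi)) <= 0.2
        assert np.all(curve.values >= 0)

    def test_duplicate_filters_leave_curve_unchanged(self):
        bank = make_gabor_bank(size=7, n_orientations=4)
        arrs = np.stack([k.array for k in bank])
        doubled = np.concatenate([arrs, arrs])
        freqs = np.linspace(0.5, 2.5, 5)
        a = sensitivity_curve(arrs, freqs, n_orientations=2, n_phases=4)
        b = sensitivity_curve(doubled, freqs, n_orientations=2, n_phases=4)
        assert np.allclose(a.values, b.values)

    def test_zero_filters_give_zero_curve(self):
        curve = sensitivity_curve(
            np.zeros((2, 7, 7)), np.linspace(0.5, 2.0, 4), n_orientations=2, n_phases=4
        )
        assert np.all(curve.values == 0)


class TestDominantFrequency:
    def test_pure_grating_assigned_its_own_frequency(self):
        pyramid = build_gabor_pyramid(64, np.array([2.0, 4.0, 8.0, 16.0]), 4)
        f_img = 8.0  # cycles per 64-px image
        g = make_grating(GratingSpec(90.0, f_img, size=64, fov=1.0), rgb=False)
        fm = dominant_frequency_map(g, pyramid)
        interior = fm.dominant_cpi[16:-16, 16:-16]
        assert np.all(interior == f_img)

    def test_constant_image_undefined(self):
        pyramid = build_gabor_pyramid(32, np.array([2.0, 4.0]), 2)
        fm = dominant_frequency_map(np.full((32, 32), 0.5), pyramid)
        assert not fm.defined.any()
        assert np.all(np.isnan(fm.dominant_cpi))

    def test_decreasing_pyramid_frequencies_rejected(self):
        with pytest.raises(ValueError):
            build_gabor_pyramid(32, np.array([4.0, 2.0]), 2)


class TestPredictedResponse:
    def _freq_map(self):
        dom = np.full((8, 8), 4.0)
        dom[0, 0] = np.nan
        defined = ~np.isnan(dom)
        return FrequencyMap(
            dominant_cpi=dom,
            magnitude=np.ones((8, 8)),
            frequencies_cpi=np.array([2.0, 4.0]),
            defined=defined,
        )

    def test_flat_sensitivity_marks_defined_pixels(self):
        sens = SensitivityCurve(np.linspace(0.1, 3.0, 5), np.full(5, 2.0), 8)
        out = predicted_response_map(self._freq_map(), sens)
        assert out[0, 0] == 0.0
        assert np.allclose(out[self._freq_map().defined], 2.0)

    def test_zero_sensitivity_gives_zero_map(self):
        sens = SensitivityCurve(np.linspace(0.1, 3.0, 5), np.zeros(5), 8)
        assert np.all(predicted_response_map(self._freq_map(), sens) == 0)


class TestCurvatureSimilarity:
    def test_identical_and_orthogonal_vectors(self):
        stimuli = make_curved_line_set()
        straight = [s for s in stimuli if s.level == 0 and s.orientation == 0.0][:1]
        filt = straight[0].image.mean(axis=2)
        sim = curvature_similarity(filt - filt.mean() * 0, straight)
        assert sim.similarity[0] == pytest.approx(1.0)
        orth = np.zeros((7, 7))
        orth[:, 0] = 1.0
        orth[3, 0] = 0.0  # no overlap with the horizontal line
        sim2 = curvature_similarity(orth, straight)
        assert sim2.similarity[0] == pytest.approx(0.0, abs=1e-12)

    def test_levels_sorted_and_bounded(self):
        bank = make_gabor_bank(size=7, n_orientations=8)
        sim = curvature_similarity(bank, make_curved_line_set())
        assert np.array_equal(sim.levels, np.arange(6))
        assert np.all(np.abs(sim.similarity) <= 1.0)


class TestSFTuningPlumbing:
    def test_normalized_maximum_is_one_per_eccentricity(self, small_adapter):
        curve = sf_tuning(
            small_adapter,
            eccentricities=(2.0, 6.0),
            coefficients=(2, 8, 14),
            n_phases=2,
        )
        assert curve.responses.shape == (2, 3)
        assert np.allclose(curve.responses.max(axis=1), 1.0)
        assert np.all(curve.responses > 0)
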