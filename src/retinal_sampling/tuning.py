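"""Spatial-frequency tuning, radial bias and the frequency-mechanism analyses.

Three families of measurements on a layer adapter:

* ``sf_tuning`` — sinring responses grouped by eccentricity, max-normalized,
  yielding the preferred spatial frequency per eccentricity and an
  exponential-decay fit of preference over eccentricity.
* ``orientation_maps`` / ``polar_bin_profile`` / ``radial_bias_ratio`` /
  ``bias_sweep`` — the radial-bias statistic: phase-averaged population
  maps per grating orientation, binned into 16 overlapping 45-deg polar
  wedges (outer 1.2 deg excluded), with the A_grating/A_orthogonal ratio
  (1 = no bias, >1 radial, <1 orthogonal) swept over spatial frequency.
* ``sensitivity_curve`` / ``dominant_frequency_map`` /
  ``predicted_response_map`` / ``curvature_similarity`` — the mechanism
  analyses: the filter bank's spatial-frequency sensitivity, per-pixel
  dominant frequency of resampled stimuli from a Gabor pyramid, the layer
  response predicted from the two combined, and cosine similarity of
  filters with parametrically curved lines.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .network import LayerAdapter
from .prf import fit_exponential_decay, population_map
from .resampler import SamplingSpec, unit_eccentricity, unit_position_linear
from .stimuli import (
    SINRING_CPR_COEFFICIENTS,
    SINRING_ECCENTRICITIES,
    CurvedLineStimulus,
    GaborKernel,
    GratingSpec,
    make_gabor_kernel,
    make_grating,
    make_sinring,
    make_sinring_batch,
)

__all__ = [
    "SFTuningCurve",
    "PolarBinProfile",
    "BiasResult",
    "SensitivityCurve",
    "FrequencyMap",
    "CurvatureSimilarity",
    "GaborPyramid",
    "sf_tuning",
    "orientation_maps",
    "polar_bin_profile",
    "radial_bias_ratio",
    "bias_sweep",
    "sensitivity_curve",
    "build_gabor_pyramid",
    "dominant_frequency_map",
    "predicted_response_map",
    "curvature_similarity",
    "BIAS_SWEEP_FREQUENCIES",
]

#: Default spatial-frequency sweep (c/deg) of the radial-bias experiment.
BIAS_SWEEP_FREQUENCIES = (0.10, 0.25, 0.50, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0)


# ---------------------------------------------------------------------------
# Eccentricity-dependent spatial-frequency tuning (sinrings)
# ---------------------------------------------------------------------------


@dataclass
class SFTuningCurve:
    """Normalized layer response per (eccentricity, frequency level).

    ``responses[i, j]`` is the pooled mean population response at
    eccentricity ``eccentricities[i]`` and arc frequency
    ``frequencies_cdeg[j]`` (= coefficient / pi c/deg, matched across
    eccentricities), divided by the row maximum. ``preferred_cdeg`` is the
    argmax frequency per eccentricity; ``exp_fit``/``exp_r2`` fit preference
    over eccentricity with a * exp(-b E) + c.
    """

    eccentricities: np.ndarray
    frequencies_cdeg: np.ndarray
    responses: np.ndarray
    preferred_cdeg: np.ndarray
    exp_fit: tuple[float, float, float]
    exp_r2: float


def sf_tuning(
    adapter: LayerAdapter,
    batch: list | None = None,
    eccentricities: tuple[float, ...] = SINRING_ECCENTRICITIES,
    coefficients: tuple[float, ...] = SINRING_CPR_COEFFICIENTS,
    n_phases: int = 8,
    fov: float = 20.0,
) -> SFTuningCurve:
    """Sinring spatial-frequency tuning per eccentricity.

    ``batch`` defaults to the full eccentricity x frequency x phase sweep at
    the adapter's input size. Per stimulus the response is the pooled mean
    of the population map; responses are averaged over phases, grouped by
    eccentricity and divided by the group maximum.
    """
    if batch is None:
        batch = make_sinring_batch(
            eccentricities, coefficients, n_phases, size=adapter.input_width, fov=fov
        )
    eccs = np.asarray(sorted({s.eccentricity for s in batch}))
    # arc spatial frequency c/pi c/deg (angular frequency normalized by
    # eccentricity), matched across eccentricities by construction; rounded
    # so float roundoff does not split matched frequencies across groups
    freqs_cdeg = np.unique(
        np.round([s.angular_frequency / s.eccentricity for s in batch], 9)
    )
    responses = np.zeros((eccs.size, freqs_cdeg.size))
    counts = np.zeros_like(responses)
    images = np.stack([make_sinring(s) for s in batch])
    feats = adapter.batch(images)
    for spec, fmap in zip(batch, feats):
        i = int(np.argmin(np.abs(eccs - spec.eccentricity)))
        j = int(
            np.argmin(np.abs(freqs_cdeg - spec.angular_frequency / spec.eccentricity))
        )
        responses[i, j] += population_map(fmap).mean()
        counts[i, j] += 1
    responses /= counts
    group_max = responses.max(axis=1, keepdims=True)
    if np.any(group_max == 0):
        warnings.warn("all-zero responses at some eccentricity; normalization undefined")
        group_max = np.where(group_max == 0, 1.0, group_max)
    normalized = responses / group_max
    preferred = freqs_cdeg[np.argmax(normalized, axis=1)]
    exp_fit, exp_r2 = fit_exponential_decay(eccs, preferred)
    return SFTuningCurve(
        eccentricities=eccs,
        frequencies_cdeg=freqs_cdeg,
        responses=normalized,
        preferred_cdeg=preferred,
        exp_fit=exp_fit,
        exp_r2=exp_r2,
    )


# ---------------------------------------------------------------------------
# Orientation maps and the polar-bin radial-bias statistic
# ---------------------------------------------------------------------------


def orientation_maps(
    adapter: LayerAdapter,
    orientations: np.ndarray | tuple[float, ...],
    spatial_frequency: float,
    n_phases: int = 32,
    fov: float = 20.0,
    contrast: float = 1.0,
) -> dict[float, np.ndarray]:
    """Phase-averaged population maps per grating orientation.

    Phases are 32 equidistant offsets in [-pi, pi); the map for each
    orientation is the mean population map over phases.
    """
    phases = -math.pi + np.arange(n_phases) * 2.0 * math.pi / n_phases
    out: dict[float, np.ndarray] = {}
    for ori in orientations:
        images = np.stack(
            [
                make_grating(
                    GratingSpec(
                        orientation=float(ori),
                        spatial_frequency=spatial_frequency,
                        phase=float(ph),
                        size=adapter.input_width,
                        fov=fov,
                        contrast=contrast,
                    )
                )
                for ph in phases
            ]
        )
        feats = adapter.batch(images)
        out[float(ori)] = feats.mean(axis=(0, 1))
    return out


@dataclass
class PolarBinProfile:
    """Mean activity in 16 overlapping polar-angle bins.

    Bin centers at 0, 22.5, ..., 337.5 deg; each bin spans +-22.5 deg, so
    adjacent bins share half their angular support. ``normalized`` divides
    by the maximum bin mean.
    """

    bin_centers: np.ndarray
    means: np.ndarray
    normalized: np.ndarray
    n_units: np.ndarray


def polar_bin_profile(
    activity_map: np.ndarray,
    spec: SamplingSpec,
    downsample_factor: float,
    coord_offset: float | None = None,
    outer_margin: float = 1.2,
    geometry: str = "rgc",
) -> PolarBinProfile:
    """Bin a layer map into 16 overlapping 45-deg polar wedges.

    Unit eccentricities and angles come from the sampling geometry
    (:func:`unit_eccentricity`, or the linear pixel-to-degree map with
    ``geometry="linear"`` for uniform-sampling controls); units beyond
    ``fov/2 - outer_margin`` deg (stimulus-edge and vignetting zone) are
    excluded. Empty bins get mean 0 with a warning.
    """
    activity_map = np.asarray(activity_map, dtype=float)
    h, w = activity_map.shape
    rows, cols = np.mgrid[0:h, 0:w]
    if geometry == "rgc":
        ecc, angle = unit_eccentricity(
            rows.ravel(), cols.ravel(), downsample_factor, spec, offset=coord_offset
        )
    elif geometry == "linear":
        ecc, angle = unit_position_linear(
            rows.ravel(),
            cols.ravel(),
            downsample_factor,
            spec.output_width,
            spec.fov,
            offset=coord_offset,
        )
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    keep = ecc <= spec.fov / 2.0 - outer_margin
    act = activity_map.ravel()[keep]
    ang = angle[keep]
    centers = np.arange(16) * 22.5
    means = np.zeros(16)
    n_units = np.zeros(16, dtype=int)
    for b, ctr in enumerate(centers):
        delta = np.abs((ang - ctr + 180.0) % 360.0 - 180.0)
        members = delta <= 22.5
        n_units[b] = members.sum()
        if n_units[b] == 0:
            warnings.warn(f"empty polar bin at {ctr} deg")
        else:
            means[b] = act[members].mean()
    top = means.max()
    normalized = means / top if top > 0 else means.copy()
    return PolarBinProfile(
        bin_centers=centers, means=means, normalized=normalized, n_units=n_units
    )


def radial_bias_ratio(profile: PolarBinProfile, grating_orientation: float) -> float:
    """A_grating / A_orthogonal for a grating aligned with a bin center.

    A_grating sums the bins at the grating's polar axis (orientation and
    orientation + 180), A_orthogonal the two orthogonal bins. Returns inf
    for a zero denominator (degenerate).
    """
    ori = grating_orientation % 360.0
    if not np.isclose(ori % 22.5, 0.0):
        raise ValueError("grating orientation must align with a bin center")

    def bin_at(angle: float) -> float:
        idx = int(round((angle % 360.0) / 22.5)) % 16
        return profile.means[idx]

    a_grating = bin_at(ori) + bin_at(ori + 180.0)
    a_orth = bin_at(ori + 90.0) + bin_at(ori + 270.0)
    if a_orth == 0:
        warnings.warn("zero orthogonal-axis activity; ratio degenerate")
        return math.inf
    return a_grating / a_orth


@dataclass
class BiasResult:
    """Radial-bias ratios per spatial frequency and grating orientation."""

    spatial_frequencies: np.ndarray
    orientations: np.ndarray
    ratios: np.ndarray  # (n_sf, n_orientations)
    mean_ratios: np.ndarray  # (n_sf,), degenerate ratios excluded


def bias_sweep(
    adapter: LayerAdapter,
    spatial_frequencies: tuple[float, ...] = BIAS_SWEEP_FREQUENCIES,
    orientations: np.ndarray | None = None,
    n_phases: int = 32,
    fov: float = 20.0,
    sampling: SamplingSpec | None = None,
    outer_margin: float = 1.2,
) -> BiasResult:
    """Radial-bias ratio (mean over orientations) per spatial frequency.

    Default orientations: 8 values at 22.5-deg spacing, each aligned with a
    polar-bin center. ``sampling`` defaults to the adapter's RSL geometry;
    pass an identity-free geometry for uniform-sampling controls.
    """
    if orientations is None:
        orientations = np.arange(8) * 22.5
    geometry = "rgc"
    if sampling is None:
        sampling = adapter.config.sampling
        if not adapter.config.include_rsl:
            geometry = "linear"
    ratios = np.empty((len(spatial_frequencies), len(orientations)))
    for i, sf in enumerate(spatial_frequencies):
        omaps = orientation_maps(adapter, orientations, sf, n_phases=n_phases, fov=fov)
        for j, ori in enumerate(orientations):
            prof = polar_bin_profile(
                omaps[float(ori)],
                sampling,
                adapter.downsample_factor,
                adapter.coord_offset,
                outer_margin=outer_margin,
                geometry=geometry,
            )
            ratios[i, j] = radial_bias_ratio(prof, float(ori))
    finite = np.isfinite(ratios)
    if not finite.all():
        warnings.warn("degenerate (infinite) bias ratios excluded from sweep means")
    mean_ratios = np.array(
        [
            row[ok].mean() if ok.any() else math.inf
            for row, ok in zip(ratios, finite)
        ]
    )
    return BiasResult(
        spatial_frequencies=np.asarray(spatial_frequencies, dtype=float),
        orientations=np.asarray(orientations, dtype=float),
        ratios=ratios,
        mean_ratios=mean_ratios,
    )


# ---------------------------------------------------------------------------
# Frequency-mechanism analyses
# ---------------------------------------------------------------------------


@dataclass
class SensitivityCurve:
    """Layer spatial-frequency sensitivity on the filter patch.

    ``frequencies_cpi`` are grating frequencies in cycles per image (patch
    width); ``values`` is the mean over gratings of the per-grating maximum
    rectified filter response.
    """

    frequencies_cpi: np.ndarray
    values: np.ndarray
    patch_size: int

    def at_cycles_per_pixel(self, f_cpp: np.ndarray) -> np.ndarray:
        """Interpolate sensitivity at frequencies in cycles/pixel (edge
        values beyond the measured range)."""
        cpp = self.frequencies_cpi / self.patch_size
        return np.interp(f_cpp, cpp, self.values)


def sensitivity_curve(
    filters: np.ndarray | list[GaborKernel],
    frequencies_cpi: np.ndarray | None = None,
    n_orientations: int = 8,
    n_phases: int = 12,
    patch_size: int | None = None,
) -> SensitivityCurve:
    """Spatial-frequency sensitivity of a filter set.

    Gratings on the filter-sized patch sweep frequency (default 0.10 to 3.00
    cycles/image in 30 steps), orientation (0..pi in ``n_orientations``
    steps) and phase (0..2 pi in ``n_phases`` steps). Each grating's score
    is the maximum over filters of the rectified (ReLU) dot product; scores
    are averaged per frequency level.
    """
    if isinstance(filters, list):
        bank = np.stack([k.array for k in filters])
    else:
        bank = np.asarray(filters)
        if bank.ndim == 2:
            bank = bank[None]
    size = bank.shape[-1] if patch_size is None else patch_size
    if frequencies_cpi is None:
        frequencies_cpi = np.linspace(0.10, 3.00, 30)
    oris = np.arange(n_orientations) * 180.0 / n_orientations
    phases = np.arange(n_phases) * 2.0 * math.pi / n_phases
    flat = bank.reshape(bank.shape[0], -1)
    values = np.empty(len(frequencies_cpi))
    for i, f_cpi in enumerate(frequencies_cpi):
        best = []
        for ori in oris:
            for ph in phases:
                patch = make_grating(
                    GratingSpec(
                        orientation=float(ori),
                        spatial_frequency=float(f_cpi),
                        phase=float(ph),
                        size=size,
                        fov=1.0,  # image is one "degree" wide: f in cycles/image
                    ),
                    rgb=False,
                )
                resp = np.maximum(flat @ patch.ravel() * 3.0, 0.0)  # 3 channels
                best.append(resp.max())
        values[i] = np.mean(best)
    return SensitivityCurve(
        frequencies_cpi=np.asarray(frequencies_cpi, dtype=float),
        values=values,
        patch_size=size,
    )


@dataclass
class GaborPyramid:
    """Quadrature Gabor wavelet set over frequencies x orientations."""

    frequencies_cpi: np.ndarray  # strictly increasing, cycles per image
    orientations: np.ndarray
    image_width: int
    kernels: list[list[tuple[np.ndarray, np.ndarray]]]  # [freq][ori] -> (even, odd)


def build_gabor_pyramid(
    image_width: int,
    frequencies_cpi: np.ndarray | None = None,
    n_orientations: int = 8,
    max_kernel: int | None = None,
) -> GaborPyramid:
    """Gabor pyramid for local frequency analysis.

    Default: 12 log-spaced frequencies spanning 0.5 to 64 cycles/image,
    8 orientations, quadrature phase pairs; kernel support is 6 envelope
    standard deviations, capped at the image width.
    """
    if frequencies_cpi is None:
        frequencies_cpi = np.geomspace(0.5, 64.0, 12)
    frequencies_cpi = np.asarray(frequencies_cpi, dtype=float)
    if np.any(np.diff(frequencies_cpi) <= 0):
        raise ValueError("pyramid frequencies must be strictly increasing")
    cap = image_width if max_kernel is None else max_kernel
    oris = np.arange(n_orientations) * 180.0 / n_orientations
    kernels = []
    for f in frequencies_cpi:
        wavelength = image_width / f  # px per cycle
        sd = wavelength / 2.0
        ksize = int(min(2 * round(3 * sd) + 1, cap if cap % 2 else cap - 1))
        per_ori = []
        for ori in oris:
            even = make_gabor_kernel(ksize, wavelength, ori, 0.0, sd, normalize=True)
            odd = make_gabor_kernel(
                ksize, wavelength, ori, math.pi / 2.0, sd, normalize=True
            )
            per_ori.append((even.array, odd.array))
        kernels.append(per_ori)
    return GaborPyramid(
        frequencies_cpi=frequencies_cpi,
        orientations=oris,
        image_width=image_width,
        kernels=kernels,
    )


@dataclass
class FrequencyMap:
    """Per-pixel dominant frequency of an image.

    ``dominant_cpi`` holds the winning pyramid frequency (NaN where the
    winning magnitude falls below ``magnitude_floor``); ``magnitude`` the
    winning quadrature energy.
    """

    dominant_cpi: np.ndarray
    magnitude: np.ndarray
    frequencies_cpi: np.ndarray
    defined: np.ndarray


def dominant_frequency_map(
    image: np.ndarray,
    pyramid: GaborPyramid,
    magnitude_floor: float = 1e-6,
    background: float | None = None,
    valid_mask: np.ndarray | None = None,
) -> FrequencyMap:
    """Assign each pixel the pyramid frequency with the largest response.

    The image (channel-averaged, ``background``-subtracted -- defaults to
    the image mean) is convolved with every wavelet; per frequency the
    response magnitude is the maximum over orientations of the
    quadrature-pair energy, and the dominant frequency is the per-pixel
    argmax over frequencies. ``valid_mask`` zeroes pixels outside the
    region of interest before analysis (e.g. the covered disk of a
    resampled image, so the disk-vs-corner step does not masquerade as
    low-frequency content) and marks them undefined.
    """
    image = np.asarray(image, dtype=float)
    plane = image.mean(axis=2) if image.ndim == 3 else image
    plane = plane - (plane.mean() if background is None else background)
    if valid_mask is not None:
        plane = np.where(valid_mask, plane, 0.0)
    best_mag = np.full(plane.shape, -np.inf)
    best_f = np.zeros(plane.shape)
    for f, per_ori in zip(pyramid.frequencies_cpi, pyramid.kernels):
        mag_f = np.zeros(plane.shape)
        for even, odd in per_ori:
            re = fftconvolve(plane, even[::-1, ::-1], mode="same")
            im = fftconvolve(plane, odd[::-1, ::-1], mode="same")
            np.maximum(mag_f, np.hypot(re, im), out=mag_f)
        better = mag_f > best_mag
        best_mag[better] = mag_f[better]
        best_f[better] = f
    defined = best_mag >= magnitude_floor
    if valid_mask is not None:
        defined &= valid_mask
    dominant = np.where(defined, best_f, np.nan)
    return FrequencyMap(
        dominant_cpi=dominant,
        magnitude=best_mag,
        frequencies_cpi=pyramid.frequencies_cpi,
        defined=defined,
    )


def predicted_response_map(
    freq_map: FrequencyMap,
    sens: SensitivityCurve,
    image_width: int | None = None,
) -> np.ndarray:
    """Layer response predicted from local frequency content and sensitivity.

    Per pixel: the sensitivity curve evaluated at the pixel's dominant
    frequency (converted to cycles/pixel to align the patch-based curve with
    image-based pyramid frequencies); 0 where the dominant frequency is
    undefined. Bin the result with :func:`polar_bin_profile`
    (downsample_factor 1) exactly like a measured orientation map.
    """
    if image_width is None:
        image_width = freq_map.dominant_cpi.shape[0]
    cpp = freq_map.dominant_cpi / image_width
    out = np.zeros(freq_map.dominant_cpi.shape)
    d = freq_map.defined
    out[d] = sens.at_cycles_per_pixel(cpp[d])
    return out


@dataclass
class CurvatureSimilarity:
    """Mean best cosine similarity per curvature level."""

    levels: np.ndarray
    similarity: np.ndarray


def curvature_similarity(
    filters: np.ndarray | list[GaborKernel],
    stimuli: list[CurvedLineStimulus],
) -> CurvatureSimilarity:
    """Cosine similarity of a filter set with curved-line stimuli.

    Per stimulus: the maximum over filters of the cosine similarity between
    the vectorized filter and the vectorized stimulus; averaged over line
    orientations and bend directions per curvature level. Zero-norm filters
    or stimuli are excluded with a warning.
    """
    if isinstance(filters, list):
        bank = np.stack([k.array for k in filters])
    else:
        bank = np.asarray(filters)
        if bank.ndim == 2:
            bank = bank[None]
    flat = bank.reshape(bank.shape[0], -1)
    norms = np.linalg.norm(flat, axis=1)
    ok = norms > 0
    if not ok.all():
        warnings.warn("zero-norm filters excluded from cosine similarity")
    unit_filters = flat[ok] / norms[ok, None]
    levels = sorted({s.level for s in stimuli})
    sims = []
    for level in levels:
        vals = []
        for s in stimuli:
            if s.level != level:
                continue
            v = s.image.mean(axis=2).ravel()
            n = np.linalg.norm(v)
            if n == 0:
                warnings.warn("zero-norm stimulus excluded")
                continue
            vals.append(float((unit_filters @ (v / n)).max()))
        sims.append(np.mean(vals))
    return CurvatureSimilarity(
        levels=np.asarray(levels), similarity=np.asarray(sims)
    )
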