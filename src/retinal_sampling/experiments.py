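"""Canned desk-scale experiments on the surrogate V1.

These functions reproduce, at workstation scale, the four organizational
principles the retinal sampling layer induces: cortical magnification,
eccentricity-dependent receptive-field size, eccentricity-dependent
spatial-frequency tuning and frequency-dependent radial bias -- plus the
frequency-mechanism account (sensitivity curve x local frequency content)
and the curvature control.

Scale choices (documented in the methods note): visual-field rasters of
512 px (256 px for the bar-sweep pRF stimuli) over a 20-deg field, a 128-px
ganglion raster, and a pRF grating family reduced to 4 orientations x
4 spatial frequencies x 4 phases. The full-scale family (2048-px images,
1024 gratings per bar position) is a GPU workload; every qualitative
prediction tested here is scale-free. All runs are deterministic -- there
is no randomness anywhere in the pipeline.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .network import SurrogateV1, SurrogateV1Config, build_surrogate_v1
from .prf import (
    CandidateGrid,
    RetinotopyResult,
    activation_profiles,
    candidate_profiles,
    fit_prf,
)
from .resampler import SamplingSpec, unit_eccentricity, unit_position_linear
from .stimuli import (
    GratingFamily,
    GratingSpec,
    make_bar_aperture_set,
    make_gabor_bank,
    make_grating,
    make_prf_stimulus_batch,
)
from .tuning import (
    SensitivityCurve,
    SFTuningCurve,
    bias_sweep,
    build_gabor_pyramid,
    dominant_frequency_map,
    orientation_maps,
    polar_bin_profile,
    predicted_response_map,
    radial_bias_ratio,
    sensitivity_curve,
    sf_tuning,
)

__all__ = [
    "FOV",
    "surrogate_adapter",
    "control_adapter",
    "prf_experiment",
    "prf_magnification",
    "prf_ecc_size",
    "geometric_unit_positions",
    "full_coverage_eccentricity",
    "radial_bias_experiment",
    "sf_tuning_experiment",
    "layer_sensitivity",
    "mechanism_experiment",
    "curvature_experiment",
]

#: Field of view (deg, diameter) of all desk-scale experiments.
FOV = 20.0

#: Ganglion-space (RSL output) raster width.
GANGLION_WIDTH = 128

#: Visual-field raster for full-field stimuli (gratings, sinrings).
FIELD_WIDTH = 512

#: Visual-field raster for the bar-sweep pRF stimuli.
PRF_FIELD_WIDTH = 256

#: pRF grating family, scaled down from the 1024-grating full-scale family;
#: spatial frequencies span the surrogate's band across eccentricities.
PRF_FAMILY = GratingFamily(
    orientations=(0.0, 45.0, 90.0, 135.0),
    spatial_frequencies=(1.0, 2.0, 4.0, 6.0),
    n_phases=4,
    phase_span="full",
)


@lru_cache(maxsize=4)
def surrogate_adapter(
    input_width: int = FIELD_WIDTH, output_width: int = GANGLION_WIDTH
) -> SurrogateV1:
    """Surrogate V1 behind the RSL (the RSL-network condition)."""
    spec = SamplingSpec(input_width=input_width, output_width=output_width, fov=FOV)
    return build_surrogate_v1(SurrogateV1Config(sampling=spec, include_rsl=True))


@lru_cache(maxsize=2)
def control_adapter(input_width: int = GANGLION_WIDTH) -> SurrogateV1:
    """Same filter stage without the RSL (uniform-sampling control)."""
    spec = SamplingSpec(input_width=input_width, output_width=input_width, fov=FOV)
    return build_surrogate_v1(SurrogateV1Config(sampling=spec, include_rsl=False))


def _bar_geometry(size: int) -> tuple[int, int]:
    """Bar width/stride in px for a raster: 8 px / 8 px at 256 (0.625 deg),
    scaled with the raster so bar geometry is constant in degrees."""
    width = max(1, round(8 * size / 256))
    return width, width


@lru_cache(maxsize=2)
def desk_apertures(size: int):
    """Bar aperture set at the desk-scale raster (0.625-deg bars/stride)."""
    width, stride = _bar_geometry(size)
    return make_bar_aperture_set(size, bar_width=width, stride=stride)


@lru_cache(maxsize=2)
def desk_candidate_profiles(size: int):
    """Candidate-Gaussian profiles (16,384 locations x 20 sizes) for the
    desk-scale aperture set."""
    return candidate_profiles(CandidateGrid(fov=FOV), desk_apertures(size))


@lru_cache(maxsize=4)
def prf_experiment(include_rsl: bool = True) -> RetinotopyResult:
    """Run the full pRF mapping pipeline on the surrogate (or control).

    Bars sweep the field at 4 orientations revealing the scaled-down grating
    family; unit response profiles are fitted against the default candidate
    grid (16,384 locations x 20 sizes).
    """
    if include_rsl:
        size = PRF_FIELD_WIDTH
        adapter = surrogate_adapter(size, GANGLION_WIDTH)
    else:
        size = GANGLION_WIDTH
        adapter = control_adapter(size)
    apertures = desk_apertures(size)
    batch = make_prf_stimulus_batch(apertures, PRF_FAMILY, fov=FOV)
    profiles = activation_profiles(adapter, batch)
    cand = desk_candidate_profiles(size)
    return fit_prf(profiles, cand)


def geometric_unit_positions(adapter: SurrogateV1) -> tuple[np.ndarray, np.ndarray]:
    """(eccentricity, polar angle) of every map unit from pure geometry
    (RGC inverse map behind the RSL, linear mapping for the control)."""
    m = adapter.map_width
    rows, cols = np.mgrid[0:m, 0:m]
    spec = adapter.config.sampling
    if adapter.config.include_rsl:
        return unit_eccentricity(
            rows.ravel(), cols.ravel(), adapter.downsample_factor, spec,
            adapter.coord_offset,
        )
    return unit_position_linear(
        rows.ravel(), cols.ravel(), adapter.downsample_factor,
        spec.input_width, spec.fov, adapter.coord_offset,
    )


def full_coverage_eccentricity(adapter: SurrogateV1 | None = None) -> float:
    """Largest eccentricity whose annulus is fully inside the square layer
    map (the map's inscribed circle); units and bins beyond it are clipped
    by map geometry rather than thinned by the sampling model."""
    if adapter is None:
        adapter = surrogate_adapter(PRF_FIELD_WIDTH, GANGLION_WIDTH)
    spec = adapter.config.sampling
    center = (adapter.map_width - 1) / 2.0
    if adapter.config.include_rsl:
        ecc, _ = unit_eccentricity(
            0.0, center, adapter.downsample_factor, spec, adapter.coord_offset
        )
    else:
        ecc, _ = unit_position_linear(
            0.0, center, adapter.downsample_factor, spec.input_width, spec.fov,
            adapter.coord_offset,
        )
    return float(ecc)


def _covered_result(include_rsl: bool):
    """pRF result restricted to units whose pooling window lies inside the
    fully-covered field (map-corner units are clipped by the square map and
    their estimates are edge artifacts)."""
    result = prf_experiment(include_rsl)
    adapter = (
        surrogate_adapter(PRF_FIELD_WIDTH, GANGLION_WIDTH)
        if include_rsl
        else control_adapter(GANGLION_WIDTH)
    )
    limit = full_coverage_eccentricity(adapter)
    gecc, _ = geometric_unit_positions(adapter)
    table = result.table[gecc <= limit].reset_index(drop=True)
    return RetinotopyResult(table=table, map_shape=result.map_shape), limit


def prf_magnification(include_rsl: bool = True):
    """Cortical magnification curve over fully-covered 1-deg bins."""
    from .prf import magnification

    result, limit = _covered_result(include_rsl)
    return magnification(result, max_ecc=float(np.floor(limit)))


def prf_ecc_size(include_rsl: bool = True):
    """Receptive-field size vs eccentricity fit over fully-covered units."""
    from .prf import fit_ecc_size

    result, _ = _covered_result(include_rsl)
    return fit_ecc_size(result)


@lru_cache(maxsize=8)
def radial_bias_experiment(
    spatial_frequencies: tuple[float, ...],
    include_rsl: bool = True,
    n_phases: int = 32,
):
    """Radial-bias sweep on the surrogate (8 orientations, 32 phases)."""
    adapter = (
        surrogate_adapter(FIELD_WIDTH, GANGLION_WIDTH)
        if include_rsl
        else control_adapter(GANGLION_WIDTH)
    )
    return bias_sweep(
        adapter, spatial_frequencies=spatial_frequencies, n_phases=n_phases, fov=FOV
    )


@lru_cache(maxsize=2)
def sf_tuning_experiment(include_rsl: bool = True) -> SFTuningCurve:
    """Sinring eccentricity x frequency sweep on the surrogate."""
    adapter = (
        surrogate_adapter(FIELD_WIDTH, GANGLION_WIDTH)
        if include_rsl
        else control_adapter(GANGLION_WIDTH)
    )
    return sf_tuning(adapter, fov=FOV)


@lru_cache(maxsize=1)
def layer_sensitivity() -> SensitivityCurve:
    """Spatial-frequency sensitivity of the surrogate's filter bank on its
    own 11-px patch (cycles per image of the patch)."""
    adapter = surrogate_adapter(FIELD_WIDTH, GANGLION_WIDTH)
    return sensitivity_curve(adapter.filters)


@lru_cache(maxsize=8)
def mechanism_experiment(
    spatial_frequency: float,
    orientation: float = 45.0,
    n_phases: int = 4,
) -> dict:
    """Frequency-mechanism prediction vs direct measurement at one grating.

    Predicted: the grating is resampled, its local dominant frequency
    extracted with a Gabor pyramid and combined with the layer sensitivity
    curve; the predicted response map is polar-binned and summarized by the
    radial-bias ratio. Measured: orientation maps of the surrogate at the
    same frequency, binned identically. Returns both ratios.
    """
    from .resampler import build_weights, resample

    adapter = surrogate_adapter(FIELD_WIDTH, GANGLION_WIDTH)
    spec = adapter.config.sampling
    sens = layer_sensitivity()
    pyramid = build_gabor_pyramid(GANGLION_WIDTH)
    weights = build_weights(spec)

    phases = -np.pi + np.arange(n_phases) * 2.0 * np.pi / n_phases
    predicted = np.zeros((GANGLION_WIDTH, GANGLION_WIDTH))
    for ph in phases:
        grating = make_grating(
            GratingSpec(
                orientation=orientation,
                spatial_frequency=spatial_frequency,
                phase=float(ph),
                size=FIELD_WIDTH,
                fov=FOV,
            ),
            rgb=False,
        )
        resampled = resample(grating, weights)
        fmap = dominant_frequency_map(
            resampled, pyramid, background=0.5, valid_mask=weights.covered
        )
        predicted += predicted_response_map(fmap, sens)
    predicted /= n_phases
    pred_profile = polar_bin_profile(predicted, spec, downsample_factor=1.0,
                                     coord_offset=0.0)
    pred_ratio = radial_bias_ratio(pred_profile, orientation)

    omaps = orientation_maps(
        adapter, (orientation,), spatial_frequency, n_phases=32, fov=FOV
    )
    meas_profile = polar_bin_profile(
        omaps[orientation], spec, adapter.downsample_factor, adapter.coord_offset
    )
    meas_ratio = radial_bias_ratio(meas_profile, orientation)
    return {
        "predicted_ratio": pred_ratio,
        "measured_ratio": meas_ratio,
        "predicted_map": predicted,
        "orientation": orientation,
        "spatial_frequency": spatial_frequency,
    }


def curvature_experiment():
    """Gabor-bank cosine similarity over curvature levels (7-px raster)."""
    from .stimuli import make_curved_line_set
    from .tuning import curvature_similarity

    bank = make_gabor_bank(size=7, wavelength=2.0 * np.pi, n_orientations=16)
    return curvature_similarity(bank, make_curved_line_set())
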