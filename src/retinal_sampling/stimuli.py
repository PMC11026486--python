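"""Stimulus families for the in-silico neurophysiology experiments.

All generators are deterministic and produce images with values in [0, 1].

Orientation convention (used package-wide): the ``orientation`` of a grating,
bar or Gabor is the orientation of its *stripes* / long axis, measured
counterclockwise from the +x axis with "up" at +90 deg. The luminance of a
grating of orientation ``theta`` therefore modulates along ``theta + 90``:
a 45 deg grating has stripes running along the 45-225 deg meridian, which is
what "radially aligned at 45 deg polar angle" means in the radial-bias
analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GratingSpec",
    "BarApertureSet",
    "SinringSpec",
    "GaborKernel",
    "CurvedLineStimulus",
    "GratingFamily",
    "PRFStimulusBatch",
    "make_grating",
    "make_bar_aperture_set",
    "make_prf_stimulus_batch",
    "make_sinring",
    "make_sinring_batch",
    "make_curved_line",
    "make_curved_line_set",
    "make_gabor_kernel",
    "make_gabor_bank",
    "SINRING_ECCENTRICITIES",
    "SINRING_CPR_COEFFICIENTS",
    "PRF_SPATIAL_FREQUENCIES",
]

#: Sinring eccentricities (deg) of the eccentricity/spatial-frequency sweep.
SINRING_ECCENTRICITIES = (1.0, 2.8, 4.7, 6.6, 8.5)

#: Angular-frequency coefficients c: the ring at eccentricity e is driven at
#: (c / pi) * e cycles per radian, i.e. an arc frequency of c/pi cycles/deg
#: that is identical across eccentricities for a fixed coefficient.
SINRING_CPR_COEFFICIENTS = (2, 5, 8, 11, 14, 17, 20, 23)

#: Grating spatial frequencies (c/deg) of the full-scale pRF mapping family.
PRF_SPATIAL_FREQUENCIES = (0.0735, 0.147, 0.294, 0.5885)


def _degree_grid(size: int, fov: float) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-center coordinates in degrees (x right, y up), centered."""
    deg_per_px = fov / size
    c = (size - 1) / 2.0
    rows, cols = np.mgrid[0:size, 0:size]
    return (cols - c) * deg_per_px, (c - rows) * deg_per_px


def _to_rgb(plane: np.ndarray) -> np.ndarray:
    return np.repeat(plane[:, :, None], 3, axis=2)


# ---------------------------------------------------------------------------
# Sinusoidal gratings
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GratingSpec:
    """Full-field sinusoidal grating: stripe orientation (deg), spatial
    frequency (cycles/deg), phase (rad), raster size (px), fov (deg)."""

    orientation: float
    spatial_frequency: float
    phase: float = 0.0
    size: int = 512
    fov: float = 20.0
    contrast: float = 1.0

    def __post_init__(self) -> None:
        if self.spatial_frequency <= 0:
            raise ValueError("spatial_frequency must be > 0")
        if not 0.0 <= self.contrast <= 1.0:
            raise ValueError("contrast must lie in [0, 1]")


def make_grating(spec: GratingSpec, rgb: bool = True) -> np.ndarray:
    """Render a grating; luminance 0.5 + 0.5*contrast*sin(2 pi f u + phase),
    where u is the coordinate along the modulation direction (orientation+90)."""
    x, y = _degree_grid(spec.size, spec.fov)
    theta = math.radians(spec.orientation + 90.0)
    u = x * math.cos(theta) + y * math.sin(theta)
    plane = 0.5 + 0.5 * spec.contrast * np.sin(
        2.0 * math.pi * spec.spatial_frequency * u + spec.phase
    )
    return _to_rgb(plane) if rgb else plane


# ---------------------------------------------------------------------------
# Bar apertures and the pRF stimulus batch
# ---------------------------------------------------------------------------


@dataclass
class BarApertureSet:
    """Ordered binary bar masks sweeping the image at four orientations.

    ``masks`` is (n_positions, size, size) uint8; ``orientations`` and
    ``offsets`` give, per mask, the bar's long-axis orientation (deg) and its
    sweep offset (px along the bar normal).
    """

    size: int
    bar_width: int
    stride: int
    masks: np.ndarray
    orientations: np.ndarray
    offsets: np.ndarray

    @property
    def n_positions(self) -> int:
        return self.masks.shape[0]


def make_bar_aperture_set(
    size: int,
    bar_width: int = 8,
    stride: int = 4,
    orientations: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0),
) -> BarApertureSet:
    """Bars of ``bar_width`` px swept in ``stride``-px steps at each
    orientation; offsets run while the bar fits fully inside its sweep range
    (size=256, width=8, stride=4 gives 63 positions for axis-aligned bars).
    """
    if bar_width > size:
        raise ValueError("bar_width must not exceed the image size")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    rows, cols = np.mgrid[0:size, 0:size].astype(float)
    masks, oris, offs = [], [], []
    for ori in orientations:
        # signed coordinate along the bar normal, shifted to start at 0
        if ori == 0.0:  # horizontal bar swept vertically
            n = rows
        elif ori == 90.0:
            n = cols
        elif ori == 45.0:
            n = (rows + cols) / math.sqrt(2.0)
        elif ori == 135.0:
            n = (cols - rows) / math.sqrt(2.0)
            n = n - n.min()
        else:
            phi = math.radians(ori + 90.0)
            n = cols * math.cos(phi) - rows * math.sin(phi)
            n = n - n.min()
        # sweep extent in px; +1 counts the last pixel's full footprint so
        # that size=256, width=8, stride=4 yields offsets 0..248 (63 masks)
        n_max = n.max() + 1.0
        offsets = []
        o = 0.0
        while o + bar_width <= n_max + 1e-9:
            offsets.append(o)
            o += stride
        # diagonal sweep lengths are not multiples of the stride: append a
        # right-aligned bar when the regular sweep leaves an uncovered edge
        if offsets and offsets[-1] + bar_width < n_max - 1e-9:
            offsets.append(n_max - bar_width)
        for o in offsets:
            masks.append(((n >= o) & (n < o + bar_width)).astype(np.uint8))
            oris.append(ori)
            offs.append(o)
    return BarApertureSet(
        size=size,
        bar_width=bar_width,
        stride=stride,
        masks=np.stack(masks),
        orientations=np.asarray(oris),
        offsets=np.asarray(offs),
    )


@dataclass(frozen=True)
class GratingFamily:
    """The grating family revealed behind each bar aperture."""

    orientations: tuple[float, ...] = tuple(np.arange(8) * 22.5)
    spatial_frequencies: tuple[float, ...] = PRF_SPATIAL_FREQUENCIES
    n_phases: int = 32
    phase_span: str = "printed"  # "printed": 0..1.75*pi incl.; "full": 0..2*pi excl.
    contrast: float = 1.0

    @property
    def phases(self) -> np.ndarray:
        if self.phase_span == "printed":
            return np.linspace(0.0, 1.75 * math.pi, self.n_phases)
        if self.phase_span == "full":
            return np.arange(self.n_phases) * 2.0 * math.pi / self.n_phases
        raise ValueError(f"unknown phase_span {self.phase_span!r}")

    @property
    def n_gratings(self) -> int:
        return len(self.orientations) * len(self.spatial_frequencies) * self.n_phases


@dataclass
class PRFStimulusBatch:
    """Lazily evaluated batch of masked gratings, ordered (position, grating).

    ``gratings_for(position)`` returns the (n_gratings, size, size) stack of
    single-channel stimuli for one bar position: the grating inside the bar,
    zero background.
    """

    apertures: BarApertureSet
    family: GratingFamily
    fov: float = 20.0
    _gratings: np.ndarray = field(default=None, repr=False)

    @property
    def n_positions(self) -> int:
        return self.apertures.n_positions

    @property
    def n_gratings(self) -> int:
        return self.family.n_gratings

    def grating_stack(self) -> np.ndarray:
        """All gratings of the family (unmasked), cached, float32."""
        if self._gratings is None:
            fam = self.family
            stack = np.empty(
                (fam.n_gratings, self.apertures.size, self.apertures.size),
                dtype=np.float32,
            )
            i = 0
            for ori in fam.orientations:
                for sf in fam.spatial_frequencies:
                    for ph in fam.phases:
                        stack[i] = make_grating(
                            GratingSpec(
                                orientation=ori,
                                spatial_frequency=sf,
                                phase=ph,
                                size=self.apertures.size,
                                fov=self.fov,
                                contrast=fam.contrast,
                            ),
                            rgb=False,
                        )
                        i += 1
            self._gratings = stack
        return self._gratings

    def gratings_for(self, position: int) -> np.ndarray:
        mask = self.apertures.masks[position]
        return self.grating_stack() * mask[None, :, :]


def make_prf_stimulus_batch(
    apertures: BarApertureSet,
    family: GratingFamily | None = None,
    fov: float = 20.0,
) -> PRFStimulusBatch:
    """Bundle apertures with a grating family (defaults to the full-scale
    8 orientations x 4 spatial frequencies x 32 phases = 1024 gratings)."""
    return PRFStimulusBatch(apertures=apertures, family=family or GratingFamily(), fov=fov)


# ---------------------------------------------------------------------------
# Sinrings
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SinringSpec:
    """Annulus at ``eccentricity`` deg whose luminance varies sinusoidally
    with polar angle at ``angular_frequency`` cycles/radian."""

    eccentricity: float
    angular_frequency: float
    phase: float = 0.0
    annulus_halfwidth: float = 0.9
    size: int = 512
    fov: float = 20.0

    def __post_init__(self) -> None:
        if self.eccentricity + self.annulus_halfwidth > self.fov / 2.0:
            raise ValueError("annulus extends beyond the field of view")
        if self.eccentricity - self.annulus_halfwidth < 0:
            raise ValueError("annulus extends through the fovea")


def make_sinring(spec: SinringSpec, rgb: bool = True) -> np.ndarray:
    """Render a sinring: 0.5 + 0.5*sin(2 pi f_ang theta + phase) inside the
    annulus (f_ang in cycles/radian, so the ring carries 2 pi f_ang cycles),
    mid-gray 0.5 outside (hard annulus edges)."""
    x, y = _degree_grid(spec.size, spec.fov)
    r = np.hypot(x, y)
    theta = np.arctan2(y, x)
    ring = np.abs(r - spec.eccentricity) <= spec.annulus_halfwidth
    plane = np.full((spec.size, spec.size), 0.5)
    plane[ring] = 0.5 + 0.5 * np.sin(
        2.0 * math.pi * spec.angular_frequency * theta[ring] + spec.phase
    )
    return _to_rgb(plane) if rgb else plane


def make_sinring_batch(
    eccentricities: tuple[float, ...] = SINRING_ECCENTRICITIES,
    coefficients: tuple[float, ...] = SINRING_CPR_COEFFICIENTS,
    n_phases: int = 8,
    size: int = 512,
    fov: float = 20.0,
    annulus_halfwidth: float = 0.9,
) -> list[SinringSpec]:
    """Specs for the full eccentricity x frequency (x phase) sinring sweep.

    The ring at eccentricity ``e`` and coefficient ``c`` runs at
    ``(c / pi) * e`` cycles/radian, so its arc spatial frequency ``c / pi``
    c/deg is matched across eccentricities.
    """
    phases = np.arange(n_phases) * 2.0 * math.pi / n_phases
    return [
        SinringSpec(
            eccentricity=e,
            angular_frequency=(c / math.pi) * e,
            phase=ph,
            annulus_halfwidth=annulus_halfwidth,
            size=size,
            fov=fov,
        )
        for e in eccentricities
        for c in coefficients
        for ph in phases
    ]


# ---------------------------------------------------------------------------
# Curved lines
# ---------------------------------------------------------------------------


@dataclass
class CurvedLineStimulus:
    """White 1-px line on black, 7x7x3; curvature via midpoint displacement."""

    image: np.ndarray
    orientation: float
    level: int
    direction: int


_LINE_ENDPOINTS = {
    # (row, col) endpoints on the 7x7 raster, orientation = line axis
    0.0: ((3, 0), (3, 6)),
    90.0: ((0, 3), (6, 3)),
    45.0: ((6, 0), (0, 6)),
    135.0: ((0, 0), (6, 6)),
}

#: Maximum midpoint displacement (px) at the top curvature level.
_MAX_MIDPOINT_DISPLACEMENT = 3.0


def make_curved_line(
    orientation: float, level: int, direction: int = 1, n_levels: int = 6
) -> CurvedLineStimulus:
    """Rasterize a 1-px line with fixed endpoints whose midpoint is displaced
    perpendicularly by ``3 * level / (n_levels - 1)`` px (level 0 straight,
    level 5 maximally curved, bending toward ``direction``)."""
    if orientation not in _LINE_ENDPOINTS:
        raise ValueError("orientation must be one of 0, 45, 90, 135")
    if not 0 <= level < n_levels:
        raise ValueError(f"level must lie in [0, {n_levels - 1}]")
    if direction not in (1, -1):
        raise ValueError("direction must be +1 or -1")
    (r0, c0), (r1, c1) = _LINE_ENDPOINTS[orientation]
    p0 = np.array([r0, c0], dtype=float)
    p2 = np.array([r1, c1], dtype=float)
    axis = p2 - p0
    normal = np.array([-axis[1], axis[0]]) / np.linalg.norm(axis)
    d = _MAX_MIDPOINT_DISPLACEMENT * level / (n_levels - 1) * direction
    # one pixel per sample along the line axis (a 1-px "function graph":
    # pixel count is constant over levels and orientations, so cosine
    # similarities are not confounded by rasterization density); the
    # parabolic displacement profile peaks at d on the midpoint
    t = np.linspace(0.0, 1.0, 7)[:, None]
    pts = p0 + t * axis + (4.0 * t * (1.0 - t) * d) * normal
    rr = np.clip(np.round(pts[:, 0]).astype(int), 0, 6)
    cc = np.clip(np.round(pts[:, 1]).astype(int), 0, 6)
    plane = np.zeros((7, 7))
    plane[rr, cc] = 1.0
    return CurvedLineStimulus(
        image=_to_rgb(plane), orientation=orientation, level=level, direction=direction
    )


def make_curved_line_set(n_levels: int = 6) -> list[CurvedLineStimulus]:
    """All orientations x curvature levels x bend directions."""
    out = []
    for level in range(n_levels):
        for ori in _LINE_ENDPOINTS:
            for direction in (1, -1):
                out.append(make_curved_line(ori, level, direction, n_levels))
    return out


# ---------------------------------------------------------------------------
# Gabor kernels
# ---------------------------------------------------------------------------


@dataclass
class GaborKernel:
    """2-D Gabor with isotropic Gaussian envelope (replicated over RGB when
    used as a 3-channel filter). Zero mean after DC removal."""

    array: np.ndarray
    size: int
    wavelength: float
    orientation: float
    phase: float
    envelope_sd: float

    @property
    def rgb(self) -> np.ndarray:
        return np.repeat(self.array[:, :, None], 3, axis=2)


def make_gabor_kernel(
    size: int,
    wavelength: float,
    orientation: float,
    phase: float = 0.0,
    envelope_sd: float | None = None,
    normalize: bool = True,
) -> GaborKernel:
    """Single Gabor kernel; ``orientation`` is the stripe orientation, the
    carrier modulates along ``orientation + 90``. Envelope sd defaults to
    half the wavelength. DC is removed; optionally L2-normalized."""
    sd = wavelength / 2.0 if envelope_sd is None else envelope_sd
    c = (size - 1) / 2.0
    rows, cols = np.mgrid[0:size, 0:size]
    x = cols - c
    y = c - rows
    theta = math.radians(orientation + 90.0)
    u = x * math.cos(theta) + y * math.sin(theta)
    g = np.exp(-(x**2 + y**2) / (2.0 * sd**2)) * np.cos(
        2.0 * math.pi * u / wavelength + phase
    )
    g = g - g.mean()
    if normalize:
        norm = np.linalg.norm(g)
        if norm > 0:
            g = g / norm
    return GaborKernel(
        array=g,
        size=size,
        wavelength=wavelength,
        orientation=orientation % 180.0,
        phase=phase,
        envelope_sd=sd,
    )


def make_gabor_bank(
    size: int = 11,
    wavelength: float = 2.0 * math.pi,
    n_orientations: int = 16,
    phases: tuple[float, ...] = (0.0,),
    envelope_sd: float | None = None,
    normalize: bool = True,
) -> list[GaborKernel]:
    """Bank of Gabors at evenly spaced orientations over [0, 180)."""
    if n_orientations < 1:
        raise ValueError("n_orientations must be >= 1")
    oris = np.arange(n_orientations) * 180.0 / n_orientations
    return [
        make_gabor_kernel(size, wavelength, ori, ph, envelope_sd, normalize)
        for ori in oris
        for ph in phases
    ]
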