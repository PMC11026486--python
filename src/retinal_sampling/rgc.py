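"""Closed-form model of retinal ganglion cell (RGC) density over eccentricity.

The density of retinal ganglion cells falls off steeply with eccentricity
``r`` (degrees of visual angle from fixation)::

    rho(r) = rho0 * [ alpha * (1 + r/k)**-2 + (1 - alpha) * exp(-r/sigma) ]

where ``rho0`` is the foveal density (cells/deg^2), ``k`` the eccentricity at
which density has dropped to a quarter, ``sigma`` the scale of a small
exponential correction and ``alpha`` the weight of the quadratic term.

With ``alpha == 1`` the cumulative 1-D cell count along a ray (the "ganglion
cell radius") has the closed form::

    r_gc(r) = rho0 * k * r / (k + r)

which is bounded above by ``rho0 * k`` and is inverted exactly by::

    r_vf(r_gc) = k * r_gc / (rho0 * k - r_gc)

These three maps are the geometric core of the retinal sampling layer: they
convert visual-field radii to ganglion-cell radii and back.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "RGCDensityParams",
    "DEFAULT_PARAMS",
    "density",
    "cumulative_radius",
    "inverse_radius",
]


@dataclass(frozen=True)
class RGCDensityParams:
    """Parameters of the RGC density model.

    Attributes
    ----------
    rho0 : float
        Density at zero eccentricity, cells/deg^2.
    k : float
        Eccentricity (deg) at which density is reduced by a factor of four.
    sigma : float
        Scale factor (deg) of the exponential term.
    alpha : float
        Weight of the quadratic term, in [0, 1]. The cumulative/inverse pair
        is only available for ``alpha == 1``.
    fov : float
        Modeled field of view, *diameter* in degrees (radius ``fov / 2``).
    """

    rho0: float = 33162.0
    k: float = 1.05
    sigma: float = 22.0
    alpha: float = 1.0
    fov: float = 20.0

    def __post_init__(self) -> None:
        if self.rho0 <= 0 or self.k <= 0 or self.sigma <= 0 or self.fov <= 0:
            raise ValueError("rho0, k, sigma and fov must all be positive")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")

    @property
    def max_cell_radius(self) -> float:
        """Asymptotic 1-D cell count ``rho0 * k`` (alpha == 1 closed form)."""
        return self.rho0 * self.k

    def as_dict(self) -> dict:
        return asdict(self)

    def replace(self, **kwargs) -> "RGCDensityParams":
        return replace(self, **kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "RGCDensityParams":
        """Load parameters from a YAML or JSON config with keys
        rho0, k, sigma, alpha, fov (missing keys keep the packaged defaults)."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"config {path} does not contain a mapping")
        known = {"rho0", "k", "sigma", "alpha", "fov"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown parameter keys {sorted(unknown)} in {path}")
        return cls(**{k: float(v) for k, v in data.items()})


#: Packaged defaults (human RGC density, 20 deg field of view).
DEFAULT_PARAMS = RGCDensityParams()


def _check_nonnegative(r, name: str) -> np.ndarray:
    arr = np.asarray(r, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"{name} must be non-negative")
    return arr


def _require_alpha_one(params: RGCDensityParams, what: str) -> None:
    if params.alpha != 1.0:
        raise ValueError(
            f"{what} requires alpha == 1 (closed form); got alpha={params.alpha}"
        )


def density(r_vf, params: RGCDensityParams = DEFAULT_PARAMS):
    """RGC density (cells/deg^2) at eccentricity ``r_vf`` (deg).

    Strictly positive and non-increasing in ``r_vf``. Accepts scalars or
    arrays; negative eccentricities raise ``ValueError``.
    """
    r = _check_nonnegative(r_vf, "r_vf")
    p = params
    quad = p.alpha * (1.0 + r / p.k) ** -2
    expo = (1.0 - p.alpha) * np.exp(-r / p.sigma)
    out = p.rho0 * (quad + expo)
    return out if out.ndim else float(out)


def cumulative_radius(r_vf, params: RGCDensityParams = DEFAULT_PARAMS):
    """Ganglion-cell radius: 1-D cell count accumulated over ``[0, r_vf]``.

    Closed form ``rho0 * k * r / (k + r)`` for ``alpha == 1``; equals the
    integral of :func:`density` along the ray. Strictly increasing from 0 and
    bounded above by ``rho0 * k``.
    """
    _require_alpha_one(params, "cumulative_radius")
    r = _check_nonnegative(r_vf, "r_vf")
    out = params.rho0 * params.k * r / (params.k + r)
    return out if out.ndim else float(out)


def inverse_radius(r_gc, params: RGCDensityParams = DEFAULT_PARAMS):
    """Eccentricity (deg) at which the cumulative cell count equals ``r_gc``.

    Exact functional inverse of :func:`cumulative_radius`; defined for
    ``0 <= r_gc < rho0 * k``.
    """
    _require_alpha_one(params, "inverse_radius")
    g = _check_nonnegative(r_gc, "r_gc")
    if np.any(g >= params.max_cell_radius):
        raise ValueError(
            f"r_gc must be < rho0*k = {params.max_cell_radius}; "
            "larger values exceed the total 1-D cell count"
        )
    out = params.k * g / (params.rho0 * params.k - g)
    return out if out.ndim else float(out)
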