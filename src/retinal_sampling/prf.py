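"""Population receptive field (pRF) mapping for layer adapters.

The procedure mirrors visual-field mapping in neuroimaging, adapted to
feature maps: bar apertures sweep the visual field revealing gratings;
channel-averaged *population maps* are averaged over the gratings of each
bar position into activation maps; each map unit's response profile over bar
positions is correlated against the profiles of a grid of candidate
isotropic-Gaussian receptive fields, and the best-correlated candidate gives
the unit's position (hence eccentricity and polar angle) and size sigma.

Downstream summaries: cortical magnification (unit counts per 1-deg
eccentricity bin, with linear and exponential-decay fits) and the linear
receptive-field-size vs eccentricity fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .network import LayerAdapter
from .stimuli import BarApertureSet, PRFStimulusBatch

__all__ = [
    "CandidateGrid",
    "CandidateProfiles",
    "ResponseProfiles",
    "RetinotopyResult",
    "MagnificationCurve",
    "EccSizeFit",
    "population_map",
    "activation_profiles",
    "candidate_profiles",
    "fit_prf",
    "magnification",
    "fit_ecc_size",
]


def population_map(feature_maps: np.ndarray) -> np.ndarray:
    """Channel mean of (C, H, W) feature maps -> (H, W) population map."""
    feature_maps = np.asarray(feature_maps)
    if feature_maps.ndim != 3 or feature_maps.shape[0] < 1:
        raise ValueError("expected non-empty (channels, H, W) feature maps")
    return feature_maps.mean(axis=0)


@dataclass
class ResponseProfiles:
    """Per-unit response profiles: (n_units, n_positions), plus map shape.

    Unit ``u`` is map pixel ``(u // map_width, u % map_width)``.
    """

    profiles: np.ndarray
    map_shape: tuple[int, int]


def activation_profiles(
    adapter: LayerAdapter, batch: PRFStimulusBatch, chunk: int = 16
) -> ResponseProfiles:
    """Mean population response of every map unit to every bar position.

    For each position, population maps over the batch's gratings are
    averaged into one activation map; a unit's profile is its activation
    across positions (ordering follows the aperture set).
    """
    n_pos = batch.n_positions
    maps = None
    for p in range(n_pos):
        stimuli = batch.gratings_for(p)
        feats = adapter.batch(stimuli, chunk=chunk)  # (G, C, H, W)
        act = feats.mean(axis=(0, 1))  # grating- and channel-average
        if maps is None:
            maps = np.empty((n_pos,) + act.shape)
        maps[p] = act
    profiles = maps.reshape(n_pos, -1).T
    return ResponseProfiles(profiles=profiles, map_shape=maps.shape[1:])


@dataclass(frozen=True)
class CandidateGrid:
    """Candidate Gaussian receptive fields on a uniform location x size grid.

    Default: 128 x 128 locations covering the fov square (16,384) and 20
    linear sizes in [0.025, 1.6] deg.
    """

    fov: float = 20.0
    n_locations_side: int = 128
    n_sizes: int = 20
    size_range: tuple[float, float] = (0.025, 1.6)

    @property
    def locations(self) -> np.ndarray:
        """1-D location coordinates (deg) shared by x and y."""
        return np.linspace(-self.fov / 2.0, self.fov / 2.0, self.n_locations_side)

    @property
    def sizes(self) -> np.ndarray:
        return np.linspace(self.size_range[0], self.size_range[1], self.n_sizes)

    @property
    def n_candidates(self) -> int:
        return self.n_sizes * self.n_locations_side**2


@dataclass
class CandidateProfiles:
    """Precomputed candidate response profiles.

    ``profiles`` has shape (n_sizes, n_y, n_x, n_positions) float32 where
    ``n_y``/``n_x`` index candidate center y (deg, ascending) and x. Profile
    entries are unit-sum-Gaussian x mask dot products.
    """

    grid: CandidateGrid
    profiles: np.ndarray

    def flat(self) -> np.ndarray:
        return self.profiles.reshape(-1, self.profiles.shape[-1])

    def candidate_params(self, index: int) -> tuple[float, float, float]:
        """(x, y, sigma) of a flat candidate index (size-major ordering)."""
        n = self.grid.n_locations_side
        s, rest = divmod(index, n * n)
        iy, ix = divmod(rest, n)
        locs = self.grid.locations
        return float(locs[ix]), float(locs[iy]), float(self.grid.sizes[s])


def candidate_profiles(
    grid: CandidateGrid, apertures: BarApertureSet, fov: float | None = None
) -> CandidateProfiles:
    """Dot products of every candidate Gaussian with every bar mask.

    Exploits separability: for an isotropic Gaussian the dot product with a
    mask M is ``g_y^T M g_x``, so for each size the full location grid is two
    matrix products per mask. Gaussians are evaluated in degrees on the
    stimulus raster and normalized to unit sum (correlation-based fitting is
    scale-invariant, so this only fixes a convention).
    """
    fov = grid.fov if fov is None else fov
    size_px = apertures.size
    deg_per_px = fov / size_px
    c = (size_px - 1) / 2.0
    x_px = (np.arange(size_px) - c) * deg_per_px  # ascending x (deg)
    y_px = (c - np.arange(size_px)) * deg_per_px  # descending with row
    locs = grid.locations
    masks = apertures.masks.astype(np.float64)  # (P, H, W)
    n_pos = masks.shape[0]
    out = np.empty(
        (grid.n_sizes, locs.size, locs.size, n_pos), dtype=np.float32
    )
    for si, sg in enumerate(grid.sizes):
        gx = np.exp(-((x_px[:, None] - locs[None, :]) ** 2) / (2.0 * sg**2))
        gy = np.exp(-((y_px[:, None] - locs[None, :]) ** 2) / (2.0 * sg**2))
        gx /= gx.sum(axis=0, keepdims=True)
        gy /= gy.sum(axis=0, keepdims=True)
        for p in range(n_pos):
            # (n_y, H) @ (H, W) @ (W, n_x) -> (n_y, n_x)
            out[si, :, :, p] = gy.T @ masks[p] @ gx
    return CandidateProfiles(grid=grid, profiles=out)


@dataclass
class RetinotopyResult:
    """Per-unit pRF estimates as a DataFrame.

    Columns: x, y (deg), ecc, angle (deg), sigma (deg), r (Pearson fit),
    valid (bool). Row order matches unit order (row-major over the map).
    """

    table: pd.DataFrame
    map_shape: tuple[int, int]

    def valid(self) -> pd.DataFrame:
        return self.table[self.table["valid"]]


def _standardize(rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center and L2-normalize rows; returns (standardized, nonzero mask)."""
    centered = rows - rows.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    ok = norms > 0
    safe = np.where(ok, norms, 1.0)
    return centered / safe[:, None], ok


def fit_prf(
    unit_profiles: ResponseProfiles,
    candidates: CandidateProfiles,
    chunk: int = 20000,
) -> RetinotopyResult:
    """Assign each unit the candidate with maximal Pearson correlation.

    Zero-variance unit profiles are flagged invalid. Exact correlation ties
    break deterministically toward the smaller sigma (candidates are ordered
    size-major ascending and argmax keeps the first maximum).
    """
    cand = candidates.flat().astype(np.float64)
    cand_std, cand_ok = _standardize(cand)
    if not cand_ok.any():
        raise ValueError("all candidate profiles have zero variance")
    cand_std[~cand_ok] = 0.0

    units = np.asarray(unit_profiles.profiles, dtype=np.float64)
    unit_std, unit_ok = _standardize(units)

    n_units = units.shape[0]
    best_r = np.full(n_units, -np.inf)
    best_idx = np.zeros(n_units, dtype=np.int64)
    for start in range(0, cand_std.shape[0], chunk):
        block = cand_std[start : start + chunk]
        corr = unit_std @ block.T  # (n_units, chunk)
        corr[:, ~cand_ok[start : start + chunk]] = -np.inf
        idx = np.argmax(corr, axis=1)
        r = corr[np.arange(n_units), idx]
        better = r > best_r
        best_r[better] = r[better]
        best_idx[better] = idx[better] + start

    params = np.array(
        [candidates.candidate_params(i) for i in best_idx], dtype=float
    )
    x, y, sigma = params.T
    ecc = np.hypot(x, y)
    angle = np.degrees(np.arctan2(y, x)) % 360.0
    best_r[~unit_ok] = np.nan
    table = pd.DataFrame(
        {
            "x": x,
            "y": y,
            "ecc": ecc,
            "angle": angle,
            "sigma": sigma,
            "r": best_r,
            "valid": unit_ok,
        }
    )
    return RetinotopyResult(table=table, map_shape=unit_profiles.map_shape)


@dataclass
class MagnificationCurve:
    """Unit counts per eccentricity bin with linear and exponential fits."""

    bin_edges: np.ndarray
    counts: np.ndarray
    linear: tuple[float, float]  # slope, intercept
    linear_r2: float
    exponential: tuple[float, float, float]  # a, b, c of a*exp(-b E) + c
    exponential_r2: float


def _r_squared(yhat: np.ndarray, y: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0


def fit_exponential_decay(
    x: np.ndarray, y: np.ndarray
) -> tuple[tuple[float, float, float], float]:
    """Least-squares fit of ``a * exp(-b x) + c``, initialized from a
    log-linear fit of the min-shifted data. Returns ((a, b, c), R^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:  # under-determined: three parameters
        return (math.nan, math.nan, math.nan), math.nan
    shift = y - y.min() + 1e-9
    b0_slope, b0_icpt = np.polyfit(x, np.log(shift), 1)
    p0 = (float(np.exp(b0_icpt)), float(-b0_slope), float(y.min()))

    def model(xx, a, b, c):
        return a * np.exp(-b * xx) + c

    try:
        popt, _ = optimize.curve_fit(model, x, y, p0=p0, maxfev=20000, xtol=1e-8)
    except (RuntimeError, TypeError):
        popt = p0
    r2 = _r_squared(model(x, *popt), y)
    return (float(popt[0]), float(popt[1]), float(popt[2])), r2


def magnification(
    result: RetinotopyResult,
    bin_width: float = 1.0,
    max_ecc: float | None = None,
    outlier_sd: float = 3.0,
) -> MagnificationCurve:
    """Cortical magnification: valid-unit counts per eccentricity bin.

    Units whose fit correlation deviates from the mean by ``outlier_sd``
    standard deviations or more are discarded; counts are binned in
    ``bin_width``-deg contiguous bins up to ``max_ecc`` (default: the largest
    whole bin containing data) and fitted with a line and an exponential
    decay ``D = a exp(-b E) + c``.
    """
    valid = result.valid()
    if len(valid) == 0:
        raise ValueError("no valid units to bin")
    r = valid["r"].to_numpy()
    keep = np.abs(r - r.mean()) < outlier_sd * r.std() if r.std() > 0 else np.ones(
        len(r), dtype=bool
    )
    ecc = valid["ecc"].to_numpy()[keep]
    if max_ecc is None:
        max_ecc = np.ceil(ecc.max() / bin_width) * bin_width
    edges = np.arange(0.0, max_ecc + bin_width / 2.0, bin_width)
    counts, _ = np.histogram(ecc, bins=edges)
    if np.count_nonzero(counts) < 3:
        raise ValueError("fewer than 3 nonempty eccentricity bins; cannot fit")
    centers = (edges[:-1] + edges[1:]) / 2.0
    lin = np.polyfit(centers, counts, 1)
    lin_r2 = _r_squared(np.polyval(lin, centers), counts.astype(float))
    exp_params, exp_r2 = fit_exponential_decay(centers, counts.astype(float))
    return MagnificationCurve(
        bin_edges=edges,
        counts=counts,
        linear=(float(lin[0]), float(lin[1])),
        linear_r2=lin_r2,
        exponential=exp_params,
        exponential_r2=exp_r2,
    )


@dataclass
class EccSizeFit:
    """Ordinary least squares of pRF size on eccentricity."""

    slope: float
    intercept: float
    r2: float
    n_units: int


def fit_ecc_size(result: RetinotopyResult) -> EccSizeFit:
    """Fit sigma = slope * ecc + intercept over valid units."""
    valid = result.valid()
    ecc = valid["ecc"].to_numpy()
    sigma = valid["sigma"].to_numpy()
    if len(np.unique(ecc)) < 2:
        raise ValueError("need at least two distinct eccentricities")
    if np.ptp(sigma) == 0:
        return EccSizeFit(slope=0.0, intercept=float(sigma[0]), r2=0.0, n_units=len(ecc))
    res = stats.linregress(ecc, sigma)
    r2 = float(res.rvalue**2)
    return EccSizeFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=0.0 if np.isnan(r2) else r2,
        n_units=len(ecc),
    )
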