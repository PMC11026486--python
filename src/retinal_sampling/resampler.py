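"""The retinal sampling layer (RSL): RGC-density resampling of images.

A square input image covering ``fov`` degrees of visual field is resampled
onto a square "ganglion space" raster in which pixel density mimics retinal
ganglion cell density: the fovea is magnified, the periphery compressed
(barrel distortion). The map acts on polar radius only -- a pixel at output
radius ``r_o`` is sourced from input radius::

    r_gc = r_o * r_gc(fov/2) / (w_o / 2)        (ganglion radius)
    r_vf = inverse_radius(r_gc)                 (visual-field degrees)
    r_i  = r_vf * w_i / fov                     (input pixels)

at unchanged polar angle. Resampling is realized once per geometry as a
sparse matrix of bilinear weights (inverse resampling: every output pixel
pulls a distance-weighted average of its 4 nearest input pixels), then
applied to each channel as a matrix-vector product.

Conventions: pixel centers at integer coordinates, image center at
``((w-1)/2, (w-1)/2)``, polar angle counterclockwise from the +x axis with
"up" at +90 deg (row axis flipped).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import scipy.sparse as sp

from .rgc import DEFAULT_PARAMS, RGCDensityParams, cumulative_radius, inverse_radius

__all__ = [
    "SamplingSpec",
    "SamplingWeights",
    "build_weights",
    "resample",
    "inverse_resample",
    "unit_eccentricity",
]


@dataclass(frozen=True)
class SamplingSpec:
    """Geometry of one resampling: raster widths, field of view, RGC params."""

    input_width: int
    output_width: int
    fov: float = 20.0
    params: RGCDensityParams = DEFAULT_PARAMS

    def __post_init__(self) -> None:
        if self.input_width < 2 or self.output_width < 2:
            raise ValueError("input_width and output_width must be >= 2")
        if not 5.0 <= self.fov <= 100.0:
            raise ValueError(f"fov must lie in [5, 100] degrees, got {self.fov}")

    @property
    def total_cell_radius(self) -> float:
        """Cumulative cell count at the edge of the field, r_gc(fov/2)."""
        return cumulative_radius(self.fov / 2.0, self.params)


@dataclass
class SamplingWeights:
    """Sparse output-pixel -> (input-pixel, weight) map for one geometry.

    ``matrix`` has shape ``(w_o**2, w_i**2)``; each row holds at most four
    non-negative bilinear weights summing to 1 (covered pixels) or is empty
    (pixels beyond the fov circle). ``covered`` flags covered output pixels.
    """

    matrix: sp.csr_matrix
    spec: SamplingSpec
    covered: np.ndarray


def _centered_coords(width: int) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-center coordinates (x right, y up) centered on the raster."""
    c = (width - 1) / 2.0
    rows, cols = np.mgrid[0:width, 0:width]
    return cols - c, c - rows


def _bilinear_matrix(
    row_f: np.ndarray,
    col_f: np.ndarray,
    covered: np.ndarray,
    n_out: int,
    src_width: int,
) -> sp.csr_matrix:
    """Sparse (n_out, src_width**2) matrix of renormalized bilinear weights.

    ``row_f``/``col_f`` give fractional source coordinates for the covered
    output pixels; source pixels falling off the raster are dropped and the
    remaining weights renormalized to sum 1.
    """
    out_idx = np.flatnonzero(covered.ravel())
    r0 = np.floor(row_f).astype(np.int64)
    c0 = np.floor(col_f).astype(np.int64)
    fr = row_f - r0
    fc = col_f - c0

    rows_all, cols_all, vals_all = [], [], []
    corners = (
        (r0, c0, (1 - fr) * (1 - fc)),
        (r0, c0 + 1, (1 - fr) * fc),
        (r0 + 1, c0, fr * (1 - fc)),
        (r0 + 1, c0 + 1, fr * fc),
    )
    total = np.zeros(out_idx.size)
    for rr, cc, w in corners:
        valid = (rr >= 0) & (rr < src_width) & (cc >= 0) & (cc < src_width)
        total += np.where(valid, w, 0.0)
    for rr, cc, w in corners:
        valid = (rr >= 0) & (rr < src_width) & (cc >= 0) & (cc < src_width)
        keep = valid & (w > 0) & (total > 0)
        rows_all.append(out_idx[keep])
        cols_all.append(rr[keep] * src_width + cc[keep])
        vals_all.append(w[keep] / total[keep])

    mat = sp.csr_matrix(
        (np.concatenate(vals_all), (np.concatenate(rows_all), np.concatenate(cols_all))),
        shape=(n_out, src_width * src_width),
    )
    mat.sum_duplicates()
    return mat


@lru_cache(maxsize=8)
def build_weights(spec: SamplingSpec) -> SamplingWeights:
    """Build the forward (visual field -> ganglion space) weight matrix.

    Cached per spec; requires ``spec.params.alpha == 1`` for the inverse map.
    """
    p = spec.params
    if p.alpha != 1.0:
        raise ValueError("build_weights requires params.alpha == 1")
    w_i, w_o = spec.input_width, spec.output_width
    x, y = _centered_coords(w_o)
    r_o = np.hypot(x, y)
    covered = r_o <= w_o / 2.0

    r_gc = r_o[covered] * spec.total_cell_radius / (w_o / 2.0)
    r_vf = inverse_radius(r_gc, p)
    r_i = r_vf * w_i / spec.fov
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(r_o[covered] > 0, r_i / r_o[covered], 0.0)
    x_i = x[covered] * scale
    y_i = y[covered] * scale
    c = (w_i - 1) / 2.0
    col_f = x_i + c
    row_f = c - y_i

    mat = _bilinear_matrix(row_f, col_f, covered, w_o * w_o, w_i)
    really_covered = covered.copy()
    really_covered.ravel()[covered.ravel()] = (
        np.asarray(mat.sum(axis=1)).ravel()[covered.ravel()] > 0
    )
    return SamplingWeights(matrix=mat, spec=spec, covered=really_covered)


@lru_cache(maxsize=8)
def _build_inverse_weights(spec: SamplingSpec) -> SamplingWeights:
    """Weights for rendering ganglion space back into the visual field."""
    p = spec.params
    w_i, w_o = spec.input_width, spec.output_width
    x, y = _centered_coords(w_i)
    r_px = np.hypot(x, y)
    r_vf = r_px * spec.fov / w_i
    covered = r_vf <= spec.fov / 2.0

    r_gc = cumulative_radius(r_vf[covered], p)
    r_o = r_gc * (w_o / 2.0) / spec.total_cell_radius
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(r_px[covered] > 0, r_o / r_px[covered], 0.0)
    c = (w_o - 1) / 2.0
    col_f = x[covered] * scale + c
    row_f = c - y[covered] * scale

    mat = _bilinear_matrix(row_f, col_f, covered, w_i * w_i, w_o)
    return SamplingWeights(matrix=mat, spec=spec, covered=covered)


def _apply(mat: sp.csr_matrix, image: np.ndarray, src_width: int, out_width: int):
    image = np.asarray(image, dtype=float)
    if image.shape[0] != src_width or image.shape[1] != src_width:
        raise ValueError(
            f"image raster {image.shape[:2]} does not match expected "
            f"({src_width}, {src_width})"
        )
    if image.ndim == 2:
        return (mat @ image.ravel()).reshape(out_width, out_width)
    flat = image.reshape(src_width * src_width, -1)
    out = mat @ flat
    return out.reshape(out_width, out_width, image.shape[2])


def resample(image: np.ndarray, weights: SamplingWeights) -> np.ndarray:
    """Resample a visual-field image into ganglion space (w_o x w_o).

    Linear in the image; uncovered output pixels (beyond the fov circle) are
    zero; a globally uniform image is preserved exactly on covered pixels.
    """
    spec = weights.spec
    return _apply(weights.matrix, image, spec.input_width, spec.output_width)


def inverse_resample(image: np.ndarray, spec: SamplingSpec) -> np.ndarray:
    """Render a ganglion-space image back to the visual field (w_i x w_i).

    Applies the reciprocal radial map with the same bilinear scheme, giving
    the "perceptual" rendering: sharp center, blurred periphery. Composing
    :func:`resample` then :func:`inverse_resample` approximates identity in
    the central visual field.
    """
    inv = _build_inverse_weights(spec)
    return _apply(inv.matrix, image, spec.output_width, spec.input_width)


def unit_eccentricity(
    rows,
    cols,
    downsample_factor: float,
    spec: SamplingSpec,
    offset: float | None = None,
):
    """Visual-field eccentricity and polar angle of layer-map units.

    A unit at map index ``(row, col)`` of a layer whose map pixels are
    ``downsample_factor`` ganglion pixels apart sits at ganglion coordinate
    ``index * downsample_factor + offset`` (default offset centers the unit
    in its window, ``(downsample_factor - 1) / 2``). The ganglion radius is
    converted back to degrees through the inverse cumulative map.

    Returns ``(eccentricity_deg, polar_angle_deg)``; units mapping beyond
    the total cell count (square-map corners past the fov circle) get
    eccentricity ``inf``. Polar angle is in [0, 360).
    """
    rows = np.asarray(rows, dtype=float)
    cols = np.asarray(cols, dtype=float)
    w_o = spec.output_width
    map_width = w_o / downsample_factor
    if np.any(rows < 0) or np.any(cols < 0) or np.any(rows >= map_width + 1) or np.any(
        cols >= map_width + 1
    ):
        raise IndexError("unit indices outside the layer map")
    if offset is None:
        offset = (downsample_factor - 1) / 2.0
    g_row = rows * downsample_factor + offset
    g_col = cols * downsample_factor + offset
    c = (w_o - 1) / 2.0
    x = g_col - c
    y = c - g_row
    r_o = np.hypot(x, y)
    r_gc = r_o * spec.total_cell_radius / (w_o / 2.0)
    scalar = np.ndim(rows) == 0 and np.ndim(cols) == 0
    r_gc = np.atleast_1d(r_gc)
    inside = r_gc < spec.params.max_cell_radius
    ecc = np.full(r_gc.shape, np.inf)
    if inside.any():
        ecc[inside] = inverse_radius(r_gc[inside], spec.params)
    angle = np.degrees(np.arctan2(y, x)) % 360.0
    if scalar:
        return float(ecc[0]), float(angle)
    return ecc, angle


def unit_position_linear(
    rows,
    cols,
    downsample_factor: float,
    width: int,
    fov: float,
    offset: float | None = None,
):
    """Unit eccentricity/angle under *uniform* sampling (no RSL): the map
    raster covers ``fov`` degrees linearly. Counterpart of
    :func:`unit_eccentricity` for control networks."""
    rows = np.asarray(rows, dtype=float)
    cols = np.asarray(cols, dtype=float)
    if offset is None:
        offset = (downsample_factor - 1) / 2.0
    c = (width - 1) / 2.0
    x = cols * downsample_factor + offset - c
    y = c - (rows * downsample_factor + offset)
    ecc = np.hypot(x, y) * fov / width
    angle = np.degrees(np.arctan2(y, x)) % 360.0
    if np.ndim(rows) == 0 and np.ndim(cols) == 0:
        return float(ecc), float(angle)
    return ecc, angle
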