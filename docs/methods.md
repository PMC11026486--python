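# Methods

## Retinal sampling layer

**Density model.** Ganglion cell density over eccentricity `r` (degrees of
visual angle from fixation) is modeled as

    rho(r) = rho0 * [ alpha * (1 + r/k)^-2 + (1 - alpha) * exp(-r/sigma) ]

Packaged defaults: `rho0 = 33162` cells/deg² (foveal density), `k = 1.05`
deg (quarter-density eccentricity), `sigma = 22` deg, `alpha = 1`,
field of view 20 deg (*diameter*; image radius 10 deg). Parameters load
from YAML/JSON. All eccentricities are in degrees of visual angle; no
retinal-millimeter conversion is performed.

**Cumulative count and inverse.** With `alpha = 1` the 1-D cumulative count
along a ray is `r_gc(r) = rho0*k*r/(k+r)`, implemented in this positive
bounded form (algebraically identical to the antiderivative-difference
form, better conditioned). Its exact inverse is
`r(r_gc) = k*r_gc/(rho0*k - r_gc)`, defined for `r_gc < rho0*k`. The
`alpha < 1` density remains available for evaluation, but the
cumulative/inverse pair requires `alpha = 1` (the exponential term
contributes little at moderate eccentricity and prevents closed-form
inversion). Unit tests verify the closed form against adaptive quadrature
(relative error <= 1e-8) and round-trip inversion (<= 1e-9).

**Resampling.** Inverse (pull) resampling: each output pixel's polar radius
`r_o` is scaled to a ganglion radius by `r_gc = r_o * r_gc(fov/2)/(w_o/2)`,
inverted to degrees, and converted to input pixels at unchanged polar
angle; the four nearest input pixels contribute bilinear weights,
renormalized at raster borders. The map is cached per geometry as a sparse
CSR matrix (`w_o^2 x w_i^2`, at most 4 entries per row, rows summing to 1
on covered pixels) and applied per channel as a matrix-vector product.
Output pixels beyond the fov circle (square corners) are uncovered and 0.
The normalization maps `r_vf = fov/2` to the output *radius* `w_o/2`;
normalizing to the full width would push half the field off-image.
Pixel centers sit at integer coordinates with the image center at
`((w-1)/2, (w-1)/2)`; polar angle runs counterclockwise from +x with "up"
at +90 deg. Forward rendering ("perception") is defined only through the
reciprocal radial map (`inverse_resample`), since forward splatting leaves
holes; resample-then-render is near-identity in the central field.

## Stimuli

* **Gratings** — `orientation` is always the *stripe* orientation;
  luminance modulates along `orientation + 90 deg` as
  `0.5 + 0.5*contrast*sin(2 pi f u + phase)`. This makes "radial" mean
  stripes aligned with the meridian, which is what the radial-bias
  statistic measures.
* **Bar apertures** — bars of fixed width swept perpendicular to their
  long axis at four orientations; offsets enumerate full-containment
  positions (63 positions at 256 px / width 8 / stride 4), with one
  right-aligned extra bar on diagonal sweeps whose length is not a stride
  multiple, so every sweep tiles the image.
* **pRF grating family** — full scale: 8 orientations x 4 spatial
  frequencies (0.0735, 0.147, 0.294, 0.5885 c/deg) x 32 phases. The
  printed phase span (0 to 1.75 pi inclusive) is the default; an exact
  full-circle span is available (`phase_span="full"`) and is used
  wherever phase-averaging to a flat plateau matters.
* **Sinrings** — annuli (hard edges, half-width 0.9 deg, half the ring
  spacing; the width is not prescribed by the design, so it is exposed as
  a parameter) at eccentricities 1, 2.8, 4.7, 6.6, 8.5 deg. The ring at
  eccentricity `e` with coefficient `c in {2,5,8,11,14,17,20,23}` runs at
  `(c/pi)*e` cycles/radian, so its *arc* spatial frequency `c/pi` c/deg is
  matched across eccentricities. Tuning curves report preference as this
  arc frequency: the absolute cycles/radian of a fixed level grows
  linearly with eccentricity by construction and would confound the
  preference measure. Total cycle count `2ce` is non-integer for e in
  {2.8, 4.7, 6.6}, leaving a one-pixel phase seam at the angular wrap;
  with phase-averaged responses this is negligible.
* **Curved lines** — 7x7 white-on-black 1-px lines at 0/45/90/135 deg;
  curvature realized as a perpendicular parabolic midpoint displacement
  (0 to 3 px in 6 levels) with fixed endpoints, rasterized as one pixel
  per sample along the line axis so every stimulus has exactly 7 on-pixels.
  An earlier dense-curve rasterization made diagonal curves *thicker* than
  diagonal straight lines and reversed the similarity trend — a pure
  rasterization-density artifact.
* **Gabor kernels** — isotropic Gaussian envelope (sd = wavelength/2; the
  bandwidth is a free choice), DC-removed, optionally L2-normalized;
  orientation follows the stripe convention.

## Surrogate V1

RSL -> correlation with a fixed Gabor bank (11x11 px, wavelength 2 pi px,
16 orientations x quadrature phase pair = 32 channels) -> ReLU -> 3x3 max
pooling, conv stride 2, pool stride 2. The bank stands in for learned
first-layer filters; with kernel size fixed, its preferred frequency in
ganglion space (~0.16 cycles/px) is what quasi-uniform convergence fixes
across the map. Channel-identical 3-channel filters mean RGB inputs are
collapsed by channel summation before convolution. Map unit `(i, j)` sits
at ganglion pixel `4*(i, j) + 2`; analyses use this geometry directly.
The control configuration omits the RSL (uniform sampling) and is
analyzed with the linear pixel-to-degree mapping.

## Analyses

**pRF mapping.** Population maps (channel means) are averaged over the
gratings of each bar position; a unit's response profile over positions is
correlated against profiles of candidate isotropic Gaussians (16,384
uniform locations x 20 linear sizes, 0.025-1.6 deg). Candidate profiles
are Gaussian-mask dot products, computed exactly via separability
(`g_y^T M g_x`); Gaussians are unit-sum normalized (correlation is
scale-invariant, so this only fixes a convention). The argmax-correlation
candidate gives position and sigma; zero-variance profiles are invalid;
ties resolve to the smallest sigma (size-major candidate ordering).

**Cortical magnification.** Valid units (and only units whose fit
correlation is within 3 sd of the mean) are counted in contiguous 1-deg
eccentricity bins; a line and an exponential decay `D = a*exp(-b E) + c`
(nonlinear least squares, log-linear initialization) are fitted and
compared by R². Bins are restricted to eccentricities whose annuli lie
fully inside the square layer map (the map's inscribed circle): beyond it
the square map clips annuli and corner units — whose pooling windows are
cut by the map edge and whose pRF estimates scatter broadly — dominate
the tail. The same exclusion applies to the size-vs-eccentricity fit.
This is an edge-artifact exclusion of the same kind as the outer-1.2-deg
exclusion in the bias analysis.

**Eccentricity vs pRF size.** Ordinary least squares of sigma on
eccentricity over the same unit set. Elliptical receptive fields are not
modeled; a single isotropic-Gaussian fit is used throughout.

**Spatial-frequency tuning.** Per sinring, the response is the pooled mean
of the population map; responses are phase-averaged, grouped by
eccentricity and max-normalized within groups; preference is the argmax
arc frequency, and an exponential decay is fitted to preference over
eccentricity.

**Radial bias.** Orientation maps (population maps phase-averaged within
stripe orientation; 32 phases equidistant in [-pi, pi)) are binned into 16
overlapping polar wedges (centers every 22.5 deg, each spanning +-22.5
deg) after excluding units beyond `fov/2 - 1.2` deg. The statistic is
`A_grating/A_orthogonal`: summed bin means on the grating-aligned polar
axis over the orthogonal axis. Grating orientations default to the 8 bin-
center-aligned values. Zero-denominator ratios are flagged infinite and
excluded (with a warning) from sweep means.

**Frequency mechanism.** The bank's sensitivity curve is measured on its
own 11-px patch (gratings 0.1-3.0 cycles/patch x 8 orientations x 12
phases; per grating the max rectified filter response, averaged per
frequency). Local frequency content of a resampled grating comes from a
quadrature Gabor pyramid (12 log-spaced frequencies, 0.5-64 cycles/image,
8 orientations; kernel support 6 sd capped at the image width): each pixel
takes the frequency of the strongest wavelet. Pixels outside the covered
disk are zeroed first and the known mid-gray background (0.5) is
subtracted — otherwise the disk-vs-corner luminance step floods the
low-frequency wavelets. The predicted response map evaluates the
sensitivity curve (on a common cycles/pixel axis, edge values outside the
measured range) at each pixel's dominant frequency and is polar-binned
exactly like a measured orientation map.

**Curvature control.** Cosine similarity between the (vectorized) Gabor
bank and curved-line stimuli, taking the best filter per stimulus and
averaging over orientations and bend directions per curvature level. The
max over filters is the conservative reading of "filter responses to
curved lines".

## Desk-scale choices

The reference experiments run on one CPU in minutes, not on a GPU:
visual-field rasters of 512 px (256 px for bar sweeps), ganglion raster
128 px, fov 20 deg. The pRF grating family is reduced to 4 orientations x
4 spatial frequencies (1, 2, 4, 6 c/deg) x 4 full-circle phases — chosen
a priori to span the surrogate's sensitive band across the mapped
eccentricities, standing in for the original broadband low-frequency
family, which at 252 positions x 1024 gratings is a GPU workload. The
candidate grid is kept at full size (16,384 x 20). Every claim tested is a
sign, ordering or goodness-of-fit comparison and is scale-free; absolute
slopes and ratios do depend on raster sizes and the filter bank.

The pipeline is fully deterministic: fixed filter banks, closed-form
geometry, no sampling noise. Repeated runs are bit-identical.

## What the surrogate does and does not establish

The surrogate has *fixed* Gabor filters; it demonstrates that the four
organizational principles follow from RGC-density sampling plus uniform
convergence alone, with no training. It cannot reproduce quantities that
depend on learned filters (classification accuracy, exact bias ratios or
fitted decay constants of a trained network), and it does not model
V2/V4/IT hierarchies, elliptical receptive fields, photoreceptor-level
sampling, optics, or temporal dynamics. Real retinas also differ: density
is meridian-dependent and cell-class-dependent; the packaged model is the
radially symmetric midget-pathway abstraction.

## Numerical notes

* Convolution is FFT-based with zero padding ('same'), batched with
  chunking to bound memory; pooling uses strided sliding windows.
* The exponential-decay fitter falls back to its log-linear initialization
  if the nonlinear solve fails, and declines to fit fewer than 3 points
  (NaN parameters) or fewer than 3 nonempty magnification bins (error).
* Bilinear weights at raster borders are renormalized over the in-raster
  subset of the 4 neighbors; an output pixel with no in-raster source is
  uncovered.
* `unit_eccentricity` returns +inf for units mapping beyond the total
  1-D cell count (square-map corners past the fov circle); such units are
  excluded by every analysis that bins by eccentricity.
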