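"""Surrogate V1 layer: RSL -> oriented Gabor bank -> ReLU -> max pooling.

The analyses in :mod:`retinal_sampling.prf` and :mod:`retinal_sampling.tuning`
consume a *layer adapter*: any callable mapping a visual-field image to
non-negative feature maps (channels x H x W), together with the geometry
needed to place map units in ganglion-space pixels. The built-in surrogate
mirrors a biologically inspired CNN's first stage (convolution + ReLU +
max pooling, V1-sized 11-px filters) but uses a fixed Gabor filter bank, so
every organizational-principle analysis runs without trained weights.

An externally trained network can be wrapped in the same contract; only the
surrogate is exercised by the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np

from .resampler import SamplingSpec, build_weights, resample
from .stimuli import make_gabor_bank

__all__ = [
    "LayerAdapter",
    "SurrogateV1Config",
    "SurrogateV1",
    "build_surrogate_v1",
    "apply_layer",
]


@runtime_checkable
class LayerAdapter(Protocol):
    """Contract consumed by the analysis modules.

    Calling the adapter on an (H, W, 3) image of ``input_width`` returns
    non-negative feature maps of shape (channels, map_width, map_width),
    deterministically. ``downsample_factor`` and ``coord_offset`` place map
    unit ``(i, j)`` at ganglion-space (or, without an RSL, input-space) pixel
    ``i * downsample_factor + coord_offset``.
    """

    input_width: int
    map_width: int
    downsample_factor: float
    coord_offset: float

    def __call__(self, image: np.ndarray) -> np.ndarray: ...


@dataclass(frozen=True)
class SurrogateV1Config:
    """Configuration of the surrogate V1 stage.

    Defaults follow the modified first CNN stage: 11x11x3 filters, stride-2
    convolution and 3x3/stride-2 max pooling, with a 16-orientation Gabor
    bank (wavelength 2*pi px, quadrature phase pair) standing in for learned
    filters. ``include_rsl=False`` gives the uniform-sampling control.
    """

    sampling: SamplingSpec
    kernel_size: int = 11
    n_orientations: int = 16
    wavelength: float = 2.0 * math.pi
    phases: tuple[float, ...] = (0.0, math.pi / 2.0)
    conv_stride: int = 2
    pool_size: int = 3
    pool_stride: int = 2
    include_rsl: bool = True

    def __post_init__(self) -> None:
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")
        if self.conv_stride < 1 or self.pool_stride < 1:
            raise ValueError("strides must be >= 1")


class SurrogateV1:
    """Trained-weight-free V1 stage implementing :class:`LayerAdapter`."""

    def __init__(self, config: SurrogateV1Config):
        self.config = config
        bank = make_gabor_bank(
            size=config.kernel_size,
            wavelength=config.wavelength,
            n_orientations=config.n_orientations,
            phases=config.phases,
        )
        self.filters = np.stack([k.array for k in bank])
        self.filter_orientations = np.array([k.orientation for k in bank])
        self.n_channels = self.filters.shape[0]

        spec = config.sampling
        self.input_width = spec.input_width
        self._conv_width = spec.output_width if config.include_rsl else spec.input_width
        conv_out = (self._conv_width - 1) // config.conv_stride + 1
        self.map_width = (conv_out - config.pool_size) // config.pool_stride + 1
        if self.map_width < 1:
            raise ValueError("configuration collapses the map to zero width")
        # unit (i, j) pools conv outputs centered at conv index
        # i*pool_stride + (pool_size-1)/2, i.e. pre-conv pixel:
        self.downsample_factor = float(config.conv_stride * config.pool_stride)
        self.coord_offset = config.conv_stride * (config.pool_size - 1) / 2.0
        self._filter_fft = None

    # -- internals ----------------------------------------------------------

    def _collapse(self, image: np.ndarray) -> np.ndarray:
        """Sum RGB channels (the 3-channel filters are channel-identical, so
        convolution with them equals single-channel convolution of the sum)."""
        image = np.asarray(image, dtype=float)
        if image.shape[0] != self.input_width or image.shape[1] != self.input_width:
            raise ValueError(
                f"expected {self.input_width}x{self.input_width} input, "
                f"got {image.shape[:2]}"
            )
        return image.sum(axis=2) if image.ndim == 3 else image * 3.0

    def _fft_filters(self, padded: int):
        if self._filter_fft is None or self._filter_fft[0] != padded:
            ks = self.config.kernel_size
            kernels = np.zeros((self.n_channels, padded, padded))
            kernels[:, :ks, :ks] = self.filters[:, ::-1, ::-1]  # flip: correlate
            self._filter_fft = (padded, np.fft.rfft2(kernels))
        return self._filter_fft[1]

    def _conv_relu_pool(self, planes: np.ndarray) -> np.ndarray:
        """(B, W, W) ganglion/input planes -> (B, C, map, map) maps."""
        cfg = self.config
        w = planes.shape[-1]
        ks = cfg.kernel_size
        half = (ks - 1) // 2
        padded = w + ks - 1
        fft_k = self._fft_filters(padded)
        imgs = np.zeros((planes.shape[0], padded, padded))
        imgs[:, :w, :w] = planes
        prod = np.fft.rfft2(imgs)[:, None, :, :] * fft_k[None, :, :, :]
        full = np.fft.irfft2(prod, s=(padded, padded))
        same = full[:, :, half : half + w, half : half + w]
        strided = same[:, :, :: cfg.conv_stride, :: cfg.conv_stride]
        rect = np.maximum(strided, 0.0)
        win = np.lib.stride_tricks.sliding_window_view(
            rect, (cfg.pool_size, cfg.pool_size), axis=(2, 3)
        )
        pooled = win[:, :, :: cfg.pool_stride, :: cfg.pool_stride].max(axis=(4, 5))
        return pooled

    # -- public surface ------------------------------------------------------

    def __call__(self, image: np.ndarray) -> np.ndarray:
        return self.batch(np.asarray(image, dtype=float)[None])[0]

    def batch(self, images: np.ndarray, chunk: int = 16) -> np.ndarray:
        """Apply to a batch (B, H, W, 3) or (B, H, W); stable ordering."""
        images = np.asarray(images, dtype=float)
        planes = np.stack([self._collapse(im) for im in images])
        if self.config.include_rsl:
            weights = build_weights(self.config.sampling)
            planes = np.stack([resample(p, weights) for p in planes])
        out = np.empty(
            (planes.shape[0], self.n_channels, self.map_width, self.map_width)
        )
        for i in range(0, planes.shape[0], chunk):
            out[i : i + chunk] = self._conv_relu_pool(planes[i : i + chunk])
        return out


def build_surrogate_v1(config: SurrogateV1Config) -> SurrogateV1:
    """Build the surrogate V1 adapter for a sampling geometry."""
    return SurrogateV1(config)


def apply_layer(image: np.ndarray, adapter: LayerAdapter) -> np.ndarray:
    """Run one image (H, W, 3) through an adapter -> (C, map, map) maps."""
    image = np.asarray(image, dtype=float)
    if image.ndim not in (2, 3):
        raise ValueError("expected an (H, W) or (H, W, 3) image")
    return adapter(image)
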