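"""Two-scale base/detail decomposition with a Gaussian filter.

Each source image ``X`` is split into a low-frequency *base* layer
``Y = X * G`` (2-D convolution with a normalized Gaussian kernel, symmetric
border padding) and a signed high-frequency *detail* residual ``Z = X - Y``,
so that ``X = Y + Z`` holds exactly.  The base layer carries large-scale
structure to the fuzzy fusion stage; the detail layer carries edges to the
spatial-frequency fusion stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import validate_gray

__all__ = ["GaussianParams", "LayerPair", "gaussian_kernel", "decompose"]


@dataclass(frozen=True)
class GaussianParams:
    """Gaussian smoothing parameters.

    Parameters
    ----------
    sigma : float
        Standard deviation in pixels.  Default 5, large enough for the base
        layer to carry only coarse anatomical structure.
    kernel_size : int, optional
        Odd kernel side length.  When omitted it is derived as
        ``2 * ceil(3 * sigma) + 1`` so the kernel captures ±3σ.
    """

    sigma: float = 5.0
    kernel_size: int | None = None

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise ValueError(f"gaussian.sigma must be positive, got {self.sigma}")
        size = self.resolved_kernel_size()
        if size < 3 or size % 2 == 0:
            raise ValueError(
                f"gaussian.kernel_size must be an odd integer >= 3, got {size}"
            )

    def resolved_kernel_size(self) -> int:
        if self.kernel_size is None:
            return 2 * math.ceil(3.0 * self.sigma) + 1
        return int(self.kernel_size)


@dataclass(frozen=True)
class LayerPair:
    """Base layer and signed detail residual of one source image."""

    base: np.ndarray
    detail: np.ndarray

    def reconstruct(self) -> np.ndarray:
        return self.base + self.detail


def gaussian_kernel(params: GaussianParams) -> np.ndarray:
    """Build a separable, symmetric, normalized 2-D Gaussian kernel.

    The kernel is the outer product of identical 1-D Gaussian samples,
    normalized so its weights sum to 1; the center weight is the maximum.
    """
    size = params.resolved_kernel_size()
    offsets = np.arange(size, dtype=np.float64) - (size - 1) / 2.0
    w = np.exp(-(offsets**2) / (2.0 * params.sigma**2))
    kernel = np.outer(w, w)
    return kernel / kernel.sum()


def decompose(image: np.ndarray, params: GaussianParams | None = None) -> LayerPair:
    """Split an image into Gaussian base and residual detail layers.

    The base layer is the 2-D convolution of the image with the Gaussian
    kernel using symmetric (edge-reflecting) padding, which preserves
    constants and avoids border halos that would contaminate the
    min/max fuzzification anchors.  The detail layer is the signed
    difference ``image - base``.
    """
    img = validate_gray(image)
    kernel = gaussian_kernel(params if params is not None else GaussianParams())
    base = ndimage.convolve(img, kernel, mode="reflect")
    return LayerPair(base=base, detail=img - base)
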