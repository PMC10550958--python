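"""Color (MRI + PET/SPECT) fusion through the YUV luminance pathway.

Functional color images are converted to analog BT.601 YUV; the MRI is
fused with the luminance plane by the grayscale pipeline while the
chrominance planes pass through untouched, which preserves the functional
pseudo-color.  The inverse transform is the exact matrix inverse, clipped
to [0, 255] only at the end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import FusionConfig
from .fusion import FusionResult, fuse_gray
from .io import validate_color, validate_gray

__all__ = ["YUVImage", "rgb_to_yuv", "yuv_to_rgb", "fuse_color"]

# BT.601 luma weights; U/V are scaled color differences.
_WR, _WG, _WB = 0.299, 0.587, 0.114
_KU, _KV = 0.492, 0.877


@dataclass(frozen=True)
class YUVImage:
    """Luminance plane in [0, 255] plus signed, unquantized chrominance planes."""

    y: np.ndarray
    u: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        if not (self.y.shape == self.u.shape == self.v.shape):
            raise ValueError("Y, U, V planes must share dimensions")


def rgb_to_yuv(img: np.ndarray) -> YUVImage:
    """Analog BT.601: Y = 0.299R + 0.587G + 0.114B, U = 0.492(B−Y), V = 0.877(R−Y)."""
    rgb = validate_color(img)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    y = _WR * r + _WG * g + _WB * b
    return YUVImage(y=y, u=_KU * (b - y), v=_KV * (r - y))


def yuv_to_rgb(img: YUVImage) -> np.ndarray:
    """Exact inverse of :func:`rgb_to_yuv`, clipped to [0, 255]."""
    y, u, v = img.y, img.u, img.v
    r = y + v / _KV
    b = y + u / _KU
    g = (y - _WR * r - _WB * b) / _WG
    return np.clip(np.stack([r, g, b], axis=-1), 0.0, 255.0)


def fuse_color(
    mri: np.ndarray, functional: np.ndarray, cfg: FusionConfig | None = None
) -> tuple[np.ndarray, FusionResult]:
    """Fuse a grayscale MRI with an RGB functional (PET/SPECT) image.

    The functional image is converted to YUV, the MRI is fused with the Y
    plane by :func:`pfsfusion.fusion.fuse_gray`, and the fused luminance is
    recombined with the *unchanged* U and V planes.  Returns the RGB result
    and the underlying grayscale :class:`FusionResult` for inspection.
    """
    mri = validate_gray(mri)
    rgb = validate_color(functional)
    if mri.shape != rgb.shape[:2]:
        raise ValueError(
            f"source shapes differ: {mri.shape} vs {rgb.shape[:2]}"
        )
    yuv = rgb_to_yuv(rgb)
    result = fuse_gray(mri, yuv.y, cfg)
    fused_rgb = yuv_to_rgb(YUVImage(y=result.fused, u=yuv.u, v=yuv.v))
    return fused_rgb, result
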