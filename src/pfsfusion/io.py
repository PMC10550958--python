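"""Raster image input/output and validation.

Images are held in memory as floating-point :class:`numpy.ndarray` objects on
the display scale ``[0, 255]``: grayscale images as 2-D ``(A, B)`` arrays and
color images as 3-D ``(A, B, 3)`` RGB arrays, row-major with the origin at the
top-left pixel.  The fuzzification stage performs its own min–max
normalization, so pixel values are never rescaled to ``[0, 1]`` on read.

Supported formats are PNG, TIFF and JPEG for reading and PNG/TIFF for
writing; 16-bit sources are linearly rescaled to ``[0, 255]`` and alpha
channels are dropped.  DICOM is out of scope — convert to PNG/TIFF first.
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np

__all__ = ["read_image", "write_image", "validate_gray", "validate_color"]


def validate_gray(image: np.ndarray) -> np.ndarray:
    """Validate a grayscale image and return it as a float64 array.

    Parameters
    ----------
    image : ndarray
        2-D array of intensities (nominally in ``[0, 255]``).

    Returns
    -------
    ndarray
        The image as a C-contiguous float64 array.

    Raises
    ------
    ValueError
        If the array is not 2-D, smaller than 2x2, or contains
        non-finite values.
    """
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"grayscale image must be 2-D, got shape {arr.shape}")
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError(f"image must be at least 2x2, got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    return np.ascontiguousarray(arr)


def validate_color(image: np.ndarray) -> np.ndarray:
    """Validate an RGB color image and return it as a float64 ``(A, B, 3)`` array."""
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"color image must have shape (A, B, 3), got {arr.shape}")
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError(f"image must be at least 2x2, got {arr.shape[:2]}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    return np.ascontiguousarray(arr)


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read a raster image as a float array on the ``[0, 255]`` scale.

    Single-channel files yield a 2-D grayscale array; 3-channel files yield
    an ``(A, B, 3)`` RGB array (equal channels are *not* collapsed to gray).
    Alpha channels are dropped; 16-bit integer data is linearly rescaled by
    ``255 / 65535``.
    """
    arr = iio.imread(os.fspath(path))
    arr = np.asarray(arr)
    if arr.dtype == np.uint16:
        arr = arr.astype(np.float64) * (255.0 / 65535.0)
    elif arr.dtype == np.int32 or arr.dtype == np.uint32:
        arr = arr.astype(np.float64) * (255.0 / float(np.iinfo(arr.dtype).max))
    else:
        arr = arr.astype(np.float64)
    if arr.ndim == 3:
        if arr.shape[2] == 2:  # luminance + alpha
            arr = arr[:, :, 0]
        elif arr.shape[2] == 4:  # RGBA
            arr = arr[:, :, :3]
    if arr.ndim == 2:
        return validate_gray(arr)
    return validate_color(arr)


def write_image(image: np.ndarray, path: str | os.PathLike) -> None:
    """Write an image as 8-bit PNG or TIFF chosen by file extension.

    Values are clipped to ``[0, 255]`` and rounded half-up before writing.
    """
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim == 2:
        arr = validate_gray(arr)
    else:
        arr = validate_color(arr)
    quantized = np.floor(np.clip(arr, 0.0, 255.0) + 0.5).astype(np.uint8)
    iio.imwrite(os.fspath(path), quantized)
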