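"""Objective fusion-quality metrics.

Seven reference-free and source-referenced measures of a fused image ``U``
against its sources ``X1, X2``:

* **M** — mean intensity (brightness).
* **SD** — population standard deviation (overall contrast).
* **AG** — average gradient: mean over the interior grid of
  ``sqrt((Δa² + Δb²)/2)`` with forward differences.
* **SF** — spatial frequency: ``sqrt(RF² + CF²)`` with both the row and
  column RMS difference terms normalized by ``1/(A·B)``.
* **MSF** — modified spatial frequency: SF plus a diagonal activity term
  ``DF = A_U + B_U`` (sum of the two diagonal RMS terms); here RF is
  normalized by ``1/(A·(B−1))``, CF by ``1/((A−1)·B)`` and the diagonal
  terms by ``1/((A−1)·(B−1))``.  The SF and MSF normalizers differ by
  construction and are kept as defined, not harmonized.
* **MI** — total mutual information ``MI(U,X1) + MI(U,X2)`` from joint
  histograms of quantized intensities (256 bins over [0, 255], log base 2).
* **FS** — fusion symmetry ``2 − |MI(U,X1)/MI_T − 0.5|`` ∈ [1.5, 2]; near 2
  when both sources contribute equally.  Undefined (reported missing) when
  ``MI_T = 0``.

Higher is better for every metric.  All metrics except MI operate on the
unquantized floating-point image.
"""

from __future__ import annotations

import csv
import json
import math
import os
from dataclasses import dataclass

import numpy as np

from .io import validate_gray

__all__ = [
    "MetricsReport",
    "mean_metric",
    "sd_metric",
    "avg_gradient",
    "sf_metric",
    "msf_metric",
    "mutual_information",
    "fusion_symmetry",
    "report",
    "write_report",
]

#: Column order used by report serialization.
COLUMNS = ("mean", "sd", "ag", "sf", "msf", "mi", "fs")


@dataclass(frozen=True)
class MetricsReport:
    """The seven quality metrics plus the per-source MI terms.

    ``fs`` is ``None`` when the total mutual information is zero (the
    symmetry ratio is then 0/0 and undefined).
    """

    mean: float
    sd: float
    ag: float
    sf: float
    msf: float
    mi: float
    fs: float | None
    mi_ux1: float
    mi_ux2: float

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "ag": self.ag,
            "sf": self.sf,
            "msf": self.msf,
            "mi": self.mi,
            "fs": self.fs,
            "mi_ux1": self.mi_ux1,
            "mi_ux2": self.mi_ux2,
        }


def mean_metric(u: np.ndarray) -> float:
    """Arithmetic mean of all pixel intensities."""
    return float(np.mean(validate_gray(u)))


def sd_metric(u: np.ndarray) -> float:
    """Population standard deviation (normalized by the pixel count)."""
    return float(np.std(validate_gray(u)))


def avg_gradient(u: np.ndarray) -> float:
    """Mean magnitude of the forward-difference gradient on the interior grid."""
    img = validate_gray(u)
    da = img[:-1, :-1] - img[1:, :-1]
    db = img[:-1, :-1] - img[:-1, 1:]
    return float(np.mean(np.sqrt((da**2 + db**2) / 2.0)))


def sf_metric(u: np.ndarray) -> float:
    """Spatial frequency with row/column terms normalized by the full pixel count."""
    img = validate_gray(u)
    n = img.size
    rf2 = np.sum(np.diff(img, axis=1) ** 2) / n
    cf2 = np.sum(np.diff(img, axis=0) ** 2) / n
    return float(np.sqrt(rf2 + cf2))


def msf_metric(u: np.ndarray) -> float:
    """Modified spatial frequency including the summed diagonal activity term."""
    img = validate_gray(u)
    a, b = img.shape
    rf2 = np.sum(np.diff(img, axis=1) ** 2) / (a * (b - 1))
    cf2 = np.sum(np.diff(img, axis=0) ** 2) / ((a - 1) * b)
    diag_n = (a - 1) * (b - 1)
    main_diag = np.sqrt(np.sum((img[1:, 1:] - img[:-1, :-1]) ** 2) / diag_n)
    anti_diag = np.sqrt(np.sum((img[:-1, 1:] - img[1:, :-1]) ** 2) / diag_n)
    df = main_diag + anti_diag
    return float(np.sqrt(rf2 + cf2 + df**2))


def _quantize(img: np.ndarray, bins: int) -> np.ndarray:
    codes = np.rint(np.clip(img, 0.0, 255.0) * (bins - 1) / 255.0).astype(np.intp)
    return codes


def mutual_information(u: np.ndarray, x: np.ndarray, bins: int = 256) -> float:
    """Mutual information of the joint intensity histogram, in bits.

    Intensities are rounded to the nearest of ``bins`` equal bins spanning
    [0, 255] (the default 256 bins round to integer gray levels); empty
    joint cells contribute zero.
    """
    u = validate_gray(u)
    x = validate_gray(x)
    if u.shape != x.shape:
        raise ValueError(f"image shapes differ: {u.shape} vs {x.shape}")
    if bins < 2:
        raise ValueError(f"bins must be >= 2, got {bins}")
    cu = _quantize(u, bins).ravel()
    cx = _quantize(x, bins).ravel()
    joint = np.bincount(cu * bins + cx, minlength=bins * bins).astype(np.float64)
    joint = joint.reshape(bins, bins) / cu.size
    pu = joint.sum(axis=1)
    px = joint.sum(axis=0)
    nz = joint > 0
    outer = np.outer(pu, px)
    return float(np.sum(joint[nz] * np.log2(joint[nz] / outer[nz])))


def fusion_symmetry(
    u: np.ndarray, x1: np.ndarray, x2: np.ndarray, bins: int = 256
) -> tuple[float | None, float]:
    """Fusion symmetry and total mutual information.

    Returns ``(fs, mi_t)`` with ``fs = 2 − |MI(U,X1)/mi_t − 0.5|``, bounded
    in [1.5, 2] and equal to 2 when both sources share the information
    equally.  ``fs`` is ``None`` when ``mi_t == 0``.
    """
    mi1 = mutual_information(u, x1, bins)
    mi2 = mutual_information(u, x2, bins)
    mi_t = mi1 + mi2
    if mi_t == 0:
        return None, 0.0
    return 2.0 - abs(mi1 / mi_t - 0.5), mi_t


def report(u: np.ndarray, x1: np.ndarray, x2: np.ndarray,
           bins: int = 256) -> MetricsReport:
    """Assemble all seven metrics of a fused image against its two sources."""
    mi1 = mutual_information(u, x1, bins)
    mi2 = mutual_information(u, x2, bins)
    mi_t = mi1 + mi2
    fs = None if mi_t == 0 else 2.0 - abs(mi1 / mi_t - 0.5)
    return MetricsReport(
        mean=mean_metric(u),
        sd=sd_metric(u),
        ag=avg_gradient(u),
        sf=sf_metric(u),
        msf=msf_metric(u),
        mi=mi_t,
        fs=fs,
        mi_ux1=mi1,
        mi_ux2=mi2,
    )


def write_report(rep: MetricsReport, path: str | os.PathLike) -> None:
    """Serialize a report to JSON or CSV (chosen by extension).

    The CSV uses the standard column order M, SD, AG, SF, MSF, MI, FS with
    six significant digits; a missing FS is written as an empty cell.
    """
    path = os.fspath(path)
    if path.lower().endswith(".csv"):
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow([c.upper() for c in COLUMNS])
            row = []
            for col in COLUMNS:
                value = getattr(rep, col)
                row.append("" if value is None else format(value, ".6g"))
            writer.writerow(row)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(rep.to_dict(), fh, indent=2)
            fh.write("\n")
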