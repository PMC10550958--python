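"""Pythagorean fuzzy image construction, entropy-driven α selection,
contrast enhancement, and (de)fuzzification.

A gray-level plane ``Y`` is fuzzified by min–max normalization,

    μ(a, b) = (Y(a, b) − Y_min) / (Y_max − Y_min),

and turned into a Pythagorean fuzzy image (PFI) with per-pixel membership,
non-membership and indeterminacy planes

    μ_PFS = 1 − N(μ; α),   ν_PFS = N(μ_PFS; α),
    π_PFS = sqrt(1 − μ_PFS² − ν_PFS²),

where ``N(x; α) = α²(1−x) / (α²(1−x) + x)`` is a Sugeno-style fuzzy negation
with ``N(0) = 1`` and ``N(1) = 0``.  For α ∈ (0, 1] the planes satisfy the
Pythagorean constraint ``μ_PFS² + ν_PFS² ≤ 1``.  The fuzzification parameter
α is selected per image by maximizing the Pythagorean fuzzy entropy (PFE)

    PFE = mean over pixels of (π² + 1 − |μ² − ν²|) / (π² + 1 + |μ² − ν²|),

over a grid of candidate values.  Contrast enhancement raises the membership
plane to a hedge power λ ≥ 1 and applies the piecewise-quadratic INT
intensification operator.  Defuzzification maps a fuzzy plane back to gray
levels with the inverse of the min–max normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import validate_gray

__all__ = [
    "MembershipPlane",
    "PFI",
    "default_alpha_grid",
    "fuzzify",
    "pfs_negation",
    "build_pfi",
    "pfe",
    "optimize_alpha",
    "enhance",
    "defuzzify",
]


@dataclass(frozen=True)
class MembershipPlane:
    """A fuzzy-domain plane in ``[0, 1]`` with its gray-level anchors.

    ``y_min`` and ``y_max`` record the gray-level range used for the min–max
    normalization so the plane can later be defuzzified.
    """

    mu: np.ndarray
    y_min: float
    y_max: float

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=np.float64)
        if np.any(mu < -1e-12) or np.any(mu > 1 + 1e-12):
            raise ValueError("membership values must lie in [0, 1]")
        if self.y_min > self.y_max:
            raise ValueError(f"y_min ({self.y_min}) exceeds y_max ({self.y_max})")
        object.__setattr__(self, "mu", np.clip(mu, 0.0, 1.0))


@dataclass(frozen=True)
class PFI:
    """Pythagorean fuzzy image: aligned (μ, ν, π) planes plus the α used.

    The defuzzification anchors of the membership plane the PFI was built
    from are carried along so enhancement can hand them forward.
    """

    mu_pfs: np.ndarray
    nu_pfs: np.ndarray
    pi_pfs: np.ndarray
    alpha: float
    y_min: float = 0.0
    y_max: float = 255.0


def default_alpha_grid(
    start: float = 0.01, stop: float = 1.0, step: float = 0.01
) -> np.ndarray:
    """Candidate α values: ``start, start+step, …`` up to ``stop`` inclusive.

    The default 0.01…1.00 grid is finer than a coarse 0.1-spaced sweep so
    the entropy maximizer resolves α to two decimals.
    """
    if not (0 < start <= stop) or step <= 0:
        raise ValueError("alpha grid requires 0 < start <= stop and step > 0")
    n = int(np.floor((stop - start) / step + 1e-9)) + 1
    return np.round(start + step * np.arange(n), 12)


def fuzzify(image: np.ndarray) -> MembershipPlane:
    """Min–max normalize a gray image to a membership plane.

    A constant image (``Y_max == Y_min``) maps to ``μ ≡ 0.5`` with both
    anchors equal to the constant, so defuzzification restores it exactly.
    """
    img = validate_gray(image)
    y_min = float(img.min())
    y_max = float(img.max())
    if y_max == y_min:
        return MembershipPlane(np.full_like(img, 0.5), y_min, y_max)
    return MembershipPlane((img - y_min) / (y_max - y_min), y_min, y_max)


def pfs_negation(x, alpha: float):
    """Parametric fuzzy negation ``N(x; α) = α²(1−x) / (α²(1−x) + x)``.

    Strictly decreasing in ``x`` with ``N(0) = 1`` and ``N(1) = 0``; at
    ``α = 1`` it reduces to the standard negation ``1 − x``.
    Accepts scalars or arrays in ``[0, 1]``.
    """
    if not (alpha > 0):
        raise ValueError(f"alpha must be positive, got {alpha}")
    arr = np.asarray(x, dtype=np.float64)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("negation argument must lie in [0, 1]")
    a2 = alpha * alpha
    result = a2 * (1.0 - arr) / (a2 * (1.0 - arr) + arr)
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(result)
    return result


def build_pfi(plane: MembershipPlane, alpha: float) -> PFI:
    """Construct the Pythagorean fuzzy image for a membership plane.

    ``μ_PFS = 1 − N(μ; α)`` and ``ν_PFS = N(μ_PFS; α)`` (the negation is
    applied to the already-lifted membership, not the original μ).  The
    indeterminacy is ``π_PFS = sqrt(1 − μ_PFS² − ν_PFS²)``; the radicand is
    nonnegative for α ∈ (0, 1] and only clipped against round-off.
    """
    if not (0 < alpha <= 1):
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    mu_pfs = 1.0 - pfs_negation(plane.mu, alpha)
    nu_pfs = pfs_negation(mu_pfs, alpha)
    radicand = 1.0 - mu_pfs**2 - nu_pfs**2
    pi_pfs = np.sqrt(np.clip(radicand, 0.0, None))
    return PFI(mu_pfs, nu_pfs, pi_pfs, float(alpha), plane.y_min, plane.y_max)


def pfe(pfi: PFI) -> float:
    """Pythagorean fuzzy entropy of a PFI, in ``[0, 1]``.

    Mean over pixels of ``(π² + 1 − |μ² − ν²|) / (π² + 1 + |μ² − ν²|)``:
    1 when μ and ν coincide everywhere, 0 when the image is fully crisp
    (μ ≡ 1 with ν = π = 0).
    """
    d = np.abs(pfi.mu_pfs**2 - pfi.nu_pfs**2)
    base = pfi.pi_pfs**2 + 1.0
    return float(np.mean((base - d) / (base + d)))


def optimize_alpha(
    plane: MembershipPlane, grid=None
) -> tuple[float, list[tuple[float, float]]]:
    """Select the entropy-maximizing α over a candidate grid.

    Evaluates ``PFE(build_pfi(plane, α))`` for every grid value and returns
    the maximizer (ties broken toward the smallest α, making the choice
    deterministic) together with the full (α, PFE) curve for reporting.
    """
    if grid is None:
        grid = default_alpha_grid()
    grid = np.asarray(grid, dtype=np.float64)
    if grid.size == 0:
        raise ValueError("alpha grid must be nonempty")
    if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("alpha grid must be strictly increasing and positive")
    best_alpha = None
    best_pfe = -np.inf
    curve: list[tuple[float, float]] = []
    for alpha in grid:
        value = pfe(build_pfi(plane, float(alpha)))
        curve.append((float(alpha), value))
        if value > best_pfe:  # strict: ties keep the earlier (smaller) alpha
            best_pfe = value
            best_alpha = float(alpha)
    return best_alpha, curve


def enhance(pfi: PFI, lambda_hedge: float = 2.0) -> MembershipPlane:
    """Hedge-and-intensify contrast enhancement of the PFI membership plane.

    The membership is concentrated with ``μ_new = μ_PFS ** λ`` (λ ≥ 1) and
    stretched away from 0.5 with the INT operator::

        2·μ_new²            if μ_new ≤ 0.5
        1 − 2·(1 − μ_new)²  otherwise

    Both steps fix 0 and 1 and are monotone, so ordering of pixels is
    preserved.  The output carries the PFI's defuzzification anchors.
    """
    if lambda_hedge < 1:
        raise ValueError(f"enhance.lambda must be >= 1, got {lambda_hedge}")
    mu_new = np.asarray(pfi.mu_pfs, dtype=np.float64) ** lambda_hedge
    out = np.where(mu_new <= 0.5, 2.0 * mu_new**2, 1.0 - 2.0 * (1.0 - mu_new) ** 2)
    return MembershipPlane(out, pfi.y_min, pfi.y_max)


def defuzzify(plane: MembershipPlane, y_min: float | None = None,
              y_max: float | None = None) -> np.ndarray:
    """Map a fuzzy plane back to gray levels: ``(y_max − y_min)·μ + y_min``.

    Anchors default to the ones stored on the plane; fused planes pass the
    shared range of both sources explicitly.  Exact inverse of
    :func:`fuzzify` when used with the plane's own anchors.
    """
    lo = plane.y_min if y_min is None else float(y_min)
    hi = plane.y_max if y_max is None else float(y_max)
    if lo > hi:
        raise ValueError(f"y_min ({lo}) exceeds y_max ({hi})")
    return (hi - lo) * plane.mu + lo
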