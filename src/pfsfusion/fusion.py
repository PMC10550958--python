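"""Block-based fusion rules and the grayscale fusion pipeline.

The base layers of the two sources, after fuzzification (and optionally
Pythagorean-fuzzy enhancement), are partitioned into blocks and fused per
block by the blackness/whiteness rule: if the pooled count of fuzzy values
below 0.5 across both blocks exceeds the count above 0.5 the block is dark
and the elementwise minimum is kept; if whiteness dominates the maximum is
kept; ties average.  The detail layers are fused per block by spatial
frequency: the block with the clearly higher SF wins, otherwise the blocks
are averaged.  The fused image is the sum of the defuzzified base and the
fused detail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import FusionConfig
from .decomposition import decompose
from .io import validate_gray
from .pfs import MembershipPlane, build_pfi, defuzzify, enhance, fuzzify, optimize_alpha

__all__ = [
    "BlockGrid",
    "FusionResult",
    "partition",
    "black_white_counts",
    "fuse_base",
    "block_sf",
    "fuse_detail",
    "reconstruct",
    "fuse_gray",
]


@dataclass(frozen=True)
class BlockGrid:
    """Tiling of a plane (padded by edge replication) into fixed-size blocks."""

    block_h: int
    block_w: int
    orig_shape: tuple[int, int]
    padded_shape: tuple[int, int]
    windows: tuple[tuple[slice, slice], ...]

    def pad(self, plane: np.ndarray) -> np.ndarray:
        """Edge-replicate ``plane`` up to the padded shape."""
        pad_r = self.padded_shape[0] - self.orig_shape[0]
        pad_c = self.padded_shape[1] - self.orig_shape[1]
        return np.pad(plane, ((0, pad_r), (0, pad_c)), mode="edge")

    def crop(self, padded: np.ndarray) -> np.ndarray:
        return padded[: self.orig_shape[0], : self.orig_shape[1]]


@dataclass(frozen=True)
class FusionResult:
    """Output bundle of the grayscale pipeline.

    ``fused = base_fused + detail_fused`` is kept unclipped; clipping to
    ``[0, 255]`` happens only when the image is written to disk.
    ``alpha1``/``alpha2`` are the fuzzification parameters actually used for
    each source (the entropy maximizers, or 1.0 when enhancement is off);
    ``pfe_curves`` holds the per-source (α, PFE) grids.
    """

    fused: np.ndarray
    base_fused: np.ndarray
    detail_fused: np.ndarray
    alpha1: float
    alpha2: float
    pfe_curves: tuple[list, list] = field(default_factory=lambda: ([], []))


def partition(plane: np.ndarray, block_h: int, block_w: int) -> BlockGrid:
    """Tile a plane into ``block_h x block_w`` windows, padding by edge replication.

    The plane is padded up to the next multiples of the block dimensions so
    that the windows are disjoint and cover it exactly.
    """
    if block_h < 1 or block_w < 1:
        raise ValueError(f"block size must be positive, got {block_h}x{block_w}")
    rows, cols = plane.shape
    padded_r = -(-rows // block_h) * block_h
    padded_c = -(-cols // block_w) * block_w
    windows = tuple(
        (slice(r, r + block_h), slice(c, c + block_w))
        for r in range(0, padded_r, block_h)
        for c in range(0, padded_c, block_w)
    )
    return BlockGrid(block_h, block_w, (rows, cols), (padded_r, padded_c), windows)


def black_white_counts(block1: np.ndarray, block2: np.ndarray) -> tuple[int, int]:
    """Pooled blackness/whiteness counts over both fuzzy blocks.

    Blackness counts entries strictly below 0.5 across *both* blocks,
    whiteness entries strictly above; values exactly at 0.5 count toward
    neither.
    """
    if block1.shape != block2.shape:
        raise ValueError(f"block shapes differ: {block1.shape} vs {block2.shape}")
    blackness = int(np.count_nonzero(block1 < 0.5) + np.count_nonzero(block2 < 0.5))
    whiteness = int(np.count_nonzero(block1 > 0.5) + np.count_nonzero(block2 > 0.5))
    return blackness, whiteness


def fuse_base(
    plane1: MembershipPlane, plane2: MembershipPlane, cfg: FusionConfig | None = None
) -> MembershipPlane:
    """Blackness/whiteness block fusion of two fuzzy base-layer planes.

    Per block: blackness > whiteness selects the elementwise minimum (keep
    the darker structure), whiteness > blackness the maximum, ties the
    average.  The output carries shared defuzzification anchors — the min of
    both planes' ``y_min`` and the max of both ``y_max`` — since fused
    blocks mix both sources.
    """
    cfg = cfg if cfg is not None else FusionConfig()
    m1, m2 = plane1.mu, plane2.mu
    if m1.shape != m2.shape:
        raise ValueError(f"plane shapes differ: {m1.shape} vs {m2.shape}")
    grid = partition(m1, cfg.block_h, cfg.block_w)
    p1, p2 = grid.pad(m1), grid.pad(m2)
    out = np.empty_like(p1)
    for win in grid.windows:
        b1, b2 = p1[win], p2[win]
        blackness, whiteness = black_white_counts(b1, b2)
        if blackness > whiteness:
            out[win] = np.minimum(b1, b2)
        elif blackness < whiteness:
            out[win] = np.maximum(b1, b2)
        else:
            out[win] = (b1 + b2) / 2.0
    return MembershipPlane(
        grid.crop(out),
        min(plane1.y_min, plane2.y_min),
        max(plane1.y_max, plane2.y_max),
    )


def block_sf(block: np.ndarray) -> float:
    """Spatial frequency of one block: ``sqrt(RF² + CF²)``.

    Row frequency RF is the RMS of horizontal first differences and column
    frequency CF of vertical first differences, both normalized by the
    block area ``i*j``.  Invariant to adding a constant.
    """
    block = np.asarray(block, dtype=np.float64)
    if block.ndim != 2 or block.shape[0] < 2 or block.shape[1] < 2:
        raise ValueError(f"block must be at least 2x2, got shape {block.shape}")
    area = block.size
    rf2 = np.sum(np.diff(block, axis=1) ** 2) / area
    cf2 = np.sum(np.diff(block, axis=0) ** 2) / area
    return float(np.sqrt(rf2 + cf2))


def fuse_detail(
    detail1: np.ndarray, detail2: np.ndarray, cfg: FusionConfig | None = None
) -> np.ndarray:
    """Spatial-frequency block fusion of two detail layers.

    Per block: keep block 1 if ``SF1 > SF2 + TH``, block 2 if
    ``SF2 > SF1 + TH``, otherwise average.  TH = 0 reduces to pure max-SF
    selection with averaging on exact ties.
    """
    cfg = cfg if cfg is not None else FusionConfig()
    d1 = np.asarray(detail1, dtype=np.float64)
    d2 = np.asarray(detail2, dtype=np.float64)
    if d1.shape != d2.shape:
        raise ValueError(f"detail shapes differ: {d1.shape} vs {d2.shape}")
    grid = partition(d1, cfg.block_h, cfg.block_w)
    p1, p2 = grid.pad(d1), grid.pad(d2)
    out = np.empty_like(p1)
    for win in grid.windows:
        b1, b2 = p1[win], p2[win]
        if min(b1.shape) >= 2:
            sf1, sf2 = block_sf(b1), block_sf(b2)
        else:  # 1-pixel-wide blocks have no differences; treat as tied
            sf1 = sf2 = 0.0
        if sf1 > sf2 + cfg.th:
            out[win] = b1
        elif sf2 > sf1 + cfg.th:
            out[win] = b2
        else:
            out[win] = (b1 + b2) / 2.0
    return grid.crop(out)


def reconstruct(base_fused: np.ndarray, detail_fused: np.ndarray) -> np.ndarray:
    """Final fused image: elementwise sum of fused base and fused detail."""
    base = np.asarray(base_fused, dtype=np.float64)
    detail = np.asarray(detail_fused, dtype=np.float64)
    if base.shape != detail.shape:
        raise ValueError(f"layer shapes differ: {base.shape} vs {detail.shape}")
    return base + detail


def fuse_gray(
    x1: np.ndarray, x2: np.ndarray, cfg: FusionConfig | None = None
) -> FusionResult:
    """Full grayscale fusion of two pre-registered same-size images.

    Pipeline: Gaussian base/detail decomposition of both sources →
    fuzzification of the base layers → per-image entropy-optimized α →
    Pythagorean fuzzy enhancement (when enabled) → blackness/whiteness
    block fusion → defuzzification over the shared gray range → SF block
    fusion of the detail layers → sum.

    With enhancement disabled the PFI is built at α = 1, where the PFS
    membership coincides with the plain min–max membership, and the
    hedge/INT stage is skipped; the pipeline is then the identity on
    identical inputs.  α curves are still computed for reporting.
    """
    cfg = cfg if cfg is not None else FusionConfig()
    x1 = validate_gray(x1)
    x2 = validate_gray(x2)
    if x1.shape != x2.shape:
        raise ValueError(f"source shapes differ: {x1.shape} vs {x2.shape}")

    gp = cfg.gaussian_params()
    layers1 = decompose(x1, gp)
    layers2 = decompose(x2, gp)

    plane1 = fuzzify(layers1.base)
    plane2 = fuzzify(layers2.base)

    grid = cfg.alpha_grid()
    alpha_opt1, curve1 = optimize_alpha(plane1, grid)
    alpha_opt2, curve2 = optimize_alpha(plane2, grid)

    if cfg.enhance_enabled:
        used1, used2 = alpha_opt1, alpha_opt2
        fuzzy1 = enhance(build_pfi(plane1, used1), cfg.lambda_hedge)
        fuzzy2 = enhance(build_pfi(plane2, used2), cfg.lambda_hedge)
    else:
        used1 = used2 = 1.0
        fuzzy1 = MembershipPlane(
            build_pfi(plane1, 1.0).mu_pfs, plane1.y_min, plane1.y_max
        )
        fuzzy2 = MembershipPlane(
            build_pfi(plane2, 1.0).mu_pfs, plane2.y_min, plane2.y_max
        )

    fused_plane = fuse_base(fuzzy1, fuzzy2, cfg)
    base_fused = defuzzify(fused_plane)
    detail_fused = fuse_detail(layers1.detail, layers2.detail, cfg)
    fused = reconstruct(base_fused, detail_fused)
    return FusionResult(
        fused=fused,
        base_fused=base_fused,
        detail_fused=detail_fused,
        alpha1=used1,
        alpha2=used2,
        pfe_curves=(curve1, curve2),
    )
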