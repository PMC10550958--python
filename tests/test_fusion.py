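import numpy as np
import pytest

from pfsfusion.config import FusionConfig
from pfsfusion.decomposition import GaussianParams, decompose
from pfsfusion.fusion import (
    black_white_counts,
    block_sf,
    fuse_base,
    fuse_detail,
    fuse_gray,
    partition,
    reconstruct,
)
from pfsfusion.pfs import (
    MembershipPlane,
    build_pfi,
    defuzzify,
    enhance,
    fuzzify,
    optimize_alpha,
)
from pfsfusion.phantoms import make_pair


def brute_force_fuse_base(m1, m2, bh, bw):
    """Independent per-block reference for the blackness/whiteness rule."""
    rows, cols = m1.shape
    pr = ((rows + bh - 1) // bh) * bh
    pc = ((cols + bw - 1) // bw) * bw
    p1 = np.pad(m1, ((0, pr - rows), (0, pc - cols)), mode="edge")
    p2 = np.pad(m2, ((0, pr - rows), (0, pc - cols)), mode="edge")
    out = np.zeros_like(p1)
    for r0 in range(0, pr, bh):
        for c0 in range(0, pc, bw):
            b1 = p1[r0 : r0 + bh, c0 : c0 + bw]
            b2 = p2[r0 : r0 + bh, c0 : c0 + bw]
            black = white = 0
            for blk in (b1, b2):
                for v in blk.ravel():
                    if v < 0.5:
                        black += 1
                    elif v > 0.5:
                        white += 1
            if black > white:
                out[r0 : r0 + bh, c0 : c0 + bw] = np.minimum(b1, b2)
            elif black < white:
                out[r0 : r0 + bh, c0 : c0 + bw] = np.maximum(b1, b2)
            else:
                out[r0 : r0 + bh, c0 : c0 + bw] = (b1 + b2) / 2
    return out[:rows, :cols]


def brute_force_block_sf(block):
    i, j = block.shape
    rf = 0.0
    for q in range(i):
        for r in range(1, j):
            rf += (block[q, r] - block[q, r - 1]) ** 2
    cf = 0.0
    for q in range(1, i):
        for r in range(j):
            cf += (block[q, r] - block[q - 1, r]) ** 2
    return np.sqrt(rf / (i * j) + cf / (i * j))


def brute_force_fuse_detail(d1, d2, bh, bw, th):
    rows, cols = d1.shape
    pr = ((rows + bh - 1) // bh) * bh
    pc = ((cols + bw - 1) // bw) * bw
    p1 = np.pad(d1, ((0, pr - rows), (0, pc - cols)), mode="edge")
    p2 = np.pad(d2, ((0, pr - rows), (0, pc - cols)), mode="edge")
    out = np.zeros_like(p1)
    for r0 in range(0, pr, bh):
        for c0 in range(0, pc, bw):
            b1 = p1[r0 : r0 + bh, c0 : c0 + bw]
            b2 = p2[r0 : r0 + bh, c0 : c0 + bw]
            sf1 = brute_force_block_sf(b1)
            sf2 = brute_force_block_sf(b2)
            if sf1 > sf2 + th:
                out[r0 : r0 + bh, c0 : c0 + bw] = b1
            elif sf2 > sf1 + th:
                out[r0 : r0 + bh, c0 : c0 + bw] = b2
            else:
                out[r0 : r0 + bh, c0 : c0 + bw] = (b1 + b2) / 2
    return out[:rows, :cols]


class TestPartition:
    @pytest.mark.parametrize(
        "shape,bh,bw,n_windows,padded",
        [
            ((16, 16), 8, 8, 4, (16, 16)),
            ((10, 10), 8, 8, 4, (16, 16)),
            ((5, 7), 1, 1, 35, (5, 7)),
        ],
    )
    def test_tiling_and_padding(self, shape, bh, bw, n_windows, padded):
        grid = partition(np.zeros(shape), bh, bw)
        assert len(grid.windows) == n_windows
        assert grid.padded_shape == padded
        # windows are disjoint and tile the padded plane exactly
        cover = np.zeros(padded, dtype=int)
        for win in grid.windows:
            assert cover[win].shape == (bh, bw)
            cover[win] += 1
        assert np.all(cover == 1)

    def test_pad_then_crop_round_trip(self, rng):
        plane = rng.uniform(0, 1, (10, 13))
        grid = partition(plane, 8, 8)
        np.testing.assert_array_equal(grid.crop(grid.pad(plane)), plane)

    def test_rejects_nonpositive_blocks(self):
        with pytest.raises(ValueError):
            partition(np.zeros((4, 4)), 0, 8)


class TestBlackWhiteCounts:
    def test_uniform_blocks(self):
        dark = np.full((4, 4), 0.2)
        assert black_white_counts(dark, dark) == (32, 0)
        bright = np.full((4, 4), 0.8)
        assert black_white_counts(bright, bright) == (0, 32)

    def test_half_counts_toward_neither(self):
        half = np.full((4, 4), 0.5)
        assert black_white_counts(half, half) == (0, 0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            black_white_counts(np.zeros((2, 2)), np.zeros((3, 3)))


class TestFuseBase:
    def test_identical_inputs_idempotent(self, rng):
        mu = rng.uniform(0, 1, (32, 32))
        plane = MembershipPlane(mu, 0.0, 255.0)
        out = fuse_base(plane, plane)
        np.testing.assert_allclose(out.mu, mu)

    def test_dark_blocks_take_minimum(self):
        p1 = MembershipPlane(np.full((8, 8), 0.1), 0, 255)
        p2 = MembershipPlane(np.full((8, 8), 0.3), 0, 255)
        np.testing.assert_allclose(fuse_base(p1, p2).mu, 0.1)

    def test_bright_blocks_take_maximum(self):
        p1 = MembershipPlane(np.full((8, 8), 0.7), 0, 255)
        p2 = MembershipPlane(np.full((8, 8), 0.9), 0, 255)
        np.testing.assert_allclose(fuse_base(p1, p2).mu, 0.9)

    def test_matches_brute_force_oracle(self, rng):
        cfg = FusionConfig()
        for _ in range(25):
            m1 = rng.uniform(0, 1, (32, 32))
            m2 = rng.uniform(0, 1, (32, 32))
            out = fuse_base(
                MembershipPlane(m1, 0, 255), MembershipPlane(m2, 0, 255), cfg
            )
            np.testing.assert_allclose(out.mu, brute_force_fuse_base(m1, m2, 8, 8))

    def test_output_within_pointwise_envelope(self, rng):
        m1 = rng.uniform(0, 1, (24, 24))
        m2 = rng.uniform(0, 1, (24, 24))
        out = fuse_base(MembershipPlane(m1, 0, 255), MembershipPlane(m2, 0, 255)).mu
        assert np.all(out >= np.minimum(m1, m2) - 1e-12)
        assert np.all(out <= np.maximum(m1, m2) + 1e-12)

    def test_anchors_are_shared_range(self):
        p1 = MembershipPlane(np.full((4, 4), 0.4), 10.0, 150.0)
        p2 = MembershipPlane(np.full((4, 4), 0.6), 30.0, 220.0)
        out = fuse_base(p1, p2)
        assert (out.y_min, out.y_max) == (10.0, 220.0)

    def test_non_divisible_shape_is_cropped_back(self, rng):
        m1 = rng.uniform(0, 1, (13, 19))
        m2 = rng.uniform(0, 1, (13, 19))
        out = fuse_base(MembershipPlane(m1, 0, 255), MembershipPlane(m2, 0, 255))
        assert out.mu.shape == (13, 19)


class TestBlockSf:
    def test_constant_block_zero(self):
        assert block_sf(np.full((8, 8), 3.7)) == 0.0

    def test_checkerboard_exact_value(self):
        assert block_sf(np.array([[0.0, 1.0], [1.0, 0.0]])) == pytest.approx(1.0)

    def test_shift_invariance_and_oracle(self, rng):
        for _ in range(20):
            block = rng.uniform(-50, 50, (8, 8))
            assert block_sf(block) == pytest.approx(brute_force_block_sf(block), abs=1e-9)
            assert block_sf(block + 17.3) == pytest.approx(block_sf(block), abs=1e-9)

    def test_rejects_undersized(self):
        with pytest.raises(ValueError):
            block_sf(np.zeros((1, 5)))


class TestFuseDetail:
    def test_identical_inputs_unchanged(self, rng):
        d = rng.uniform(-30, 30, (32, 32))
        np.testing.assert_allclose(fuse_detail(d, d), d)

    def test_active_block_wins_over_flat(self):
        d1 = np.indices((8, 8)).sum(axis=0) % 2 * 40.0  # checkerboard
        d2 = np.zeros((8, 8))
        np.testing.assert_allclose(fuse_detail(d1, d2), d1)

    def test_matches_brute_force_oracle_with_threshold(self, rng):
        cfg = FusionConfig(th=0.1)
        for _ in range(25):
            d1 = rng.uniform(-20, 20, (32, 32))
            d2 = rng.uniform(-20, 20, (32, 32))
            np.testing.assert_allclose(
                fuse_detail(d1, d2, cfg), brute_force_fuse_detail(d1, d2, 8, 8, 0.1)
            )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fuse_detail(np.zeros((8, 8)), np.zeros((8, 9)))


class TestReconstruct:
    def test_sum_and_identity(self):
        base = np.full((4, 4), 50.0)
        detail = np.full((4, 4), -10.0)
        np.testing.assert_array_equal(reconstruct(base, detail), 40.0)
        np.testing.assert_array_equal(reconstruct(base, np.zeros((4, 4))), base)

    def test_inverts_decomposition(self, random_image):
        layers = decompose(random_image, GaussianParams(sigma=3.0))
        np.testing.assert_allclose(
            reconstruct(layers.base, layers.detail), random_image, atol=1e-9
        )


class TestFuseGray:
    def test_identity_fusion_without_enhancement(self, rng):
        cfg = FusionConfig(enhance_enabled=False)
        for _ in range(5):
            img = rng.uniform(0, 255, (40, 40))
            result = fuse_gray(img, img, cfg)
            assert np.abs(result.fused - img).max() <= 1e-6

    def test_constant_pair_stays_constant(self):
        img = np.full((32, 32), 100.0)
        for cfg in (FusionConfig(), FusionConfig(enhance_enabled=False)):
            result = fuse_gray(img, img, cfg)
            np.testing.assert_allclose(result.fused, 100.0, atol=1e-9)

    def test_result_is_sum_of_its_layers(self, rng):
        x1 = rng.uniform(0, 255, (48, 48))
        x2 = rng.uniform(0, 255, (48, 48))
        result = fuse_gray(x1, x2)
        np.testing.assert_allclose(
            result.fused, result.base_fused + result.detail_fused, atol=1e-9
        )

    def test_shape_preserved_for_non_divisible_sizes(self, rng):
        x1 = rng.uniform(0, 255, (37, 45))
        x2 = rng.uniform(0, 255, (37, 45))
        assert fuse_gray(x1, x2).fused.shape == (37, 45)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fuse_gray(np.zeros((8, 8)), np.zeros((8, 9)))

    def test_matches_step_by_step_composition(self):
        """Pipeline equals a straight-line reference assembled from the stages."""
        cfg = FusionConfig(sigma=2.0, block_h=8, block_w=8)
        x1, x2 = make_pair("mri_ct", (64, 64), 11)
        result = fuse_gray(x1, x2, cfg)

        gp = cfg.gaussian_params()
        l1, l2 = decompose(x1, gp), decompose(x2, gp)
        pl1, pl2 = fuzzify(l1.base), fuzzify(l2.base)
        a1, _ = optimize_alpha(pl1, cfg.alpha_grid())
        a2, _ = optimize_alpha(pl2, cfg.alpha_grid())
        e1 = enhance(build_pfi(pl1, a1), cfg.lambda_hedge)
        e2 = enhance(build_pfi(pl2, a2), cfg.lambda_hedge)
        base = defuzzify(fuse_base(e1, e2, cfg))
        detail = fuse_detail(l1.detail, l2.detail, cfg)
        expected = base + detail

        assert result.alpha1 == a1 and result.alpha2 == a2
        np.testing.assert_allclose(result.fused, expected, atol=1e-12)

    def test_alpha_curves_reported_per_source(self):
        x1, x2 = make_pair("mr_t1_t2", (32, 32), 5)
        result = fuse_gray(x1, x2)
        assert len(result.pfe_curves) == 2
        assert len(result.pfe_curves[0]) == 100
        assert all(0 <= v <= 1 for _, v in result.pfe_curves[0])
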