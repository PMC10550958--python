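"""Deterministic synthetic image-pair generator.

Geometric head phantoms stand in for pre-registered clinical pairs so every
stage of the pipeline is testable offline: a CT-like image (bright skull
ring, dark soft tissue, a few dense calcifications), an MRI-like image
(dim skull, smooth soft-tissue blobs), an MRA-like vessel image, and a
pseudo-colored functional (PET/SPECT-like) image built from a smooth
hotspot field.  Simple analytic kinds (checkerboard, ramp, constant, noise)
support unit tests.  Every generator is a pure function of its spec: the
same seed always reproduces the same pixels, and all intensities lie in
[0, 255].

These phantoms emulate complementary structure between modalities, not
scanner physics; noise is additive Gaussian only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PhantomSpec", "make_phantom", "make_pair", "PHANTOM_KINDS", "PAIR_KINDS"]

PHANTOM_KINDS = (
    "ct_like",
    "mri_like",
    "pet_like",
    "checkerboard",
    "ramp",
    "constant",
    "noise",
)
PAIR_KINDS = ("mr_t1_t2", "mri_ct", "mr_mra", "mri_pet", "mri_spect")


@dataclass(frozen=True)
class PhantomSpec:
    """Specification of one synthetic image.

    ``noise_sd`` is the standard deviation of the additive Gaussian noise
    in gray levels; ``value`` is the level of the ``constant`` kind.
    """

    size: tuple[int, int] = (256, 256)
    kind: str = "mri_like"
    seed: int = 0
    noise_sd: float = 2.0
    value: float = 128.0

    def __post_init__(self) -> None:
        if self.kind not in PHANTOM_KINDS:
            raise ValueError(f"unknown phantom kind: {self.kind!r}")
        a, b = self.size
        structured = self.kind in ("ct_like", "mri_like", "pet_like")
        minimum = 16 if structured else 2
        if a < minimum or b < minimum:
            raise ValueError(
                f"{self.kind} phantoms require size >= {minimum}x{minimum}, got {self.size}"
            )
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be nonnegative, got {self.noise_sd}")


def _grids(size: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    a, b = size
    y = np.linspace(-1.0, 1.0, a)[:, None] * np.ones((1, b))
    x = np.ones((a, 1)) * np.linspace(-1.0, 1.0, b)[None, :]
    return y, x


def _head_radius(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    # elliptical "head" coordinate: 1.0 at the outer skull boundary
    return np.sqrt((y / 0.92) ** 2 + (x / 0.78) ** 2)


def _blob(y, x, cy, cx, sy, sx):
    return np.exp(-(((y - cy) / sy) ** 2 + ((x - cx) / sx) ** 2))


def _ct_like(size, rng: np.random.Generator) -> np.ndarray:
    y, x = _grids(size)
    r = _head_radius(y, x)
    img = np.full(size, 8.0)
    img[r < 1.0] = 28.0  # soft tissue: nearly uniform, CT shows it poorly
    img[(r >= 0.84) & (r < 1.0)] = 235.0  # dense skull ring
    # dense structures CT captures well: calcifications and a bone septum
    for _ in range(3):
        cy, cx = rng.uniform(-0.45, 0.45, size=2)
        s = rng.uniform(0.04, 0.09)
        img += 190.0 * _blob(y, x, cy, cx, s, s) * (r < 0.8)
    img += 170.0 * (np.abs(x) < 0.02) * (np.abs(y) < 0.5) * (r < 0.8)
    return img


def _mri_like(size, rng: np.random.Generator) -> np.ndarray:
    y, x = _grids(size)
    r = _head_radius(y, x)
    img = np.full(size, 5.0)
    inside = r < 0.84
    img[inside] = 95.0
    img[(r >= 0.84) & (r < 1.0)] = 40.0  # bone is dim on MR
    # smooth soft-tissue blobs (gray/white matter contrast, lesions)
    for _ in range(6):
        cy, cx = rng.uniform(-0.55, 0.55, size=2)
        sy, sx = rng.uniform(0.10, 0.32, size=2)
        amp = rng.uniform(-60.0, 75.0)
        img += amp * _blob(y, x, cy, cx, sy, sx) * inside
    # ventricle-like dark region
    img -= 55.0 * _blob(y, x, 0.05, 0.0, 0.18, 0.10) * inside
    return img


def _mra_like(size, rng: np.random.Generator) -> np.ndarray:
    """Thin bright vessel tracks on a dark background."""
    y, x = _grids(size)
    r = _head_radius(y, x)
    img = np.full(size, 12.0)
    img[(r >= 0.84) & (r < 1.0)] = 55.0
    t = np.linspace(-0.75, 0.75, 400)
    for _ in range(4):
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.15, 0.4)
        freq = rng.uniform(2.0, 5.0)
        x0 = rng.uniform(-0.4, 0.4)
        track = np.zeros(size)
        for ty in t:
            tx = x0 + amp * np.sin(freq * ty + phase)
            track += _blob(y, x, ty, tx, 0.02, 0.02)
        img += 210.0 * np.clip(track, 0, 1) * (r < 0.8)
    return img


def _hotspot_field(size, rng: np.random.Generator) -> np.ndarray:
    y, x = _grids(size)
    r = _head_radius(y, x)
    field = np.zeros(size)
    for _ in range(4):
        cy, cx = rng.uniform(-0.5, 0.5, size=2)
        sy, sx = rng.uniform(0.12, 0.30, size=2)
        field += rng.uniform(0.4, 1.0) * _blob(y, x, cy, cx, sy, sx)
    field *= r < 0.95
    peak = field.max()
    return field / peak if peak > 0 else field


def _pseudo_color(h: np.ndarray) -> np.ndarray:
    """Jet-like piecewise-linear colormap mapping [0, 1] to RGB in [0, 255]."""
    r = np.clip(1.5 - np.abs(4.0 * h - 3.0), 0.0, 1.0)
    g = np.clip(1.5 - np.abs(4.0 * h - 2.0), 0.0, 1.0)
    b = np.clip(1.5 - np.abs(4.0 * h - 1.0), 0.0, 1.0)
    return np.stack([r, g, b], axis=-1) * 255.0


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Generate one phantom image from its spec (grayscale, or RGB for pet_like)."""
    rng = np.random.default_rng(spec.seed)
    a, b = spec.size
    if spec.kind == "constant":
        return np.full(spec.size, float(spec.value))
    if spec.kind == "checkerboard":
        rows, cols = np.indices(spec.size)
        return (((rows // 8) + (cols // 8)) % 2) * 255.0
    if spec.kind == "ramp":
        return np.tile(np.linspace(0.0, 255.0, b), (a, 1))
    if spec.kind == "noise":
        return np.clip(128.0 + spec.noise_sd * rng.standard_normal(spec.size), 0, 255)
    if spec.kind == "ct_like":
        img = _ct_like(spec.size, rng)
    elif spec.kind == "mri_like":
        img = _mri_like(spec.size, rng)
    else:  # pet_like
        field = _hotspot_field(spec.size, rng)
        rgb = _pseudo_color(field)
        if spec.noise_sd > 0:
            rgb = rgb + spec.noise_sd * rng.standard_normal(rgb.shape)
        return np.clip(rgb, 0.0, 255.0)
    if spec.noise_sd > 0:
        img = img + spec.noise_sd * rng.standard_normal(spec.size)
    return np.clip(img, 0.0, 255.0)


def make_pair(
    kind: str, size: tuple[int, int] = (256, 256), seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Generate a registered, structurally complementary modality pair.

    Grayscale kinds return two 2-D images; ``mri_pet`` and ``mri_spect``
    return (grayscale MRI, RGB functional image).
    """
    if kind not in PAIR_KINDS:
        raise ValueError(f"unknown pair kind: {kind!r}")
    if kind == "mr_t1_t2":
        t1 = make_phantom(PhantomSpec(size=size, kind="mri_like", seed=seed))
        # T2 contrast is roughly inverted relative to T1 (fluid bright)
        t2 = 255.0 - make_phantom(PhantomSpec(size=size, kind="mri_like", seed=seed + 1))
        return t1, np.clip(t2, 0.0, 255.0)
    if kind == "mri_ct":
        return (
            make_phantom(PhantomSpec(size=size, kind="mri_like", seed=seed)),
            make_phantom(PhantomSpec(size=size, kind="ct_like", seed=seed + 1)),
        )
    if kind == "mr_mra":
        mri = make_phantom(PhantomSpec(size=size, kind="mri_like", seed=seed))
        rng = np.random.default_rng(seed + 1)
        mra = np.clip(_mra_like(size, rng) + 2.0 * rng.standard_normal(size), 0, 255)
        return mri, mra
    # mri_pet / mri_spect
    offset = 1 if kind == "mri_pet" else 2
    return (
        make_phantom(PhantomSpec(size=size, kind="mri_like", seed=seed)),
        make_phantom(PhantomSpec(size=size, kind="pet_like", seed=seed + offset)),
    )
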