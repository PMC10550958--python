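# Methods

This note documents the model implemented by `pfsfusion`, the choices made
where the method leaves details open, and what the synthetic phantoms do
and do not establish about real clinical data.

## Pipeline

Two pre-registered source images `X₁, X₂` of equal size `A×B` (8-bit
display scale, held internally as float64 on `[0, 255]`) are fused in four
stages.

**1. Two-scale decomposition.** `Y_i = X_i * G` (2-D convolution with a
normalized Gaussian, symmetric border padding) and `Z_i = X_i − Y_i`. The
decomposition is exactly additive by construction; symmetric padding
preserves constant images and keeps border values inside the source range,
so the min/max fuzzification anchors are never contaminated by padding
artifacts.

**2. Base-layer fusion via Pythagorean fuzzy sets.** Each base layer is
min–max normalized to a membership plane μ (a constant layer maps to
μ ≡ 0.5 with both anchors equal, making the round trip exact). The plane is
lifted to a PFI with the parametric negation
`N(x; α) = α²(1−x)/(α²(1−x)+x)`:

- `μ_PFS = 1 − N(μ; α)`; `ν_PFS = N(μ_PFS; α)` — the negation is applied to
  the already-lifted membership, not the original μ;
- `π_PFS = √(1 − μ_PFS² − ν_PFS²)`.

For α ∈ (0, 1], `N(x; α) ≤ 1 − x`, hence `μ_PFS + ν_PFS ≤ 1` and the
π radicand is nonnegative analytically; it is clipped at 0 only against
floating-point round-off. α is selected per image as the maximizer of the
Pythagorean fuzzy entropy over a grid; ties break to the smallest α so the
selection is deterministic. The enhanced membership (hedge `μ_PFS^λ`
followed by the INT operator) is partitioned into blocks and fused by the
blackness/whiteness rule; counts are pooled over both corresponding blocks,
with strict inequalities against 0.5 (a value exactly at 0.5 counts toward
neither). Defuzzification uses the *shared* gray range — min of both base
minima to max of both maxima — because a fused block can mix values from
both sources and per-source anchors could push crisp values out of range.

**3. Detail-layer fusion.** Per block, `SF = √(RF² + CF²)` with RF/CF the
RMS of horizontal/vertical first differences normalized by the block area.
The selection rule is symmetric: block 1 wins if `SF₁ > SF₂ + TH`, block 2
if `SF₂ > SF₁ + TH`, otherwise average. (The asymmetric second branch
sometimes written for this rule overlaps the tie branch; the symmetric form
is the only total, consistent reading and is what is implemented.)

**4. Reconstruction.** `U = Y_B + Z_D`, kept unclipped in memory; clipping
to `[0, 255]` and half-up rounding happen only when writing an 8-bit file.

**Color pathway.** "YUV" is implemented as analog BT.601
(`Y = 0.299R + 0.587G + 0.114B`, `U = 0.492(B−Y)`, `V = 0.877(R−Y)`); the
inverse is the exact matrix inverse. Chrominance is kept signed and
unquantized between the transforms, so the U/V planes of the output are
bitwise those of the source functional image. Results are mildly dependent
on the choice of YUV matrix; the choice is isolated in two functions.

## Parameters

| key | default | meaning |
|---|---|---|
| `gaussian.sigma` | 5 px | base/detail cut-off scale; larger → more content in the detail layer |
| `gaussian.kernel_size` | 2·ceil(3σ)+1 = 31 | odd kernel side; derived from σ unless set |
| `block.h`, `block.w` | 8 × 8 | block size for both fusion rules |
| `detail.th` | 0 | SF decision margin; 0 = pure max-SF with tie averaging |
| `enhance.lambda` | 2 | fuzzy hedge exponent (≥ 1); 2 is the classical concentration hedge |
| `alpha.start/stop/step` | 0.01 / 1.00 / 0.01 | entropy search grid; two-decimal resolution |
| `enhance.enabled` | true | toggles the PFS enhancement stage |

The method itself fixes none of σ, block size, TH or λ — fusion quality
scores depend on them, so all are exposed as configuration and recorded in
the run manifest.

## Design choices made where the design was open

- **Enhancement off means the true identity pipeline.** With
  `enhance.enabled=false` the PFI is built at α = 1, where the parametric
  negation degenerates to the standard negation and `μ_PFS = μ`, and the
  hedge/INT stage is skipped. The pipeline is then exactly invertible:
  fusing an image with itself returns it to within 1e-6. This is the
  package's strongest end-to-end self-check and the reason the switch
  bypasses the α optimization for the constructed planes (the entropy
  curves are still computed and reported).
- **Blackness/whiteness counts** are not formally defined by the rule's
  usual statement; the standard fuzzy-image convention is used (dark ↔
  membership < 0.5), pooled over both blocks.
- **Run manifests contain no timestamp.** Identical inputs and config must
  reproduce the manifest bitwise; a timestamp would break that for no
  auditing gain (file mtimes carry the wall-clock information).
- **Metric normalizers are kept as defined, not harmonized.** SF normalizes
  RF and CF by `1/(A·B)`; MSF normalizes by `1/(A·(B−1))` and
  `1/((A−1)·B)` and adds the summed diagonal RMS term. The two definitions
  are internally inconsistent with each other but each is implemented
  exactly as stated; consequently MSF ≥ SF always.
- **MI histogram**: 256 equal bins over [0, 255] with round-to-nearest
  assignment, log base 2. The FS ratio is invariant to the log base.
- **FS with zero total MI** is reported as missing (`None`/empty), never as
  a number: the ratio is 0/0.

## Numerical notes

- Degenerate constant images: fuzzification maps to μ ≡ 0.5 with equal
  anchors; every later stage is constant-preserving, so constant pairs fuse
  to the same constant even with enhancement on.
- Non-divisible image sizes are edge-replicated up to block multiples and
  cropped after reassembly; output shape always equals input shape.
- Blocks narrower than 2 pixels (possible only with `block.h` or `block.w`
  of 1) have no first differences; their SF comparison is treated as a tie.
- The entire pipeline contains no randomness: identical inputs and config
  give bitwise-identical outputs and manifests.

## Synthetic phantoms

The generator emulates what matters to the fusion logic: registered pairs
with *complementary* structure (a CT-like image with a bright skull ring
and dense calcifications against an MRI-like image with smooth soft-tissue
blobs; thin bright vessel tracks for MRA; a smooth hotspot field under a
jet-like pseudo-colormap for PET/SPECT), plus analytic kinds
(checkerboard, ramp, constant, noise) for unit tests. All generators are
pure functions of their spec and seed, intensities stay in [0, 255], and
noise is additive Gaussian only.

Phantoms do **not** model scanner physics, partial-volume effects,
bias fields, registration error, or realistic anatomy. Passing tests
demonstrate the correctness and determinism of the algorithm, not clinical
fusion quality; scores on real data depend on the unfixed hyperparameters
above.

## Problem sizes used in validation

The test suite and the acceptance script run on phantom pairs of 256×256
and smaller (64×64 for repeated-property checks, 16×16–32×32 for
brute-force oracle comparisons), sizes at which the brute-force references
are cheap while every code path — padding, block tiling, both fusion
branches, both color transforms — is exercised.

## Known limitations

- Exactly two source images; no multi-image fusion.
- No registration or resampling: inputs must be pre-registered and
  identically sized.
- 8-bit display-scale semantics; 16-bit input is linearly rescaled on read.
- No consistency verification / smoothing of the block decision maps, which
  can leave block-boundary artifacts on strongly conflicting inputs.
- DICOM is not read directly; convert to PNG/TIFF first.
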