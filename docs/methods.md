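# Methods

## Problem and model

`ronisteg` hides a patient record inside the *medically insignificant*
region of a 12/16-bit grayscale medical image (the near-black background of
a CT or MR slice) so that the diagnostic foreground is untouched and the
record can be recovered exactly by a receiver holding the embedding key.

The pipeline has four stages:

1. **Segmentation.** A binary mask labels significant pixels 1 and
   background 0. In production this would come from a trained segmentation
   network; the package ships a deterministic intensity-threshold provider
   with morphological cleanup, plus an adapter for externally computed
   masks. Only the provider's *contract* matters to the rest of the
   pipeline: the same mask must be reproducible from the stego image.
2. **Payload preparation.** The record is rendered as a QR symbol (byte
   mode, error-correction level M), its bits are mapped onto the levels
   {α, 1−α} with α = 0.02, and the array is zero-padded (with the bit-0
   level) to multiples of 4 and tiled into 4×4 blocks, row-major.
3. **Quantization embedding.** The cover is min-max normalized to [0, 1].
   Each selected background 4×4 tile is transformed with the orthonormal
   type-II 2D-DCT; pixel values in [0, 1] then give coefficient magnitudes
   at most 4. The magnitude axis [0, 4] is partitioned into β cells of
   width Δ = 4/β, and a coefficient in cell k is replaced by
   `|c′| = 4k/β + Δ·m` with m the message value — quantization-index
   modulation with the message as the within-cell position. All 16
   coefficients of a tile carry one message value each (1 bit per
   background pixel of raw capacity). The tile is inverse-transformed,
   clamped to [0, 1], and the image is de-normalized back to integers.
4. **Extraction.** The receiver re-segments the *stego* image (the mask is
   never transmitted), re-derives the same tile plan from the key,
   transforms each tile, and reads `m′ = (|c| − 4k/β)·β/4` with k
   recomputed from the stego coefficient itself. Bits are decided by
   `m′ ≥ 0.5` (maximum-margin rule between the two levels, ties → 1), the
   QR symbol is reassembled and decoded; its Reed–Solomon parity absorbs
   residual bit errors.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| β | 1000 | quantization cells on [0, 4]; larger β ⇒ smaller perturbation (≤ Δ per coefficient), higher PSNR, thinner noise margin |
| α | 0.02 | message levels {α, 1−α}; the distance of an embedded value from its cell boundary, hence the rounding margin α·Δ |
| rel_threshold | 0.05 | mask provider: scaled-intensity cutoff for candidate foreground |
| closing / opening radius | 5 / 3 px | provider cleanup: fill holes; delete structures thinner than ~8 px |
| min_component_px | 128 | provider cleanup: drop tiny components |
| scale_percentile | 90 | provider intensity scale reference (see below) |
| margin_px | 12 | embedded tiles keep this distance from the significant region |
| tile_spacing | 3 tiles | minimum Chebyshev spacing between used tiles |
| tile_order_seed | 0 | seeded deterministic permutation of the tile plan |
| QR EC level | M | balances payload capacity against noise tolerance |

## Why extraction is lossless: the numerical design

Three effects could corrupt embedded values between embedding and
extraction, and each drives a design choice.

**Integer rounding.** Storage rounds every pixel to a grid of step
1/(norm_max − norm_min). An orthonormal transform maps the per-pixel
rounding error (at most half a step) to a per-coefficient error of at most
4 half-steps in ℓ2, which must stay below the margin α·Δ. On the 16-bit
grid this holds up to β = 1000 with an order of magnitude to spare; on a
12-bit (1/4095) grid it fails already near β ≈ 300. For that reason stego
output for 12-bit covers is written on the full 16-bit grid
(`bit_depth 16`, values `round(x·65535)`), following the convention that
stego frames are materialized in the 16-bit range. 16-bit covers keep
their own extrema, so de-normalization is the exact inverse of
normalization and untouched pixels survive bit-identically. A 16-bit cover
with a very small dynamic range would thin the margin the same way; the
post-embed self-verification (below) reports such cases instead of
silently corrupting them.

**The [0, 1] clamp.** At small β the embedded magnitudes Δ·(1−α) are large
(0.392 at β = 10), and a tile whose reconstruction leaves [0, 1] would be
clipped, destroying its coefficients. Two extraction-invariant freedoms
prevent this: the coefficient *sign* (extraction reads magnitudes only) and
*whole-cell shifts* (k is re-derived at extraction). `embed` chooses AC
signs greedily (with a 2-opt refinement) to minimize the tile's pixel
range, then lifts the DC coefficient by whole cells until the minimum
clears the clamp. When even the optimal sign pattern cannot fit — possible
for all-ones tiles at β = 10, where the tile energy is fixed by Parseval —
and every coefficient sits in cell 0 (the generic dark-background case),
all coefficients are shrunk by a common factor γ; recovered values become
γ·m, which preserves the ≥ 0.5 bit decision for γ > 0.52. The shrink
target leaves one DC-lift step of slack so an integer lift always exists.

**Mask drift.** Extraction re-plans tiles from the stego-derived mask; a
single label change anywhere in the background would shift the tile
enumeration and misalign every subsequent block. The provider and the
planner are co-designed so the stego mask equals the cover mask exactly:

* the provider's *opening* step deletes any structure thinner than ~8 px —
  which includes every embedded 4×4 tile, however bright the quantizer
  made it — and the component filter drops residues of rare tile clusters;
* used tiles keep a 12 px margin from the significant region (more than
  twice the closing radius), so cleanup morphology can never bridge an
  embedded tile to an organ boundary;
* used tiles keep ≥ 3 tiles of spacing from each other (a seeded,
  deterministic spread selection reproduced identically at extraction), so
  closing cannot merge them into thick structures;
* the provider scales intensities by the 90th-percentile value rather than
  the maximum, so a handful of bright embedded pixels (or salt noise)
  cannot move the threshold that defines organ contours.

The spacing constraint is relaxed (deterministically) only when the
payload approaches the raw capacity; at that point mask stability is no
longer guaranteed and the self-verification flag reports it.

**Self-verification.** After writing the stego values, `embed` re-runs the
full receiver path — provider mask from the stego image, re-planning,
extraction — and sets `verified` in the manifest; a failure raises a
`VerificationWarning` (and exit code 3 in the CLI) rather than shipping an
unrecoverable stego.

## The key / manifest

Extraction needs: β, α, the message shape (bits before padding), the tile
permutation seed, margin and spacing, and the normalization grid
(norm_min, norm_max) of the stego image. The CLI serializes these as a
JSON sidecar. None of it reveals the payload; treating the tile
permutation seed as a secret adds a weak scrambling layer but the scheme
is steganography, not encryption.

## Metrics and attacks

MSE is the mean squared pixel difference in integer units; PSNR is
10·log10(R²/MSE) with R = 2^bit_depth − 1 (+∞ for identical images). Mask
agreement is measured by IoU (two empty masks score 1 by convention) and
by Pearson-style NCC. Message robustness is the NCC between the embedded
adjusted values and the recovered continuous values — affine-invariant, so
the per-tile γ shrink does not depress it — alongside the plain bit
accuracy and whether the QR still decodes.

Attacks are seeded and operate in integer pixel units: additive Gaussian
noise (σ), additive uniform noise (±half-width), and salt-and-pepper (a
density fraction of pixels forced to 0 or R). With α = 0.02 the margin to
a cell boundary is only 0.02·Δ (≈ 5 integer units at β = 1000 on the
16-bit grid), so even mild noise flips many within-cell positions: the QR
parity decides whether the payload survives. Robustness therefore degrades
steeply but monotonically with attack strength; the evaluation harness
verifies the trend (Spearman ρ < 0 over seeded replicate grids) rather
than any absolute noise level.

## Synthetic phantoms

The generator emulates abdominal slices only in the respects the method
cares about: 512×512 16-bit CT-style or 256×256 12-bit MR-style frames; a
near-black background with bounded non-negative sensor noise (default ≤
0.3 % of the range, with true zeros); 1–n bright elliptical blobs with
smooth multiplicative texture, steep (~2.5 px) edges, interiors ≥ 0.3 of
the range and a brightest pixel spanning the full range; and the exact
analytic foreground mask as ground truth. Blob axes are rescaled (up to 10
attempts) until foreground coverage lands in the configured 0.3–0.6 band,
mirroring the organ coverage of typical annotated abdominal slices.
Everything is deterministic per seed.

What the phantoms do *not* model: anatomical shape and texture statistics,
Hounsfield calibration, partial-volume edges, bias fields, or backgrounds
containing faint structures (patient table, coils). Passing tests
therefore demonstrate the *mechanics* of the pipeline — losslessness,
locality, capacity accounting, trend behavior — on favorable, well-
separated foreground/background scenes; they do not certify segmentation
quality on clinical data, where a trained model (via the external-mask
adapter) should replace the threshold provider.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run at desk scale, chosen to
exercise every code path while staying quick: transform/quantizer oracles
on 10³–10⁴ random inputs; lossless round-trips over 6–20 phantoms × β ∈
{10, 100, 200, 500, 1000} through real DICOM files; robustness grids of 3
attack kinds × 5 strengths × 10–20 seeded replicates on a 256² phantom.

## Known limitations

* Payloads near raw capacity abandon the tile-spacing guarantee, and with
  it the mask-stability guarantee (flagged by verification).
* A 16-bit cover occupying a tiny fraction of its dynamic range thins the
  rounding margin at large β (flagged by verification).
* β > ~1500 at 16-bit leaves the margin α·Δ comparable to rounding noise;
  the default β = 1000 is the practical ceiling.
* Geometric attacks (cropping, rotation, JPEG) are out of scope; the tile
  plan is position-based and would not survive them.
* QR versions 1–10 at EC level M only: payloads up to 213 UTF-8 bytes.
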