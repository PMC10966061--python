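"""Block-DCT quantization embedding in the insignificant region.

The embedding core: each 4x4 background tile of the normalized cover is
transformed with the orthonormal type-II 2D-DCT (pixels in [0,1] then give
coefficient magnitudes <= 4), and every coefficient carries one message
value. The magnitude range [0, 4] is partitioned into beta cells of width
4/beta; a coefficient in cell k is replaced by

    |c'| = 4k/beta + (4/beta) * m,      m in {alpha, 1 - alpha},

so the message value is the coefficient's position inside its cell. The
extractor re-derives k from the stego coefficient alone (k = floor(|c'|
beta/4)), which makes the scheme self-inverting and - crucially - invariant
to whole-cell shifts and to the coefficient's sign. Both freedoms are used
to keep the reconstructed tile inside [0, 1]: AC signs are chosen to
minimize the tile's pixel range and the DC coefficient is lifted by whole
cells until no pixel underruns 0. Without this the clamp that precedes
integer storage would corrupt embedded bits at small beta.

Larger beta means narrower cells, hence smaller perturbation and higher
stego fidelity; the margin against pixel-rounding noise is alpha * 4/beta,
which on the 16-bit storage grid survives down to beta = 1000 with room to
spare.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.fft import dctn, idctn

from .errors import (
    CapacityError,
    ParameterError,
    TruncationError,
    VerificationWarning,
)
from .image_io import MedicalImage, Modality, NormalizedImage, denormalize, normalize
from .mask import BinaryMask, threshold_mask
from .payload import BLOCK, MessageBlocks

__all__ = [
    "TilePlan",
    "EmbeddingKey",
    "StegoResult",
    "dct2",
    "idct2",
    "qun",
    "iqun",
    "plan_tiles",
    "embed",
    "extract",
    "capacity_report",
    "DEFAULT_BETA",
]

DEFAULT_BETA = 1000
DEFAULT_MARGIN_PX = 12
DEFAULT_TILE_SPACING = 3

# headroom kept between tile pixels and the [0, 1] clamp, in normalized units;
# a few 16-bit grid steps, well below the alpha*4/beta decision margin
_CLAMP_MARGIN = 5e-5


def dct2(block: np.ndarray) -> np.ndarray:
    """Orthonormal type-II 2D-DCT of a 4x4 block (Parseval-preserving)."""
    block = np.asarray(block, dtype=np.float64)
    if block.shape != (BLOCK, BLOCK):
        raise ValueError(f"expected a 4x4 block, got {block.shape}")
    return dctn(block, type=2, norm="ortho")


def idct2(coeffs: np.ndarray) -> np.ndarray:
    """Exact inverse of :func:`dct2`."""
    coeffs = np.asarray(coeffs, dtype=np.float64)
    if coeffs.shape != (BLOCK, BLOCK):
        raise ValueError(f"expected a 4x4 coefficient block, got {coeffs.shape}")
    return idctn(coeffs, type=2, norm="ortho")


@dataclass
class EmbeddingKey:
    """Everything the extractor needs besides the stego image itself.

    beta is the number of quantization cells on the coefficient magnitude
    range [0, 4]; alpha the message-level adjustment; message_shape the
    unpadded QR bitmap shape; tile_order_seed seeds the deterministic
    permutation of the tile plan (None = plain row-major); margin_px keeps
    embedded tiles at least that many pixels away from the significant
    region; tile_spacing is the minimum Chebyshev distance, in tiles,
    between used tiles (spread keeps the mask provider stable).
    """

    beta: int = DEFAULT_BETA
    alpha: float = 0.02
    message_shape: tuple[int, int] | None = None
    tile_order_seed: int | None = 0
    margin_px: int = DEFAULT_MARGIN_PX
    tile_spacing: int = DEFAULT_TILE_SPACING

    def __post_init__(self) -> None:
        if self.beta < 2:
            raise ParameterError(f"beta must be >= 2, got {self.beta}")
        if not 0.0 < self.alpha < 0.5:
            raise ParameterError(f"alpha must lie in (0, 0.5), got {self.alpha}")
        if self.margin_px < 0 or self.tile_spacing < 1:
            raise ParameterError("margin_px must be >= 0 and tile_spacing >= 1")

    @property
    def n_blocks(self) -> int:
        if self.message_shape is None:
            raise ParameterError("key carries no message_shape")
        r, c = self.message_shape
        return (-(-r // BLOCK)) * (-(-c // BLOCK))


@dataclass
class TilePlan:
    """Ordered 4-aligned 4x4 tile origins wholly inside the background."""

    tile_origins: list[tuple[int, int]]
    image_shape: tuple[int, int]

    def __len__(self) -> int:
        return len(self.tile_origins)


@dataclass
class StegoResult:
    stego: MedicalImage
    manifest: dict = field(default_factory=dict)

    @property
    def verified(self) -> bool:
        return bool(self.manifest.get("verified", False))


def plan_tiles(
    mask: BinaryMask,
    key: EmbeddingKey | None = None,
    margin_px: int = 0,
) -> TilePlan:
    """Enumerate embeddable tiles: 4-aligned 4x4 squares, all 16 pixels 0.

    Row-major order; if ``key.tile_order_seed`` is set the seeded
    deterministic permutation is applied. ``margin_px`` > 0 additionally
    excludes tiles within that distance of the significant region (used by
    embed/extract so that mask cleanup morphology can never interact with
    organ boundaries). Identical inputs always give identical plans.
    """
    rows, cols = mask.shape
    sig = mask.labels.astype(bool)
    if margin_px > 0 and sig.any():
        from scipy.ndimage import binary_dilation, generate_binary_structure

        sig = binary_dilation(sig, generate_binary_structure(2, 2), iterations=margin_px)
    bg = ~sig
    tr, tc = rows // BLOCK, cols // BLOCK
    ok = bg[: tr * BLOCK, : tc * BLOCK].reshape(tr, BLOCK, tc, BLOCK).all(axis=(1, 3))
    origins = [(int(r) * BLOCK, int(c) * BLOCK) for r, c in np.argwhere(ok)]
    if key is not None and key.tile_order_seed is not None and origins:
        rng = np.random.default_rng(key.tile_order_seed)
        origins = [origins[i] for i in rng.permutation(len(origins))]
    return TilePlan(tile_origins=origins, image_shape=(rows, cols))


def _select_tiles(plan: TilePlan, n: int, spacing: int) -> list[tuple[int, int]]:
    """First n plan tiles subject to a minimum tile spacing; deterministic.

    A second pass without the spacing constraint runs only when the spread
    pass cannot supply n tiles, so small payloads always come out spread.
    """
    if n > len(plan):
        raise CapacityError(required=n, available=len(plan))
    chosen: list[tuple[int, int]] = []
    blocked: set[tuple[int, int]] = set()
    taken: set[tuple[int, int]] = set()
    for r, c in plan.tile_origins:
        if len(chosen) == n:
            return chosen
        t = (r // BLOCK, c // BLOCK)
        if t in blocked:
            continue
        chosen.append((r, c))
        taken.add((r, c))
        for dr in range(-(spacing - 1), spacing):
            for dc in range(-(spacing - 1), spacing):
                blocked.add((t[0] + dr, t[1] + dc))
    for rc in plan.tile_origins:
        if len(chosen) == n:
            break
        if rc not in taken:
            chosen.append(rc)
            taken.add(rc)
    return chosen


def _cells(c_abs: np.ndarray | float, beta: int) -> np.ndarray:
    """Quantization cell index: k = min(floor(|c| beta / 4), beta - 1)."""
    k = np.floor(np.asarray(c_abs, dtype=np.float64) * beta / 4.0)
    return np.clip(k, 0, beta - 1)


def qun(cover_coeff, message_value, beta: int):
    """Quantization embedding of one message value into one coefficient.

    Returns ``sign(c) * (4k/beta + (4/beta) * m)`` with k the cell of the
    cover coefficient: the cell base plus the message offset. Accepts
    scalars or arrays.
    """
    if beta < 2:
        raise ParameterError(f"beta must be >= 2, got {beta}")
    c = np.asarray(cover_coeff, dtype=np.float64)
    m = np.asarray(message_value, dtype=np.float64)
    if np.any(np.abs(c) > 4.0 + 1e-9):
        raise ParameterError("cover coefficient magnitude exceeds 4")
    if np.any((m <= 0.0) | (m >= 1.0)):
        raise ParameterError("message values must lie strictly inside (0, 1)")
    k = _cells(np.abs(c), beta)
    sign = np.where(c < 0, -1.0, 1.0)
    out = sign * (4.0 * k / beta + (4.0 / beta) * m)
    return out if out.ndim else float(out)


def iqun(stego_coeff, beta: int):
    """Inverse quantization: recover the within-cell position in [0, 1].

    ``k`` is re-derived from the stego coefficient itself, so the operation
    is a left inverse of :func:`qun` regardless of sign or cell shifts.
    """
    if beta < 2:
        raise ParameterError(f"beta must be >= 2, got {beta}")
    c = np.abs(np.asarray(stego_coeff, dtype=np.float64))
    k = _cells(c, beta)
    out = np.clip((c - 4.0 * k / beta) * beta / 4.0, 0.0, 1.0)
    return out if out.ndim else float(out)


# 16 orthonormal DCT basis images, basis[u*4+v] = idct2(delta_uv)
_BASIS = np.stack(
    [idctn(np.eye(16)[i].reshape(4, 4), type=2, norm="ortho") for i in range(16)]
)


def _condition_block(coeffs: np.ndarray, beta: int) -> np.ndarray:
    """Fit an embedded coefficient block's pixels into [0, 1].

    Three extraction-invariant or decision-preserving freedoms are used:

    * AC signs (extraction reads magnitudes only): greedy assignment by
      descending magnitude plus a 2-opt refinement, minimizing the
      reconstructed pixel range;
    * a uniform shrink of all coefficients when every one sits in cell
      k = 0 (the generic dark-background case): scaling by gamma < 1 maps
      recovered values m to gamma*m, which preserves the >= 0.5 bit
      decision as long as gamma > 0.52 - used only when the sign search
      alone cannot fit the range, i.e. at very small beta;
    * whole-cell DC shifts (k is re-derived at extraction): a uniform
      brightness lift placing the pixel minimum just above the clamp.

    Returns the adjusted coefficients; the decided message is unchanged.
    """
    cell = 4.0 / beta
    mags = np.abs(coeffs).ravel()
    dc_mag = mags[0]
    order = np.argsort(mags[1:])[::-1] + 1  # AC indices, big first
    field_ = np.zeros((BLOCK, BLOCK))
    signs = np.ones(16)
    for a in order:
        if mags[a] == 0.0:
            continue
        plus = field_ + mags[a] * _BASIS[a]
        minus = field_ - mags[a] * _BASIS[a]
        if plus.max() - plus.min() <= minus.max() - minus.min():
            field_ = plus
        else:
            field_ = minus
            signs[a] = -1.0
    for _ in range(3):  # 2-opt refinement
        improved = False
        for a in order:
            if mags[a] == 0.0:
                continue
            flipped = field_ - 2.0 * signs[a] * mags[a] * _BASIS[a]
            if flipped.max() - flipped.min() < field_.max() - field_.min() - 1e-15:
                field_ = flipped
                signs[a] = -signs[a]
                improved = True
        if not improved:
            break

    # uniform shrink if even the best sign pattern cannot fit the clamp;
    # the DC lift moves the block mean in steps of cell/4, so the range
    # must leave at least one full step of slack for an integer lift
    capacity = 1.0 - 2.0 * _CLAMP_MARGIN - cell / 4.0
    span = field_.max() - field_.min()
    if span > capacity and np.all(mags < cell):
        gamma = max(capacity / span, 0.55)
        mags = mags * gamma
        dc_mag *= gamma
        field_ *= gamma

    # DC lift: pixels = dc/4 + field with dc = dc_mag + j*cell, j integer
    # (j >= -k so dc stays non-negative; k re-derived at extraction). Pick
    # the smallest j that clears the clamp margin at the bottom without
    # clipping at the top; when no j fits, minimize the worst violation.
    lo, hi = float(field_.min()), float(field_.max())
    k_dc = int(np.floor(dc_mag / cell + 1e-12))
    j_lo = int(np.ceil((_CLAMP_MARGIN - lo - dc_mag / 4.0) * 4.0 / cell - 1e-9))
    j_hi = int(np.floor(((1.0 - _CLAMP_MARGIN) - hi - dc_mag / 4.0) * 4.0 / cell + 1e-9))
    j_min = -k_dc
    if j_lo <= j_hi:
        j = min(max(j_lo, j_min), j_hi)
    else:  # cannot satisfy both bounds: balance under- and overshoot
        j = max(int(round((j_lo + j_hi) / 2.0)), j_min)
    out = signs * mags
    out[0] = dc_mag + j * cell
    return out.reshape(BLOCK, BLOCK)


def capacity_report(mask: BinaryMask, image_shape: tuple[int, int] | None = None) -> dict:
    """Raw embedding capacity of a mask: one bit per insignificant pixel.

    ``usable_fraction`` counts insignificant pixels; ``capacity_bits`` is
    16 x the number of fully-insignificant 4-aligned tiles; ``capacity_bpp``
    divides by the pixel count.
    """
    if image_shape is None:
        image_shape = mask.shape
    total = int(image_shape[0]) * int(image_shape[1])
    plan = plan_tiles(mask)
    bits = 16 * len(plan)
    return {
        "usable_fraction": float(np.count_nonzero(mask.labels == 0) / total),
        "capacity_bits": bits,
        "capacity_bpp": bits / total,
    }


def _stego_grid(cover: MedicalImage) -> tuple[float, float, int]:
    """Output grid for the stego image.

    16-bit covers keep their own extrema (exact inverse of normalization,
    so untouched pixels survive bit-identically). 12-bit covers are
    re-gridded onto the full 16-bit range [0, 65535]: the 1/4095 step of
    the source grid is coarser than the extraction margin at large beta,
    and the de-normalization convention for stego output is the 16-bit
    DICOM range.
    """
    if cover.bit_depth == 16:
        lo = float(cover.pixels.min())
        hi = float(cover.pixels.max())
        return lo, hi, 16
    return 0.0, 65535.0, 16


def embed(
    cover: MedicalImage,
    mask: BinaryMask,
    msg_blocks: MessageBlocks,
    key: EmbeddingKey | None = None,
    verify: bool = True,
) -> StegoResult:
    """Conceal the message blocks in the cover's insignificant region.

    Pipeline per tile: DCT -> qun (all 16 coefficients, one message value
    each) -> range conditioning -> inverse DCT -> write back; then clamp,
    de-normalize and (optionally) self-verify by running :func:`extract`
    against a mask recomputed from the stego image, exactly as a receiver
    would. An empty message returns a pixel-identical stego.
    """
    if key is None:
        key = EmbeddingKey()
    key = replace(key, message_shape=tuple(msg_blocks.original_shape))
    if mask.shape != cover.shape:
        raise ValueError("mask and cover shapes differ")

    nimg = normalize(cover)  # validates the cover is non-degenerate
    n = len(msg_blocks)
    grid_lo, grid_hi, out_depth = _stego_grid(cover)
    manifest = {
        "norm_min": grid_lo,
        "norm_max": grid_hi,
        "cover_norm_min": nimg.norm_min,
        "cover_norm_max": nimg.norm_max,
        "bit_depth": out_depth,
        "key": {
            "beta": key.beta,
            "alpha": key.alpha,
            "message_shape": list(key.message_shape),
            "tile_order_seed": key.tile_order_seed,
            "margin_px": key.margin_px,
            "tile_spacing": key.tile_spacing,
        },
        "tiles_used": 0,
        "verified": False,
    }
    if n == 0:
        manifest["verified"] = True
        return StegoResult(stego=MedicalImage(cover.pixels.copy(), cover.bit_depth,
                                              cover.modality), manifest=manifest)

    plan = plan_tiles(mask, key=key, margin_px=key.margin_px)
    tiles = _select_tiles(plan, n, key.tile_spacing)

    # embed on the output-grid scale: the quantizer and the storage rounding
    # must share one [0, 1] axis, otherwise cell positions are scrambled
    values = (cover.pixels.astype(np.float64) - grid_lo) / (grid_hi - grid_lo)
    for (r, c), block in zip(tiles, msg_blocks.blocks):
        coeffs = dct2(values[r: r + BLOCK, c: c + BLOCK])
        embedded = qun(coeffs, block, key.beta)
        embedded = _condition_block(embedded, key.beta)
        values[r: r + BLOCK, c: c + BLOCK] = idct2(embedded)
    values = np.clip(values, 0.0, 1.0)

    stego = denormalize(
        NormalizedImage(values, norm_min=grid_lo, norm_max=grid_hi),
        bit_depth=out_depth,
        modality=cover.modality,
    )
    manifest["tiles_used"] = len(tiles)
    result = StegoResult(stego=stego, manifest=manifest)

    if verify:
        rx_mask = threshold_mask(stego)
        try:
            recovered = extract(stego, rx_mask, key, (grid_lo, grid_hi))
            sent_bits = msg_blocks.blocks >= 0.5
            got_bits = recovered.blocks >= 0.5
            manifest["verified"] = bool(np.array_equal(sent_bits, got_bits))
        except (TruncationError, CapacityError):
            manifest["verified"] = False
        if not manifest["verified"]:
            warnings.warn(
                "post-embed self-check could not recover the embedded bits; "
                "the receiver's mask may not match the embedding mask",
                VerificationWarning,
                stacklevel=2,
            )
    return result


def extract(
    stego: MedicalImage,
    mask: BinaryMask,
    key: EmbeddingKey,
    manifest_norm: tuple[float, float],
) -> MessageBlocks:
    """Recover the message blocks from a stego image.

    ``mask`` is the receiver's own segmentation of the *stego* image (the
    mask is never transmitted); ``manifest_norm`` is the normalization grid
    recorded at embedding. Returns continuous recovered values - the bit
    decision happens in :func:`ronisteg.payload.unblockify_and_decide`.
    """
    if key.message_shape is None:
        raise ParameterError("extraction key must carry message_shape")
    lo, hi = manifest_norm
    values = (stego.pixels.astype(np.float64) - lo) / (hi - lo)
    n = key.n_blocks
    plan = plan_tiles(mask, key=key, margin_px=key.margin_px)
    try:
        tiles = _select_tiles(plan, n, key.tile_spacing)
    except CapacityError as exc:
        raise TruncationError(
            f"stego mask provides {exc.available} tiles but the message needs {exc.required}"
        ) from exc
    blocks = np.empty((n, BLOCK, BLOCK))
    for i, (r, c) in enumerate(tiles):
        coeffs = dct2(values[r: r + BLOCK, c: c + BLOCK])
        blocks[i] = iqun(coeffs, key.beta)
    return MessageBlocks(blocks=blocks, original_shape=key.message_shape, alpha=key.alpha)
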