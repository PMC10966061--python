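"""Fidelity metrics (MSE / PSNR) and seeded noise-attack simulators.

PSNR uses the peak value R = 2^bit_depth - 1 of the stored data type, so a
16-bit pair with MSE 1 scores 10*log10(65535^2) ~ 96.3 dB. Attacks operate
in integer pixel units and are reproducible from their seed; the
robustness harness embeds, attacks, re-extracts the way a receiver would
(mask recomputed from the attacked image) and reports the message
correlation, bit accuracy and whether the QR still decodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, ParameterError, QRDecodeError
from .image_io import MedicalImage
from .mask import BinaryMask, compute_ncc, threshold_mask
from .payload import MessageBlocks, qr_to_text, unblockify_and_decide
from .stego import EmbeddingKey, embed, extract

__all__ = [
    "MetricsReport",
    "AttackSpec",
    "compute_mse",
    "compute_psnr",
    "apply_attack",
    "robustness_trial",
]


@dataclass
class MetricsReport:
    """One row of the evaluation tables."""

    mse: float
    psnr_db: float
    ncc_mask: float | None = None
    ncc_message: float | None = None
    capacity_bpp: float | None = None
    payload_bpp: float | None = None

    def __post_init__(self) -> None:
        if (self.mse == 0.0) != np.isinf(self.psnr_db):
            raise ValueError("psnr_db must be +inf exactly when mse is 0")


@dataclass
class AttackSpec:
    """A seeded noise attack: gaussian, uniform or salt_pepper.

    params holds ``sigma`` (gaussian std, pixel units), ``half_width``
    (uniform +-bound, pixel units) or ``density`` (fraction of pixels hit
    by salt/pepper).
    """

    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "uniform", "salt_pepper"):
            raise ParameterError(f"unknown attack kind {self.kind!r}")
        d = self.params.get("density", 0.0)
        if not 0.0 <= d <= 1.0:
            raise ParameterError("density must lie in [0, 1]")
        if self.params.get("sigma", 0.0) < 0 or self.params.get("half_width", 0.0) < 0:
            raise ParameterError("sigma and half_width must be >= 0")

    @property
    def strength(self) -> float:
        return float(
            self.params.get("sigma")
            or self.params.get("half_width")
            or self.params.get("density")
            or 0.0
        )


def compute_mse(a: MedicalImage, b: MedicalImage) -> float:
    """Mean squared pixel difference, in integer pixel units."""
    if a.shape != b.shape:
        raise AlignmentError(f"image shapes differ: {a.shape} vs {b.shape}")
    diff = a.pixels.astype(np.float64) - b.pixels.astype(np.float64)
    return float(np.mean(diff * diff))


def compute_psnr(a: MedicalImage, b: MedicalImage) -> float:
    """``10 log10(R^2 / MSE)`` in dB; +inf for identical images."""
    if a.bit_depth != b.bit_depth:
        raise AlignmentError(f"bit depths differ: {a.bit_depth} vs {b.bit_depth}")
    mse = compute_mse(a, b)
    if mse == 0.0:
        return float("inf")
    r = float(a.max_value)
    return float(10.0 * np.log10(r * r / mse))


def apply_attack(img: MedicalImage, spec: AttackSpec) -> MedicalImage:
    """Additive gaussian / uniform noise or salt-and-pepper corruption.

    Output is rounded and clamped back to the valid pixel range; a
    zero-strength attack returns a pixel-identical image.
    """
    rng = np.random.default_rng(spec.seed)
    pix = img.pixels.astype(np.float64)
    if spec.kind == "gaussian":
        sigma = float(spec.params.get("sigma", 0.0))
        if sigma > 0:
            pix = pix + rng.normal(0.0, sigma, img.shape)
    elif spec.kind == "uniform":
        hw = float(spec.params.get("half_width", 0.0))
        if hw > 0:
            pix = pix + rng.uniform(-hw, hw, img.shape)
    else:  # salt_pepper
        density = float(spec.params.get("density", 0.0))
        if density > 0:
            hit = rng.random(img.shape) < density
            salt = rng.random(img.shape) < 0.5
            pix = np.where(hit, np.where(salt, float(img.max_value), 0.0), pix)
    out = np.clip(np.floor(pix + 0.5), 0, img.max_value).astype(np.uint16)
    return MedicalImage(out, bit_depth=img.bit_depth, modality=img.modality)


def robustness_trial(
    cover: MedicalImage,
    mask: BinaryMask,
    message: MessageBlocks,
    key: EmbeddingKey,
    spec: AttackSpec,
) -> dict:
    """Embed, attack the stego image, extract, and score the damage.

    Returns ``ncc_message`` (correlation between the embedded adjusted
    values and the recovered continuous values), ``bit_accuracy``,
    ``psnr_db`` between the cover and the attacked stego, and ``decoded``
    (does the recovered QR still yield the payload text). The receiver's
    mask is recomputed from the attacked image, as in real extraction.
    """
    result = embed(cover, mask, message, key, verify=False)
    attacked = apply_attack(result.stego, spec)
    rx_key = EmbeddingKey(
        beta=key.beta, alpha=key.alpha, message_shape=message.original_shape,
        tile_order_seed=key.tile_order_seed, margin_px=key.margin_px,
        tile_spacing=key.tile_spacing,
    )
    norm = (result.manifest["norm_min"], result.manifest["norm_max"])
    sent_bits = message.blocks >= 0.5
    try:
        recovered = extract(attacked, threshold_mask(attacked), rx_key, norm)
        ncc = compute_ncc(message.blocks.ravel(), recovered.blocks.ravel())
        bit_acc = float(np.mean((recovered.blocks >= 0.5) == sent_bits))
        try:
            qr_to_text(unblockify_and_decide(recovered))
            decoded = True
        except QRDecodeError:
            decoded = False
    except Exception:
        ncc, bit_acc, decoded = 0.0, 0.5, False

    cover16 = cover
    if cover.bit_depth != attacked.bit_depth:
        # widened stego keeps the cover's pixel values in a 16-bit container
        cover16 = MedicalImage(cover.pixels, bit_depth=attacked.bit_depth,
                               modality=cover.modality)
    return {
        "ncc_message": float(ncc),
        "bit_accuracy": bit_acc,
        "psnr_db": compute_psnr(cover16, attacked),
        "decoded": decoded,
        "attack": spec.kind,
        "strength": spec.strength,
        "seed": spec.seed,
    }
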