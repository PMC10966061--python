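"""Payload preparation: QR rendering, the alpha level adjustment, and 4x4
message tiling.

Bits are never embedded as hard 0/1. They are mapped to the two levels
``alpha`` and ``1 - alpha`` (default alpha = 0.02), which keeps every
embedded value strictly inside its quantization cell and leaves a margin of
``alpha * 4/beta`` against rounding before a cell boundary is crossed. The
min-max normalization that precedes the adjustment is the identity on a
{0,1} bitmap, so it is not re-applied here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, ParameterError
from .qr import QRBitmap, qr_to_text, text_to_qr

__all__ = [
    "QRBitmap",
    "AdjustedMessage",
    "MessageBlocks",
    "text_to_qr",
    "qr_to_text",
    "adjust_message",
    "blockify_message",
    "unblockify_and_decide",
    "DEFAULT_ALPHA",
]

DEFAULT_ALPHA = 0.02
BLOCK = 4


@dataclass
class AdjustedMessage:
    """QR bitmap mapped onto the two levels {alpha, 1 - alpha}."""

    values: np.ndarray
    alpha: float

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 0.5:
            raise ParameterError(f"alpha must lie in (0, 0.5), got {self.alpha}")
        vals = np.asarray(self.values, dtype=np.float64)
        levels = np.isclose(vals, self.alpha) | np.isclose(vals, 1.0 - self.alpha)
        if not np.all(levels):
            raise ValueError("adjusted values must all equal alpha or 1 - alpha")
        self.values = vals

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass
class MessageBlocks:
    """Row-major sequence of 4x4 message tiles plus the unpadded shape."""

    blocks: np.ndarray  # (n, 4, 4)
    original_shape: tuple[int, int]
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        arr = np.asarray(self.blocks, dtype=np.float64)
        if arr.ndim != 3 or arr.shape[1:] != (BLOCK, BLOCK):
            raise ValueError(f"blocks must have shape (n, 4, 4), got {arr.shape}")
        rows, cols = self.original_shape
        need = (-(-rows // BLOCK)) * (-(-cols // BLOCK))
        if arr.shape[0] != need:
            raise AlignmentError(
                f"{arr.shape[0]} blocks inconsistent with original shape {self.original_shape} "
                f"(expected {need})"
            )
        self.blocks = arr

    def __len__(self) -> int:
        return int(self.blocks.shape[0])

    @property
    def padded_shape(self) -> tuple[int, int]:
        rows, cols = self.original_shape
        return (-(-rows // BLOCK) * BLOCK, -(-cols // BLOCK) * BLOCK)


def adjust_message(qr: QRBitmap, alpha: float = DEFAULT_ALPHA) -> AdjustedMessage:
    """Map bit 1 to ``1 - alpha`` and bit 0 to ``alpha``."""
    if not 0.0 < alpha < 0.5:
        raise ParameterError(f"alpha must lie in (0, 0.5), got {alpha}")
    values = np.where(qr.bits >= 1, 1.0 - alpha, alpha)
    return AdjustedMessage(values=values, alpha=alpha)


def blockify_message(msg: AdjustedMessage) -> MessageBlocks:
    """Pad to multiples of 4 (with the bit-0 level alpha) and tile row-major."""
    rows, cols = msg.shape
    pr = (-rows) % BLOCK
    pc = (-cols) % BLOCK
    padded = np.pad(msg.values, ((0, pr), (0, pc)), constant_values=msg.alpha)
    nr, nc = padded.shape[0] // BLOCK, padded.shape[1] // BLOCK
    blocks = padded.reshape(nr, BLOCK, nc, BLOCK).swapaxes(1, 2).reshape(-1, BLOCK, BLOCK)
    return MessageBlocks(blocks=blocks, original_shape=(rows, cols), alpha=msg.alpha)


def unblockify_and_decide(blocks: MessageBlocks, module_scale: int = 1) -> QRBitmap:
    """Reassemble tiles row-major, strip padding, and threshold to bits.

    Each recovered real value v becomes bit 1 iff ``v >= 0.5`` — the
    maximum-margin rule between the levels {alpha, 1 - alpha}, with the tie
    at exactly 0.5 resolved to 1.
    """
    prows, pcols = blocks.padded_shape
    nr, nc = prows // BLOCK, pcols // BLOCK
    grid = blocks.blocks.reshape(nr, nc, BLOCK, BLOCK).swapaxes(1, 2).reshape(prows, pcols)
    rows, cols = blocks.original_shape
    bits = (grid[:rows, :cols] >= 0.5).astype(np.uint8)
    return QRBitmap(bits=bits, module_scale=module_scale)
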