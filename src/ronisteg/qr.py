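"""Minimal QR symbol codec: byte mode, versions 1-10, error-correction level M.

The payload pipeline needs QR generation and decoding as plumbing around the
embedding core. This module implements the standard symbol construction
(Reed-Solomon over GF(256) with the 0x11d primitive polynomial, BCH-protected
format information, the usual function patterns and zigzag placement) and a
grid-aligned decoder. The decoder assumes the module grid is axis-aligned and
at a known scale - which extracted bitmaps are - so no finder-pattern
localization is performed; Reed-Solomon correction still repairs modules
flipped by channel noise, up to half the parity budget per block.

Error-correction level M parity (roughly 15% of codewords correctable) is the
only level wired up: it balances payload capacity against the noise attacks
the robustness harness applies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import QRCapacityError, QRDecodeError

__all__ = ["QRBitmap", "text_to_qr", "qr_to_text"]

# ---------------------------------------------------------------------------
# GF(256) arithmetic (primitive polynomial x^8+x^4+x^3+x^2+1 = 0x11d)
# ---------------------------------------------------------------------------

_GF_EXP = np.zeros(512, dtype=np.int64)
_GF_LOG = np.zeros(256, dtype=np.int64)
_x = 1
for _i in range(255):
    _GF_EXP[_i] = _x
    _GF_LOG[_x] = _i
    _x <<= 1
    if _x & 0x100:
        _x ^= 0x11D
for _i in range(255, 512):
    _GF_EXP[_i] = _GF_EXP[_i - 255]


def _gf_mul(a: int, b: int) -> int:
    if a == 0 or b == 0:
        return 0
    return int(_GF_EXP[_GF_LOG[a] + _GF_LOG[b]])


def _gf_div(a: int, b: int) -> int:
    if b == 0:
        raise ZeroDivisionError
    if a == 0:
        return 0
    return int(_GF_EXP[(_GF_LOG[a] - _GF_LOG[b]) % 255])


def _poly_mul(p: list[int], q: list[int]) -> list[int]:
    out = [0] * (len(p) + len(q) - 1)
    for i, pi in enumerate(p):
        if pi:
            for j, qj in enumerate(q):
                out[i + j] ^= _gf_mul(pi, qj)
    return out


def _poly_eval(p: list[int], x: int) -> int:
    """Evaluate polynomial (p[0] = highest-degree coefficient) at x."""
    y = p[0]
    for c in p[1:]:
        y = _gf_mul(y, x) ^ c
    return y


def _rs_generator(nsym: int) -> list[int]:
    g = [1]
    for i in range(nsym):
        g = _poly_mul(g, [1, int(_GF_EXP[i])])
    return g


def _rs_encode(data: list[int], nsym: int) -> list[int]:
    """Systematic RS: returns data + nsym parity bytes."""
    gen = _rs_generator(nsym)
    rem = list(data) + [0] * nsym
    for i in range(len(data)):
        coef = rem[i]
        if coef:
            for j in range(1, len(gen)):
                rem[i + j] ^= _gf_mul(gen[j], coef)
    return list(data) + rem[len(data):]


def _rs_decode(codeword: list[int], nsym: int) -> list[int]:
    """Correct up to nsym//2 byte errors in place; return the data part."""
    msg = list(codeword)
    synd = [_poly_eval(msg, int(_GF_EXP[i])) for i in range(nsym)]
    if max(synd) == 0:
        return msg[:-nsym]

    # Berlekamp-Massey for the error locator polynomial
    err_loc = [1]
    old_loc = [1]
    for i in range(nsym):
        delta = synd[i]
        for j in range(1, len(err_loc)):
            delta ^= _gf_mul(err_loc[-(j + 1)], synd[i - j])
        old_loc.append(0)
        if delta != 0:
            if len(old_loc) > len(err_loc):
                new_loc = [_gf_mul(c, delta) for c in old_loc]
                old_loc = [_gf_div(c, delta) for c in err_loc]
                err_loc = new_loc
            for j in range(len(old_loc)):
                err_loc[-(j + 1)] ^= _gf_mul(delta, old_loc[-(j + 1)])
    while err_loc and err_loc[0] == 0:
        err_loc.pop(0)
    n_err = len(err_loc) - 1
    if n_err * 2 > nsym:
        raise QRDecodeError("too many byte errors for the parity budget")

    # Chien search for error positions
    positions = []
    for i in range(len(msg)):
        if _poly_eval(err_loc, int(_GF_EXP[(255 - i) % 255])) == 0:
            positions.append(len(msg) - 1 - i)
    if len(positions) != n_err:
        raise QRDecodeError("error locator degree does not match its roots")

    # Forney algorithm for magnitudes
    synd_poly = list(reversed(synd))
    err_eval = _poly_mul(synd_poly, err_loc)
    err_eval = err_eval[len(err_eval) - nsym:]
    for pos in positions:
        degree = len(msg) - 1 - pos
        x_i = int(_GF_EXP[degree % 255])
        x_inv = int(_GF_EXP[(255 - degree) % 255])
        # formal derivative of the locator, evaluated at x_inv
        deriv = 0
        x_inv_sq = _gf_mul(x_inv, x_inv)
        coeffs = list(reversed(err_loc))  # coeffs[k] multiplies x^k
        term = 1
        for k in range(1, len(coeffs), 2):
            deriv ^= _gf_mul(coeffs[k], term)
            term = _gf_mul(term, x_inv_sq)
        if deriv == 0:
            raise QRDecodeError("degenerate error locator derivative")
        magnitude = _gf_div(_gf_mul(x_i, _poly_eval(err_eval, x_inv)), deriv)
        msg[pos] ^= magnitude

    if any(_poly_eval(msg, int(_GF_EXP[i])) for i in range(nsym)):
        raise QRDecodeError("Reed-Solomon correction failed to converge")
    return msg[:-nsym]


# ---------------------------------------------------------------------------
# Symbol structure tables (error-correction level M)
# ---------------------------------------------------------------------------

# version -> (ec codewords per block, [(n_blocks, data_codewords_per_block), ...])
_BLOCKS_M: dict[int, tuple[int, list[tuple[int, int]]]] = {
    1: (10, [(1, 16)]),
    2: (16, [(1, 28)]),
    3: (26, [(1, 44)]),
    4: (18, [(2, 32)]),
    5: (24, [(2, 43)]),
    6: (16, [(4, 27)]),
    7: (18, [(4, 31)]),
    8: (22, [(2, 38), (2, 39)]),
    9: (22, [(3, 36), (2, 37)]),
    10: (26, [(4, 43), (1, 44)]),
}

_ALIGNMENT: dict[int, list[int]] = {
    1: [],
    2: [6, 18],
    3: [6, 22],
    4: [6, 26],
    5: [6, 30],
    6: [6, 34],
    7: [6, 22, 38],
    8: [6, 24, 42],
    9: [6, 26, 46],
    10: [6, 28, 50],
}

_EC_LEVEL_BITS_M = 0b00  # level M indicator


def _data_capacity_bytes(version: int) -> int:
    ecc, groups = _BLOCKS_M[version]
    data_cw = sum(n * d for n, d in groups)
    count_bits = 8 if version <= 9 else 16
    return (8 * data_cw - 4 - count_bits) // 8


@dataclass
class QRBitmap:
    """QR symbol as a {0,1} array, 1 = dark module; no quiet zone."""

    bits: np.ndarray
    module_scale: int = 1

    def __post_init__(self) -> None:
        arr = np.asarray(self.bits)
        if arr.ndim != 2:
            raise ValueError("QR bitmap must be 2D")
        if not np.all(np.isin(np.unique(arr), (0, 1))):
            raise ValueError("QR bitmap values must be 0 or 1")
        if self.module_scale < 1:
            raise ValueError("module_scale must be >= 1")
        self.bits = np.ascontiguousarray(arr.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.bits.shape  # type: ignore[return-value]


def _bch_format(data5: int) -> int:
    v = data5 << 10
    for i in range(14, 9, -1):
        if v & (1 << i):
            v ^= 0x537 << (i - 10)
    return ((data5 << 10) | v) ^ 0x5412


def _bch_version(version: int) -> int:
    v = version << 12
    for i in range(17, 11, -1):
        if v & (1 << i):
            v ^= 0x1F25 << (i - 12)
    return (version << 12) | v


def _function_mask(version: int) -> np.ndarray:
    """Boolean map of modules reserved for function patterns/format/version."""
    size = 17 + 4 * version
    fn = np.zeros((size, size), dtype=bool)
    for r0, c0 in ((0, 0), (0, size - 7), (size - 7, 0)):  # finder + separator
        fn[max(r0 - 1, 0): min(r0 + 8, size), max(c0 - 1, 0): min(c0 + 8, size)] = True
    fn[6, :] = True
    fn[:, 6] = True  # timing
    fn[8, :9] = True
    fn[:9, 8] = True  # format copy 1
    fn[8, size - 8:] = True
    fn[size - 8:, 8] = True  # format copy 2 + dark module
    for rc in _ALIGNMENT[version]:
        for cc in _ALIGNMENT[version]:
            on_finder = (rc < 9 and cc < 9) or (rc < 9 and cc > size - 10) or (
                rc > size - 10 and cc < 9
            )
            if not on_finder:
                fn[rc - 2: rc + 3, cc - 2: cc + 3] = True
    if version >= 7:
        fn[size - 11: size - 8, :6] = True
        fn[:6, size - 11: size - 8] = True
    return fn


def _draw_function_patterns(m: np.ndarray, version: int) -> None:
    size = m.shape[0]

    def finder(r0: int, c0: int) -> None:
        m[r0: r0 + 7, c0: c0 + 7] = 1
        m[r0 + 1: r0 + 6, c0 + 1: c0 + 6] = 0
        m[r0 + 2: r0 + 5, c0 + 2: c0 + 5] = 1

    finder(0, 0)
    finder(0, size - 7)
    finder(size - 7, 0)
    for i in range(8, size - 8):
        m[6, i] = m[i, 6] = (i + 1) % 2
    for rc in _ALIGNMENT[version]:
        for cc in _ALIGNMENT[version]:
            on_finder = (rc < 9 and cc < 9) or (rc < 9 and cc > size - 10) or (
                rc > size - 10 and cc < 9
            )
            if on_finder:
                continue
            m[rc - 2: rc + 3, cc - 2: cc + 3] = 1
            m[rc - 1: rc + 2, cc - 1: cc + 2] = 0
            m[rc, cc] = 1
    m[size - 8, 8] = 1  # dark module
    if version >= 7:
        bits = _bch_version(version)
        for i in range(18):
            bit = (bits >> i) & 1
            m[size - 11 + i % 3, i // 3] = bit
            m[i // 3, size - 11 + i % 3] = bit


_FORMAT_POS_1 = [
    (8, 0), (8, 1), (8, 2), (8, 3), (8, 4), (8, 5), (8, 7), (8, 8),
    (7, 8), (5, 8), (4, 8), (3, 8), (2, 8), (1, 8), (0, 8),
]


def _format_positions_2(size: int) -> list[tuple[int, int]]:
    pos = [(size - 1 - i, 8) for i in range(7)]
    pos += [(8, size - 8 + i) for i in range(8)]
    return pos


def _write_format(m: np.ndarray, mask_id: int) -> None:
    size = m.shape[0]
    bits = _bch_format((_EC_LEVEL_BITS_M << 3) | mask_id)
    for i, (r, c) in enumerate(_FORMAT_POS_1):
        m[r, c] = (bits >> i) & 1
    for i, (r, c) in enumerate(_format_positions_2(size)):
        m[r, c] = (bits >> i) & 1


def _data_coords(version: int) -> list[tuple[int, int]]:
    """Module coordinates in placement order (zigzag, bottom-right first)."""
    size = 17 + 4 * version
    fn = _function_mask(version)
    coords: list[tuple[int, int]] = []
    col = size - 1
    upward = True
    while col > 0:
        if col == 6:
            col -= 1
        rows = range(size - 1, -1, -1) if upward else range(size)
        for row in rows:
            for c in (col, col - 1):
                if not fn[row, c]:
                    coords.append((row, c))
        upward = not upward
        col -= 2
    return coords


_MASK_RULES = (
    lambda r, c: (r + c) % 2 == 0,
    lambda r, c: r % 2 == 0,
    lambda r, c: c % 3 == 0,
    lambda r, c: (r + c) % 3 == 0,
    lambda r, c: (r // 2 + c // 3) % 2 == 0,
    lambda r, c: (r * c) % 2 + (r * c) % 3 == 0,
    lambda r, c: ((r * c) % 2 + (r * c) % 3) % 2 == 0,
    lambda r, c: ((r + c) % 2 + (r * c) % 3) % 2 == 0,
)


def _mask_bit(mask_id: int, r: int, c: int) -> int:
    return int(_MASK_RULES[mask_id](r, c))


def _make_codewords(text_bytes: bytes, version: int) -> list[int]:
    ecc, groups = _BLOCKS_M[version]
    data_cw = sum(n * d for n, d in groups)
    count_bits = 8 if version <= 9 else 16
    bits: list[int] = []

    def push(value: int, n: int) -> None:
        for i in range(n - 1, -1, -1):
            bits.append((value >> i) & 1)

    push(0b0100, 4)  # byte mode
    push(len(text_bytes), count_bits)
    for b in text_bytes:
        push(b, 8)
    push(0, min(4, 8 * data_cw - len(bits)))  # terminator
    while len(bits) % 8:
        bits.append(0)
    data = [int("".join(map(str, bits[i: i + 8])), 2) for i in range(0, len(bits), 8)]
    pad = (0xEC, 0x11)
    i = 0
    while len(data) < data_cw:
        data.append(pad[i % 2])
        i += 1

    # split into blocks, RS-encode, interleave
    blocks: list[list[int]] = []
    idx = 0
    for n, d in groups:
        for _ in range(n):
            blocks.append(data[idx: idx + d])
            idx += d
    parities = [_rs_encode(b, ecc)[len(b):] for b in blocks]
    out: list[int] = []
    maxd = max(len(b) for b in blocks)
    for i in range(maxd):
        for b in blocks:
            if i < len(b):
                out.append(b[i])
    for i in range(ecc):
        for p in parities:
            out.append(p[i])
    return out


def text_to_qr(text: str, module_scale: int = 1) -> QRBitmap:
    """Render ``text`` as a QR symbol at ``module_scale`` pixels per module.

    The smallest version (1-10) whose level-M byte-mode capacity fits the
    UTF-8 encoding of ``text`` is chosen automatically.
    """
    if not text:
        raise QRCapacityError("payload text must be non-empty")
    if module_scale < 1:
        raise ValueError("module_scale must be >= 1")
    payload = text.encode("utf-8")
    version = next(
        (v for v in sorted(_BLOCKS_M) if _data_capacity_bytes(v) >= len(payload)), None
    )
    if version is None:
        raise QRCapacityError(
            f"payload of {len(payload)} bytes exceeds the {_data_capacity_bytes(10)}-byte "
            "capacity of version 10 at level M"
        )
    size = 17 + 4 * version
    m = np.zeros((size, size), dtype=np.uint8)
    _draw_function_patterns(m, version)
    mask_id = 0
    _write_format(m, mask_id)
    codewords = _make_codewords(payload, version)
    coords = _data_coords(version)
    bitstream = [(cw >> (7 - i)) & 1 for cw in codewords for i in range(8)]
    bitstream += [0] * (len(coords) - len(bitstream))  # remainder bits
    for (r, c), bit in zip(coords, bitstream):
        m[r, c] = bit ^ _mask_bit(mask_id, r, c)
    if module_scale > 1:
        m = np.kron(m, np.ones((module_scale, module_scale), dtype=np.uint8))
    return QRBitmap(m, module_scale=module_scale)


def _read_format(m: np.ndarray) -> int:
    """Recover the mask id from the two BCH-protected format copies."""
    size = m.shape[0]
    copy1 = sum(int(m[r, c]) << i for i, (r, c) in enumerate(_FORMAT_POS_1))
    copy2 = sum(int(m[r, c]) << i for i, (r, c) in enumerate(_format_positions_2(size)))
    best = None
    for mask_id in range(8):
        for ec_bits in (0b00, 0b01, 0b10, 0b11):
            cand = _bch_format((ec_bits << 3) | mask_id)
            dist = bin(cand ^ copy1).count("1") + bin(cand ^ copy2).count("1")
            if best is None or dist < best[0]:
                best = (dist, ec_bits, mask_id)
    assert best is not None
    _, ec_bits, mask_id = best
    if ec_bits != _EC_LEVEL_BITS_M:
        raise QRDecodeError("format information does not indicate level M")
    return mask_id


def qr_to_text(qr: QRBitmap) -> str:
    """Decode a (possibly noise-corrupted) QR bitmap back to its text.

    Each module is read by majority vote over its ``module_scale`` x
    ``module_scale`` pixel cell; Reed-Solomon correction then repairs
    flipped modules within the level-M parity budget.
    """
    arr = qr.bits
    s = qr.module_scale
    if arr.shape[0] % s or arr.shape[1] % s:
        raise QRDecodeError(f"bitmap shape {arr.shape} is not a multiple of scale {s}")
    if s > 1:
        h, w = arr.shape[0] // s, arr.shape[1] // s
        cells = arr.reshape(h, s, w, s).sum(axis=(1, 3))
        m = (cells * 2 > s * s).astype(np.uint8)
    else:
        m = arr
    if m.shape[0] != m.shape[1] or (m.shape[0] - 17) % 4:
        raise QRDecodeError(f"module grid {m.shape} is not a QR symbol size")
    version = (m.shape[0] - 17) // 4
    if version not in _BLOCKS_M:
        raise QRDecodeError(f"unsupported QR version {version}")
    mask_id = _read_format(m)
    coords = _data_coords(version)
    bits = [int(m[r, c]) ^ _mask_bit(mask_id, r, c) for r, c in coords]
    n_cw = len(bits) // 8
    stream = [int("".join(map(str, bits[i * 8: i * 8 + 8])), 2) for i in range(n_cw)]

    ecc, groups = _BLOCKS_M[version]
    blocks: list[list[int]] = [[] for _ in range(sum(n for n, _ in groups))]
    sizes = [d for n, d in groups for _ in range(n)]
    idx = 0
    maxd = max(sizes)
    for i in range(maxd):
        for b, d in zip(blocks, sizes):
            if i < d:
                b.append(stream[idx])
                idx += 1
    for i in range(ecc):
        for b in blocks:
            b.append(stream[idx])
            idx += 1
    data: list[int] = []
    for b in blocks:
        data.extend(_rs_decode(b, ecc))

    # parse the byte-mode bitstream
    bitpos = 0

    def take(n: int) -> int:
        nonlocal bitpos
        v = 0
        for _ in range(n):
            v = (v << 1) | ((data[bitpos // 8] >> (7 - bitpos % 8)) & 1)
            bitpos += 1
        return v

    mode = take(4)
    if mode != 0b0100:
        raise QRDecodeError(f"expected byte mode, got mode indicator {mode:04b}")
    count = take(8 if version <= 9 else 16)
    if count * 8 > len(data) * 8 - bitpos:
        raise QRDecodeError("declared byte count exceeds the data stream")
    payload = bytes(take(8) for _ in range(count))
    try:
        return payload.decode("utf-8")
    except UnicodeDecodeError as exc:
        raise QRDecodeError("decoded payload is not valid UTF-8") from exc
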