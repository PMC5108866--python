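"""Minimal QR symbology (ISO/IEC 18004): byte-mode encode and matrix decode.

Implements the subset this toolkit needs to carry sequence payloads:
byte-mode segments, Reed-Solomon error-correction codewords over GF(256)
(primitive polynomial 0x11d), the standard error-correction block tables
for versions 1-40 at levels L/M/Q/H, data placement, the eight mask
patterns with penalty-based selection, and format/version information
(BCH-protected).  A matrix-level decoder (format read-back, unmasking,
de-interleaving, Reed-Solomon syndrome verification, bitstream parsing)
provides the independent return path used as the round-trip oracle.

The geometric layout is computed from first principles (finder, timing,
alignment, format and version areas), and the block tables are asserted at
import time to sum exactly to the free-module codeword count of every
version - a structural consistency check between the published tables and
the layout.
"""

from __future__ import annotations

import numpy as np

__all__ = ["QRCodecError", "encode_bytes", "decode_matrix", "choose_version",
           "capacity_bytes", "matrix_size"]


class QRCodecError(ValueError):
    pass


# ---------------------------------------------------------------------------
# GF(256) arithmetic and Reed-Solomon codewords
# ---------------------------------------------------------------------------

_EXP = [0] * 512
_LOG = [0] * 256
_x = 1
for _i in range(255):
    _EXP[_i] = _x
    _LOG[_x] = _i
    _x <<= 1
    if _x & 0x100:
        _x ^= 0x11d
for _i in range(255, 512):
    _EXP[_i] = _EXP[_i - 255]


def _gf_mul(a: int, b: int) -> int:
    if a == 0 or b == 0:
        return 0
    return _EXP[_LOG[a] + _LOG[b]]


_GEN_CACHE: dict[int, list[int]] = {}


def _rs_generator(n_ecc: int) -> list[int]:
    """Generator polynomial prod_i (x + alpha^i), coefficients high->low."""
    if n_ecc not in _GEN_CACHE:
        g = [1]
        for i in range(n_ecc):
            ng = [0] * (len(g) + 1)
            for j, c in enumerate(g):
                ng[j] ^= c
                ng[j + 1] ^= _gf_mul(c, _EXP[i])
            g = ng
        _GEN_CACHE[n_ecc] = g
    return _GEN_CACHE[n_ecc]


def rs_ecc(data: bytes, n_ecc: int) -> bytes:
    """Reed-Solomon error-correction codewords for one block."""
    gen = _rs_generator(n_ecc)
    rem = [0] * (len(gen) - 1)
    for b in data:
        factor = b ^ rem[0]
        rem = rem[1:] + [0]
        if factor:
            lf = _LOG[factor]
            for i in range(len(rem)):
                if gen[i + 1]:
                    rem[i] ^= _EXP[lf + _LOG[gen[i + 1]]]
    return bytes(rem)


def rs_syndromes_ok(codeword: bytes, n_ecc: int) -> bool:
    """True iff all syndromes of (data+ecc) vanish — a valid RS codeword."""
    for i in range(n_ecc):
        s = 0
        for b in codeword:
            s = _gf_mul(s, _EXP[i]) ^ b
        if s != 0:
            return False
    return True


# ---------------------------------------------------------------------------
# Standard tables (ISO/IEC 18004)
# ---------------------------------------------------------------------------

LEVELS = ("L", "M", "Q", "H")
_LEVEL_BITS = {"L": 0b01, "M": 0b00, "Q": 0b11, "H": 0b10}
_BITS_LEVEL = {v: k for k, v in _LEVEL_BITS.items()}

# (ecc codewords per block, ((n_blocks, data_codewords), ...)) per level,
# versions 1..40 in order L, M, Q, H.
_EC_TABLE: dict[int, dict[str, tuple[int, tuple[tuple[int, int], ...]]]] = {}

_EC_RAW = """
1  7 1x19       | 10 1x16       | 13 1x13       | 17 1x9
2  10 1x34      | 16 1x28       | 22 1x22       | 28 1x16
3  15 1x55      | 26 1x44       | 18 2x17       | 22 2x13
4  20 1x80      | 18 2x32       | 26 2x24       | 16 4x9
5  26 1x108     | 24 2x43       | 18 2x15,2x16  | 22 2x11,2x12
6  18 2x68      | 16 4x27       | 24 4x19       | 28 4x15
7  20 2x78      | 18 4x31       | 18 2x14,4x15  | 26 4x13,1x14
8  24 2x97      | 22 2x38,2x39  | 22 4x18,2x19  | 26 4x14,2x15
9  30 2x116     | 22 3x36,2x37  | 20 4x16,4x17  | 24 4x12,4x13
10 18 2x68,2x69 | 26 4x43,1x44  | 24 6x19,2x20  | 28 6x15,2x16
11 20 4x81      | 30 1x50,4x51  | 28 4x22,4x23  | 24 3x12,8x13
12 24 2x92,2x93 | 22 6x36,2x37  | 26 4x20,6x21  | 28 7x14,4x15
13 26 4x107     | 22 8x37,1x38  | 24 8x20,4x21  | 22 12x11,4x12
14 30 3x115,1x116 | 24 4x40,5x41 | 20 11x16,5x17 | 24 11x12,5x13
15 22 5x87,1x88 | 24 5x41,5x42  | 30 5x24,7x25  | 24 11x12,7x13
16 24 5x98,1x99 | 28 7x45,3x46  | 24 15x19,2x20 | 30 3x15,13x16
17 28 1x107,5x108 | 28 10x46,1x47 | 28 1x22,15x23 | 28 2x14,17x15
18 30 5x120,1x121 | 26 9x43,4x44 | 28 17x22,1x23 | 28 2x14,19x15
19 28 3x113,4x114 | 26 3x44,11x45 | 26 17x21,4x22 | 26 9x13,16x14
20 28 3x107,5x108 | 26 3x41,13x42 | 30 15x24,5x25 | 28 15x15,10x16
21 28 4x116,4x117 | 26 17x42     | 28 17x22,6x23 | 30 19x16,6x17
22 28 2x111,7x112 | 28 17x46     | 30 7x24,16x25 | 24 34x13
23 30 4x121,5x122 | 28 4x47,14x48 | 30 11x24,14x25 | 30 16x15,14x16
24 30 6x117,4x118 | 28 6x45,14x46 | 30 11x24,16x25 | 30 30x16,2x17
25 26 8x106,4x107 | 28 8x47,13x48 | 30 7x24,22x25 | 30 22x15,13x16
26 28 10x114,2x115 | 28 19x46,4x47 | 28 28x22,6x23 | 30 33x16,4x17
27 30 8x122,4x123 | 28 22x45,3x46 | 30 8x23,26x24 | 30 12x15,28x16
28 30 3x117,10x118 | 28 3x45,23x46 | 30 4x24,31x25 | 30 11x15,31x16
29 30 7x116,7x117 | 28 21x45,7x46 | 30 1x23,37x24 | 30 19x15,26x16
30 30 5x115,10x116 | 28 19x47,10x48 | 30 15x24,25x25 | 30 23x15,25x16
31 30 13x115,3x116 | 28 2x46,29x47 | 30 42x24,1x25 | 30 23x15,28x16
32 30 17x115    | 28 10x46,23x47 | 30 10x24,35x25 | 30 19x15,35x16
33 30 17x115,1x116 | 28 14x46,21x47 | 30 29x24,19x25 | 30 11x15,46x16
34 30 13x115,6x116 | 28 14x46,23x47 | 30 44x24,7x25 | 30 59x16,1x17
35 30 12x121,7x122 | 28 12x47,26x48 | 30 39x24,14x25 | 30 22x15,41x16
36 30 6x121,14x122 | 28 6x47,34x48 | 30 46x24,10x25 | 30 2x15,64x16
37 30 17x122,4x123 | 28 29x46,14x47 | 30 49x24,10x25 | 30 24x15,46x16
38 30 4x122,18x123 | 28 13x46,32x47 | 30 48x24,14x25 | 30 42x15,32x16
39 30 20x117,4x118 | 28 40x47,7x48 | 30 43x24,22x25 | 30 10x15,67x16
40 30 19x118,6x119 | 28 18x47,31x48 | 30 34x24,34x25 | 30 20x15,61x16
"""

for _line in _EC_RAW.strip().splitlines():
    _head, *_rest = _line.split("|")
    _parts = _head.split()
    _v = int(_parts[0])
    _specs = [" ".join(_parts[1:])] + _rest
    _EC_TABLE[_v] = {}
    for _lvl, _spec in zip(LEVELS, _specs):
        _tok = _spec.split()
        _ec = int(_tok[0])
        _blocks = tuple(
            (int(_b.split("x")[0]), int(_b.split("x")[1]))
            for _b in _tok[1].split(","))
        _EC_TABLE[_v][_lvl] = (_ec, _blocks)

_ALIGNMENT_POS: dict[int, tuple[int, ...]] = {
    1: (), 2: (6, 18), 3: (6, 22), 4: (6, 26), 5: (6, 30), 6: (6, 34),
    7: (6, 22, 38), 8: (6, 24, 42), 9: (6, 26, 46), 10: (6, 28, 50),
    11: (6, 30, 54), 12: (6, 32, 58), 13: (6, 34, 62), 14: (6, 26, 46, 66),
    15: (6, 26, 48, 70), 16: (6, 26, 50, 74), 17: (6, 30, 54, 78),
    18: (6, 30, 56, 82), 19: (6, 30, 58, 86), 20: (6, 34, 62, 90),
    21: (6, 28, 50, 72, 94), 22: (6, 26, 50, 74, 98), 23: (6, 30, 54, 78, 102),
    24: (6, 28, 54, 80, 106), 25: (6, 32, 58, 84, 110),
    26: (6, 30, 58, 86, 114), 27: (6, 34, 62, 90, 118),
    28: (6, 26, 50, 74, 98, 122), 29: (6, 30, 54, 78, 102, 126),
    30: (6, 26, 52, 78, 104, 130), 31: (6, 30, 56, 82, 108, 134),
    32: (6, 34, 60, 86, 112, 138), 33: (6, 30, 58, 86, 114, 142),
    34: (6, 34, 62, 90, 118, 146), 35: (6, 30, 54, 78, 102, 126, 150),
    36: (6, 24, 50, 76, 102, 128, 154), 37: (6, 28, 54, 80, 106, 132, 158),
    38: (6, 32, 58, 84, 110, 136, 162), 39: (6, 26, 54, 82, 110, 138, 166),
    40: (6, 30, 58, 86, 114, 142, 170),
}


def matrix_size(version: int) -> int:
    return 17 + 4 * version


# ---------------------------------------------------------------------------
# Symbol layout
# ---------------------------------------------------------------------------

def _function_map(version: int) -> tuple[np.ndarray, np.ndarray]:
    """(reserved, pattern) — which modules are function modules, and their
    fixed colours (True = dark).  Format/version areas are reserved with
    placeholder colour; the dark module is set."""
    size = matrix_size(version)
    reserved = np.zeros((size, size), dtype=bool)
    pattern = np.zeros((size, size), dtype=bool)

    def finder(r0: int, c0: int) -> None:
        for dr in range(-1, 8):
            for dc in range(-1, 8):
                r, c = r0 + dr, c0 + dc
                if 0 <= r < size and 0 <= c < size:
                    reserved[r, c] = True
                    dark = (0 <= dr <= 6 and 0 <= dc <= 6
                            and (dr in (0, 6) or dc in (0, 6)
                                 or (2 <= dr <= 4 and 2 <= dc <= 4)))
                    pattern[r, c] = dark

    finder(0, 0)
    finder(0, size - 7)
    finder(size - 7, 0)

    for i in range(8, size - 8):  # timing
        for r, c in ((6, i), (i, 6)):
            reserved[r, c] = True
            pattern[r, c] = i % 2 == 0

    pos = _ALIGNMENT_POS[version]
    for r0 in pos:
        for c0 in pos:
            # skip patterns that would overlap the three finders
            if (r0 < 9 and c0 < 9) or (r0 < 9 and c0 > size - 10) or \
               (r0 > size - 10 and c0 < 9):
                continue
            for dr in range(-2, 3):
                for dc in range(-2, 3):
                    r, c = r0 + dr, c0 + dc
                    reserved[r, c] = True
                    pattern[r, c] = max(abs(dr), abs(dc)) != 1

    for r, c in _format_positions(size)[0] + _format_positions(size)[1]:
        reserved[r, c] = True
    reserved[size - 8, 8] = True
    pattern[size - 8, 8] = True  # dark module

    if version >= 7:
        for i in range(18):
            reserved[i // 3, size - 11 + i % 3] = True
            reserved[size - 11 + i % 3, i // 3] = True

    return reserved, pattern


def _format_positions(size: int) -> tuple[list, list]:
    """Module coordinates of the two format-information copies, bit 0 first."""
    copy1 = ([(8, c) for c in range(6)] + [(8, 7), (8, 8), (7, 8)]
             + [(r, 8) for r in range(5, -1, -1)])
    copy2 = ([(size - 1 - i, 8) for i in range(7)]
             + [(8, size - 8 + i) for i in range(8)])
    return copy1, copy2


def _bch_format(data5: int) -> int:
    """15-bit format information: 5 data bits + BCH(15,5), masked."""
    v = data5 << 10
    g = 0b10100110111
    rem = v
    for shift in range(14, 9, -1):
        if rem & (1 << shift):
            rem ^= g << (shift - 10)
    return ((data5 << 10) | rem) ^ 0b101010000010010


def _bch_version(version: int) -> int:
    """18-bit version information: 6 data bits + BCH(18,6)."""
    v = version << 12
    g = 0b1111100100101
    rem = v
    for shift in range(17, 11, -1):
        if rem & (1 << shift):
            rem ^= g << (shift - 12)
    return (version << 12) | rem


def _data_coords(version: int, reserved: np.ndarray) -> list[tuple[int, int]]:
    """Module coordinates in codeword placement order (zigzag from the
    bottom-right, skipping the vertical timing column)."""
    size = matrix_size(version)
    coords: list[tuple[int, int]] = []
    col = size - 1
    upward = True
    while col > 0:
        if col == 6:
            col -= 1
        rows = range(size - 1, -1, -1) if upward else range(size)
        for r in rows:
            for c in (col, col - 1):
                if not reserved[r, c]:
                    coords.append((r, c))
        upward = not upward
        col -= 2
    return coords


def _mask_bit(mask: int, r: int, c: int) -> bool:
    if mask == 0:
        return (r + c) % 2 == 0
    if mask == 1:
        return r % 2 == 0
    if mask == 2:
        return c % 3 == 0
    if mask == 3:
        return (r + c) % 3 == 0
    if mask == 4:
        return (r // 2 + c // 3) % 2 == 0
    if mask == 5:
        return (r * c) % 2 + (r * c) % 3 == 0
    if mask == 6:
        return ((r * c) % 2 + (r * c) % 3) % 2 == 0
    if mask == 7:
        return ((r + c) % 2 + (r * c) % 3) % 2 == 0
    raise QRCodecError(f"invalid mask {mask}")


def _mask_matrix(mask: int, size: int) -> np.ndarray:
    r = np.arange(size)[:, None]
    c = np.arange(size)[None, :]
    if mask == 0:
        m = (r + c) % 2 == 0
    elif mask == 1:
        m = r % 2 == 0
    elif mask == 2:
        m = c % 3 == 0
    elif mask == 3:
        m = (r + c) % 3 == 0
    elif mask == 4:
        m = (r // 2 + c // 3) % 2 == 0
    elif mask == 5:
        m = (r * c) % 2 + (r * c) % 3 == 0
    elif mask == 6:
        m = ((r * c) % 2 + (r * c) % 3) % 2 == 0
    elif mask == 7:
        m = ((r + c) % 2 + (r * c) % 3) % 2 == 0
    else:
        raise QRCodecError(f"invalid mask {mask}")
    return np.broadcast_to(m, (size, size)).copy()


def _penalty(matrix: np.ndarray) -> int:
    """Mask-selection penalty: runs, 2x2 blocks, finder-like patterns,
    dark-module balance (weights 3/3/40/10)."""
    size = matrix.shape[0]
    m = matrix.astype(np.int8)
    score = 0
    for grid in (m, m.T):
        for line in grid:
            bounds = np.flatnonzero(np.diff(line)) + 1
            runs = np.diff(np.concatenate([[0], bounds, [size]]))
            long = runs[runs >= 5]
            score += int((long - 2).sum())  # 3 + (run - 5) per long run
    blocks = (m[:-1, :-1] == m[1:, :-1]) & (m[:-1, :-1] == m[:-1, 1:]) \
        & (m[:-1, :-1] == m[1:, 1:])
    score += 3 * int(blocks.sum())
    pat1 = np.array([1, 0, 1, 1, 1, 0, 1, 0, 0, 0, 0], dtype=np.int8)
    pat2 = pat1[::-1]
    from numpy.lib.stride_tricks import sliding_window_view

    for grid in (m, m.T):
        wins = sliding_window_view(grid, 11, axis=1)
        score += 40 * int(((wins == pat1).all(-1) | (wins == pat2).all(-1)).sum())
    dark_pct = 100.0 * m.sum() / m.size
    score += 10 * int(abs(dark_pct - 50) // 5)
    return score


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

def _block_structure(version: int, level: str):
    ec, blocks = _EC_TABLE[version][level]
    data_lens = [d for n, d in blocks for _ in range(n)]
    return ec, data_lens


def data_codewords(version: int, level: str) -> int:
    _, lens = _block_structure(version, level)
    return sum(lens)


def _count_bits(version: int) -> int:
    return 8 if version <= 9 else 16


def capacity_bytes(version: int, level: str) -> int:
    """Maximum byte-mode payload for one symbol."""
    return (8 * data_codewords(version, level) - 4 - _count_bits(version)) // 8


def choose_version(n_bytes: int, level: str) -> int:
    """Smallest version whose byte-mode capacity fits ``n_bytes``."""
    if level not in LEVELS:
        raise QRCodecError(f"unknown EC level {level!r}")
    for version in range(1, 41):
        if capacity_bytes(version, level) >= n_bytes:
            return version
    raise QRCodecError(
        f"payload of {n_bytes} bytes exceeds version-40 capacity "
        f"({capacity_bytes(40, level)} bytes at level {level})")


def _bitstream(payload: bytes, version: int, level: str) -> bytes:
    """Byte-mode segment + terminator + padding, as data codewords."""
    n_data = data_codewords(version, level)
    bits: list[int] = []

    def push(value: int, width: int) -> None:
        for i in range(width - 1, -1, -1):
            bits.append((value >> i) & 1)

    push(0b0100, 4)
    push(len(payload), _count_bits(version))
    for b in payload:
        push(b, 8)
    total_bits = 8 * n_data
    if len(bits) > total_bits:
        raise QRCodecError("payload too large for chosen version")
    push(0, min(4, total_bits - len(bits)))  # terminator
    while len(bits) % 8:
        bits.append(0)
    out = bytearray()
    for i in range(0, len(bits), 8):
        out.append(int("".join(map(str, bits[i:i + 8])), 2))
    pad = (0xEC, 0x11)
    i = 0
    while len(out) < n_data:
        out.append(pad[i % 2])
        i += 1
    return bytes(out)


def _interleave(data: bytes, version: int, level: str) -> bytes:
    ec, lens = _block_structure(version, level)
    blocks = []
    pos = 0
    for ln in lens:
        blocks.append(data[pos:pos + ln])
        pos += ln
    eccs = [rs_ecc(b, ec) for b in blocks]
    out = bytearray()
    for i in range(max(lens)):
        for b in blocks:
            if i < len(b):
                out.append(b[i])
    for i in range(ec):
        for e in eccs:
            out.append(e[i])
    return bytes(out)


def encode_bytes(payload: bytes, level: str = "L",
                 version: int | None = None,
                 mask: int | None = None) -> tuple[np.ndarray, int, int]:
    """Encode a byte payload into a QR module matrix.

    Returns ``(matrix, version, mask)`` where matrix is a boolean array
    (True = dark).  Deterministic: version is the smallest sufficient one
    and the mask minimises the standard penalty (ties to the lowest id).
    """
    if not payload:
        raise QRCodecError("empty payload")
    if level not in LEVELS:
        raise QRCodecError(f"unknown EC level {level!r}")
    if version is None:
        version = choose_version(len(payload), level)
    elif capacity_bytes(version, level) < len(payload):
        raise QRCodecError(f"payload does not fit version {version} at {level}")

    size = matrix_size(version)
    reserved, pattern = _function_map(version)
    coords = _data_coords(version, reserved)
    codewords = _interleave(_bitstream(payload, version, level), version, level)

    bits = np.zeros(len(coords), dtype=bool)
    for i, byte in enumerate(codewords):
        for j in range(8):
            bits[8 * i + j] = (byte >> (7 - j)) & 1
    # any remainder coordinates stay 0

    base = pattern.copy()
    rows = np.array([rc[0] for rc in coords])
    cols = np.array([rc[1] for rc in coords])

    def fill(mask_id: int) -> np.ndarray:
        mat = base.copy()
        mvals = _mask_matrix(mask_id, size)[rows, cols]
        mat[rows, cols] = bits ^ mvals
        _place_format(mat, size, level, mask_id)
        if version >= 7:
            _place_version(mat, size, version)
        return mat

    if mask is None:
        best = None
        for mask_id in range(8):
            mat = fill(mask_id)
            p = _penalty(mat)
            if best is None or p < best[0]:
                best = (p, mask_id, mat)
        _, mask, matrix = best
    else:
        matrix = fill(mask)
    return matrix, version, mask


def _place_format(mat: np.ndarray, size: int, level: str, mask_id: int) -> None:
    fmt = _bch_format((_LEVEL_BITS[level] << 3) | mask_id)
    copy1, copy2 = _format_positions(size)
    for i, (r, c) in enumerate(copy1):
        mat[r, c] = (fmt >> i) & 1
    for i, (r, c) in enumerate(copy2):
        mat[r, c] = (fmt >> i) & 1
    mat[size - 8, 8] = True


def _place_version(mat: np.ndarray, size: int, version: int) -> None:
    vbits = _bch_version(version)
    for i in range(18):
        bit = (vbits >> i) & 1
        mat[i // 3, size - 11 + i % 3] = bit
        mat[size - 11 + i % 3, i // 3] = bit


# ---------------------------------------------------------------------------
# Decoding (matrix level)
# ---------------------------------------------------------------------------

def decode_matrix(matrix: np.ndarray) -> bytes:
    """Decode a clean module matrix back to its byte payload.

    Verifies the format information's BCH code and every block's
    Reed-Solomon syndromes; raises :class:`QRCodecError` on any mismatch.
    (No error correction is attempted: this is a verification decoder for
    losslessly stored matrices, not a camera pipeline.)
    """
    size = matrix.shape[0]
    if matrix.shape != (size, size) or (size - 17) % 4:
        raise QRCodecError(f"invalid matrix shape {matrix.shape}")
    version = (size - 17) // 4
    if not 1 <= version <= 40:
        raise QRCodecError(f"invalid version {version}")

    copy1, _ = _format_positions(size)
    fmt = 0
    for i, (r, c) in enumerate(copy1):
        fmt |= int(bool(matrix[r, c])) << i
    data5 = (fmt ^ 0b101010000010010) >> 10
    if _bch_format(data5) != fmt:
        raise QRCodecError("format information failed BCH check")
    level = _BITS_LEVEL[data5 >> 3]
    mask_id = data5 & 0b111

    reserved, _ = _function_map(version)
    coords = _data_coords(version, reserved)
    mvals = _mask_matrix(mask_id, size)
    raw_bits = [int(bool(matrix[r, c]) ^ bool(mvals[r, c])) for r, c in coords]

    ec, lens = _block_structure(version, level)
    n_data = sum(lens)
    n_total = n_data + ec * len(lens)
    raw = bytearray()
    for i in range(n_total):
        byte = 0
        for j in range(8):
            byte = (byte << 1) | raw_bits[8 * i + j]
        raw.append(byte)

    # de-interleave
    blocks = [bytearray() for _ in lens]
    pos = 0
    for i in range(max(lens)):
        for bi, ln in enumerate(lens):
            if i < ln:
                blocks[bi].append(raw[pos])
                pos += 1
    eccs = [bytearray() for _ in lens]
    for i in range(ec):
        for bi in range(len(lens)):
            eccs[bi].append(raw[pos])
            pos += 1
    for bi, (blk, ecb) in enumerate(zip(blocks, eccs)):
        if not rs_syndromes_ok(bytes(blk) + bytes(ecb), ec):
            raise QRCodecError(f"Reed-Solomon check failed in block {bi}")

    data = b"".join(bytes(b) for b in blocks)
    bits = []
    for byte in data:
        for j in range(7, -1, -1):
            bits.append((byte >> j) & 1)

    def take(width: int) -> int:
        nonlocal bits
        v = 0
        for b in bits[:width]:
            v = (v << 1) | b
        bits = bits[width:]
        return v

    mode = take(4)
    if mode != 0b0100:
        raise QRCodecError(f"unsupported mode indicator {mode:04b}")
    count = take(_count_bits(version))
    payload = bytes(take(8) for _ in range(count))
    return payload


# ---------------------------------------------------------------------------
# Structural self-check: block tables must tile the free modules exactly
# ---------------------------------------------------------------------------

def _free_codewords(version: int) -> int:
    reserved, _ = _function_map(version)
    return int((~reserved).sum()) // 8


for _v in range(1, 41):
    _free = _free_codewords(_v)
    for _lvl in LEVELS:
        _ec, _lens = _block_structure(_v, _lvl)
        _total = sum(_lens) + _ec * len(_lens)
        if _total != _free:
            raise AssertionError(
                f"EC table inconsistent at version {_v} level {_lvl}: "
                f"{_total} codewords vs {_free} free")
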