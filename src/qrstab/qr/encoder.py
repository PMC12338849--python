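"""QR model 2 symbol construction: byte-mode bitstream, block interleaving,
matrix placement and mask selection.

The matrix is a numpy boolean array, True = dark module. Format information
uses the convention that the least-significant bit of the 15-bit string sits
at (row 8, col 0) in the first copy; encoder and decoder in this package
share the convention.
"""

from __future__ import annotations

import numpy as np

from ..errors import CapacityExceededError, RangeError
from . import tables
from .gf256 import rs_encode

_PAD_BYTES = (0xEC, 0x11)


def make_bitstream(payload: bytes, version: int, ec: str) -> bytes:
    """Byte-mode segment + terminator + padding, as full data codewords."""
    capacity = tables.byte_mode_capacity(version, ec)
    if len(payload) > capacity:
        raise CapacityExceededError(
            f"{len(payload)} bytes exceed version {version}-{ec} "
            f"byte-mode capacity {capacity}")
    length_bits = 8 if version <= 9 else 16
    bits: list[int] = []

    def put(value: int, n: int) -> None:
        for k in range(n - 1, -1, -1):
            bits.append((value >> k) & 1)

    put(0b0100, 4)
    put(len(payload), length_bits)
    for b in payload:
        put(b, 8)
    total_bits = tables.data_codewords(version, ec) * 8
    put(0, min(4, total_bits - len(bits)))          # terminator
    while len(bits) % 8:
        bits.append(0)
    out = bytearray()
    for i in range(0, len(bits), 8):
        out.append(int("".join(map(str, bits[i: i + 8])), 2))
    i = 0
    while len(out) < total_bits // 8:
        out.append(_PAD_BYTES[i % 2])
        i += 1
    return bytes(out)


def interleave(data: bytes, version: int, ec: str) -> bytes:
    """Split data codewords into RS blocks and interleave data then parity."""
    structure = tables.block_structure(version, ec)
    blocks = []
    pos = 0
    for dlen, eclen in structure:
        chunk = data[pos: pos + dlen]
        pos += dlen
        blocks.append((chunk, rs_encode(chunk, eclen)))
    out = bytearray()
    max_d = max(dlen for dlen, _ in structure)
    for i in range(max_d):
        for chunk, _ in blocks:
            if i < len(chunk):
                out.append(chunk[i])
    max_e = max(eclen for _, eclen in structure)
    for i in range(max_e):
        for _, parity in blocks:
            if i < len(parity):
                out.append(parity[i])
    return bytes(out)


# ---------------------------------------------------------------------------
# matrix construction
# ---------------------------------------------------------------------------

def function_patterns(version: int) -> tuple[np.ndarray, np.ndarray]:
    """(matrix, reserved): function modules drawn, reserved = non-data area."""
    n = tables.modules(version)
    m = np.zeros((n, n), dtype=bool)
    reserved = np.zeros((n, n), dtype=bool)

    def finder(r0: int, c0: int) -> None:
        for dr in range(-1, 8):
            for dc in range(-1, 8):
                r, c = r0 + dr, c0 + dc
                if not (0 <= r < n and 0 <= c < n):
                    continue
                reserved[r, c] = True
                in_outer = 0 <= dr <= 6 and 0 <= dc <= 6
                on_ring = dr in (0, 6) or dc in (0, 6)
                in_core = 2 <= dr <= 4 and 2 <= dc <= 4
                m[r, c] = in_outer and (on_ring or in_core)

    finder(0, 0)
    finder(0, n - 7)
    finder(n - 7, 0)

    # timing patterns
    for k in range(8, n - 8):
        dark = k % 2 == 0
        m[6, k] = dark
        m[k, 6] = dark
        reserved[6, k] = True
        reserved[k, 6] = True

    # alignment patterns
    coords = tables.ALIGNMENT_POSITIONS[version]
    for r in coords:
        for c in coords:
            if tables._alignment_in_finder(r, c, n):
                continue
            for dr in range(-2, 3):
                for dc in range(-2, 3):
                    reserved[r + dr, c + dc] = True
                    m[r + dr, c + dc] = (max(abs(dr), abs(dc)) != 1)

    # format information areas + dark module
    for r, c in _format_positions(n)[0] + _format_positions(n)[1]:
        reserved[r, c] = True
    m[n - 8, 8] = True
    reserved[n - 8, 8] = True

    # version information areas
    if version >= 7:
        for i in range(18):
            reserved[n - 11 + i % 3, i // 3] = True
            reserved[i // 3, n - 11 + i % 3] = True
    return m, reserved


def _format_positions(n: int):
    """Module coordinates of the two format-info copies, LSB first."""
    copy1 = [(8, 0), (8, 1), (8, 2), (8, 3), (8, 4), (8, 5), (8, 7), (8, 8),
             (7, 8), (5, 8), (4, 8), (3, 8), (2, 8), (1, 8), (0, 8)]
    copy2 = [(n - 1, 8), (n - 2, 8), (n - 3, 8), (n - 4, 8), (n - 5, 8),
             (n - 6, 8), (n - 7, 8),
             (8, n - 8), (8, n - 7), (8, n - 6), (8, n - 5), (8, n - 4),
             (8, n - 3), (8, n - 2), (8, n - 1)]
    return copy1, copy2


def placement_order(version: int, reserved: np.ndarray) -> list[tuple[int, int]]:
    """Zigzag module order for data bits: column pairs right to left."""
    n = tables.modules(version)
    order = []
    col = n - 1
    upward = True
    while col > 0:
        if col == 6:  # timing column is skipped entirely
            col -= 1
        rows = range(n - 1, -1, -1) if upward else range(n)
        for r in rows:
            for c in (col, col - 1):
                if not reserved[r, c]:
                    order.append((r, c))
        upward = not upward
        col -= 2
    return order


def place_data(matrix: np.ndarray, order: list[tuple[int, int]],
               codewords: bytes, version: int) -> None:
    bits = []
    for b in codewords:
        for k in range(7, -1, -1):
            bits.append((b >> k) & 1)
    bits += [0] * tables.remainder_bits(version)
    if len(bits) != len(order):
        raise RangeError(
            f"bitstream of {len(bits)} bits does not fill the "
            f"{len(order)} data modules of version {version}")
    for (r, c), bit in zip(order, bits):
        matrix[r, c] = bool(bit)


def apply_mask(matrix: np.ndarray, reserved: np.ndarray, mask: int) -> np.ndarray:
    n = matrix.shape[0]
    i, j = np.mgrid[0:n, 0:n]
    cond = _mask_array(mask, i, j)
    out = matrix.copy()
    flip = cond & ~reserved
    out[flip] = ~out[flip]
    return out


def _mask_array(mask: int, i: np.ndarray, j: np.ndarray) -> np.ndarray:
    if mask == 0:
        return (i + j) % 2 == 0
    if mask == 1:
        return i % 2 == 0
    if mask == 2:
        return j % 3 == 0
    if mask == 3:
        return (i + j) % 3 == 0
    if mask == 4:
        return (i // 2 + j // 3) % 2 == 0
    if mask == 5:
        return (i * j) % 2 + (i * j) % 3 == 0
    if mask == 6:
        return ((i * j) % 2 + (i * j) % 3) % 2 == 0
    if mask == 7:
        return ((i + j) % 2 + (i * j) % 3) % 2 == 0
    raise RangeError(f"mask pattern {mask} outside [0, 7]")


def write_format(matrix: np.ndarray, ec: str, mask: int) -> None:
    n = matrix.shape[0]
    fmt = tables.format_bits(ec, mask)
    copy1, copy2 = _format_positions(n)
    for bit_index in range(15):
        bit = bool((fmt >> bit_index) & 1)
        matrix[copy1[bit_index]] = bit
        matrix[copy2[bit_index]] = bit


def write_version_info(matrix: np.ndarray, version: int) -> None:
    if version < 7:
        return
    n = matrix.shape[0]
    vbits = tables.version_bits(version)
    for i in range(18):
        bit = bool((vbits >> i) & 1)
        matrix[n - 11 + i % 3, i // 3] = bit
        matrix[i // 3, n - 11 + i % 3] = bit


_FINDER_RUN_A = np.array([1, 0, 1, 1, 1, 0, 1, 0, 0, 0, 0], dtype=bool)
_FINDER_RUN_B = _FINDER_RUN_A[::-1].copy()


def _run_penalty(grid: np.ndarray) -> int:
    """Rule 1 along rows: 3 points per run of 5, +1 per extra module."""
    score = 0
    for row in grid:
        change = np.flatnonzero(row[1:] != row[:-1])
        runs = np.diff(np.concatenate(([0], change + 1, [len(row)])))
        long = runs[runs >= 5]
        score += int((long - 2).sum())
    return score


def penalty_score(matrix: np.ndarray) -> int:
    """The four standard mask-evaluation penalties."""
    n = matrix.shape[0]
    score = _run_penalty(matrix) + _run_penalty(matrix.T)
    # rule 2: 2x2 blocks of one colour
    blocks = (matrix[:-1, :-1] == matrix[1:, :-1]) & \
             (matrix[:-1, :-1] == matrix[:-1, 1:]) & \
             (matrix[:-1, :-1] == matrix[1:, 1:])
    score += 3 * int(blocks.sum())
    # rule 3: finder-like 1011101 run flanked by 4 light modules
    for grid in (matrix, matrix.T):
        windows = np.lib.stride_tricks.sliding_window_view(grid, 11, axis=1)
        hits = (windows == _FINDER_RUN_A).all(-1).sum() \
            + (windows == _FINDER_RUN_B).all(-1).sum()
        score += 40 * int(hits)
    # rule 4: dark-module proportion deviation from 50%
    dark_pct = 100.0 * matrix.sum() / (n * n)
    score += 10 * int(abs(dark_pct - 50) // 5)
    return score


def encode_matrix(payload: bytes, version: int, ec: str = "L",
                  mask: int | None = None) -> np.ndarray:
    """Full pipeline from payload bytes to a finished module matrix."""
    codewords = interleave(make_bitstream(payload, version, ec), version, ec)
    base, reserved = function_patterns(version)
    order = placement_order(version, reserved)
    place_data(base, order, codewords, version)
    if mask is None:
        best = None
        for candidate in range(8):
            masked = apply_mask(base, reserved, candidate)
            write_format(masked, ec, candidate)
            write_version_info(masked, version)
            score = penalty_score(masked)
            if best is None or score < best[0]:
                best = (score, masked)
        return best[1]
    masked = apply_mask(base, reserved, mask)
    write_format(masked, ec, mask)
    write_version_info(masked, version)
    return masked
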