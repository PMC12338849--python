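"""Constant tables for QR model 2 symbols (versions 1-40).

Sourced from the public QR specification: per-version error-correction
block structure, alignment-pattern centre coordinates, and the BCH-protected
format/version information strings. Data codeword splits follow the
standard rule: with D data codewords in B blocks, the first
``B - D mod B`` blocks carry ``floor(D/B)`` codewords and the rest one more.
"""

from __future__ import annotations

from ..errors import RangeError

EC_LEVELS = ("L", "M", "Q", "H")

#: format-information EC-level indicator bits
EC_LEVEL_BITS = {"L": 0b01, "M": 0b00, "Q": 0b11, "H": 0b10}

#: (ec_codewords_per_block, number_of_blocks) for levels L, M, Q, H
EC_BLOCKS: dict[int, dict[str, tuple[int, int]]] = {
    1:  {"L": (7, 1),   "M": (10, 1),  "Q": (13, 1),  "H": (17, 1)},
    2:  {"L": (10, 1),  "M": (16, 1),  "Q": (22, 1),  "H": (28, 1)},
    3:  {"L": (15, 1),  "M": (26, 1),  "Q": (18, 2),  "H": (22, 2)},
    4:  {"L": (20, 1),  "M": (18, 2),  "Q": (26, 2),  "H": (16, 4)},
    5:  {"L": (26, 1),  "M": (24, 2),  "Q": (18, 4),  "H": (22, 4)},
    6:  {"L": (18, 2),  "M": (16, 4),  "Q": (24, 4),  "H": (28, 4)},
    7:  {"L": (20, 2),  "M": (18, 4),  "Q": (18, 6),  "H": (26, 5)},
    8:  {"L": (24, 2),  "M": (22, 4),  "Q": (22, 6),  "H": (26, 6)},
    9:  {"L": (30, 2),  "M": (22, 5),  "Q": (20, 8),  "H": (24, 8)},
    10: {"L": (18, 4),  "M": (26, 5),  "Q": (24, 8),  "H": (28, 8)},
    11: {"L": (20, 4),  "M": (30, 5),  "Q": (28, 8),  "H": (24, 11)},
    12: {"L": (24, 4),  "M": (22, 8),  "Q": (26, 10), "H": (28, 11)},
    13: {"L": (26, 4),  "M": (22, 9),  "Q": (24, 12), "H": (22, 16)},
    14: {"L": (30, 4),  "M": (24, 9),  "Q": (20, 16), "H": (24, 16)},
    15: {"L": (22, 6),  "M": (24, 10), "Q": (30, 12), "H": (24, 18)},
    16: {"L": (24, 6),  "M": (28, 10), "Q": (24, 17), "H": (30, 16)},
    17: {"L": (28, 6),  "M": (28, 11), "Q": (28, 16), "H": (28, 19)},
    18: {"L": (30, 6),  "M": (26, 13), "Q": (28, 18), "H": (28, 21)},
    19: {"L": (28, 7),  "M": (26, 14), "Q": (26, 21), "H": (26, 25)},
    20: {"L": (28, 8),  "M": (26, 16), "Q": (30, 20), "H": (28, 25)},
    21: {"L": (28, 8),  "M": (26, 17), "Q": (28, 23), "H": (30, 25)},
    22: {"L": (28, 9),  "M": (28, 17), "Q": (30, 23), "H": (24, 34)},
    23: {"L": (30, 9),  "M": (28, 18), "Q": (30, 25), "H": (30, 30)},
    24: {"L": (30, 10), "M": (28, 20), "Q": (30, 27), "H": (30, 32)},
    25: {"L": (26, 12), "M": (28, 21), "Q": (30, 29), "H": (30, 35)},
    26: {"L": (28, 12), "M": (28, 23), "Q": (28, 34), "H": (30, 37)},
    27: {"L": (30, 12), "M": (28, 25), "Q": (30, 34), "H": (30, 40)},
    28: {"L": (30, 13), "M": (28, 26), "Q": (30, 35), "H": (30, 42)},
    29: {"L": (30, 14), "M": (28, 28), "Q": (30, 38), "H": (30, 45)},
    30: {"L": (30, 15), "M": (28, 29), "Q": (30, 40), "H": (30, 48)},
    31: {"L": (30, 16), "M": (28, 31), "Q": (30, 43), "H": (30, 51)},
    32: {"L": (30, 17), "M": (28, 33), "Q": (30, 45), "H": (30, 54)},
    33: {"L": (30, 18), "M": (28, 35), "Q": (30, 48), "H": (30, 57)},
    34: {"L": (30, 19), "M": (28, 37), "Q": (30, 51), "H": (30, 60)},
    35: {"L": (30, 19), "M": (28, 38), "Q": (30, 53), "H": (30, 63)},
    36: {"L": (30, 20), "M": (28, 40), "Q": (30, 56), "H": (30, 66)},
    37: {"L": (30, 21), "M": (28, 43), "Q": (30, 59), "H": (30, 70)},
    38: {"L": (30, 22), "M": (28, 45), "Q": (30, 62), "H": (30, 74)},
    39: {"L": (30, 24), "M": (28, 47), "Q": (30, 65), "H": (30, 77)},
    40: {"L": (30, 25), "M": (28, 49), "Q": (30, 68), "H": (30, 81)},
}

#: alignment-pattern centre coordinates per version (both axes)
ALIGNMENT_POSITIONS: dict[int, tuple[int, ...]] = {
    1: (),
    2: (6, 18), 3: (6, 22), 4: (6, 26), 5: (6, 30), 6: (6, 34),
    7: (6, 22, 38), 8: (6, 24, 42), 9: (6, 26, 46), 10: (6, 28, 50),
    11: (6, 30, 54), 12: (6, 32, 58), 13: (6, 34, 62),
    14: (6, 26, 46, 66), 15: (6, 26, 48, 70), 16: (6, 26, 50, 74),
    17: (6, 30, 54, 78), 18: (6, 30, 56, 82), 19: (6, 30, 58, 86),
    20: (6, 34, 62, 90),
    21: (6, 28, 50, 72, 94), 22: (6, 26, 50, 74, 98),
    23: (6, 30, 54, 78, 102), 24: (6, 28, 54, 80, 106),
    25: (6, 32, 58, 84, 110), 26: (6, 30, 58, 86, 114),
    27: (6, 34, 62, 90, 118),
    28: (6, 26, 50, 74, 98, 122), 29: (6, 30, 54, 78, 102, 126),
    30: (6, 26, 52, 78, 104, 130), 31: (6, 30, 56, 82, 108, 134),
    32: (6, 34, 60, 86, 112, 138), 33: (6, 30, 58, 86, 114, 142),
    34: (6, 34, 62, 90, 118, 146),
    35: (6, 30, 54, 78, 102, 126, 150), 36: (6, 24, 50, 76, 102, 128, 154),
    37: (6, 28, 54, 80, 106, 132, 158), 38: (6, 32, 58, 84, 110, 136, 162),
    39: (6, 26, 54, 82, 110, 138, 166), 40: (6, 30, 58, 86, 114, 142, 170),
}


def modules(version: int) -> int:
    """Symbol side length in modules: 17 + 4 x version."""
    _check_version(version)
    return 17 + 4 * version


def _check_version(version: int) -> None:
    if not isinstance(version, int) or not 1 <= version <= 40:
        raise RangeError(f"QR version {version} outside [1, 40]")


def total_codewords(version: int) -> int:
    """Total (data + EC) codewords, derived from the module layout."""
    _check_version(version)
    return _free_module_count(version) // 8


def remainder_bits(version: int) -> int:
    _check_version(version)
    return _free_module_count(version) % 8


def _free_module_count(version: int) -> int:
    n = modules(version)
    total = n * n
    # finder patterns + separators: three 8x8 corners
    total -= 3 * 64
    # format information: 15 modules twice, plus the dark module
    total -= 31
    # version information for versions >= 7: two 6x3 areas
    if version >= 7:
        total -= 36
    # timing patterns, excluding modules under finders/separators
    total -= 2 * (n - 16)
    # alignment patterns: 5x5 each, discounting timing overlap
    coords = ALIGNMENT_POSITIONS[version]
    count = 0
    overlap_timing = 0
    for r in coords:
        for c in coords:
            if _alignment_in_finder(r, c, n):
                continue
            count += 1
            if r == 6 or c == 6:
                overlap_timing += 1
    total -= 25 * count
    total += 5 * overlap_timing  # timing modules already subtracted
    return total


def _alignment_in_finder(r: int, c: int, n: int) -> bool:
    return ((r < 9 and c < 9) or (r < 9 and c > n - 10)
            or (r > n - 10 and c < 9))


def data_codewords(version: int, ec: str) -> int:
    """Data codewords available at this version and EC level."""
    _check_version(version)
    if ec not in EC_LEVELS:
        raise RangeError(f"EC level {ec!r} not one of {EC_LEVELS}")
    ec_per_block, blocks = EC_BLOCKS[version][ec]
    return total_codewords(version) - ec_per_block * blocks


def block_structure(version: int, ec: str) -> list[tuple[int, int]]:
    """Per-block (data_codewords, ec_codewords), short blocks first."""
    ec_per_block, blocks = EC_BLOCKS[version][ec]
    d = data_codewords(version, ec)
    short_len = d // blocks
    n_long = d % blocks
    out = [(short_len, ec_per_block)] * (blocks - n_long)
    out += [(short_len + 1, ec_per_block)] * n_long
    return out


def byte_mode_capacity(version: int, ec: str) -> int:
    """Maximum byte-mode payload: data bits minus mode and length overhead."""
    bits = data_codewords(version, ec) * 8
    length_bits = 8 if version <= 9 else 16
    return (bits - 4 - length_bits) // 8


# ---------------------------------------------------------------------------
# BCH-protected format / version information
# ---------------------------------------------------------------------------

_FORMAT_GEN = 0b10100110111
_FORMAT_MASK = 0b101010000010010
_VERSION_GEN = 0b1111100100101


def _poly_mod(value: int, generator: int) -> int:
    gen_bits = generator.bit_length()
    while value.bit_length() >= gen_bits:
        value ^= generator << (value.bit_length() - gen_bits)
    return value


def format_bits(ec: str, mask: int) -> int:
    """The masked 15-bit format information string."""
    if not 0 <= mask <= 7:
        raise RangeError(f"mask pattern {mask} outside [0, 7]")
    data = (EC_LEVEL_BITS[ec] << 3) | mask
    value = (data << 10) | _poly_mod(data << 10, _FORMAT_GEN)
    return value ^ _FORMAT_MASK


def decode_format_bits(bits: int) -> tuple[str, int]:
    """Recover (ec_level, mask) from 15 format bits; exact match required."""
    unmasked = bits ^ _FORMAT_MASK
    if _poly_mod(unmasked, _FORMAT_GEN) != 0:
        raise RangeError(f"format information BCH check failed: {bits:015b}")
    data = unmasked >> 10
    mask = data & 0b111
    level_bits = data >> 3
    for level, lb in EC_LEVEL_BITS.items():
        if lb == level_bits:
            return level, mask
    raise RangeError("unreachable: all 2-bit level codes are assigned")


def version_bits(version: int) -> int:
    """The 18-bit version information string (versions >= 7)."""
    if version < 7:
        raise RangeError("version information only exists for versions >= 7")
    return (version << 12) | _poly_mod(version << 12, _VERSION_GEN)
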