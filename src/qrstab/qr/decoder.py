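"""QR symbol reading: from a rasterized image back to payload bytes.

The reader targets clean, axis-aligned renderings (screen captures and
scanned prints of this package's own output): it binarizes the image,
locates the symbol bounding box, estimates the module pitch from the
top-left finder pattern, samples module centres, then reverses the
encoder's pipeline — format decode, unmask, deinterleave, Reed-Solomon
correction and byte-mode parsing. Perspective-distorted camera captures
are out of scope.
"""

from __future__ import annotations

import numpy as np

from ..errors import ScanError
from . import tables
from .encoder import _mask_array, _format_positions, function_patterns, \
    placement_order
from .gf256 import rs_decode


def matrix_from_image(img) -> np.ndarray:
    """Binarize + resample a PIL image or 2-D array into a module matrix."""
    arr = np.asarray(img.convert("L") if hasattr(img, "convert") else img,
                     dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise ScanError("expected a non-empty 2-D grayscale image")
    dark = arr < (arr.min() + arr.max()) / 2.0
    rows = np.flatnonzero(dark.any(axis=1))
    cols = np.flatnonzero(dark.any(axis=0))
    if rows.size == 0:
        raise ScanError("no dark modules found in image")
    box = dark[rows[0]: rows[-1] + 1, cols[0]: cols[-1] + 1]
    h, w = box.shape

    # module pitch from the top-left finder: its outer ring spans 7 modules
    top_run = np.flatnonzero(~box[0])
    run_px = top_run[0] if top_run.size else w
    pitch = run_px / 7.0
    if pitch < 1:
        raise ScanError("image resolution below one pixel per module")
    n = int(round(w / pitch))
    if n != round(h / pitch) or (n - 17) % 4 or not 21 <= n <= 177:
        raise ScanError(f"implausible module count {n}")
    centers = ((np.arange(n) + 0.5) * (w / n)).astype(int)
    sampled = box[np.clip(centers, 0, h - 1)][:, np.clip(centers, 0, w - 1)]
    return sampled


def decode_matrix(matrix: np.ndarray) -> bytes:
    """Recover the byte-mode payload from a sampled module matrix."""
    n = matrix.shape[0]
    version = (n - 17) // 4
    if not 1 <= version <= 40 or tables.modules(version) != n:
        raise ScanError(f"matrix side {n} is not a QR symbol size")

    copy1, copy2 = _format_positions(n)
    ec = mask = None
    for positions in (copy1, copy2):
        bits = 0
        for i, pos in enumerate(positions):
            bits |= int(bool(matrix[pos])) << i
        try:
            ec, mask = tables.decode_format_bits(bits)
            break
        except Exception:
            continue
    if ec is None:
        raise ScanError("format information unreadable in both copies")

    _, reserved = function_patterns(version)
    i, j = np.mgrid[0:n, 0:n]
    unmasked = matrix ^ (_mask_array(mask, i, j) & ~reserved)

    order = placement_order(version, reserved)
    bits = [int(unmasked[pos]) for pos in order]
    usable = (len(bits) // 8) * 8
    codewords = bytes(
        int("".join(map(str, bits[k: k + 8])), 2) for k in range(0, usable, 8))

    data = _deinterleave_and_correct(codewords, version, ec)
    return _parse_bitstream(data, version)


def _deinterleave_and_correct(codewords: bytes, version: int, ec: str) -> bytes:
    structure = tables.block_structure(version, ec)
    n_blocks = len(structure)
    data_lens = [d for d, _ in structure]
    ec_lens = [e for _, e in structure]
    blocks_data: list[list[int]] = [[] for _ in range(n_blocks)]
    blocks_ec: list[list[int]] = [[] for _ in range(n_blocks)]
    pos = 0
    for i in range(max(data_lens)):
        for b in range(n_blocks):
            if i < data_lens[b]:
                blocks_data[b].append(codewords[pos])
                pos += 1
    for i in range(max(ec_lens)):
        for b in range(n_blocks):
            if i < ec_lens[b]:
                blocks_ec[b].append(codewords[pos])
                pos += 1
    out = bytearray()
    for b in range(n_blocks):
        codeword = bytes(blocks_data[b] + blocks_ec[b])
        try:
            out += rs_decode(codeword, ec_lens[b])
        except ValueError as exc:
            raise ScanError(f"block {b} uncorrectable: {exc}") from exc
    return bytes(out)


def _parse_bitstream(data: bytes, version: int) -> bytes:
    length_bits = 8 if version <= 9 else 16
    bits = []
    for b in data:
        for k in range(7, -1, -1):
            bits.append((b >> k) & 1)

    def take(n: int) -> int:
        nonlocal pos
        if pos + n > len(bits):
            raise ScanError("bitstream truncated")
        v = 0
        for k in range(n):
            v = (v << 1) | bits[pos + k]
        pos += n
        return v

    pos = 0
    payload = bytearray()
    while pos + 4 <= len(bits):
        mode = take(4)
        if mode == 0:  # terminator
            break
        if mode != 0b0100:
            raise ScanError(f"unsupported segment mode {mode:04b}")
        count = take(length_bits)
        for _ in range(count):
            payload.append(take(8))
    return bytes(payload)


def read_payload(img) -> bytes:
    """Image straight to payload bytes."""
    return decode_matrix(matrix_from_image(img))
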