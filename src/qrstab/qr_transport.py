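"""Packet splitting, QR rendering/reading, and print-geometry arithmetic.

A transmission's ciphertext is sliced into subpackets of
``capacity - 6`` bytes (6 bytes of header must fit inside every symbol),
each rendered as one QR symbol. The default configuration is a version 25
symbol (117x117 modules) at error-correction level L — 1273 bytes of
byte-mode capacity — printed at 4 pixels per module and 200 dpi with a
4-module quiet zone: a theoretical edge of 2.5 inches, grown to about
3 x 3 inches (7.62 cm) once the 20% print-tolerance redundancy is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np

from .errors import RangeError, ScanError
from .protocol import HEADER_LEN, MessageHeader, QRPacket, chunk_body
from .qr import decoder as _qr_decoder
from .qr import encoder as _qr_encoder
from .qr import tables as _qr_tables

__all__ = [
    "QRConfig",
    "qr_modules",
    "qr_capacity",
    "print_edge_inches",
    "print_edge_cm",
    "split_body",
    "merge_packets",
    "render_qr",
    "read_qr",
]


@dataclass(frozen=True)
class QRConfig:
    """Symbol and print geometry for one transmission."""

    version: int = 25
    ec_level: str = "L"
    module_px: int = 4
    dpi: int = 200
    quiet_zone: int = 4
    redundancy: float = 0.20
    mask: int | None = None  # None = choose by penalty score

    def __post_init__(self):
        _qr_tables.modules(self.version)  # validates the range
        if self.ec_level not in _qr_tables.EC_LEVELS:
            raise RangeError(f"ec_level {self.ec_level!r} not in L/M/Q/H")
        if self.module_px < 1:
            raise RangeError("module_px must be >= 1")

    @property
    def capacity(self) -> int:
        return qr_capacity(self.version, self.ec_level)


def qr_modules(version: int) -> int:
    """Modules per side: 17 + 4 x version (117 for version 25)."""
    return _qr_tables.modules(version)


def qr_capacity(version: int, ec: str = "L") -> int:
    """Byte-mode capacity in bytes (1273 for version 25 at level L)."""
    return _qr_tables.byte_mode_capacity(version, ec)


def print_edge_inches(cfg: QRConfig, with_redundancy: bool = False) -> float:
    """Printed edge length: (modules + 2 x quiet zone) x pixel pitch / dpi."""
    edge = (qr_modules(cfg.version) + 2 * cfg.quiet_zone) * cfg.module_px / cfg.dpi
    if with_redundancy:
        edge *= 1.0 + cfg.redundancy
    return edge


def print_edge_cm(cfg: QRConfig, with_redundancy: bool = False) -> float:
    return print_edge_inches(cfg, with_redundancy) * 2.54


def split_body(cipher: bytes, cfg: QRConfig, version: int, transaction: int,
               fingerprint_fn: Callable[[bytes], int] | None = None
               ) -> list[QRPacket]:
    """Slice a ciphertext into sequenced packets for one transaction.

    `fingerprint_fn` maps each body chunk to its 16-bit header tag; when
    omitted the tag is 0 (useful for framing-only tests).
    """
    chunks = chunk_body(cipher, cfg.capacity, HEADER_LEN)
    count = len(chunks)
    packets = []
    for seq, chunk in enumerate(chunks):
        tag = fingerprint_fn(chunk) if fingerprint_fn else 0
        header = MessageHeader(version=version, fingerprint=tag,
                               transaction=transaction, count=count, seq=seq)
        packets.append(QRPacket(header=header, body=chunk))
    return packets


def merge_packets(packets: Iterable[QRPacket]) -> bytes:
    """Reassemble the ciphertext from packets in any order."""
    ordered = sorted(packets, key=lambda p: p.header.seq)
    return b"".join(p.body for p in ordered)


def render_qr(packet: QRPacket, cfg: QRConfig | None = None):
    """Render one packet as a PIL image (PNG-ready), quiet zone included."""
    from PIL import Image

    cfg = cfg or QRConfig()
    raw = packet.to_bytes()
    matrix = _qr_encoder.encode_matrix(raw, cfg.version, cfg.ec_level,
                                       mask=cfg.mask)
    q = cfg.quiet_zone
    n = matrix.shape[0]
    canvas = np.ones((n + 2 * q, n + 2 * q), dtype=bool)
    canvas[q: q + n, q: q + n] = ~matrix
    img = Image.fromarray((canvas * 255).astype(np.uint8), mode="L")
    scale = cfg.module_px
    return img.resize((img.width * scale, img.height * scale),
                      resample=Image.NEAREST)


def read_qr(img) -> bytes:
    """Decode a QR image back to its raw packet bytes (header + body)."""
    raw = _qr_decoder.read_payload(img)
    if len(raw) < HEADER_LEN:
        raise ScanError(f"decoded payload of {len(raw)} bytes is shorter "
                        "than a packet header")
    return raw
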