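"""Bit-exact message framing for the QR transmission protocol.

Every QR symbol carries a 6-byte header followed by a ciphertext chunk. The
header packs five fields MSB-first, big-endian:

=============  ====  =======================================================
field          bits  meaning
=============  ====  =======================================================
version           8  protocol/codec version; selects the decoding profile
fingerprint      16  truncated hash of (ciphertext chunk || identity id)
transaction      16  day offset of the admission date from the tag epoch;
                     groups the subpackets of one transmission
count             4  number of subpackets the body was split into (1-15)
seq               4  position of this subpacket (0-based, < count)
=============  ====  =======================================================

`count` is stored as its raw value; 0 is reserved and rejected, so one
transmission spans at most 15 symbols.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass

from .errors import (
    CapacityExceededError,
    EmptyMessageError,
    FramingError,
    RangeError,
)

HEADER_LEN = 6

#: Epoch from which transaction ids count days, unless a profile overrides it.
DEFAULT_TAG_EPOCH = datetime.date(2020, 1, 1)

MAX_COUNT = 15


@dataclass(frozen=True)
class MessageHeader:
    """The 6-byte packet header; validated on construction."""

    version: int
    fingerprint: int
    transaction: int
    count: int
    seq: int

    def __post_init__(self):
        _check_range("version", self.version, 0, 255)
        _check_range("fingerprint", self.fingerprint, 0, 0xFFFF)
        _check_range("transaction", self.transaction, 0, 0xFFFF)
        _check_range("count", self.count, 1, MAX_COUNT)
        _check_range("seq", self.seq, 0, self.count - 1)


@dataclass(frozen=True)
class QRPacket:
    """One QR symbol's payload: header plus a ciphertext chunk."""

    header: MessageHeader
    body: bytes

    def to_bytes(self) -> bytes:
        return pack_header(self.header) + self.body

    @classmethod
    def from_bytes(cls, raw: bytes) -> "QRPacket":
        header = unpack_header(raw)
        return cls(header=header, body=bytes(raw[HEADER_LEN:]))


def _check_range(name: str, value: int, lo: int, hi: int) -> None:
    if not isinstance(value, int) or isinstance(value, bool):
        raise RangeError(f"{name} must be an integer, got {value!r}")
    if not lo <= value <= hi:
        raise RangeError(f"{name}={value} outside valid range [{lo}, {hi}]")


def pack_header(h: MessageHeader) -> bytes:
    """Serialize a header to exactly 6 bytes (big-endian, count in high nibble)."""
    return (
        h.version.to_bytes(1, "big")
        + h.fingerprint.to_bytes(2, "big")
        + h.transaction.to_bytes(2, "big")
        + bytes([(h.count << 4) | h.seq])
    )


def unpack_header(raw: bytes) -> MessageHeader:
    """Parse the first 6 bytes of `raw` back into a header.

    Raises :class:`FramingError` on short input, a zero count nibble, or
    ``seq >= count`` (all unrepresentable by :func:`pack_header`).
    """
    if len(raw) < HEADER_LEN:
        raise FramingError(f"header needs {HEADER_LEN} bytes, got {len(raw)}")
    count = raw[5] >> 4
    seq = raw[5] & 0x0F
    if count == 0:
        raise FramingError("count nibble is 0 (reserved)")
    if seq >= count:
        raise FramingError(f"seq={seq} not below count={count}")
    return MessageHeader(
        version=raw[0],
        fingerprint=int.from_bytes(raw[1:3], "big"),
        transaction=int.from_bytes(raw[3:5], "big"),
        count=count,
        seq=seq,
    )


def encode_transaction(
    adm_date: datetime.date, tag_date: datetime.date = DEFAULT_TAG_EPOCH
) -> int:
    """Whole-day count from the tag epoch to the admission date (16-bit)."""
    offset = (adm_date - tag_date).days
    if offset < 0:
        raise RangeError(
            f"admission date {adm_date} precedes tag epoch {tag_date}"
        )
    if offset > 0xFFFF:
        raise RangeError(
            f"admission date {adm_date} is {offset} days after the epoch; "
            f"maximum representable is 65535"
        )
    return offset


def compute_count(body_len: int, qr_capacity: int, header_len: int = HEADER_LEN) -> int:
    """Number of subpackets needed for a body: ceil(body / (capacity - header))."""
    if qr_capacity <= header_len:
        raise RangeError(
            f"qr_capacity={qr_capacity} must exceed header_len={header_len}"
        )
    if body_len == 0:
        raise EmptyMessageError("cannot packetize an empty body")
    if body_len < 0:
        raise RangeError(f"body_len={body_len} negative")
    chunk = qr_capacity - header_len
    count = -(-body_len // chunk)
    if count > MAX_COUNT:
        raise CapacityExceededError(
            f"body of {body_len} bytes needs {count} subpackets; "
            f"protocol maximum is {MAX_COUNT}"
        )
    return count


def chunk_body(body: bytes, qr_capacity: int, header_len: int = HEADER_LEN) -> list[bytes]:
    """Greedy slice of the body into count pieces of (capacity - header) bytes."""
    chunk = qr_capacity - header_len
    count = compute_count(len(body), qr_capacity, header_len)
    return [body[i * chunk: (i + 1) * chunk] for i in range(count)]
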