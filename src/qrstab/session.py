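"""End-to-end encoding and decoder-side authenticated reassembly.

Encoding runs the full pipeline in fixed order — tokenize, serialize,
compress, encrypt, split, then fingerprint each subpacket over its
ciphertext chunk concatenated with the patient identifier. Authenticating
ciphertext (rather than plaintext) is what lets the decoder check a tag
*before* investing any work in decryption.

The decoder is a state machine keyed by (version, transaction). Every scan
returns one of six status codes:

==============  ===========================================================
finished        all subpackets present; record decoded and returned
waiting         subpacket accepted; others still outstanding
duplicated      byte-identical repeat of an already-held subpacket
tag_error       not a parseable packet, or no profile for its version
auth_failed     fingerprint mismatch under the logged-in identity
exception       post-authentication failure (tamper, decode error,
                inconsistent count, same seq with different payload)
==============  ===========================================================

Precedence is framing > authentication > duplication > completion: the
cheapest check fails first and an unauthenticated packet leaks nothing
about buffer state.
"""

from __future__ import annotations

import datetime
import enum
from dataclasses import dataclass, field as dc_field

from . import crypto
from .errors import ProfileError, QRSTError
from .protocol import (
    HEADER_LEN,
    QRPacket,
    encode_transaction,
    unpack_header,
)
from .qr_transport import QRConfig, render_qr, split_body
from .serialization import deserialize_record, serialize_record

__all__ = [
    "StatusCode",
    "ScanResult",
    "EncodedTransmission",
    "DecodeSession",
    "ProfileRegistry",
    "encode_record",
    "submit_scan",
    "register_profile",
]


class StatusCode(str, enum.Enum):
    FINISHED = "finished"
    WAITING = "waiting"
    DUPLICATED = "duplicated"
    TAG_ERROR = "tag_error"
    AUTH_FAILED = "auth_failed"
    EXCEPTION = "exception"


@dataclass(frozen=True)
class ScanResult:
    code: StatusCode
    payload: dict | None = None
    transaction: int | None = None
    detail: str = ""


@dataclass
class EncodedTransmission:
    """Encoder output: the packets (and optionally rendered symbols)."""

    packets: list[QRPacket]
    images: list = dc_field(default_factory=list)
    transaction: int = 0

    @property
    def packet_bytes(self) -> list[bytes]:
        return [p.to_bytes() for p in self.packets]


class ProfileRegistry:
    """Version byte -> codec profile; the decoder's multiversion manager."""

    def __init__(self):
        self._profiles: dict[int, crypto.CodecProfile] = {}

    def register(self, profile: crypto.CodecProfile) -> "ProfileRegistry":
        if profile.version in self._profiles:
            raise ProfileError(
                f"version {profile.version} already registered")
        self._profiles[profile.version] = profile
        return self

    def get(self, version: int) -> crypto.CodecProfile | None:
        return self._profiles.get(version)

    def __len__(self) -> int:
        return len(self._profiles)


def register_profile(registry: ProfileRegistry,
                     profile: crypto.CodecProfile) -> ProfileRegistry:
    return registry.register(profile)


def _tag_int(chunk: bytes, identity_id: str, profile: crypto.CodecProfile) -> int:
    tag = crypto.fingerprint(chunk, identity_id, profile.fingerprint_len)
    return int.from_bytes(tag[:2].ljust(2, b"\x00"), "big")


def encode_record(rec: dict, identity_id: str, profile: crypto.CodecProfile,
                  cfg: QRConfig | None = None,
                  render: bool = True) -> EncodedTransmission:
    """Record -> authenticated QR packets (pipeline order is fixed)."""
    cfg = cfg or QRConfig()
    try:
        plain = serialize_record(rec, profile.schema, profile.tokenizer)
    except QRSTError as exc:
        raise type(exc)(f"serialize stage: {exc}") from exc
    compressed = crypto.gzip_compress(plain)

    adm = datetime.date.fromisoformat(rec["base"]["admissionDate"])
    transaction = encode_transaction(adm, profile.tag_epoch)

    from .protocol import compute_count
    count = compute_count(len(compressed), cfg.capacity, HEADER_LEN)
    nonce = crypto.derive_nonce(profile, profile.version, transaction, count)
    cipher = crypto.encrypt(compressed, profile.secret, nonce)

    packets = split_body(
        cipher, cfg, profile.version, transaction,
        fingerprint_fn=lambda chunk: _tag_int(chunk, identity_id, profile))
    images = [render_qr(p, cfg) for p in packets] if render else []
    return EncodedTransmission(packets=packets, images=images,
                               transaction=transaction)


@dataclass
class _Buffer:
    count: int
    chunks: dict[int, bytes] = dc_field(default_factory=dict)
    finished: bool = False


class DecodeSession:
    """Reassembly state for one logged-in identity."""

    def __init__(self, identity_id: str, registry: ProfileRegistry):
        self.identity_id = identity_id
        self.registry = registry
        self._buffers: dict[tuple[int, int], _Buffer] = {}
        self.history: list[ScanResult] = []

    def submit(self, raw: bytes) -> ScanResult:
        result = self._classify(raw)
        self.history.append(result)
        return result

    # -- internals ----------------------------------------------------------

    def _classify(self, raw: bytes) -> ScanResult:
        try:
            header = unpack_header(raw)
        except QRSTError as exc:
            return ScanResult(StatusCode.TAG_ERROR, detail=str(exc))
        profile = self.registry.get(header.version)
        if profile is None:
            return ScanResult(StatusCode.TAG_ERROR,
                              detail=f"unknown version {header.version}")
        body = bytes(raw[HEADER_LEN:])

        expected = _tag_int(body, self.identity_id, profile)
        if expected != header.fingerprint:
            return ScanResult(StatusCode.AUTH_FAILED,
                              transaction=header.transaction,
                              detail="fingerprint mismatch for this identity")

        key = (header.version, header.transaction)
        buf = self._buffers.get(key)
        if buf is None:
            buf = self._buffers[key] = _Buffer(count=header.count)
        elif buf.count != header.count:
            return ScanResult(StatusCode.EXCEPTION,
                              transaction=header.transaction,
                              detail="count disagrees with earlier packets")

        held = buf.chunks.get(header.seq)
        if held is not None:
            if held == body:
                return ScanResult(StatusCode.DUPLICATED,
                                  transaction=header.transaction)
            return ScanResult(StatusCode.EXCEPTION,
                              transaction=header.transaction,
                              detail="same seq with different payload")
        buf.chunks[header.seq] = body

        if len(buf.chunks) < buf.count:
            return ScanResult(StatusCode.WAITING,
                              transaction=header.transaction)

        try:
            record = self._decode(buf, header, profile)
        except Exception as exc:  # all post-auth failures map to one code
            del self._buffers[key]
            return ScanResult(StatusCode.EXCEPTION,
                              transaction=header.transaction,
                              detail=f"decode failed: {exc}")
        buf.finished = True
        buf.chunks = {}
        return ScanResult(StatusCode.FINISHED, payload=record,
                          transaction=header.transaction)

    def _decode(self, buf: _Buffer, header, profile) -> dict:
        cipher = b"".join(buf.chunks[s] for s in sorted(buf.chunks))
        nonce = crypto.derive_nonce(profile, header.version,
                                    header.transaction, header.count)
        compressed = crypto.decrypt(cipher, profile.secret, nonce)
        plain = crypto.gzip_decompress(compressed)
        return deserialize_record(plain, profile.schema, profile.tokenizer)


def submit_scan(session: DecodeSession, raw: bytes,
                registry: ProfileRegistry | None = None) -> ScanResult:
    """Functional wrapper over :meth:`DecodeSession.submit`."""
    if registry is not None:
        session.registry = registry
    return session.submit(raw)
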