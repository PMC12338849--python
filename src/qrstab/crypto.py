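"""Compression, encryption and authentication for the QR pipeline.

The security layer adds exactly 2 bytes per packet: ChaCha20 is a stream
cipher (ciphertext length equals plaintext length) and the only
authentication material is the truncated hash fingerprint carried in the
packet header. A forged packet therefore passes with probability 2^-16
under the default 2-byte tag — acceptable for paper-borne codes, whose
physical distribution makes online brute force impractical.

The cipher nonce is never transmitted. Both ends derive it from the shared
secret and the header's (version, transaction, count) triple via a keyed
hash, keeping the wire overhead at the 2 tag bytes. The cost of that choice
is documented in the package methods note: two *different* bodies encrypted
under the same (version, transaction, count) would reuse a keystream, so an
encoder must not re-issue a transaction with altered content.
"""

from __future__ import annotations

import binascii
import datetime
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

from ._blake3 import blake3, blake3_derive_key, blake3_keyed
from ._chacha20 import xor_stream
from .errors import QRSTError, RangeError
from .serialization import RecordSchema, load_default_schema
from .tokenization import TokenizerModel

__all__ = [
    "CodecProfile",
    "gzip_compress",
    "gzip_decompress",
    "derive_nonce",
    "encrypt",
    "decrypt",
    "fingerprint",
]

KEY_LEN = 32
NONCE_LEN = 8
DEFAULT_TAG_LEN = 2

_NONCE_CONTEXT = "qrstab v1 packet nonce derivation"

# Fixed gzip header: magic, deflate, no flags, mtime 0, max-compression, OS 255
_GZIP_HEADER = b"\x1f\x8b\x08\x00\x00\x00\x00\x00\x02\xff"


@dataclass
class CodecProfile:
    """One protocol version's trust bundle: key, schema, tokenizer, epoch.

    Encoder and decoder are assumed to have synchronized this material
    offline; none of it ever travels inside a QR code.
    """

    version: int
    secret: bytes
    schema: RecordSchema = field(default_factory=load_default_schema)
    tokenizer: TokenizerModel | None = None
    tag_epoch: datetime.date = datetime.date(2020, 1, 1)
    fingerprint_len: int = DEFAULT_TAG_LEN

    def __post_init__(self):
        if not 0 <= self.version <= 255:
            raise RangeError(f"version={self.version} outside [0, 255]")
        if len(self.secret) != KEY_LEN:
            raise RangeError(
                f"secret must be {KEY_LEN} bytes (256-bit), got {len(self.secret)}")
        if not 1 <= self.fingerprint_len <= 64:
            raise RangeError(
                f"fingerprint_len={self.fingerprint_len} outside [1, 64]")

    # -- persistence: directory of {profile.json, schema.avsc, tokenizer/, key} --

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        (d / "key.hex").write_text(self.secret.hex(), "utf-8")
        self.schema.to_file(d / "schema.avsc")
        if self.tokenizer is not None:
            self.tokenizer.save(d / "tokenizer")
        (d / "profile.json").write_text(json.dumps({
            "version": self.version,
            "tag_epoch": self.tag_epoch.isoformat(),
            "fingerprint_len": self.fingerprint_len,
            "schema_fingerprint": self.schema.fingerprint,
            "has_tokenizer": self.tokenizer is not None,
        }, indent=2), "utf-8")

    @classmethod
    def load(cls, directory) -> "CodecProfile":
        d = Path(directory)
        meta = json.loads((d / "profile.json").read_text("utf-8"))
        key_text = (d / "key.hex").read_text("utf-8").strip()
        try:
            secret = binascii.unhexlify(key_text)
        except binascii.Error as exc:
            raise QRSTError(f"malformed key file: {exc}") from exc
        epoch = datetime.date.fromisoformat(meta["tag_epoch"])
        schema = RecordSchema.from_file(d / "schema.avsc", tag_epoch=epoch)
        tokenizer = (TokenizerModel.load(d / "tokenizer")
                     if meta.get("has_tokenizer") else None)
        return cls(version=meta["version"], secret=secret, schema=schema,
                   tokenizer=tokenizer, tag_epoch=epoch,
                   fingerprint_len=meta["fingerprint_len"])


# ---------------------------------------------------------------------------
# deterministic gzip
# ---------------------------------------------------------------------------

def gzip_compress(data: bytes) -> bytes:
    """Gzip with a fixed header (zero mtime, unknown OS): byte-reproducible."""
    compressor = zlib.compressobj(9, zlib.DEFLATED, -zlib.MAX_WBITS)
    deflated = compressor.compress(data) + compressor.flush()
    trailer = (zlib.crc32(data).to_bytes(4, "little")
               + (len(data) & 0xFFFFFFFF).to_bytes(4, "little"))
    return _GZIP_HEADER + deflated + trailer


def gzip_decompress(data: bytes) -> bytes:
    try:
        import gzip as _gzip
        return _gzip.decompress(data)
    except (OSError, EOFError, zlib.error) as exc:
        raise QRSTError(f"corrupt gzip stream: {exc}") from exc


# ---------------------------------------------------------------------------
# cipher and authentication
# ---------------------------------------------------------------------------

def derive_nonce(profile: CodecProfile, version: int, transaction: int,
                 count: int) -> bytes:
    """64-bit nonce both ends can derive: keyed hash of the header triple.

    The subkey is bound to a derivation context so the nonce-derivation key
    is never the raw traffic secret.
    """
    subkey = blake3_derive_key(_NONCE_CONTEXT, profile.secret)
    material = bytes([version]) + transaction.to_bytes(2, "big") + bytes([count])
    return blake3_keyed(subkey, material, NONCE_LEN)


def encrypt(plain: bytes, key: bytes, nonce: bytes) -> bytes:
    """ChaCha20 (64-bit-nonce variant); output length equals input length."""
    return xor_stream(plain, key, nonce)


def decrypt(cipher: bytes, key: bytes, nonce: bytes) -> bytes:
    return xor_stream(cipher, key, nonce)


def fingerprint(message: bytes, identity_id: str, n: int = DEFAULT_TAG_LEN) -> bytes:
    """Truncated authentication tag: hash(message || identity)[:n].

    The identity string is hashed as its exact UTF-8 bytes, no
    normalization. Truncation keeps the prefix, so tags of different lengths
    over the same input are prefixes of one another.
    """
    if not 1 <= n <= 64:
        raise RangeError(f"fingerprint length {n} outside [1, 64]")
    return blake3(message + identity_id.encode("utf-8"), n)
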