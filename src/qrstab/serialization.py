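"""Schema-driven binary serialization of health records (Avro wire format).

Records are encoded field-by-field in schema order using the Avro binary
encoding: no field names or type tags appear in the output, so the stream is
unreadable without the writer's schema. Integers use zig-zag-then-varint
coding (11 -> zig-zag 22 -> byte 0x16); strings and byte fields are
length-prefixed; arrays are written as blocks terminated by a zero count;
unions write the branch index first.

Two logical-type annotations extend the plain schema:

``tokenized-text``
    A string field that, when a tokenizer model is supplied, is replaced on
    the wire by its packed 2-byte token ids. The wire format of Avro
    ``string`` and ``bytes`` is identical (length + payload), so the same
    schema serves both the tokenized and plain-text pipelines.

``epoch-days``
    An int field holding a calendar date as the day offset from the schema's
    tag epoch; presented as an ISO ``YYYY-MM-DD`` string in JSON.
"""

from __future__ import annotations

import datetime
import io
import json
import struct
from dataclasses import dataclass, field
from importlib import resources
from typing import Any

from ._blake3 import blake3
from .errors import DeserializationError, FramingError, SchemaValidationError

__all__ = [
    "RecordSchema",
    "load_default_schema",
    "serialize_record",
    "deserialize_record",
    "validate_record",
    "zigzag_encode",
    "zigzag_decode",
    "minified_json_bytes",
]

_INT64_MIN = -(1 << 63)
_INT64_MAX = (1 << 63) - 1


# ---------------------------------------------------------------------------
# zig-zag varint primitives
# ---------------------------------------------------------------------------

def zigzag_value(n: int) -> int:
    """Map a signed integer to its unsigned zig-zag value (0,-1,1,-2 -> 0,1,2,3)."""
    return (n << 1) ^ (n >> 63)


def zigzag_encode(n: int) -> bytes:
    """Encode a signed 64-bit integer as a zig-zag varint byte string."""
    if not _INT64_MIN <= n <= _INT64_MAX:
        raise FramingError(f"{n} outside signed 64-bit range")
    zz = (n << 1) ^ (n >> 63)
    out = bytearray()
    while True:
        bits = zz & 0x7F
        zz >>= 7
        if zz:
            out.append(bits | 0x80)
        else:
            out.append(bits)
            return bytes(out)


def zigzag_decode(raw: bytes) -> int:
    """Decode a complete zig-zag varint; rejects empty, truncated or overlong input."""
    value, pos = _read_varint(raw, 0)
    if pos != len(raw):
        raise FramingError(f"{len(raw) - pos} trailing bytes after varint")
    return value


def _read_varint(raw: bytes, pos: int) -> tuple[int, int]:
    zz = 0
    shift = 0
    start = pos
    while True:
        if pos >= len(raw):
            raise FramingError("varint truncated" if pos > start else "empty varint")
        b = raw[pos]
        pos += 1
        zz |= (b & 0x7F) << shift
        if not b & 0x80:
            break
        shift += 7
        if shift > 63:
            raise FramingError("varint longer than 10 bytes (overlong)")
    return (zz >> 1) ^ -(zz & 1), pos


# ---------------------------------------------------------------------------
# schema container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecordSchema:
    """An Avro record schema plus this protocol's logical-type designations."""

    schema: dict
    tag_epoch: datetime.date = field(default=datetime.date(2020, 1, 1))

    @property
    def tokenized_paths(self) -> tuple[str, ...]:
        """Dotted paths of every tokenized-text field, in schema order."""
        found: list[str] = []
        _collect_logical(self.schema, "", "tokenized-text", found)
        return tuple(found)

    @property
    def fingerprint(self) -> str:
        """Hex digest identifying the schema document (canonical JSON hash)."""
        canon = json.dumps(self.schema, sort_keys=True, separators=(",", ":"))
        return blake3(canon.encode("utf-8"), 8).hex()

    @classmethod
    def from_file(cls, path, tag_epoch: datetime.date | None = None) -> "RecordSchema":
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
        return cls(doc, tag_epoch or datetime.date(2020, 1, 1))

    def to_file(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.schema, fh, indent=2, ensure_ascii=False)


def _collect_logical(node: Any, path: str, logical: str, out: list[str]) -> None:
    if isinstance(node, list):
        for branch in node:
            _collect_logical(branch, path, logical, out)
        return
    if not isinstance(node, dict):
        return
    if node.get("logicalType") == logical:
        out.append(path)
        return
    t = node.get("type")
    if t == "record":
        for f in node["fields"]:
            _collect_logical(f["type"], f"{path}.{f['name']}" if path else f["name"],
                             logical, out)
    elif t == "array":
        _collect_logical(node["items"], path + "[]", logical, out)
    elif isinstance(t, (dict, list)):
        _collect_logical(t, path, logical, out)


def load_default_schema(tag_epoch: datetime.date | None = None) -> RecordSchema:
    """The packaged seven-section EHR schema (version 1)."""
    text = (resources.files("qrstab") / "schemas" / "ehr_v1.avsc").read_text("utf-8")
    return RecordSchema(json.loads(text), tag_epoch or datetime.date(2020, 1, 1))


def minified_json_bytes(rec: dict) -> bytes:
    """UTF-8 size baseline: the record as whitespace-free JSON."""
    return json.dumps(rec, separators=(",", ":"), ensure_ascii=False).encode("utf-8")


# ---------------------------------------------------------------------------
# writer
# ---------------------------------------------------------------------------

def serialize_record(rec: dict, schema: RecordSchema, tok=None) -> bytes:
    """Encode a JSON-style record dict to schema-ordered binary.

    `tok` is a trained :class:`~qrstab.tokenization.TokenizerModel`; when
    given, tokenized-text fields are written as packed 2-byte token ids,
    otherwise as plain UTF-8.
    """
    validate_record(rec, schema)
    out = io.BytesIO()
    _write(schema.schema, rec, out, schema, tok, "$")
    return out.getvalue()


def _write(node: Any, value: Any, out: io.BytesIO, schema: RecordSchema,
           tok, path: str) -> None:
    if isinstance(node, list):  # union: write branch index, then value
        idx = _union_branch(node, value)
        out.write(zigzag_encode(idx))
        _write(node[idx], value, out, schema, tok, path)
        return
    if isinstance(node, str):
        node = {"type": node}
    t = node["type"]
    logical = node.get("logicalType")
    if t == "null":
        return
    if t == "boolean":
        out.write(b"\x01" if value else b"\x00")
    elif t in ("int", "long"):
        if logical == "epoch-days":
            value = (datetime.date.fromisoformat(value) - schema.tag_epoch).days
        out.write(zigzag_encode(value))
    elif t == "float":
        out.write(struct.pack("<f", value))
    elif t == "double":
        out.write(struct.pack("<d", value))
    elif t == "string":
        if logical == "tokenized-text" and tok is not None:
            from .tokenization import pack_tokens
            payload = pack_tokens(tok.encode(value))
        else:
            payload = value.encode("utf-8")
        out.write(zigzag_encode(len(payload)))
        out.write(payload)
    elif t == "bytes":
        out.write(zigzag_encode(len(value)))
        out.write(value)
    elif t == "record":
        for f in node["fields"]:
            _write(f["type"], value[f["name"]], out, schema, tok,
                   f"{path}.{f['name']}")
    elif t == "array":
        if value:
            out.write(zigzag_encode(len(value)))
            for i, item in enumerate(value):
                _write(node["items"], item, out, schema, tok, f"{path}[{i}]")
        out.write(zigzag_encode(0))
    else:
        raise SchemaValidationError(path, f"unsupported schema type {t!r}")


def _union_branch(branches: list, value: Any) -> int:
    for i, branch in enumerate(branches):
        name = branch if isinstance(branch, str) else branch.get("type")
        if value is None and name == "null":
            return i
        if value is not None and name != "null":
            return i
    raise SchemaValidationError("$", f"no union branch accepts {value!r}")


# ---------------------------------------------------------------------------
# reader
# ---------------------------------------------------------------------------

def deserialize_record(raw: bytes, schema: RecordSchema, tok=None) -> dict:
    """Exact inverse of :func:`serialize_record` under the same schema + tokenizer."""
    try:
        value, pos = _read(schema.schema, raw, 0, schema, tok)
    except (FramingError, IndexError, UnicodeDecodeError, ValueError,
            OverflowError) as exc:
        if isinstance(exc, DeserializationError):
            raise
        raise DeserializationError(f"stream unreadable under schema: {exc}") from exc
    if pos != len(raw):
        raise DeserializationError(f"{len(raw) - pos} trailing bytes after record")
    return value


def _read(node: Any, raw: bytes, pos: int, schema: RecordSchema, tok):
    if isinstance(node, list):
        idx, pos = _read_varint(raw, pos)
        if not 0 <= idx < len(node):
            raise DeserializationError(f"union branch {idx} out of range")
        return _read(node[idx], raw, pos, schema, tok)
    if isinstance(node, str):
        node = {"type": node}
    t = node["type"]
    logical = node.get("logicalType")
    if t == "null":
        return None, pos
    if t == "boolean":
        if pos >= len(raw):
            raise DeserializationError("truncated boolean")
        return raw[pos] != 0, pos + 1
    if t in ("int", "long"):
        value, pos = _read_varint(raw, pos)
        if logical == "epoch-days":
            value = (schema.tag_epoch + datetime.timedelta(days=value)).isoformat()
        return value, pos
    if t == "float":
        if pos + 4 > len(raw):
            raise DeserializationError("truncated float")
        return struct.unpack_from("<f", raw, pos)[0], pos + 4
    if t == "double":
        if pos + 8 > len(raw):
            raise DeserializationError("truncated double")
        return struct.unpack_from("<d", raw, pos)[0], pos + 8
    if t in ("string", "bytes"):
        length, pos = _read_varint(raw, pos)
        if length < 0 or pos + length > len(raw):
            raise DeserializationError("truncated length-prefixed field")
        payload = raw[pos: pos + length]
        pos += length
        if t == "bytes":
            return bytes(payload), pos
        if logical == "tokenized-text" and tok is not None:
            from .tokenization import unpack_tokens
            return tok.decode(unpack_tokens(bytes(payload))), pos
        return payload.decode("utf-8"), pos
    if t == "record":
        rec = {}
        for f in node["fields"]:
            rec[f["name"]], pos = _read(f["type"], raw, pos, schema, tok)
        return rec, pos
    if t == "array":
        items = []
        while True:
            count, pos = _read_varint(raw, pos)
            if count == 0:
                return items, pos
            if count < 0:  # block with byte-size prefix (valid Avro; skip size)
                _, pos = _read_varint(raw, pos)
                count = -count
            if count > len(raw):  # cheap sanity bound against garbage streams
                raise DeserializationError(f"implausible array block count {count}")
            for _ in range(count):
                item, pos = _read(node["items"], raw, pos, schema, tok)
                items.append(item)
    raise DeserializationError(f"unsupported schema type {t!r}")


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_record(rec: dict, schema: RecordSchema) -> None:
    """Check a record dict against the schema; raises with the failing path."""
    _validate(schema.schema, rec, schema, "$")


def _validate(node: Any, value: Any, schema: RecordSchema, path: str) -> None:
    if isinstance(node, list):
        idx = _union_branch(node, value)
        _validate(node[idx], value, schema, path)
        return
    if isinstance(node, str):
        node = {"type": node}
    t = node["type"]
    logical = node.get("logicalType")
    if t == "null":
        if value is not None:
            raise SchemaValidationError(path, f"expected null, got {value!r}")
    elif t == "boolean":
        if not isinstance(value, bool):
            raise SchemaValidationError(path, f"expected boolean, got {type(value).__name__}")
    elif t in ("int", "long"):
        if logical == "epoch-days":
            if not isinstance(value, str):
                raise SchemaValidationError(path, "expected ISO date string")
            try:
                datetime.date.fromisoformat(value)
            except ValueError as exc:
                raise SchemaValidationError(path, f"bad date: {exc}") from exc
        elif not isinstance(value, int) or isinstance(value, bool):
            raise SchemaValidationError(path, f"expected integer, got {type(value).__name__}")
        elif t == "int" and not -(1 << 31) <= value < (1 << 31):
            raise SchemaValidationError(path, f"{value} outside 32-bit range")
    elif t in ("float", "double"):
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            raise SchemaValidationError(path, f"expected number, got {type(value).__name__}")
    elif t == "string":
        if not isinstance(value, str):
            raise SchemaValidationError(path, f"expected string, got {type(value).__name__}")
    elif t == "bytes":
        if not isinstance(value, (bytes, bytearray)):
            raise SchemaValidationError(path, f"expected bytes, got {type(value).__name__}")
    elif t == "record":
        if not isinstance(value, dict):
            raise SchemaValidationError(path, f"expected object, got {type(value).__name__}")
        names = {f["name"] for f in node["fields"]}
        extra = set(value) - names
        if extra:
            raise SchemaValidationError(path, f"unknown fields {sorted(extra)}")
        for f in node["fields"]:
            if f["name"] not in value:
                raise SchemaValidationError(f"{path}.{f['name']}", "missing field")
            _validate(f["type"], value[f["name"]], schema, f"{path}.{f['name']}")
    elif t == "array":
        if not isinstance(value, list):
            raise SchemaValidationError(path, f"expected array, got {type(value).__name__}")
        for i, item in enumerate(value):
            _validate(node["items"], item, schema, f"{path}[{i}]")
    else:
        raise SchemaValidationError(path, f"unsupported schema type {t!r}")
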