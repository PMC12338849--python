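"""Zig-zag varints, the binary record codec, and its information hiding."""

import json

import pytest
from hypothesis import given
from hypothesis import strategies as st

from qrstab import (
    DeserializationError,
    FramingError,
    RecordSchema,
    SchemaValidationError,
    deserialize_record,
    generate_record,
    load_default_schema,
    minified_json_bytes,
    serialize_record,
    validate_record,
    zigzag_decode,
    zigzag_encode,
)


class TestZigZag:
    def test_hospital_stay_worked_example(self):
        # 11 (integer) -> 22 (zig-zag) -> 0x16 (octet)
        assert (11 << 1) ^ (11 >> 63) == 22
        assert zigzag_encode(11) == b"\x16"

    def test_zero_and_minus_one(self):
        assert zigzag_encode(0) == b"\x00"
        assert zigzag_encode(-1) == b"\x01"

    def test_brute_force_against_bit_arithmetic_oracle(self):
        for n in range(-10000, 10001):
            zz = (n << 1) ^ (n >> 63)  # arbitrary-precision arithmetic oracle
            expected = bytearray()
            while True:
                if zz < 0x80:
                    expected.append(zz)
                    break
                expected.append((zz & 0x7F) | 0x80)
                zz >>= 7
            assert zigzag_encode(n) == bytes(expected)
            assert zigzag_decode(bytes(expected)) == n

    @pytest.mark.parametrize("raw", [b"", b"\x80", b"\xff" * 11,
                                     b"\x16\x00"])
    def test_malformed_varints_rejected(self, raw):
        with pytest.raises(FramingError):
            zigzag_decode(raw)

    @given(st.integers(-(2 ** 63), 2 ** 63 - 1))
    def test_round_trip_full_int64(self, n):
        assert zigzag_decode(zigzag_encode(n)) == n


@pytest.fixture(scope="module")
def minimal_record():
    return {
        "base": {"age": 0, "gender": "", "height": 0.0, "weight": 0.0,
                 "department": "", "hospitalDays": 11,
                 "admissionDate": "2020-01-01", "dischargeDate": "2020-01-01",
                 "nursingLevel": "", "allergyHistory": None},
        "operate": [], "image": [], "lab": [], "ass": [], "disease": [],
        "drug": [],
    }


class TestRecordCodec:
    def test_empty_lists_record_round_trips(self, schema, minimal_record):
        raw = serialize_record(minimal_record, schema)
        assert deserialize_record(raw, schema) == minimal_record

    def test_hospital_days_eleven_appears_as_0x16(self, schema, minimal_record):
        """Byte offset computed by serializing the preceding fields."""
        raw = serialize_record(minimal_record, schema)
        # preceding base fields: age(1) gender(1) height(8) weight(8) dept(1)
        offset = 1 + 1 + 8 + 8 + 1
        assert raw[offset] == 0x16

    def test_generator_records_round_trip(self, schema, gen_profile,
                                          bpe_model, records):
        for rec in records[:120]:
            for tok in (None, bpe_model):
                raw = serialize_record(rec, schema, tok)
                assert deserialize_record(raw, schema, tok) == rec

    def test_truncated_stream_raises(self, schema, gen_profile):
        rec = generate_record(gen_profile, 0)
        raw = serialize_record(rec, schema)
        with pytest.raises(DeserializationError):
            deserialize_record(raw[:-1], schema)
        with pytest.raises(DeserializationError):
            deserialize_record(raw + b"\x00", schema)

    def test_foreign_schema_bytes_never_crash(self, schema):
        """Streams written under a different schema error out or produce a
        (wrong) record — anything except an unhandled crash."""
        other = RecordSchema({
            "type": "record", "name": "Other", "fields": [
                {"name": "a", "type": "string"},
                {"name": "b", "type": {"type": "array", "items": "int"}},
            ]})
        for seed in range(30):
            import random
            blob = random.Random(seed).randbytes(64)
            try:
                deserialize_record(blob, schema)
            except DeserializationError:
                pass
            payload = serialize_record(
                {"a": "x" * seed, "b": list(range(seed))}, other)
            try:
                deserialize_record(payload, schema)
            except DeserializationError:
                pass

    def test_no_field_names_leak_into_stream(self, schema, records):
        names = set()

        def collect(node):
            if isinstance(node, dict):
                for f in node.get("fields", []):
                    names.add(f["name"].encode())
                    collect(f["type"])
                if "items" in node:
                    collect(node["items"])
            elif isinstance(node, list):
                for b in node:
                    collect(b)

        collect(schema.schema)
        assert len(names) >= 25
        for rec in records[:40]:
            raw = serialize_record(rec, schema)
            assert not any(name in raw for name in names)

    def test_binary_smaller_than_minified_json(self, schema, records):
        for rec in records[:80]:
            assert len(serialize_record(rec, schema)) < \
                len(minified_json_bytes(rec))

    def test_validation_error_carries_path(self, schema, minimal_record):
        bad = json.loads(json.dumps(minimal_record))
        bad["lab"] = [{"indicatorName": "x", "value": 3, "unit": "",
                       "riskFlag": "", "normalRange": ""}]
        with pytest.raises(SchemaValidationError, match=r"lab\[0\].value"):
            validate_record(bad, schema)

    def test_schema_fingerprint_is_content_sensitive(self, schema):
        other = RecordSchema({"type": "record", "name": "X", "fields": []})
        assert schema.fingerprint != other.fingerprint
        assert schema.fingerprint == load_default_schema().fingerprint
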