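"""Decoder state machine: status codes, reassembly, multiversion registry."""

import itertools
import random

import numpy as np
import pytest

from qrstab import (
    CodecProfile,
    DecodeSession,
    ProfileError,
    ProfileRegistry,
    QRConfig,
    StatusCode,
    encode_record,
    generate_record,
    submit_scan,
)
from qrstab.protocol import HEADER_LEN, pack_header, unpack_header

IDENTITY = "patient-001"


@pytest.fixture(scope="module")
def small_record(gen_profile):
    rec = generate_record(gen_profile, 101)
    rec["lab"] = rec["lab"][:5]
    rec["image"] = rec["image"][:1]
    return rec


@pytest.fixture(scope="module")
def big_record(gen_profile, codec_profile):
    """First seeded record whose ciphertext needs more than one symbol."""
    for seed in range(102, 160):
        rec = generate_record(gen_profile, seed)
        enc = encode_record(rec, IDENTITY, codec_profile, render=False)
        if len(enc.packets) >= 2:
            return rec
    raise AssertionError("no multi-packet record in seed range")


def fresh_session(registry):
    return DecodeSession(IDENTITY, registry)


class TestEncode:
    def test_minimal_record_is_single_symbol(self, small_record, codec_profile):
        enc = encode_record(small_record, IDENTITY, codec_profile, render=True)
        assert len(enc.packets) == 1
        assert len(enc.images) == 1

    def test_forced_multi_packet(self, big_record, codec_profile):
        enc = encode_record(big_record, IDENTITY, codec_profile, render=False)
        assert len(enc.packets) >= 2
        headers = [p.header for p in enc.packets]
        assert len({h.transaction for h in headers}) == 1
        assert [h.seq for h in headers] == list(range(len(headers)))

    def test_packet_bodies_hide_plaintext(self, big_record, codec_profile):
        """No serialized field string may appear in packet bytes."""
        enc = encode_record(big_record, IDENTITY, codec_profile, render=False)
        blob = b"".join(enc.packet_bytes)
        probes = [big_record["base"]["department"].encode("utf-8")]
        probes += [r["diseaseName"].encode("utf-8") for r in big_record["disease"]]
        probes += [r["indicatorName"].encode("utf-8") for r in big_record["lab"][:10]]
        assert not any(p in blob for p in probes)


class TestScanStateMachine:
    def test_single_packet_finishes(self, small_record, codec_profile, registry):
        enc = encode_record(small_record, IDENTITY, codec_profile, render=False)
        res = fresh_session(registry).submit(enc.packet_bytes[0])
        assert res.code == StatusCode.FINISHED
        assert res.payload == small_record

    def test_wrong_identity_auth_failed(self, small_record, codec_profile,
                                        registry):
        enc = encode_record(small_record, IDENTITY, codec_profile, render=False)
        res = DecodeSession("someone-else", registry).submit(enc.packet_bytes[0])
        assert res.code == StatusCode.AUTH_FAILED
        assert res.payload is None

    def test_waiting_duplicated_finished_walk(self, big_record, codec_profile,
                                              registry):
        enc = encode_record(big_record, IDENTITY, codec_profile, render=False)
        first, *rest = enc.packet_bytes
        ses = fresh_session(registry)
        assert ses.submit(first).code == StatusCode.WAITING
        assert ses.submit(first).code == StatusCode.DUPLICATED
        for raw in rest[:-1]:
            assert ses.submit(raw).code == StatusCode.WAITING
        final = ses.submit(rest[-1])
        assert final.code == StatusCode.FINISHED
        assert final.payload == big_record

    def test_completion_is_order_independent(self, big_record, codec_profile,
                                             registry):
        enc = encode_record(big_record, IDENTITY, codec_profile, render=False)
        perms = itertools.permutations(enc.packet_bytes)
        for perm in itertools.islice(perms, 6):
            ses = fresh_session(registry)
            results = [ses.submit(raw) for raw in perm]
            assert results[-1].code == StatusCode.FINISHED
            assert results[-1].payload == big_record
            assert all(r.code == StatusCode.WAITING for r in results[:-1])

    def test_garbage_is_tag_error(self, registry):
        ses = fresh_session(registry)
        assert ses.submit(b"\x01\x02").code == StatusCode.TAG_ERROR
        assert ses.submit(bytes(6)).code == StatusCode.TAG_ERROR  # count==0

    def test_tampered_body_auth_failed(self, small_record, codec_profile,
                                       registry):
        enc = encode_record(small_record, IDENTITY, codec_profile, render=False)
        raw = bytearray(enc.packet_bytes[0])
        raw[-1] ^= 0xFF
        assert fresh_session(registry).submit(bytes(raw)).code == \
            StatusCode.AUTH_FAILED

    def test_same_seq_different_payload_is_exception(self, big_record,
                                                     codec_profile, registry):
        enc = encode_record(big_record, IDENTITY, codec_profile, render=False)
        ses = fresh_session(registry)
        ses.submit(enc.packet_bytes[0])
        # craft a different chunk with a *valid* tag for this identity
        header = unpack_header(enc.packet_bytes[0])
        from qrstab import fingerprint
        body = b"\x00" * len(enc.packet_bytes[0][HEADER_LEN:])
        from qrstab.protocol import MessageHeader
        tag = int.from_bytes(fingerprint(body, IDENTITY), "big")
        forged = pack_header(MessageHeader(header.version, tag,
                                           header.transaction, header.count,
                                           header.seq)) + body
        assert ses.submit(forged).code == StatusCode.EXCEPTION

    def test_count_disagreement_is_exception(self, big_record, codec_profile,
                                             registry):
        enc = encode_record(big_record, IDENTITY, codec_profile, render=False)
        ses = fresh_session(registry)
        ses.submit(enc.packet_bytes[0])
        header = unpack_header(enc.packet_bytes[1])
        from qrstab import fingerprint
        from qrstab.protocol import MessageHeader
        body = enc.packet_bytes[1][HEADER_LEN:]
        tag = int.from_bytes(fingerprint(body, IDENTITY), "big")
        lying = pack_header(MessageHeader(header.version, tag,
                                          header.transaction,
                                          header.count + 1, header.seq)) + body
        assert ses.submit(lying).code == StatusCode.EXCEPTION

    def test_forged_random_tags_rarely_pass(self, small_record, codec_profile,
                                            registry):
        """Empirical false-accept rate of random 16-bit tags ~ 2^-16."""
        enc = encode_record(small_record, IDENTITY, codec_profile, render=False)
        raw = enc.packet_bytes[0]
        true_tag = unpack_header(raw).fingerprint
        rng = np.random.default_rng(123)
        n = 200_000
        tags = rng.integers(0, 65536, size=n)
        accepts = int((tags == true_tag).sum())
        # 99.99% binomial envelope around p = 2^-16
        assert accepts <= 20


class TestRegistry:
    def test_duplicate_version_rejected(self, codec_profile):
        reg = ProfileRegistry().register(codec_profile)
        with pytest.raises(ProfileError):
            reg.register(codec_profile)

    def test_empty_registry_rejects_everything(self, small_record,
                                               codec_profile):
        enc = encode_record(small_record, IDENTITY, codec_profile, render=False)
        empty = ProfileRegistry()
        ses = DecodeSession(IDENTITY, empty)
        assert ses.submit(enc.packet_bytes[0]).code == StatusCode.TAG_ERROR

    def test_unregistered_version_is_tag_error(self, small_record,
                                               codec_profile, registry):
        other = CodecProfile(version=9, secret=bytes(reversed(range(32))),
                             schema=codec_profile.schema,
                             tokenizer=codec_profile.tokenizer)
        enc = encode_record(small_record, IDENTITY, other, render=False)
        assert fresh_session(registry).submit(enc.packet_bytes[0]).code == \
            StatusCode.TAG_ERROR

    def test_two_versions_decode_in_one_session(self, small_record,
                                                gen_profile, codec_profile):
        other_rec = generate_record(gen_profile, 103)
        v2 = CodecProfile(version=2, secret=bytes(reversed(range(32))),
                          schema=codec_profile.schema,
                          tokenizer=codec_profile.tokenizer)
        reg = ProfileRegistry().register(codec_profile).register(v2)
        ses = DecodeSession(IDENTITY, reg)
        enc1 = encode_record(small_record, IDENTITY, codec_profile, render=False)
        enc2 = encode_record(other_rec, IDENTITY, v2, render=False)
        raws = enc1.packet_bytes + enc2.packet_bytes
        random.Random(0).shuffle(raws)
        finished = [r for r in (ses.submit(x) for x in raws)
                    if r.code == StatusCode.FINISHED]
        payloads = [r.payload for r in finished]
        assert small_record in payloads and other_rec in payloads


def test_submit_scan_functional_wrapper(small_record, codec_profile, registry):
    enc = encode_record(small_record, IDENTITY, codec_profile, render=False)
    ses = DecodeSession(IDENTITY, registry)
    res = submit_scan(ses, enc.packet_bytes[0], registry)
    assert res.code == StatusCode.FINISHED
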