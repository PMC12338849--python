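"""Header framing, transaction-date arithmetic and subpacket counting."""

import datetime

import pytest
from hypothesis import given
from hypothesis import strategies as st

from qrstab import (
    CapacityExceededError,
    EmptyMessageError,
    FramingError,
    MessageHeader,
    RangeError,
    compute_count,
    encode_transaction,
    pack_header,
    unpack_header,
)
from qrstab.protocol import chunk_body

valid_headers = st.builds(
    MessageHeader,
    version=st.integers(0, 255),
    fingerprint=st.integers(0, 0xFFFF),
    transaction=st.integers(0, 0xFFFF),
    count=st.integers(1, 15),
    seq=st.just(0),
).flatmap(lambda h: st.integers(0, h.count - 1).map(
    lambda s: MessageHeader(h.version, h.fingerprint, h.transaction,
                            h.count, s)))


def test_zero_header_layout():
    h = MessageHeader(version=0, fingerprint=0, transaction=0, count=1, seq=0)
    assert pack_header(h) == bytes([0, 0, 0, 0, 0, 0x10])


def test_pack_is_six_bytes_and_round_trips():
    h = MessageHeader(version=1, fingerprint=0xBEEF, transaction=745,
                      count=2, seq=1)
    raw = pack_header(h)
    assert len(raw) == 6
    assert unpack_header(raw) == h


@given(valid_headers)
def test_pack_matches_bit_concatenation_oracle(h):
    """Independent oracle: concatenate the five fields as a bit string."""
    bits = (format(h.version, "08b") + format(h.fingerprint, "016b")
            + format(h.transaction, "016b") + format(h.count, "04b")
            + format(h.seq, "04b"))
    expected = int(bits, 2).to_bytes(6, "big")
    assert pack_header(h) == expected
    assert unpack_header(expected) == h


def test_unpack_reads_only_first_six_bytes():
    h = MessageHeader(version=9, fingerprint=1, transaction=2, count=3, seq=2)
    assert unpack_header(pack_header(h) + b"tail-bytes") == h


@pytest.mark.parametrize("raw", [b"", b"\x00" * 5])
def test_short_input_is_framing_error(raw):
    with pytest.raises(FramingError):
        unpack_header(raw)


def test_zero_count_nibble_rejected():
    for low_nibble in range(16):
        raw = bytes([1, 0, 0, 0, 0, low_nibble])  # count nibble == 0
        with pytest.raises(FramingError):
            unpack_header(raw)


def test_seq_not_below_count_rejected():
    raw = bytes([1, 0, 0, 0, 0, (2 << 4) | 2])  # seq == count
    with pytest.raises(FramingError):
        unpack_header(raw)


@pytest.mark.parametrize("field,value", [
    ("version", 256), ("fingerprint", -1), ("transaction", 70000),
    ("count", 0), ("count", 16), ("seq", 5),
])
def test_out_of_range_fields_name_the_field(field, value):
    kwargs = dict(version=0, fingerprint=0, transaction=0, count=5, seq=0)
    kwargs[field] = value
    with pytest.raises(RangeError, match=field):
        MessageHeader(**kwargs)


class TestTransactionEncoding:
    EPOCH = datetime.date(2020, 1, 1)

    def test_same_day_is_zero(self):
        assert encode_transaction(self.EPOCH, self.EPOCH) == 0

    def test_leap_year_offset(self):
        # independent oracle: the standard library's date arithmetic
        adm = datetime.date(2022, 1, 16)
        assert (adm - self.EPOCH).days == 746
        assert encode_transaction(adm, self.EPOCH) == 746

    def test_overflow_day_rejected(self):
        # calendar oracle: day 65535 is 2199-06-06, the last representable
        last_ok = self.EPOCH + datetime.timedelta(days=65535)
        assert last_ok == datetime.date(2199, 6, 6)
        assert encode_transaction(last_ok, self.EPOCH) == 65535
        with pytest.raises(RangeError):
            encode_transaction(datetime.date(2199, 6, 7), self.EPOCH)

    def test_admission_before_epoch_rejected(self):
        with pytest.raises(RangeError):
            encode_transaction(datetime.date(2019, 12, 31), self.EPOCH)


class TestComputeCount:
    def test_exactly_one_full_payload(self):
        assert compute_count(1267, 1273, 6) == 1

    def test_one_byte_over(self):
        assert compute_count(1268, 1273, 6) == 2

    def test_matches_greedy_slicing_oracle(self):
        data = b"x" * 19005  # 15 * 1267, the widest legal body
        for n in range(1, 19006, 13):
            sliced = [data[:n][i: i + 1267] for i in range(0, n, 1267)]
            assert compute_count(n, 1273, 6) == len(sliced)

    def test_empty_body_rejected(self):
        with pytest.raises(EmptyMessageError):
            compute_count(0, 1273, 6)

    def test_over_fifteen_packets_rejected(self):
        assert compute_count(15 * 1267, 1273, 6) == 15
        with pytest.raises(CapacityExceededError):
            compute_count(15 * 1267 + 1, 1273, 6)

    @given(st.integers(1, 30000), st.integers(7, 3000))
    def test_monotonicity(self, body_len, capacity):
        try:
            c = compute_count(body_len, capacity, 6)
        except CapacityExceededError:
            return
        try:
            assert compute_count(body_len + 1, capacity, 6) >= c
        except CapacityExceededError:
            pass
        assert compute_count(body_len, capacity + 1, 6) <= c


@given(st.binary(min_size=1, max_size=6000), st.integers(100, 1400))
def test_chunking_partitions_exactly(body, capacity):
    try:
        chunks = chunk_body(body, capacity)
    except CapacityExceededError:
        return
    assert b"".join(chunks) == body
    assert all(len(c) == capacity - 6 for c in chunks[:-1])
    assert 1 <= len(chunks[-1]) <= capacity - 6
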