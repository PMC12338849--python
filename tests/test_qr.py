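"""QR geometry, capacity tables, symbol codec and the split/merge layer."""

import random

import numpy as np
import pytest

from qrstab import (
    QRConfig,
    RangeError,
    ScanError,
    merge_packets,
    print_edge_cm,
    print_edge_inches,
    qr_capacity,
    qr_modules,
    read_qr,
    render_qr,
    split_body,
)
from qrstab.protocol import QRPacket, MessageHeader
from qrstab.qr import decode_matrix, encode_matrix, matrix_from_image, tables


class TestGeometry:
    def test_module_counts(self):
        assert qr_modules(25) == 117
        assert qr_modules(40) == 177
        assert qr_modules(1) == 21

    def test_version_out_of_range(self):
        for v in (0, 41):
            with pytest.raises(RangeError):
                qr_modules(v)

    def test_print_edges(self):
        v25 = QRConfig(version=25)
        assert print_edge_inches(v25) == pytest.approx(2.5)
        assert print_edge_inches(QRConfig(version=40)) == pytest.approx(3.7)
        assert print_edge_inches(v25, with_redundancy=True) == pytest.approx(3.0)
        assert print_edge_cm(v25, with_redundancy=True) == pytest.approx(7.62)


class TestCapacity:
    def test_study_symbol_capacity(self):
        assert qr_capacity(25, "L") == 1273

    def test_smallest_symbol_capacity(self):
        assert qr_capacity(1, "H") == 7

    def test_published_extremes(self):
        assert qr_capacity(40, "L") == 2953
        assert qr_capacity(40, "H") == 1273

    def test_non_increasing_in_ec_level(self):
        for v in range(1, 41):
            caps = [qr_capacity(v, e) for e in ("L", "M", "Q", "H")]
            assert caps == sorted(caps, reverse=True)

    def test_layout_consistency_with_remainder_schedule(self):
        """Free modules mod 8 must reproduce the published remainder bits —
        a strong joint check on the alignment and function-pattern layout."""
        published = [0] + [7] * 5 + [0] * 7 + [3] * 7 + [4] * 7 + [3] * 7 + [0] * 6
        for v in range(1, 41):
            assert tables.remainder_bits(v) == published[v - 1]


class TestSymbolCodec:
    @pytest.mark.parametrize("version,ec", [(1, "L"), (1, "H"), (3, "M"),
                                            (7, "Q"), (10, "L"), (25, "L")])
    def test_matrix_round_trip(self, version, ec):
        cap = qr_capacity(version, ec)
        for size in {1, cap // 2, cap}:
            payload = random.Random(size + version).randbytes(size)
            assert decode_matrix(encode_matrix(payload, version, ec)) == payload

    def test_full_capacity_boundary_at_study_config(self):
        payload = random.Random(1273).randbytes(1273)
        assert decode_matrix(encode_matrix(payload, 25, "L")) == payload

    def test_all_masks_decodable(self):
        payload = b"mask sweep payload"
        for mask in range(8):
            m = encode_matrix(payload, 2, "M", mask=mask)
            assert decode_matrix(m) == payload

    def test_module_errors_within_budget_corrected(self):
        payload = random.Random(9).randbytes(600)
        m = encode_matrix(payload, 25, "L")
        rng = random.Random(10)
        for _ in range(10):
            m[rng.randrange(117), rng.randrange(117)] ^= True
        assert decode_matrix(m) == payload


class TestImageRoundTrip:
    def _packet(self, body: bytes, count=1, seq=0) -> QRPacket:
        return QRPacket(MessageHeader(1, 0xABCD, 745, count, seq), body)

    def test_render_then_read(self):
        pkt = self._packet(random.Random(3).randbytes(200))
        img = render_qr(pkt, QRConfig())
        assert read_qr(img) == pkt.to_bytes()

    def test_four_pixel_modules_survive_rasterization(self):
        # full-capacity symbol at the print premise of 4 px per module
        pkt = self._packet(random.Random(4).randbytes(1273 - 6))
        img = render_qr(pkt, QRConfig(module_px=4))
        assert read_qr(img) == pkt.to_bytes()

    def test_blank_image_is_scan_error(self):
        from PIL import Image

        with pytest.raises(ScanError):
            matrix_from_image(Image.new("L", (200, 200), 255))

    def test_noise_image_is_scan_error(self):
        from PIL import Image

        noise = (np.random.default_rng(0).random((90, 90)) * 255).astype("u1")
        with pytest.raises(ScanError):
            read_qr(Image.fromarray(noise, "L"))


class TestSplitMerge:
    CFG = QRConfig()

    def test_single_packet(self):
        pkts = split_body(b"\x01" * 100, self.CFG, version=1, transaction=9)
        assert len(pkts) == 1
        assert pkts[0].header.seq == 0 and pkts[0].header.count == 1

    def test_one_byte_over_boundary(self):
        pkts = split_body(b"z" * 1268, self.CFG, version=1, transaction=9)
        assert [len(p.body) for p in pkts] == [1267, 1]

    def test_merge_inverts_split_any_order(self):
        rng = random.Random(6)
        for size in (1, 1267, 1268, 5000, 15000):
            body = rng.randbytes(size)
            pkts = split_body(body, self.CFG, version=1, transaction=1)
            shuffled = pkts[:]
            rng.shuffle(shuffled)
            assert merge_packets(shuffled) == body

    def test_headers_differ_only_in_seq_and_tag(self):
        pkts = split_body(b"q" * 4000, self.CFG, version=3, transaction=77,
                          fingerprint_fn=lambda c: len(c) % 65536)
        assert len({p.header.transaction for p in pkts}) == 1
        assert len({p.header.count for p in pkts}) == 1
        assert [p.header.seq for p in pkts] == list(range(len(pkts)))
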