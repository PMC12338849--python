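"""Compression-pipeline benchmarking on record corpora.

For each record the five pipeline combinations are applied to identical
input and the compression ratio (original minified-JSON UTF-8 bytes divided
by compressed bytes) is recorded:

* ``gzip`` — deflate over the minified JSON text (the traditional baseline)
* ``serial`` — binary serialization alone, plain text fields
* ``serial_gzip`` — serialization then deflate
* ``serial_bpe`` — serialization with tokenized text fields
* ``serial_bpe_gzip`` — the full pipeline (tokenize + serialize + deflate)

Every combination is verified to round-trip back to the source record
before its size counts. Aggregates report both the mean of per-record
ratios (the headline statistic) and the ratio of byte totals, which differ
whenever size and ratio correlate; paired two-sided t-tests compare named
combination pairs on the per-record ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

from .crypto import CodecProfile, gzip_compress, gzip_decompress
from .errors import RangeError
from .protocol import HEADER_LEN, compute_count
from .qr_transport import QRConfig
from .serialization import (
    deserialize_record,
    minified_json_bytes,
    serialize_record,
)

__all__ = ["BenchmarkResult", "compression_ratio", "run_combos",
           "qr_count_distribution", "COMBOS"]

COMBOS = ("gzip", "serial", "serial_gzip", "serial_bpe", "serial_bpe_gzip")

#: combination pairs compared by paired t-test
TEST_PAIRS = (
    ("serial_bpe_gzip", "gzip"),
    ("serial_gzip", "serial"),
    ("serial_bpe_gzip", "serial_gzip"),
)


def compression_ratio(orig_bytes: int, comp_bytes: int) -> float:
    """Original size over compressed size (>1 means the pipeline shrank it)."""
    if comp_bytes < 1:
        raise RangeError(f"compressed size must be >= 1, got {comp_bytes}")
    if orig_bytes < 0:
        raise RangeError(f"original size must be >= 0, got {orig_bytes}")
    return orig_bytes / comp_bytes


@dataclass
class BenchmarkResult:
    """Per-record sizes/ratios for every combination, plus aggregates."""

    original_bytes: list[int]
    combo_bytes: dict[str, list[int]]
    combo_ratios: dict[str, list[float]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.combo_ratios:
            self.combo_ratios = {
                name: [compression_ratio(o, c)
                       for o, c in zip(self.original_bytes, sizes)]
                for name, sizes in self.combo_bytes.items()
            }

    def mean_ratio(self, combo: str) -> float:
        return float(np.mean(self.combo_ratios[combo]))

    def ratio_of_totals(self, combo: str) -> float:
        return compression_ratio(sum(self.original_bytes),
                                 sum(self.combo_bytes[combo]))

    def summary(self) -> dict:
        out = {}
        for combo in self.combo_bytes:
            r = np.asarray(self.combo_ratios[combo])
            out[combo] = {
                "mean_ratio": float(r.mean()),
                "median_ratio": float(np.median(r)),
                "iqr": (float(np.percentile(r, 25)), float(np.percentile(r, 75))),
                "min_ratio": float(r.min()),
                "max_ratio": float(r.max()),
                "ratio_of_totals": self.ratio_of_totals(combo),
                "mean_bytes": float(np.mean(self.combo_bytes[combo])),
            }
        return out

    def paired_tests(self) -> dict:
        out = {}
        for a, b in TEST_PAIRS:
            if a in self.combo_ratios and b in self.combo_ratios:
                t = _stats.ttest_rel(self.combo_ratios[a], self.combo_ratios[b])
                out[f"{a}_vs_{b}"] = {"t": float(t.statistic),
                                      "p": float(t.pvalue)}
        return out


def run_combos(records: list[dict], profile: CodecProfile) -> BenchmarkResult:
    """Apply every combination to every record, verifying round-trips."""
    if profile.tokenizer is None:
        raise RangeError("profile needs a trained tokenizer for BPE combos")
    schema = profile.schema
    tok = profile.tokenizer
    original: list[int] = []
    sizes: dict[str, list[int]] = {c: [] for c in COMBOS}

    for i, rec in enumerate(records):
        json_bytes = minified_json_bytes(rec)
        original.append(len(json_bytes))

        gz = gzip_compress(json_bytes)
        assert gzip_decompress(gz) == json_bytes
        sizes["gzip"].append(len(gz))

        serial = serialize_record(rec, schema, tok=None)
        _verify(deserialize_record(serial, schema, tok=None), rec, i, "serial")
        sizes["serial"].append(len(serial))
        sizes["serial_gzip"].append(len(gzip_compress(serial)))

        serial_bpe = serialize_record(rec, schema, tok=tok)
        _verify(deserialize_record(serial_bpe, schema, tok=tok), rec, i,
                "serial_bpe")
        sizes["serial_bpe"].append(len(serial_bpe))
        sizes["serial_bpe_gzip"].append(len(gzip_compress(serial_bpe)))

    return BenchmarkResult(original_bytes=original, combo_bytes=sizes)


def _verify(decoded: dict, rec: dict, index: int, combo: str) -> None:
    if decoded != rec:
        raise AssertionError(
            f"round-trip failure in combo {combo!r} at record index {index}")


def qr_count_distribution(result: BenchmarkResult,
                          cfg: QRConfig | None = None,
                          combo: str = "serial_bpe_gzip") -> dict:
    """Histogram + CDF of QR symbols per record for the final pipeline."""
    cfg = cfg or QRConfig()
    counts = [compute_count(nbytes, cfg.capacity, HEADER_LEN)
              for nbytes in result.combo_bytes[combo]]
    hist: dict[int, int] = {}
    for c in counts:
        hist[c] = hist.get(c, 0) + 1
    n = len(counts)
    cdf = {}
    acc = 0
    for c in sorted(hist):
        acc += hist[c]
        cdf[c] = acc / n
    return {"histogram": hist, "cdf": cdf, "counts": counts}
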