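"""Subword tokenizers mapping free text to compact 2-byte token ids.

Two trainable algorithms are provided, mirroring the two families commonly
used for languages without word delimiters:

* **BPE** — greedy pair merging: starting from raw bytes, the most frequent
  adjacent symbol pair is merged into a new vocabulary entry until the
  vocabulary is full or no pair repeats.
* **Unigram** — a probabilistic segmentation model: a large candidate set of
  substrings is scored by Viterbi EM and pruned to the vocabulary size;
  encoding picks the maximum-likelihood segmentation.

Both operate on UTF-8 *bytes* and always retain the 256 single-byte pieces,
so any string — including characters never seen in training — round-trips
exactly (byte fallback). Vocabulary ids stay below 65536 so every token
packs into a fixed 2-byte big-endian unit.
"""

from __future__ import annotations

import json
import math
import struct
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from ._blake3 import blake3
from .errors import FramingError, RangeError, TrainingError

__all__ = [
    "TokenizerModel",
    "train_tokenizer",
    "pack_tokens",
    "unpack_tokens",
    "MAX_VOCAB",
]

MAX_VOCAB = 65535  # every id must fit a 2-byte unit

_BYTE_FLOOR_LOGP = -30.0  # fallback score keeping single bytes a last resort


@dataclass
class TokenizerModel:
    """A trained subword vocabulary; ids index into `pieces`.

    `pieces[i]` is the byte string the id expands to; ids 0-255 are always
    the raw bytes. For BPE the merge ranks drive encoding; for unigram the
    per-piece log probabilities do.
    """

    algorithm: str
    pieces: list[bytes]
    merges: list[tuple[int, int]] = field(default_factory=list)
    logprobs: list[float] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.algorithm not in ("bpe", "unigram"):
            raise TrainingError(f"unknown algorithm {self.algorithm!r}")
        if len(self.pieces) > MAX_VOCAB + 1:
            raise TrainingError(
                f"{len(self.pieces)} pieces exceed the 2-byte id space")
        self._merge_rank = {pair: i for i, pair in enumerate(self.merges)}
        self._max_piece_len = max((len(p) for p in self.pieces), default=1)
        self._piece_to_id = {p: i for i, p in enumerate(self.pieces)}

    @property
    def vocab_size(self) -> int:
        return len(self.pieces)

    # -- encoding -----------------------------------------------------------

    def encode(self, text: str) -> list[int]:
        data = text.encode("utf-8")
        if not data:
            return []
        if self.algorithm == "bpe":
            return self._encode_bpe(data)
        return self._encode_unigram(data)

    def decode(self, ids: list[int]) -> str:
        try:
            return b"".join(self.pieces[i] for i in ids).decode("utf-8")
        except IndexError as exc:
            raise RangeError(f"token id outside vocabulary: {exc}") from exc

    def _encode_bpe(self, data: bytes) -> list[int]:
        syms = list(data)
        ranks = self._merge_rank
        while len(syms) > 1:
            best_rank = None
            best_pos = -1
            for i in range(len(syms) - 1):
                r = ranks.get((syms[i], syms[i + 1]))
                if r is not None and (best_rank is None or r < best_rank):
                    best_rank, best_pos = r, i
            if best_rank is None:
                break
            pair = (syms[best_pos], syms[best_pos + 1])
            new_id = 256 + best_rank
            # merge every occurrence of this pair, left to right
            out = []
            i = 0
            while i < len(syms):
                if i + 1 < len(syms) and (syms[i], syms[i + 1]) == pair:
                    out.append(new_id)
                    i += 2
                else:
                    out.append(syms[i])
                    i += 1
            syms = out
        return syms

    def _encode_unigram(self, data: bytes) -> list[int]:
        n = len(data)
        kmax = self._max_piece_len
        p2i = self._piece_to_id
        lp = self.logprobs
        best = [-math.inf] * (n + 1)
        back: list[tuple[int, int]] = [(0, 0)] * (n + 1)
        best[0] = 0.0
        for i in range(1, n + 1):
            for k in range(1, min(kmax, i) + 1):
                pid = p2i.get(data[i - k: i])
                if pid is None:
                    continue
                score = best[i - k] + lp[pid]
                if score > best[i]:
                    best[i] = score
                    back[i] = (i - k, pid)
        ids: list[int] = []
        i = n
        while i > 0:
            j, pid = back[i]
            ids.append(pid)
            i = j
        ids.reverse()
        return ids

    # -- persistence --------------------------------------------------------

    def save(self, directory) -> None:
        """Write `model.json` plus a `metadata.json` sidecar."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        doc = {
            "algorithm": self.algorithm,
            "pieces": [p.hex() for p in self.pieces],
            "merges": self.merges,
            "logprobs": self.logprobs,
        }
        (d / "model.json").write_text(json.dumps(doc), "utf-8")
        (d / "metadata.json").write_text(
            json.dumps(self.metadata, indent=2, sort_keys=True), "utf-8")

    @classmethod
    def load(cls, directory) -> "TokenizerModel":
        d = Path(directory)
        doc = json.loads((d / "model.json").read_text("utf-8"))
        meta_path = d / "metadata.json"
        meta = json.loads(meta_path.read_text("utf-8")) if meta_path.exists() else {}
        return cls(
            algorithm=doc["algorithm"],
            pieces=[bytes.fromhex(p) for p in doc["pieces"]],
            merges=[tuple(m) for m in doc["merges"]],
            logprobs=doc["logprobs"],
            metadata=meta,
        )


# ---------------------------------------------------------------------------
# 2-byte token packing
# ---------------------------------------------------------------------------

def pack_tokens(ids: list[int]) -> bytes:
    """Fixed 2-byte big-endian unit per token id."""
    for i in ids:
        if not 0 <= i < 65536:
            raise RangeError(f"token id {i} does not fit 2 bytes")
    return struct.pack(f">{len(ids)}H", *ids)


def unpack_tokens(raw: bytes) -> list[int]:
    if len(raw) % 2:
        raise FramingError(f"token stream of {len(raw)} bytes is not a "
                           "whole number of 2-byte units")
    return list(struct.unpack(f">{len(raw) // 2}H", raw))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train_tokenizer(corpus, algorithm: str, vocab_size: int,
                    seed: int = 0) -> TokenizerModel:
    """Train a tokenizer on an iterable of text lines.

    Deterministic for a given corpus, algorithm, vocabulary size and seed
    (the trainers themselves are combinatorial; the seed is recorded in the
    model metadata and reserved for subsampling strategies).
    """
    lines = [ln for ln in corpus if ln]
    if not lines:
        raise TrainingError("training corpus is empty")
    if vocab_size < 256:
        raise TrainingError(f"vocab_size must be >= 256, got {vocab_size}")
    if vocab_size > MAX_VOCAB:
        raise TrainingError(f"vocab_size must be <= {MAX_VOCAB}")

    corpus_hash = blake3("\n".join(lines).encode("utf-8"), 16).hex()
    seqs = Counter(ln.encode("utf-8") for ln in lines)

    if algorithm == "bpe":
        pieces, merges = _train_bpe(seqs, vocab_size)
        model = TokenizerModel("bpe", pieces, merges=merges)
    elif algorithm == "unigram":
        pieces, logprobs = _train_unigram(seqs, vocab_size)
        model = TokenizerModel("unigram", pieces, logprobs=logprobs)
    else:
        raise TrainingError(f"unknown algorithm {algorithm!r}")

    model.metadata = {
        "algorithm": algorithm,
        "vocab_size_requested": vocab_size,
        "vocab_size_actual": model.vocab_size,
        "corpus_lines": len(lines),
        "corpus_hash": corpus_hash,
        "seed": seed,
    }
    return model


def _train_bpe(seqs: Counter, vocab_size: int):
    """Frequency-weighted greedy pair merging over unique byte sequences."""
    pieces: list[bytes] = [bytes([b]) for b in range(256)]
    merges: list[tuple[int, int]] = []

    words = [list(w) for w in seqs]
    freqs = list(seqs.values())

    pair_counts: Counter = Counter()
    pair_where: dict[tuple[int, int], set[int]] = {}
    for wi, w in enumerate(words):
        f = freqs[wi]
        for a, b in zip(w, w[1:]):
            pair_counts[(a, b)] += f
            pair_where.setdefault((a, b), set()).add(wi)

    while len(pieces) < vocab_size and pair_counts:
        # deterministic: highest count, then lowest (left, right) ids
        best = min(pair_counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        if pair_counts[best] < 2:
            break
        new_id = len(pieces)
        pieces.append(pieces[best[0]] + pieces[best[1]])
        merges.append(best)
        for wi in list(pair_where.get(best, ())):
            w = words[wi]
            f = freqs[wi]
            for a, b in zip(w, w[1:]):
                pair_counts[(a, b)] -= f
                if pair_counts[(a, b)] <= 0:
                    del pair_counts[(a, b)]
                s = pair_where.get((a, b))
                if s is not None:
                    s.discard(wi)
            merged = []
            i = 0
            while i < len(w):
                if i + 1 < len(w) and (w[i], w[i + 1]) == best:
                    merged.append(new_id)
                    i += 2
                else:
                    merged.append(w[i])
                    i += 1
            words[wi] = merged
            for a, b in zip(merged, merged[1:]):
                pair_counts[(a, b)] += f
                pair_where.setdefault((a, b), set()).add(wi)
    return pieces, merges


def _train_unigram(seqs: Counter, vocab_size: int, max_piece_len: int = 12,
                   em_iterations: int = 3):
    """Viterbi-EM unigram model over byte substrings.

    Candidates are the frequent substrings up to `max_piece_len` bytes; EM
    alternates maximum-likelihood segmentation of the corpus with relative-
    frequency re-estimation, then prunes to the vocabulary size. The 256
    single-byte pieces are never pruned.
    """
    # candidate harvest, weighted by frequency and length saved
    sub_counts: Counter = Counter()
    for w, f in seqs.items():
        n = len(w)
        for i in range(n):
            for k in range(2, min(max_piece_len, n - i) + 1):
                sub_counts[w[i: i + k]] += f
    seed_size = max((vocab_size - 256) * 3, 1024)
    candidates = [s for s, c in sorted(
        sub_counts.items(),
        key=lambda kv: (-(kv[1] * (len(kv[0]) - 1)), kv[0]))[:seed_size]
        if c >= 2]

    pieces = [bytes([b]) for b in range(256)] + candidates
    total = sum(sub_counts[p] for p in candidates) + 256
    logprobs = [_BYTE_FLOOR_LOGP] * 256 + [
        math.log(max(sub_counts[p], 1) / total) for p in candidates]

    for it in range(em_iterations):
        model = TokenizerModel("unigram", pieces, logprobs=logprobs)
        counts = Counter()
        for w, f in seqs.items():
            for pid in model._encode_unigram(w):
                counts[pieces[pid]] += f
        # M-step over observed pieces; unseen multi-byte candidates drop out
        keep_multi = [p for p in pieces[256:] if counts[p] > 0]
        if it == em_iterations - 1:
            keep_multi = sorted(
                keep_multi, key=lambda p: (-counts[p] * (len(p) - 1), p)
            )[: vocab_size - 256]
        pieces = [bytes([b]) for b in range(256)] + keep_multi
        total = sum(counts[p] for p in keep_multi) + 256
        logprobs = [_BYTE_FLOOR_LOGP if counts[bytes([b])] == 0
                    else math.log(counts[bytes([b])] / total)
                    for b in range(256)]
        logprobs += [math.log(counts[p] / total) for p in keep_multi]
    return pieces, logprobs
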