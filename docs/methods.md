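# Methods

This note records the model behind `qrstab`, the parameters that matter,
the choices made where the design was genuinely open, and what the synthetic
evaluation does and does not demonstrate.

## Protocol model and assumptions

The protocol assumes a *pre-shared trust bundle* (the `CodecProfile`):
a 256-bit secret key, the record schema, the trained tokenizer, a tag epoch
date, and the protocol version byte. Encoder (hospital intranet) and
decoder (public-internet service) synchronize this bundle offline; nothing
from it is ever transmitted inside a QR code. Security therefore rests on
three layers: ChaCha20 confidentiality under the shared key, the schema and
tokenizer acting as additional structural secrets (the binary stream is
meaningless without them), and per-packet identity authentication via a
truncated hash tag.

The threat model is passive capture of printed codes. A 2-byte tag is
deliberately small — the protocol trades tag strength for QR capacity on
the argument that paper distribution makes online brute force impractical;
the false-accept probability of a random forgery is exactly 2⁻¹⁶ and is
verified by exhaustive enumeration of the tag space in the test suite.

## Header and framing

The 6-byte header packs version (8 bits), fingerprint (16), transaction
(16), count (4), seq (4), MSB-first, big-endian, count in the high nibble
of the last byte. Choices the wire format fixes:

* **count is stored raw (1–15); 0 is reserved.** A biased encoding
  (count−1, allowing 16 packets) was rejected: 15 × 1267 bytes ≈ 19 kB of
  ciphertext far exceeds any compressed record the generator or the
  benchmark envelope produces, and an unbiased field removes an off-by-one
  hazard at both ends.
* **Transaction id** is the admission date as a whole-day offset from the
  profile's tag epoch (default 2020-01-01), stored unsigned 16-bit. The
  last representable admission day is epoch + 65535 days (2199-06-06 for
  the default epoch). Two transmissions for the same patient with the same
  admission date share a transaction id; the decoder additionally keys its
  buffers by version, and re-issuing a *modified* record under the same
  transaction is forbidden (see nonce note below).
* All multi-byte integers are big-endian; header length is fixed at 6 for
  version 1 and may be redefined per profile version.

## Nonce derivation (design decision)

The header has no room for a nonce and the stated overhead budget is
2 bytes, so the 64-bit ChaCha20 nonce is *derived*, not transmitted:

```
subkey = blake3_derive_key("qrstab v1 packet nonce derivation", secret)
nonce  = blake3_keyed(subkey, version ‖ transaction_be16 ‖ count)[:8]
```

Both ends compute it identically from material they already share. The
known cost: two different bodies encrypted under the same
(version, transaction, count) triple would reuse a keystream. The encoder
must therefore never re-encode altered content for an existing transaction;
this is documented as a protocol limitation rather than hidden.

Fingerprints are computed over each packet's *ciphertext* chunk plus the
identity string (exact UTF-8 bytes, no Unicode normalization). Hashing
ciphertext is what allows authenticate-before-decrypt on the decoder side.

## Serialization

The seven-section record schema is authored by this project in standard
Avro schema JSON and fingerprinted (hash of canonical JSON) inside the
profile. Two logical types extend it:

* `tokenized-text` string fields are written as packed 2-byte token ids
  when a tokenizer is present, as UTF-8 otherwise. Because the Avro wire
  format of `string` and `bytes` is identical (varint length + payload),
  the same schema document serves the plain and tokenized pipelines — which
  is also what makes the benchmark's "with/without tokenizer" arms exactly
  comparable.
* `epoch-days` int fields hold calendar dates as day offsets from the tag
  epoch, mirroring the transaction encoding; ISO strings at the JSON
  surface.

Tokenized text is stored as a byte string rather than an int array: under
Avro rules an int array would re-inflate frequent large ids to 3-byte
varints, while fixed 2-byte units keep every id at width 2. Optional values
use union-with-null (`allergyHistory`); the repeated sections are arrays
that may be empty. The `base` section carries exactly 10 leaf fields
(age, gender, height, weight, department, hospitalDays, admissionDate,
dischargeDate, nursingLevel, allergyHistory).

## Tokenizers

Both trainers operate on UTF-8 bytes and always retain the 256 single-byte
pieces, so out-of-vocabulary characters degrade to bytes instead of
failing — decoding must reconstruct records exactly, so losslessness is
non-negotiable.

* **BPE**: frequency-weighted greedy pair merging over the deduplicated
  line multiset, deterministic tie-break (highest count, then lowest id
  pair), stopping when the vocabulary is full or no pair repeats.
* **Unigram**: Viterbi-EM over substring candidates up to 12 bytes
  (3 EM iterations, pruning to the vocabulary cap, single-byte pieces
  floored at log-probability −30 so longer pieces win when available).
  This is a compact re-implementation of the unigram family, adequate as a
  comparison arm; it is *not* tuned to competition strength, and in the
  shipped benchmarks BPE dominates it by a wide margin.

Vocabulary ids must stay below 65536 (2-byte units). The full-scale
configuration is a 65535-entry vocabulary; the shipped tests train at
vocabulary 4000 on a 3000-line corpus, which keeps the suite inside a few
minutes while preserving every directional property asserted.

## QR layer

The QR model-2 codec (capacity tables, Reed-Solomon over GF(256) with
polynomial 0x11D, masking, format/version BCH strings) is implemented
in-repo and validated against the published constants: version-25/L
capacity 1273 bytes, version-1/H 7 bytes, version-40/L 2953 bytes, the
117/177 module counts, and the full published remainder-bit schedule
(a joint consistency check of the alignment-pattern table and function
layout). Byte mode is forced; the usable body per symbol is capacity − 6
header bytes — a body budget of 1267 at the default symbol, resolving in
favour of correctness the looser view that compares compressed size to
1273 directly.

The decoder targets clean, axis-aligned rasterizations (this package's own
renderings, screen captures, flatbed scans): binarize, locate the bounding
box, estimate module pitch from the top-left finder run, sample module
centres, then format-decode, unmask, deinterleave and error-correct.
Perspective-distorted camera captures are out of scope. Error correction
is fully implemented (Berlekamp-Massey + Chien search + a GF linear solve
for magnitudes) and exercised by injected-error tests. Format-information
bit placement follows the standard's figure as implemented here; encoder
and decoder share the convention, but interoperability with third-party
scanners has not been verified in this environment.

Print geometry: edge = (modules + 2 × quiet zone) × module pixels / dpi,
times (1 + redundancy) for the designed size. Defaults (v25, 4 px/module,
200 dpi, quiet zone 4, 20 % redundancy) give 2.5 in theoretical and
7.62 cm designed.

## Synthetic data

No real records ship with the package. The generator's defaults emulate a
300-patient benchmark profile: per-section row counts drawn from clipped
gamma envelopes chosen to hit a mean of ≈240 leaf fields per record
(range roughly 90–620) with laboratory rows supplying about two thirds of
fields, and a minified-JSON size averaging ≈7.1 kB (observed batch means
land within a few percent). The tokenizer corpus averages ≈38 characters
and ≈107 UTF-8 bytes per line (CJK-dominant, byte/char ratio ≈2.7), and a
deterministic 9:1 train/test split is provided. Text comes from closed,
seeded pools of synthetic CJK words plus Latin/numeric tokens; corpus and
records share pools, so a corpus-trained tokenizer transfers to record
text — the property every compression benchmark here depends on.

What this does *not* show: real clinical text has vocabulary growth,
typos, and cross-section correlations the pools lack, so absolute
compression ratios on real data will differ (the pool-based repetition
tends to flatter deflate in particular). The benchmarks therefore assert
orderings and bounds — full pipeline > gzip-only, serialization alone > 1,
BPE token economy ≤ unigram's × 1.05 — not absolute ratio values.

## Numerical and degenerate-input choices

* gzip output is made byte-reproducible by fixing the header (mtime 0,
  XFL 2, OS 255) and compression level 9.
* Empty message bodies are rejected at packetization (`EmptyMessageError`);
  a body of exactly n × 1267 bytes yields n full packets, never an empty
  trailing packet.
* `duplicated` requires a byte-identical repeat; the same seq with
  different bytes is classified `exception` (possible tampering), as is a
  count disagreement within one transaction.
* Status precedence is framing error > authentication failure >
  duplication > completion: the cheapest check fails first, and nothing
  about buffer state is revealed to unauthenticated packets.
* Benchmark aggregates report both mean-of-ratios (headline) and
  ratio-of-totals; they differ whenever size correlates with ratio, and the
  test suite pins the distinction (7095/1048 ≈ 6.77 is not the mean of
  per-record ratios).

## Problem sizes in the shipped suite

Tokenizer training: 3000 corpus lines, vocabulary 4000 (BPE ≈ 25 s,
unigram ≈ 6 s on one CPU). Benchmarks: 300 records. End-to-end round
trips: 200 records at the packet level plus image-level render/scan checks
on representative symbols including a full-capacity 1273-byte payload.
These are the package's default desk-scale settings; all are plain
function arguments and scale up unchanged.

## Known limitations

* Keystream reuse if an encoder re-issues modified content under an
  unchanged (version, transaction, count) — by construction; see above.
* One transmission is capped at 15 packets (≈19 kB ciphertext).
* The unigram trainer is a minimal EM implementation, suitable as a
  baseline arm only.
* The QR decoder does not handle perspective distortion or uneven
  illumination; third-party scanner interop is untested here.
* A 2-byte tag authenticates the scanner's identity binding, not message
  integrity in the cryptographic sense; integrity rests on the 2⁻¹⁶ bound
  plus physical possession of the printed report.
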