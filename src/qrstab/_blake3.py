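"""Pure-Python BLAKE3 (hash, keyed hash, key derivation, arbitrary output length).

Implements the published BLAKE3 construction: 1024-byte chunks compressed in
64-byte blocks by a 7-round ChaCha-style permutation, chunk chaining values
merged in a binary tree, and an extendable root output. Only what this
package needs — one-shot hashing of byte strings — is exposed; there is no
streaming API.
"""

from __future__ import annotations

OUT_LEN = 32
KEY_LEN = 32
BLOCK_LEN = 64
CHUNK_LEN = 1024

CHUNK_START = 1 << 0
CHUNK_END = 1 << 1
PARENT = 1 << 2
ROOT = 1 << 3
KEYED_HASH = 1 << 4
DERIVE_KEY_CONTEXT = 1 << 5
DERIVE_KEY_MATERIAL = 1 << 6

IV = (
    0x6A09E667, 0xBB67AE85, 0x3C6EF372, 0xA54FF53A,
    0x510E527F, 0x9B05688C, 0x1F83D9AB, 0x5BE0CD19,
)

_MSG_PERMUTATION = (2, 6, 3, 10, 7, 0, 4, 13, 1, 11, 12, 5, 9, 14, 15, 8)

_MASK = 0xFFFFFFFF


def _rotr(x: int, n: int) -> int:
    return ((x >> n) | (x << (32 - n))) & _MASK


def _g(state: list[int], a: int, b: int, c: int, d: int, mx: int, my: int) -> None:
    state[a] = (state[a] + state[b] + mx) & _MASK
    state[d] = _rotr(state[d] ^ state[a], 16)
    state[c] = (state[c] + state[d]) & _MASK
    state[b] = _rotr(state[b] ^ state[c], 12)
    state[a] = (state[a] + state[b] + my) & _MASK
    state[d] = _rotr(state[d] ^ state[a], 8)
    state[c] = (state[c] + state[d]) & _MASK
    state[b] = _rotr(state[b] ^ state[c], 7)


def _round(state: list[int], m: list[int]) -> None:
    # Columns, then diagonals.
    _g(state, 0, 4, 8, 12, m[0], m[1])
    _g(state, 1, 5, 9, 13, m[2], m[3])
    _g(state, 2, 6, 10, 14, m[4], m[5])
    _g(state, 3, 7, 11, 15, m[6], m[7])
    _g(state, 0, 5, 10, 15, m[8], m[9])
    _g(state, 1, 6, 11, 12, m[10], m[11])
    _g(state, 2, 7, 8, 13, m[12], m[13])
    _g(state, 3, 4, 9, 14, m[14], m[15])


def _permute(m: list[int]) -> list[int]:
    return [m[i] for i in _MSG_PERMUTATION]


def compress(
    cv: list[int],
    block_words: list[int],
    counter: int,
    block_len: int,
    flags: int,
) -> list[int]:
    """The BLAKE3 compression function; returns 16 output words."""
    state = [
        cv[0], cv[1], cv[2], cv[3],
        cv[4], cv[5], cv[6], cv[7],
        IV[0], IV[1], IV[2], IV[3],
        counter & _MASK, (counter >> 32) & _MASK, block_len, flags,
    ]
    m = list(block_words)
    for _ in range(7):
        _round(state, m)
        m = _permute(m)
    for i in range(8):
        state[i] ^= state[i + 8]
        state[i + 8] ^= cv[i]
    return state


def _words_from_block(block: bytes) -> list[int]:
    if len(block) < BLOCK_LEN:
        block = block + b"\x00" * (BLOCK_LEN - len(block))
    return [int.from_bytes(block[i: i + 4], "little") for i in range(0, BLOCK_LEN, 4)]


class _Output:
    """A deferred compression whose root form can squeeze arbitrary bytes."""

    __slots__ = ("cv", "block_words", "counter", "block_len", "flags")

    def __init__(self, cv, block_words, counter, block_len, flags):
        self.cv = cv
        self.block_words = block_words
        self.counter = counter
        self.block_len = block_len
        self.flags = flags

    def chaining_value(self) -> list[int]:
        return compress(self.cv, self.block_words, self.counter,
                        self.block_len, self.flags)[:8]

    def root_bytes(self, length: int) -> bytes:
        out = bytearray()
        counter = 0
        while len(out) < length:
            words = compress(self.cv, self.block_words, counter,
                             self.block_len, self.flags | ROOT)
            for w in words:
                out += w.to_bytes(4, "little")
            counter += 1
        return bytes(out[:length])


def _chunk_output(chunk: bytes, key_words: list[int], chunk_counter: int,
                  flags: int) -> _Output:
    """Compress one ≤1024-byte chunk down to its output state."""
    blocks = [chunk[i: i + BLOCK_LEN] for i in range(0, len(chunk), BLOCK_LEN)]
    if not blocks:
        blocks = [b""]
    cv = list(key_words)
    for i, block in enumerate(blocks[:-1]):
        block_flags = flags | (CHUNK_START if i == 0 else 0)
        cv = compress(cv, _words_from_block(block), chunk_counter,
                      BLOCK_LEN, block_flags)[:8]
    last = blocks[-1]
    last_flags = flags | CHUNK_END | (CHUNK_START if len(blocks) == 1 else 0)
    return _Output(cv, _words_from_block(last), chunk_counter, len(last), last_flags)


def _parent_output(left_cv: list[int], right_cv: list[int],
                   key_words: list[int], flags: int) -> _Output:
    return _Output(list(key_words), left_cv + right_cv, 0, BLOCK_LEN,
                   flags | PARENT)


def _hash_tree(data: bytes, key_words: list[int], flags: int) -> _Output:
    """Iterative chunk loop with a chaining-value stack (reference layout)."""
    n_chunks = max(1, (len(data) + CHUNK_LEN - 1) // CHUNK_LEN)
    if n_chunks == 1:
        return _chunk_output(data, key_words, 0, flags)
    stack: list[list[int]] = []
    for counter in range(n_chunks):
        chunk = data[counter * CHUNK_LEN: (counter + 1) * CHUNK_LEN]
        cv = _chunk_output(chunk, key_words, counter, flags).chaining_value()
        # Merge completed subtrees: total chunks so far has a trailing-zero
        # count equal to the number of parents to fold.
        total = counter + 1
        if total < n_chunks:
            while total & 1 == 0:
                cv = _parent_output(stack.pop(), cv, key_words,
                                    flags).chaining_value()
                total >>= 1
            stack.append(cv)
        else:
            # Last chunk: fold everything, keeping the final parent deferred.
            while len(stack) > 1:
                cv = _parent_output(stack.pop(), cv, key_words,
                                    flags).chaining_value()
            return _parent_output(stack.pop(), cv, key_words, flags)
    raise AssertionError("unreachable")


def _key_words(key: bytes) -> list[int]:
    if len(key) != KEY_LEN:
        raise ValueError(f"BLAKE3 key must be {KEY_LEN} bytes, got {len(key)}")
    return [int.from_bytes(key[i: i + 4], "little") for i in range(0, KEY_LEN, 4)]


def blake3(data: bytes, length: int = OUT_LEN) -> bytes:
    """Hash `data`, returning `length` output bytes."""
    return _hash_tree(data, list(IV), 0).root_bytes(length)


def blake3_keyed(key: bytes, data: bytes, length: int = OUT_LEN) -> bytes:
    """Keyed hash (MAC) of `data` under a 32-byte key."""
    return _hash_tree(data, _key_words(key), KEYED_HASH).root_bytes(length)


def blake3_derive_key(context: str, key_material: bytes,
                      length: int = OUT_LEN) -> bytes:
    """Derive a subkey from `key_material` bound to a context string."""
    context_cv = _hash_tree(context.encode("utf-8"), list(IV),
                            DERIVE_KEY_CONTEXT).root_bytes(KEY_LEN)
    return _hash_tree(key_material, _key_words(context_cv),
                      DERIVE_KEY_MATERIAL).root_bytes(length)
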