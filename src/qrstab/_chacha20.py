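"""Pure-Python ChaCha20 stream cipher, original (djb) 64-bit-nonce variant.

State layout: 4 constant words, 8 key words, a 64-bit block counter in words
12-13, and a 64-bit nonce in words 14-15, all little-endian; 20 rounds
(10 column/diagonal double rounds). The IETF variant differs only in splitting
words 12-15 as a 32-bit counter plus 96-bit nonce; the core permutation is
identical, which the test suite exploits for vector checks.
"""

from __future__ import annotations

_MASK = 0xFFFFFFFF

_CONSTANTS = (0x61707865, 0x3320646E, 0x79622D32, 0x6B206574)  # "expand 32-byte k"

KEY_LEN = 32
NONCE_LEN = 8


def _rotl(x: int, n: int) -> int:
    return ((x << n) | (x >> (32 - n))) & _MASK


def _quarter(s: list[int], a: int, b: int, c: int, d: int) -> None:
    s[a] = (s[a] + s[b]) & _MASK
    s[d] = _rotl(s[d] ^ s[a], 16)
    s[c] = (s[c] + s[d]) & _MASK
    s[b] = _rotl(s[b] ^ s[c], 12)
    s[a] = (s[a] + s[b]) & _MASK
    s[d] = _rotl(s[d] ^ s[a], 8)
    s[c] = (s[c] + s[d]) & _MASK
    s[b] = _rotl(s[b] ^ s[c], 7)


def block(state16: list[int]) -> bytes:
    """One 64-byte keystream block from a full 16-word input state."""
    w = list(state16)
    for _ in range(10):
        _quarter(w, 0, 4, 8, 12)
        _quarter(w, 1, 5, 9, 13)
        _quarter(w, 2, 6, 10, 14)
        _quarter(w, 3, 7, 11, 15)
        _quarter(w, 0, 5, 10, 15)
        _quarter(w, 1, 6, 11, 12)
        _quarter(w, 2, 7, 8, 13)
        _quarter(w, 3, 4, 9, 14)
    out = bytearray()
    for i in range(16):
        out += ((w[i] + state16[i]) & _MASK).to_bytes(4, "little")
    return bytes(out)


def _initial_state(key: bytes, nonce: bytes, counter: int) -> list[int]:
    if len(key) != KEY_LEN:
        raise ValueError(f"ChaCha20 key must be {KEY_LEN} bytes, got {len(key)}")
    if len(nonce) != NONCE_LEN:
        raise ValueError(
            f"ChaCha20 nonce must be {NONCE_LEN} bytes (64-bit variant), "
            f"got {len(nonce)}"
        )
    kw = [int.from_bytes(key[i: i + 4], "little") for i in range(0, 32, 4)]
    nw = [int.from_bytes(nonce[i: i + 4], "little") for i in range(0, 8, 4)]
    return [
        *_CONSTANTS, *kw,
        counter & _MASK, (counter >> 32) & _MASK,
        nw[0], nw[1],
    ]


def keystream(key: bytes, nonce: bytes, length: int, counter: int = 0) -> bytes:
    out = bytearray()
    while len(out) < length:
        out += block(_initial_state(key, nonce, counter))
        counter += 1
    return bytes(out[:length])


def xor_stream(data: bytes, key: bytes, nonce: bytes, counter: int = 0) -> bytes:
    """Encrypt or decrypt: XOR `data` with the keystream. Length-preserving."""
    ks = keystream(key, nonce, len(data), counter)
    return bytes(a ^ b for a, b in zip(data, ks))
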