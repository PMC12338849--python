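"""Reed-Solomon codec over GF(2^8) with the QR polynomial x^8+x^4+x^3+x^2+1.

Encoding appends the remainder of polynomial division by the generator
(roots a^0 .. a^(n-1)). Decoding runs Berlekamp-Massey, Chien search and
Forney's formula; clean codewords short-circuit on zero syndromes.
"""

from __future__ import annotations

_PRIM = 0x11D

EXP = [0] * 512
LOG = [0] * 256
_x = 1
for _i in range(255):
    EXP[_i] = _x
    LOG[_x] = _i
    _x <<= 1
    if _x & 0x100:
        _x ^= _PRIM
for _i in range(255, 512):
    EXP[_i] = EXP[_i - 255]


def gf_mul(a: int, b: int) -> int:
    if a == 0 or b == 0:
        return 0
    return EXP[LOG[a] + LOG[b]]


def gf_div(a: int, b: int) -> int:
    if b == 0:
        raise ZeroDivisionError("GF(256) division by zero")
    if a == 0:
        return 0
    return EXP[(LOG[a] - LOG[b]) % 255]


def _poly_mul(p: list[int], q: list[int]) -> list[int]:
    out = [0] * (len(p) + len(q) - 1)
    for i, a in enumerate(p):
        if a:
            la = LOG[a]
            for j, b in enumerate(q):
                if b:
                    out[i + j] ^= EXP[la + LOG[b]]
    return out


def generator_poly(nsym: int) -> list[int]:
    g = [1]
    for i in range(nsym):
        g = _poly_mul(g, [1, EXP[i]])
    return g


_GEN_CACHE: dict[int, list[int]] = {}


def rs_encode(data: bytes, nsym: int) -> bytes:
    """Return `nsym` parity bytes for `data`."""
    gen = _GEN_CACHE.get(nsym)
    if gen is None:
        gen = _GEN_CACHE[nsym] = generator_poly(nsym)
    rem = [0] * nsym
    for b in data:
        factor = b ^ rem[0]
        rem = rem[1:] + [0]
        if factor:
            lf = LOG[factor]
            for i in range(nsym):
                g = gen[i + 1]
                if g:
                    rem[i] ^= EXP[lf + LOG[g]]
    return bytes(rem)


def _syndromes(codeword: bytes, nsym: int) -> list[int]:
    synd = []
    for i in range(nsym):
        x = EXP[i]
        acc = 0
        for b in codeword:
            acc = gf_mul(acc, x) ^ b
        synd.append(acc)
    return synd


def rs_decode(codeword: bytes, nsym: int) -> bytes:
    """Correct up to nsym//2 byte errors; returns the data part.

    Raises ValueError when the error pattern is uncorrectable.
    """
    synd = _syndromes(codeword, nsym)
    if not any(synd):
        return bytes(codeword[:-nsym])

    # Berlekamp-Massey for the error locator polynomial
    err_loc = [1]
    old_loc = [1]
    for i in range(nsym):
        delta = synd[i]
        for j in range(1, len(err_loc)):
            delta ^= gf_mul(err_loc[-(j + 1)], synd[i - j])
        old_loc.append(0)
        if delta:
            if len(old_loc) > len(err_loc):
                new_loc = [gf_mul(c, delta) for c in old_loc]
                old_loc = [gf_div(c, delta) for c in err_loc]
                err_loc = new_loc
            for j in range(len(old_loc)):
                err_loc[-(j + 1)] ^= gf_mul(delta, old_loc[-(j + 1)])
    err_loc = err_loc[next((i for i, c in enumerate(err_loc) if c), 0):]
    n_errors = len(err_loc) - 1
    if n_errors * 2 > nsym:
        raise ValueError("too many errors to correct")

    # Chien search for error positions
    positions = []
    n = len(codeword)
    for pos in range(n):
        x_inv = EXP[(255 - (n - 1 - pos)) % 255]
        acc = 0
        for c in err_loc:
            acc = gf_mul(acc, x_inv) ^ c
        if acc == 0:
            positions.append(pos)
    if len(positions) != n_errors:
        raise ValueError("error locator roots do not match error count")

    # Error magnitudes: solve sum_j e_j * X_j^i = synd[i] over GF(256).
    locators = [_gf_pow(EXP[(n - 1 - pos) % 255], 1) for pos in positions]
    rows = [[_gf_pow(x, i) for x in locators] + [synd[i]]
            for i in range(len(positions))]
    magnitudes = _gf_solve(rows)
    corrected = bytearray(codeword)
    for pos, mag in zip(positions, magnitudes):
        corrected[pos] ^= mag
    if any(_syndromes(bytes(corrected), nsym)):
        raise ValueError("correction failed syndrome re-check")
    return bytes(corrected[:-nsym])


def _gf_solve(rows: list[list[int]]) -> list[int]:
    """Gaussian elimination over GF(256); rows are [coeffs..., rhs]."""
    m = len(rows)
    for col in range(m):
        pivot = next((r for r in range(col, m) if rows[r][col]), None)
        if pivot is None:
            raise ValueError("singular error-magnitude system")
        rows[col], rows[pivot] = rows[pivot], rows[col]
        inv = gf_div(1, rows[col][col])
        rows[col] = [gf_mul(v, inv) for v in rows[col]]
        for r in range(m):
            if r != col and rows[r][col]:
                factor = rows[r][col]
                rows[r] = [v ^ gf_mul(factor, w)
                           for v, w in zip(rows[r], rows[col])]
    return [rows[i][m] for i in range(m)]


def _gf_pow(a: int, n: int) -> int:
    if a == 0:
        return 0
    return EXP[(LOG[a] * n) % 255]
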