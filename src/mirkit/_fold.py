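"""Base-pair-maximization secondary-structure folder (Nussinov-style DP).

Objective is lexicographic: (1) maximize base pairs over {AU, GC, GU} with a
minimum hairpin loop of 3 nt; (2) among co-optimal structures minimize the
number of hairpin (terminal) loops; (3) then maximize stacked adjacent pairs.
The two tie-breaks make the traceback deterministic and select contiguous
helices out of the (hugely degenerate) max-pair optimum set; the pair count
itself is the classic Nussinov optimum.

The three counters are packed into one int64 so the DP stays a plain max:
``value = pairs * 2**20 - loops * 2**10 + stacks``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MIN_LOOP = 3
_P = 1 << 20  # pair weight
_L = 1 << 10  # loop weight (subtracted)
INVALID = np.int64(-1)

_ENC = {"A": 0, "C": 1, "G": 2, "U": 3}
# pseudo-energy weight per pair type, indexed by base codes
_PAIR_W = np.zeros((4, 4), dtype=np.int64)
for _a, _b, _w in [
    ("A", "U", 1), ("U", "A", 1),
    ("G", "C", 2), ("C", "G", 2),
    ("G", "U", 1), ("U", "G", 1),
]:
    _PAIR_W[_ENC[_a], _ENC[_b]] = _w


def encode(seq: str) -> np.ndarray:
    try:
        return np.array([_ENC[c] for c in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"disallowed character {exc} in RNA sequence") from None


@njit(cache=True)
def _dp(code, pair_w):  # pragma: no cover - exercised via fold()
    n = code.shape[0]
    W = np.zeros((n, n), dtype=np.int64)
    Q = np.full((n, n), INVALID)
    h = MIN_LOOP
    for span in range(1, n):
        for i in range(0, n - span):
            j = i + span
            # Q[i, j]: best structure of seq[i..j] in which (i, j) pair
            if pair_w[code[i], code[j]] > 0 and span >= h + 1:
                best = _P - _L  # hairpin: 1 pair, 1 loop
                ii, jj = i + 1, j - 1
                if jj - ii >= h + 1 and Q[ii, jj] != INVALID:
                    c = Q[ii, jj] + _P + 1  # stacked pair
                    if c > best:
                        best = c
                # enclosing a paired inner region without stacking
                o = INVALID
                if jj - 1 >= ii:
                    t = W[ii, jj - 1]
                    if t > 0:
                        o = t
                for k in range(ii + 1, jj - h):
                    if Q[k, jj] != INVALID:
                        left = W[ii, k - 1] if k - 1 >= ii else 0
                        t = left + Q[k, jj]
                        if t > o:
                            o = t
                if o > 0:
                    c = o + _P
                    if c > best:
                        best = c
                Q[i, j] = best
            # W[i, j]: best structure of seq[i..j]
            w = W[i, j - 1] if j - 1 >= i else 0
            for k in range(i, j - h):
                if Q[k, j] != INVALID:
                    left = W[i, k - 1] if k - 1 >= i else 0
                    t = left + Q[k, j]
                    if t > w:
                        w = t
            W[i, j] = w
    return W, Q


def fold(seq: str) -> tuple[str, int]:
    """Fold an RNA string; returns (dot-bracket structure, pseudo-energy).

    Pseudo-energy is -(2*GC + 1*AU + 1*GU) over paired positions, in
    kcal/mol-like units. Deterministic for a given sequence.
    """
    code = encode(seq)
    n = len(code)
    if n == 0:
        return "", 0
    if n < MIN_LOOP + 2:
        return "." * n, 0
    W, Q = _dp(code, _PAIR_W)
    struct = ["."] * n
    energy = 0
    h = MIN_LOOP
    stack: list[tuple[str, int, int]] = [("W", 0, n - 1)]
    while stack:
        kind, i, j = stack.pop()
        if j <= i:
            continue
        if kind == "W":
            w = W[i, j]
            if w == 0:
                continue
            prev = W[i, j - 1] if j - 1 >= i else 0
            if prev == w:
                stack.append(("W", i, j - 1))
                continue
            found = False
            for k in range(i, j - h):
                if Q[k, j] != INVALID:
                    left = W[i, k - 1] if k - 1 >= i else 0
                    if left + Q[k, j] == w:
                        if k - 1 >= i:
                            stack.append(("W", i, k - 1))
                        stack.append(("Q", k, j))
                        found = True
                        break
            if not found:  # pragma: no cover - DP/traceback mismatch
                raise AssertionError("traceback failed in W")
        else:  # Q: (i, j) are paired
            struct[i], struct[j] = "(", ")"
            energy -= int(_PAIR_W[code[i], code[j]])
            q = Q[i, j]
            ii, jj = i + 1, j - 1
            if jj - ii >= h + 1 and Q[ii, jj] != INVALID and Q[ii, jj] + _P + 1 == q:
                stack.append(("Q", ii, jj))
                continue
            if q == _P - _L:  # hairpin, inner unpaired
                continue
            found = False
            if jj - 1 >= ii and W[ii, jj - 1] > 0 and W[ii, jj - 1] + _P == q:
                stack.append(("W", ii, jj - 1))
                found = True
            else:
                for k in range(ii + 1, jj - h):
                    if Q[k, jj] != INVALID:
                        left = W[ii, k - 1] if k - 1 >= ii else 0
                        if left + Q[k, jj] + _P == q:
                            if k - 1 >= ii:
                                stack.append(("W", ii, k - 1))
                            stack.append(("Q", k, jj))
                            found = True
                            break
            if not found:  # pragma: no cover - DP/traceback mismatch
                raise AssertionError("traceback failed in Q")
    return "".join(struct), energy


def max_pairs(seq: str) -> int:
    """Maximum number of base pairs (the primary DP objective)."""
    code = encode(seq)
    n = len(code)
    if n < MIN_LOOP + 2:
        return 0
    W, _ = _dp(code, _PAIR_W)
    # packed value = pairs*2**20 - loops*2**10 + stacks; the correction term
    # is well inside +-2**19, so rounding recovers the pair count
    return int(round(int(W[0, n - 1]) / _P))
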