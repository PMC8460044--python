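"""Smith-Waterman local alignment kernel (numba-compiled).

Linear gap penalty. Ties during the matrix fill are broken toward the
diagonal, and the maximum-scoring cell is the first one encountered in
row-major order, so results are deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_BASE_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i  # lowercase


def encode(seq: str) -> np.ndarray:
    """Encode DNA to int8 codes (A=0 C=1 G=2 T=3, anything else 4)."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def _sw_kernel(q, t, match, mismatch, gap):  # pragma: no cover - numba
    n = q.shape[0]
    m = t.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 stop, 1 diag, 2 up, 3 left
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            if qi == t[j - 1] and qi < 4:
                s = match
            else:
                s = mismatch
            h = H[i - 1, j - 1] + s
            p = 1
            u = H[i - 1, j] + gap
            if u > h:
                h = u
                p = 2
            l = H[i, j - 1] + gap
            if l > h:
                h = l
                p = 3
            if h <= 0:
                h = 0
                p = 0
            H[i, j] = h
            ptr[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    i = bi
    j = bj
    matches = 0
    mismatches = 0
    gaps = 0
    while ptr[i, j] != 0:
        p = ptr[i, j]
        if p == 1:
            if q[i - 1] == t[j - 1] and q[i - 1] < 4:
                matches += 1
            else:
                mismatches += 1
            i -= 1
            j -= 1
        elif p == 2:
            gaps += 1
            i -= 1
        else:
            gaps += 1
            j -= 1
    return best, i, bi, j, bj, matches, mismatches, gaps


def smith_waterman(
    query: np.ndarray,
    target: np.ndarray,
    match: int = 1,
    mismatch: int = -2,
    gap: int = -3,
):
    """Best local alignment of encoded query vs target.

    Returns ``(score, q_start, q_end, t_start, t_end, matches, mismatches,
    gaps)`` with 0-based half-open spans; score 0 means no positive-scoring
    alignment exists.
    """
    return _sw_kernel(
        np.ascontiguousarray(query),
        np.ascontiguousarray(target),
        np.int32(match),
        np.int32(mismatch),
        np.int32(gap),
    )
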