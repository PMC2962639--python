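"""Affine-gap extension dynamic programming kernel.

One kernel serves every extension in the package: BLAST-style gapped
extension from a GE starting pair (``alpha = 0``, integer scores) and the
seed-anchored final alignment with its length-adjusted comparison score
(``alpha > 0``).  The kernel extends *forward* from an implicit anchor cell
that sits just outside the score window: DP cell ``(i, j)`` (1-based) means
"target offset i, query offset j past the anchor", and ``(0, 0)`` is the
anchor itself with relative score 0.  Extension is local in the trimmed
sense — the best-scoring cell wins and the path is traced back to the
anchor — but intermediate scores are never floored at zero, because every
path must start at the anchor.

Backward extension is handled by the callers by reversing the score window.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1e18

# traceback states
M_STATE, X_STATE, Y_STATE = 0, 1, 2


@njit(cache=True)
def _fill(S, gop, gep, alpha):
    """Fill the three affine-gap DP layers over score window ``S``.

    States: M — column aligns a residue pair; X — gap in the query
    (target residue consumed); Y — gap in the target.  Every DP step adds
    ``alpha`` (one alignment column), which implements the length-adjusted
    comparison score ``adjusted = raw + alpha * length``.

    Returns (best, bi, bj, bstate, pM, pX, pY) where best is the maximal
    relative adjusted score over all cells (anchor = 0.0) and the p* arrays
    encode the traceback.  Ties prefer the earliest cell in row-major order
    and the state order M > X > Y, for determinism.
    """
    nt, nq = S.shape
    M = np.full((nt + 1, nq + 1), NEG)
    X = np.full((nt + 1, nq + 1), NEG)
    Y = np.full((nt + 1, nq + 1), NEG)
    pM = np.zeros((nt + 1, nq + 1), dtype=np.int8)
    pX = np.zeros((nt + 1, nq + 1), dtype=np.int8)  # 0: opened from M, 1: extended
    pY = np.zeros((nt + 1, nq + 1), dtype=np.int8)
    M[0, 0] = 0.0
    best = 0.0
    bi, bj, bstate = 0, 0, M_STATE
    for i in range(nt + 1):
        for j in range(nq + 1):
            if i == 0 and j == 0:
                continue
            if i > 0:
                a = M[i - 1, j] - gop - gep
                b = X[i - 1, j] - gep
                if a >= b:
                    X[i, j] = a + alpha
                    pX[i, j] = 0
                else:
                    X[i, j] = b + alpha
                    pX[i, j] = 1
            if j > 0:
                a = M[i, j - 1] - gop - gep
                b = Y[i, j - 1] - gep
                if a >= b:
                    Y[i, j] = a + alpha
                    pY[i, j] = 0
                else:
                    Y[i, j] = b + alpha
                    pY[i, j] = 1
            if i > 0 and j > 0:
                v = M[i - 1, j - 1]
                st = M_STATE
                if X[i - 1, j - 1] > v:
                    v = X[i - 1, j - 1]
                    st = X_STATE
                if Y[i - 1, j - 1] > v:
                    v = Y[i - 1, j - 1]
                    st = Y_STATE
                M[i, j] = v + S[i - 1, j - 1] + alpha
                pM[i, j] = st
            # strict > keeps the earliest maximum; M before X before Y
            if M[i, j] > best:
                best = M[i, j]
                bi, bj, bstate = i, j, M_STATE
            if X[i, j] > best:
                best = X[i, j]
                bi, bj, bstate = i, j, X_STATE
            if Y[i, j] > best:
                best = Y[i, j]
                bi, bj, bstate = i, j, Y_STATE
    return best, bi, bj, bstate, pM, pX, pY


def extend(S: np.ndarray, gop: float, gep: float, alpha: float = 0.0):
    """Best anchored extension over score window ``S``.

    Returns ``(best, path)`` where ``best`` is the relative adjusted score
    of the extension (0.0 when no extension improves on the anchor) and
    ``path`` is a list of 1-based offset columns ``(di, dj)`` with ``None``
    marking the gapped side, ordered away from the anchor.
    """
    S = np.ascontiguousarray(S, dtype=np.float64)
    if S.size == 0:
        return 0.0, []
    best, bi, bj, bstate, pM, pX, pY = _fill(S, float(gop), float(gep), float(alpha))
    path: list[tuple[int | None, int | None]] = []
    i, j, st = bi, bj, bstate
    while not (i == 0 and j == 0):
        if st == M_STATE:
            path.append((i, j))
            st = int(pM[i, j])
            i -= 1
            j -= 1
        elif st == X_STATE:
            path.append((i, None))
            nxt = int(pX[i, j])
            i -= 1
            st = M_STATE if nxt == 0 else X_STATE
        else:
            path.append((None, j))
            nxt = int(pY[i, j])
            j -= 1
            st = M_STATE if nxt == 0 else Y_STATE
    path.reverse()
    return float(best), path
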