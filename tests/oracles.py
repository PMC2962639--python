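"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's DP kernel and vectorized scans:
plain double loops and a score-only three-state affine DP, slow but easy
to audit.
"""

from __future__ import annotations

import numpy as np

NEG = float("-inf")


def brute_force_hits(profile, query: str, word_size: int, min_word_score: int):
    """Every (i, j) whose word window scores strictly above the threshold."""
    n, m = len(profile), len(query)
    out = []
    for i in range(n - word_size + 1):
        for j in range(m - word_size + 1):
            s = sum(profile.score(i + t, query[j + t]) for t in range(word_size))
            if s > min_word_score:
                out.append((i, j))
    return out


def best_extension(S: np.ndarray, gop: float, gep: float, alpha: float = 0.0) -> float:
    """Best score of any alignment path that starts at an anchor just
    outside S[0, 0] (i.e. the first DP step consumes S[0, 0] diagonally or
    opens a gap) — score-only, python loops.  Returns 0.0 if no extension
    is profitable."""
    nt, nq = S.shape
    if nt == 0 or nq == 0:
        # only gap-runs possible along the non-empty axis
        best = 0.0
        for g in range(1, max(nt, nq) + 1):
            best = max(best, -(gop + g * gep) + alpha * g)
        return best
    M = [[NEG] * (nq + 1) for _ in range(nt + 1)]
    GX = [[NEG] * (nq + 1) for _ in range(nt + 1)]  # gap consuming target
    GY = [[NEG] * (nq + 1) for _ in range(nt + 1)]  # gap consuming query
    M[0][0] = 0.0
    best = 0.0
    for i in range(nt + 1):
        for j in range(nq + 1):
            if i == 0 and j == 0:
                continue
            if i > 0:
                GX[i][j] = max(M[i - 1][j] - gop - gep, GX[i - 1][j] - gep) + alpha
            if j > 0:
                GY[i][j] = max(M[i][j - 1] - gop - gep, GY[i][j - 1] - gep) + alpha
            if i > 0 and j > 0:
                prev = max(M[i - 1][j - 1], GX[i - 1][j - 1], GY[i - 1][j - 1])
                M[i][j] = prev + S[i - 1][j - 1] + alpha
            best = max(best, M[i][j], GX[i][j], GY[i][j])
    return best


def sw_through_anchor(S: np.ndarray, i0: int, j0: int, gop: float, gep: float) -> float:
    """Best Smith-Waterman affine-gap score over paths that align the pair
    (i0, j0), trimmed at the score maxima on both sides."""
    fwd = best_extension(S[i0 + 1 :, j0 + 1 :], gop, gep)
    bwd = best_extension(S[:i0, :j0][::-1, ::-1], gop, gep)
    return float(S[i0, j0]) + fwd + bwd


def best_diagonal_segment(S: np.ndarray) -> tuple[float, int, int, int]:
    """Max-sum contiguous diagonal segment over all diagonals:
    (score, diag_target_start, diag_query_start, length)."""
    n, m = S.shape
    best = (NEG, 0, 0, 0)
    for d in range(-(n - 1), m):
        i0, j0 = (0, d) if d >= 0 else (-d, 0)
        length = min(n - i0, m - j0)
        v = [S[i0 + t, j0 + t] for t in range(length)]
        for a in range(length):
            run = 0.0
            for b in range(a, length):
                run += v[b]
                if run > best[0]:
                    best = (run, i0 + a, j0 + a, b - a + 1)
    return best
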