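"""BLAST-like alignment substrate: word hits, ungapped HSPs, gapped extension.

Both search modes (exhaustive chimera embedding and the adaptive
seed-placement search) run on the primitives here.  Scoring is column-wise
against a :class:`~agb.seqio.ScoringProfile`; a substitution matrix can
stand in for the profile columns by scoring each query residue against the
profile's consensus residue.  All scores in this module are integers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from Bio.Align import substitution_matrices

from . import _dp
from .seqio import ALPHABET, AA_INDEX, ScoringProfile, X_SCORE

_EXTENDED = ALPHABET + "X"


class SubstitutionMatrix:
    """A 20x20 (plus X) integer residue substitution matrix.

    ``scores`` is a 21x21 array ordered as :data:`~agb.seqio.ALPHABET`
    followed by X.  A pair is *positive* when its score is > 0.
    """

    def __init__(self, name: str, scores: np.ndarray):
        scores = np.asarray(scores, dtype=np.int64)
        if scores.shape != (21, 21):
            raise ValueError("expected a 21x21 score array (20 residues + X)")
        if not np.array_equal(scores, scores.T):
            raise ValueError(f"matrix {name} is not symmetric")
        if not np.all(np.diag(scores)[:20] > 0):
            raise ValueError(f"matrix {name} has a non-positive diagonal entry")
        self.name = name
        self.scores = scores

    @classmethod
    def load(cls, name: str = "BLOSUM62") -> "SubstitutionMatrix":
        """Load one of the standard NCBI matrices (via Biopython's copies)."""
        bio = substitution_matrices.load(name)
        out = np.full((21, 21), X_SCORE, dtype=np.int64)
        for i, a in enumerate(_EXTENDED):
            for j, b in enumerate(_EXTENDED):
                if a in bio.alphabet and b in bio.alphabet:
                    out[i, j] = int(bio[a, b])
        return cls(name, out)

    @classmethod
    def from_ncbi_file(cls, path: str | Path, name: str | None = None) -> "SubstitutionMatrix":
        """Parse a matrix in the standard NCBI text layout (# comments,
        header row of residue letters, one labelled row per residue)."""
        path = Path(path)
        header: list[str] | None = None
        rows: dict[str, list[int]] = {}
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            toks = line.split()
            if header is None:
                header = toks
                continue
            rows[toks[0]] = [int(t) for t in toks[1:]]
        if header is None:
            raise ValueError(f"{path}: no header row")
        out = np.full((21, 21), X_SCORE, dtype=np.int64)
        for i, a in enumerate(_EXTENDED):
            if a not in rows:
                continue
            for j, b in enumerate(_EXTENDED):
                if b in header:
                    out[i, j] = rows[a][header.index(b)]
        return cls(name or path.stem, out)

    def _idx(self, r: str) -> int:
        return AA_INDEX.get(r, 20)

    def score(self, a: str, b: str) -> int:
        return int(self.scores[self._idx(a), self._idx(b)])

    def is_positive(self, a: str, b: str) -> bool:
        return self.score(a, b) > 0

    def row(self, residue: str) -> np.ndarray:
        """The 20-entry score column for one residue, in alphabet order."""
        return self.scores[self._idx(residue), :20].copy()


def as_profile(profile: ScoringProfile, matrix: Optional[SubstitutionMatrix]) -> ScoringProfile:
    """Resolve the scoring source for a target.

    With ``matrix`` None the profile's own PSSM columns are used; otherwise
    each column is replaced by the matrix row of the consensus residue, so
    that ``score(pos, r) == matrix[consensus[pos], r]``.
    """
    if matrix is None:
        return profile
    cols = np.stack([matrix.row(c) for c in profile.consensus])
    return ScoringProfile(profile.id, profile.consensus, cols)


def score_pair(
    target_pos: int,
    query_residue: str,
    profile: ScoringProfile,
    matrix: Optional[SubstitutionMatrix] = None,
) -> int:
    """Score one query residue against one target position."""
    if matrix is not None:
        if not 0 <= target_pos < len(profile):
            raise IndexError(f"position {target_pos} outside profile")
        return matrix.score(profile.consensus[target_pos], query_residue)
    return profile.score(target_pos, query_residue)


@dataclass(frozen=True)
class GapParams:
    """Affine gap penalties: a gap of length g costs open + g * extend."""

    open: int = 11
    extend: int = 1

    def __post_init__(self) -> None:
        if self.open < 0 or self.extend <= 0:
            raise ValueError("require gap open >= 0 and gap extend > 0")


@dataclass(frozen=True)
class Hit:
    """An exact-width word match: target_start x query_start, ``width`` long."""

    target_start: int
    query_start: int
    width: int
    score: int

    @property
    def diagonal(self) -> int:
        return self.query_start - self.target_start


@dataclass(frozen=True)
class Hsp:
    """An ungapped high-scoring segment pair (equal-length spans)."""

    target_span: tuple[int, int]
    query_span: tuple[int, int]
    score: int

    def __post_init__(self) -> None:
        ts, te = self.target_span
        qs, qe = self.query_span
        if te - ts != qe - qs:
            raise ValueError("HSP spans must have equal length")


@dataclass
class LocalAlignment:
    """A gapped local alignment as an explicit column list.

    Columns are ``(target_index, query_index)`` with ``None`` on the gapped
    side; indices increase strictly on each side and no column is
    gap-on-both-sides.
    """

    columns: list[tuple[Optional[int], Optional[int]]]
    score: int

    @property
    def target_span(self) -> tuple[int, int]:
        idx = [t for t, _ in self.columns if t is not None]
        return (idx[0], idx[-1] + 1) if idx else (0, 0)

    @property
    def query_span(self) -> tuple[int, int]:
        idx = [q for _, q in self.columns if q is not None]
        return (idx[0], idx[-1] + 1) if idx else (0, 0)

    def __len__(self) -> int:
        return len(self.columns)

    def rescore(self, profile: ScoringProfile, query: str, gap: GapParams) -> int:
        """Recompute the raw score from the columns (match scores minus
        affine gap penalties); used to assert internal consistency."""
        total = 0
        run = None  # which side is currently gapped
        for t, q in self.columns:
            if t is not None and q is not None:
                total += profile.score(t, query[q])
                run = None
            else:
                side = "t" if t is None else "q"
                total -= gap.extend + (gap.open if run != side else 0)
                run = side
        return total


# ---------------------------------------------------------------------------
# Step primitives

def find_hits(
    profile: ScoringProfile,
    query: str,
    word_size: int = 3,
    min_word_score: int = 11,
) -> list[Hit]:
    """All word hits: windows of ``word_size`` consecutive column-vs-residue
    scores summing strictly above ``min_word_score``.  Exhaustive over every
    (target, query) start pair."""
    if word_size < 1:
        raise ValueError("word_size must be >= 1")
    n, m = len(profile), len(query)
    w = word_size
    if m < w or n < w:
        return []
    S = profile.score_matrix(query)
    W = np.zeros((n - w + 1, m - w + 1), dtype=np.int64)
    for t in range(w):
        W += S[t : n - w + 1 + t, t : m - w + 1 + t]
    ii, jj = np.nonzero(W > min_word_score)
    return [Hit(int(i), int(j), w, int(W[i, j])) for i, j in zip(ii, jj)]


def extend_ungapped(
    hits: list[Hit],
    profile: ScoringProfile,
    query: str,
    dropoff: int = 7,
    min_hsp_score: int = 25,
) -> list[Hsp]:
    """X-drop ungapped extension of word hits into HSPs.

    Each hit is extended along its diagonal in both directions until the
    running score falls more than ``dropoff`` below the running maximum,
    then trimmed back to the maximum.  An accepted HSP consumes the hits it
    covers: hits overlapping an accepted HSP on the same diagonal are
    skipped, and later extensions may not cross an accepted HSP, so HSPs on
    one diagonal are disjoint.  HSPs scoring <= ``min_hsp_score`` are
    discarded (but still consume their hits, mirroring the hit-removal rule).
    """
    if not hits:
        return []
    n, m = len(profile), len(query)
    S = profile.score_matrix(query)
    # strongest words first; ties broken by coordinates for determinism
    order = sorted(hits, key=lambda h: (-h.score, h.target_start, h.query_start))
    taken: dict[int, list[tuple[int, int]]] = {}  # diagonal -> query-span list
    out: list[Hsp] = []
    for h in order:
        d = h.diagonal
        spans = taken.setdefault(d, [])
        j0, j1 = h.query_start, h.query_start + h.width
        if any(j0 < e and s < j1 for s, e in spans):
            continue
        # free window on this diagonal, bounded by sequence ends and by
        # previously accepted HSPs
        lo = max(0, d)
        hi = min(m, n + d)
        for s, e in spans:
            if e <= j0:
                lo = max(lo, e)
            if s >= j1:
                hi = min(hi, s)
        # rightward
        run = best_r = 0
        end = j1
        for j in range(j1, hi):
            run += S[j - d, j]
            if run > best_r:
                best_r, end = run, j + 1
            elif best_r - run > dropoff:
                break
        # leftward
        run = best_l = 0
        start = j0
        for j in range(j0 - 1, lo - 1, -1):
            run += S[j - d, j]
            if run > best_l:
                best_l, start = run, j
            elif best_l - run > dropoff:
                break
        score = int(S[np.arange(start - d, end - d), np.arange(start, end)].sum())
        spans.append((start, end))
        spans.sort()
        if score > min_hsp_score:
            out.append(Hsp((start - d, end - d), (start, end), score))
    out.sort(key=lambda x: (x.target_span, x.query_span))
    return out


def ge_starting_pair(hsp: Hsp, S: np.ndarray) -> tuple[int, int]:
    """The residue pair gapped extension starts from: the central pair of
    the maximal-scoring length-11 window of the HSP (whole HSP if shorter)."""
    ts, te = hsp.target_span
    qs, _ = hsp.query_span
    length = te - ts
    v = S[np.arange(ts, te), np.arange(qs, qs + length)]
    w = min(11, length)
    sums = np.convolve(v, np.ones(w, dtype=np.int64), mode="valid")
    ws = int(np.argmax(sums))  # first maximum
    t0 = ws + (w - 1) // 2
    return ts + t0, qs + t0


def extend_gapped(
    hsp: Hsp,
    profile: ScoringProfile,
    query: str,
    gap: GapParams = GapParams(),
    matrix: Optional[SubstitutionMatrix] = None,
) -> LocalAlignment:
    """Affine-gap local extension of an HSP in both directions from its GE
    starting pair.  Equivalent to the best Smith-Waterman path constrained
    to align the starting pair, trimmed at the score maxima on each side."""
    prof = as_profile(profile, matrix)
    S = prof.score_matrix(query)
    i0, j0 = ge_starting_pair(hsp, S)
    best_f, path_f = _dp.extend(S[i0 + 1 :, j0 + 1 :], gap.open, gap.extend)
    best_b, path_b = _dp.extend(S[:i0, :j0][::-1, ::-1], gap.open, gap.extend)
    cols: list[tuple[Optional[int], Optional[int]]] = []
    for di, dj in reversed(path_b):
        cols.append(
            (i0 - di if di is not None else None, j0 - dj if dj is not None else None)
        )
    cols.append((i0, j0))
    for di, dj in path_f:
        cols.append(
            (i0 + di if di is not None else None, j0 + dj if dj is not None else None)
        )
    score = int(round(best_b + int(S[i0, j0]) + best_f))
    return LocalAlignment(cols, score)
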