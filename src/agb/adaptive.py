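"""The adaptive embedded search: four steps.

1. Find non-overlapping gapped *partial alignments* between query and
   target (plain seed-and-extend on the unmodified query).
2. From each partial alignment and the seed's self-score, select the query
   positions where an embedded seed could profitably extend into it — the
   seed can bridge at most the *maximum gap* G(S) that its score pays for.
3. At each selected position, build the chimera and run the seeded final
   alignment: an affine-gap DP anchored at the seed's inner end whose
   comparison score is adjusted by alignment length (longer, lower-scoring
   alignments can outrank short high-scoring ones in the twilight zone).
4. Filter survivors on %coverage of the target and %identity excluding the
   seed columns.

The output is always a subset of what the exhaustive search (seed at every
position) finds, at a small fraction of the DP invocations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _dp
from .align_core import (
    GapParams,
    LocalAlignment,
    SubstitutionMatrix,
    as_profile,
    extend_gapped,
    extend_ungapped,
    find_hits,
)
from .embedding import Chimera, Seed, build_chimera, extract_seed
from .seqio import ProteinSequence, ScoringProfile


@dataclass(frozen=True)
class FilterThresholds:
    """Significance gates for final alignments (strict > comparisons)."""

    min_coverage_pct: float = 60.0
    min_identity_pct: float = 10.0
    min_partial_fraction: float = 0.10  # of target length, Step 1 length gate

    def __post_init__(self) -> None:
        if not (0 <= self.min_coverage_pct <= 100 and 0 <= self.min_identity_pct <= 100):
            raise ValueError("percentage thresholds must lie in [0, 100]")


@dataclass(frozen=True)
class SearchParams:
    """Everything the two search modes share, with BLAST-protein defaults."""

    seed_fraction_pct: float = 10.0
    word_size: int = 3
    min_word_score: int = 11
    dropoff: int = 7
    min_hsp_score: int = 25
    gap: GapParams = field(default_factory=GapParams)
    alpha: float = 0.25
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    matrix: Optional[SubstitutionMatrix] = None  # None: score on the PSSM columns


@dataclass
class PartialAlignment:
    """A non-overlapping local alignment from Step 1."""

    alignment: LocalAlignment
    non_overlapping: bool = True

    @property
    def query_span(self) -> tuple[int, int]:
        return self.alignment.query_span

    @property
    def target_span(self) -> tuple[int, int]:
        return self.alignment.target_span


@dataclass(frozen=True)
class SeedPlacementRange:
    """Inclusive range of insert positions derived from one partial alignment."""

    terminal: str
    q_start: int
    q_end: int

    def positions(self) -> range:
        return range(self.q_start, self.q_end + 1)


@dataclass
class FinalAlignment:
    """A seeded alignment with its quality metrics.

    ``columns`` pair profile positions with chimera positions (None on a
    gapped side); the seed block is the ``k`` columns at chimera positions
    ``[q, q + k)``.  ``coverage_pct`` is the aligned target span as a
    percentage of the target length; ``identity_pct`` counts identical
    columns only outside the seed, over the non-seed alignment length.
    """

    query_id: str
    profile_id: str
    terminal: str
    q: int
    k: int
    columns: list[tuple[Optional[int], Optional[int]]]
    raw_score: int
    adjusted_score: float
    coverage_pct: float
    identity_pct: float
    target_span: tuple[int, int]
    query_span_chimera: tuple[int, int]
    query_span_original: Optional[tuple[int, int]]
    chimera: Chimera

    def key(self) -> tuple:
        return (self.terminal, self.q, self.target_span, self.query_span_chimera)

    def aligned_strings(self, profile: ScoringProfile) -> tuple[str, str, str]:
        """(target, midline, query) strings; midline marks | identity,
        + positive PSSM score, space otherwise."""
        t_s, m_s, q_s = [], [], []
        for t, c in self.columns:
            tr = profile.consensus[t] if t is not None else "-"
            qr = self.chimera.residues[c] if c is not None else "-"
            if t is None or c is None:
                mid = " "
            elif tr == qr:
                mid = "|"
            elif profile.score(t, qr) > 0:
                mid = "+"
            else:
                mid = " "
            t_s.append(tr)
            m_s.append(mid)
            q_s.append(qr)
        return "".join(t_s), "".join(m_s), "".join(q_s)


@dataclass
class SearchResult:
    """Survivors plus the work counter used for the speed-up property."""

    alignments: list[FinalAlignment]
    dp_invocations: int
    partials: list[PartialAlignment] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Step 1

def find_partial_alignments(
    profile: ScoringProfile,
    query: ProteinSequence,
    params: SearchParams = SearchParams(),
) -> list[PartialAlignment]:
    """Non-overlapping gapped local alignments between query and target.

    Word hits are extended to HSPs with hit consumption, each surviving HSP
    is gap-extended, alignments shorter than ``min_partial_fraction * n``
    columns are dropped, and remaining alignments are made pairwise
    non-overlapping greedily by descending score.  Two alignments overlap
    when their target AND query spans both intersect (they compete for the
    same DP cells); two query repeats aligning to one target region are
    kept as separate partial alignments.
    """
    prof = as_profile(profile, params.matrix)
    hits = find_hits(prof, query.residues, params.word_size, params.min_word_score)
    hsps = extend_ungapped(
        hits, prof, query.residues, params.dropoff, params.min_hsp_score
    )
    n = len(profile)
    min_len = params.thresholds.min_partial_fraction * n
    cands = []
    for hsp in hsps:
        la = extend_gapped(hsp, prof, query.residues, params.gap)
        if len(la) > min_len:
            cands.append(la)
    cands.sort(key=lambda a: (-a.score, a.target_span, a.query_span))
    kept: list[LocalAlignment] = []

    def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
        return a[0] < b[1] and b[0] < a[1]

    for la in cands:
        if any(
            _overlaps(la.target_span, k.target_span)
            and _overlaps(la.query_span, k.query_span)
            for k in kept
        ):
            continue
        kept.append(la)
    kept.sort(key=lambda a: (a.query_span, a.target_span))
    return [PartialAlignment(la) for la in kept]


# ---------------------------------------------------------------------------
# Step 2

def max_gap(seed: Seed, gap: GapParams) -> int:
    """G(S): the longest gap whose affine penalty the seed's self-score can
    pay for — floor((Score(S) - GOP) / GEP), floored at 0."""
    return max(0, (seed.score - gap.open) // gap.extend)


def select_seed_positions(
    partial: PartialAlignment, seed: Seed, gap: GapParams, m: int
) -> Optional[SeedPlacementRange]:
    """Insert positions (original-query coordinates) from which the seed can
    reach the partial alignment.

    An N-terminal seed extends rightward, so it can converge onto the
    partial from up to ``G(S) + k`` positions before its query start ``ys``
    (the seed score pays the bridging gap), and from anywhere inside the
    partial's span (the remaining piece of the partial is reached with no
    gap at all); the range is ``[ys - G(S) - k, ye - 1]``.  Symmetrically a
    C-terminal seed gets ``[ys + 1, ye + G(S)]``.  Ranges are clipped to
    the positions the exhaustive search enumerates (0..m-1); a range that
    empties under clipping is not emitted.
    """
    g = max_gap(seed, gap)
    ys, ye = partial.query_span
    if seed.terminal == "N":
        q_start = max(0, ys - g - seed.k)
        q_end = min(ye - 1, m - 1)
    else:
        q_start = max(0, ys + 1)
        q_end = min(ye + g, m - 1)
    if q_start > q_end:
        return None
    return SeedPlacementRange(seed.terminal, q_start, q_end)


# ---------------------------------------------------------------------------
# Step 3

def _raw_from_path(
    path: list[tuple[Optional[int], Optional[int]]],
    S: np.ndarray,
    gap: GapParams,
    map_cell,
) -> int:
    total = 0
    run = None
    for di, dj in path:
        if di is not None and dj is not None:
            i, j = map_cell(di, dj)
            total += int(S[i, j])
            run = None
        else:
            side = "t" if di is None else "q"
            total -= gap.extend + (gap.open if run != side else 0)
            run = side
    return total


def seeded_alignment(
    chimera: Chimera,
    profile: ScoringProfile,
    gap: GapParams = GapParams(),
    alpha: float = 0.25,
) -> Optional[FinalAlignment]:
    """Step 3: the final alignment anchored at the embedded seed.

    The seed block aligns exactly (profile terminus vs its own copy) and
    contributes ``Score(S)``.  The DP then extends from the seed's inner
    end into the region of interest — rightward/downward for an N-terminal
    seed, leftward/upward for a C-terminal one.  During the DP, cell
    comparisons use ``adjusted = raw + alpha * length`` so that long
    low-scoring extensions can win; ``alpha = 0`` recovers the standard
    anchored Smith-Waterman extension.  The length adjustment arbitrates
    between extensions but cannot create one: if the best adjusted cell's
    extension does not improve the raw score over the seed alone, the
    seed-only alignment is returned (the Step 4 filter drops it, since its
    excluding-seed identity is 0).
    """
    seed = chimera.seed
    k, q = seed.k, chimera.q
    n = len(profile)
    S = profile.score_matrix(chimera.residues)
    seed_cols = [(seed.target_span[0] + t, q + t) for t in range(k)]
    if seed.terminal == "N":
        sub = S[k:, q + k :]
        best, path = _dp.extend(sub, gap.open, gap.extend, alpha)
        map_cell = lambda di, dj: (k - 1 + di, q + k - 1 + dj)
        ext_cols = [
            (
                k - 1 + di if di is not None else None,
                q + k - 1 + dj if dj is not None else None,
            )
            for di, dj in path
        ]
        columns = seed_cols + ext_cols
        raw = seed.score + _raw_from_path(path, S, gap, map_cell)
    else:
        sub = S[: n - k, :q][::-1, ::-1]
        best, path = _dp.extend(sub, gap.open, gap.extend, alpha)
        map_cell = lambda di, dj: (n - k - di, q - dj)
        ext_cols = [
            (
                n - k - di if di is not None else None,
                q - dj if dj is not None else None,
            )
            for di, dj in reversed(path)
        ]
        columns = ext_cols + seed_cols
        raw = seed.score + _raw_from_path(path, S, gap, map_cell)
    if raw <= seed.score and path:
        # extension carried by the length bonus alone: discard it
        columns, path, best = list(seed_cols), [], 0.0
        raw = seed.score
    adjusted = seed.score + alpha * k + best
    t_idx = [t for t, _ in columns if t is not None]
    c_idx = [c for _, c in columns if c is not None]
    target_span = (min(t_idx), max(t_idx) + 1)
    chim_span = (min(c_idx), max(c_idx) + 1)
    coverage = 100.0 * (target_span[1] - target_span[0]) / n
    nonseed = [
        (t, c) for t, c in columns if not (c is not None and q <= c < q + k)
    ]
    if nonseed:
        matches = sum(
            1
            for t, c in nonseed
            if t is not None and c is not None
            and profile.consensus[t] == chimera.residues[c]
        )
        identity = 100.0 * matches / len(nonseed)
        orig = [chimera.to_original(c) for _, c in nonseed if c is not None]
        orig = [o for o in orig if o is not None]
        orig_span = (min(orig), max(orig) + 1) if orig else None
    else:
        identity = 0.0
        orig_span = None
    return FinalAlignment(
        query_id=chimera.query_id,
        profile_id=profile.id,
        terminal=seed.terminal,
        q=q,
        k=k,
        columns=columns,
        raw_score=int(raw),
        adjusted_score=float(adjusted),
        coverage_pct=coverage,
        identity_pct=identity,
        target_span=target_span,
        query_span_chimera=chim_span,
        query_span_original=orig_span,
        chimera=chimera,
    )


# ---------------------------------------------------------------------------
# Step 4

def filter_alignments(
    alignments: list[FinalAlignment], thresholds: FilterThresholds = FilterThresholds()
) -> list[FinalAlignment]:
    """Keep alignments with coverage AND excluding-seed identity strictly
    above their thresholds.  Seed-only alignments (identity 0) never pass a
    positive identity threshold."""
    return [
        fa
        for fa in alignments
        if fa.coverage_pct > thresholds.min_coverage_pct
        and fa.identity_pct > thresholds.min_identity_pct
    ]


# ---------------------------------------------------------------------------
# The composed search

def adaptive_search(
    query: ProteinSequence,
    profile: ScoringProfile,
    params: SearchParams = SearchParams(),
) -> SearchResult:
    """Steps 1-4 composed for both terminals.

    Seeded DP runs only at positions selected from the partial alignments,
    so the invocation count is far below the exhaustive ``2 m``; with no
    partial alignments (unrelated pair) no seeded DP runs at all.
    Survivors are deduplicated on (terminal, q, target span, query span)
    and sorted deterministically.
    """
    partials = find_partial_alignments(profile, query, params)
    m = len(query)
    survivors: list[FinalAlignment] = []
    n_dp = 0
    for terminal in ("N", "C"):
        seed = extract_seed(profile, params.seed_fraction_pct, terminal)
        positions: set[int] = set()
        for pa in partials:
            rng = select_seed_positions(pa, seed, params.gap, m)
            if rng is not None:
                positions.update(rng.positions())
        for q in sorted(positions):
            chim = build_chimera(query, seed, q)
            fa = seeded_alignment(chim, profile, gap=params.gap, alpha=params.alpha)
            n_dp += 1
            if fa is not None:
                survivors.extend(filter_alignments([fa], params.thresholds))
    seen: set[tuple] = set()
    unique: list[FinalAlignment] = []
    for fa in survivors:
        if fa.key() not in seen:
            seen.add(fa.key())
            unique.append(fa)
    unique.sort(key=lambda fa: (fa.terminal, fa.q, fa.target_span[0]))
    return SearchResult(alignments=unique, dp_invocations=n_dp, partials=partials)
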