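"""Seed extraction, chimera construction, and the exhaustive embedded search.

A *chimera* is the query with a short stretch of a target profile's
consensus (the *seed*) inserted at one position, which guarantees an exact
anchor from which an alignment can extend.  The exhaustive search embeds
the seed at every query position for both terminals; it is the reference
that the adaptive search must reproduce a subset of.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .align_core import GapParams, SubstitutionMatrix
from .seqio import ProteinSequence, ScoringProfile


@dataclass(frozen=True)
class Seed:
    """The N- or C-terminal ``k`` consensus residues of a profile.

    ``score`` is the seed's self-score: each residue scored against its own
    profile column, i.e. the exact-match anchor score the seed contributes.
    """

    residues: str
    terminal: str  # "N" or "C"
    source_profile_id: str
    score: int
    target_span: tuple[int, int]  # profile positions the seed copies

    @property
    def k(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Chimera:
    """Query ``Y`` with a seed inserted at position ``q`` (0 <= q <= m).

    Chimera index ``c`` maps to original query index ``c`` for ``c < q``
    and ``c - k`` for ``c >= q + k``; the seed occupies ``[q, q + k)``.
    """

    query_id: str
    seed: Seed
    q: int
    residues: str

    @property
    def k(self) -> int:
        return self.seed.k

    def __len__(self) -> int:
        return len(self.residues)

    def to_original(self, c: int) -> Optional[int]:
        """Original query index for chimera index ``c`` (None inside seed)."""
        if c < self.q:
            return c
        if c < self.q + self.k:
            return None
        return c - self.k

    def strip_seed(self) -> str:
        return self.residues[: self.q] + self.residues[self.q + self.k :]


def seed_length(n: int, fraction_pct: float) -> int:
    """k = max(1, floor(p/100 * n))."""
    return max(1, math.floor(fraction_pct * n / 100.0))


def extract_seed(
    profile: ScoringProfile, fraction_pct: float = 10.0, terminal: str = "N"
) -> Seed:
    """Take p% of the profile consensus as a seed (N prefix or C suffix) and
    score it against the profile's own columns."""
    if not 0 < fraction_pct <= 100:
        raise ValueError("seed fraction must be in (0, 100]")
    if terminal not in ("N", "C"):
        raise ValueError("terminal must be 'N' or 'C'")
    n = len(profile)
    if n == 0:
        raise ValueError(f"profile {profile.id!r} has an empty consensus")
    k = seed_length(n, fraction_pct)
    span = (0, k) if terminal == "N" else (n - k, n)
    residues = profile.consensus[span[0] : span[1]]
    score = sum(profile.score(pos, r) for pos, r in zip(range(span[0], span[1]), residues))
    return Seed(residues, terminal, profile.id, int(score), span)


def build_chimera(query: ProteinSequence, seed: Seed, q: int) -> Chimera:
    """Insert the seed at query position ``q`` (0 <= q <= m allowed)."""
    m = len(query)
    if not 0 <= q <= m:
        raise ValueError(f"insert position {q} outside 0..{m}")
    res = query.residues[:q] + seed.residues + query.residues[q:]
    return Chimera(query.id, seed, q, res)


def exhaustive_embedded_search(
    query: ProteinSequence,
    profile: ScoringProfile,
    fraction_pct: float = 10.0,
    thresholds=None,
    gap: GapParams = GapParams(),
    matrix: Optional[SubstitutionMatrix] = None,
    alpha: float = 0.25,
):
    """Embed a seed at every query position 0..m-1 for both terminals, run
    the seeded final alignment at each, and keep the filter survivors.

    This is the reference oracle for the adaptive search: exactly ``2 m``
    seeded DP invocations, with the same anchored DP, length adjustment and
    filters.  Returns a :class:`~agb.adaptive.SearchResult`.
    """
    from .adaptive import FilterThresholds, SearchResult, filter_alignments, seeded_alignment

    thresholds = thresholds or FilterThresholds()
    m = len(query)
    survivors = []
    n_dp = 0
    for terminal in ("N", "C"):
        seed = extract_seed(profile, fraction_pct, terminal)
        for q in range(m):
            chim = build_chimera(query, seed, q)
            fa = seeded_alignment(chim, profile, gap=gap, alpha=alpha)
            n_dp += 1
            if fa is not None:
                survivors.extend(filter_alignments([fa], thresholds))
    return SearchResult(alignments=survivors, dp_invocations=n_dp)
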