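"""Per-residue structure-annotation tracks from overlapping alignments.

For every profile with surviving alignments, the union of the survivors'
query regions is realigned (full Smith-Waterman, affine gaps) against the
profile consensus under BLOSUM62 and BLOSUM45.  Aligned residues score 2
when identical and 1 when non-identical but conserved (positive matrix
score); the per-matrix tracks are summed over profiles and averaged across
the two matrices.  The raw track is then normalized to mean zero, smoothed
with a centered moving average, and baselined to its local minima, giving
a curve whose peaks mark conserved structural elements.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .adaptive import FinalAlignment
from .align_core import GapParams
from .seqio import ProteinSequence, ScoringProfile


@dataclass
class PositionalTrack:
    """One value per residue of a protein, tagged with its pipeline stage."""

    protein_id: str
    scores: np.ndarray
    stage: str  # raw | normalized | smoothed | baselined

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)


def _merge_spans(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals (overlapping or touching spans merge)."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(spans):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _aligner(matrix_name: str, gap: GapParams) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = substitution_matrices.load(matrix_name)
    al.open_gap_score = -(gap.open + gap.extend)
    al.extend_gap_score = -gap.extend
    return al


def positional_track(
    protein: ProteinSequence,
    survivors_by_profile: Sequence[tuple[ScoringProfile, Sequence[FinalAlignment]]],
    matrices: tuple[str, str] = ("BLOSUM62", "BLOSUM45"),
    gap: GapParams = GapParams(),
) -> PositionalTrack:
    """Raw positional track: 2 per identical aligned residue, 1 per
    conserved one, summed over positive profiles, averaged over the two
    substitution matrices.  Residues outside every realigned region are 0."""
    L = len(protein)
    per_matrix = [np.zeros(L) for _ in matrices]
    for prof, survivors in survivors_by_profile:
        spans = [
            fa.query_span_original for fa in survivors if fa.query_span_original is not None
        ]
        if not spans:
            continue
        for a, b in _merge_spans(spans):
            segment = protein.residues[a:b]
            for t_idx, mat_name in enumerate(matrices):
                aligner = _aligner(mat_name, gap)
                mat = aligner.substitution_matrix
                alns = aligner.align(segment, prof.consensus)
                if len(alns) == 0:
                    continue
                aln = alns[0]  # deterministic first optimal alignment
                seg_blocks, cons_blocks = aln.aligned
                for (ss, se), (cs, _) in zip(seg_blocks, cons_blocks):
                    for off in range(se - ss):
                        r_prot = segment[ss + off]
                        r_cons = prof.consensus[cs + off]
                        if r_prot == r_cons:
                            per_matrix[t_idx][a + ss + off] += 2
                        elif mat[r_prot, r_cons] > 0:
                            per_matrix[t_idx][a + ss + off] += 1
    raw = np.mean(per_matrix, axis=0)
    return PositionalTrack(protein.id, raw, "raw")


def normalize(track: PositionalTrack) -> PositionalTrack:
    """Center the track at mean zero."""
    return PositionalTrack(track.protein_id, track.scores - track.scores.mean(), "normalized")


def smooth(track: PositionalTrack, window: int = 8) -> PositionalTrack:
    """Centered moving average of width ``window`` with edge truncation
    (shorter windows at the ends, so a constant track is unchanged).  For
    even widths the window extends one further to the left."""
    x = track.scores
    n = len(x)
    if not 1 <= window <= n:
        raise ValueError(f"window must be in 1..{n}")
    left, right = window // 2, (window - 1) // 2
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - left), min(n, i + right + 1)
        out[i] = x[lo:hi].mean()
    return PositionalTrack(track.protein_id, out, "smoothed")


def baseline(track: PositionalTrack) -> PositionalTrack:
    """Discontinuous baselining: the piecewise-linear curve through the
    endpoints and every local minimum is subtracted, so the result is
    exactly 0 at each anchor.  A plateau flanked by higher values on both
    sides counts as a minimum (all its points anchor)."""
    s = track.scores
    n = len(s)
    anchors = {0, n - 1} if n > 1 else {0}
    # run-length encode to treat flat valleys as minima
    runs = []  # (value, start, end)
    start = 0
    for i in range(1, n + 1):
        if i == n or s[i] != s[start]:
            runs.append((s[start], start, i))
            start = i
    for r, (val, a, b) in enumerate(runs):
        if 0 < r < len(runs) - 1 and runs[r - 1][0] > val and runs[r + 1][0] > val:
            anchors.update(range(a, b))
    anchors = sorted(anchors)
    base = np.interp(np.arange(n), anchors, s[anchors])
    return PositionalTrack(track.protein_id, s - base, "baselined")


def smooth_and_baseline(track: PositionalTrack, window: int = 8) -> PositionalTrack:
    """Smooth a mean-zero track and subtract its local-minima baseline."""
    if track.stage != "normalized":
        raise ValueError("smooth_and_baseline expects a normalized (mean-zero) track")
    return baseline(smooth(track, window))


def annotate(
    protein: ProteinSequence,
    survivors_by_profile: Sequence[tuple[ScoringProfile, Sequence[FinalAlignment]]],
    window: int = 8,
    matrices: tuple[str, str] = ("BLOSUM62", "BLOSUM45"),
    gap: GapParams = GapParams(),
) -> dict[str, PositionalTrack]:
    """Run the whole pipeline; returns all four stages keyed by stage name."""
    raw = positional_track(protein, survivors_by_profile, matrices, gap)
    norm = normalize(raw)
    sm = smooth(norm, window)
    return {"raw": raw, "normalized": norm, "smoothed": sm, "baselined": baseline(sm)}
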