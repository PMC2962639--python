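"""Deterministic synthetic data: profiles, planted homologs, benchmarks.

The generator emulates twilight-zone remote-homology test pairs: a hidden
"fold" profile, and query sequences carrying a mutated copy of its
consensus (identity controlled by an i.i.d. substitution model) between
random flanks.  Everything derives from an integer seed, so every fixture
is reproducible byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .align_core import SubstitutionMatrix
from .seqio import ALPHABET, ProteinSequence, ScoringProfile

_B62: Optional[SubstitutionMatrix] = None


def _blosum62() -> SubstitutionMatrix:
    global _B62
    if _B62 is None:
        _B62 = SubstitutionMatrix.load("BLOSUM62")
    return _B62


@dataclass(frozen=True)
class PlantSpec:
    """How to plant one homologous domain copy into a query.

    ``planted_identity`` is the per-position probability of keeping the
    consensus residue; mutated positions are replaced uniformly by one of
    the other 19 residues.  ``indel_rate`` (default 0 so span ground truth
    stays exact) additionally deletes or inserts residues at that rate.
    """

    planted_identity: float
    flank_before: int
    flank_after: int
    rng_seed: int
    indel_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.planted_identity <= 1:
            raise ValueError("planted_identity must be in (0, 1]")
        if self.flank_before < 0 or self.flank_after < 0:
            raise ValueError("flank lengths must be >= 0")


@dataclass(frozen=True)
class PlantedSpan:
    """Ground truth of one planted domain copy (0-based, half-open)."""

    start: int
    end: int
    realized_identity: float


def _random_residues(rng: np.random.Generator, length: int) -> str:
    return "".join(ALPHABET[i] for i in rng.integers(0, 20, size=length))


def generate_profile(n: int, rng_seed: int, profile_id: Optional[str] = None) -> ScoringProfile:
    """A random profile: uniform random consensus, PSSM columns equal to the
    BLOSUM62 row of each consensus residue (so each column peaks at its
    consensus residue and the consensus self-score is the diagonal sum)."""
    if n < 5:
        raise ValueError("profile length must be >= 5")
    rng = np.random.default_rng(rng_seed)
    idx = rng.integers(0, 20, size=n)
    consensus = "".join(ALPHABET[i] for i in idx)
    b62 = _blosum62().scores[:20, :20]
    return ScoringProfile(profile_id or f"prof{rng_seed}", consensus, b62[idx].copy())


def plant_homolog(
    profile: ScoringProfile, spec: PlantSpec, query_id: Optional[str] = None
) -> tuple[ProteinSequence, PlantedSpan]:
    """A query carrying one mutated consensus copy between random flanks."""
    rng = np.random.default_rng(spec.rng_seed)
    n = len(profile)
    keep = rng.random(n) < spec.planted_identity
    shift = rng.integers(1, 20, size=n)  # offset into the other 19 residues
    copy = []
    cons_idx = np.array([ALPHABET.index(c) for c in profile.consensus])
    for i in range(n):
        j = cons_idx[i] if keep[i] else (cons_idx[i] + shift[i]) % 20
        copy.append(ALPHABET[j])
    realized = float(keep.mean())
    domain = "".join(copy)
    if spec.indel_rate > 0:
        kept_chars = []
        for ch in domain:
            if rng.random() < spec.indel_rate:
                continue  # deletion
            kept_chars.append(ch)
            if rng.random() < spec.indel_rate:
                kept_chars.append(_random_residues(rng, 1))  # insertion
        domain = "".join(kept_chars)
    before = _random_residues(rng, spec.flank_before)
    after = _random_residues(rng, spec.flank_after)
    residues = before + domain + after
    span = PlantedSpan(len(before), len(before) + len(domain), realized)
    qid = query_id or f"q{spec.rng_seed}"
    return ProteinSequence(qid, residues), span


@dataclass
class Benchmark:
    """A desk-scale fold-recognition benchmark: hidden group profiles, member
    queries planted from them, and fold-group labels for ROC evaluation."""

    queries: list[ProteinSequence]
    labels: dict[str, str]
    profiles: list[ScoringProfile]
    truths: dict[str, PlantedSpan]


def generate_benchmark(
    n_groups: int,
    members_per_group: int,
    identity: float,
    rng_seed: int,
    profile_length: int = 60,
    flank_range: tuple[int, int] = (10, 30),
) -> Benchmark:
    """One hidden profile per fold group; each member query is an
    independent planted-homolog draw at the given identity."""
    if n_groups < 1 or members_per_group < 1:
        raise ValueError("counts must be >= 1")
    ss = np.random.SeedSequence(rng_seed)
    children = ss.spawn(n_groups * (members_per_group + 1))
    queries, labels, profiles, truths = [], {}, [], {}
    ci = 0
    for g in range(n_groups):
        gid = f"g{g}"
        prof_seed = int(children[ci].generate_state(1)[0] % 2**31)
        ci += 1
        prof = generate_profile(profile_length, prof_seed, profile_id=f"{gid}_prof")
        profiles.append(prof)
        for mem in range(members_per_group):
            child = children[ci]
            ci += 1
            mseed = int(child.generate_state(1)[0] % 2**31)
            rng = np.random.default_rng(mseed)
            fb = int(rng.integers(flank_range[0], flank_range[1] + 1))
            fa = int(rng.integers(flank_range[0], flank_range[1] + 1))
            spec = PlantSpec(identity, fb, fa, mseed)
            qid = f"{gid}_m{mem}"
            seq, span = plant_homolog(prof, spec, query_id=qid)
            queries.append(seq)
            labels[qid] = gid
            truths[qid] = span
    return Benchmark(queries, labels, profiles, truths)
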