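from __future__ import annotations

import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from agb.adaptive import SearchParams, adaptive_search
from agb.embedding import exhaustive_embedded_search
from agb.fixtures import PlantSpec, generate_profile, plant_homolog


@dataclass
class PlantedFixture:
    profile: object
    query: object
    span: object
    identity: float
    adaptive: object
    exhaustive: object


def make_planted(trial_seed: int, identity: float, n: int, flank_before: int, flank_after: int):
    profile = generate_profile(n, trial_seed * 2 + 1)
    query, span = plant_homolog(
        profile, PlantSpec(identity, flank_before, flank_after, trial_seed * 2 + 2)
    )
    return profile, query, span


def run_batch(n_fixtures: int, seed: int, ident_lo: float, ident_hi: float) -> list[PlantedFixture]:
    """Planted-domain fixtures with both search modes run under identical
    parameters (query <= 120 aa, profile 40-60 aa)."""
    rng = np.random.default_rng(seed)
    out = []
    params = SearchParams()
    for _ in range(n_fixtures):
        ident = float(rng.uniform(ident_lo, ident_hi))
        n = int(rng.integers(40, 61))
        fb = int(rng.integers(10, 31))
        fa = int(rng.integers(10, 31))
        profile, query, span = make_planted(int(rng.integers(2**30)), ident, n, fb, fa)
        res_a = adaptive_search(query, profile, params)
        res_e = exhaustive_embedded_search(
            query, profile, params.seed_fraction_pct, params.thresholds,
            params.gap, alpha=params.alpha,
        )
        out.append(PlantedFixture(profile, query, span, ident, res_a, res_e))
    return out


@pytest.fixture(scope="session")
def planted_batch() -> list[PlantedFixture]:
    """The 200-fixture batch shared by the soundness / sensitivity /
    work-reduction checks (identities 0.3-0.7)."""
    return run_batch(200, seed=20260101, ident_lo=0.3, ident_hi=0.7)


@pytest.fixture(scope="session")
def unrelated_pairs():
    """100 (profile, random query) pairs with no planted homology."""
    rng = np.random.default_rng(777)
    from agb.fixtures import _random_residues
    from agb.seqio import ProteinSequence

    pairs = []
    for t in range(100):
        prof = generate_profile(int(rng.integers(40, 61)), 5000 + t)
        qlen = int(rng.integers(60, 121))
        pairs.append((prof, ProteinSequence(f"u{t}", _random_residues(rng, qlen))))
    return pairs


@pytest.fixture
def small_profile():
    return generate_profile(40, 11)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
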