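import numpy as np
import pytest

import oracles
from agb import _dp
from agb.adaptive import (
    FilterThresholds,
    SearchParams,
    adaptive_search,
    filter_alignments,
    find_partial_alignments,
    max_gap,
    seeded_alignment,
    select_seed_positions,
)
from agb.align_core import GapParams
from agb.embedding import build_chimera, extract_seed
from agb.fixtures import PlantSpec, generate_profile, plant_homolog, _random_residues
from agb.seqio import ProteinSequence


class TestPartialAlignments:
    def test_self_query_full_diagonal(self):
        prof = generate_profile(40, 11)
        query = ProteinSequence("q", prof.consensus)
        parts = find_partial_alignments(prof, query)
        assert len(parts) == 1
        assert parts[0].target_span == (0, 40) and parts[0].query_span == (0, 40)

    def test_two_copies_two_partials(self, rng):
        """Two consensus copies around a 30-residue random linker give two
        partial alignments, one per copy, non-overlapping on the query."""
        prof = generate_profile(40, 11)
        query = ProteinSequence(
            "q", prof.consensus + _random_residues(rng, 30) + prof.consensus
        )
        parts = find_partial_alignments(prof, query)
        assert len(parts) == 2
        (a, b) = sorted(p.query_span for p in parts)
        assert a[1] <= b[0]  # disjoint on the query
        assert all(p.target_span == (0, 40) for p in parts)

    def test_length_gate(self):
        """With the partial-length threshold at the full target length, a
        query holding only half the profile yields nothing."""
        prof = generate_profile(40, 12)
        query = ProteinSequence("q", prof.consensus[:20])
        params = SearchParams(thresholds=FilterThresholds(min_partial_fraction=1.0))
        assert find_partial_alignments(prof, query, params) == []

    @pytest.mark.parametrize("trial", range(5))
    def test_pairwise_non_overlapping(self, trial):
        rng = np.random.default_rng(trial)
        prof = generate_profile(50, 600 + trial)
        query, _ = plant_homolog(prof, PlantSpec(0.5, 20, 20, 700 + trial))
        parts = find_partial_alignments(prof, query)
        for i, a in enumerate(parts):
            for b in parts[i + 1 :]:
                t_ov = a.target_span[0] < b.target_span[1] and b.target_span[0] < a.target_span[1]
                q_ov = a.query_span[0] < b.query_span[1] and b.query_span[0] < a.query_span[1]
                assert not (t_ov and q_ov)


class TestMaxGap:
    @pytest.mark.parametrize(
        "score, gop, gep, expected",
        [(30, 11, 1, 19), (11, 11, 1, 0), (5, 11, 1, 0), (31, 11, 2, 10)],
    )
    def test_formula(self, score, gop, gep, expected):
        prof = generate_profile(50, 1)
        seed = extract_seed(prof, 10, "N")
        seed = type(seed)(seed.residues, "N", seed.source_profile_id, score, seed.target_span)
        assert max_gap(seed, GapParams(gop, gep)) == expected


class TestSelectSeedPositions:
    def _partial(self, prof, query):
        parts = find_partial_alignments(prof, query)
        assert parts
        return parts[0]

    def test_clipping_at_query_start(self):
        """A partial starting at query position 0 gives an N range that
        begins at 0."""
        prof = generate_profile(40, 13)
        query = ProteinSequence("q", prof.consensus + "AAAAA")
        pa = self._partial(prof, query)
        seed = extract_seed(prof, 10, "N")
        rng_ = select_seed_positions(pa, seed, GapParams(), len(query))
        assert rng_.q_start == 0

    def test_range_bounds(self):
        prof = generate_profile(50, 14)
        query, _ = plant_homolog(prof, PlantSpec(0.7, 25, 25, 15))
        pa = self._partial(prof, query)
        m = len(query)
        ys, ye = pa.query_span
        for terminal in ("N", "C"):
            seed = extract_seed(prof, 10, terminal)
            g = max_gap(seed, GapParams())
            r = select_seed_positions(pa, seed, GapParams(), m)
            assert 0 <= r.q_start <= r.q_end <= m - 1
            if terminal == "N":
                assert r.q_start == max(0, ys - g - seed.k)
                assert r.q_end == min(ye - 1, m - 1)
            else:
                assert r.q_start == ys + 1
                assert r.q_end == min(ye + g, m - 1)


class TestSeededAlignment:
    def test_alpha_zero_equals_anchored_sw(self):
        """With the length adjustment off, the seeded DP is the standard
        anchored local extension (independent python DP oracle)."""
        for trial in range(6):
            rng = np.random.default_rng(trial)
            prof = generate_profile(30, 800 + trial)
            query, _ = plant_homolog(prof, PlantSpec(0.5, 10, 10, 900 + trial))
            for terminal in ("N", "C"):
                seed = extract_seed(prof, 10, terminal)
                for q in [0, len(query) // 2, len(query) - 1]:
                    chim = build_chimera(query, seed, q)
                    fa = seeded_alignment(chim, prof, alpha=0.0)
                    S = prof.score_matrix(chim.residues).astype(float)
                    n, k = len(prof), seed.k
                    if terminal == "N":
                        ext = oracles.best_extension(S[k:, q + k :], 11, 1)
                    else:
                        ext = oracles.best_extension(S[: n - k, :q][::-1, ::-1], 11, 1)
                    assert fa.raw_score == seed.score + int(round(ext))
                    assert fa.adjusted_score == pytest.approx(fa.raw_score)

    def test_verbatim_consensus_full_coverage(self):
        prof = generate_profile(40, 16)
        query = ProteinSequence("q", "AAAA" + prof.consensus)
        seed = extract_seed(prof, 10, "N")
        chim = build_chimera(query, seed, 4)
        fa = seeded_alignment(chim, prof)
        assert fa.coverage_pct == 100.0

    def test_length_bonus_prefers_long_low_score(self):
        """Two candidate extensions — short/high (raw 40, length 10) vs
        long/low (raw 36, length 30) — flip order under alpha = 0.25."""
        diag = [4.0] * 10 + [-2.0] * 10 + [1.6] * 10
        S = np.full((30, 30), -100.0)
        np.fill_diagonal(S, diag)
        best0, path0 = _dp.extend(S, 11, 1, 0.0)
        best25, path25 = _dp.extend(S, 11, 1, 0.25)
        assert best0 == pytest.approx(40.0) and len(path0) == 10
        assert best25 == pytest.approx(36.0 + 0.25 * 30) and len(path25) == 30

    def test_identity_excludes_seed(self):
        """A seed-only alignment has identity 0 (no non-seed columns)."""
        prof = generate_profile(40, 17)
        query = ProteinSequence("q", _random_residues(np.random.default_rng(3), 60))
        seed = extract_seed(prof, 10, "N")
        chim = build_chimera(query, seed, 59)
        fa = seeded_alignment(chim, prof)
        if all(fa.q <= c < fa.q + fa.k for _, c in fa.columns if c is not None):
            assert fa.identity_pct == 0.0

    def test_raw_score_consistency(self, planted_batch):
        """adjusted = raw + alpha * length holds on real survivors."""
        for fx in planted_batch[:20]:
            for fa in fx.exhaustive.alignments[:5]:
                assert fa.adjusted_score == pytest.approx(
                    fa.raw_score + 0.25 * len(fa.columns), abs=1e-6
                )


class TestFilter:
    def _fake(self, cov, ident):
        from agb.adaptive import FinalAlignment

        return FinalAlignment(
            "q", "p", "N", 0, 4, [], 0, 0.0, cov, ident, (0, 10), (0, 10), None, None
        )

    def test_strict_gates(self):
        th = FilterThresholds(60, 10)
        assert filter_alignments([self._fake(59.9, 50)], th) == []
        assert filter_alignments([self._fake(60.0, 50)], th) == []  # strict >
        assert not filter_alignments([self._fake(100, 0.0)], th)  # seed-only
        assert len(filter_alignments([self._fake(100, 100)], th)) == 1

    def test_monotone_in_thresholds(self, planted_batch):
        """Raising either threshold never increases the survivor count."""
        for fx in planted_batch[:10]:
            alns = fx.exhaustive.alignments
            for covs in ([40, 60, 85, 100],):
                counts = [
                    len(filter_alignments(alns, FilterThresholds(c, 10))) for c in covs
                ]
                assert counts == sorted(counts, reverse=True)
            counts = [
                len(filter_alignments(alns, FilterThresholds(60, i)))
                for i in [0, 10, 25, 50]
            ]
            assert counts == sorted(counts, reverse=True)


class TestAdaptiveSearch:
    def test_subset_of_oracle(self, planted_batch):
        for fx in planted_batch[:50]:
            ka = {fa.key() for fa in fx.adaptive.alignments}
            ke = {fa.key() for fa in fx.exhaustive.alignments}
            assert ka <= ke

    def test_unrelated_no_work(self, unrelated_pairs):
        """Unrelated pairs trigger few or no seeded DP calls, always < 2m."""
        counts = []
        for prof, query in unrelated_pairs[:60]:
            res = adaptive_search(query, prof)
            assert res.dp_invocations < 2 * len(query)
            counts.append(res.dp_invocations)
        assert float(np.median(counts)) == 0.0
        assert np.mean(counts) < 0.2 * np.mean([2 * len(q) for _, q in unrelated_pairs[:60]])

    def test_planted_domain_recovered(self):
        """A 70%-identity planted domain yields a survivor covering >= 80%
        of the planted query span."""
        for trial in range(5):
            prof = generate_profile(60, 40 + trial)
            query, span = plant_homolog(prof, PlantSpec(0.7, 20, 20, 50 + trial))
            res = adaptive_search(query, prof)
            best = 0.0
            for fa in res.alignments:
                if fa.query_span_original:
                    a, b = fa.query_span_original
                    ov = max(0, min(b, span.end) - max(a, span.start))
                    best = max(best, ov / (span.end - span.start))
            assert best >= 0.8

    def test_coverage_bound(self, planted_batch):
        for fx in planted_batch[:50]:
            for fa in fx.adaptive.alignments:
                assert 0 <= fa.coverage_pct <= 100
                assert 0 <= fa.identity_pct <= 100

    def test_deterministic(self):
        prof = generate_profile(50, 60)
        query, _ = plant_homolog(prof, PlantSpec(0.5, 15, 15, 61))
        r1 = adaptive_search(query, prof)
        r2 = adaptive_search(query, prof)
        assert [f.key() for f in r1.alignments] == [f.key() for f in r2.alignments]
        assert r1.dp_invocations == r2.dp_invocations
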