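# Methods

## Model and procedure

The package measures remote homology by *seed embedding*. Inserting a
short exact copy of a profile terminus into the query guarantees a
perfect local anchor, and the alignment that grows from that anchor
reports whether weak homologous signal surrounds the insertion point.
Repeating the insertion at every query position (the exhaustive mode)
amplifies all alignments the query can support; the adaptive mode
reproduces a subset of those alignments from far fewer dynamic-programming
runs by predicting, from ordinary unseeded alignments, where an inserted
seed could extend.

Coordinates are 0-based and half-open everywhere. A chimera with seed
length `k` at position `q` maps original query index `j` to chimera index
`j` for `j < q` and `j + k` for `j ≥ q`; the seed occupies `[q, q+k)`.
Chimera insert positions are enumerated over `q ∈ 0..m−1` (a seed behind
the last residue is constructible but adds no new region of interest).

### The alignment substrate

Word hits (width 3, window score strictly above 11), X-drop ungapped
extension (drop-off 7, minimum HSP score 25, hits consumed by accepted
HSPs so same-diagonal HSPs are disjoint), and affine-gap gapped extension
(gap open 11, extend 1; a gap of length g costs `11 + g`) from the *GE
starting pair*, defined as the central pair of the maximal-scoring
length-11 window of the HSP. Scores in this layer are integers; DP
traceback ties resolve diagonal > gap-in-query > gap-in-target, and the
earliest best cell (row-major) wins, so outputs are byte-reproducible.
Scoring is column-wise against the PSSM; a substitution matrix may stand
in, scoring each query residue against the consensus residue. The
unknown residue X scores −1 against any PSSM column.

### Seeded alignment and the length adjustment

The seed block aligns exactly (profile terminus against its own copy) and
contributes its self-score `Score(S)`. The DP extends only into the
region of interest — rightward of the seed for N-terminal seeds, leftward
for C-terminal ones — because alignments on the other side exist already
in the unseeded search. During the DP, cell comparisons use
`adjusted = raw + α·a`, where `a` is the alignment length at that cell:
in the twilight zone a long alignment with a slightly lower raw score is
the biologically better answer, and `α` (default 0.25, 0 disables)
implements exactly that trade. The final alignment is the traceback from
the best adjusted cell.

One guard applies: the length adjustment arbitrates between extensions
but cannot create one. If the best adjusted cell's extension does not
increase the *raw* score over the seed alone, the seed-only alignment is
returned instead. Without this guard the `+α` per column lets the DP
assemble long, meandering chance alignments on unrelated sequence pairs
whose span coverage then passes the filters; with it, chance survivors
drop sharply while genuinely scoring extensions are untouched.

Filters are strict: coverage (aligned target span as % of target length)
must exceed 60 and identity must exceed 10. Identity is counted only
outside the seed columns, over the non-seed alignment length including
gap columns; a seed-only alignment has identity 0 and never survives.

### Seed-position selection

For a partial alignment with query span `[ys, ye)` and a seed with score
`Score(S)`, the maximum bridgeable gap is
`G(S) = max(0, ⌊(Score(S) − GOP)/GEP⌋)` — the longest gap whose
open-plus-extend penalty the seed's score offsets. An N-terminal seed is
placed at `q ∈ [max(0, ys − G − k), min(ye − 1, m − 1)]`: up to `G + k`
positions before the partial (the seed pays the bridge) and anywhere
inside its span, where the remaining piece of the partial is reached with
no gap at all. C-terminal seeds get the mirror image
`[ys + 1, min(ye + G, m − 1)]`. Upper clipping at `m − 1` keeps the
adaptive search inside the position set the exhaustive reference
enumerates, preserving exact containment of its output.

Selection is a heuristic and intentionally one-sided: it is *sound*
(never invents an alignment the exhaustive search would not find — the
same DP runs at a subset of positions) but not complete. The anchored DP
can cross unrelated flanking sequence at roughly one mismatch penalty per
column and can borrow against the homologous domain's own score surplus,
so filter survivors occasionally arise at insert positions farther from
the partial alignment than `G(S)` anticipates, or in instances where
Step 1 found no partial alignment at all. On planted-domain data at
identities 0.3–0.7 the adaptive search recovers ~85–90% of the exhaustive
survivors while running well under half (typically a tenth) of the `2m`
seeded DPs; the missing survivors are overwhelmingly redundant placements
of the same domain hit, which is why fold-recognition rankings built from
the composite scores are essentially unchanged.

### Composite scores, ROC, trees

Per query/profile pair, survivors from both terminals pool into one list
and `composite = count × mean(identity) × max(coverage)` with identity
and coverage as fractions — 0 exactly when nothing survives, never more
than the survivor count. Pearson similarity is undefined for constant
profile vectors; such pairs are reported missing and excluded from
rankings rather than coerced to 0. Top-k ROC points pool TP/FP/TN/FN
counts over queries whose fold group has at least one other member, so
`sensitivity = TP/(TP+FN)` and `FPR = FP/(FP+TN)` hold exactly on the
reported counts; for equal-size groups this coincides with per-query
averaging. Similarity ties break lexicographically by query id.
Dendrograms use average-linkage clustering on `1 − r` (Pearson) or
Euclidean distance, written as Newick with branch lengths.

### Positional tracks

For every profile with survivors, the union of survivor query spans
(merged intervals, in original query coordinates) is realigned in full by
local Smith–Waterman under BLOSUM62 and BLOSUM45 (gap costs as above).
Aligned residues score 2 if identical, 1 if the matrix score of the pair
is positive, 0 otherwise (gap-aligned residues score 0); "positive" means
substitution-matrix score > 0 since the realignment itself is
matrix-based. Per-matrix tracks are summed over profiles, then averaged
across the two matrices — neither matrix is reliably better, so their
mean is reported. The raw track is normalized to mean zero, smoothed and
baselined:

* smoothing is a centered moving average of width `window` (default 8,
  width 7 also used for repeat-domain profiles) with edge truncation, so
  a constant track is unchanged — a transparent linear-phase low-pass
  stand-in for proprietary spreadsheet smoothers, with the window
  exposed;
* baselining subtracts the piecewise-linear curve through the endpoints
  and every local minimum of the smoothed track (a flat valley counts as
  a minimum and all its points anchor), so the result is exactly 0 at
  each anchor and peaks are measured from their local floor.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| seed fraction `p` | 10 | % of profile length | seed size `k = max(1, ⌊p·n/100⌋)` |
| word size / min word score | 3 / 11 | residues / score | hit definition |
| drop-off / min HSP score | 7 / 25 | score | ungapped extension and HSP gate |
| GOP / GEP | 11 / 1 | score | affine gaps, also in `G(S)` |
| `α` | 0.25 | score per column | length adjustment; 0 = plain DP |
| min coverage / min identity | 60 / 10 | % | survivor filter (strict >) |
| min partial fraction | 0.10 | of target length | Step 1 length gate |
| smoothing window | 8 | residues | positional track |

BLAST-protein conventions fill the values the method names but does not
fix; all are overridable from the CLI and the `SearchParams` bundle.

## The synthetic generator

`fixtures` emulates twilight-zone fold-recognition pairs: a random
consensus over the 20 residues with PSSM columns equal to the BLOSUM62
row of the consensus residue (columns peak at the consensus; the
consensus self-score is the diagonal sum), and queries carrying one
mutated consensus copy — each position independently kept with the
planted identity, otherwise replaced uniformly by one of the other 19
residues — between uniform random flanks (10–30 residues in the bundled
benchmarks). The substitution model has no indels by default so planted
spans are exact ground truth; an indel rate exists for stress tests.
Benchmarks draw one hidden profile per fold group (default length 60)
and independent member queries, with all randomness derived from one
integer seed, so every fixture is byte-reproducible.

What the generator does *not* emulate: real PSSM column sharpness
(log-odds columns from deep alignments are spikier than BLOSUM rows),
compositional bias and low-complexity regions, domain architecture with
multiple distinct domains, and insertions/deletions inside the homologous
copy. Passing tests therefore demonstrate the algorithmic properties —
soundness, work reduction, reuse laws, filter behaviour, ranking
separation — under a clean substitution-only model, not database-scale
performance on natural sequences.

## Numerical choices and degenerate inputs

Integer scoring throughout the substrate; the seeded DP runs in float64
only because of `α`, and raw scores are recomputed from the traceback
columns (an invariant `adjusted = raw + α·length` is asserted in tests).
Empty extension regions, seed-only alignments, queries shorter than the
word size, and profiles shorter than the seed all degrade gracefully
(empty results rather than errors). Hierarchical clustering requires at
least two rows; Pearson clustering refuses constant rows by name.
Problem sizes in the test suite and the acceptance script — 200
planted fixtures with queries ≤ 120 and profiles 40–60 residues, 50
fixtures ≤ 80 residues for the reuse laws, 100 unrelated pairs, a
5-group × 4-member ROC benchmark — are the package's chosen desk-scale
study conditions; all complete in well under a minute each on one CPU.

## Known limitations

* Seed-position selection is incomplete in the ways described above;
  survivor-level recovery of the exhaustive reference plateaus around
  85–90% on twilight-zone fixtures (composite-score rankings are far less
  affected, since misses are redundant placements).
* Unrelated sequence pairs can still pass the 60/10 filter through
  chance embedded alignments (the anchored DP grants every insert
  position an independent chance); such survivors stay at low identity
  and contribute small composite scores, and the score gap to genuine
  homology remains large, but the survivor count on random pairs is not
  zero.
* The smoothing filter is a moving average, not a reproduction of any
  proprietary implementation; only its linear-phase low-pass behaviour is
  relied upon.
* No e-value statistics: significance is handled entirely by the
  coverage/identity filters, as the method intends.
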