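# Methods

## Planar alignment model

An alignment is a path of points (r_n, q_n) in the plane spanned by the
reference (x-axis) and query (y-axis); consecutive points differ by a
deletion (r+1, q), an insertion (r, q+1) or a match/mismatch step
(r+1, q+1), and both coordinate sequences are monotone. CIGAR strings are the
run-length encoding of these steps, with soft clips for unaligned query ends.

## Index

The reference contigs are concatenated with a separator character (`#`) that
never matches a nucleotide, followed by the reverse complement of the whole
block and a terminator. Seeds therefore cannot span contig boundaries or the
strand junction, and both strands are searched by one index. Packed
coordinates `[0, L)` are forward-strand, `[L+1, 2L+1)` reverse; a reverse hit
(r, l) maps to forward start `2L + 1 − r − l`.

The index is a bidirectional FM-index: suffix array (numpy prefix-doubling,
O(n log² n), exact for any alphabet), BWT with full cumulative occurrence
counts, and bi-intervals `(start, mirror_start, size)` that support O(1)-style
backward and forward extension (forward extension is backward extension of the
complement on the mirror interval). `locate` reads positions from the retained
suffix array; an LF-stepped sampled array was rejected because the duplicated
separator class breaks the BWT wraparound's rank correspondence (extension is
unaffected — it never extends by a separator). `N` never matches during
seeding and scores as a mismatch in DP.

At the scales this package targets (up to a few megabases) the plain int64
suffix array and occurrence table are small; no compressed-index machinery is
attempted.

## Seeding

*Maximally spanning* seeds at query position i: maximal backward extension
then maximal forward extension gives one set of seeds sharing a query
interval; the opposite order gives a second set; the union is returned.
Extension stops when the next extension would empty the occurrence set, so the
returned set attains the extremal query begin/end reachable from i (verified
against exhaustive seed enumeration in the tests). *Binary seeding* seeds from
the center of the current query interval and recurses on the uncovered left
and right remainders; it terminates because the center set always covers the
center position, and it fully covers every query position whose character
occurs in the reference. Positions with characters absent from both strands
(including N) stay uncovered and are skipped — the alternative of failing the
whole read would make a single N fatal.

SMEMs (all non-enclosed maximal matches) are computed for comparison using the
monotonicity of the maximal forward reach end(i): the non-enclosed query
intervals are exactly the [i, end(i)) whose end exceeds every earlier one.

Seed filters: seeds shorter than `min_seed_size` are dropped; if more than
`max_ambiguity` seeds share one query interval, the entire group is purged
(over-ambiguous intervals are also skipped before locating, but their query
span still bounds the binary-seeding recursion). The coverage check
`Σ|s|/α ≥ |Q|/β` gives up on reads without periodic seed support; failing
reads are reported unmapped rather than guessed.

## Strip of consideration

λ = ⌊(s_M·|Q| − p_O)/p_E⌋ is the largest diagonal offset two seeds may have
while one alignment containing both can still score positively; a pathological
p_O > s_M·|Q| clamps λ to 0 with a warning. Seeds sorted by δ are swept with
two pointers (each advances at most |A_S| times); the maximal window ending at
each seed is a candidate strip, and strips are selected greedily by score so
that no returned strip's full-width window [δ_lo, δ_lo + λ] overlaps a
higher-scored one (ties keep the smallest δ_lo). The top strip provably
attains the global best window score (checked against an O(n²) oracle).
Because reverse-strand seeds carry packed coordinates, forward and reverse
hits land in disjoint δ-ranges and form separate strips; translocated or
inverted segments surface as separate strips and are emitted as supplementary
alignments. Strips below max(γ, ξ·|Q|) are purged before and after
harmonization.

## Harmonization

Two seeds conflict iff one's quadrant-II or quadrant-IV shadow encloses the
other's, i.e. (a) q ≤ q′ ∧ r′+l′ ≤ r+l or (b) r ≤ r′ ∧ q′+l′ ≤ q+l in either
argument order. Conflicts are enumerated by one line sweep per quadrant:
seeds visited by ascending start on one axis while the end positions on the
other axis sit in a sorted sweep status; any earlier seed whose stored end is
≥ the incoming seed's end is in conflict with it, and seeds with equal starts
always conflict. The union over both sweeps equals the brute-force pairwise
conflict set (property-tested), so the harmonization fixpoint is genuinely
pairwise-consistent.

The δ-guideline is fitted by RANSAC over the 3|S| start/center/end points of
the strip's seeds: 100 two-point hypotheses drawn with a seeded generator,
inlier tolerance max(10, 0.01·|Q|) reference-axis units, least-squares refit
on the best inlier set; fewer than two distinct points (or a single seed)
fall back to a slope-1 line through the longest seed's start. Distance of a
seed to the line is the reference-axis offset at the seed's center. Each
round purges, per surviving conflict pair, the more distant seed (ties:
shorter seed, then larger r, then larger q — fully deterministic); rounds
repeat until no conflict remains, at most |S| rounds since every round with
conflicts removes a seed.

Strip scheduling: strips pop by score. Long queries (> 1000 nt) inspect
exactly `soc_count_long` strips and discard those harmonizing below an
earlier harmonized score; short queries stop once the best harmonized score
was unchanged `lookahead_short` consecutive pops. Every emitted set re-passes
the score filter — except that when the filter would reject everything, the
best harmonized set is still emitted, preserving the guarantee that a read
passing the coverage check receives at least one alignment.

## Dynamic programming and assembly

Gotoh affine-gap DP with gaps opening from the match state only (no direct
insertion↔deletion transitions); the independent full-matrix oracle in the
test suite implements the same model. The banded variant restricts columns to
|j − i| ≤ band and must receive band ≥ |len(q) − len(r)| + 1; with a band
spanning the matrix it equals the full matrix (500-instance oracle check).
Matrices are filled row-wise in numpy; horizontal-gap scores within a row use
a prefix-max trick (`maximum.accumulate` of M + j·p_E), keeping the fill
vectorized. Traceback compares stored matrix values with a deterministic
M > Ix > Iy preference.

Assembly sorts the harmonized seeds, truncates the later seed of any
query/reference overlap (harmonization deliberately keeps overlapping
consistent seeds; the DP needs disjoint anchors), fills inter-seed gaps with
banded DP (band = |Δgap| + 16), encodes pure one-sided gaps directly, and
extends the ends semi-globally into reference windows of twice the tail
length plus slack, clamped at separators. Extension never ends in a gap and
clips the unconsumed query tail. The emitted score equals re-scoring the
CIGAR against the sequences (tested), and NM counts mismatches plus indel
bases.

Mapping quality is a score-gap heuristic (the original system never defines
its formula): round(60 · (best − second)/best · min(1, best/(s_M·|Q|))),
0 for ties, 60 when no same-locus competitor exists, clamped to the SAM range.
It is deliberately simple and not probability-calibrated.

## Scoring defaults

s_M = 2, s_X = 4, p_O = 24, p_E = 1. The heavy open / light extend profile is
a single-affine stand-in for the long-gap piece of two-piece schemes: with a
cheap open (e.g. p_O = 4, p_E = 2), splitting a structural deletion around a
chance in-gap match island gains s_M + s_X per rescued noisy flank base
against only one extra p_O, so the DP optimum fragments 100-nt gaps; with
p_O = 24 a split must rescue ≥ 4 such bases, which is rare, and injected
100-nt indels are reported as one gap run. The cost is that small true indels
pay the full open penalty, which lowers absolute scores on noisy reads but
not placements.

## Heuristic defaults

| symbol | meaning | default |
|---|---|---|
| α | coverage-check minimum seed length | 12 (10 for noisy presets) |
| β | coverage-check segment size (nt) | 100 |
| γ | absolute SoC score floor | 30 |
| ξ | SoC score floor as fraction of |Q| | 0.1 |
| minSeedSize | seed length floor | 16 (10 for noisy presets) |
| maxAmbiguity | max seeds per query interval | 100 |
| soc_count_long | strips inspected, long queries | 30 |
| lookahead_short | unchanged-score stop, short queries | 3 |
| long_query_cutoff | long/short boundary (nt) | 1000 |

γ, ξ, minSeedSize and maxAmbiguity are named but not valued by the method's
description; the defaults were chosen so 100-kb random genomes give tractable
seed counts, and all are CLI-exposed. `AlignerConfig.for_noisy_long_reads()`
lowers the seed floor to 10 because at 10–20 % error the mean exact-match run
is 5–10 nt while 10-mers remain near-unique on 10^5-bp genomes; for short
queries the pipeline additionally caps the floor at |Q|/4 so 100-nt reads are
not starved.

## Simulator

Genomes are i.i.d. uniform ACGT, optionally with planted duplicate segments
to create ambiguous placements. Reads draw a uniform origin and strand. The
error process walks the template: per base, an insertion run may be emitted
(probability ins_rate; geometric length, counted as one event) and a deletion
run may swallow the base and successors (del_rate, geometric, one event);
copied bases substitute with sub_rate to a uniformly different base. A
per-read scalar from equal-mass bins of width 0.5 over [0, 2] multiplies all
three rates, emulating the quality spread of real runs. The generator logs
Bernoulli trials per event class, so realized rates are compared to nominal
ones at the exact trial counts (binomial 3σ) without denominator bias.

Presets: `pacbio-like` 3.8 / 6.15 / 2.75 % (sub/ins/del), `uon-like`
4.5 / 5.0 / 8.5 % (a declared approximation of ultralong-nanopore,
deletion-heavy error), `illumina-like` 0.1 / 0.01 / 0.01 % at 250 nt, and
`error-free`. Quality strings are a constant Q20 placeholder (qualities are
ignored by the aligner). What the simulator does **not** model: sequence- and
position-dependent error (homopolymer compression), chimeric artefacts,
empirical read-length distributions, and base-quality information — so
passing tests demonstrate algorithmic correctness under calibrated random
noise, not performance on any particular instrument's reads.

SV injection places exactly one deletion (reference gap under the read) or
insertion (novel random sequence) at the read center before noise is applied,
recording breakpoints in the truth table.

## Evaluation

A seed is relevant if its reference interval overlaps the read's origin
interval (contig match; strand-agnostic since either strand leads to the
locus). A read aligns correctly if its primary alignment overlaps the truth
interval on the right contig and strand — placements at alternative copies of
duplicated segments count as wrong, since only the template location is known
correct. SV detection classifies the read's alignments into precise / split /
indicated / forced / trimmed / unaligned via a deterministic cascade with a
10-nt breakpoint window and 10 % size tolerance (all exposed): gap ops below
the window are treated as sequencing noise, and "precise" demands the
matching op be the only op of its type reaching half the SV size. Alignments
that cross the SV without representing it fall to "indicated" as the
catch-all — the original categories' exact boundary conditions are not public,
so this codification is the package's own and is stated here rather than
inferred.

## Problem sizes

The test and acceptance workloads run on 100-kb synthetic genomes with
30–200 reads of 1000 nt (plus 100 SV reads), 100 000 Monte-Carlo trials for
the indel-overlap probability, and oracle comparisons on hundreds of random
micro-instances; these sizes make every stage verifiable against brute force
while keeping the whole suite in tens of seconds. Relevance rates measured at
this scale (≈ 19 % for maximally-spanning seeds vs ≈ 8 % for SMEMs) are far
above what whole-genome references produce — only the ordering is meaningful,
and it is the ordering the tests assert.

## Known limitations

Single-end only. The semi-global end extension uses a fixed band rather than
an adaptive one. MAPQ is uncalibrated. Insertions and duplications are not
distinguished (insertions are always reported). The worst-case O(|S|²)
harmonization bound is accepted as-is; no adversarial-instance defenses are
attempted.
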