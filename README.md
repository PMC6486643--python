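# stripalign

A sequence-to-genome aligner for single-end reads from ~100 nt (Illumina) to
tens of kilobases (PacBio, ultralong nanopore), built on a three-stage scheme:

1. **Seeding.** A bidirectional FMD-style index over the packed reference
   (forward strand + reverse complement) yields *maximally spanning* seeds: at
   a query position *i*, maximal backward-then-forward and
   forward-then-backward extensions produce the seeds covering *i* that reach
   the extremal query begin/end. A divide-and-conquer *binary seeding* applies
   this from the query center outward and returns a fully covering seed set —
   a subset of the SMEMs with a much higher fraction of relevant seeds.
2. **Seed processing.** Each seed (q, r, l) lies on the reference diagonal
   δ = r − q. Sorting seeds by δ and sweeping a window of width
   λ = (s_M·|Q| − p_O)/p_E collects **strips of consideration (SoC)** —
   candidate regions scored by accumulated seed length, kept in a priority
   queue. Within each strip, **seed harmonization** purges pairwise
   inconsistent seeds (detected by a line sweep over the seeds' quadrant
   shadows) keeping, per conflict, the seed closer to a RANSAC-fitted
   **δ-guideline**. Unlike chaining, harmonization keeps consistent seeds that
   overlap on the query — which happens with probability 7/16 around an
   isolated indel.
3. **Dynamic programming.** Gaps between harmonized seeds are filled by banded
   Needleman–Wunsch/Gotoh with affine gap penalties; unaligned read ends are
   extended semi-globally with free end points, the remainder soft-clipped.

The package also ships a parametric read simulator (substitution / insertion /
deletion processes with per-read error scaling and optional injected
structural variants) and an evaluation harness (seed relevance rate, alignment
accuracy against simulation truth, and a six-way SV-detection classification:
precise / split / indicated / forced / trimmed / unaligned).

## Worked example

The classic seeding example — query `AATGG` against reference `AATCTGG`:

```python
>>> from stripalign import ReferencePack, build_index, smems
>>> idx = build_index(ReferencePack([("ref", "AATCTGG")]))
>>> [(s.q, s.r, s.l) for s in smems(idx, "AATGG") if s.l > 1]
[(0, 0, 3), (2, 4, 3)]
```

Two non-enclosed maximal seeds: `AAT` (query [0,3)) and `TGG` (query [2,5)),
overlapping by one base on the query because a `T` flanks the `CT` insertion
on either side. Gap-cost chaining must drop one of them; harmonization keeps
both, and assembly truncates the overlap before the DP fills the 2-nt gap.

Command line, end to end:

```sh
$ stripalign simulate --genome-length 20000 --reads 5 --preset error-free \
      --read-length 400 --seed 1 -o sim
wrote 5 reads -> sim.fq
$ stripalign index sim_ref.fa -o ref
indexed 20000 bp (1 contig(s)) -> ref.npz/.json
$ stripalign align ref sim.fq -o out.sam
aligned 5/5 reads
$ stripalign eval sim_truth.tsv out.sam
reads	5
aligned	5
accuracy	1.0000
```

`accuracy` is the fraction of reads whose primary alignment overlaps the
read's true origin interval on the correct contig and strand; error-free reads
from unique regions align exactly (all-match CIGAR at the truth position).

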