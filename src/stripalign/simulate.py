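"""Synthetic genomes and noisy reads with ground truth.

Reads are drawn from uniform random origins on either strand. Sequencing
noise is a parametric substitution/insertion/deletion process: per template
base an insertion run may be emitted (one *event* regardless of run length)
and a deletion run may swallow the base and its successors (also one event);
copied bases substitute to a different base with the substitution rate. A
per-read scalar multiplier of the three rates models read-quality spread,
drawn from equal-mass bins over [0, 2] of the mean error. Optionally exactly
one structural variant (insertion of novel sequence or deletion of reference)
is injected at the read center before noise is applied.

The generator logs the number of Bernoulli trials per event class so realized
rates can be checked against the nominal ones without denominator bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reference import ReferencePack, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class ErrorProfile:
    """Per-base event probabilities plus length/read-length distributions."""

    sub_rate: float = 0.038
    ins_rate: float = 0.0615
    del_rate: float = 0.0275
    indel_len_geom_p: float = 0.55  # geometric P(success); mean run = 1/p
    read_length: int = 1000
    read_length_sd: float = 0.0
    # per-read scale over the mean error: equal-mass bins of width 0.5
    scale_bins: tuple[tuple[float, float], ...] = (
        (0.0, 0.5),
        (0.5, 1.0),
        (1.0, 1.5),
        (1.5, 2.0),
    )

    def __post_init__(self) -> None:
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not 0 <= r < 1:
                raise ValueError("rates must lie in [0, 1)")

    def draw_scale(self, rng: np.random.Generator) -> float:
        lo, hi = self.scale_bins[rng.integers(len(self.scale_bins))]
        return float(rng.uniform(lo, hi))


#: Named presets. PacBio-like rates are half the twice-mean 7.6/12.3/5.5
#: substitution/insertion/deletion percentages; the UON-like and
#: Illumina-like presets are declared approximations (see docs/methods.md).
PRESETS: dict[str, ErrorProfile] = {
    "pacbio-like": ErrorProfile(sub_rate=0.038, ins_rate=0.0615, del_rate=0.0275),
    "uon-like": ErrorProfile(sub_rate=0.045, ins_rate=0.05, del_rate=0.085),
    "illumina-like": ErrorProfile(
        sub_rate=0.001, ins_rate=0.0001, del_rate=0.0001, read_length=250,
        scale_bins=((1.0, 1.0),),
    ),
    "error-free": ErrorProfile(sub_rate=0.0, ins_rate=0.0, del_rate=0.0,
                               scale_bins=((0.0, 0.0),)),
}


@dataclass
class ReadTruth:
    """Origin of a simulated read plus any injected structural variant."""

    read_id: str
    contig: str
    start: int  # origin interval [start, end) on the forward strand
    end: int
    strand: str
    sv_type: str = "none"  # none | insertion | deletion
    sv_size: int = 0
    sv_pos_ref: int = -1  # SV breakpoint, forward-strand contig coordinate
    sv_pos_read: int = -1  # SV breakpoint on the (pre-noise) read

    TSV_HEADER = "read_id\tcontig\tstart\tend\tstrand\tsv_type\tsv_size\tsv_pos_ref\tsv_pos_read"

    def tsv_line(self) -> str:
        return "\t".join(
            str(v)
            for v in (
                self.read_id, self.contig, self.start, self.end, self.strand,
                self.sv_type, self.sv_size, self.sv_pos_ref, self.sv_pos_read,
            )
        )


@dataclass
class EventLog:
    """Bernoulli trial/event counters for rate-recovery checks."""

    sub_trials: int = 0
    sub_events: int = 0
    ins_trials: int = 0
    ins_events: int = 0
    del_trials: int = 0
    del_events: int = 0

    def merge(self, other: "EventLog") -> None:
        for f in self.__dataclass_fields__:
            setattr(self, f, getattr(self, f) + getattr(other, f))


def generate_genome(
    length: int,
    rng_seed: int = 0,
    repeat_spec: list[tuple[int, int, int]] | None = None,
    n_contigs: int = 1,
) -> ReferencePack:
    """Uniform-random genome, optionally with planted duplicate segments.

    ``repeat_spec`` entries are (source_start, segment_length, n_extra_copies);
    each extra copy overwrites a random location, creating the ambiguous
    regions that exercise the seed-ambiguity cap.
    """
    if length < 1:
        raise ValueError("genome length must be >= 1")
    rng = np.random.default_rng(rng_seed)
    seq = _BASES[rng.integers(0, 4, size=length)]
    for src, seglen, copies in repeat_spec or []:
        segment = seq[src : src + seglen].copy()
        for _ in range(copies):
            dst = int(rng.integers(0, length - seglen + 1))
            seq[dst : dst + seglen] = segment
    full = seq.tobytes().decode("ascii")
    if n_contigs <= 1:
        return ReferencePack([("chr1", full)])
    bounds = np.linspace(0, length, n_contigs + 1).astype(int)
    return ReferencePack(
        [(f"chr{i+1}", full[bounds[i] : bounds[i + 1]]) for i in range(n_contigs)]
    )


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def apply_errors(
    template: str, profile: ErrorProfile, scale: float, rng: np.random.Generator,
    log: EventLog | None = None,
) -> str:
    """Run the per-base error process over a template, logging trials."""
    sub = min(0.95, profile.sub_rate * scale)
    ins = min(0.95, profile.ins_rate * scale)
    dele = min(0.95, profile.del_rate * scale)
    p_geom = profile.indel_len_geom_p
    out: list[str] = []
    i = 0
    n = len(template)
    while i < n:
        if log is not None:
            log.ins_trials += 1
            log.del_trials += 1
        if ins and rng.random() < ins:
            if log is not None:
                log.ins_events += 1
            out.append(_random_seq(rng, rng.geometric(p_geom)))
        if dele and rng.random() < dele:
            if log is not None:
                log.del_events += 1
            i += int(rng.geometric(p_geom))
            continue
        base = template[i]
        if log is not None:
            log.sub_trials += 1
        if sub and rng.random() < sub:
            if log is not None:
                log.sub_events += 1
            base = "ACGT"[(("ACGT".index(base) if base in "ACGT" else 0) + int(rng.integers(1, 4))) % 4]
        out.append(base)
        i += 1
    return "".join(out)


def inject_sv(
    ref: ReferencePack,
    read_origin: tuple[str, int, int, str],
    sv_type: str,
    sv_size: int,
    rng_seed: int = 0,
) -> tuple[str, ReadTruth]:
    """Error-free read with exactly one SV at its center, plus truth.

    A deletion removes ``sv_size`` reference bases under the read center (the
    origin interval widens accordingly); an insertion splices ``sv_size``
    novel random bases into the read. ``sv_size`` 0 returns the plain read.
    """
    contig, start, read_len, strand = read_origin
    rng = np.random.default_rng(rng_seed)
    if sv_size >= read_len:
        raise ValueError("SV size must be smaller than the read")
    seq = ref.contig_seq(contig)
    half = read_len // 2
    if sv_type == "deletion" and sv_size > 0:
        end = start + read_len + sv_size
        if end > len(seq):
            raise ValueError("origin interval exceeds contig")
        read = seq[start : start + half] + seq[start + half + sv_size : end]
        truth = ReadTruth("", contig, start, end, strand, "deletion", sv_size,
                          sv_pos_ref=start + half, sv_pos_read=half)
    elif sv_type == "insertion" and sv_size > 0:
        end = start + read_len - sv_size
        if end > len(seq):
            raise ValueError("origin interval exceeds contig")
        novel = _random_seq(rng, sv_size)
        read = seq[start : start + half] + novel + seq[start + half : end]
        truth = ReadTruth("", contig, start, end, strand, "insertion", sv_size,
                          sv_pos_ref=start + half, sv_pos_read=half)
    else:
        end = start + read_len
        if end > len(seq):
            raise ValueError("origin interval exceeds contig")
        read = seq[start:end]
        truth = ReadTruth("", contig, start, end, strand)
    if strand == "-":
        read = revcomp(read)
        if truth.sv_pos_read >= 0:
            truth.sv_pos_read = len(read) - truth.sv_pos_read
    return read, truth


def generate_reads(
    ref: ReferencePack,
    n: int,
    profile: ErrorProfile,
    rng_seed: int = 0,
    sv_type: str | None = None,
    sv_size: int = 0,
    log: EventLog | None = None,
    id_prefix: str = "read",
) -> tuple[list[tuple[str, str]], list[ReadTruth]]:
    """Simulate ``n`` reads; returns ([(read_id, sequence)], [ReadTruth]).

    Each read gets a uniform origin and strand, its own error scale, and (if
    requested) one injected SV before the error process runs.
    """
    rng = np.random.default_rng(rng_seed)
    reads: list[tuple[str, str]] = []
    truths: list[ReadTruth] = []
    contigs = ref.contigs
    weights = np.array([c.length for c in contigs], dtype=float)
    weights /= weights.sum()
    for k in range(n):
        rl = profile.read_length
        if profile.read_length_sd:
            rl = max(50, int(rng.normal(rl, profile.read_length_sd)))
        margin = rl + (sv_size if sv_type == "deletion" else 0)
        for _ in range(100):
            ci = int(rng.choice(len(contigs), p=weights))
            c = contigs[ci]
            if c.length >= margin:
                break
        else:
            raise ValueError("read length exceeds every contig")
        start = int(rng.integers(0, c.length - margin + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        read, truth = inject_sv(
            ref, (c.name, start, rl, strand), sv_type or "none", sv_size,
            rng_seed=int(rng.integers(0, 2**31 - 1)),
        )
        scale = profile.draw_scale(rng)
        read = apply_errors(read, profile, scale, rng, log)
        truth.read_id = f"{id_prefix}{k}"
        reads.append((truth.read_id, read))
        truths.append(truth)
    return reads, truths


def indel_overlap_simulation(
    n_trials: int, rng_seed: int = 0, flank: int = 12
) -> dict[str, float]:
    """Monte-Carlo rate of query-overlapping seeds around a 1-nt insertion.

    Each trial draws random flanks A and B and a random inserted base c,
    forming reference A+c+B against query A+B. The seed covering A extends
    maximally rightwards across the insertion, the seed covering B maximally
    leftwards; the two seeds overlap on the query exactly when either
    extension is non-empty. Under random sequences each side extends with
    probability 1/4, so the overlap probability is 7/16.

    Returns the observed overlap rate and the per-side extension rates.
    """
    rng = np.random.default_rng(rng_seed)
    chars = rng.integers(0, 4, size=(n_trials, 2 * flank + 1))
    overlap = left = right = 0
    for t in range(n_trials):
        row = chars[t]
        a, c, b = row[:flank], int(row[flank]), row[flank + 1 :]
        # reference around the breakpoint: ... a[-1] | c | b[0] ...
        # left seed walks right past the insertion while query (= b) matches
        # the reference continuation (= c then b again, shifted by one)
        ref_right = np.concatenate(([c], b))
        k = 0
        while k < flank and b[k] == ref_right[k]:
            k += 1
        ext_left = k
        # right seed walks left symmetrically
        ref_left = np.concatenate((a, [c]))[::-1]
        arev = a[::-1]
        k = 0
        while k < flank and arev[k] == ref_left[k]:
            k += 1
        ext_right = k
        left += ext_left >= 1
        right += ext_right >= 1
        overlap += (ext_left >= 1) or (ext_right >= 1)
    return {
        "overlap_rate": overlap / n_trials,
        "left_rate": left / n_trials,
        "right_rate": right / n_trials,
        "n": n_trials,
    }


def write_fastq(reads: list[tuple[str, str]], path: str, quality_char: str = "5") -> None:
    """Plain FASTQ with a constant Q20 placeholder quality string."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")


def write_truth(truths: list[ReadTruth], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(ReadTruth.TSV_HEADER + "\n")
        for t in truths:
            fh.write(t.tsv_line() + "\n")
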