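"""Evaluation against simulated truth: seed relevance, accuracy, SV classes.

A seed is *relevant* for a read when its reference interval overlaps the
read's true origin interval; the relevance rate of a seed set is the relevant
fraction. Alignment accuracy counts a read correct when its primary alignment
overlaps the truth interval on the right contig and strand — a placement at
an alternative copy of a duplicated region counts as wrong, since only the
template location is known to be correct.

SV detection is classified into six mutually exclusive categories (precise,
split, indicated, forced, trimmed, unaligned) from the CIGAR(s) an aligner
reports for a read with one injected indel.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
import pysam

from .reference import ReferencePack
from .seeding import Seed
from .simulate import ReadTruth

SV_CATEGORIES = ("precise", "split", "indicated", "forced", "trimmed", "unaligned")


def read_truth(path: str) -> dict[str, ReadTruth]:
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "contig": str})
    out: dict[str, ReadTruth] = {}
    for row in df.itertuples(index=False):
        out[row.read_id] = ReadTruth(
            row.read_id, row.contig, int(row.start), int(row.end), row.strand,
            row.sv_type, int(row.sv_size), int(row.sv_pos_ref), int(row.sv_pos_read),
        )
    return out


def _overlaps(a0: int, a1: int, b0: int, b1: int, tol: int = 0) -> bool:
    return a0 < b1 + tol and b0 < a1 + tol


def relevance_rate(seeds: list[Seed], truth: ReadTruth, pack: ReferencePack) -> float | None:
    """Fraction of seeds whose reference interval overlaps the truth interval.

    Strand-agnostic: a seed on either strand of the origin locus leads the
    aligner to the correct position. Returns None for an empty seed set.
    """
    if not seeds:
        return None
    hit = 0
    for s in seeds:
        try:
            contig, start, _ = pack.to_forward(s.r, s.l)
        except ValueError:
            continue  # seed crossing a boundary cannot be placed
        if contig == truth.contig and _overlaps(start, start + s.l, truth.start, truth.end):
            hit += 1
    return hit / len(seeds)


@dataclass(frozen=True)
class _Aln:
    """The slice of a SAM record the evaluator needs."""

    contig: str
    start: int  # 0-based reference interval [start, end)
    end: int
    strand: str
    cigar: list[tuple[int, str]]  # (length, op)
    is_primary: bool


def load_sam(path: str) -> dict[str, list[_Aln]]:
    """Group alignments by read name; unmapped records yield empty lists."""
    out: dict[str, list[_Aln]] = {}
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for rec in fh:
            out.setdefault(rec.query_name, [])
            if rec.is_unmapped:
                continue
            ops = "MIDNSHP=XB"
            cigar = [(ln, ops[op]) for op, ln in ((c[0], c[1]) for c in rec.cigartuples)]
            out[rec.query_name].append(
                _Aln(
                    contig=rec.reference_name,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                    cigar=cigar,
                    is_primary=not (rec.is_supplementary or rec.is_secondary),
                )
            )
    return out


def records_from_alignments(alignments) -> list[_Aln]:
    """Adapt in-memory Alignment objects (gapfill) to evaluator records."""
    out = []
    for a in alignments:
        cigar = list(reversed(a.cigar)) if a.strand == "-" else a.cigar
        out.append(
            _Aln(a.contig, a.pos, a.pos + a.ref_span, a.strand, cigar,
                 not a.is_supplementary)
        )
    return out


def alignment_accuracy(
    sam: str | dict[str, list[_Aln]],
    truths: dict[str, ReadTruth],
    tolerance: int = 0,
) -> float:
    """Fraction of reads whose primary alignment hits the truth locus."""
    grouped = load_sam(sam) if isinstance(sam, str) else sam
    missing = set(truths) - set(grouped)
    if missing:
        raise ValueError(f"{len(missing)} truth reads missing from SAM")
    correct = 0
    for rid, truth in truths.items():
        for a in grouped[rid]:
            if not a.is_primary:
                continue
            if (
                a.contig == truth.contig
                and a.strand == truth.strand
                and _overlaps(a.start, a.end, truth.start, truth.end, tolerance)
            ):
                correct += 1
            break
    return correct / len(truths) if truths else 0.0


def _gap_ops_with_positions(a: _Aln) -> list[tuple[str, int, int]]:
    """(op, size, reference breakpoint) for every I/D op of an alignment."""
    out = []
    rpos = a.start
    for n, op in a.cigar:
        if op == "D":
            out.append(("D", n, rpos))
            rpos += n
        elif op == "I":
            out.append(("I", n, rpos))
        elif op in ("M", "=", "X"):
            rpos += n
    return out


def classify_sv(
    alns: list[_Aln],
    truth: ReadTruth,
    window: int = 10,
    size_tol: float = 0.10,
    forced_min_frac: float = 0.5,
) -> str:
    """Assign one of the six SV-detection categories.

    precise    one alignment carries a single significant indel op of the
               truth type, size within ``size_tol``, breakpoint within window
    split      two alignments whose clip breakpoints bracket the SV
    indicated  a matching indel op exists but is misplaced or missized
    forced     the SV appears as >= 2 gap ops summing to >= half its size
    trimmed    an alignment is clipped within the window of the SV, no gap op
    unaligned  no alignment near the SV position

    Gap ops shorter than the window are regarded as sequencing noise; only
    ops reaching half the SV size count against the uniqueness required for
    "precise" (noise-scale indel runs elsewhere in the read do not).
    """
    want = "D" if truth.sv_type == "deletion" else "I"
    bp = truth.sv_pos_ref
    sv_ref_interval = (bp, bp + truth.sv_size) if want == "D" else (bp, bp)
    near = [
        a
        for a in alns
        if a.contig == truth.contig
        and _overlaps(a.start, a.end, sv_ref_interval[0], sv_ref_interval[1] + 1, window)
    ]
    if not near:
        return "unaligned"

    sig: list[tuple[str, int, int]] = []
    per_aln_sig: list[list[tuple[str, int, int]]] = []
    for a in near:
        g = [x for x in _gap_ops_with_positions(a) if x[1] >= window]
        per_aln_sig.append(g)
        sig.extend(g)

    def size_ok(n: int) -> bool:
        return abs(n - truth.sv_size) <= size_tol * truth.sv_size

    # precise: one alignment reports the SV as a single op of the right type,
    # size and breakpoint; no second comparably sized op of that type
    big_floor = max(window, forced_min_frac * truth.sv_size)
    for g in per_aln_sig:
        typed = [x for x in g if x[0] == want]
        big = [x for x in typed if x[1] >= big_floor]
        if (
            len(big) == 1
            and size_ok(big[0][1])
            and abs(big[0][2] - bp) <= window
        ):
            return "precise"

    # split: clip-adjacent breakpoints of two alignments bracket the SV
    if len(near) >= 2:
        left_bp = bp
        right_bp = bp + truth.sv_size if want == "D" else bp
        for a1 in near:
            for a2 in near:
                if a1 is a2:
                    continue
                if abs(a1.end - left_bp) <= window and abs(a2.start - right_bp) <= window:
                    return "split"

    # indicated: an op of the right type and size exists, but misplaced
    if any(x[0] == want and size_ok(x[1]) for x in sig):
        return "indicated"

    # forced: fragmented representation
    typed = [x for x in sig if x[0] == want]
    if len(typed) >= 2 and sum(x[1] for x in typed) >= forced_min_frac * truth.sv_size:
        return "forced"

    # trimmed: clipped near the SV without a matching gap op
    for a in near:
        clip_left = a.cigar and a.cigar[0][1] == "S" and abs(a.start - bp) <= window
        clip_right = a.cigar and a.cigar[-1][1] == "S" and abs(a.end - bp) <= window
        if clip_left or clip_right:
            return "trimmed"

    # the SV region is covered but not represented: counted as indicated
    return "indicated"


def sv_category_counts(
    sam: str | dict[str, list[_Aln]],
    truths: dict[str, ReadTruth],
    window: int = 10,
) -> dict[str, int]:
    grouped = load_sam(sam) if isinstance(sam, str) else sam
    counts = {c: 0 for c in SV_CATEGORIES}
    for rid, truth in truths.items():
        counts[classify_sv(grouped.get(rid, []), truth, window)] += 1
    return counts


def summary_report(
    sam: str | dict[str, list[_Aln]],
    truths: dict[str, ReadTruth],
    tolerance: int = 0,
    window: int = 10,
) -> dict:
    grouped = load_sam(sam) if isinstance(sam, str) else sam
    report: dict = {
        "reads": len(truths),
        "aligned": sum(1 for rid in truths if grouped.get(rid)),
        "accuracy": alignment_accuracy(grouped, truths, tolerance),
    }
    if any(t.sv_type != "none" for t in truths.values()):
        sv_truths = {rid: t for rid, t in truths.items() if t.sv_type != "none"}
        report["sv_categories"] = sv_category_counts(grouped, sv_truths, window)
    return report
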