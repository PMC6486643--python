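"""Minimal SAM emission for placed alignments.

Records are written on the forward reference strand: for reverse-strand hits
the CIGAR is reversed and the stored sequence is the reverse complement of
the read, per the SAM convention (flag 16).
"""

from __future__ import annotations

from .gapfill import Alignment
from .reference import ReferencePack, revcomp

FLAG_REVERSE = 16
FLAG_UNMAPPED = 4
FLAG_SUPPLEMENTARY = 2048


def sam_header(pack: ReferencePack, program_args: str = "") -> str:
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for c in pack.contigs:
        lines.append(f"@SQ\tSN:{c.name}\tLN:{c.length}")
    pg = "@PG\tID:stripalign\tPN:stripalign"
    if program_args:
        pg += f"\tCL:{program_args}"
    lines.append(pg)
    return "\n".join(lines) + "\n"


def sam_record(aln: Alignment, query: str, qual: str | None = None) -> str:
    if aln.is_unmapped:
        q = qual or "*"
        return f"{aln.query_name}\t{FLAG_UNMAPPED}\t*\t0\t0\t*\t*\t0\t0\t{query}\t{q}\n"
    flag = 0
    cigar = aln.cigar
    seq = query
    if aln.strand == "-":
        flag |= FLAG_REVERSE
        cigar = list(reversed(cigar))
        seq = revcomp(query)
    if aln.is_supplementary:
        flag |= FLAG_SUPPLEMENTARY
    cig = "".join(f"{n}{op}" for n, op in cigar) if cigar else "*"
    q = qual if qual is not None else "*"
    if q != "*" and aln.strand == "-":
        q = q[::-1]
    return (
        f"{aln.query_name}\t{flag}\t{aln.contig}\t{aln.pos + 1}\t{aln.mapq}\t{cig}"
        f"\t*\t0\t0\t{seq}\t{q}\tAS:i:{round(aln.score)}\tNM:i:{aln.nm}\n"
    )
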