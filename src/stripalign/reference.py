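"""Reference packing and coordinate bookkeeping.

A reference genome is a list of contigs. For indexing and seeding we work on a
single *packed* text that contains every contig on the forward strand followed
by the reverse complement of the whole block, so that seeds on either strand
are found by one index. Contigs (and the two strand blocks) are joined by a
separator character that can never match a nucleotide, so no seed can span a
contig boundary or the strand junction.

Packed coordinates:

    [0, L)            forward strand (L = len(packed_forward), incl. separators)
    [L + 1, 2L + 1)   reverse-complement strand

A reverse-strand hit at packed position ``r`` with length ``l`` corresponds to
the forward-strand interval starting at ``2L + 1 - r - l``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from Bio import SeqIO

SEPARATOR = "#"
TERMINATOR = "$"

_COMPLEMENT = str.maketrans("ACGTNacgtn#$", "TGCANtgcan#$")

VALID_BASES = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement; N and separator characters map to themselves."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Contig:
    name: str
    length: int
    offset: int  # start of the contig within packed_forward


class ReferencePack:
    """Contigs packed into one forward-strand text plus coordinate maps."""

    def __init__(self, contigs: Iterable[tuple[str, str]]):
        items = [(str(n), str(s).upper()) for n, s in contigs]
        if not items or all(len(s) == 0 for _, s in items):
            raise ValueError("reference must contain at least one non-empty contig")
        self.contigs: list[Contig] = []
        parts: list[str] = []
        offset = 0
        for name, seq in items:
            self.contigs.append(Contig(name, len(seq), offset))
            parts.append(seq)
            offset += len(seq) + 1  # +1 for the separator
        self.packed_forward: str = SEPARATOR.join(parts)
        self.L: int = len(self.packed_forward)
        # doubled text used by the index and by gap filling
        self.text: str = (
            self.packed_forward + SEPARATOR + revcomp(self.packed_forward) + TERMINATOR
        )

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_fasta(cls, path: str) -> "ReferencePack":
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")]
        if not records:
            raise ValueError(f"no FASTA records in {path!r}")
        return cls(records)

    def to_fasta(self, path: str, width: int = 70) -> None:
        with open(path, "w") as fh:
            for c in self.contigs:
                seq = self.contig_seq(c.name)
                fh.write(f">{c.name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    # ------------------------------------------------------- coordinate maps

    @property
    def span(self) -> int:
        """Size of the packed coordinate space (both strands)."""
        return 2 * self.L + 1

    def contig_seq(self, name: str) -> str:
        c = self._contig(name)
        return self.packed_forward[c.offset : c.offset + c.length]

    def _contig(self, name: str) -> Contig:
        for c in self.contigs:
            if c.name == name:
                return c
        raise KeyError(name)

    def is_reverse(self, packed: int) -> bool:
        return packed > self.L

    def to_packed(self, contig: str, offset: int, strand: str = "+", length: int = 1) -> int:
        """Packed start position of a length-``length`` interval."""
        c = self._contig(contig)
        if not 0 <= offset <= c.length - length:
            raise ValueError("interval outside contig")
        fwd = c.offset + offset
        if strand == "+":
            return fwd
        return 2 * self.L + 1 - fwd - length

    def to_forward(self, packed: int, length: int = 1) -> tuple[str, int, str]:
        """Map a packed interval start to (contig, forward offset, strand)."""
        if self.is_reverse(packed):
            fwd = 2 * self.L + 1 - packed - length
            strand = "-"
        else:
            fwd = packed
            strand = "+"
        for c in self.contigs:
            if c.offset <= fwd and fwd + length <= c.offset + c.length:
                return c.name, fwd - c.offset, strand
        raise ValueError(f"packed interval ({packed}, len {length}) crosses a boundary")
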