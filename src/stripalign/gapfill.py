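"""Banded affine-gap dynamic programming and alignment assembly.

Harmonized seeds become diagonal path segments; the gaps between consecutive
seeds are filled with banded global Gotoh DP, and unaligned query ends are
extended semi-globally (free end point, unconsumed query becomes a soft clip).
Gaps open from the match state and pay ``gap_open + length * gap_extend``;
direct insertion<->deletion transitions are not allowed.

An alignment is a monotone path of (reference, query) points in the plane;
consecutive points differ by a deletion (r+1, q), an insertion (r, q+1) or a
match/mismatch step (r+1, q+1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .harmonize import conflicting
from .reference import ReferencePack
from .seeding import Seed
from .soc import ScoringScheme

NEG = -np.inf

# traceback states
_M, _IX, _IY = 0, 1, 2


class BandError(ValueError):
    """The band is too narrow to connect the corners of the DP matrix."""


def _dp_matrices(q: str, r: str, scoring: ScoringScheme, band: int | None):
    """Fill Gotoh matrices M (match), Ix (ref gap / D), Iy (query gap / I).

    Rows follow the query, columns the reference. ``band`` restricts columns
    to |j - i| <= band; None means full matrix.
    """
    n, m = len(q), len(r)
    if band is None:
        band = max(n, m)
    sM = np.full((n + 1, m + 1), NEG)
    sIx = np.full((n + 1, m + 1), NEG)
    sIy = np.full((n + 1, m + 1), NEG)
    open_ext = scoring.gap_open + scoring.gap_extend
    ext = scoring.gap_extend
    sM[0, 0] = 0.0
    top = min(m, band)
    if top >= 1:
        sIx[0, 1 : top + 1] = -(scoring.gap_open + ext * np.arange(1, top + 1))
    qa = np.frombuffer(q.encode("ascii"), dtype=np.uint8)
    ra = np.frombuffer(r.encode("ascii"), dtype=np.uint8)
    acgt = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in range(1, n + 1):
        jlo, jhi = max(0, i - band), min(m, i + band)
        if jlo > jhi:
            raise BandError("band excludes every column of a row")
        js = np.arange(max(1, jlo), jhi + 1)
        if js.size:
            prev = np.maximum(np.maximum(sM[i - 1, js - 1], sIx[i - 1, js - 1]), sIy[i - 1, js - 1])
            is_match = (qa[i - 1] == ra[js - 1]) & np.isin(qa[i - 1], acgt)
            sub = np.where(is_match, scoring.match, -scoring.mismatch)
            sM[i, js] = prev + sub
            sIy[i, js] = np.maximum(sM[i - 1, js] - open_ext, sIy[i - 1, js] - ext)
        if jlo == 0:
            sIy[i, 0] = max(sM[i - 1, 0] - open_ext, sIy[i - 1, 0] - ext)
        # horizontal (reference-consuming) gaps start from M within the row
        row = sM[i, jlo : jhi + 1]
        with np.errstate(invalid="ignore"):
            t = row + ext * np.arange(jlo, jhi + 1)
            run = np.maximum.accumulate(t)
            sIx[i, jlo + 1 : jhi + 1] = (
                run[:-1] - scoring.gap_open - ext * np.arange(jlo + 1, jhi + 1)
            )
    return sM, sIx, sIy


def _traceback(sM, sIx, sIy, q, r, scoring, i, j, state):
    """Walk back from (i, j, state) to (0, 0); returns ops newest-last."""
    ops: list[str] = []
    open_ext = scoring.gap_open + scoring.gap_extend
    ext = scoring.gap_extend
    while i > 0 or j > 0:
        if state == _M:
            val = sM[i, j] - scoring.substitution(q[i - 1], r[j - 1])
            ops.append("M")
            i, j = i - 1, j - 1
            for cand, mat in ((_M, sM), (_IX, sIx), (_IY, sIy)):
                if np.isclose(mat[i, j], val):
                    state = cand
                    break
        elif state == _IX:
            ops.append("D")
            if np.isclose(sIx[i, j], sM[i, j - 1] - open_ext):
                state = _M
            j -= 1
        else:
            ops.append("I")
            if np.isclose(sIy[i, j], sM[i - 1, j] - open_ext):
                state = _M
            i -= 1
    ops.reverse()
    return ops


def banded_align(
    qseg: str, rseg: str, scoring: ScoringScheme, band: int
) -> tuple[float, list[str]]:
    """Global banded Gotoh alignment of two non-empty segments.

    Returns the score and the per-step operation list ('M'/'I'/'D'). With a
    band spanning the whole matrix this equals full-matrix affine-gap DP.
    """
    if not qseg or not rseg:
        raise ValueError("segments must be non-empty")
    if band < abs(len(qseg) - len(rseg)) + 1:
        raise BandError("band cannot connect the matrix corners")
    sM, sIx, sIy = _dp_matrices(qseg, rseg, scoring, band)
    n, m = len(qseg), len(rseg)
    finals = (sM[n, m], sIx[n, m], sIy[n, m])
    state = int(np.argmax(finals))
    score = finals[state]
    if score == NEG:
        raise BandError("band cannot connect the matrix corners")
    ops = _traceback(sM, sIx, sIy, qseg, rseg, scoring, n, m, state)
    return float(score), ops


def semiglobal_extend(
    qtail: str,
    rwindow: str,
    scoring: ScoringScheme,
    direction: str = "right",
    band: int | None = None,
) -> tuple[float, list[str], int, int]:
    """Best extension of a query tail into a reference window, free end.

    The alignment is anchored at the seed-adjacent corner and may stop
    anywhere in both sequences; it never ends in a gap. Returns
    (score, ops, query consumed, reference consumed); a zero-length extension
    is valid and scores 0. ``direction`` 'left' extends leftwards (both
    sequences are reversed internally).
    """
    if direction not in ("left", "right"):
        raise ValueError(direction)
    if not qtail or not rwindow:
        return 0.0, [], 0, 0
    q = qtail[::-1] if direction == "left" else qtail
    r = rwindow[::-1] if direction == "left" else rwindow
    if band is None:
        band = abs(len(q) - len(r)) + 16
    sM, sIx, sIy = _dp_matrices(q, r, scoring, band)
    with np.errstate(invalid="ignore"):
        flat = np.where(np.isfinite(sM), sM, NEG)
    best = np.unravel_index(int(np.argmax(flat)), flat.shape)
    i, j = int(best[0]), int(best[1])
    score = float(sM[i, j])
    if score <= 0.0:
        return 0.0, [], 0, 0
    ops = _traceback(sM, sIx, sIy, q, r, scoring, i, j, _M)
    if direction == "left":
        ops.reverse()
    return score, ops, i, j


def validate_path(path: list[tuple[int, int]]) -> bool:
    """True iff every consecutive point pair is one of the three step kinds."""
    for (r0, q0), (r1, q1) in zip(path, path[1:]):
        step = (r1 - r0, q1 - q0)
        if step not in ((1, 0), (0, 1), (1, 1)):
            return False
    return True


def ops_to_path(ops: list[str], r0: int = 0, q0: int = 0) -> list[tuple[int, int]]:
    """Expand an op list into the monotone (r, q) point sequence."""
    path = [(r0, q0)]
    r, q = r0, q0
    for op in ops:
        if op in ("M", "X"):
            r, q = r + 1, q + 1
        elif op == "D":
            r += 1
        elif op == "I":
            q += 1
        else:
            raise ValueError(op)
        path.append((r, q))
    return path


def _compress(ops: list[str]) -> list[tuple[int, str]]:
    out: list[tuple[int, str]] = []
    for op in ops:
        if out and out[-1][1] == op:
            out[-1] = (out[-1][0] + 1, op)
        else:
            out.append((1, op))
    return out


@dataclass
class Alignment:
    """A placed alignment: CIGAR on the packed text plus SAM-facing fields."""

    packed_start: int  # reference start in packed (doubled-text) coordinates
    cigar: list[tuple[int, str]]  # (length, op) with ops M/I/D/S
    score: float
    contig: str = ""
    pos: int = 0  # 0-based forward-strand position on the contig
    strand: str = "+"
    mapq: int = 0
    is_supplementary: bool = False
    is_unmapped: bool = False
    nm: int = 0
    query_name: str = ""

    @property
    def ref_span(self) -> int:
        return sum(n for n, op in self.cigar if op in ("M", "D"))

    @property
    def query_span(self) -> tuple[int, int]:
        """Aligned query interval [start, end) (soft clips excluded)."""
        start = self.cigar[0][0] if self.cigar and self.cigar[0][1] == "S" else 0
        used = sum(n for n, op in self.cigar if op in ("M", "I"))
        return start, start + used

    def cigar_string(self) -> str:
        return "".join(f"{n}{op}" for n, op in self.cigar) if self.cigar else "*"

    def path(self) -> list[tuple[int, int]]:
        ops = [op for n, op in self.cigar if op != "S" for _ in range(n)]
        q0 = self.query_span[0]
        return ops_to_path(ops, self.packed_start, q0)


def assemble_alignment(
    seeds: list[Seed],
    query: str,
    pack: ReferencePack,
    scoring: ScoringScheme,
    band_extra: int = 16,
    _check_consistency: bool = True,
) -> Alignment:
    """Assemble seeds, gap DP and end extensions into one placed alignment.

    Consecutive seeds overlapping on query or reference are truncated from the
    later seed's start; inter-seed gaps are filled with banded DP
    (band = |gap_q - gap_r| + band_extra); ends are extended semi-globally and
    leftover query becomes soft clips. The input set must be mutually
    consistent.
    """
    if not seeds:
        raise ValueError("cannot assemble an empty seed set")
    seeds = sorted(seeds)
    if _check_consistency:
        for a, b in zip(seeds, seeds[1:]):
            if conflicting(a, b):
                raise ValueError("seed set is not mutually consistent")
    # truncate overlaps so anchors are disjoint
    anchors: list[Seed] = [seeds[0]]
    for s in seeds[1:]:
        prev = anchors[-1]
        t = max(0, prev.qend - s.q, prev.rend - s.r)
        if s.l - t >= 1:
            anchors.append(Seed(s.q + t, s.r + t, s.l - t))
    text = pack.text
    ops: list[str] = []
    score = 0.0
    first, last = anchors[0], anchors[-1]

    # left end
    lclip = first.q
    if lclip:
        wstart = max(0, first.r - 2 * lclip - band_extra)
        window = text[wstart : first.r]
        sep = max((window.rfind(c) for c in "#$"), default=-1)
        if sep >= 0:
            window = window[sep + 1 :]
        esc, eops, qc, rc = semiglobal_extend(query[:lclip], window, scoring, "left")
        if lclip - qc:
            ops.append(("S", lclip - qc))  # type: ignore[arg-type]
        ops.extend(eops)
        score += esc
        start = first.r - rc
    else:
        start = first.r

    # seeds and inter-seed gaps
    prev = None
    for s in anchors:
        if prev is not None:
            qgap, rgap = s.q - prev.qend, s.r - prev.rend
            if qgap and rgap:
                band = abs(qgap - rgap) + band_extra
                gsc, gops = banded_align(
                    query[prev.qend : s.q], text[prev.rend : s.r], scoring, band
                )
                ops.extend(gops)
                score += gsc
            elif rgap:
                ops.extend("D" * rgap)
                score += scoring.gap(rgap)
            elif qgap:
                ops.extend("I" * qgap)
                score += scoring.gap(qgap)
        ops.extend("M" * s.l)
        score += scoring.match * s.l
        prev = s

    # right end
    rclip = len(query) - last.qend
    if rclip:
        wend = min(len(text), last.rend + 2 * rclip + band_extra)
        window = text[last.rend : wend]
        sep = min((p for p in (window.find(c) for c in "#$") if p >= 0), default=-1)
        if sep >= 0:
            window = window[:sep]
        esc, eops, qc, rc = semiglobal_extend(query[last.qend :], window, scoring, "right")
        ops.extend(eops)
        if rclip - qc:
            ops.append(("S", rclip - qc))  # type: ignore[arg-type]
        score += esc

    # flatten (the S markers were stashed as tuples)
    cigar: list[tuple[int, str]] = []
    flat: list[str] = []
    for item in ops:
        if isinstance(item, tuple):
            if flat:
                cigar.extend(_compress(flat))
                flat = []
            cigar.append((item[1], item[0]))
        else:
            flat.append(item)
    if flat:
        cigar.extend(_compress(flat))

    aln = Alignment(packed_start=start, cigar=cigar, score=score)
    # mismatch/indel count along the path (soft clips advance the query)
    nm = 0
    rpos, qpos = start, 0
    for n, op in cigar:
        if op == "M":
            nm += sum(
                1
                for k in range(n)
                if scoring.substitution(query[qpos + k], text[rpos + k]) < 0
            )
            rpos += n
            qpos += n
        elif op == "D":
            nm += n
            rpos += n
        elif op == "I":
            nm += n
            qpos += n
        else:
            qpos += n
    aln.nm = nm
    # place on a contig; the CIGAR stays in packed orientation — the SAM
    # writer reverses it (and the read) for reverse-strand hits
    contig, pos, strand = pack.to_forward(start, aln.ref_span)
    aln.contig, aln.pos, aln.strand = contig, pos, strand
    return aln


MAPQ_CAP = 60


def compute_mapq(
    best_score: float, second_score: float | None, qlen: int, scoring: ScoringScheme
) -> int:
    """Score-gap mapping quality, 0 when ambiguous, capped at MAPQ_CAP.

    Monotone in (best - second) / best, scaled by how close the best score is
    to a perfect match; clamped to the SAM range [0, 254].
    """
    if best_score <= 0:
        return 0
    if second_score is None:
        return MAPQ_CAP
    gap = max(0.0, min(1.0, (best_score - second_score) / best_score))
    frac = min(1.0, best_score / (scoring.match * qlen))
    return max(0, min(254, round(MAPQ_CAP * gap * frac)))
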