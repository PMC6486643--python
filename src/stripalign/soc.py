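"""Strip of consideration (SoC): candidate-region detection over seeds.

Seeds are sorted by their delta value (``r - q``, the reference diagonal).
A strip of consideration is a window of width lambda over that sorted array,
scored by the accumulated length of the seeds inside it. A single two-pointer
sweep collects the candidate windows; the strips that do not overlap a higher
scored strip are returned in score order (a ready-made priority queue).

The width lambda = (s_M |Q| - p_O) / p_E is the largest diagonal offset two
seeds may have while an alignment containing both can still score positively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .seeding import Seed


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap scoring: match bonus, mismatch/gap penalties (all >= 0).

    The default (2, 4, 24, 1) charges gap opening heavily and extension
    lightly — a single-affine stand-in for the long-gap piece of two-piece
    schemes — so structural indels are reported as one gap run instead of
    fragmenting around chance match islands inside the gap.
    """

    match: int = 2  # s_M
    mismatch: int = 4  # s_X
    gap_open: int = 24  # p_O
    gap_extend: int = 1  # p_E

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch < 0 or self.gap_open < 0:
            raise ValueError("penalties must be non-negative")
        if self.gap_extend <= 0:
            raise ValueError("gap-extend penalty must be positive")

    def substitution(self, a: str, b: str) -> int:
        if a == b and a in "ACGT":
            return self.match
        return -self.mismatch

    def gap(self, length: int) -> int:
        return -(self.gap_open + length * self.gap_extend) if length else 0


@dataclass
class StripOfConsideration:
    """A delta-window over the sorted seed array with its accumulated score."""

    first_index: int
    last_index: int  # inclusive, into the delta-sorted array
    score: int  # sum of member seed lengths
    delta_lo: int
    delta_hi: int
    width: int  # the lambda the strip was collected with
    seeds: list[Seed] = field(default_factory=list)

    @property
    def window(self) -> tuple[int, int]:
        """Full-width delta window [delta_lo, delta_lo + lambda] of the strip."""
        return self.delta_lo, self.delta_lo + self.width


def compute_lambda(scoring: ScoringScheme, qlen: int) -> int:
    """SoC width lambda = floor((s_M |Q| - p_O) / p_E), clamped at zero."""
    if qlen < 1:
        raise ValueError("query length must be >= 1")
    lam = (scoring.match * qlen - scoring.gap_open) // scoring.gap_extend
    if lam < 0:
        warnings.warn("lambda < 0 (gap-open penalty exceeds max score); clamping to 0")
        return 0
    return int(lam)


def spatially_local(s: Seed, s2: Seed, lam: int) -> bool:
    """True iff the two seeds' diagonals are within lambda of each other."""
    return abs(s.delta - s2.delta) <= lam


def sweep_candidates(
    sorted_seeds: list[Seed], lam: int
) -> tuple[list[tuple[int, int, int]], int]:
    """Two-pointer sweep over delta-sorted seeds.

    Returns the maximal window ``(first, last, score)`` ending at each seed,
    plus the total number of pointer advances (bounded by 2 |A_S|).
    """
    cands: list[tuple[int, int, int]] = []
    visits = 0
    i = 0
    score = 0
    for j, s in enumerate(sorted_seeds):
        score += s.l
        visits += 1
        while s.delta - sorted_seeds[i].delta > lam:
            score -= sorted_seeds[i].l
            i += 1
            visits += 1
        cands.append((i, j, score))
    return cands, visits


def collect_socs(seeds: list[Seed], lam: int) -> list[StripOfConsideration]:
    """Collect strips, highest score first, none overlapping a better strip.

    The top strip attains the globally best window score. Equal-scoring
    overlapping windows keep the leftmost (smallest delta). The returned list
    is sorted by descending score and serves as the priority queue the
    harmonization stage pops from.
    """
    if not seeds:
        return []
    order = sorted(seeds, key=lambda s: (s.delta, s.r, s.q))
    cands, _ = sweep_candidates(order, lam)
    strips: list[StripOfConsideration] = []
    taken: list[tuple[int, int]] = []
    for i, j, score in sorted(cands, key=lambda c: (-c[2], order[c[0]].delta, c[0])):
        lo = order[i].delta
        win = (lo, lo + lam)
        if any(win[0] <= t[1] and t[0] <= win[1] for t in taken):
            continue
        taken.append(win)
        strips.append(
            StripOfConsideration(
                first_index=i,
                last_index=j,
                score=score,
                delta_lo=lo,
                delta_hi=order[j].delta,
                width=lam,
                seeds=order[i : j + 1],
            )
        )
    strips.sort(key=lambda t: (-t.score, t.delta_lo))
    return strips


def soc_score_filter(score: int, gamma: float, xi: float, qlen: int) -> bool:
    """Keep a strip iff its accumulated seed length reaches max(gamma, xi |Q|)."""
    if not 0 < xi <= 1:
        raise ValueError("xi must be in (0, 1]")
    return score >= max(gamma, xi * qlen)
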