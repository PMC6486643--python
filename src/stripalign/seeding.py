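"""Seed computation: maximally-spanning seeds, binary seeding, SMEMs, filters.

A seed is a perfect match between query and packed reference, stored as
``(q, r, l)`` — query start, packed reference start and length. Its
``delta = r - q`` is the reference diagonal it lies on.

Maximally-spanning seeding starts at a query position ``i`` and maximally
extends in one direction and then the other (both orders), yielding the seeds
covering ``i`` that reach the extremal query begin/end attainable from ``i``.
Binary seeding applies this divide-and-conquer from the query center outward
and returns a fully covering seed set. SMEMs (all non-enclosed maximal exact
matches) are computed for comparison; maximally-spanning seeds are a subset of
them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import groupby

from .index import BiInterval, FmdIndex


@dataclass(frozen=True, order=True)
class Seed:
    q: int  # query start (0-based)
    r: int  # packed reference start (0-based)
    l: int  # length >= 1

    @property
    def delta(self) -> int:
        return self.r - self.q

    @property
    def qend(self) -> int:
        return self.q + self.l

    @property
    def rend(self) -> int:
        return self.r + self.l


@dataclass
class SeedSet:
    """Seeds plus the outermost query positions they reach.

    ``begin``/``end`` default to the members' extremes but may be wider when
    ambiguous (over-occurring) intervals were purged before locating: the
    query span of a purged interval still bounds the binary-seeding recursion.
    """

    seeds: list[Seed] = field(default_factory=list)
    begin: int | None = None
    end: int | None = None

    def __post_init__(self) -> None:
        if self.seeds:
            b = min(s.q for s in self.seeds)
            e = max(s.qend for s in self.seeds)
            self.begin = b if self.begin is None else min(self.begin, b)
            self.end = e if self.end is None else max(self.end, e)

    @property
    def empty(self) -> bool:
        return self.begin is None


def _max_extend(
    index: FmdIndex, query: str, i: int, backward_first: bool
) -> tuple[int, int, BiInterval] | None:
    """Maximal extension from position i; returns (qstart, qend, interval)."""
    iv = index.init_interval(query[i])
    if iv.empty:
        return None
    lo, hi = i, i + 1
    n = len(query)
    first = (True, False) if backward_first else (False, True)
    for go_backward in first:
        if go_backward:
            while lo > 0:
                nxt = index.extend_backward(query[lo - 1], iv)
                if nxt.empty:
                    break
                iv, lo = nxt, lo - 1
        else:
            while hi < n:
                nxt = index.extend_forward(query[hi], iv)
                if nxt.empty:
                    break
                iv, hi = nxt, hi + 1
    return lo, hi, iv


def maximally_spanning(
    index: FmdIndex, query: str, i: int, max_ambiguity: int | None = None
) -> SeedSet:
    """Maximally-spanning seed set covering query position ``i``.

    Union of the backward-then-forward and forward-then-backward maximal
    extension products. Empty when ``query[i]`` does not occur in the
    reference (including N). Intervals with more than ``max_ambiguity``
    occurrences are purged before locating, but their query span still widens
    ``begin``/``end``.
    """
    if not 0 <= i < len(query):
        raise IndexError(i)
    seeds: set[Seed] = set()
    begin = end = None
    for backward_first in (True, False):
        ext = _max_extend(index, query, i, backward_first)
        if ext is None:
            continue
        lo, hi, iv = ext
        begin = lo if begin is None else min(begin, lo)
        end = hi if end is None else max(end, hi)
        if max_ambiguity is not None and iv.size > max_ambiguity:
            continue
        for pos in index.locate(iv):
            seeds.add(Seed(lo, pos, hi - lo))
    return SeedSet(sorted(seeds), begin=begin, end=end)


def binary_seeding(
    index: FmdIndex, query: str, max_ambiguity: int | None = None
) -> list[Seed]:
    """Fully covering seed set by divide-and-conquer around interval centers.

    Each step seeds from the center of the current query interval; the covered
    span [begin, end) splits the interval into a left and right remainder that
    are processed recursively. Positions whose character is absent from the
    reference stay uncovered and are skipped.
    """
    out: set[Seed] = set()
    stack = [(0, len(query))]
    while stack:
        b, e = stack.pop()
        if e <= b:
            continue
        m = (b + e) // 2
        ss = maximally_spanning(index, query, m, max_ambiguity)
        if ss.empty:
            stack.append((b, m))
            stack.append((m + 1, e))
            continue
        out.update(ss.seeds)
        stack.append((b, ss.begin))
        stack.append((ss.end, e))
    return sorted(out)


def smems(
    index: FmdIndex, query: str, max_ambiguity: int | None = None
) -> list[Seed]:
    """All supermaximal exact matches (non-enclosed maximal seeds).

    Uses the fact that the furthest reach ``end(i)`` of a maximal forward
    extension from ``i`` is non-decreasing over positions whose character
    occurs in the reference: the non-enclosed query intervals are exactly the
    ``[i, end(i))`` with a strictly larger end than every earlier position.
    """
    out: set[Seed] = set()
    n = len(query)
    best_end = 0
    for i in range(n):
        iv = index.init_interval(query[i])
        if iv.empty:
            continue
        hi = i + 1
        while hi < n:
            nxt = index.extend_forward(query[hi], iv)
            if nxt.empty:
                break
            iv, hi = nxt, hi + 1
        if hi <= best_end:
            continue  # enclosed by an earlier interval
        best_end = hi
        if max_ambiguity is not None and iv.size > max_ambiguity:
            continue
        for pos in index.locate(iv):
            out.add(Seed(i, pos, hi - i))
    return sorted(out)


def filter_seeds(
    seeds: list[Seed], min_seed_size: int = 16, max_ambiguity: int = 100
) -> list[Seed]:
    """Drop short seeds; purge *entire* groups of over-ambiguous query intervals.

    A group is the set of seeds sharing one query interval ``(q, l)``; if the
    group is larger than ``max_ambiguity`` every member is removed.
    """
    kept = [s for s in seeds if s.l >= min_seed_size]
    out: list[Seed] = []
    for _, grp in groupby(sorted(kept, key=lambda s: (s.q, s.l, s.r)), key=lambda s: (s.q, s.l)):
        grp = list(grp)
        if len(grp) <= max_ambiguity:
            out.extend(grp)
    return sorted(out)


def coverage_check(seeds: list[Seed], qlen: int, alpha: float, beta: float) -> bool:
    """Accumulative periodic-seed test: sum(|s|)/alpha >= |Q|/beta.

    alpha is a minimum seed length, beta a segment size; a query failing the
    test is reported unaligned.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    return sum(s.l for s in seeds) / alpha >= qlen / beta
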