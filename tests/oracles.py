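"""Independent brute-force oracles used to check the package's algorithms.

Everything here is deliberately naive (exhaustive scans, full-matrix DP,
O(n^2) pair enumeration) and shares no code with the implementations it
verifies.
"""

from __future__ import annotations

import math


def naive_positions(text: str, pat: str) -> list[int]:
    """All start positions of ``pat`` in ``text`` by direct scanning."""
    if not pat or any(c not in "ACGT" for c in pat):
        return []
    return [i for i in range(len(text) - len(pat) + 1) if text[i : i + len(pat)] == pat]


def all_match_triples(query: str, text: str) -> list[tuple[int, int, int]]:
    """Every perfect-match triple (q, r, l), l >= 1, ACGT only."""
    out = []
    for q in range(len(query)):
        for l in range(1, len(query) - q + 1):
            pat = query[q : q + l]
            if any(c not in "ACGT" for c in pat):
                break
            for r in naive_positions(text, pat):
                out.append((q, r, l))
    return out


def maximal_query_intervals(query: str, text: str) -> list[tuple[int, int]]:
    """Query intervals [q, e) of matches that extend in neither direction."""
    out = []
    for q in range(len(query)):
        for e in range(q + 1, len(query) + 1):
            pat = query[q:e]
            if not naive_positions(text, pat):
                continue
            left_ok = q == 0 or not naive_positions(text, query[q - 1 : e])
            right_ok = e == len(query) or not naive_positions(text, query[q : e + 1])
            if left_ok and right_ok:
                out.append((q, e))
    return sorted(set(out))


def smem_triples(query: str, text: str) -> set[tuple[int, int, int]]:
    """Non-enclosed maximal matches (SMEMs) as located (q, r, l) triples."""
    intervals = maximal_query_intervals(query, text)
    keep = [
        (q, e)
        for q, e in intervals
        if not any((q2 <= q and e <= e2) for q2, e2 in intervals if (q2, e2) != (q, e))
    ]
    out = set()
    for q, e in keep:
        for r in naive_positions(text, query[q:e]):
            out.add((q, r, e - q))
    return out


def spanning_extremes(query: str, text: str, i: int) -> tuple[int, int] | None:
    """(min q, max end) over all match triples covering query position i."""
    covering = [
        (q, q + l) for q, r, l in all_match_triples(query, text) if q <= i < q + l
    ]
    if not covering:
        return None
    return min(q for q, _ in covering), max(e for _, e in covering)


def gotoh_score(q: str, r: str, match: int, mismatch: int, gap_open: int, gap_extend: int) -> float:
    """Full-matrix affine-gap global alignment score (gaps open from match)."""
    n, m = len(q), len(r)
    NEG = -math.inf
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for j in range(1, m + 1):
        Ix[0][j] = -(gap_open + j * gap_extend)
    for i in range(1, n + 1):
        Iy[i][0] = -(gap_open + i * gap_extend)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = match if q[i - 1] == r[j - 1] and q[i - 1] in "ACGT" else -mismatch
            M[i][j] = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]) + sub
            Ix[i][j] = max(M[i][j - 1] - gap_open - gap_extend, Ix[i][j - 1] - gap_extend)
            Iy[i][j] = max(M[i - 1][j] - gap_open - gap_extend, Iy[i - 1][j] - gap_extend)
    return max(M[n][m], Ix[n][m], Iy[n][m])


def best_window_score(deltas_lengths: list[tuple[int, int]], lam: int) -> int:
    """Exhaustive best score over all delta-windows of width <= lam."""
    best = 0
    for d0, _ in deltas_lengths:
        score = sum(l for d, l in deltas_lengths if d0 <= d <= d0 + lam)
        best = max(best, score)
    return best


def conflict_pairs(triples: list[tuple[int, int, int]]) -> set[tuple[int, int]]:
    """O(n^2) enumeration of conflicting index pairs (both shadow conditions)."""

    def encl(s, sp):
        q, r, l = s
        q2, r2, l2 = sp
        return (q <= q2 and r2 + l2 <= r + l) or (r <= r2 and q2 + l2 <= q + l)

    out = set()
    for i in range(len(triples)):
        for j in range(i + 1, len(triples)):
            if encl(triples[i], triples[j]) or encl(triples[j], triples[i]):
                out.add((i, j))
    return out
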