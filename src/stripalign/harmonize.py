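"""Seed harmonization: purge inconsistent seeds inside a strip.

Two seeds are consistent when they occur in the same order on query and
reference; an alignment can only contain mutually consistent seeds. Each seed
casts two shadows in the reference x query plane (second and fourth quadrant);
a pair conflicts exactly when one seed's shadow encloses the other's, which
reduces to the two interval-inclusion conditions

    (a)  q <= q'  and  r' + l' <= r + l
    (b)  r <= r'  and  q' + l' <= q + l

checked in both argument orders. Conflicts are enumerated by a line sweep over
one axis while tracking end positions on the other, and resolved by purging
the seed more distant from the delta-guideline — a robust line (RANSAC) fitted
through the start/center/end points of all strip seeds that approximates the
expected alignment path.
"""

from __future__ import annotations

from bisect import bisect_left, insort
from dataclasses import dataclass

import numpy as np

from .seeding import Seed
from .soc import StripOfConsideration, soc_score_filter


@dataclass(frozen=True)
class Shadow:
    """Rectangle [lo, hi) x [lo, hi) cast by a seed into one quadrant."""

    ref_interval: tuple[int, int]
    query_interval: tuple[int, int]
    quadrant: str  # "II" or "IV"


@dataclass(frozen=True)
class DeltaGuideline:
    """Line r = slope * q + intercept approximating the alignment path."""

    slope: float
    intercept: float
    inlier_count: int
    n_points: int


@dataclass(frozen=True)
class HeuristicParams:
    """Runtime heuristics; symbols follow the seed-processing conventions."""

    alpha: float = 12.0  # minimum seed length in the coverage check
    beta: float = 100.0  # segment size in the coverage check
    gamma: float = 30.0  # absolute SoC score floor
    xi: float = 0.1  # SoC score floor as a fraction of |Q|
    min_seed_size: int = 16
    max_ambiguity: int = 100
    soc_count_long: int = 30  # strips inspected for long queries
    lookahead_short: int = 3  # unchanged-score break threshold (short queries)
    long_query_cutoff: int = 1000  # nt

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.gamma, self.xi) <= 0:
            raise ValueError("heuristic parameters must be positive")
        if not 0 < self.xi <= 1:
            raise ValueError("xi must be in (0, 1]")


def shadows(s: Seed, qlen: int, rlen: int) -> tuple[Shadow, Shadow]:
    """Second- and fourth-quadrant shadows of a seed."""
    sigma_ii = Shadow((0, s.rend), (s.q, qlen), "II")
    sigma_iv = Shadow((s.r, rlen), (0, s.qend), "IV")
    return sigma_ii, sigma_iv


def _encloses(s: Seed, sp: Seed) -> bool:
    a = s.q <= sp.q and sp.rend <= s.rend
    b = s.r <= sp.r and sp.qend <= s.qend
    return a or b


def conflicting(s: Seed, s2: Seed) -> bool:
    """True iff the seeds cannot coexist in one alignment."""
    return _encloses(s, s2) or _encloses(s2, s)


def fit_guideline(
    soc_seeds: list[Seed],
    rng_seed: int = 0,
    qlen: int | None = None,
    n_iterations: int = 100,
) -> DeltaGuideline:
    """RANSAC fit of the delta-guideline over the 3|S|-point cloud.

    Two-point line hypotheses, ``n_iterations`` draws, inlier tolerance
    max(10, 0.01 |Q|) reference-axis units, least-squares refit on the best
    inlier set. Deterministic under ``rng_seed``. Fewer than two distinct
    points fall back to a slope-1 line through the longest seed's start.
    """
    if not soc_seeds:
        raise ValueError("cannot fit a guideline to an empty strip")
    qs, rs = [], []
    for s in soc_seeds:
        qs.extend((s.q, s.q + s.l / 2.0, s.qend))
        rs.extend((s.r, s.r + s.l / 2.0, s.rend))
    qarr = np.asarray(qs, dtype=np.float64)
    rarr = np.asarray(rs, dtype=np.float64)
    n = qarr.size
    if qlen is None:
        qlen = int(max(s.qend for s in soc_seeds))
    tol = max(10.0, 0.01 * qlen)

    def fallback() -> DeltaGuideline:
        best = max(soc_seeds, key=lambda s: (s.l, -s.r, -s.q))
        return DeltaGuideline(1.0, float(best.r - best.q), len(soc_seeds) * 3, n)

    distinct = np.unique(np.stack([qarr, rarr]), axis=1).shape[1]
    if len(soc_seeds) == 1 or distinct < 2:
        # a lone seed defines its own diagonal exactly
        return fallback()

    rng = np.random.default_rng(rng_seed)
    ii = rng.integers(0, n, size=n_iterations)
    jj = rng.integers(0, n, size=n_iterations)
    dq = qarr[jj] - qarr[ii]
    ok = dq != 0
    if not ok.any():
        return fallback()  # all points on one vertical line
    slopes = np.where(ok, (rarr[jj] - rarr[ii]) / np.where(ok, dq, 1.0), np.nan)
    inters = rarr[ii] - slopes * qarr[ii]
    resid = np.abs(rarr[None, :] - (slopes[:, None] * qarr[None, :] + inters[:, None]))
    inliers = (resid <= tol) & ok[:, None]
    counts = inliers.sum(axis=1)
    best = int(np.argmax(counts))
    mask = inliers[best]
    if mask.sum() < 2:
        return fallback()
    slope, intercept = np.polyfit(qarr[mask], rarr[mask], 1)
    final = np.abs(rarr - (slope * qarr + intercept)) <= tol
    return DeltaGuideline(float(slope), float(intercept), int(final.sum()), n)


def guideline_distance(s: Seed, g: DeltaGuideline) -> float:
    """Reference-axis offset between the seed's center and the guideline."""
    qc = s.q + s.l / 2.0
    rc = s.r + s.l / 2.0
    return abs(rc - (g.slope * qc + g.intercept))


def sweep_contradictions(soc_seeds: list[Seed]) -> list[tuple[int, int]]:
    """All conflicting index pairs, by line sweep.

    One sweep per shadow quadrant: seeds are visited by ascending query start
    (reference start for the second sweep) while the end positions on the
    other axis are kept in a sorted sweep-status structure; a pair whose order
    disagrees between the two axes is a contradiction. Equal starts always
    conflict. The union over both sweeps equals the pairwise conflict set.
    """
    pairs: set[tuple[int, int]] = set()
    n = len(soc_seeds)

    def one_axis(start_of, end_of) -> None:
        order = sorted(range(n), key=lambda k: (start_of(soc_seeds[k]), k))
        status: list[tuple[int, int]] = []  # sorted (end, index)
        prev_start = None
        group_begin = 0
        for pos, k in enumerate(order):
            s = soc_seeds[k]
            st, en = start_of(s), end_of(s)
            if st != prev_start:
                prev_start, group_begin = st, pos
            # seeds with a strictly smaller start whose end is >= ours
            for e_prev, k_prev in status[bisect_left(status, (en, -1)) :]:
                pairs.add((min(k, k_prev), max(k, k_prev)))
            # equal starts conflict regardless of end order
            for k_prev in order[group_begin:pos]:
                pairs.add((min(k, k_prev), max(k, k_prev)))
            if pos + 1 < n and start_of(soc_seeds[order[pos + 1]]) != st:
                for k_grp in order[group_begin : pos + 1]:
                    insort(status, (end_of(soc_seeds[k_grp]), k_grp))
        # (last group never needs inserting)

    one_axis(lambda s: s.q, lambda s: s.rend)  # quadrant-II shadows
    one_axis(lambda s: s.r, lambda s: s.qend)  # quadrant-IV shadows
    return sorted(pairs)


def harmonize_soc(
    soc_seeds: list[Seed],
    guideline: DeltaGuideline,
    max_rounds: int | None = None,
) -> list[Seed]:
    """Iteratively purge the guideline-distant seed of every conflicting pair.

    Ties purge the shorter seed, then the larger reference position. Repeats
    until the sweep reports no contradiction; the survivors are mutually
    consistent and a subset of the input.
    """
    seeds = sorted(soc_seeds)
    rounds = max_rounds if max_rounds is not None else max(1, len(seeds))
    for _ in range(rounds):
        pairs = sweep_contradictions(seeds)
        if not pairs:
            break
        dist = [guideline_distance(s, guideline) for s in seeds]
        removed: set[int] = set()
        for i, j in pairs:
            if i in removed or j in removed:
                continue
            si, sj = seeds[i], seeds[j]
            # purge the more distant; tie-break: shorter seed, then larger r
            key_i = (dist[i], -si.l, si.r, si.q)
            key_j = (dist[j], -sj.l, sj.r, sj.q)
            removed.add(i if key_i > key_j else j)
        seeds = [s for k, s in enumerate(seeds) if k not in removed]
    return seeds


def schedule_socs(
    strips: list[StripOfConsideration],
    qlen: int,
    params: HeuristicParams,
    rng_seed: int = 0,
    guarantee_one: bool = False,
) -> list[tuple[list[Seed], StripOfConsideration]]:
    """Pop strips by score and harmonize them under the two stop heuristics.

    Long queries (> long_query_cutoff): exactly ``soc_count_long`` strips are
    inspected and strips harmonizing below an earlier harmonized score are
    discarded. Short queries: stop once the best harmonized score stayed
    unchanged for ``lookahead_short`` consecutive pops. Every emitted set has
    re-passed the SoC score filter; with ``guarantee_one`` the best set is
    emitted even if the filter rejects it (so a covered query still aligns).
    """
    results: list[tuple[list[Seed], StripOfConsideration]] = []
    long_query = qlen > params.long_query_cutoff
    best_score: int | None = None
    unchanged = 0
    inspected = 0
    fallback: tuple[list[Seed], StripOfConsideration] | None = None
    for strip in strips:
        if long_query and inspected >= params.soc_count_long:
            break
        inspected += 1
        g = fit_guideline(strip.seeds, rng_seed=rng_seed, qlen=qlen)
        seeds = harmonize_soc(strip.seeds, g)
        score = sum(s.l for s in seeds)
        if fallback is None or score > sum(s.l for s in fallback[0]):
            fallback = (seeds, strip)
        keep = soc_score_filter(score, params.gamma, params.xi, qlen)
        if long_query:
            if best_score is not None and score < best_score:
                continue
            if keep:
                results.append((seeds, strip))
                best_score = score if best_score is None else max(best_score, score)
        else:
            if best_score is None or score > best_score:
                best_score = score
                unchanged = 0
            else:
                unchanged += 1
            if keep:
                results.append((seeds, strip))
            if unchanged >= params.lookahead_short:
                break
    if guarantee_one and not results and fallback is not None:
        results.append(fallback)
    return results
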