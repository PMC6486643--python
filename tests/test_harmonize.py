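"""Shadows, conflict detection, guideline fitting, harmonization, scheduling."""

import pytest

from stripalign import (
    DeltaGuideline,
    HeuristicParams,
    Seed,
    collect_socs,
    conflicting,
    fit_guideline,
    harmonize_soc,
    schedule_socs,
    sweep_contradictions,
)
from stripalign.harmonize import guideline_distance, shadows

from oracles import conflict_pairs


def pair_indices(seeds):
    return set(sweep_contradictions(seeds))


class TestShadows:
    def test_rectangles_from_definition(self):
        s2, s4 = shadows(Seed(q=2, r=3, l=2), qlen=10, rlen=20)
        assert s2.ref_interval == (0, 5) and s2.query_interval == (2, 10)
        assert s4.ref_interval == (3, 20) and s4.query_interval == (0, 4)

    def test_origin_seed(self):
        s2, s4 = shadows(Seed(0, 0, 1), qlen=7, rlen=9)
        assert s2.ref_interval == (0, 1) and s2.query_interval == (0, 7)
        assert s4.ref_interval == (0, 9) and s4.query_interval == (0, 1)

    def test_shadows_overlap_on_own_rectangle(self):
        s = Seed(2, 3, 2)
        s2, s4 = shadows(s, 10, 20)
        # the seed's own rectangle lies in both shadows
        assert s2.ref_interval[0] <= s.r and s.rend <= s4.ref_interval[1]
        assert s4.query_interval[0] <= s.q and s.qend <= s2.query_interval[1]


class TestConflicting:
    def test_overlapping_but_consistent_pair_kept(self):
        # the AAT / TGG seeds overlap by one query base yet do not conflict
        assert not conflicting(Seed(0, 0, 3), Seed(2, 4, 3))

    def test_same_query_interval_distant_diagonal(self):
        assert conflicting(Seed(0, 0, 3), Seed(0, 10, 3))

    def test_collinear_disjoint(self):
        assert not conflicting(Seed(0, 0, 3), Seed(4, 4, 3))

    def test_duplicates_conflict(self):
        assert conflicting(Seed(1, 5, 4), Seed(1, 5, 4))


class TestGuideline:
    def test_collinear_cloud_recovers_diagonal(self):
        seeds = [Seed(q, q + 7, 4) for q in (0, 10, 25, 40)]
        g = fit_guideline(seeds, rng_seed=1, qlen=50)
        assert g.slope == pytest.approx(1.0, abs=1e-6)
        assert g.intercept == pytest.approx(7.0, abs=1e-6)
        assert g.inlier_count == g.n_points

    def test_outlier_seed_excluded_from_inliers(self):
        inline = [Seed(q, q, 6) for q in (0, 15, 30, 45, 60)]
        outlier = Seed(30, 400, 3)
        g = fit_guideline(inline + [outlier], rng_seed=3, qlen=70)
        assert g.slope == pytest.approx(1.0, abs=0.05)
        assert g.n_points - g.inlier_count == 3  # the outlier's three points

    def test_single_seed_fallback_slope_one(self):
        g = fit_guideline([Seed(4, 9, 3)], rng_seed=0, qlen=20)
        assert (g.slope, g.intercept) == (1.0, 5.0)

    def test_deterministic_under_seed(self):
        seeds = [Seed(q, q + (q % 11), 5) for q in range(0, 90, 7)]
        a = fit_guideline(seeds, rng_seed=42, qlen=100)
        b = fit_guideline(seeds, rng_seed=42, qlen=100)
        assert a == b

    def test_empty_strip_rejected(self):
        with pytest.raises(ValueError):
            fit_guideline([], rng_seed=0)

    def test_distance_on_and_off_line(self):
        g = DeltaGuideline(1.0, 0.0, 0, 0)
        assert guideline_distance(Seed(5, 5, 4), g) == 0.0
        assert guideline_distance(Seed(0, 10, 2), g) == 10.0


class TestSweepContradictions:
    def test_out_of_order_reference_end_detected(self):
        # three seeds; the third ends on the reference before the second:
        # its end position pops out of order, one contradiction
        seeds = [Seed(0, 0, 2), Seed(3, 10, 2), Seed(6, 5, 2)]
        assert pair_indices(seeds) == {(1, 2)}

    def test_consistent_staircase_has_no_contradiction(self):
        seeds = [Seed(i * 3, i * 4, 2) for i in range(6)]
        assert pair_indices(seeds) == set()

    def test_matches_pairwise_oracle_on_random_socs(self, rng):
        for _ in range(80):
            seeds = [
                Seed(rng.randrange(60), rng.randrange(90), rng.randint(1, 12))
                for _ in range(rng.randint(2, 20))
            ]
            got = pair_indices(seeds)
            want = conflict_pairs([(s.q, s.r, s.l) for s in seeds])
            assert got == want


class TestHarmonizeSoc:
    def _diag_guideline(self):
        return DeltaGuideline(1.0, 0.0, 0, 0)

    def test_guided_purge_removes_distant_seed(self):
        # s and s' shadow each other; s' sits far off the diagonal guideline
        s = Seed(10, 10, 4)
        s_prime = Seed(10, 40, 4)  # same query interval, distant diagonal
        s2 = Seed(0, 0, 4)
        s3 = Seed(20, 20, 4)
        out = harmonize_soc([s2, s, s_prime, s3], self._diag_guideline())
        assert out == sorted([s2, s, s3])

    def test_consistent_set_returned_unchanged(self):
        seeds = [Seed(0, 0, 3), Seed(2, 4, 3), Seed(8, 10, 4)]
        assert harmonize_soc(seeds, self._diag_guideline()) == sorted(seeds)

    def test_duplicate_seeds_collapse_to_one(self):
        s = Seed(5, 5, 6)
        assert harmonize_soc([s, Seed(5, 5, 6)], self._diag_guideline()) == [s]

    def test_overlapping_query_pair_survives_end_to_end(self):
        """The 1-nt query-overlapping AAT/TGG pair passes harmonization."""
        seeds = [Seed(0, 0, 3), Seed(2, 4, 3)]
        g = fit_guideline(seeds, rng_seed=0, qlen=5)
        assert harmonize_soc(seeds, g) == seeds

    def test_output_consistent_and_monotone_on_random_socs(self, rng):
        for _ in range(60):
            seeds = [
                Seed(rng.randrange(60), rng.randrange(120), rng.randint(1, 10))
                for _ in range(rng.randint(1, 25))
            ]
            g = fit_guideline(seeds, rng_seed=7, qlen=60)
            out = harmonize_soc(seeds, g)
            assert len(out) <= len(seeds)
            assert set(out) <= set(seeds)
            assert conflict_pairs([(s.q, s.r, s.l) for s in out]) == set()

    def test_kept_seed_is_closer_to_guideline(self, rng):
        g = self._diag_guideline()
        for _ in range(40):
            a = Seed(10, 10 + rng.randrange(30), 4)
            b = Seed(10, 10 + rng.randrange(30), 4)
            out = harmonize_soc([a, b], g)
            if len(out) == 1 and guideline_distance(a, g) != guideline_distance(b, g):
                kept = out[0]
                other = b if kept == a else a
                assert guideline_distance(kept, g) <= guideline_distance(other, g)


class TestScheduleSocs:
    def _strips(self, specs, lam=1000):
        seeds = [Seed(q, r, l) for q, r, l in specs]
        return collect_socs(seeds, lam)

    def test_single_strip_single_set(self):
        strips = self._strips([(0, 0, 30), (35, 35, 30)], lam=10)
        params = HeuristicParams(gamma=10, xi=0.01)
        out = schedule_socs(strips, qlen=100, params=params)
        assert len(out) >= 1
        assert all(sum(s.l for s in seeds) >= 10 for seeds, _ in out)

    def test_short_query_lookahead_stops_after_threshold(self):
        # many identical-score strips: stop after lookahead_short + 1 pops
        specs = [(0, 200 * k, 20) for k in range(10)]
        strips = self._strips(specs, lam=10)
        params = HeuristicParams(gamma=5, xi=0.01, lookahead_short=3)
        out = schedule_socs(strips, qlen=100, params=params)
        assert len(out) == params.lookahead_short + 1

    def test_long_query_inspects_at_most_soc_count(self):
        specs = [(0, 300 * k, 20 + (k % 5)) for k in range(50)]
        strips = self._strips(specs, lam=10)
        params = HeuristicParams(gamma=5, xi=0.001, soc_count_long=30)
        out = schedule_socs(strips, qlen=2000, params=params)
        assert len(out) <= 30

    def test_empty_queue_gives_empty_list(self):
        assert schedule_socs([], 100, HeuristicParams()) == []

    def test_determinism(self):
        specs = [(q, q * 3 + 7, 5 + q % 4) for q in range(0, 60, 5)]
        strips = self._strips(specs)
        params = HeuristicParams(gamma=5, xi=0.01)
        a = schedule_socs(strips, 100, params, rng_seed=11)
        b = schedule_socs(strips, 100, params, rng_seed=11)
        assert [x[0] for x in a] == [x[0] for x in b]
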