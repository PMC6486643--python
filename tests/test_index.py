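"""Index contract: extension equals naive substring search on both strands."""

import random

import numpy as np
import pytest

from stripalign import BiInterval, ReferencePack, build_index
from stripalign.index import AmbiguityError, FmdIndex, suffix_array, encode

from oracles import naive_positions
from conftest import random_dna


def naive_suffix_order(text: str) -> list[int]:
    coded = [tuple(encode(text[i:]).tolist()) for i in range(len(text))]
    return sorted(range(len(text)), key=lambda i: coded[i])


class TestReferencePack:
    def test_round_trip_packed_coordinates(self):
        pack = ReferencePack([("a", "ACGTACG"), ("b", "TTGCA")])
        for contig, off, strand, length in [
            ("a", 0, "+", 3), ("a", 4, "-", 2), ("b", 1, "+", 4), ("b", 0, "-", 5),
        ]:
            packed = pack.to_packed(contig, off, strand, length)
            assert pack.to_forward(packed, length) == (contig, off, strand)

    def test_reverse_coordinate_formula(self):
        # a reverse hit at r maps to the forward interval span - r - l
        pack = ReferencePack([("a", "ACGTACG")])
        length = 3
        packed = pack.to_packed("a", 2, "-", length)
        assert pack.span - packed - length == pack.to_packed("a", 2, "+", length)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            ReferencePack([])
        with pytest.raises(ValueError):
            ReferencePack([("a", "")])


class TestSuffixArray:
    @pytest.mark.parametrize("text", ["A", "BANANA-like: ACGTACGTAA", "TTTTTTT", "ACGT#TGCA$"])
    def test_matches_naive_sort(self, text):
        got = suffix_array(encode(text)).tolist()
        assert got == naive_suffix_order(text)

    def test_random_texts_match_naive_sort(self, rng):
        for _ in range(50):
            text = "".join(rng.choice("ACGT#$") for _ in range(rng.randint(1, 80)))
            assert suffix_array(encode(text)).tolist() == naive_suffix_order(text)


class TestFmdIndex:
    def test_single_character_text(self):
        idx = build_index(ReferencePack([("c", "A")]))
        assert idx.init_interval("A").size >= 1

    def test_doubled_text_single_bases(self):
        # in ACGT + its reverse complement every base occurs exactly twice
        idx = build_index(ReferencePack([("c", "ACGT")]))
        for c in "ACGT":
            assert idx.init_interval(c).size == 2

    def test_init_interval_worked_example(self, worked_example):
        pack, idx, _ = worked_example
        g = idx.init_interval("G")
        fwd = [p for p in idx.locate(g) if p < pack.L]
        assert fwd == [5, 6]
        t = idx.init_interval("T")
        assert [p for p in idx.locate(t) if p < pack.L] == [2, 4]

    def test_init_interval_n_never_matches(self, worked_example):
        _, idx, _ = worked_example
        assert idx.init_interval("N").size == 0

    def test_strand_asymmetric_characters(self):
        # TTTT has no A forward, but its revcomp strand is AAAA
        pack = ReferencePack([("c", "TTTT")])
        idx = build_index(pack)
        a = idx.init_interval("A")
        assert [p for p in idx.locate(a) if p < pack.L] == []
        assert a.size == 4  # all hits on the reverse strand
        assert idx.init_interval("C").size == 0  # absent from both strands

    def test_extensions_worked_example(self, worked_example):
        pack, idx, _ = worked_example
        gg = idx.extend_backward("G", idx.init_interval("G"))
        assert [p for p in idx.locate(gg) if p < pack.L] == [5]
        tgg = idx.extend_backward("T", gg)
        assert [p for p in idx.locate(tgg) if p < pack.L] == [4]
        at = idx.extend_backward("A", idx.init_interval("T"))
        aat = idx.extend_backward("A", at)
        assert [p for p in idx.locate(aat) if p < pack.L] == [0]
        aatc = idx.extend_forward("C", aat)
        assert [p for p in idx.locate(aatc) if p < pack.L] == [0]
        assert idx.extend_forward("G", aat).size == 0  # AATG absent on both strands
        tg = idx.extend_forward("G", idx.init_interval("T"))
        assert [p for p in idx.locate(tg) if p < pack.L] == [4]

    def test_extension_on_empty_interval_stays_empty(self, worked_example):
        _, idx, _ = worked_example
        empty = idx.init_interval("N")
        assert idx.extend_backward("A", empty).size == 0
        assert idx.extend_forward("A", empty).size == 0

    def test_locate_whole_reference(self, worked_example):
        pack, idx, _ = worked_example
        iv = idx.init_interval(pack.packed_forward[0])
        for c in pack.packed_forward[1:]:
            iv = idx.extend_forward(c, iv)
        assert [p for p in idx.locate(iv) if p < pack.L] == [0]

    def test_locate_refuses_above_cap(self):
        idx = build_index(ReferencePack([("c", "AAAA")]))
        iv = idx.init_interval("A")
        with pytest.raises(AmbiguityError):
            idx.locate(iv, max_hits=iv.size - 1)

    def test_save_load_round_trip(self, tmp_path, worked_example):
        _, idx, _ = worked_example
        prefix = str(tmp_path / "idx")
        idx.save(prefix)
        loaded = FmdIndex.load(prefix)
        iv1, iv2 = idx.init_interval("T"), loaded.init_interval("T")
        assert (iv1.start, iv1.mirror_start, iv1.size) == (iv2.start, iv2.mirror_start, iv2.size)
        assert idx.locate(iv1) == loaded.locate(iv2)


def chained_interval(idx, pat, rng):
    """Build the interval of pat by a random order of fwd/bwd extensions."""
    pos = rng.randrange(len(pat))
    iv = idx.init_interval(pat[pos])
    lo, hi = pos, pos + 1
    while hi - lo < len(pat):
        if (rng.random() < 0.5 and lo > 0) or hi == len(pat):
            iv = idx.extend_backward(pat[lo - 1], iv)
            lo -= 1
        else:
            iv = idx.extend_forward(pat[hi], iv)
            hi += 1
    return iv


class TestOracleEquivalence:
    def test_extension_chains_equal_naive_search(self, rng):
        """200 random texts: located chained-extension intervals == naive scan."""
        for _ in range(200):
            n = rng.randint(2, 64)
            if rng.random() < 0.25 and n >= 4:
                cut = rng.randint(1, n - 1)
                pack = ReferencePack(
                    [("c0", random_dna(rng, cut)), ("c1", random_dna(rng, n - cut))]
                )
            else:
                pack = ReferencePack([("c0", random_dna(rng, n))])
            idx = build_index(pack)
            text = pack.text
            sizes_seen = []
            for _ in range(10):
                plen = rng.randint(1, min(8, len(text) - 1))
                start = rng.randrange(len(text) - plen + 1)
                pat = text[start : start + plen]
                if any(c not in "ACGT" for c in pat):
                    continue
                iv = chained_interval(idx, pat, rng)
                assert idx.locate(iv) == naive_positions(text, pat)
                sizes_seen.append(iv.size)

    def test_interval_size_non_increasing_under_extension(self, rng):
        pack = ReferencePack([("c", random_dna(rng, 60))])
        idx = build_index(pack)
        for _ in range(50):
            plen = rng.randint(2, 8)
            start = rng.randrange(pack.L - plen)
            pat = pack.packed_forward[start : start + plen]
            iv = idx.init_interval(pat[0])
            prev = iv.size
            for c in pat[1:]:
                iv = idx.extend_forward(c, iv)
                assert iv.size <= prev
                prev = iv.size
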