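"""FMD-style bidirectional substring index.

The index is built over the packed doubled text (forward strand plus reverse
complement, see :mod:`stripalign.reference`). A pattern occurrence set is kept
implicitly as a :class:`BiInterval` — a suffix-array interval for the pattern
together with the start of the mirror interval for its reverse complement —
which supports O(1)-style backward *and* forward extension by one character.

Construction uses a numpy prefix-doubling suffix array (O(n log^2 n)) and a
BWT with full cumulative occurrence counts; ``locate`` reads positions straight
from the retained suffix array.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .reference import ReferencePack

# alphabet: 0 = separator/terminator/N/anything non-ACGT, 1..4 = A,C,G,T
_CODE = np.zeros(256, dtype=np.uint8)
for _i, _c in enumerate("ACGT", start=1):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i

INDEX_FORMAT_VERSION = 1


def encode(text: str) -> np.ndarray:
    """Encode a text to the 0..4 alphabet (non-ACGT -> 0)."""
    return _CODE[np.frombuffer(text.encode("ascii"), dtype=np.uint8)]


def _comp(c: int) -> int:
    return 5 - c  # A<->T, C<->G on the 1..4 alphabet


def suffix_array(t: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (Manber–Myers) with numpy sorts."""
    n = int(t.size)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    rank = t.astype(np.int64)
    k = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        if k < n:
            key2[:-k] = rank[k:]
        order = np.lexsort((key2, rank))
        r1, r2 = rank[order], key2[order]
        bump = np.empty(n, dtype=np.int64)
        bump[0] = 0
        bump[1:] = (r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1])
        ranks_sorted = np.cumsum(bump)
        rank = np.empty(n, dtype=np.int64)
        rank[order] = ranks_sorted
        if ranks_sorted[-1] == n - 1:
            return order.astype(np.int64)
        k *= 2


@dataclass(frozen=True)
class BiInterval:
    """Implicit occurrence set of a pattern in the doubled text.

    ``start`` is the suffix-array rank of the first occurrence, ``mirror_start``
    the rank of the reverse-complement pattern's interval, ``size`` the
    occurrence count. Extension never increases ``size``.
    """

    start: int
    mirror_start: int
    size: int

    @property
    def empty(self) -> bool:
        return self.size == 0


EMPTY_INTERVAL = BiInterval(0, 0, 0)


class AmbiguityError(ValueError):
    """Raised when ``locate`` is asked to expand an interval above its cap."""


class FmdIndex:
    """Bidirectional FM-index over a :class:`ReferencePack`'s doubled text."""

    def __init__(self, pack: ReferencePack, _sa: np.ndarray | None = None):
        self.pack = pack
        self.text = pack.text
        t = encode(self.text)
        self._t = t
        n = t.size
        sa = suffix_array(t) if _sa is None else _sa
        bwt = np.where(sa > 0, t[np.maximum(sa - 1, 0)], t[n - 1]).astype(np.uint8)
        # cumulative occurrence counts: occ[i, c] = #{j < i : bwt[j] == c}
        occ = np.zeros((n + 1, 5), dtype=np.int64)
        for c in range(5):
            np.cumsum(bwt == c, out=occ[1:, c])
        counts = occ[n]
        self._C = np.zeros(6, dtype=np.int64)
        self._C[1:] = np.cumsum(counts)
        self._occ = occ
        self._bwt = bwt
        self._full_sa = sa

    # ------------------------------------------------------------ queries

    def init_interval(self, c: str) -> BiInterval:
        """Occurrence set of the single character ``c`` (empty for non-ACGT)."""
        code = int(_CODE[ord(c)]) if c else 0
        if code == 0:
            return EMPTY_INTERVAL
        k = int(self._C[code])
        size = int(self._C[code + 1] - self._C[code])
        kp = int(self._C[_comp(code)])
        return BiInterval(k, kp, size)

    def extend_backward(self, c: str, iv: BiInterval) -> BiInterval:
        """O(R, c + s) from O(R, s)."""
        code = int(_CODE[ord(c)]) if c else 0
        if code == 0 or iv.size == 0:
            return EMPTY_INTERVAL
        occ_k = self._occ[iv.start]
        cnt = self._occ[iv.start + iv.size] - occ_k
        size = int(cnt[code])
        if size == 0:
            return EMPTY_INTERVAL
        k = int(self._C[code] + occ_k[code])
        # mirror side: intervals of revcomp(s)+x stack in the order x = 0,A,C,G,T,
        # and |revcomp(s)+x| == |comp(x)+s|; chars above `code` on the
        # complement scale come first.
        kp = int(iv.mirror_start + cnt[0] + cnt[code + 1 : 5].sum())
        return BiInterval(k, kp, size)

    def extend_forward(self, c: str, iv: BiInterval) -> BiInterval:
        """O(R, s + c) from O(R, s), via backward extension on the mirror."""
        code = int(_CODE[ord(c)]) if c else 0
        if code == 0 or iv.size == 0:
            return EMPTY_INTERVAL
        mirrored = BiInterval(iv.mirror_start, iv.start, iv.size)
        ext = self.extend_backward("TGCA"[code - 1], mirrored)
        if ext.size == 0:
            return EMPTY_INTERVAL
        return BiInterval(ext.mirror_start, ext.start, ext.size)

    def locate(self, iv: BiInterval, max_hits: int | None = None) -> list[int]:
        """Packed text positions of all occurrences in the interval."""
        if max_hits is not None and iv.size > max_hits:
            raise AmbiguityError(f"interval size {iv.size} exceeds cap {max_hits}")
        return sorted(int(p) for p in self._full_sa[iv.start : iv.start + iv.size])

    # ------------------------------------------------------------ storage

    def save(self, prefix: str) -> None:
        """Write a versioned two-file index set (<prefix>.npz, <prefix>.json)."""
        np.savez_compressed(prefix + ".npz", sa=self._full_sa)
        meta = {
            "format_version": INDEX_FORMAT_VERSION,
            "contigs": [[c.name, self.pack.contig_seq(c.name)] for c in self.pack.contigs],
        }
        with open(prefix + ".json", "w") as fh:
            json.dump(meta, fh)

    @classmethod
    def load(cls, prefix: str) -> "FmdIndex":
        with open(prefix + ".json") as fh:
            meta = json.load(fh)
        if meta.get("format_version") != INDEX_FORMAT_VERSION:
            raise ValueError("unsupported index format version")
        pack = ReferencePack([(n, s) for n, s in meta["contigs"]])
        sa = np.load(prefix + ".npz")["sa"]
        return cls(pack, _sa=sa)


def build_index(reference: ReferencePack) -> FmdIndex:
    """Build the FMD index for a packed reference."""
    return FmdIndex(reference)
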