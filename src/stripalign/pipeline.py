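"""End-to-end alignment pipeline and configuration.

``align_read`` wires the three stages together: binary seeding with the seed
filters and the coverage check, SoC collection with the score filter, scheduled
harmonization, and DP assembly per harmonized set. The best-scoring alignment
is primary; alignments from other strips that cover a clearly different part
of the read (chimeric/translocated segments) are emitted as supplementary
records, while same-locus alternatives only inform the mapping quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

from .gapfill import Alignment, assemble_alignment, compute_mapq
from .harmonize import HeuristicParams, schedule_socs
from .index import FmdIndex
from .seeding import binary_seeding, coverage_check, filter_seeds
from .soc import ScoringScheme, collect_socs, compute_lambda, soc_score_filter


@dataclass
class AlignerConfig:
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    params: HeuristicParams = field(default_factory=HeuristicParams)
    rng_seed: int = 0
    band_extra: int = 16
    max_supplementary: int = 4
    supplementary_overlap: float = 0.5  # max query-overlap fraction

    @classmethod
    def for_noisy_long_reads(cls, rng_seed: int = 0) -> "AlignerConfig":
        """Configuration for PacBio/nanopore-grade error rates.

        At 10-20% total error the mean exact-match run is 5-10 nt, so the
        seed-length floor drops to 10 (still near-unique on a 10^5-bp genome:
        4^10 >> 2e5) and the coverage check expects one such seed per 100-nt
        segment rather than a longer one.
        """
        return cls(
            params=HeuristicParams(alpha=10.0, beta=100.0, min_seed_size=10),
            rng_seed=rng_seed,
        )

    # ----------------------------------------------------- key=value config

    def to_file(self, path: str) -> None:
        with open(path, "w") as fh:
            for group in (self.scoring, self.params):
                for f in fields(group):
                    fh.write(f"{f.name} = {getattr(group, f.name)}\n")
            for name in ("rng_seed", "band_extra", "max_supplementary",
                         "supplementary_overlap"):
                fh.write(f"{name} = {getattr(self, name)}\n")

    @classmethod
    def from_file(cls, path: str) -> "AlignerConfig":
        raw: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, val = line.partition("=")
                raw[key.strip()] = val.strip()

        def pick(dc_cls):
            kw = {}
            for f in fields(dc_cls):
                if f.name in raw:
                    typ = float if f.type in ("float", float) else int
                    kw[f.name] = typ(raw[f.name])
            return dc_cls(**kw)

        cfg = cls(scoring=pick(ScoringScheme), params=pick(HeuristicParams))
        for name, typ in (("rng_seed", int), ("band_extra", int),
                          ("max_supplementary", int), ("supplementary_overlap", float)):
            if name in raw:
                setattr(cfg, name, typ(raw[name]))
        return cfg


def _query_overlap_frac(a: Alignment, b: Alignment) -> float:
    a0, a1 = a.query_span
    b0, b1 = b.query_span
    inter = max(0, min(a1, b1) - max(a0, b0))
    denom = min(a1 - a0, b1 - b0)
    return inter / denom if denom else 1.0


def align_read(
    index: FmdIndex, query: str, config: AlignerConfig | None = None
) -> list[Alignment]:
    """Align one read; returns [] when the read should be reported unmapped.

    Once the coverage check passes, at least one alignment is returned. The
    first returned alignment is primary; any further ones are supplementary.
    """
    config = config or AlignerConfig()
    p = config.params
    pack = index.pack
    qlen = len(query)
    if qlen == 0:
        return []
    seeds = binary_seeding(index, query, max_ambiguity=p.max_ambiguity)
    min_seed = min(p.min_seed_size, max(1, qlen // 4))
    seeds = filter_seeds(seeds, min_seed, p.max_ambiguity)
    if not seeds or not coverage_check(seeds, qlen, p.alpha, p.beta):
        return []
    lam = compute_lambda(config.scoring, qlen)
    strips = collect_socs(seeds, lam)
    strips = [s for s in strips if soc_score_filter(s.score, p.gamma, p.xi, qlen)] or strips[:1]
    harmonized = schedule_socs(strips, qlen, p, rng_seed=config.rng_seed, guarantee_one=True)
    candidates: list[Alignment] = []
    for seed_set, _strip in harmonized:
        if not seed_set:
            continue
        try:
            aln = assemble_alignment(
                seed_set, query, pack, config.scoring,
                band_extra=config.band_extra, _check_consistency=False,
            )
        except ValueError:
            continue
        candidates.append(aln)
    if not candidates:
        return []
    candidates.sort(key=lambda a: (-a.score, a.contig, a.pos))
    primary = candidates[0]
    emitted = [primary]
    second_score: float | None = None
    for aln in candidates[1:]:
        if _query_overlap_frac(aln, primary) > config.supplementary_overlap:
            if second_score is None:
                second_score = aln.score
            continue
        if len(emitted) - 1 < config.max_supplementary and soc_score_filter(
            sum(n for n, op in aln.cigar if op == "M"), p.gamma, p.xi, qlen
        ):
            aln.is_supplementary = True
            emitted.append(aln)
    primary.mapq = compute_mapq(primary.score, second_score, qlen, config.scoring)
    for aln in emitted[1:]:
        aln.mapq = primary.mapq
    return emitted
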