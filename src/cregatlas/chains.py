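"""Chain maps and liftOver-style coordinate projection.

A :class:`Chain` is one co-linear run of equal-width aligned blocks
between a source genome and a target genome (one record of a UCSC chain
file).  A :class:`ChainMap` bundles all records for one ordered species
pair and supports interval projection with the classic liftOver
semantics: a minimum matched-base fraction (``minMatch``), rejection of
intervals whose blocks scatter over more than one target locus, and a
reciprocal-mapping wrapper with a maximum size-change filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from cregatlas.intervals import GenomicInterval

__all__ = ["Chain", "ChainMap", "MapResult", "liftover_interval", "reciprocal_map"]

#: two split targets on one chromosome closer than this are bridged into
#: one span rather than being called multi-mapped (liftOver span behaviour)
BRIDGE_DISTANCE = 10_000


@dataclass
class Chain:
    """One chain record: sorted, non-overlapping, equal-width blocks.

    Blocks are stored as parallel arrays of source starts, target starts
    and sizes.  For ``strand == '-'`` the target coordinates are kept on
    the forward strand of the target assembly; block k maps source span
    ``[src[k], src[k]+size[k])`` onto the reverse-oriented target span
    whose forward coordinates are ``[tgt[k], tgt[k]+size[k])``.
    """

    src_chrom: str
    tgt_chrom: str
    src_size: int
    tgt_size: int
    strand: str = "+"
    src_starts: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    tgt_starts: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    sizes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    chain_id: int = 0

    def __post_init__(self) -> None:
        self.src_starts = np.asarray(self.src_starts, dtype=np.int64)
        self.tgt_starts = np.asarray(self.tgt_starts, dtype=np.int64)
        self.sizes = np.asarray(self.sizes, dtype=np.int64)
        if not (len(self.src_starts) == len(self.tgt_starts) == len(self.sizes)):
            raise ValueError("block arrays must have equal length")
        if len(self.src_starts) > 1:
            ends = self.src_starts[:-1] + self.sizes[:-1]
            if np.any(self.src_starts[1:] < ends):
                raise ValueError("source blocks overlap or are unsorted")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    def invert(self) -> "Chain":
        """The chain mapping target coordinates back onto the source."""
        if self.strand == "+":
            order = np.argsort(self.tgt_starts)
            return Chain(
                src_chrom=self.tgt_chrom,
                tgt_chrom=self.src_chrom,
                src_size=self.tgt_size,
                tgt_size=self.src_size,
                strand="+",
                src_starts=self.tgt_starts[order],
                tgt_starts=self.src_starts[order],
                sizes=self.sizes[order],
                chain_id=self.chain_id,
            )
        # reverse orientation: target forward coords ascend as source descends
        order = np.argsort(self.tgt_starts)
        return Chain(
            src_chrom=self.tgt_chrom,
            tgt_chrom=self.src_chrom,
            src_size=self.tgt_size,
            tgt_size=self.src_size,
            strand="-",
            src_starts=self.tgt_starts[order],
            tgt_starts=self.src_starts[order],
            sizes=self.sizes[order],
            chain_id=self.chain_id,
        )


@dataclass
class ChainMap:
    """All chain records for one ordered (source species, target species) pair."""

    source_species: str
    target_species: str
    chains: list[Chain] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_chrom: dict[str, list[Chain]] = {}
        for ch in self.chains:
            self._by_chrom.setdefault(ch.src_chrom, []).append(ch)

    def invert(self) -> "ChainMap":
        return ChainMap(
            source_species=self.target_species,
            target_species=self.source_species,
            chains=[c.invert() for c in self.chains],
        )

    def chains_for(self, chrom: str) -> list[Chain]:
        return self._by_chrom.get(chrom, [])


@dataclass(frozen=True)
class MapResult:
    """Outcome of projecting one interval through a chain map."""

    status: str  # mapped | unmapped_low_match | multi_mapped | size_violation
    interval: GenomicInterval | None
    matched_fraction: float
    reason: str = ""

    def __post_init__(self) -> None:
        if (self.status == "mapped") != (self.interval is not None):
            raise ValueError("interval present iff status is 'mapped'")
        if not (0.0 <= self.matched_fraction <= 1.0):
            raise ValueError("matched_fraction outside [0, 1]")


def _project_pieces(iv: GenomicInterval, chain: Chain):
    """Intersect ``iv`` with a chain's blocks; yield (bases, tstart, tend)."""
    s = np.maximum(chain.src_starts, iv.start)
    e = np.minimum(chain.src_starts + chain.sizes, iv.end)
    hit = s < e
    if not np.any(hit):
        return []
    s, e = s[hit], e[hit]
    off_s = s - chain.src_starts[hit]
    off_e = e - chain.src_starts[hit]
    ts0 = chain.tgt_starts[hit]
    sz = chain.sizes[hit]
    pieces = []
    for k in range(len(s)):
        if chain.strand == "+":
            t0 = int(ts0[k] + off_s[k])
            t1 = int(ts0[k] + off_e[k])
        else:
            t0 = int(ts0[k] + sz[k] - off_e[k])
            t1 = int(ts0[k] + sz[k] - off_s[k])
        pieces.append((int(e[k] - s[k]), t0, t1))
    return pieces


def liftover_interval(
    iv: GenomicInterval,
    chainmap: ChainMap,
    min_match: float = 0.1,
) -> MapResult:
    """Project one interval through ``chainmap``.

    The mapped span is the ``[min, max)`` hull of the targets of all
    intersected blocks, provided the matched-base fraction reaches
    ``min_match`` and all intersecting blocks agree on one target locus
    (same chromosome and orientation, split targets bridged only within
    :data:`BRIDGE_DISTANCE`).
    """
    if iv.species != chainmap.source_species:
        raise ValueError(
            f"interval species {iv.species!r} does not match chain source "
            f"{chainmap.source_species!r}"
        )
    hits: list[tuple[str, str, int, int, int]] = []  # chrom, strand, bases, t0, t1
    for chain in chainmap.chains_for(iv.chrom):
        for bases, t0, t1 in _project_pieces(iv, chain):
            hits.append((chain.tgt_chrom, chain.strand, bases, t0, t1))
    matched = sum(h[2] for h in hits)
    fraction = matched / iv.width
    if matched == 0 or fraction < min_match:
        return MapResult("unmapped_low_match", None, fraction)
    loci = {(h[0], h[1]) for h in hits}
    if len(loci) > 1:
        return MapResult(
            "multi_mapped", None, fraction, reason="targets on multiple loci"
        )
    tgt_chrom, strand = next(iter(loci))
    spans = sorted((h[3], h[4]) for h in hits)
    for (s0, e0), (s1, _) in zip(spans, spans[1:]):
        if s1 - e0 > BRIDGE_DISTANCE:
            return MapResult(
                "multi_mapped", None, fraction, reason="split target beyond bridge"
            )
    start = spans[0][0]
    end = max(e for _, e in spans)
    mapped = GenomicInterval(
        species=chainmap.target_species, chrom=tgt_chrom, start=start, end=end, id=iv.id
    )
    return MapResult("mapped", mapped, fraction)


def reciprocal_map(
    iv: GenomicInterval,
    chain_fwd: ChainMap,
    chain_rev: ChainMap,
    min_match: float = 0.1,
    max_size_change: float = 0.5,
) -> MapResult:
    """Project an interval and require the round trip to return home.

    Accepts only if the forward projection succeeds, its relative size
    change is at most ``max_size_change`` (strictly larger changes are
    rejected), the back-projection succeeds, and the back-projected
    interval overlaps the original by at least 1 bp.
    """
    fwd = liftover_interval(iv, chain_fwd, min_match=min_match)
    if fwd.status != "mapped":
        return fwd
    size_change = abs(fwd.interval.width - iv.width) / iv.width
    if size_change > max_size_change:
        return MapResult(
            "size_violation",
            None,
            fwd.matched_fraction,
            reason=f"size change {size_change:.3f} > {max_size_change}",
        )
    back = liftover_interval(fwd.interval, chain_rev, min_match=min_match)
    if back.status != "mapped":
        return MapResult(
            back.status if back.status != "mapped" else "unmapped_low_match",
            None,
            fwd.matched_fraction,
            reason="back-projection failed",
        )
    if back.interval.chrom != iv.chrom or back.interval.overlap(iv) < 1:
        return MapResult(
            "unmapped_low_match",
            None,
            fwd.matched_fraction,
            reason="round trip left the source locus",
        )
    return MapResult("mapped", fwd.interval, fwd.matched_fraction)


def identity_chainmap(
    source_species: str,
    target_species: str,
    chrom_sizes: dict[str, int],
) -> ChainMap:
    """A chain map sending every coordinate to itself (testing aid)."""
    chains = [
        Chain(
            src_chrom=c,
            tgt_chrom=c,
            src_size=n,
            tgt_size=n,
            strand="+",
            src_starts=np.array([0]),
            tgt_starts=np.array([0]),
            sizes=np.array([n]),
            chain_id=k,
        )
        for k, (c, n) in enumerate(sorted(chrom_sizes.items()))
    ]
    return ChainMap(source_species, target_species, chains)
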