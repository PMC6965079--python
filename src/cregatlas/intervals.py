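"""Genomic-interval algebra and peak post-processing.

All coordinates are 0-based half-open (BED convention) on a named
chromosome of a named species/assembly.  Regulatory regions are
unstranded; strand only matters for TSS annotation and is handled there.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "extend_to_min_width",
    "merge_stitch",
    "reproducible_regions",
    "overlap_query",
    "overlap_bases",
    "total_overlap",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A species-tagged half-open coordinate span ``[start, end)``."""

    species: str
    chrom: str
    start: int
    end: int
    id: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on "
                f"{self.species}:{self.chrom}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Shared bases with ``other`` (0 if different chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class PeakSet:
    """Sorted peak calls for one species/tissue/replicate."""

    species: str
    tissue: str = ""
    replicate: str = ""
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = sorted(
            self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )
        ids = [iv.id for iv in self.intervals if iv.id is not None]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate interval ids in PeakSet")

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)


def overlap_bases(a: GenomicInterval, b: GenomicInterval) -> int:
    return a.overlap(b)


def extend_to_min_width(
    peak: GenomicInterval,
    min_width: int = 2000,
    chrom_length: int | None = None,
) -> GenomicInterval:
    """Extend a narrow peak to ``min_width`` around its centre.

    Peaks already at least ``min_width`` wide are returned unchanged.
    Narrow peaks are replaced by ``[center - ceil(w/2), center + floor(w/2))``
    clamped to ``[0, chrom_length)``; clamping truncates rather than
    shifting, so a peak at a chromosome edge may stay below ``min_width``.
    """
    if peak.width >= min_width:
        return peak
    center = (peak.start + peak.end) // 2
    left = min_width - min_width // 2  # left half gets the extra base
    new_start = max(0, center - left)
    new_end = center + min_width // 2
    if chrom_length is not None:
        new_end = min(new_end, chrom_length)
    return replace(peak, start=new_start, end=new_end)


def merge_stitch(
    intervals: Sequence[GenomicInterval],
    min_overlap: int = 1,
) -> list[tuple[GenomicInterval, list[str]]]:
    """Stitch intervals overlapping by ``>= min_overlap`` bases.

    Returns the transitive closure of the overlap relation as a list of
    ``(merged_interval, member_ids)`` pairs, sorted by coordinate.  Member
    ids are the ``id`` fields of the constituents (positional ids
    ``"i<k>"`` are substituted for anonymous intervals).  Half-open
    adjacency (``end == start``) shares zero bases and is never merged.
    """
    if not intervals:
        return []
    species = {iv.species for iv in intervals}
    if len(species) > 1:
        raise ValueError(f"merge_stitch requires a single species, got {species}")
    ivs = sorted(
        (
            (iv, iv.id if iv.id is not None else f"i{k}")
            for k, iv in enumerate(intervals)
        ),
        key=lambda t: (t[0].chrom, t[0].start, t[0].end),
    )
    out: list[tuple[GenomicInterval, list[str]]] = []
    cur_iv, cur_members = ivs[0][0], [ivs[0][1]]
    cur_start, cur_end = cur_iv.start, cur_iv.end
    for iv, member in ivs[1:]:
        if iv.chrom == cur_iv.chrom and min(cur_end, iv.end) - iv.start >= min_overlap:
            cur_end = max(cur_end, iv.end)
            cur_members.append(member)
        else:
            out.append(
                (replace(cur_iv, start=cur_start, end=cur_end, id=None), cur_members)
            )
            cur_iv, cur_members = iv, [member]
            cur_start, cur_end = iv.start, iv.end
    out.append((replace(cur_iv, start=cur_start, end=cur_end, id=None), cur_members))
    merged = [
        (replace(iv, id=f"m{k}"), members) for k, (iv, members) in enumerate(out)
    ]
    return merged


def _build_trees(intervals: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def overlap_query(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    min_overlap: int = 1,
) -> list[tuple[str, str]]:
    """All pairs ``(id_a, id_b)`` sharing ``>= min_overlap`` bases.

    Anonymous intervals get positional ids ``a<k>`` / ``b<k>``.  The
    relation is symmetric in the sense that swapping the argument order
    swaps the pair components.
    """
    trees = _build_trees(
        replace(iv, id=iv.id if iv.id is not None else f"b{k}")
        for k, iv in enumerate(b)
    )
    pairs: list[tuple[str, str]] = []
    for k, iv in enumerate(a):
        ida = iv.id if iv.id is not None else f"a{k}"
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(iv.start, iv.end):
            if min(iv.end, hit.end) - max(iv.start, hit.begin) >= min_overlap:
                pairs.append((ida, hit.data.id))
    return sorted(pairs)


def total_overlap(
    iv: GenomicInterval, others: Sequence[GenomicInterval]
) -> int:
    """Bases of ``iv`` covered by the union of ``others`` (same chrom)."""
    spans = sorted(
        (max(iv.start, o.start), min(iv.end, o.end))
        for o in others
        if o.chrom == iv.chrom and o.start < iv.end and o.end > iv.start
    )
    covered = 0
    cur_s = cur_e = None
    for s, e in spans:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered


def reproducible_regions(
    replicate_sets: Sequence[PeakSet],
    min_replicates: int = 2,
) -> PeakSet:
    """Merged regions supported by at least ``min_replicates`` replicates.

    All replicate peaks are stitched together (>= 1 bp overlap); a merged
    region is retained when peaks from at least ``min_replicates``
    distinct replicates overlap it by >= 1 bp.
    """
    if not replicate_sets:
        raise ValueError("reproducible_regions requires at least one replicate set")
    if len(replicate_sets) < min_replicates:
        raise ValueError(
            f"{len(replicate_sets)} replicate sets cannot satisfy "
            f"min_replicates={min_replicates}"
        )
    species = {ps.species for ps in replicate_sets}
    if len(species) > 1:
        raise ValueError("replicates must come from one species")
    tagged: list[GenomicInterval] = []
    rep_of: dict[str, str] = {}
    k = 0
    for ps in replicate_sets:
        for iv in ps.intervals:
            tag = f"r{k}"
            k += 1
            tagged.append(replace(iv, id=tag))
            rep_of[tag] = ps.replicate or str(id(ps))
    merged = merge_stitch(tagged, min_overlap=1)
    kept = [
        replace(iv, id=None)
        for iv, members in merged
        if len({rep_of[m] for m in members}) >= min_replicates
    ]
    kept = [replace(iv, id=f"rep{k}") for k, iv in enumerate(kept)]
    return PeakSet(
        species=replicate_sets[0].species,
        tissue=replicate_sets[0].tissue,
        replicate="pooled",
        intervals=kept,
    )
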