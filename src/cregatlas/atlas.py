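"""Cross-species atlas construction.

Builds the set of regulatory regions carrying coordinates on all four
genomes: non-reference peak lists are reciprocally projected onto the
reference, merged with the reference list, re-projected reciprocally to
every genome, and filtered for assembly-gap content and repeat overlap.
Every discarded region lands in a ledger partitioned by reason, so the
conservation identity |merged input| = |atlas| + Σ discards always holds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import pandas as pd

from cregatlas.chains import ChainMap, reciprocal_map
from cregatlas.intervals import (
    GenomicInterval,
    PeakSet,
    merge_stitch,
    overlap_query,
    total_overlap,
)

__all__ = [
    "AtlasEntry",
    "GREAtlas",
    "mappability_filter",
    "detect_repetitive",
    "build_atlas",
]


def mappability_filter(
    iv: GenomicInterval,
    gap_track: Sequence[GenomicInterval],
    min_annotated: float = 0.9,
) -> tuple[bool, float]:
    """Check that enough of a region is properly annotated (non-gap).

    Returns ``(passed, annotated_fraction)``; the region passes when at
    least ``min_annotated`` of its bases fall outside assembly gaps
    (boundary kept: exactly ``min_annotated`` passes).
    """
    gap_bases = total_overlap(iv, list(gap_track))
    annotated = 1.0 - gap_bases / iv.width
    return annotated >= min_annotated, annotated


def detect_repetitive(
    unique_enriched: PeakSet, multimap_enriched: PeakSet
) -> list[GenomicInterval]:
    """Regions enriched only when multi-mapping reads are allowed.

    A peak present in the multimap peak set with zero (>=1 bp) overlap
    against any uniquely-mapped peak marks a locus whose enrichment is
    carried by repetitive sequence.
    """
    if unique_enriched.species != multimap_enriched.species:
        raise ValueError("peak sets must come from the same species")
    mm = [
        replace(iv, id=iv.id if iv.id is not None else f"mm{k}")
        for k, iv in enumerate(multimap_enriched.intervals)
    ]
    hits = {ida for ida, _ in overlap_query(mm, unique_enriched.intervals)}
    return [iv for iv in mm if iv.id not in hits]


@dataclass
class AtlasEntry:
    region_id: str
    coords: dict[str, GenomicInterval]  # species -> coordinates
    members: list[str] = field(default_factory=list)
    provenance: dict[str, float | str | bool] = field(default_factory=dict)
    gre_class: str = ""  # promoter | enhancer, filled by annotation


@dataclass
class GREAtlas:
    reference: str
    species: list[str]
    regions: list[AtlasEntry]

    def __len__(self) -> int:
        return len(self.regions)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.regions:
            row: dict = {"region_id": e.region_id, "class": e.gre_class}
            for sp in self.species:
                iv = e.coords[sp]
                row[f"{sp}_chrom"] = iv.chrom
                row[f"{sp}_start"] = iv.start
                row[f"{sp}_end"] = iv.end
            row["members"] = ",".join(e.members)
            rows.append(row)
        return pd.DataFrame(rows)


def _map_peaks_to_reference(
    peaks: PeakSet,
    fwd: ChainMap,
    rev: ChainMap,
    min_match: float,
    max_size_change: float,
):
    mapped, dropped = [], []
    for iv in peaks.intervals:
        res = reciprocal_map(
            iv, fwd, rev, min_match=min_match, max_size_change=max_size_change
        )
        if res.status == "mapped":
            mapped.append(res.interval)
        else:
            dropped.append((iv, res.status))
    return mapped, dropped


def build_atlas(
    peaks_by_species: Mapping[str, PeakSet],
    chains: Mapping[tuple[str, str], ChainMap],
    gap_tracks: Mapping[str, Sequence[GenomicInterval]],
    repeat_sets: Mapping[str, Sequence[GenomicInterval]],
    reference: str = "human",
    min_match: float = 0.1,
    max_size_change: float = 0.5,
    min_annotated: float = 0.9,
) -> tuple[GREAtlas, pd.DataFrame, pd.DataFrame]:
    """Build the 4-genome atlas from per-species reproducible peak lists.

    Parameters
    ----------
    peaks_by_species :
        Nonredundant reproducible peak list per species.
    chains :
        ``(source_species, target_species) -> ChainMap`` for every pair
        involving the reference, in both directions.
    gap_tracks, repeat_sets :
        Assembly-gap and repetitive-region intervals per species.

    Returns
    -------
    atlas, ledger, input_ledger
        ``ledger`` partitions the merged candidate list by discard reason
        (``unmappable``, ``multi_mapped``, ``size_violation``, ``gap``,
        ``repeat``); ``input_ledger`` records pre-merge projection
        failures of the individual non-reference peak lists.
    """
    species = sorted(peaks_by_species)
    if reference not in species:
        raise ValueError(f"reference {reference!r} not among peak sets {species}")
    others = [sp for sp in species if sp != reference]
    for sp in others:
        for pair in [(sp, reference), (reference, sp)]:
            if pair not in chains:
                raise ValueError(f"missing chain map for species pair {pair}")

    # stage 1: project every non-reference list onto the reference
    on_ref: list[GenomicInterval] = []
    input_rows = []
    for k, iv in enumerate(peaks_by_species[reference].intervals):
        on_ref.append(replace(iv, id=f"{reference}:{iv.id or k}"))
    for sp in others:
        mapped, dropped = _map_peaks_to_reference(
            peaks_by_species[sp],
            chains[(sp, reference)],
            chains[(reference, sp)],
            min_match,
            max_size_change,
        )
        for k, iv in enumerate(mapped):
            on_ref.append(
                GenomicInterval(
                    reference, iv.chrom, iv.start, iv.end, id=f"{sp}:{iv.id or k}"
                )
            )
        for iv, status in dropped:
            input_rows.append(
                {
                    "species": sp,
                    "chrom": iv.chrom,
                    "start": iv.start,
                    "end": iv.end,
                    "reason": status,
                }
            )
    input_ledger = pd.DataFrame(
        input_rows, columns=["species", "chrom", "start", "end", "reason"]
    )

    # stage 2: merge the four lists on the reference (>=1 bp stitching)
    merged = merge_stitch(on_ref, min_overlap=1)

    # stages 3-5: reciprocal re-projection, mappability, repeat overlap
    entries: list[AtlasEntry] = []
    ledger_rows = []

    def discard(region_id, iv, reason, detail=""):
        ledger_rows.append(
            {
                "region_id": region_id,
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "reason": reason,
                "detail": detail,
            }
        )

    repeat_by_species = {sp: list(repeat_sets.get(sp, [])) for sp in species}
    gap_by_species = {sp: list(gap_tracks.get(sp, [])) for sp in species}

    for k, (iv, members) in enumerate(merged):
        region_id = f"GRE{k:05d}"
        region = replace(iv, id=region_id)
        coords: dict[str, GenomicInterval] = {reference: region}
        fail_reason = None
        detail = ""
        for sp in others:
            res = reciprocal_map(
                region,
                chains[(reference, sp)],
                chains[(sp, reference)],
                min_match=min_match,
                max_size_change=max_size_change,
            )
            if res.status != "mapped":
                reason_map = {
                    "unmapped_low_match": "unmappable",
                    "multi_mapped": "multi_mapped",
                    "size_violation": "size_violation",
                }
                fail_reason = reason_map[res.status]
                detail = sp
                break
            coords[sp] = res.interval
        if fail_reason is not None:
            discard(region_id, region, fail_reason, detail)
            continue
        annotated = {
            sp: mappability_filter(coords[sp], gap_by_species[sp], min_annotated)
            for sp in species
        }
        bad = [sp for sp, (ok, _) in annotated.items() if not ok]
        if bad:
            discard(region_id, region, "gap", ",".join(bad))
            continue
        rep = [
            sp
            for sp in species
            if total_overlap(coords[sp], repeat_by_species[sp]) >= 1
        ]
        if rep:
            discard(region_id, region, "repeat", ",".join(rep))
            continue
        entries.append(
            AtlasEntry(
                region_id=region_id,
                coords=coords,
                members=list(members),
                provenance={
                    "n_members": len(members),
                    **{f"annotated_{sp}": annotated[sp][1] for sp in species},
                },
            )
        )

    ledger = pd.DataFrame(
        ledger_rows,
        columns=["region_id", "chrom", "start", "end", "reason", "detail"],
    )
    atlas = GREAtlas(reference=reference, species=species, regions=entries)
    assert len(merged) == len(atlas) + len(ledger), "region conservation violated"
    return atlas, ledger, input_ledger
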