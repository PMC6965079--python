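"""Promoter/enhancer classification, gene linkage, cell-type assignment.

Regions within 1000 bp of an annotated TSS are promoters (linked to the
associated genes); the rest are putative enhancers, linked to a gene by
a chromatin loop when one anchors in the region, otherwise to the
closest H3K4me3-active TSS.  Cell-type identity is inherited from
single-cell open-chromatin sets: a region overlapping regions of exactly
one cell-type label takes that label, anything else is not
cell-type-specific.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from cregatlas.intervals import GenomicInterval

__all__ = [
    "GeneLink",
    "classify_tss_proximity",
    "link_enhancer_gene",
    "assign_cell_type",
    "annotate_regions",
]


@dataclass(frozen=True)
class GeneLink:
    region_id: str
    gene_id: str | None
    evidence: str  # promoter | hic_loop | nearest_active_tss | unlinked


def _tss_distance(region: GenomicInterval, pos: int) -> int:
    """Gap in bases between the TSS base and the nearest region base."""
    if region.start <= pos < region.end:
        return 0
    if pos < region.start:
        return region.start - pos
    return pos - (region.end - 1)


def classify_tss_proximity(
    region: GenomicInterval,
    tss: pd.DataFrame,
    window: int = 1000,
) -> tuple[str, list[str]]:
    """Classify a region as promoter or enhancer by TSS proximity.

    ``tss`` is a BED6-style frame (chrom, start, end, name, score,
    strand) whose ``start`` is the TSS base and ``name`` the gene id.
    Promoter iff any TSS lies within ``window`` bases of the region edge
    (0 if contained); all such genes are returned.
    """
    if tss.empty:
        return "enhancer", []
    near = tss[tss["chrom"] == region.chrom]
    genes = [
        str(row.name)
        for row in near.itertuples(index=False)
        if _tss_distance(region, int(row.start)) <= window
    ]
    if genes:
        return "promoter", sorted(set(genes))
    return "enhancer", []


def link_enhancer_gene(
    region: GenomicInterval,
    loops: pd.DataFrame,
    tss: pd.DataFrame,
    activity_threshold: float = 0.0,
) -> GeneLink:
    """Assign an enhancer to its target gene.

    Prefer a chromatin loop whose one anchor overlaps the region (>=1 bp)
    and whose other anchor contains a TSS; among several, the loop with
    the largest anchor overlap wins.  Without a loop, link the closest
    TSS whose H3K4me3 score exceeds ``activity_threshold``; distance ties
    break toward the lower-coordinate gene.
    """
    best_gene, best_ov = None, 0
    for row in loops.itertuples(index=False):
        for (c1, s1, e1), (c2, s2, e2) in (
            ((row.chrom1, row.start1, row.end1), (row.chrom2, row.start2, row.end2)),
            ((row.chrom2, row.start2, row.end2), (row.chrom1, row.start1, row.end1)),
        ):
            if c1 != region.chrom:
                continue
            ov = min(region.end, e1) - max(region.start, s1)
            if ov < 1:
                continue
            other = tss[(tss["chrom"] == c2) & (tss["start"] >= s2) & (tss["start"] < e2)]
            for t in other.itertuples(index=False):
                if ov > best_ov:
                    best_gene, best_ov = str(t.name), ov
    if best_gene is not None:
        return GeneLink(region.id or "", best_gene, "hic_loop")
    active = tss[(tss["chrom"] == region.chrom) & (tss["score"] > activity_threshold)]
    if active.empty:
        return GeneLink(region.id or "", None, "unlinked")
    ranked = sorted(
        (
            (_tss_distance(region, int(t.start)), int(t.start), str(t.name))
            for t in active.itertuples(index=False)
        )
    )
    return GeneLink(region.id or "", ranked[0][2], "nearest_active_tss")


def assign_cell_type(
    region: GenomicInterval,
    celltype_sets: Mapping[str, Sequence[GenomicInterval]],
) -> str:
    """Label a region by single-cell open-chromatin overlap.

    Returns the label when the region overlaps (>=1 bp) regions of
    exactly one cell type, ``"not_specific"`` for none or several.
    """
    hit_labels = []
    for label in sorted(celltype_sets):
        for iv in celltype_sets[label]:
            if region.overlap(iv) >= 1:
                hit_labels.append(label)
                break
    return hit_labels[0] if len(hit_labels) == 1 else "not_specific"


def annotate_regions(
    regions: Sequence[GenomicInterval],
    tss: pd.DataFrame,
    loops: pd.DataFrame,
    celltype_sets: Mapping[str, Sequence[GenomicInterval]],
    window: int = 1000,
) -> pd.DataFrame:
    """Full annotation table: class, gene link with evidence, cell type."""
    rows = []
    for region in regions:
        cls, genes = classify_tss_proximity(region, tss, window=window)
        if cls == "promoter":
            gene, evidence = ",".join(genes), "promoter"
        else:
            link = link_enhancer_gene(region, loops, tss)
            gene = link.gene_id or ""
            evidence = link.evidence
        rows.append(
            {
                "region_id": region.id,
                "class": cls,
                "gene": gene,
                "evidence": evidence,
                "cell_type": assign_cell_type(region, celltype_sets),
            }
        )
    return pd.DataFrame(rows)
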