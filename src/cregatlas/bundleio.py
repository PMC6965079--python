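"""Serialize a simulated bundle to the standard on-disk formats."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from cregatlas import io
from cregatlas.simulate import SimulatedBundle

__all__ = ["write_bundle"]


def write_bundle(bundle: SimulatedBundle, out_dir) -> Path:
    """Write every simulated artifact under ``out_dir`` (plain text).

    Peaks, gap/repeat tracks and annotation sets go to BED; chain maps to
    UCSC chain files; counts, sample sheet, truth and the 4C profile to
    TSV; loops to BEDPE; conservation to bedGraph.
    """
    out = io.ensure_dir(out_dir)
    sim = bundle.config
    bundle.truth.to_csv(out / "truth.tsv", sep="\t", index=False, float_format="%.6g", lineterminator="\n")
    io.write_counts(out / "counts.tsv", bundle.counts)
    io.write_sample_sheet(out / "sample_sheet.tsv", bundle.design)
    bundle.truth[["region_id", "chrom", "start", "end"]].to_csv(
        out / "candidate_regions.tsv", sep="\t", index=False, lineterminator="\n"
    )

    peaks_dir = io.ensure_dir(out / "peaks")
    for (sp, tissue, rep), ps in sorted(bundle.peaks.items()):
        io.write_bed(peaks_dir / f"{sp}_{tissue}_{rep}.bed", ps.intervals)
    for sp, (unique, multi) in sorted(bundle.multimap_peaks.items()):
        io.write_bed(peaks_dir / f"{sp}_unique_merged.bed", unique.intervals)
        io.write_bed(peaks_dir / f"{sp}_multimap_merged.bed", multi.intervals)

    genomes_dir = io.ensure_dir(out / "genomes")
    sizes_rows = [
        {"species": sp, "chrom": c, "length": n}
        for sp, sizes in sorted(bundle.genomes.chrom_sizes.items())
        for c, n in sorted(sizes.items())
    ]
    pd.DataFrame(sizes_rows).to_csv(
        genomes_dir / "chrom_sizes.tsv", sep="\t", index=False, lineterminator="\n"
    )
    for sp, track in sorted(bundle.genomes.gap_tracks.items()):
        io.write_bed(genomes_dir / f"{sp}_gaps.bed", track)
    for sp, track in sorted(bundle.genomes.repeat_tracks.items()):
        io.write_bed(genomes_dir / f"{sp}_repeats.bed", track)
    for (src, tgt), cm in sorted(bundle.genomes.chains.items()):
        io.write_chain(genomes_dir / f"{src}_to_{tgt}.chain", cm)

    ann_dir = io.ensure_dir(out / "annotation")
    for label, ivs in sorted(bundle.annotations.celltype_sets.items()):
        io.write_bed(ann_dir / f"celltype_{label}.bed", ivs)
    io.write_bed(ann_dir / "asd_down.bed", bundle.annotations.asd_down)
    io.write_bed(ann_dir / "ad_down.bed", bundle.annotations.ad_down)
    io.write_bed6(ann_dir / "tss.bed", bundle.annotations.tss)
    io.write_bedpe(ann_dir / "loops.bedpe", bundle.annotations.loops)
    io.write_bedgraph(ann_dir / "conservation.bedgraph", bundle.annotations.conservation)
    io.write_bed(ann_dir / "open_chromatin_mask.bed", bundle.annotations.open_chromatin_mask)

    aln_path = out / "alignments.tsv"
    with open(aln_path, "wt", encoding="utf-8", newline="\n") as fh:
        fh.write("region_id\tspecies\tbases\n")
        for rid in sorted(bundle.alignments):
            cols = bundle.alignments[rid]
            for sp in sim.species:
                fh.write(f"{rid}\t{sp}\t{cols.bases[sp]}\n")

    prof = bundle.fourc
    fourc = pd.DataFrame(
        {"chrom": prof.chrom, "fragment_end_pos": prof.positions, "count": prof.counts}
    )
    fourc.to_csv(out / "fourc_fragments.tsv", sep="\t", index=False, float_format="%.6g", lineterminator="\n")
    with open(out / "fourc_viewpoint.txt", "wt", encoding="utf-8", newline="\n") as fh:
        fh.write(f"{prof.chrom}\t{prof.viewpoint}\n")
    return out
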