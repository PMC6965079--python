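"""End-to-end orchestration: simulate → peaks → atlas → DE → annotate →
enrichment → scores → 4C, with a run report and deterministic outputs.

The pipeline consumes a :class:`~cregatlas.simulate.SimulatedBundle`
(generated in memory from the config seed) and writes every stage
product as plain text under the output directory.  Re-running with an
identical config yields byte-identical files; a manifest of content
hashes is written alongside the report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from cregatlas import annotate, diffexp, enrich, io, seqscores
from cregatlas.atlas import build_atlas, detect_repetitive
from cregatlas.evaluate import match_regions_to_truth
from cregatlas.fourc import smooth_fragment_profile
from cregatlas.intervals import (
    GenomicInterval,
    PeakSet,
    extend_to_min_width,
    merge_stitch,
    reproducible_regions,
)
from cregatlas.simulate import SimulationConfig, SimulatedBundle, simulate_bundle

__all__ = ["RunConfig", "validate_config", "run_pipeline"]


@dataclass
class RunConfig:
    """All stage parameters plus the synthetic-source configuration."""

    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    out_dir: str = "results/run"
    min_width: int = 2000
    min_replicates: int = 2
    min_match: float = 0.1
    max_size_change: float = 0.5
    min_annotated: float = 0.9
    lfc_threshold: float = 1.0
    fdr: float = 0.01
    tss_window: int = 1000
    llm3d_alpha: float = 0.05
    covariate_alpha: float = 0.01
    fourc_window: int = 41
    lineages: tuple[str, ...] = ("hominin",)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulate"] = dataclasses.asdict(self.simulate)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        sim = d.pop("simulate", {})
        if not isinstance(sim, SimulationConfig):
            known = {f.name for f in dataclasses.fields(SimulationConfig)}
            sim_kwargs = {k: v for k, v in dict(sim).items() if k in known}
            for key in ("species", "tissues"):
                if key in sim_kwargs:
                    sim_kwargs[key] = tuple(sim_kwargs[key])
            sim = SimulationConfig(**sim_kwargs)
        known = {f.name for f in dataclasses.fields(cls)} - {"simulate"}
        kwargs = {k: v for k, v in d.items() if k in known}
        if "lineages" in kwargs:
            kwargs["lineages"] = tuple(kwargs["lineages"])
        return cls(simulate=sim, **kwargs)


def validate_config(config: RunConfig) -> list[str]:
    """Collect violations; an empty list means the config is runnable."""
    v = list(config.simulate.validate())
    for name, lo, hi in [
        ("min_match", 0.0, 1.0),
        ("max_size_change", 0.0, 10.0),
        ("min_annotated", 0.0, 1.0),
        ("fdr", 0.0, 1.0),
        ("llm3d_alpha", 0.0, 1.0),
        ("covariate_alpha", 0.0, 1.0),
    ]:
        x = getattr(config, name)
        if not (lo <= x <= hi):
            v.append(f"{name}={x} outside [{lo}, {hi}]")
    if config.min_width < 1:
        v.append("min_width must be positive")
    if config.min_replicates < 1:
        v.append("min_replicates must be positive")
    if config.fourc_window < 1 or config.fourc_window % 2 == 0:
        v.append("fourc_window must be a positive odd integer")
    for lin in config.lineages:
        if lin not in ("hominin", "human", "chimpanzee"):
            v.append(f"unknown lineage {lin!r}")
    return v


def _postprocess_peaks(bundle: SimulatedBundle, config: RunConfig) -> dict[str, PeakSet]:
    """Min-width extension, replicate reproducibility, tissue union."""
    sim = bundle.config
    nonredundant: dict[str, PeakSet] = {}
    for sp in sim.species:
        tissue_sets = []
        for tissue in sim.tissues:
            reps = []
            for r in range(1, sim.replicates_per_group + 1):
                ps = bundle.peaks[(sp, tissue, f"r{r}")]
                extended = [
                    extend_to_min_width(
                        iv, config.min_width, bundle.genomes.chrom_sizes[sp][iv.chrom]
                    )
                    for iv in ps.intervals
                ]
                reps.append(PeakSet(sp, tissue, ps.replicate, extended))
            tissue_sets.append(reproducible_regions(reps, config.min_replicates))
        pooled = [iv for ts in tissue_sets for iv in ts.intervals]
        merged = [
            dataclasses.replace(iv, id=f"{sp}_{k}")
            for k, (iv, _) in enumerate(
                merge_stitch([dataclasses.replace(iv, id=None) for iv in pooled])
            )
        ]
        nonredundant[sp] = PeakSet(sp, "union", "pooled", merged)
    return nonredundant


def _region_membership(
    atlas_regions: list[GenomicInterval], ann_intervals
) -> set[str]:
    from cregatlas.intervals import overlap_query

    return {rid for rid, _ in overlap_query(atlas_regions, list(ann_intervals))}


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the run report (also written as JSON)."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid RunConfig: " + "; ".join(problems))
    out = io.ensure_dir(config.out_dir)
    sim = config.simulate
    config_echo = config.to_dict()
    config_echo.pop("out_dir", None)  # keep the report location-independent
    report: dict = {"config": config_echo}
    report["config_hash"] = hashlib.sha256(
        json.dumps(report["config"], sort_keys=True).encode()
    ).hexdigest()

    bundle = simulate_bundle(sim)
    truth = bundle.truth

    # ---- peaks ----------------------------------------------------------
    nonredundant = _postprocess_peaks(bundle, config)
    report["peaks"] = {sp: len(ps) for sp, ps in nonredundant.items()}

    # ---- repeats and atlas ---------------------------------------------
    repeat_sets = {
        sp: detect_repetitive(*bundle.multimap_peaks[sp]) for sp in sim.species
    }
    atlas, ledger, input_ledger = build_atlas(
        nonredundant,
        bundle.genomes.chains,
        bundle.genomes.gap_tracks,
        repeat_sets,
        reference=sim.reference,
        min_match=config.min_match,
        max_size_change=config.max_size_change,
        min_annotated=config.min_annotated,
    )
    atlas.to_frame().to_csv(out / "atlas.tsv", sep="\t", index=False, lineterminator="\n")
    ledger.to_csv(out / "atlas_ledger.tsv", sep="\t", index=False, lineterminator="\n")
    input_ledger.to_csv(
        out / "atlas_input_ledger.tsv", sep="\t", index=False, lineterminator="\n"
    )
    discards = ledger["reason"].value_counts().to_dict()
    report["atlas"] = {
        "n_regions": len(atlas),
        "discards": {k: int(v) for k, v in sorted(discards.items())},
        "n_merged_input": len(atlas) + int(len(ledger)),
    }

    # ---- link atlas regions to the count matrix ------------------------
    ref_regions = [e.coords[sim.reference] for e in atlas.regions]
    link = match_regions_to_truth(ref_regions, truth, sim.reference)
    tested_ids = sorted(set(link.values()))
    counts = bundle.counts.loc[tested_ids]

    # ---- differential enrichment and consensus -------------------------
    comparisons_needed = set()
    for lineage in config.lineages:
        if lineage == "hominin":
            comparisons_needed.update(diffexp.HOMININ_COMPARISONS)
        elif lineage == "human":
            comparisons_needed.update(
                [("human", "chimp"), ("human", "macaque"), ("human", "marmoset")]
            )
        elif lineage == "chimpanzee":
            comparisons_needed.update(
                [("chimp", "human"), ("chimp", "macaque"), ("chimp", "marmoset")]
            )
    consensus_frames = []
    de_counts: dict[str, dict[str, int]] = {}
    excluded_total = 0
    for tissue in sim.tissues:
        comps = {}
        for pair in sorted(comparisons_needed):
            res = diffexp.run_comparison(
                counts,
                bundle.design,
                pair[0],
                pair[1],
                tissue,
                lfc_threshold=config.lfc_threshold,
                fdr=config.fdr,
            )
            comps[pair] = res
            de_counts.setdefault(tissue, {})[f"{pair[0]}_vs_{pair[1]}"] = int(
                res["significant"].sum()
            )
            excluded_total += int(res["excluded_zero"].sum())
            res.reset_index(names="region_id").to_csv(
                out / f"de_{tissue}_{pair[0]}_vs_{pair[1]}.tsv",
                sep="\t",
                index=False,
                lineterminator="\n",
            )
        for lineage in config.lineages:
            calls = diffexp.consensus_lineage_calls(comps, tissue, lineage)
            consensus_frames.append(calls)
    consensus = (
        pd.concat(consensus_frames, ignore_index=True)
        if consensus_frames
        else pd.DataFrame(columns=["region_id", "tissue", "lineage", "direction"])
    )
    consensus.to_csv(out / "consensus.tsv", sep="\t", index=False, lineterminator="\n")
    report["de"] = de_counts
    report["zero_excluded_total"] = excluded_total
    report["consensus"] = {
        f"{lin}_{t}_{d}": int(
            (
                (consensus["lineage"] == lin)
                & (consensus["tissue"] == t)
                & (consensus["direction"] == d)
            ).sum()
        )
        for lin in config.lineages
        for t in sim.tissues
        for d in ("gain", "loss")
    }

    # ---- annotation -----------------------------------------------------
    truth_regions = [
        GenomicInterval(sim.reference, row.chrom, row.start, row.end, id=row.region_id)
        for row in truth.itertuples(index=False)
        if row.region_id in set(tested_ids)
    ]
    ann = annotate.annotate_regions(
        truth_regions,
        bundle.annotations.tss,
        bundle.annotations.loops,
        bundle.annotations.celltype_sets,
        window=config.tss_window,
    )
    ann.to_csv(out / "annotation.tsv", sep="\t", index=False, lineterminator="\n")
    report["annotation"] = {
        "n_promoter": int((ann["class"] == "promoter").sum()),
        "n_enhancer": int((ann["class"] == "enhancer").sum()),
        "n_cell_type_specific": int((ann["cell_type"] != "not_specific").sum()),
    }

    # ---- disease / cell-type enrichment grid ---------------------------
    universe = set(tested_ids)
    asd_ids = _region_membership(truth_regions, bundle.annotations.asd_down)
    ad_ids = _region_membership(truth_regions, bundle.annotations.ad_down)
    grid_rows = []
    for lineage in config.lineages:
        for tissue in sim.tissues:
            for direction in ("gain", "loss"):
                called = set(
                    consensus.loc[
                        (consensus["lineage"] == lineage)
                        & (consensus["tissue"] == tissue)
                        & (consensus["direction"] == direction),
                        "region_id",
                    ]
                )
                for set_name, disease in (("asd_down", asd_ids), ("ad_down", ad_ids)):
                    if not called:
                        grid_rows.append(
                            {
                                "lineage": lineage,
                                "tissue": tissue,
                                "direction": direction,
                                "set": set_name,
                                "odds_ratio": float("nan"),
                                "p": float("nan"),
                            }
                        )
                        continue
                    odds, p, _ = enrich.fisher_enrichment(called, disease, universe)
                    grid_rows.append(
                        {
                            "lineage": lineage,
                            "tissue": tissue,
                            "direction": direction,
                            "set": set_name,
                            "odds_ratio": odds,
                            "p": p,
                        }
                    )
    grid = pd.DataFrame(grid_rows)
    ok = grid["p"].notna()
    grid["q"] = np.nan
    if ok.any():
        grid.loc[ok, "q"] = enrich.bh_adjust_matrix(grid.loc[ok, "p"].to_numpy())
    grid.to_csv(out / "enrichment_grid.tsv", sep="\t", index=False, lineterminator="\n")

    # ---- LLM3D interdependence (PFC gains x ASD x oligodendrocyte) -----
    pfc_gains = set(
        consensus.loc[
            (consensus["lineage"] == "hominin")
            & (consensus["tissue"] == "PFC")
            & (consensus["direction"] == "gain"),
            "region_id",
        ]
    )
    oligo_ids = set(ann.loc[ann["cell_type"] == "oligodendrocyte", "region_id"])
    tbl = np.zeros((2, 2, 2))
    for rid in universe:
        tbl[int(rid in pfc_gains), int(rid in asd_ids), int(rid in oligo_ids)] += 1
    llm = enrich.llm3d_fit(tbl, select_alpha=config.llm3d_alpha)
    llm.fits.to_csv(out / "llm3d.tsv", sep="\t", index=False, lineterminator="\n")
    report["llm3d"] = {
        "selected": llm.selected,
        "independence_p": llm.independence_p,
    }

    # ---- covariate variance partition on changed regions ---------------
    changed = sorted(set(consensus["region_id"]))
    if changed:
        widths = (
            truth.set_index("region_id").loc[changed, "end"]
            - truth.set_index("region_id").loc[changed, "start"]
        ).to_numpy()
        rpkm = enrich.rpkm_normalize(
            counts.loc[changed],
            widths,
            bundle.design["library_size"].to_numpy(),
        )
        cov = bundle.design[["species", "tissue", "batch", "library_size"]].copy()
        cov = cov.rename(columns={"library_size": "depth"})
        vp = enrich.covariate_variance_partition(
            rpkm,
            cov,
            order=["species", "tissue", "batch", "depth"],
            alpha=config.covariate_alpha,
            nuisance=("batch", "depth"),
        )
        vp.reset_index(names="region_id").to_csv(
            out / "variance_partition.tsv", sep="\t", index=False, lineterminator="\n"
        )
        report["covariates"] = {
            "n_changed": len(changed),
            "n_significant_nuisance": int(vp["significant"].sum()),
        }

    # ---- sequence scores ------------------------------------------------
    score_rows = []
    for row in truth.itertuples(index=False):
        if row.region_id not in universe:
            continue
        pct = seqscores.hominin_nucleotide_change_pct(bundle.alignments[row.region_id])
        iv = GenomicInterval(sim.reference, row.chrom, row.start, row.end, id=row.region_id)
        cons = seqscores.mean_conservation_masked(
            iv, bundle.annotations.conservation, bundle.annotations.open_chromatin_mask
        )
        score_rows.append(
            {
                "region_id": row.region_id,
                "pct_hominin_change": pct,
                "mean_conservation": cons,
            }
        )
    scores = pd.DataFrame(score_rows)
    scores.to_csv(out / "scores.tsv", sep="\t", index=False, float_format="%.6g", lineterminator="\n")
    gains_ids = set(
        consensus.loc[
            (consensus["lineage"] == "hominin") & (consensus["direction"] == "gain"),
            "region_id",
        ]
    )
    g = scores[scores["region_id"].isin(gains_ids)]["pct_hominin_change"].dropna()
    s = scores[~scores["region_id"].isin(set(consensus["region_id"]))][
        "pct_hominin_change"
    ].dropna()
    if len(g) >= 2 and len(s) >= 2:
        t, p = seqscores.compare_score_distributions(g.to_numpy(), s.to_numpy())
        report["scores"] = {
            "gain_mean_pct_change": float(g.mean()),
            "stable_mean_pct_change": float(s.mean()),
            "welch_t": t,
            "welch_p": p,
        }

    # ---- 4C --------------------------------------------------------------
    smoothed = smooth_fragment_profile(bundle.fourc, window=config.fourc_window)
    prof = bundle.fourc
    fourc_df = pd.DataFrame(
        {
            "chrom": prof.chrom,
            "start": prof.positions,
            "end": prof.positions + 1,
            "value": smoothed,
        }
    )
    io.write_bedgraph(out / "fourc_smoothed.bedgraph", fourc_df)
    report["fourc"] = {"n_fragment_ends": len(prof), "window": config.fourc_window}

    # ---- report and manifest --------------------------------------------
    with open(out / "report.json", "wt", encoding="utf-8", newline="\n") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest = {
        p.name: _hash_file(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name not in ("manifest.json", "run.log")
    }
    with open(out / "manifest.json", "wt", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
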