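"""Contracts of the synthetic-data generators: determinism, planted moments."""

import numpy as np
import pandas as pd
import pytest

from cregatlas.simulate import (
    SimulationConfig,
    make_design,
    make_truth,
    simulate_alignments,
    simulate_annotation_sets,
    simulate_bundle,
    simulate_counts,
    simulate_genomes,
)
from cregatlas.seqscores import hominin_nucleotide_change_pct


class TestConfig:
    def test_default_config_valid(self):
        assert SimulationConfig().validate() == []

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"planted_gain_fraction": 1.2},
            {"nb_dispersion": -0.1},
            {"species": ("a", "b")},
            {"replicates_per_group": 1},
        ],
    )
    def test_violations_reported(self, kwargs):
        assert SimulationConfig(**kwargs).validate() != []

    def test_oversubscribed_chromosome_is_sizing_error(self):
        cfg = SimulationConfig(n_regions=1000, n_chroms=1, chrom_length=100_000)
        with pytest.raises(ValueError):
            make_truth(cfg)


class TestDeterminism:
    def test_same_seed_identical_bundle(self, small_config):
        a = simulate_bundle(small_config)
        b = simulate_bundle(small_config)
        assert a.truth.equals(b.truth)
        assert a.counts.equals(b.counts)
        assert a.design.equals(b.design)
        for key in a.peaks:
            assert [(i.start, i.end) for i in a.peaks[key]] == [
                (i.start, i.end) for i in b.peaks[key]
            ]
        for pair in a.genomes.chains:
            for ca, cb in zip(a.genomes.chains[pair].chains, b.genomes.chains[pair].chains):
                assert np.array_equal(ca.src_starts, cb.src_starts)
                assert np.array_equal(ca.tgt_starts, cb.tgt_starts)
        assert np.array_equal(a.fourc.counts, b.fourc.counts)

    def test_different_seed_differs(self, small_config):
        import dataclasses

        other = dataclasses.replace(small_config, seed=small_config.seed + 1)
        assert not simulate_bundle(small_config).counts.equals(
            simulate_bundle(other).counts
        )


class TestTruth:
    def test_class_frequencies_within_three_binomial_sd(self):
        cfg = SimulationConfig(n_regions=4000, n_chroms=4, seed=5)
        truth = make_truth(cfg)
        n = len(truth)
        for cls, frac in [
            ("hominin_gain", cfg.planted_gain_fraction),
            ("hominin_loss", cfg.planted_loss_fraction),
            ("unmappable", cfg.unmappable_fraction),
            ("repeat_confounded", cfg.repeat_fraction),
        ]:
            got = (truth["true_class"] == cls).sum()
            sd = np.sqrt(n * frac * (1 - frac))
            assert abs(got - n * frac) <= 3 * sd, cls

    def test_exactly_one_class_per_region(self):
        truth = make_truth(SimulationConfig(seed=2))
        assert truth["region_id"].is_unique
        assert truth["true_class"].isin(
            ["stable", "hominin_gain", "hominin_loss", "human_gain", "chimp_gain",
             "repeat_confounded", "unmappable"]
        ).all()

    def test_planted_fold_change_on_hominin_branch(self):
        cfg = SimulationConfig(seed=3)
        truth = make_truth(cfg)
        gains = truth[truth["true_class"] == "hominin_gain"]
        assert np.allclose(gains["mean_human"] / gains["mean_macaque"], 4.0)
        assert np.allclose(gains["mean_chimp"] / gains["mean_marmoset"], 4.0)
        stable = truth[truth["true_class"] == "stable"]
        assert np.allclose(stable["mean_human"], stable["mean_marmoset"])


class TestCounts:
    def test_nb_variance_formula(self):
        """baseline 50, alpha 0.05: Var ~= 50 + 0.05*2500 = 175 within 10%."""
        cfg = SimulationConfig(
            n_regions=10, n_chroms=1, chrom_length=1_000_000, seed=6,
            baseline_mean=50.0, nb_dispersion=0.05,
        )
        truth = make_truth(cfg)
        truth.loc[:, [f"mean_{sp}" for sp in cfg.species]] = 50.0
        design = pd.DataFrame(
            {
                "sample_id": [f"s{k}" for k in range(10_000)],
                "species": ["human"] * 10_000,
                "tissue": ["CB"] * 10_000,
                "replicate": ["r1"] * 10_000,
                "batch": ["b1"] * 10_000,
                "library_size": [30_000_000] * 10_000,
            }
        )
        counts = simulate_counts(truth, design, cfg)
        v = counts.iloc[0].to_numpy().var()
        assert v == pytest.approx(175.0, rel=0.10)

    def test_poisson_limit(self):
        cfg = SimulationConfig(
            n_regions=10, n_chroms=1, chrom_length=1_000_000, seed=6,
            baseline_mean=50.0, nb_dispersion=0.0,
        )
        truth = make_truth(cfg)
        truth.loc[:, [f"mean_{sp}" for sp in cfg.species]] = 50.0
        design = pd.DataFrame(
            {
                "sample_id": [f"s{k}" for k in range(10_000)],
                "species": ["human"] * 10_000,
                "tissue": ["CB"] * 10_000,
                "replicate": ["r1"] * 10_000,
                "batch": ["b1"] * 10_000,
                "library_size": [30_000_000] * 10_000,
            }
        )
        counts = simulate_counts(truth, design, cfg)
        row = counts.iloc[0].to_numpy()
        assert row.var() == pytest.approx(row.mean(), rel=0.10)

    def test_no_planted_effect_means_unit_ratio(self):
        cfg = SimulationConfig(seed=7, planted_log2fc=0.0)
        truth = make_truth(cfg)
        design = make_design(cfg)
        counts = simulate_counts(truth, design, cfg)
        stable = truth[truth["true_class"] == "stable"]["region_id"]
        hu = counts.loc[stable, [c for c in counts if c.startswith("human")]].mean(axis=1)
        mm = counts.loc[stable, [c for c in counts if c.startswith("marmoset")]].mean(axis=1)
        ratio = (hu / mm).to_numpy()
        se = ratio.std() / np.sqrt(len(ratio))
        assert abs(ratio.mean() - 1.0) <= 3 * se + 0.02

    def test_unknown_species_in_design_rejected(self):
        cfg = SimulationConfig(seed=1)
        truth = make_truth(cfg)
        design = make_design(cfg)
        design.loc[0, "species"] = "gorilla"
        with pytest.raises(ValueError):
            simulate_counts(truth, design, cfg)


class TestGenomes:
    def test_gap_bases_near_binomial_expectation(self):
        cfg = SimulationConfig(
            n_regions=40, n_chroms=1, chrom_length=1_000_000, seed=9,
            gap_fraction=0.1,
        )
        genomes = simulate_genomes(cfg)
        for sp, track in genomes.gap_tracks.items():
            total = sum(iv.width for iv in track)
            expect = 0.1 * genomes.chrom_sizes[sp]["chr1"]
            sd = np.sqrt(expect * 0.9)
            assert abs(total - expect) <= 3 * sd, sp

    def test_repeat_confounded_regions_overlap_repeat_track(self):
        cfg = SimulationConfig(n_regions=400, n_chroms=1, chrom_length=4_000_000, seed=10)
        truth = make_truth(cfg)
        genomes = simulate_genomes(cfg, truth)
        planted = set(truth.loc[truth["true_class"] == "repeat_confounded", "region_id"])
        annotated = {
            iv.id.split(":")[0]
            for sp in cfg.species
            for iv in genomes.repeat_tracks[sp]
        }
        assert planted == annotated

    def test_unmappable_regions_lost_from_one_chain(self):
        from cregatlas.chains import liftover_interval

        cfg = SimulationConfig(n_regions=400, n_chroms=1, chrom_length=4_000_000, seed=10)
        truth = make_truth(cfg)
        genomes = simulate_genomes(cfg, truth)
        from cregatlas.intervals import GenomicInterval

        for row in truth[truth["true_class"] == "unmappable"].itertuples(index=False):
            region = GenomicInterval("human", row.chrom, row.start, row.end)
            fractions = [
                liftover_interval(region, genomes.chains[("human", sp)]).matched_fraction
                for sp in cfg.species[1:]
            ]
            assert min(fractions) == 0.0


class TestAlignments:
    def test_zero_rates_give_zero_percent(self):
        cfg = SimulationConfig(
            n_regions=50, n_chroms=1, chrom_length=1_000_000, seed=4,
            hominin_substitution_rate_gain=0.0,
            hominin_substitution_rate_background=0.0,
        )
        truth = make_truth(cfg)
        aln = simulate_alignments(truth, cfg)
        assert all(hominin_nucleotide_change_pct(a) == 0.0 for a in aln.values())

    def test_planted_rate_recovered(self):
        cfg = SimulationConfig(
            n_regions=200, n_chroms=1, chrom_length=3_000_000, seed=4,
            planted_gain_fraction=1.0, planted_loss_fraction=0.0,
            unmappable_fraction=0.0, repeat_fraction=0.0,
            hominin_substitution_rate_gain=0.02,
        )
        truth = make_truth(cfg)
        aln = simulate_alignments(truth, cfg)
        counts = [
            hominin_nucleotide_change_pct(aln[r.region_id]) / 100 * (r.end - r.start)
            for r in truth.itertuples(index=False)
        ]
        widths = (truth["end"] - truth["start"]).to_numpy()
        expect = 0.02 * widths.mean()
        sd = np.sqrt(widths.mean() * 0.02 * 0.98)
        assert abs(np.mean(counts) - expect) <= 3 * sd / np.sqrt(len(counts))

    def test_same_seed_identical(self, small_config):
        truth = make_truth(small_config)
        a = simulate_alignments(truth, small_config)
        b = simulate_alignments(truth, small_config)
        assert all(a[r].bases == b[r].bases for r in a)


class TestAnnotationSets:
    def test_planted_membership_fractions(self):
        cfg = SimulationConfig(n_regions=3000, n_chroms=3, seed=12)
        truth = make_truth(cfg)
        gains = truth["true_class"] == "hominin_gain"
        got_gain = (truth.loc[gains, "true_cell_type"] == "oligodendrocyte").mean()
        got_bg = (truth.loc[~gains, "true_cell_type"] == "oligodendrocyte").mean()
        assert got_gain == pytest.approx(cfg.oligo_fraction_in_gains, abs=0.12)
        assert got_bg == pytest.approx(cfg.oligo_fraction_background, abs=0.03)

    def test_degenerate_fractions_give_infinite_odds(self):
        from cregatlas.enrich import fisher_enrichment

        cfg = SimulationConfig(
            n_regions=500, n_chroms=1, chrom_length=5_000_000, seed=13,
            oligo_fraction_in_gains=1.0, oligo_fraction_background=0.0,
        )
        truth = make_truth(cfg)
        gains = set(truth.loc[truth["true_class"] == "hominin_gain", "region_id"])
        oligo = set(
            truth.loc[truth["true_cell_type"] == "oligodendrocyte", "region_id"]
        )
        odds, _, _ = fisher_enrichment(gains, oligo, set(truth["region_id"]))
        assert odds == float("inf")

    def test_conservation_planted_lower_at_gains(self):
        cfg = SimulationConfig(n_regions=500, n_chroms=1, chrom_length=5_000_000, seed=14)
        truth = make_truth(cfg)
        sets = simulate_annotation_sets(truth, cfg)
        cons = sets.conservation
        merged = cons.merge(
            truth[["region_id", "chrom", "start", "end", "true_class"]],
            left_on="chrom", right_on="chrom",
        )
        inside = merged[(merged["start_x"] >= merged["start_y"]) & (merged["end_x"] <= merged["end_y"])]
        by_class = inside.groupby("true_class")["value"].mean()
        assert by_class["hominin_gain"] < by_class["stable"]
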