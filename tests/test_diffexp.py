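"""NB differential-enrichment engine and the lineage consensus logic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cregatlas import diffexp
from cregatlas.simulate import (
    SimulationConfig,
    make_design,
    make_truth,
    simulate_counts,
)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self, rng):
        col = rng.integers(1, 100, 50)
        counts = np.column_stack([col, col, col])
        assert np.allclose(diffexp.size_factors(counts), 1.0)

    def test_hand_computed_median_of_ratios(self):
        counts = np.array([[10, 20], [20, 40], [30, 60]])
        f = diffexp.size_factors(counts)
        assert np.allclose(f, [1 / np.sqrt(2), np.sqrt(2)])

    def test_scale_equivariance_of_factor_ratios(self, rng):
        """Scaling one sample by c scales its factor by c relative to the
        others (the geometric-mean reference absorbs a common c^(1/m))."""
        counts = rng.integers(1, 200, (100, 4))
        f = diffexp.size_factors(counts)
        scaled = counts.astype(float).copy()
        scaled[:, 2] *= 5
        f2 = diffexp.size_factors(scaled)
        assert f2[2] / f2[0] == pytest.approx(5 * f[2] / f[0])
        assert f2[1] / f2[0] == pytest.approx(f[1] / f[0])

    def test_no_all_positive_region_is_an_error(self):
        with pytest.raises(ValueError):
            diffexp.size_factors(np.array([[0, 1], [1, 0]]))


class TestDispersions:
    def _groups(self):
        ga = np.array([True] * 3 + [False] * 3)
        return [ga, ~ga]

    def test_poisson_counts_give_near_zero_dispersion(self, rng):
        mu = 100 * rng.lognormal(0, 0.5, 2000)
        counts = rng.poisson(mu[:, None], (2000, 6))
        a = diffexp.estimate_dispersions(counts, np.ones(6), self._groups())
        assert np.median(a) <= 0.01

    def test_recovers_planted_dispersion(self, rng):
        alpha = 0.1
        size = 1 / alpha
        mu = 100 * rng.lognormal(0, 0.5, 2000)
        counts = rng.negative_binomial(size, size / (size + mu[:, None]), (2000, 6))
        a = diffexp.estimate_dispersions(counts, np.ones(6), self._groups())
        assert 0.05 <= np.median(a) <= 0.2

    def test_constant_counts_hit_floor(self):
        counts = np.full((20, 6), 50)
        a = diffexp.estimate_dispersions(counts, np.ones(6), self._groups())
        assert np.all(a <= 2 * diffexp.DISPERSION_FLOOR + 1e-12)


class TestWaldTest:
    def test_exact_fourfold_ratio(self):
        counts = np.array([[400, 400, 400, 100, 100, 100]] * 5)
        ga = np.array([True] * 3 + [False] * 3)
        res = diffexp.nb_wald_test(counts, np.ones(6), np.full(5, 0.05), ga, ~ga)
        assert np.allclose(res["beta"], 2.0, atol=0.05)

    def test_null_p_approximately_uniform(self, rng):
        """Identical groups: p is near-uniform.  At 3 vs 3 the Wald p
        carries a known mild anti-conservativeness from dispersion-
        estimation noise (ECDF within ~2-3% of uniform), so the check
        bounds the ECDF deviation and the tail rates rather than
        demanding exact uniformity a 5000-point KS would refute."""
        mu = 100 * rng.lognormal(0, 0.5, 5000)
        size = 1 / 0.05
        counts = rng.negative_binomial(size, size / (size + mu[:, None]), (5000, 6))
        ga = np.array([True] * 3 + [False] * 3)
        sf = diffexp.size_factors(counts)
        al = diffexp.estimate_dispersions(counts, sf, [ga, ~ga])
        res = diffexp.nb_wald_test(counts, sf, al, ga, ~ga)
        p = res["p"].to_numpy()
        assert np.abs(res["beta"].mean()) < 0.05
        assert stats.kstest(p, "uniform").statistic < 0.035
        assert np.mean(p < 0.05) < 0.075
        assert np.mean(p < 0.01) < 0.025

    def test_power_at_planted_effect(self, rng):
        mu_b = np.full(1000, 100.0)
        mu_a = mu_b * 4
        size = 1 / 0.05
        a = rng.negative_binomial(size, size / (size + mu_a[:, None]), (1000, 3))
        b = rng.negative_binomial(size, size / (size + mu_b[:, None]), (1000, 3))
        counts = np.hstack([a, b])
        ga = np.array([True] * 3 + [False] * 3)
        sf = np.ones(6)
        al = diffexp.estimate_dispersions(counts, sf, [ga, ~ga])
        res = diffexp.nb_wald_test(counts, sf, al, ga, ~ga)
        assert np.mean(res["p"] < 0.01) >= 0.9

    def test_zero_mean_group_handled_by_pseudo_mean(self):
        counts = np.array([[10, 12, 8, 0, 0, 0]])
        ga = np.array([True] * 3 + [False] * 3)
        res = diffexp.nb_wald_test(counts, np.ones(6), np.array([0.05]), ga, ~ga)
        assert np.isfinite(res["beta"]).all() and np.isfinite(res["p"]).all()


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert diffexp.bh_adjust(np.array([0.037]))[0] == pytest.approx(0.037)

    def test_hand_stepped_example(self):
        q = diffexp.bh_adjust(np.array([0.01, 0.02, 0.03]))
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_matches_definition_oracle(self, rng):
        for _ in range(200):
            p = rng.random(rng.integers(1, 50))
            m = p.size
            # direct definition: q_i = min over p_j >= p_i of p_j*m/rank_j
            order = np.argsort(p)
            ranks = np.empty(m, dtype=int)
            ranks[order] = np.arange(1, m + 1)
            brute = np.array(
                [min(min(p[j] * m / ranks[j] for j in range(m) if p[j] >= p[i]), 1.0)
                 for i in range(m)]
            )
            assert np.allclose(diffexp.bh_adjust(p), brute, atol=1e-12)

    def test_rejects_invalid_p(self):
        with pytest.raises(ValueError):
            diffexp.bh_adjust(np.array([0.5, 1.5]))


class TestZeroExclusion:
    def _sheet(self):
        return pd.DataFrame(
            {
                "sample_id": ["h1", "h2", "m1", "m2"],
                "species": ["human", "human", "marmoset", "marmoset"],
                "tissue": ["CB"] * 4,
                "replicate": ["r1", "r2", "r1", "r2"],
                "batch": ["b1", "b2", "b1", "b2"],
                "library_size": [1] * 4,
            }
        )

    def test_all_zero_in_one_species_excluded(self):
        counts = pd.DataFrame(
            {"h1": [10, 5], "h2": [8, 7], "m1": [0, 3], "m2": [0, 1]},
            index=["R0", "R1"],
        )
        mask = diffexp.zero_exclusion(counts, self._sheet(), "human", "marmoset", "CB")
        assert list(mask) == [True, False]

    def test_one_nonzero_replicate_retains(self):
        counts = pd.DataFrame(
            {"h1": [0], "h2": [1], "m1": [0], "m2": [2]}, index=["R0"]
        )
        mask = diffexp.zero_exclusion(counts, self._sheet(), "human", "marmoset", "CB")
        assert not mask[0]

    def test_matches_brute_force_scan(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 3, (200, 4)), columns=["h1", "h2", "m1", "m2"]
        )
        mask = diffexp.zero_exclusion(counts, self._sheet(), "human", "marmoset", "CB")
        brute = [
            (row[["h1", "h2"]] == 0).all() or (row[["m1", "m2"]] == 0).all()
            for _, row in counts.iterrows()
        ]
        assert list(mask) == brute


class TestCallDE:
    @pytest.mark.parametrize(
        "beta,q,expect_sig,expect_dir",
        [
            (1.5, 0.005, True, "up"),
            (0.9, 1e-6, False, ""),  # fold change short
            (-2.0, 0.02, False, ""),  # FDR short
            (-1.2, 0.001, True, "down"),
        ],
    )
    def test_threshold_logic(self, beta, q, expect_sig, expect_dir):
        df = pd.DataFrame({"beta": [beta], "q": [q]})
        out = diffexp.call_de(df)
        assert bool(out["significant"][0]) is expect_sig
        assert out["direction"][0] == expect_dir


class TestConsensus:
    def _comps(self, directions, excluded=False):
        """Build four comparison frames for one region with given directions."""
        comps = {}
        for pair, d in zip(diffexp.HOMININ_COMPARISONS, directions):
            comps[pair] = pd.DataFrame(
                {
                    "beta": [2.0 if d == "up" else -2.0 if d == "down" else 0.0],
                    "q": [0.001 if d else 0.5],
                    "significant": [bool(d)],
                    "direction": [d],
                    "excluded_zero": [excluded],
                },
                index=["R0"],
            )
        return comps

    def test_up_in_all_four_is_gain(self):
        calls = diffexp.consensus_lineage_calls(self._comps(["up"] * 4), "CB")
        assert list(calls["direction"]) == ["gain"]

    def test_human_legs_only_is_no_hominin_call(self):
        calls = diffexp.consensus_lineage_calls(
            self._comps(["up", "up", "", ""]), "CB"
        )
        assert len(calls) == 0

    def test_direction_conflict_yields_no_call(self):
        calls = diffexp.consensus_lineage_calls(
            self._comps(["up", "down", "up", "up"]), "CB"
        )
        assert len(calls) == 0

    def test_excluded_region_not_callable(self):
        calls = diffexp.consensus_lineage_calls(
            self._comps(["up"] * 4, excluded=True), "CB"
        )
        assert len(calls) == 0

    def test_missing_comparison_is_configuration_error(self):
        comps = self._comps(["up"] * 4)
        del comps[("chimp", "marmoset")]
        with pytest.raises(ValueError):
            diffexp.consensus_lineage_calls(comps, "CB")


class TestPipelineInvariances:
    def _run(self, counts, design, tissue="CB"):
        comps = {
            p: diffexp.run_comparison(counts, design, p[0], p[1], tissue)
            for p in diffexp.HOMININ_COMPARISONS
        }
        return diffexp.consensus_lineage_calls(comps, tissue)

    def test_sample_permutation_leaves_calls_unchanged(self):
        cfg = SimulationConfig(n_regions=300, n_chroms=1, chrom_length=3_000_000, seed=21)
        truth = make_truth(cfg)
        design = make_design(cfg)
        counts = simulate_counts(truth, design, cfg)
        calls1 = self._run(counts, design)
        perm = np.random.default_rng(0).permutation(len(design))
        design2 = design.iloc[perm].reset_index(drop=True)
        counts2 = counts[design2["sample_id"].tolist()]
        calls2 = self._run(counts2, design2)
        assert sorted(zip(calls1["region_id"], calls1["direction"])) == sorted(
            zip(calls2["region_id"], calls2["direction"])
        )

    def test_doubling_all_counts_leaves_calls_unchanged(self):
        cfg = SimulationConfig(n_regions=300, n_chroms=1, chrom_length=3_000_000, seed=22)
        truth = make_truth(cfg)
        design = make_design(cfg)
        counts = simulate_counts(truth, design, cfg)
        calls1 = self._run(counts, design)
        calls2 = self._run(counts * 2, design)
        assert sorted(zip(calls1["region_id"], calls1["direction"])) == sorted(
            zip(calls2["region_id"], calls2["direction"])
        )

    def test_consensus_anti_monotone_in_thresholds(self):
        cfg = SimulationConfig(n_regions=300, n_chroms=1, chrom_length=3_000_000, seed=23)
        truth = make_truth(cfg)
        design = make_design(cfg)
        counts = simulate_counts(truth, design, cfg)

        def run(lfc, fdr):
            comps = {
                p: diffexp.run_comparison(counts, design, p[0], p[1], "CB",
                                          lfc_threshold=lfc, fdr=fdr)
                for p in diffexp.HOMININ_COMPARISONS
            }
            calls = diffexp.consensus_lineage_calls(comps, "CB")
            return set(zip(calls["region_id"], calls["direction"]))

        base = run(1.0, 0.01)
        assert run(1.5, 0.01) <= base
        assert run(1.0, 0.001) <= base
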