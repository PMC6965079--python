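"""Fisher enrichment, log-linear interdependence, variance partition."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cregatlas.enrich import (
    bh_adjust_matrix,
    covariate_variance_partition,
    fisher_enrichment,
    fisher_test_2x2,
    llm3d_fit,
    rpkm_normalize,
)


def exact_fisher_p(a, b, c, d):
    """Two-sided p by exact integer arithmetic (independent of scipy)."""
    N, K, n = a + b + c + d, a + b, a + c
    kmin, kmax = max(0, n - (N - K)), min(K, n)
    obs = comb(K, a) * comb(N - K, n - a)
    total = sum(
        comb(K, k) * comb(N - K, n - k)
        for k in range(kmin, kmax + 1)
        if comb(K, k) * comb(N - K, n - k) <= obs
    )
    return total / comb(N, n)


class TestFisher:
    def test_odds_ratio_arithmetic(self):
        odds, p = fisher_test_2x2(5, 5, 5, 85)
        assert odds == pytest.approx(17.0)

    def test_zero_cell_gives_infinite_odds(self):
        odds, _ = fisher_test_2x2(5, 0, 5, 85)
        assert odds == float("inf")

    def test_symmetric_under_set_swap(self, rng):
        universe = set(range(200))
        a = set(rng.choice(200, 40, replace=False).tolist())
        b = set(rng.choice(200, 60, replace=False).tolist())
        _, p1, _ = fisher_enrichment(a, b, universe)
        _, p2, _ = fisher_enrichment(b, a, universe)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_matches_exact_oracle_small_tables(self, rng):
        for _ in range(400):
            a, b, c, d = rng.integers(0, 15, 4)
            if a + b + c + d == 0:
                continue
            _, p = fisher_test_2x2(int(a), int(b), int(c), int(d))
            assert p == pytest.approx(exact_fisher_p(int(a), int(b), int(c), int(d)),
                                      abs=1e-10)

    def test_null_calibration(self, rng):
        pvals = []
        universe = set(range(400))
        for _ in range(200):
            a = set(rng.choice(400, 80, replace=False).tolist())
            b = set(rng.choice(400, 80, replace=False).tolist())
            _, p, _ = fisher_enrichment(a, b, universe)
            pvals.append(p)
        # discrete p-values are conservative; check no excess of small ones
        assert np.mean(np.array(pvals) < 0.05) <= 0.08

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment(set(), set(), set())


class TestBHMatrix:
    def test_preserves_shape_and_delegates(self):
        p = np.array([[0.01, 0.02], [0.03, 0.5]])
        q = bh_adjust_matrix(p)
        assert q.shape == p.shape
        assert q[0, 0] == pytest.approx(0.04)


class TestLLM3D:
    def test_product_table_selects_complete_independence(self):
        px, py, pz = np.array([0.3, 0.7]), np.array([0.4, 0.6]), np.array([0.2, 0.8])
        table = 1000 * np.einsum("i,j,k->ijk", px, py, pz)
        fit = llm3d_fit(table)
        assert fit.selected == "[X][Y][Z]"
        indep = fit.fits[fit.fits["model"] == "[X][Y][Z]"]
        assert indep["gsq"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_saturated_deviance_always_zero(self, rng):
        for _ in range(50):
            tbl = rng.integers(0, 50, (2, 2, 2))
            if tbl.sum() == 0:
                continue
            fit = llm3d_fit(tbl)
            sat = fit.fits[fit.fits["model"] == "[XYZ]"]
            assert sat["gsq"].iloc[0] == 0.0

    def test_ipf_reproduces_all_two_way_margins(self, rng):
        for _ in range(50):
            tbl = rng.integers(1, 60, (2, 2, 2)).astype(float)
            fit = llm3d_fit(tbl)
            e = fit.expected("[XY][XZ][YZ]", tbl)
            assert np.abs(e.sum(axis=2) - tbl.sum(axis=2)).max() < 1e-10
            assert np.abs(e.sum(axis=1) - tbl.sum(axis=1)).max() < 1e-10
            assert np.abs(e.sum(axis=0) - tbl.sum(axis=0)).max() < 1e-10

    def test_deviance_monotone_in_model_complexity(self, rng):
        """Nested models: G2 never increases as interaction terms are added."""
        chains = [
            ["[X][Y][Z]", "[XY][Z]", "[XY][XZ]", "[XY][XZ][YZ]", "[XYZ]"],
            ["[X][Y][Z]", "[YZ][X]", "[XZ][YZ]", "[XY][XZ][YZ]", "[XYZ]"],
        ]
        for _ in range(25):
            tbl = rng.integers(1, 80, (2, 2, 2))
            fit = llm3d_fit(tbl)
            g = dict(zip(fit.fits["model"], fit.fits["gsq"]))
            for chain in chains:
                seq = [g[m] for m in chain]
                assert all(x >= y - 1e-9 for x, y in zip(seq, seq[1:]))

    def test_calibration_under_independence(self, rng):
        """Null rejection rate of the independence test near nominal 5%."""
        rej = 0
        reps = 2000
        px, py, pz = 0.3, 0.5, 0.2
        probs = np.einsum(
            "i,j,k->ijk",
            np.array([px, 1 - px]),
            np.array([py, 1 - py]),
            np.array([pz, 1 - pz]),
        ).ravel()
        for _ in range(reps):
            tbl = rng.multinomial(1000, probs).reshape(2, 2, 2)
            if llm3d_fit(tbl).independence_p < 0.05:
                rej += 1
        assert 0.03 <= rej / reps <= 0.07

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            llm3d_fit(np.zeros((2, 2, 2)))
        with pytest.raises(ValueError):
            llm3d_fit(np.ones((2, 2)))


class TestVariancePartition:
    def _covariates(self, n, rng):
        return pd.DataFrame(
            {
                "species": np.repeat(["h", "c", "m", "j"], n // 4),
                "batch": np.tile(["b1", "b2", "b3"], n // 3),
                "depth": rng.normal(30, 3, n),
            }
        )

    def test_enrichment_equal_to_covariate_explains_everything(self, rng):
        n = 24
        cov = self._covariates(n, rng)
        y = cov["depth"].to_numpy()[None, :].repeat(3, axis=0)
        enr = pd.DataFrame(y, index=[f"R{k}" for k in range(3)])
        out = covariate_variance_partition(enr, cov, order=["depth", "batch"],
                                           nuisance=("depth",))
        assert np.allclose(out["depth_frac"], 1.0)
        assert (out["depth_p"] < 1e-10).all()
        assert out["significant"].all()

    def test_null_fraction_and_p_calibration(self, rng):
        n = 24
        cov = self._covariates(n, rng)
        enr = pd.DataFrame(rng.normal(0, 1, (400, n)))
        out = covariate_variance_partition(enr, cov, order=["depth"], nuisance=())
        # one orthogonal regressor explains ~1/(n-1) of variance on average
        assert out["depth_frac"].mean() == pytest.approx(1 / (n - 1), rel=0.35)
        assert stats.kstest(out["depth_p"].to_numpy(), "uniform").pvalue > 0.01

    def test_sequential_ss_matches_projection_oracle(self, rng):
        n = 18
        cov = pd.DataFrame(
            {
                "g": np.repeat(["a", "b", "c"], 6),
                "x": rng.normal(size=n),
            }
        )
        enr = pd.DataFrame(rng.normal(size=(5, n)))
        out = covariate_variance_partition(enr, cov, order=["g", "x"], nuisance=())
        # oracle: residual-SS drops from nested OLS fits via lstsq
        X0 = np.ones((n, 1))
        Xg = np.column_stack([X0, (cov["g"] == "b").astype(float), (cov["g"] == "c").astype(float)])
        Xgx = np.column_stack([Xg, cov["x"].to_numpy()])
        for i in range(5):
            y = enr.iloc[i].to_numpy()
            rss = []
            for X in (X0, Xg, Xgx):
                beta, *_ = np.linalg.lstsq(X, y, rcond=None)
                rss.append(np.sum((y - X @ beta) ** 2))
            total = np.sum((y - y.mean()) ** 2)
            assert out["g_frac"].iloc[i] == pytest.approx((rss[0] - rss[1]) / total, abs=1e-8)
            assert out["x_frac"].iloc[i] == pytest.approx((rss[1] - rss[2]) / total, abs=1e-8)

    def test_fractions_sum_to_one(self, rng):
        n = 24
        cov = self._covariates(n, rng)
        enr = pd.DataFrame(rng.normal(0, 1, (50, n)))
        out = covariate_variance_partition(enr, cov, order=["species", "batch", "depth"])
        frac_cols = [c for c in out.columns if c.endswith("_frac")]
        assert np.allclose(out[frac_cols].sum(axis=1), 1.0, atol=1e-10)

    def test_aliased_covariate_dropped_and_recorded(self, rng):
        n = 24
        cov = self._covariates(n, rng)
        cov["species_copy"] = cov["species"]
        enr = pd.DataFrame(rng.normal(0, 1, (5, n)))
        out = covariate_variance_partition(
            enr, cov, order=["species", "species_copy", "depth"]
        )
        assert "species_copy" in out.attrs["aliased"]
        assert np.allclose(out["species_copy_frac"], 0.0)


def test_rpkm_normalization_units():
    counts = pd.DataFrame({"s1": [1000], "s2": [1000]}, index=["R0"])
    # 2 kb region, 10M and 20M reads: 1000/(2*10) = 50 and 25
    out = rpkm_normalize(counts, np.array([2000]), np.array([10_000_000, 20_000_000]))
    assert out.loc["R0", "s1"] == pytest.approx(50.0)
    assert out.loc["R0", "s2"] == pytest.approx(25.0)
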