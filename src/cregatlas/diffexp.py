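"""Negative-binomial differential enrichment and the lineage consensus.

A simplified DESeq2-style engine: median-of-ratios size factors,
method-of-moments dispersions shrunk toward a fitted mean–dispersion
trend, and a Wald test on the log2 ratio of normalized group means.
Lineage-specific activity changes are then defined by consensus over
pairwise species comparisons: a hominin gain is a region significantly
up (|log2FC| >= 1, BH-FDR < 0.01) in human-vs-macaque, human-vs-marmoset,
chimp-vs-macaque and chimp-vs-marmoset alike; losses are the mirror
image, and species-specific calls require consistency against all three
other species.  Regions with all-zero counts in either species of a
comparison are excluded from that comparison only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "size_factors",
    "estimate_dispersions",
    "nb_wald_test",
    "bh_adjust",
    "zero_exclusion",
    "call_de",
    "run_comparison",
    "consensus_lineage_calls",
    "HOMININ_COMPARISONS",
]

DISPERSION_FLOOR = 1e-8

#: the four pairwise comparisons defining hominin-specific changes,
#: each oriented hominin-over-monkey so "up" means a hominin gain
HOMININ_COMPARISONS = [
    ("human", "macaque"),
    ("human", "marmoset"),
    ("chimp", "macaque"),
    ("chimp", "marmoset"),
]


def size_factors(counts: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Median-of-ratios size factors (one per sample column).

    factor_j = median over all-positive regions of count_ij / geomean_i.
    """
    arr = np.asarray(counts, dtype=float)
    pos = np.all(arr > 0, axis=1)
    if not np.any(pos):
        raise ValueError("no region with all-positive counts; cannot normalize")
    logs = np.log(arr[pos])
    log_geomean = logs.mean(axis=1, keepdims=True)
    return np.exp(np.median(logs - log_geomean, axis=0))


def _trend_fit(mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Fit alpha(mu) = a0 + a1/mu by least squares on usable estimates."""
    ok = (mu > 0) & (alpha > 0)
    if ok.sum() < 10:
        return np.full_like(mu, max(float(np.median(alpha[ok])) if ok.any() else 0.01, DISPERSION_FLOOR))
    X = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
    coef, *_ = np.linalg.lstsq(X, alpha[ok], rcond=None)
    a0, a1 = coef
    trend = a0 + a1 / np.maximum(mu, 1e-8)
    return np.maximum(trend, DISPERSION_FLOOR)


def estimate_dispersions(
    counts: np.ndarray,
    factors: np.ndarray,
    groups: Sequence[np.ndarray],
) -> np.ndarray:
    """Per-region NB dispersion (variance = mu + alpha mu^2).

    Method-of-moments within each design group on normalized counts,
    pooled with df weights, then shrunk 50/50 toward the fitted trend
    alpha(mu) = a0 + a1/mu and floored at 1e-8.
    """
    arr = np.asarray(counts, dtype=float) / np.asarray(factors)[None, :]
    num = np.zeros(arr.shape[0])
    den = 0.0
    mu_all = arr.mean(axis=1)
    var_sum = np.zeros(arr.shape[0])
    for g in groups:
        sub = arr[:, g]
        n = sub.shape[1]
        if n < 2:
            continue
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(m > 0, (v - m) / np.maximum(m, 1e-12) ** 2, 0.0)
        num += (n - 1) * a
        den += n - 1
        var_sum += v
    if den == 0:
        raise ValueError("need at least two samples in some group")
    raw = num / den
    trend = _trend_fit(mu_all, raw)
    shrunk = 0.5 * np.maximum(raw, 0.0) + 0.5 * trend
    shrunk[var_sum == 0] = DISPERSION_FLOOR  # degenerate all-equal counts
    return np.maximum(shrunk, DISPERSION_FLOOR)


def nb_wald_test(
    counts: np.ndarray,
    factors: np.ndarray,
    alpha: np.ndarray,
    group_a: np.ndarray,
    group_b: np.ndarray,
) -> pd.DataFrame:
    """Two-group NB Wald test on the log2 ratio of normalized means.

    beta = log2(mean_A / mean_B) of size-factor-normalized counts, with a
    0.5 pseudo-mean added to both group means when either is zero;
    Var(ln mean_g) is taken from the NB variance of normalized counts,
    Var(K_ij/s_j) = mu/s_j + alpha mu^2, giving
    Var(ln) = (sum_j 1/s_j)/(n_g^2 mu) + alpha/n_g.  p is two-sided normal.
    """
    arr = np.asarray(counts, dtype=float)
    factors = np.asarray(factors, dtype=float)
    norm = arr / factors[None, :]
    res = {}
    for label, g in (("a", group_a), ("b", group_b)):
        sub = norm[:, g]
        n = sub.shape[1]
        if n == 0:
            raise ValueError("both groups must be non-empty")
        m = sub.mean(axis=1)
        inv_s = float(np.sum(1.0 / factors[g]))
        res[label] = (m, n, inv_s)
    m_a, n_a, inv_a = res["a"]
    m_b, n_b, inv_b = res["b"]
    zero = (m_a == 0) | (m_b == 0)
    m_a_eff = np.where(zero, m_a + 0.5, m_a)
    m_b_eff = np.where(zero, m_b + 0.5, m_b)
    beta = np.log2(m_a_eff / m_b_eff)
    var_ln_a = inv_a / (n_a**2 * np.maximum(m_a_eff, 0.5)) + alpha / n_a
    var_ln_b = inv_b / (n_b**2 * np.maximum(m_b_eff, 0.5)) + alpha / n_b
    se_ln = np.sqrt(var_ln_a + var_ln_b)
    z = beta * np.log(2) / se_ln
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "beta": beta,
            "se": se_ln / np.log(2),
            "stat": z,
            "p": p,
            "mean_a": m_a,
            "mean_b": m_b,
        }
    )


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def zero_exclusion(
    counts: pd.DataFrame,
    sheet: pd.DataFrame,
    species_a: str,
    species_b: str,
    tissue: str | None = None,
) -> np.ndarray:
    """Mask of regions with all-zero replicates in either species.

    Exclusion is per-comparison: a region all-zero in every replicate of
    one species of the pair (within the tissue under test) is dropped
    from that comparison only.
    """
    mask = np.zeros(len(counts), dtype=bool)
    for sp in (species_a, species_b):
        sel = sheet["species"] == sp
        if tissue is not None:
            sel &= sheet["tissue"] == tissue
        cols = sheet.loc[sel, "sample_id"].tolist()
        if not cols:
            raise ValueError(f"no samples for species {sp!r} tissue {tissue!r}")
        mask |= (counts[cols].to_numpy() == 0).all(axis=1)
    return mask


def call_de(results: pd.DataFrame, lfc_threshold: float = 1.0, fdr: float = 0.01) -> pd.DataFrame:
    """Flag significant regions: |log2FC| >= threshold and q < fdr."""
    out = results.copy()
    out["significant"] = (np.abs(out["beta"]) >= lfc_threshold) & (out["q"] < fdr)
    out["direction"] = np.where(out["beta"] > 0, "up", "down")
    out.loc[~out["significant"], "direction"] = ""
    return out


def run_comparison(
    counts: pd.DataFrame,
    sheet: pd.DataFrame,
    species_a: str,
    species_b: str,
    tissue: str,
    lfc_threshold: float = 1.0,
    fdr: float = 0.01,
) -> pd.DataFrame:
    """One pairwise species comparison within a tissue, end to end.

    Subsets the samples, applies the per-comparison zero exclusion,
    normalizes, estimates dispersions, runs the Wald test and adjusts
    with BH within the comparison.  Excluded regions carry no p/q.
    """
    sel = (sheet["species"].isin([species_a, species_b])) & (sheet["tissue"] == tissue)
    sub_sheet = sheet.loc[sel]
    cols = sub_sheet["sample_id"].tolist()
    sub = counts[cols]
    excluded = zero_exclusion(counts, sheet, species_a, species_b, tissue)
    arr = sub.to_numpy()
    tested = ~excluded
    factors = size_factors(arr[tested])
    ga = (sub_sheet["species"] == species_a).to_numpy()
    gb = (sub_sheet["species"] == species_b).to_numpy()
    alpha = estimate_dispersions(arr[tested], factors, [ga, gb])
    wald = nb_wald_test(arr[tested], factors, alpha, ga, gb)
    out = pd.DataFrame(
        index=counts.index,
        columns=["beta", "se", "p", "q", "excluded_zero"],
        dtype=float,
    )
    out["excluded_zero"] = excluded
    out.loc[tested, ["beta", "se", "p"]] = wald[["beta", "se", "p"]].to_numpy()
    out.loc[tested, "q"] = bh_adjust(wald["p"].to_numpy())
    out = call_de(out, lfc_threshold=lfc_threshold, fdr=fdr)
    out.loc[excluded, "significant"] = False
    out.attrs["comparison"] = (species_a, species_b, tissue)
    return out


@dataclass(frozen=True)
class ConsensusCall:
    region_id: str
    tissue: str
    lineage: str  # hominin | human | chimpanzee
    direction: str  # gain | loss


def _consistent(per_comp: list[pd.Series]) -> pd.Series:
    """'gain'/'loss' where every comparison is significant the same way."""
    sig = per_comp[0].copy()
    up = per_comp[0] == "up"
    down = per_comp[0] == "down"
    for s in per_comp[1:]:
        up &= s == "up"
        down &= s == "down"
    out = pd.Series("", index=sig.index)
    out[up] = "gain"
    out[down] = "loss"
    return out


def consensus_lineage_calls(
    comparisons: Mapping[tuple[str, str], pd.DataFrame],
    tissue: str,
    lineage: str = "hominin",
) -> pd.DataFrame:
    """Combine pairwise DE results into lineage-specific calls.

    For ``lineage='hominin'`` the four comparisons human/chimp vs
    macaque/marmoset must all be significant with one direction; for
    ``'human'`` (or ``'chimpanzee'``) the three comparisons of that
    species against all others must agree.  Direction conflicts yield no
    call.  Regions zero-excluded from any required comparison are not
    callable.
    """
    if lineage == "hominin":
        required = HOMININ_COMPARISONS
    elif lineage == "human":
        required = [("human", "chimp"), ("human", "macaque"), ("human", "marmoset")]
    elif lineage == "chimpanzee":
        required = [("chimp", "human"), ("chimp", "macaque"), ("chimp", "marmoset")]
    else:
        raise ValueError(f"unknown lineage {lineage!r}")
    missing = [pair for pair in required if pair not in comparisons]
    if missing:
        raise ValueError(f"missing comparisons for lineage {lineage!r}: {missing}")
    dirs = []
    excluded = None
    for pair in required:
        df = comparisons[pair]
        d = df["direction"].where(df["significant"], "")
        dirs.append(d)
        e = df["excluded_zero"].astype(bool)
        excluded = e if excluded is None else (excluded | e)
    verdict = _consistent(dirs)
    verdict[excluded] = ""
    called = verdict[verdict != ""]
    return pd.DataFrame(
        {
            "region_id": called.index,
            "tissue": tissue,
            "lineage": lineage,
            "direction": called.values,
        }
    ).reset_index(drop=True)
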