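"""Region-set enrichment, log-linear interdependence, variance partition.

Three statistical tools over the atlas annotations:

* :func:`fisher_enrichment` — two-sided Fisher's exact test on the 2x2
  membership table of two region sets within a stated universe, with the
  odds ratio ``ad/bc``.
* :func:`llm3d_fit` — the log-linear model hierarchy over a 2x2x2
  contingency table of binary region annotations (e.g. hominin gain x
  ASD-deregulated x oligodendrocyte-specific), fitted by closed-form
  maximum likelihood for decomposable models and iterative proportional
  fitting for homogeneous association; interdependence is judged against
  the complete-independence null.
* :func:`covariate_variance_partition` — per-region sequential (Type I)
  ANOVA on rpkm-normalized enrichment against declared biological and
  technical covariates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "fisher_test_2x2",
    "fisher_enrichment",
    "bh_adjust_matrix",
    "LLM3DFit",
    "llm3d_fit",
    "rpkm_normalize",
    "covariate_variance_partition",
]

# relative tie tolerance of the "at least as extreme" two-sided rule,
# matching the convention of standard exact-test implementations
_FISHER_TIE_EPS = 1e-7


def _hypergeom_pmf_all(N: int, K: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """pmf of the hypergeometric(N, K, n) over its whole support."""
    k_min = max(0, n - (N - K))
    k_max = min(K, n)
    ks = np.arange(k_min, k_max + 1)
    pmf = stats.hypergeom.pmf(ks, N, K, n)
    return ks, pmf


def fisher_test_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test on ``[[a, b], [c, d]]``.

    Returns ``(odds_ratio, p)`` with OR = ad/bc (inf when bc = 0 and
    ad > 0, nan for the empty 0/0 case).  The p-value sums the
    hypergeometric probabilities of all tables, with the observed row and
    column margins, no more probable than the observed one.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("table counts must be non-negative integers")
    N = a + b + c + d
    if N == 0:
        raise ValueError("empty table")
    if b * c == 0:
        odds = float("nan") if a * d == 0 else float("inf")
    else:
        odds = (a * d) / (b * c)
    K, n = a + b, a + c
    ks, pmf = _hypergeom_pmf_all(N, K, n)
    p_obs = pmf[ks == a][0]
    p = float(pmf[pmf <= p_obs * (1.0 + _FISHER_TIE_EPS)].sum())
    return odds, min(p, 1.0)


def fisher_enrichment(
    set_a: set, set_b: set, universe: set
) -> tuple[float, float, tuple[int, int, int, int]]:
    """Enrichment of ``set_a`` within ``set_b`` relative to ``universe``.

    Builds the membership table a = |A∩B|, b = |A\\B|, c = |B\\A|,
    d = |universe \\ (A∪B)| and applies the two-sided Fisher test.
    """
    if not universe:
        raise ValueError("empty universe")
    if not (set_a <= universe and set_b <= universe):
        raise ValueError("sets must be subsets of the universe")
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    d = len(universe) - a - b - c
    odds, p = fisher_test_2x2(a, b, c, d)
    return odds, p, (a, b, c, d)


def bh_adjust_matrix(pvals: np.ndarray) -> np.ndarray:
    """BH step-up over a grid of p-values, preserving the grid shape."""
    from cregatlas.diffexp import bh_adjust

    p = np.asarray(pvals, dtype=float)
    return bh_adjust(p.ravel()).reshape(p.shape)


# ---------------------------------------------------------------------------
# log-linear models on 2x2x2 tables
# ---------------------------------------------------------------------------

#: the fitted hierarchy, simplest first; df = 7 - free parameters
_MODELS = [
    ("[X][Y][Z]", 4),
    ("[XY][Z]", 3),
    ("[XZ][Y]", 3),
    ("[YZ][X]", 3),
    ("[XY][XZ]", 2),
    ("[XY][YZ]", 2),
    ("[XZ][YZ]", 2),
    ("[XY][XZ][YZ]", 1),
    ("[XYZ]", 0),
]


def _expected(model: str, obs: np.ndarray) -> np.ndarray:
    """MLE expected counts under ``model`` for a 2x2x2 observed table."""
    N = obs.sum()
    nx = obs.sum(axis=(1, 2))
    ny = obs.sum(axis=(0, 2))
    nz = obs.sum(axis=(0, 1))
    nxy = obs.sum(axis=2)
    nxz = obs.sum(axis=1)
    nyz = obs.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        if model == "[X][Y][Z]":
            e = np.einsum("i,j,k->ijk", nx, ny, nz) / N**2
        elif model == "[XY][Z]":
            e = np.einsum("ij,k->ijk", nxy, nz) / N
        elif model == "[XZ][Y]":
            e = np.einsum("ik,j->ijk", nxz, ny) / N
        elif model == "[YZ][X]":
            e = np.einsum("jk,i->ijk", nyz, nx) / N
        elif model == "[XY][XZ]":
            e = np.einsum("ij,ik->ijk", nxy, nxz) / np.where(nx == 0, 1, nx)[:, None, None]
            e[nx == 0] = 0.0
        elif model == "[XY][YZ]":
            e = np.einsum("ij,jk->ijk", nxy, nyz) / np.where(ny == 0, 1, ny)[None, :, None]
            e[:, ny == 0, :] = 0.0
        elif model == "[XZ][YZ]":
            e = np.einsum("ik,jk->ijk", nxz, nyz) / np.where(nz == 0, 1, nz)[None, None, :]
            e[:, :, nz == 0] = 0.0
        elif model == "[XY][XZ][YZ]":
            e = _ipf_homogeneous(obs)
        elif model == "[XYZ]":
            e = obs.astype(float)
        else:
            raise ValueError(f"unknown model {model!r}")
    return e


def _ipf_homogeneous(
    obs: np.ndarray, tol: float = 1e-12, max_iter: int = 2000
) -> np.ndarray:
    """Iterative proportional fitting to the three two-way margins."""
    obs = obs.astype(float)
    nxy = obs.sum(axis=2)
    nxz = obs.sum(axis=1)
    nyz = obs.sum(axis=0)
    e = np.full_like(obs, obs.sum() / obs.size)
    for _ in range(max_iter):
        m = e.sum(axis=2)
        e = e * np.where(m > 0, nxy / np.where(m == 0, 1, m), 0.0)[:, :, None]
        m = e.sum(axis=1)
        e = e * np.where(m > 0, nxz / np.where(m == 0, 1, m), 0.0)[:, None, :]
        m = e.sum(axis=0)
        e = e * np.where(m > 0, nyz / np.where(m == 0, 1, m), 0.0)[None, :, :]
        err = max(
            np.abs(e.sum(axis=2) - nxy).max(),
            np.abs(e.sum(axis=1) - nxz).max(),
            np.abs(e.sum(axis=0) - nyz).max(),
        )
        if err < tol:
            break
    return e


def _gsq(obs: np.ndarray, exp: np.ndarray) -> float:
    mask = obs > 0
    if np.any(mask & (exp <= 0)):
        return float("inf")
    return float(2.0 * np.sum(obs[mask] * np.log(obs[mask] / exp[mask])))


@dataclass
class LLM3DFit:
    """Full fit table of the log-linear hierarchy plus the selected model."""

    fits: pd.DataFrame  # model, df, gsq, p
    selected: str
    independence_p: float  # G² p of the complete-independence null

    def expected(self, model: str, obs: np.ndarray) -> np.ndarray:
        return _expected(model, np.asarray(obs))


def llm3d_fit(table: np.ndarray, select_alpha: float = 0.05) -> LLM3DFit:
    """Fit the log-linear hierarchy to a 2x2x2 contingency table.

    Every model in the hierarchy (complete independence, the three joint
    and three conditional independences, homogeneous association,
    saturated) is fitted; fit quality is the deviance
    G² = 2 Σ obs·ln(obs/exp) against a chi-square with the model's df.
    The selected model is the most parsimonious one not rejected at
    ``select_alpha`` (ties on df broken by larger p); the reported
    interdependence p-value is that of the complete-independence null.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2, 2):
        raise ValueError("table must be 2x2x2")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    if obs.sum() <= 0:
        raise ValueError("table total must be positive")
    rows = []
    for model, df in _MODELS:
        exp = _expected(model, obs)
        gsq = _gsq(obs, exp)
        p = 1.0 if df == 0 else float(stats.chi2.sf(gsq, df))
        rows.append({"model": model, "df": df, "gsq": gsq, "p": p})
    fits = pd.DataFrame(rows)
    selected = "[XYZ]"
    for df_level in sorted(fits["df"].unique(), reverse=True):
        level = fits[fits["df"] == df_level].sort_values("p", ascending=False)
        best = level.iloc[0]
        if best["p"] >= select_alpha:
            selected = best["model"]
            break
    indep_p = float(fits.loc[fits["model"] == "[X][Y][Z]", "p"].iloc[0])
    return LLM3DFit(fits=fits, selected=selected, independence_p=indep_p)


# ---------------------------------------------------------------------------
# covariate variance partition
# ---------------------------------------------------------------------------


def rpkm_normalize(
    counts: pd.DataFrame, widths: np.ndarray, library_sizes: np.ndarray
) -> pd.DataFrame:
    """Reads per kilobase of region per million library reads."""
    w_kb = np.asarray(widths, dtype=float) / 1e3
    lib_m = np.asarray(library_sizes, dtype=float) / 1e6
    return counts.div(w_kb, axis=0).div(lib_m, axis=1)


def _design_block(col: pd.Series) -> np.ndarray:
    """Columns for one covariate: numeric as-is, categoricals dummy-coded."""
    if pd.api.types.is_numeric_dtype(col) and col.nunique() > 2:
        return col.to_numpy(dtype=float)[:, None]
    levels = sorted(col.astype(str).unique())
    return np.column_stack(
        [(col.astype(str) == lv).to_numpy(dtype=float) for lv in levels[1:]]
    ) if len(levels) > 1 else np.empty((len(col), 0))


def covariate_variance_partition(
    enrichment: pd.DataFrame,
    covariates: pd.DataFrame,
    order: Sequence[str] | None = None,
    alpha: float = 0.01,
    nuisance: Sequence[str] = ("batch", "gender", "pmd", "platform", "depth", "frip"),
) -> pd.DataFrame:
    """Per-region sequential ANOVA variance partition.

    Fits, for each region, an ordinary least-squares model of normalized
    enrichment on the covariates in the declared ``order`` (biological
    before technical by default) and decomposes the total sum of squares
    sequentially (Type I).  Aliased covariate columns are dropped and
    recorded in ``df.attrs['aliased']``.

    Returns one row per region with ``<cov>_frac`` / ``<cov>_p`` columns,
    a ``residual_frac`` column (fractions sum to 1), and ``significant``
    — True when any nuisance covariate reaches ``p < alpha``.
    """
    if order is None:
        order = list(covariates.columns)
    Y = enrichment.to_numpy(dtype=float).T  # samples x regions
    n = Y.shape[0]
    Yc = Y - Y.mean(axis=0, keepdims=True)
    total_ss = np.sum(Yc**2, axis=0)
    total_ss = np.where(total_ss == 0, np.nan, total_ss)

    basis = np.ones((n, 1)) / np.sqrt(n)
    aliased: list[str] = []
    ss_by_cov: dict[str, np.ndarray] = {}
    df_by_cov: dict[str, int] = {}
    for cov in order:
        X = _design_block(covariates[cov])
        # residualize against everything fitted so far, then orthonormalize
        X = X - basis @ (basis.T @ X)
        q, r = np.linalg.qr(X) if X.shape[1] else (np.empty((n, 0)), np.empty((0, 0)))
        keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max() if r.size else 1.0)
        if X.shape[1] and not keep.all():
            aliased.append(cov)
        q = q[:, keep] if r.size else q
        proj = q.T @ Y
        ss_by_cov[cov] = np.sum(proj**2, axis=0)
        df_by_cov[cov] = q.shape[1]
        basis = np.hstack([basis, q])
    model_ss = sum(ss_by_cov.values())
    resid_ss = np.maximum(total_ss - model_ss, 0.0)
    df_resid = n - basis.shape[1]
    if df_resid < 2:
        raise ValueError("need at least 2 more samples than fitted terms")

    out = pd.DataFrame(index=enrichment.index)
    sig_any = np.zeros(Y.shape[1], dtype=bool)
    for cov in order:
        ss, dfc = ss_by_cov[cov], df_by_cov[cov]
        out[f"{cov}_frac"] = ss / total_ss
        if dfc == 0:
            out[f"{cov}_p"] = np.nan
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (ss / dfc) / (resid_ss / df_resid)
        p = stats.f.sf(F, dfc, df_resid)
        out[f"{cov}_p"] = p
        if cov in nuisance:
            sig_any |= np.nan_to_num(p, nan=1.0) < alpha
    out["residual_frac"] = resid_ss / total_ss
    out["significant"] = sig_any
    out.attrs["aliased"] = aliased
    out.attrs["df_resid"] = df_resid
    return out
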