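"""Heterogeneity and pleiotropy diagnostics for two-sample MR.

Cochran's Q measures dispersion of the per-SNP Wald ratios around the
fixed-effects IVW estimate; under homogeneity it is chi-square with J-1
degrees of freedom. MR-PRESSO simulates the null distribution of the
leave-one-out weighted residual sum of squares to give a global
heterogeneity p-value and per-SNP outlier p-values; flagged outliers are
removed once and IVW re-run. Leave-one-out re-estimates the causal effect
omitting each instrument in turn.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import (InsufficientInstrumentsError, MrEstimate, _as_arrays,
                         _ivw_core, ivw)

__all__ = [
    "HeterogeneityResult", "PressoResult",
    "cochran_q", "q_contributions", "mr_presso", "leave_one_out",
]


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q with its chi-square reference."""

    Q: float
    df: int
    pval: float
    phi: float  # Q/df dispersion


@dataclass
class PressoResult:
    """MR-PRESSO global and outlier test results.

    ``outlier_pvals`` are raw empirical p-values (add-one estimator);
    ``outlier_pvals_adj`` are Bonferroni-adjusted; ``outlier_ids`` are the
    SNPs whose adjusted p falls below the outlier alpha. ``ivw_corrected``
    is the IVW estimate after removing flagged outliers (None when fewer
    than two instruments remain or nothing was flagged).
    """

    rss_obs: float
    global_pval: float
    outlier_pvals: pd.Series
    outlier_pvals_adj: pd.Series
    outlier_ids: list[str]
    n_sim: int
    seed: int
    ivw_corrected: MrEstimate | None = None
    snp_order_note: str = field(default="sorted by snp_id for order invariance", repr=False)


def cochran_q(pairs: pd.DataFrame) -> HeterogeneityResult:
    """Q = sum_j w_j (ratio_j - beta_IVW_fe)², w_j = gamma_j²/se_out_j²."""
    g, _, G, sG = _as_arrays(pairs)
    j = len(g)
    if j < 2:
        raise InsufficientInstrumentsError(f"cochran_q needs J >= 2, got {j}")
    _, _, q = _ivw_core(g, G, sG)
    df = j - 1
    pval = float(stats.chi2.sf(q, df))
    return HeterogeneityResult(q, df, max(pval, np.finfo(float).tiny), q / df)


def q_contributions(pairs: pd.DataFrame) -> pd.Series:
    """Per-SNP contributions w_j (ratio_j - beta_fe)²; sums to Q exactly."""
    g, _, G, sG = _as_arrays(pairs)
    beta, _, _ = _ivw_core(g, G, sG)
    w = g**2 / sG**2
    contrib = w * (G / g - beta) ** 2
    idx = pairs["snp_id"] if "snp_id" in pairs else pd.RangeIndex(len(g))
    return pd.Series(contrib, index=pd.Index(idx, name="snp_id"))


def _loo_slopes(g: np.ndarray, G: np.ndarray, sG: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effects IVW slopes, closed form, vectorised.

    slope_{-j} = (A - g_j G_j / s_j²) / (B - g_j² / s_j²) with A, B the full
    weighted sums. Works on 1-D (J,) or 2-D (n_sim, J) inputs.
    """
    num = g * G / sG**2
    den = g**2 / sG**2
    A = num.sum(axis=-1, keepdims=True)
    B = den.sum(axis=-1, keepdims=True)
    return (A - num) / (B - den)


def mr_presso(pairs: pd.DataFrame, n_sim: int = 1000, seed: int | None = None,
              outlier_alpha: float = 0.05) -> PressoResult:
    """MR-PRESSO global heterogeneity test and per-SNP outlier test.

    The observed statistic is the leave-one-out weighted residual sum of
    squares RSS = sum_j (Gamma_j - beta_{-j} gamma_j)² / se_out_j². Its null
    distribution is simulated by drawing gamma_j* ~ N(gamma_j, se_exp_j) and
    Gamma_j* ~ N(beta_{-j} gamma_j, se_out_j) and recomputing the statistic
    ``n_sim`` times. Empirical p-values use the add-one estimator
    (1 + #{sim >= obs}) / (n_sim + 1), so they are never zero. Per-SNP
    outlier p-values compare each SNP's observed residual contribution with
    its simulated contributions and are Bonferroni-adjusted; SNPs below
    ``outlier_alpha`` after adjustment are removed once (no iteration) and
    an outlier-corrected IVW estimate is attached. The distortion test is
    not implemented.

    Internally SNPs are processed in sorted snp_id order so the result is
    invariant to input row order for a given seed.
    """
    if seed is None:
        raise ValueError("mr_presso requires an explicit seed")
    if n_sim < 100:
        warnings.warn("mr_presso with n_sim < 100 has very coarse p-value resolution")

    work = pairs.copy()
    if "snp_id" not in work:
        work = work.assign(snp_id=[f"snp{i}" for i in range(len(work))])
    work = work.sort_values("snp_id", kind="mergesort").reset_index(drop=True)
    g, sg, G, sG = _as_arrays(work)
    j = len(g)
    if j < 4:
        raise InsufficientInstrumentsError(f"mr_presso needs J >= 4, got {j}")

    beta_loo = _loo_slopes(g, G, sG)
    d_obs = (G - beta_loo * g) ** 2 / sG**2
    rss_obs = float(d_obs.sum())

    rng = np.random.default_rng(seed)
    gs = rng.normal(g, sg, size=(n_sim, j))
    Gs = rng.normal(beta_loo * g, sG, size=(n_sim, j))
    gs[gs == 0] = np.finfo(float).tiny
    beta_loo_sim = _loo_slopes(gs, Gs, sG)
    d_sim = (Gs - beta_loo_sim * gs) ** 2 / sG**2
    rss_sim = d_sim.sum(axis=1)

    global_pval = float((1 + (rss_sim >= rss_obs).sum()) / (n_sim + 1))
    p_out = (1 + (d_sim >= d_obs).sum(axis=0)) / (n_sim + 1)
    p_adj = np.minimum(p_out * j, 1.0)
    ids = work["snp_id"].to_numpy()
    flagged = [str(s) for s in ids[p_adj < outlier_alpha]]

    corrected = None
    if flagged:
        keep = work.loc[~work["snp_id"].isin(flagged)]
        if len(keep) >= 2:
            corrected = ivw(keep, model="multiplicative_random")

    return PressoResult(
        rss_obs=rss_obs,
        global_pval=global_pval,
        outlier_pvals=pd.Series(p_out, index=pd.Index(ids, name="snp_id")),
        outlier_pvals_adj=pd.Series(p_adj, index=pd.Index(ids, name="snp_id")),
        outlier_ids=flagged,
        n_sim=n_sim,
        seed=seed,
        ivw_corrected=corrected,
    )


def leave_one_out(pairs: pd.DataFrame) -> tuple[list[tuple[str, MrEstimate]], MrEstimate]:
    """IVW (multiplicative random effects) omitting each SNP in turn.

    Returns the J leave-one-out estimates (dropped snp_id, estimate) plus
    the all-SNP estimate for reference.
    """
    work = pairs.reset_index(drop=True)
    if "snp_id" not in work:
        work = work.assign(snp_id=[f"snp{i}" for i in range(len(work))])
    j = len(work)
    if j < 3:
        raise InsufficientInstrumentsError(f"leave_one_out needs J >= 3, got {j}")
    full = ivw(work, model="multiplicative_random")
    results = [
        (str(work.at[i, "snp_id"]), ivw(work.drop(index=i), model="multiplicative_random"))
        for i in range(j)
    ]
    return results, full
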