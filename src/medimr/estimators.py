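"""Causal-effect estimators for two-sample Mendelian randomization.

All estimators consume a harmonized pairs DataFrame (columns ``beta_exp``,
``se_exp``, ``beta_out``, ``se_out``, optionally ``snp_id``) in which the
per-SNP exposure effect gamma_j and outcome effect Gamma_j are expressed on
a common effect-allele frame. Per-SNP causal estimates are Wald ratios
Gamma_j / gamma_j; the IVW estimate is their inverse-variance-weighted mean,
equivalently weighted least squares of Gamma on gamma through the origin
with weights 1/se_out². MR-Egger adds an intercept (a directional-pleiotropy
estimate, valid under InSIDE); the weighted median is consistent when at
least half the weight comes from valid instruments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats_io import or_ci_to_logscale

__all__ = [
    "MrEstimate", "InsufficientInstrumentsError", "DegenerateInstrumentError",
    "wald_ratio", "ivw", "mr_egger", "weighted_median", "wald_p_from_or_ci",
]

_Z95 = stats.norm.ppf(0.975)


class InsufficientInstrumentsError(ValueError):
    """Fewer instruments than the estimator's minimum J."""


class DegenerateInstrumentError(ZeroDivisionError):
    """An instrument with zero exposure effect cannot form a Wald ratio."""


@dataclass(frozen=True)
class MrEstimate:
    """A causal estimate with normal- or t-based uncertainty.

    ``or_point/or_low/or_high`` are exp transforms of the beta fields, for
    reporting against binary outcomes (betas are log odds ratios there).
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int

    @property
    def or_point(self) -> float:
        return math.exp(self.beta)

    @property
    def or_low(self) -> float:
        return math.exp(self.ci_low)

    @property
    def or_high(self) -> float:
        return math.exp(self.ci_high)

    @classmethod
    def from_beta_se(cls, method: str, beta: float, se: float, n_snp: int,
                     df: int | None = None) -> "MrEstimate":
        """Build from a point estimate and SE; t-based if ``df`` given."""
        if se < 0:
            raise ValueError("se must be non-negative")
        if se == 0:
            p = 1.0 if beta == 0 else 0.0
            return cls(method, beta, 0.0, beta, beta, max(p, np.nextafter(0, 1)), n_snp)
        if df is not None:
            q = stats.t.ppf(0.975, df)
            p = 2.0 * stats.t.sf(abs(beta / se), df)
        else:
            q = _Z95
            p = 2.0 * stats.norm.sf(abs(beta / se))
        return cls(method, beta, se, beta - q * se, beta + q * se, min(p, 1.0), n_snp)


def _as_arrays(pairs: pd.DataFrame) -> tuple[np.ndarray, ...]:
    g = pairs["beta_exp"].to_numpy(dtype=float)
    sg = pairs["se_exp"].to_numpy(dtype=float)
    G = pairs["beta_out"].to_numpy(dtype=float)
    sG = pairs["se_out"].to_numpy(dtype=float)
    if np.any(g == 0):
        raise DegenerateInstrumentError("instrument with beta_exp == 0")
    return g, sg, G, sG


def wald_ratio(pair, second_order: bool = False) -> MrEstimate:
    """Single-SNP causal estimate Gamma/gamma.

    The default SE is the first-order delta approximation se_out/|gamma|
    (exposure-side noise ignored); ``second_order`` adds the
    beta²·se_exp²/gamma² term.
    """
    g, sg = float(pair["beta_exp"]), float(pair["se_exp"])
    G, sG = float(pair["beta_out"]), float(pair["se_out"])
    if g == 0:
        raise DegenerateInstrumentError("beta_exp == 0")
    beta = G / g
    var = (sG / g) ** 2
    if second_order:
        var += beta**2 * (sg / g) ** 2
    return MrEstimate.from_beta_se("wald", beta, math.sqrt(var), 1)


def _ivw_core(g: np.ndarray, G: np.ndarray, sG: np.ndarray) -> tuple[float, float, float]:
    """Fixed-effects slope, SE and Cochran's Q (closed form)."""
    w = g**2 / sG**2          # inverse-variance weights of the Wald ratios
    ratios = G / g
    sw = w.sum()
    beta = float((w * ratios).sum() / sw)
    se_fe = float(sw**-0.5)
    q = float((w * (ratios - beta) ** 2).sum())
    return beta, se_fe, q


def ivw(pairs: pd.DataFrame, model: str = "multiplicative_random") -> MrEstimate:
    """Inverse-variance-weighted estimate.

    ``fixed`` needs J >= 1; ``multiplicative_random`` needs J >= 2 and
    inflates the SE by max(1, sqrt(Q/(J-1))) — it never reports a smaller SE
    than fixed effects. p-values are two-sided normal.
    """
    if model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW model {model!r}")
    g, _, G, sG = _as_arrays(pairs)
    j = len(g)
    min_j = 1 if model == "fixed" else 2
    if j < min_j:
        raise InsufficientInstrumentsError(f"ivw({model}) needs J >= {min_j}, got {j}")
    beta, se_fe, q = _ivw_core(g, G, sG)
    if model == "fixed":
        se = se_fe
    else:
        se = se_fe * max(1.0, math.sqrt(q / (j - 1)))
    return MrEstimate.from_beta_se(f"ivw_{'fe' if model == 'fixed' else 'mre'}", beta, se, j)


def mr_egger(pairs: pd.DataFrame) -> tuple[MrEstimate, MrEstimate]:
    """MR-Egger regression: (slope estimate, intercept estimate).

    Pairs are oriented so every gamma_j >= 0 (jointly sign-flipping gamma and
    Gamma where needed — this changes the intercept, so the rule is part of
    the estimator's definition). Weighted least squares of Gamma on gamma
    with intercept, weights 1/se_out²; SEs multiplied by
    max(1, residual scale); p-values from t(J-2). A non-null intercept
    indicates directional horizontal pleiotropy.
    """
    g, _, G, sG = _as_arrays(pairs)
    j = len(g)
    if j < 3:
        raise InsufficientInstrumentsError(f"mr_egger needs J >= 3, got {j}")
    flip = np.sign(g)
    g, G = g * flip, G * flip

    w = 1.0 / sG**2
    # closed-form weighted least squares with intercept
    sw, sx, sy = w.sum(), (w * g).sum(), (w * G).sum()
    sxx, sxy = (w * g * g).sum(), (w * g * G).sum()
    det = sw * sxx - sx**2
    slope = (sw * sxy - sx * sy) / det
    intercept = (sxx * sy - sx * sxy) / det
    resid = G - intercept - slope * g
    rss = float((w * resid**2).sum())
    sigma = max(1.0, math.sqrt(rss / (j - 2)))
    se_slope = math.sqrt(sw / det) * sigma
    se_int = math.sqrt(sxx / det) * sigma
    return (
        MrEstimate.from_beta_se("egger_slope", float(slope), se_slope, j, df=j - 2),
        MrEstimate.from_beta_se("egger_intercept", float(intercept), se_int, j, df=j - 2),
    )


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median (cumulative-midpoint convention)."""
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    w = w / w.sum()
    p = np.cumsum(w) - 0.5 * w
    # snap an (up to rounding) exact midpoint hit, so equal weights with
    # odd J return the sample median exactly
    hit = np.abs(p - 0.5) < 1e-12
    if hit.any():
        return float(v[np.argmax(hit)])
    return float(np.interp(0.5, p, v))


def weighted_median(pairs: pd.DataFrame, n_boot: int = 1000,
                    seed: int | None = None) -> MrEstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    Ratio estimates are weighted by the inverse variance of their first-order
    Wald SEs (w_j = gamma_j²/se_out_j²); the estimate interpolates the sorted
    ratios at cumulative weight 0.5. The SE is the SD of the estimate over
    ``n_boot`` resamples with gamma_j*, Gamma_j* drawn from normals centred
    on the observed values; ``seed`` is mandatory for reproducibility.
    """
    if seed is None:
        raise ValueError("weighted_median requires an explicit seed")
    g, sg, G, sG = _as_arrays(pairs)
    j = len(g)
    if j < 3:
        raise InsufficientInstrumentsError(f"weighted_median needs J >= 3, got {j}")

    beta = _weighted_median(G / g, g**2 / sG**2)

    rng = np.random.default_rng(seed)
    gs = rng.normal(g, sg, size=(n_boot, j))
    Gs = rng.normal(G, sG, size=(n_boot, j))
    gs[gs == 0] = np.finfo(float).tiny
    ratios = Gs / gs
    weights = gs**2 / sG**2
    # vectorised weighted median across bootstrap rows
    order = np.argsort(ratios, axis=1, kind="stable")
    rows = np.arange(n_boot)[:, None]
    v = ratios[rows, order]
    w = weights[rows, order]
    w = w / w.sum(axis=1, keepdims=True)
    p = np.cumsum(w, axis=1) - 0.5 * w
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = np.interp(0.5, p[i], v[i])
    se = float(boots.std(ddof=1))
    return MrEstimate.from_beta_se("weighted_median", beta, se, j)


def wald_p_from_or_ci(or_point: float, ci_low: float, ci_high: float,
                      level: float = 0.95) -> float:
    """Two-sided p implied by a printed OR and CI (consistency check)."""
    beta, se = or_ci_to_logscale(or_point, ci_low, ci_high, level)
    if se == 0:
        if beta != 0:
            raise ValueError("zero-width CI with non-null OR")
        return 1.0
    return float(2.0 * stats.norm.sf(abs(beta / se)))
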