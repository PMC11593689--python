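"""Two-step mediation MR: effect decomposition with delta-method uncertainty.

Step 1 estimates the exposure-to-mediator effect a with the exposure's
instruments; step 2 estimates the mediator-to-outcome effect b with the
mediator's own instruments (univariable, not multivariable-adjusted). The
indirect (mediated) effect is the product a·b, the direct effect is
tau - a·b where tau is the total exposure-to-outcome effect, and the
proportion mediated is a·b / tau. Confidence intervals come from first-order
delta approximations assuming independence of a, b and tau across
non-overlapping samples; Z = indirect / SE(indirect) gives the mediation
p-value against the standard normal. On a binary outcome all effects are
log odds ratios and the proportion is interpreted on that scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .estimators import MrEstimate

__all__ = [
    "MediationResult", "delta_se_product", "delta_se_proportion",
    "two_step_mediation", "consistency_filter", "bh_fdr",
    "monte_carlo_proportion_ci",
]

_Z95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class MediationResult:
    """Two-step decomposition of a total effect through one mediator.

    Invariants hold exactly: indirect = a·b, direct = tau - indirect,
    z·se_indirect = indirect. ``proportion`` and its CI are None when
    tau = 0 (undefined). ``consistent`` records whether the indirect effect
    points the same way as the total effect.
    """

    exposure: str
    mediator: str
    outcome: str
    a: float
    se_a: float
    a_pval: float
    b: float
    se_b: float
    b_pval: float
    tau: float
    se_tau: float
    tau_pval: float
    indirect: float
    se_indirect: float
    direct: float
    proportion: float | None
    se_proportion: float | None
    ci_low_prop: float | None
    ci_high_prop: float | None
    z: float
    pval: float
    consistent: bool


def delta_se_product(a: float, se_a: float, b: float, se_b: float) -> float:
    """First-order delta SE of the product a·b: sqrt(a²se_b² + b²se_a²).

    Assumes a and b estimated from non-overlapping samples. At a = b = 0 the
    first-order term vanishes (the approximation is degenerate there); a
    warning is emitted and 0 returned.
    """
    if se_a < 0 or se_b < 0:
        raise ValueError("standard errors must be non-negative")
    if a == 0 and b == 0:
        warnings.warn("delta_se_product degenerate at a = b = 0 (first-order SE is 0)")
    return math.sqrt(a**2 * se_b**2 + b**2 * se_a**2)


def delta_se_proportion(a: float, se_a: float, b: float, se_b: float,
                        tau: float, se_tau: float) -> float:
    """First-order delta SE of the proportion mediated P = a·b/tau.

    se = |P|·sqrt(se_a²/a² + se_b²/b² + se_tau²/tau²) under independence.
    When a or b is 0 the relative-error form is singular; fall back to the
    product-delta SE divided by |tau|.
    """
    if tau == 0:
        raise ZeroDivisionError("proportion mediated undefined at tau = 0")
    if se_a < 0 or se_b < 0 or se_tau < 0:
        raise ValueError("standard errors must be non-negative")
    if a == 0 or b == 0:
        return delta_se_product(a, se_a, b, se_b) / abs(tau)
    p = a * b / tau
    return abs(p) * math.sqrt((se_a / a) ** 2 + (se_b / b) ** 2 + (se_tau / tau) ** 2)


def two_step_mediation(effect_xm: MrEstimate, effect_my: MrEstimate,
                       effect_xy: MrEstimate, exposure: str = "X",
                       mediator: str = "M", outcome: str = "Y",
                       test_on: str = "indirect") -> MediationResult:
    """Decompose a total effect into indirect (a·b) and direct parts.

    ``effect_xm`` (a), ``effect_my`` (b) and ``effect_xy`` (tau) must be on
    a common scale (log odds for a binary outcome). The mediation Z and p
    test the indirect effect by default; ``test_on="proportion"`` tests the
    proportion instead. With tau = 0 the proportion fields are None but the
    indirect effect is still returned.
    """
    a, se_a = effect_xm.beta, effect_xm.se
    b, se_b = effect_my.beta, effect_my.se
    tau, se_tau = effect_xy.beta, effect_xy.se

    indirect = a * b
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        se_ind = delta_se_product(a, se_a, b, se_b)
    direct = tau - indirect

    if tau != 0:
        proportion = indirect / tau
        se_prop = delta_se_proportion(a, se_a, b, se_b, tau, se_tau)
        ci_lo = proportion - _Z95 * se_prop
        ci_hi = proportion + _Z95 * se_prop
    else:
        proportion = se_prop = ci_lo = ci_hi = None

    if test_on == "proportion":
        if proportion is None:
            raise ZeroDivisionError("cannot test the proportion at tau = 0")
        z = proportion / se_prop if se_prop > 0 else 0.0
    elif test_on == "indirect":
        z = indirect / se_ind if se_ind > 0 else 0.0
    else:
        raise ValueError("test_on must be 'indirect' or 'proportion'")
    pval = float(2.0 * stats.norm.sf(abs(z))) if z != 0 else 1.0

    consistent = (indirect == 0) or (tau != 0 and math.copysign(1, indirect) == math.copysign(1, tau))
    return MediationResult(
        exposure=exposure, mediator=mediator, outcome=outcome,
        a=a, se_a=se_a, a_pval=effect_xm.pval,
        b=b, se_b=se_b, b_pval=effect_my.pval,
        tau=tau, se_tau=se_tau, tau_pval=effect_xy.pval,
        indirect=indirect, se_indirect=se_ind, direct=direct,
        proportion=proportion, se_proportion=se_prop,
        ci_low_prop=ci_lo, ci_high_prop=ci_hi,
        z=z, pval=min(pval, 1.0), consistent=consistent,
    )


def consistency_filter(results: list[MediationResult], alpha: float = 0.05
                       ) -> tuple[list[MediationResult], list[tuple[str, str]]]:
    """Drop direction-inconsistent or non-significant mediation results.

    Retains results with ``consistent`` True and step-1, step-2 and
    mediation p-values all below ``alpha``. Returns (kept, removed) where
    each removed entry is (mediator, reason).
    """
    kept: list[MediationResult] = []
    removed: list[tuple[str, str]] = []
    for r in results:
        if not r.consistent:
            removed.append((r.mediator, "indirect effect opposes total effect"))
        elif r.a_pval >= alpha:
            removed.append((r.mediator, f"step-1 p = {r.a_pval:.3g} >= {alpha}"))
        elif r.b_pval >= alpha:
            removed.append((r.mediator, f"step-2 p = {r.b_pval:.3g} >= {alpha}"))
        elif r.pval >= alpha:
            removed.append((r.mediator, f"mediation p = {r.pval:.3g} >= {alpha}"))
        else:
            kept.append(r)
    return kept, removed


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any(~((p > 0) & (p <= 1))):
        raise ValueError("p-values must lie in (0,1]")
    return multipletests(p, method="fdr_bh")[1]


def monte_carlo_proportion_ci(a: float, se_a: float, b: float, se_b: float,
                              tau: float, se_tau: float, level: float = 0.95,
                              n_draws: int = 100_000, seed: int | None = None
                              ) -> tuple[float, float]:
    """Simulation CI for the proportion mediated (delta-method cross-check).

    Draws (a*, b*, tau*) from independent normals and returns the empirical
    quantiles of a*·b*/tau*. Intended as a sanity check of the delta CI, not
    the primary interval.
    """
    if seed is None:
        raise ValueError("monte_carlo_proportion_ci requires an explicit seed")
    rng = np.random.default_rng(seed)
    props = (rng.normal(a, se_a, n_draws) * rng.normal(b, se_b, n_draws)
             / rng.normal(tau, se_tau, n_draws))
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(props, [alpha, 1.0 - alpha])
    return float(lo), float(hi)
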