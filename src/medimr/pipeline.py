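"""Orchestration of the multi-step mediation MR design at desk scale.

The study design: (1) screen candidate exposures against the outcome with
two-sample MR and BH-FDR across the exposure family; (2) for an exposure
passing the screen, run a two-step mediation screen over candidate
mediators with a direction-consistency filter; (3) re-estimate the retained
mediation against an independent validation outcome dataset. Instrument
selection uses the relaxed discovery threshold (p < 5e-6) for the exposure
screen and the genome-wide threshold (p < 5e-8) for mediators and later
steps. Every stochastic step derives its seed deterministically from the
run seed, so (config, seed) fully determine every output byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import estimators, instruments, mediation, sensitivity
from .instruments import DISCOVERY, STRICT, LdMatrix, SelectionParams
from .mediation import MediationResult
from .sumstats_io import SumStatsTable, harmonize, kept_pairs
from .synthetic_data import derive_seed

__all__ = [
    "AnalysisConfig", "MrAnalysis", "ScreenResult", "MediationScreenResult",
    "mr_analysis", "run_exposure_screen", "run_mediation_screen", "run_validation",
]

log = logging.getLogger("medimr")


@dataclass
class AnalysisConfig:
    """Run-wide thresholds, policies and seeds."""

    selection_discovery: SelectionParams = DISCOVERY
    selection_strict: SelectionParams = STRICT
    palindrome_policy: str = "drop_ambiguous"
    freq_threshold: float = 0.42
    alpha: float = 0.05
    fdr_alpha: float = 0.05
    n_boot: int = 1000
    presso_n_sim: int = 1000
    seed: int = 0
    output_dir: Path | None = None

    def manifest(self) -> dict:
        return {
            "discovery_p": self.selection_discovery.p_threshold,
            "strict_p": self.selection_strict.p_threshold,
            "r2_threshold": self.selection_strict.r2_threshold,
            "window_kb": self.selection_strict.window_kb,
            "maf_min": self.selection_strict.maf_min,
            "palindrome_policy": self.palindrome_policy,
            "freq_threshold": self.freq_threshold,
            "alpha": self.alpha, "fdr_alpha": self.fdr_alpha,
            "n_boot": self.n_boot, "presso_n_sim": self.presso_n_sim,
            "seed": self.seed,
        }


@dataclass
class MrAnalysis:
    """One exposure-outcome MR with estimates and sensitivity diagnostics."""

    exposure: str
    outcome: str
    pairs: pd.DataFrame
    estimates: dict[str, estimators.MrEstimate]
    heterogeneity: sensitivity.HeterogeneityResult | None
    presso: sensitivity.PressoResult | None
    seed: int

    @property
    def primary(self) -> estimators.MrEstimate:
        return self.estimates["ivw_mre"]

    @property
    def primary_corrected(self) -> estimators.MrEstimate:
        """Primary estimate after MR-PRESSO outlier elimination (falls back
        to the all-SNP estimate when nothing was flagged or J < 4)."""
        if self.presso is not None and self.presso.ivw_corrected is not None:
            return self.presso.ivw_corrected
        return self.estimates["ivw_mre"]

    def rows(self) -> list[dict]:
        out = []
        for name, est in self.estimates.items():
            out.append({
                "exposure": self.exposure, "outcome": self.outcome,
                "method": name, "n_snp": est.n_snp, "beta": est.beta,
                "se": est.se, "ci_low": est.ci_low, "ci_high": est.ci_high,
                "pval": est.pval, "or_point": est.or_point,
                "or_low": est.or_low, "or_high": est.or_high,
            })
        return out

    def sensitivity_row(self) -> dict:
        het, pr = self.heterogeneity, self.presso
        icpt = self.estimates.get("egger_intercept")
        return {
            "exposure": self.exposure, "outcome": self.outcome,
            "Q": het.Q if het else float("nan"),
            "Q_df": het.df if het else 0,
            "Q_pval": het.pval if het else float("nan"),
            "egger_intercept": icpt.beta if icpt else float("nan"),
            "egger_intercept_pval": icpt.pval if icpt else float("nan"),
            "presso_global_pval": pr.global_pval if pr else float("nan"),
            "n_outliers": len(pr.outlier_ids) if pr else 0,
            "seed": self.seed,
        }


class InsufficientInstruments(Exception):
    """Raised internally when an analysis has < 2 usable instruments."""


def select_instruments(table: SumStatsTable, params: SelectionParams,
                       ld: LdMatrix | None = None) -> SumStatsTable:
    """Significance/MAF filter, then LD clumping when a matrix is given."""
    iv = instruments.significance_filter(table, params)
    if ld is not None and iv.n_snps > 1:
        iv = instruments.ld_clump(iv, ld, params)
    return iv


def mr_analysis(config: AnalysisConfig, exposure: SumStatsTable,
                outcome: SumStatsTable, params: SelectionParams,
                ld: LdMatrix | None = None) -> MrAnalysis:
    """Instrument selection, harmonization and the full estimator battery.

    IVW multiplicative random effects is the primary estimate; fixed-effects
    IVW is always reported alongside. Egger and the weighted median need
    J >= 3, MR-PRESSO J >= 4; they are omitted (not failed) below that.
    """
    iv = select_instruments(exposure, params, ld)
    if iv.n_snps == 0:
        raise InsufficientInstruments(f"{exposure.trait_id}: no instruments pass selection")
    harm = harmonize(iv, outcome, config.palindrome_policy, config.freq_threshold)
    pairs = kept_pairs(harm)
    j = len(pairs)
    if j < 2:
        raise InsufficientInstruments(
            f"{exposure.trait_id}: only {j} instrument(s) after harmonization")

    seed = derive_seed(config.seed, exposure.trait_id, outcome.trait_id)
    est: dict[str, estimators.MrEstimate] = {
        "ivw_mre": estimators.ivw(pairs, "multiplicative_random"),
        "ivw_fe": estimators.ivw(pairs, "fixed"),
    }
    het = sensitivity.cochran_q(pairs)
    presso = None
    if j >= 3:
        slope, icpt = estimators.mr_egger(pairs)
        est["egger_slope"], est["egger_intercept"] = slope, icpt
        est["weighted_median"] = estimators.weighted_median(
            pairs, n_boot=config.n_boot, seed=derive_seed(seed, "wm"))
    if j >= 4:
        presso = sensitivity.mr_presso(
            pairs, n_sim=config.presso_n_sim, seed=derive_seed(seed, "presso"))
    return MrAnalysis(exposure.trait_id, outcome.trait_id, pairs, est, het, presso, seed)


@dataclass
class ScreenResult:
    """Exposure-screen output: all estimates, the FDR-adjusted primary
    table, sensitivity reports and a skip ledger."""

    results: pd.DataFrame
    primary: pd.DataFrame
    sensitivity: pd.DataFrame
    analyses: dict[str, MrAnalysis]
    skipped: list[tuple[str, str]] = field(default_factory=list)


def run_exposure_screen(config: AnalysisConfig, exposures: list[SumStatsTable],
                        outcome: SumStatsTable, ld: LdMatrix | None = None
                        ) -> ScreenResult:
    """MR of each candidate exposure on the outcome with BH-FDR.

    Exposures with fewer than two surviving instruments are skipped with a
    logged reason, not failed. The FDR family is the set of primary (IVW
    multiplicative random effects) p-values across screened exposures; the
    family size is recorded on every row.
    """
    analyses: dict[str, MrAnalysis] = {}
    skipped: list[tuple[str, str]] = []
    for exp in exposures:
        try:
            analyses[exp.trait_id] = mr_analysis(
                config, exp, outcome, config.selection_discovery, ld)
        except InsufficientInstruments as exc:
            skipped.append((exp.trait_id, str(exc)))
            log.info("screen: skipped %s (%s)", exp.trait_id, exc)

    rows = [r for a in analyses.values() for r in a.rows()]
    results = pd.DataFrame(rows)
    primary = pd.DataFrame([
        {"exposure": a.exposure, "outcome": a.outcome, "n_snp": a.primary.n_snp,
         "beta": a.primary.beta, "se": a.primary.se, "pval": a.primary.pval,
         "or_point": a.primary.or_point, "or_low": a.primary.or_low,
         "or_high": a.primary.or_high}
        for a in analyses.values()
    ])
    if len(primary):
        primary["qval"] = mediation.bh_fdr(primary["pval"])
        primary["fdr_family_size"] = len(primary)
        primary["fdr_significant"] = primary["qval"] < config.fdr_alpha
    sens = pd.DataFrame([a.sensitivity_row() for a in analyses.values()])

    out = ScreenResult(results, primary, sens, analyses, skipped)
    if config.output_dir is not None:
        d = Path(config.output_dir)
        d.mkdir(parents=True, exist_ok=True)
        results.to_csv(d / "screen_results.tsv", sep="\t", index=False)
        primary.to_csv(d / "screen_primary.tsv", sep="\t", index=False)
        sens.to_csv(d / "screen_sensitivity.tsv", sep="\t", index=False)
        pd.DataFrame(skipped, columns=["exposure", "reason"]).to_csv(
            d / "screen_skipped.tsv", sep="\t", index=False)
    return out


def _mediation_table(results: list[MediationResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "exposure": r.exposure, "mediator": r.mediator, "outcome": r.outcome,
        "a": r.a, "se_a": r.se_a, "a_pval": r.a_pval,
        "b": r.b, "se_b": r.se_b, "b_pval": r.b_pval,
        "tau": r.tau, "se_tau": r.se_tau,
        "indirect": r.indirect, "se_indirect": r.se_indirect,
        "direct": r.direct, "proportion": r.proportion,
        "prop_ci_low": r.ci_low_prop, "prop_ci_high": r.ci_high_prop,
        "z": r.z, "pval": r.pval, "consistent": r.consistent,
    } for r in results])


@dataclass
class MediationScreenResult:
    """Mediation-screen output: per-mediator decompositions, the subset
    passing the consistency filter, and skip/removal ledgers."""

    all_results: list[MediationResult]
    retained: list[MediationResult]
    removed: list[tuple[str, str]]
    skipped: list[tuple[str, str]]
    table: pd.DataFrame
    tau_analysis: MrAnalysis


def run_mediation_screen(config: AnalysisConfig, exposure: SumStatsTable,
                         mediators: list[SumStatsTable], outcome: SumStatsTable,
                         ld: LdMatrix | None = None) -> MediationScreenResult:
    """Two-step mediation MR over candidate mediators.

    Step 1 (exposure→mediator) uses the exposure's instruments at the
    discovery threshold; step 2 (mediator→outcome) uses each mediator's own
    instruments at the genome-wide threshold (univariable MR, mirroring the
    two-step design). Mediators failing instrument selection are skipped;
    direction-inconsistent or non-significant mediations are removed by the
    consistency filter; BH-FDR q-values are reported across the family.
    """
    tau_a = mr_analysis(config, exposure, outcome, config.selection_discovery, ld)

    results: list[MediationResult] = []
    skipped: list[tuple[str, str]] = []
    for med in mediators:
        try:
            step1 = mr_analysis(config, exposure, med, config.selection_discovery, ld)
            step2 = mr_analysis(config, med, outcome, config.selection_strict, ld)
        except InsufficientInstruments as exc:
            skipped.append((med.trait_id, str(exc)))
            log.info("mediation: skipped %s (%s)", med.trait_id, exc)
            continue
        results.append(mediation.two_step_mediation(
            step1.primary_corrected, step2.primary_corrected, tau_a.primary_corrected,
            exposure=exposure.trait_id, mediator=med.trait_id,
            outcome=outcome.trait_id))

    retained, removed = mediation.consistency_filter(results, config.alpha)
    table = _mediation_table(results)
    if len(table):
        table["qval"] = mediation.bh_fdr(table["pval"])
        table["fdr_family_size"] = len(table)
        table["retained"] = table["mediator"].isin([r.mediator for r in retained])

    out = MediationScreenResult(results, retained, removed, skipped, table, tau_a)
    if config.output_dir is not None:
        d = Path(config.output_dir)
        d.mkdir(parents=True, exist_ok=True)
        table.to_csv(d / "mediation_results.tsv", sep="\t", index=False)
        pd.DataFrame(removed + skipped, columns=["mediator", "reason"]).to_csv(
            d / "mediation_removed.tsv", sep="\t", index=False)
    return out


def run_validation(config: AnalysisConfig, exposure: SumStatsTable,
                   mediator: SumStatsTable, outcome2: SumStatsTable,
                   ld: LdMatrix | None = None,
                   discovery_result: MediationResult | None = None
                   ) -> tuple[MediationResult, pd.DataFrame]:
    """Re-estimate a mediation against an independent outcome dataset.

    Step 1 (exposure→mediator) does not involve the outcome and is
    recomputed unchanged; the total effect and step 2 are re-estimated
    against ``outcome2``. Returns the validation decomposition and a
    side-by-side comparison with the discovery result when supplied.
    """
    tau_a = mr_analysis(config, exposure, outcome2, config.selection_discovery, ld)
    step1 = mr_analysis(config, exposure, mediator, config.selection_discovery, ld)
    step2 = mr_analysis(config, mediator, outcome2, config.selection_strict, ld)
    val = mediation.two_step_mediation(
        step1.primary_corrected, step2.primary_corrected, tau_a.primary_corrected,
        exposure=exposure.trait_id, mediator=mediator.trait_id,
        outcome=outcome2.trait_id)

    rows = [_row_from_result("validation", val)]
    if discovery_result is not None:
        rows.insert(0, _row_from_result("discovery", discovery_result))
    comparison = pd.DataFrame(rows)
    if config.output_dir is not None:
        d = Path(config.output_dir)
        d.mkdir(parents=True, exist_ok=True)
        comparison.to_csv(d / "validation_comparison.tsv", sep="\t", index=False)
    return val, comparison


def _row_from_result(stage: str, r: MediationResult) -> dict:
    return {
        "stage": stage, "exposure": r.exposure, "mediator": r.mediator,
        "outcome": r.outcome, "indirect": r.indirect, "tau": r.tau,
        "proportion": r.proportion, "prop_ci_low": r.ci_low_prop,
        "prop_ci_high": r.ci_high_prop, "pval": r.pval,
    }
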