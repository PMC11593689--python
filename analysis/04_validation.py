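#!/usr/bin/env python
"""Validate the retained mediation against an independent outcome dataset.

Re-estimates the total effect and the mediator->outcome step against the
validation outcome (same causal truth, independent sampling noise, slightly
different sample size) and prints the discovery and validation mediated
proportions side by side — the analogue of confirming a mediated proportion
in a second hypertension GWAS.

Inputs: results/data/, results/mediation/ (from scripts 01 and 03)
Outputs: results/validation/validation_comparison.tsv
"""

from pathlib import Path

from medimr.instruments import read_ld_square
from medimr.pipeline import AnalysisConfig, run_mediation_screen, run_validation
from medimr.sumstats_io import read_sumstats

DATA = Path("results/data")
SEED = 20240917


def main() -> None:
    exposure = read_sumstats(DATA / "exposure_X.tsv", trait_id="X")
    mediator = read_sumstats(DATA / "mediator_M.tsv", trait_id="M")
    outcome = read_sumstats(DATA / "outcome_Y.tsv", trait_type="binary", trait_id="Y")
    outcome2 = read_sumstats(DATA / "outcome_Y_validation.tsv",
                             trait_type="binary", trait_id="Y_validation")
    ld = read_ld_square(DATA / "ld.tsv")

    config = AnalysisConfig(seed=SEED, output_dir=Path("results/validation"))
    disc = run_mediation_screen(AnalysisConfig(seed=SEED), exposure, [mediator],
                                outcome, ld).retained[0]
    val, comparison = run_validation(config, exposure, mediator, outcome2, ld,
                                     discovery_result=disc)

    for row in comparison.itertuples():
        print(f"  {row.stage}: proportion mediated "
              f"{100 * row.proportion:.1f}% "
              f"[{100 * row.prop_ci_low:.1f}%-{100 * row.prop_ci_high:.1f}%], "
              f"p = {row.pval:.2e} (outcome {row.outcome})")
    agree = (disc.ci_low_prop < val.proportion < disc.ci_high_prop)
    print("validation estimate falls inside the discovery CI"
          if agree else "validation estimate falls outside the discovery CI")
    print("comparison written to results/validation/")


if __name__ == "__main__":
    main()
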