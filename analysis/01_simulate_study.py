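#!/usr/bin/env python
"""Generate the synthetic study datasets.

Builds a three-trait world mirroring the study's structure: a dietary-style
exposure X, a circulating-protein mediator M and a binary (log-odds scale)
hypertension-like outcome Y, with true effects anchored at the reported
values (alpha = 0.11, b = 0.11, direct effect 0.088, so the true mediated
proportion is 12.1%). A validation outcome with independent sampling noise
and two null exposures for the screen are written alongside, plus the LD
matrix and the truth record.

Outputs: results/data/*.tsv, results/data/truth.yaml
"""

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from medimr.sumstats_io import SumStatsTable, write_sumstats
from medimr.synthetic_data import SimConfig, resample_outcome, simulate_sumstats

SEED = 20240917
OUT = Path("results/data")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(seed=SEED, harmonization_noise=0.05)
    sim = simulate_sumstats(cfg)
    y2 = resample_outcome(sim, seed=SEED + 1, n_y=461_880, trait_id="Y_validation")

    # two null exposures: same SNP panel, no effect anywhere
    rng = np.random.default_rng(SEED + 2)
    nulls = []
    for name in ("NULL_A", "NULL_B"):
        df = sim.x.df.copy()
        df["beta"] = rng.normal(0, df["se"])
        df["pval"] = np.clip(2 * (1 - _phi(np.abs(df["beta"] / df["se"]))), 1e-300, 1)
        nulls.append(SumStatsTable(name, "continuous", df))

    for name, table in [("exposure_X", sim.x), ("mediator_M", sim.m),
                        ("outcome_Y", sim.y), ("outcome_Y_validation", y2),
                        ("exposure_NULL_A", nulls[0]), ("exposure_NULL_B", nulls[1])]:
        write_sumstats(table, OUT / f"{name}.tsv")
    pd.DataFrame(sim.ld.r2, index=sim.ld.snp_ids, columns=sim.ld.snp_ids).to_csv(
        OUT / "ld.tsv", sep="\t")
    with open(OUT / "truth.yaml", "w") as fh:
        yaml.safe_dump({
            "seed": SEED, "alpha": cfg.alpha, "b_true": cfg.b_true,
            "theta_direct": cfg.theta_direct, "tau_true": cfg.tau_true,
            "proportion_true": cfg.proportion_true,
        }, fh)

    print(f"wrote {cfg.J + cfg.j_mediator}-SNP tables for X, M, Y, "
          f"validation Y and two null exposures to {OUT}")
    print(f"true total effect {cfg.tau_true:.4f}, "
          f"true mediated proportion {100 * cfg.proportion_true:.1f}%")


def _phi(z):
    from scipy import stats
    return stats.norm.cdf(z)


if __name__ == "__main__":
    main()
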