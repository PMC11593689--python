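import numpy as np
import pandas as pd
import pytest

from medimr.sumstats_io import SumStatsTable


def make_table(records, trait_id="T", trait_type="continuous"):
    """Build a SumStatsTable from a list of dicts with sensible defaults."""
    rows = []
    for i, rec in enumerate(records):
        row = {
            "snp_id": f"rs{i + 1}", "chrom": "1", "pos": 1_000_000 + i * 100_000,
            "effect_allele": "A", "other_allele": "G",
            "beta": 0.1, "se": 0.01, "pval": 1e-9, "eaf": 0.3, "n": 100_000.0,
        }
        row.update(rec)
        rows.append(row)
    df = pd.DataFrame(rows)
    df["pos"] = pd.array(df["pos"], dtype="Int64")
    return SumStatsTable(trait_id, trait_type, df)


def random_pairs(rng, j, beta=0.3, se_scale=0.05):
    """A random harmonized-pairs instance with heterogeneous SEs."""
    g = rng.uniform(0.05, 0.5, j) * rng.choice([-1, 1], j)
    sg = rng.uniform(0.005, 0.02, j)
    sG = rng.uniform(0.5, 1.5, j) * se_scale
    G = beta * g + rng.normal(0, sG)
    return pd.DataFrame({
        "snp_id": [f"rs{i}" for i in range(j)],
        "beta_exp": g, "se_exp": sg, "beta_out": G, "se_out": sG,
    })


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
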