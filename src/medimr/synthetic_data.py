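"""Synthetic three-trait GWAS summary statistics with known causal structure.

The generator emulates the statistical structure of a two-step mediation MR
study: an exposure X with its own instruments, a mediator M influenced by X
(alpha) and by its own mediator-specific instruments, and an outcome Y
influenced by X directly (theta_direct) and through M (b_true). Summary
statistics are drawn directly from the asymptotic sampling distribution of
GWAS effect estimates — no individual-level genotypes — with per-SNP
standard errors se = 1/sqrt(2·maf·(1-maf)·n) and independent noise across
the three trait samples (the two-sample / non-overlap assumption). A binary
outcome is emulated on the log-odds scale directly.

Mediator-specific instruments are essential: univariable step-2 MR (M→Y)
with SNPs acting through X would estimate b + theta/alpha rather than b, so
the mediator must carry SNPs of its own (j_mediator, h2_m).

Optional hazards: horizontal pleiotropy on Y (balanced when pleio_mean = 0,
directional otherwise; InSIDE-violating when the pleiotropic effects are
correlated with instrument strength), AR(1) LD blocks (correlated true
effects, correlated sampling noise, and a matching r² matrix), and
allele-encoding corruptions to exercise harmonization.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import LdMatrix
from .sumstats_io import SumStatsTable

__all__ = ["SimConfig", "SimData", "simulate_sumstats", "resample_outcome",
           "corrupt_encoding", "derive_seed"]

# ordered non-palindromic allele pairs to draw from
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def derive_seed(base: int, *tokens) -> int:
    """Deterministically derive a sub-seed (< 2**31) from a base seed."""
    h = zlib.crc32(repr(tokens).encode(), base & 0xFFFFFFFF)
    return h % (2**31 - 1)


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for the synthetic three-trait world.

    J exposure instruments explain h2_x of X's variance; j_mediator
    mediator-specific instruments explain h2_m of M's. True effects:
    X→M = alpha, M→Y = b_true, direct X→Y = theta_direct, so the total
    effect is tau = theta_direct + alpha·b_true and the proportion mediated
    is alpha·b_true/tau. Defaults anchor tau at 0.1 with proportion 0.121.

    pleio_mean/pleio_sd control per-SNP direct effects on Y for the exposure
    instruments (balanced when mean 0, directional otherwise);
    inside_violated correlates them with instrument strength. pleio_m_sd
    adds SNP→M pleiotropy on exposure instruments. ld_block_size > 1 groups
    SNPs into AR(1) blocks with neighbour correlation ld_rho.
    harmonization_noise is the fraction of SNPs emitted with corrupted
    allele encodings (see :func:`corrupt_encoding`).
    """

    J: int = 30
    j_mediator: int = 30
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2_x: float = 0.05
    h2_m: float = 0.05
    alpha: float = 0.11
    b_true: float = 0.11
    theta_direct: float = 0.088
    pleio_mean: float = 0.0
    pleio_sd: float = 0.0
    pleio_m_sd: float = 0.0
    inside_violated: bool = False
    n_x: int = 300_000
    n_m: int = 300_000
    n_y: int = 300_000
    ld_block_size: int = 1
    ld_rho: float = 0.0
    harmonization_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.J < 1 or self.j_mediator < 0:
            raise ValueError("need J >= 1 exposure instruments")
        if not (0 < self.maf_range[0] < self.maf_range[1] <= 0.5):
            raise ValueError("maf_range must be an interval within (0, 0.5]")
        if not (0 < self.h2_x <= 1) or not (0 <= self.h2_m <= 1):
            raise ValueError("heritabilities must lie in (0, 1]")
        for n in (self.n_x, self.n_m, self.n_y):
            if n < 100:
                raise ValueError("sample sizes must be >= 100")
        if not (0 <= self.ld_rho < 1):
            raise ValueError("ld_rho must lie in [0, 1)")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if not (0 <= self.harmonization_noise <= 1):
            raise ValueError("harmonization_noise must lie in [0, 1]")

    @property
    def tau_true(self) -> float:
        return self.theta_direct + self.alpha * self.b_true

    @property
    def proportion_true(self) -> float | None:
        if self.tau_true == 0:
            return None
        return self.alpha * self.b_true / self.tau_true


@dataclass
class SimData:
    """Generator output: three tables, an r² matrix and the truth record."""

    x: SumStatsTable
    m: SumStatsTable
    y: SumStatsTable
    ld: LdMatrix
    truth: dict = field(default_factory=dict)


def _block_effects(rng, n_snps: int, block_size: int, rho: float,
                   mafs: np.ndarray, h2: float) -> np.ndarray:
    """True marginal effects with one causal signal per LD block.

    Block leads carry independent effects scaled so the leads jointly
    explain h2 of trait variance; tag SNPs carry the lead's effect
    attenuated by their AR(1) correlation with it (marginal = r · lead).
    """
    leads = np.arange(0, n_snps, block_size)
    raw = rng.normal(size=len(leads))
    var_unit = 2.0 * mafs[leads] * (1.0 - mafs[leads])
    scale = np.sqrt(h2 / np.sum(var_unit * raw**2)) if h2 > 0 else 0.0
    lead_eff = raw * scale
    eff = np.zeros(n_snps)
    for k, lead in enumerate(leads):
        stop = min(lead + block_size, n_snps)
        offsets = np.arange(stop - lead)
        eff[lead:stop] = (rho**offsets) * lead_eff[k]
    return eff


def _block_noise(rng, n_snps: int, block_size: int, rho: float) -> np.ndarray:
    """Standard-normal noise with AR(1) correlation within blocks."""
    z = rng.normal(size=n_snps)
    if rho == 0 or block_size == 1:
        return z
    out = np.empty(n_snps)
    for start in range(0, n_snps, block_size):
        stop = min(start + block_size, n_snps)
        k = stop - start
        corr = rho ** np.abs(np.subtract.outer(np.arange(k), np.arange(k)))
        out[start:stop] = np.linalg.cholesky(corr) @ z[start:stop]
    return out


def _observed(true_beta: np.ndarray, se: np.ndarray, noise: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray]:
    beta = true_beta + noise * se
    pval = 2.0 * stats.norm.sf(np.abs(beta / se))
    return beta, np.clip(pval, np.finfo(float).tiny, 1.0)


def _table(trait_id, trait_type, snp_ids, chrom, pos, ea, oa, beta, se, pval,
           maf, n) -> SumStatsTable:
    df = pd.DataFrame({
        "snp_id": snp_ids, "chrom": chrom, "pos": pd.array(pos, dtype="Int64"),
        "effect_allele": ea, "other_allele": oa,
        "beta": beta, "se": se, "pval": pval,
        "eaf": maf, "n": float(n),
    })
    return SumStatsTable(trait_id, trait_type, df)


def simulate_sumstats(config: SimConfig) -> SimData:
    """Generate the three-trait summary statistics and truth record.

    Same config (including seed) gives bit-identical output. The truth
    record carries the per-SNP true effects, SNP roles, tau_true and
    proportion_true.
    """
    rng = np.random.default_rng(config.seed)
    jx, jm = config.J, config.j_mediator
    n_snps = jx + jm

    mafs = rng.uniform(*config.maf_range, size=n_snps)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n_snps)
    ea = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])
    snp_ids = np.array([f"rs{i + 1:05d}" for i in range(n_snps)])

    # blocks laid out far apart (50 Mb) across chromosomes; 5 kb within block
    n_blocks = -(-n_snps // config.ld_block_size)
    chrom = np.empty(n_snps, dtype=object)
    pos = np.empty(n_snps, dtype=np.int64)
    for b in range(n_blocks):
        start = b * config.ld_block_size
        stop = min(start + config.ld_block_size, n_snps)
        chrom[start:stop] = str(b % 22 + 1)
        base = 1_000_000 + (b // 22) * 50_000_000
        pos[start:stop] = base + 5_000 * np.arange(stop - start)

    # true per-SNP effects: exposure instruments then mediator instruments
    gamma = np.zeros(n_snps)
    gamma[:jx] = _block_effects(rng, jx, config.ld_block_size, config.ld_rho,
                                mafs[:jx], config.h2_x)
    delta = np.zeros(n_snps)
    if jm:
        delta[jx:] = _block_effects(rng, jm, config.ld_block_size, config.ld_rho,
                                    mafs[jx:], config.h2_m)

    # pleiotropic direct effects on Y are expressed in the frame of the
    # exposure-increasing allele (sign(gamma)), so a non-zero pleio_mean is
    # directional in the orientation MR-Egger fits in
    pleio_y = np.zeros(n_snps)
    if config.pleio_sd > 0 or config.pleio_mean != 0:
        eps = rng.normal(size=jx)
        if config.inside_violated and gamma[:jx].std() > 0:
            ag = np.abs(gamma[:jx])
            zg = (ag - ag.mean()) / ag.std()
            eps = 0.7 * zg + np.sqrt(1 - 0.49) * eps
        orient = np.where(gamma[:jx] >= 0, 1.0, -1.0)
        pleio_y[:jx] = orient * (config.pleio_mean + config.pleio_sd * eps)
    pleio_m = np.zeros(n_snps)
    if config.pleio_m_sd > 0:
        pleio_m[:jx] = rng.normal(0.0, config.pleio_m_sd, size=jx)

    beta_x_true = gamma
    beta_m_true = config.alpha * gamma + delta + pleio_m
    beta_y_true = (config.tau_true * gamma + config.b_true * (delta + pleio_m)
                   + pleio_y)

    unit_var = 2.0 * mafs * (1.0 - mafs)
    se_x = 1.0 / np.sqrt(unit_var * config.n_x)
    se_m = 1.0 / np.sqrt(unit_var * config.n_m)
    se_y = 1.0 / np.sqrt(unit_var * config.n_y)

    bs, rho = config.ld_block_size, config.ld_rho
    bx, px = _observed(beta_x_true, se_x, _block_noise(rng, n_snps, bs, rho))
    bm, pm = _observed(beta_m_true, se_m, _block_noise(rng, n_snps, bs, rho))
    by, py = _observed(beta_y_true, se_y, _block_noise(rng, n_snps, bs, rho))

    x = _table("X", "continuous", snp_ids, chrom, pos, ea, oa, bx, se_x, px, mafs, config.n_x)
    m = _table("M", "continuous", snp_ids, chrom, pos, ea, oa, bm, se_m, pm, mafs, config.n_m)
    y = _table("Y", "binary", snp_ids, chrom, pos, ea, oa, by, se_y, py, mafs, config.n_y)

    if config.harmonization_noise > 0:
        cseed = derive_seed(config.seed, "corrupt")
        m, _ = corrupt_encoding(m, config.harmonization_noise, cseed)
        y, _ = corrupt_encoding(y, config.harmonization_noise, cseed)

    r2 = np.eye(n_snps)
    if bs > 1 and rho > 0:
        for start in range(0, n_snps, bs):
            stop = min(start + bs, n_snps)
            k = stop - start
            block = rho ** (2.0 * np.abs(np.subtract.outer(np.arange(k), np.arange(k))))
            r2[start:stop, start:stop] = block
    ld = LdMatrix(list(snp_ids), r2)

    truth = {
        "config": asdict(config),
        "tau_true": config.tau_true,
        "proportion_true": config.proportion_true,
        "gamma": gamma, "delta": delta,
        "pleio_y": pleio_y, "pleio_m": pleio_m,
        "role": np.where(np.arange(n_snps) < jx, "exposure_iv", "mediator_iv"),
        "snp_ids": snp_ids,
    }
    return SimData(x, m, y, ld, truth)


def resample_outcome(sim: SimData, seed: int, n_y: int | None = None,
                     trait_id: str = "Y_validation") -> SumStatsTable:
    """An independent outcome GWAS drawn from the same causal truth.

    Emulates a validation outcome dataset: identical true per-SNP effects,
    fresh sampling noise (optionally a different sample size). Alleles,
    frequencies and positions are taken from the uncorrupted exposure table.
    """
    cfg = SimConfig(**sim.truth["config"])
    n = n_y or cfg.n_y
    base = sim.x.df
    mafs = base["eaf"].to_numpy()
    beta_true = (cfg.tau_true * sim.truth["gamma"]
                 + cfg.b_true * (sim.truth["delta"] + sim.truth["pleio_m"])
                 + sim.truth["pleio_y"])
    se = 1.0 / np.sqrt(2.0 * mafs * (1.0 - mafs) * n)
    rng = np.random.default_rng(seed)
    noise = _block_noise(rng, len(base), cfg.ld_block_size, cfg.ld_rho)
    beta, pval = _observed(beta_true, se, noise)
    return _table(trait_id, "binary", base["snp_id"].to_numpy(),
                  base["chrom"].to_numpy(), base["pos"].to_numpy(),
                  base["effect_allele"].to_numpy(), base["other_allele"].to_numpy(),
                  beta, se, pval, mafs, n)


def corrupt_encoding(table: SumStatsTable, fraction: float, seed: int
                     ) -> tuple[SumStatsTable, pd.DataFrame]:
    """Re-encode a seeded subset of SNPs to exercise harmonization.

    Three corruption modes, chosen uniformly per selected SNP:

    - ``swap``: effect/other alleles swapped, beta negated, eaf
      complemented — a semantically identical record;
    - ``strand``: both alleles strand-complemented — the same variant
      reported on the opposite strand;
    - ``palindromic``: alleles replaced by A/T, making the strand
      unresolvable from alleles alone.

    Selection and modes depend only on (table length, seed), so corrupting
    two row-aligned tables with the same seed hits the same SNPs the same
    way. Returns the corrupted table and a ledger (snp_id, mode).
    """
    if not (0 <= fraction <= 1):
        raise ValueError("fraction must lie in [0, 1]")
    df = table.df.copy()
    rng = np.random.default_rng(seed)
    n = len(df)
    n_pick = round(fraction * n)
    picked = rng.choice(n, size=n_pick, replace=False) if n_pick else np.array([], dtype=int)
    modes = rng.choice(["swap", "strand", "palindromic"], size=n_pick)

    ledger = []
    for i, mode in zip(picked, modes):
        if mode == "swap":
            ea, oa = df.at[i, "effect_allele"], df.at[i, "other_allele"]
            df.at[i, "effect_allele"], df.at[i, "other_allele"] = oa, ea
            df.at[i, "beta"] = -df.at[i, "beta"]
            if not pd.isna(df.at[i, "eaf"]):
                df.at[i, "eaf"] = 1.0 - df.at[i, "eaf"]
        elif mode == "strand":
            df.at[i, "effect_allele"] = _COMPLEMENT[df.at[i, "effect_allele"]]
            df.at[i, "other_allele"] = _COMPLEMENT[df.at[i, "other_allele"]]
        else:
            df.at[i, "effect_allele"], df.at[i, "other_allele"] = "A", "T"
        ledger.append({"snp_id": df.at[i, "snp_id"], "mode": mode})

    out = SumStatsTable(table.trait_id, table.trait_type, df,
                        list(table.validation_log), dict(table.meta))
    return out, pd.DataFrame(ledger, columns=["snp_id", "mode"])
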