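"""Instrument selection: significance/MAF filtering, LD clumping, cis windows.

Thresholds follow standard two-sample MR practice: genome-wide significance
(relaxed to 5e-6 for discovery screens to keep enough instruments), greedy
LD clumping at r² < 0.001 within a 10,000 kb window, and a MAF floor of 0.01.
All inequalities are strict exactly as stated: retain p < threshold and
MAF > floor; prune a neighbour when r² >= threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sumstats_io import SumStatsTable

__all__ = [
    "SelectionParams", "LdMatrix", "MissingLdError",
    "significance_filter", "ld_clump", "cis_filter",
    "read_ld_square", "read_ld_long", "f_statistics",
]


@dataclass(frozen=True)
class SelectionParams:
    """Instrument-selection thresholds.

    p_threshold: retain p strictly below this (5e-8 default; 5e-6 for
    discovery screens). r2_threshold: prune neighbours with r² >= this.
    window_kb: clumping distance, SNPs further apart are never pruned.
    maf_min: retain minor-allele frequency strictly above this.
    """

    p_threshold: float = 5e-8
    r2_threshold: float = 0.001
    window_kb: int = 10_000
    maf_min: float = 0.01

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold <= 1):
            raise ValueError("p_threshold must be in (0,1]")
        if not (0 < self.r2_threshold < 1):
            raise ValueError("r2_threshold must be in (0,1)")
        if self.window_kb <= 0 or self.maf_min <= 0:
            raise ValueError("window_kb and maf_min must be positive")


#: Relaxed threshold used for the discovery exposure screen.
DISCOVERY = SelectionParams(p_threshold=5e-6)
#: Genome-wide threshold used for mediators and downstream steps.
STRICT = SelectionParams(p_threshold=5e-8)


class MissingLdError(KeyError):
    """A table SNP has no row/column in the LD matrix."""


@dataclass
class LdMatrix:
    """Squared-correlation (r²) matrix over named SNPs."""

    snp_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.snp_ids = list(self.snp_ids)
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.snp_ids)
        if self.r2.shape != (k, k):
            raise ValueError("r2 must be square over snp_ids")
        if not np.allclose(self.r2, self.r2.T, atol=1e-12):
            raise ValueError("r2 must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-12):
            raise ValueError("r2 diagonal must be 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
            raise ValueError("r2 values must lie in [0,1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def lookup(self, snp_a: str, snp_b: str) -> float:
        try:
            return float(self.r2[self._index[snp_a], self._index[snp_b]])
        except KeyError as exc:
            raise MissingLdError(f"SNP {exc.args[0]!r} absent from LD matrix") from exc

    def __contains__(self, snp: str) -> bool:
        return snp in self._index


def read_ld_square(path) -> LdMatrix:
    """Square TSV with header row = snp ids (first column = snp id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return LdMatrix(list(df.columns), df.to_numpy(dtype=float))


def read_ld_long(path) -> LdMatrix:
    """Long-format triple list ``snp_a<TAB>snp_b<TAB>r2``; absent pairs = 0."""
    df = pd.read_csv(path, sep="\t")
    snps = sorted(set(df.iloc[:, 0]) | set(df.iloc[:, 1]))
    idx = {s: i for i, s in enumerate(snps)}
    r2 = np.eye(len(snps))
    for a, b, v in df.itertuples(index=False):
        r2[idx[a], idx[b]] = r2[idx[b], idx[a]] = float(v)
    return LdMatrix(snps, r2)


def significance_filter(table: SumStatsTable, params: SelectionParams) -> SumStatsTable:
    """Retain records with p < p_threshold and min(eaf, 1-eaf) > maf_min.

    Records with missing eaf cannot be MAF-checked and are dropped; their
    count is recorded in the output's ``validation_log``.
    """
    df = table.df
    sig = df["pval"] < params.p_threshold
    has_eaf = df["eaf"].notna()
    maf_ok = has_eaf & (np.minimum(df["eaf"], 1 - df["eaf"]) > params.maf_min)
    n_missing = int((sig & ~has_eaf).sum())
    out = table.subset(
        (sig & maf_ok).to_numpy(),
        log=f"significance_filter: dropped {n_missing} significant record(s) with missing eaf",
    )
    if out.n_snps == 0:
        out.validation_log.append("significance_filter: WARNING empty output")
    return out


def ld_clump(table: SumStatsTable, ld: LdMatrix, params: SelectionParams) -> SumStatsTable:
    """Greedy p-value-ordered clumping.

    Repeatedly promote the remaining record with the smallest p-value (ties
    broken by chromosome then position) to index SNP, then discard remaining
    SNPs on the same chromosome within ``window_kb`` of it whose r² with it
    is >= ``r2_threshold``. Output is the index SNPs in selection order; a
    report of pruned SNPs is attached as ``meta["clump_report"]``.
    """
    df = table.df
    for snp in df["snp_id"]:
        if snp not in ld:
            raise MissingLdError(f"SNP {snp!r} absent from LD matrix")

    order = df.sort_values(["pval", "chrom", "pos"], kind="mergesort").index.to_list()
    window_bp = params.window_kb * 1000
    alive = set(order)
    index_rows: list[int] = []
    report: list[dict] = []
    for i in order:
        if i not in alive:
            continue
        alive.discard(i)
        index_rows.append(i)
        idx_snp = df.at[i, "snp_id"]
        idx_chrom, idx_pos = df.at[i, "chrom"], df.at[i, "pos"]
        for j in list(alive):
            if df.at[j, "chrom"] != idx_chrom:
                continue
            if abs(int(df.at[j, "pos"]) - int(idx_pos)) > window_bp:
                continue
            if ld.lookup(df.at[j, "snp_id"], idx_snp) >= params.r2_threshold:
                alive.discard(j)
                report.append({"removed": df.at[j, "snp_id"], "index_snp": idx_snp})

    out = SumStatsTable(table.trait_id, table.trait_type,
                        df.loc[index_rows].reset_index(drop=True),
                        list(table.validation_log), dict(table.meta))
    out.meta["clump_report"] = pd.DataFrame(report, columns=["removed", "index_snp"])
    return out


def cis_filter(table: SumStatsTable, gene_chrom: str, gene_start: int,
               gene_end: int, flank_kb: int = 10) -> SumStatsTable:
    """Retain SNPs within ``flank_kb`` of the gene body (closed interval)."""
    if gene_start > gene_end:
        raise ValueError("gene_start must be <= gene_end")
    lo = gene_start - flank_kb * 1000
    hi = gene_end + flank_kb * 1000
    df = table.df
    mask = (df["chrom"].astype(str) == str(gene_chrom)) & (df["pos"] >= lo) & (df["pos"] <= hi)
    return table.subset(mask.to_numpy(), log=f"cis_filter: kept {int(mask.sum())} of {len(df)}")


def f_statistics(table: SumStatsTable) -> pd.Series:
    """Per-instrument strength F = (beta/se)², reported for information only."""
    return (table.df["beta"] / table.df["se"]) ** 2
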