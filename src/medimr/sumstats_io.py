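"""Reading, validating and harmonizing GWAS-style summary statistics.

Summary statistics are held as pandas DataFrames with a canonical column
layout, wrapped in a light :class:`SumStatsTable` carrying trait metadata.
Harmonization aligns an exposure/outcome pair of tables onto the exposure's
effect-allele frame, resolving swapped alleles and strand flips and applying
a configurable policy to palindromic (A/T, C/G) variants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SumStatsTable",
    "SumStatsError",
    "ConfigError",
    "EmptyInputError",
    "EmptyOverlapError",
    "CANONICAL_COLUMNS",
    "DEFAULT_COLUMN_MAP",
    "read_sumstats",
    "write_sumstats",
    "harmonize",
    "kept_pairs",
    "or_ci_to_logscale",
]

# canonical internal field -> canonical file header
CANONICAL_COLUMNS = (
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "beta", "se", "pval", "eaf", "n",
)

#: Built-in mapping for the common SNP/CHR/BP/EA/OA/BETA/SE/P/EAF/N dialect.
DEFAULT_COLUMN_MAP = {
    "snp_id": "SNP", "chrom": "CHR", "pos": "BP",
    "effect_allele": "EA", "other_allele": "OA",
    "beta": "BETA", "se": "SE", "pval": "P", "eaf": "EAF", "n": "N",
}

_MANDATORY = ("snp_id", "chrom", "pos", "effect_allele", "other_allele",
              "beta", "se", "pval")
_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC_SETS = (frozenset("AT"), frozenset("CG"))


class SumStatsError(Exception):
    """Base error for summary-statistics handling."""


class ConfigError(SumStatsError):
    """Missing mandatory column or invalid configuration."""


class EmptyInputError(SumStatsError):
    """A table ended up with zero valid rows."""


class EmptyOverlapError(SumStatsError):
    """Exposure and outcome share no SNP ids."""


@dataclass
class SumStatsTable:
    """One trait's GWAS/pQTL/eQTL summary statistics.

    ``df`` uses the canonical columns ``snp_id, chrom, pos, effect_allele,
    other_allele, beta, se, pval, eaf, n``; ``eaf`` and ``n`` may be NaN.
    ``trait_type`` is ``"continuous"`` or ``"binary"``; for binary traits the
    betas are log odds ratios throughout (OR is a display transform only).
    """

    trait_id: str
    trait_type: str
    df: pd.DataFrame
    validation_log: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ConfigError(f"trait_type must be continuous|binary, got {self.trait_type!r}")
        missing = [c for c in CANONICAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ConfigError(f"table missing canonical columns: {missing}")

    @property
    def n_snps(self) -> int:
        return len(self.df)

    def subset(self, mask, log: str | None = None) -> "SumStatsTable":
        """New table restricted to ``mask`` rows, preserving order."""
        out = SumStatsTable(self.trait_id, self.trait_type,
                            self.df.loc[mask].reset_index(drop=True),
                            list(self.validation_log), dict(self.meta))
        if log:
            out.validation_log.append(log)
        return out


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Row-level invariant checks. Returns (valid rows, log of rejects)."""
    log: list[str] = []
    keep = np.ones(len(df), dtype=bool)

    def reject(bad: np.ndarray, reason: str) -> None:
        for i in np.nonzero(bad & keep)[0]:
            log.append(f"row {i + 1}: rejected ({reason})")
        keep[bad] = False

    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper().str.strip()
    reject(~df["effect_allele"].isin(_VALID_ALLELES).to_numpy(), "effect_allele not in A/C/G/T")
    reject(~df["other_allele"].isin(_VALID_ALLELES).to_numpy(), "other_allele not in A/C/G/T")
    reject((df["effect_allele"] == df["other_allele"]).to_numpy(), "effect_allele == other_allele")

    for col in ("beta", "se", "pval", "eaf"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    reject(df["beta"].isna().to_numpy(), "beta missing/non-numeric")
    reject(~(df["se"] > 0).to_numpy(), "se must be > 0")
    reject(~((df["pval"] > 0) & (df["pval"] <= 1)).to_numpy(), "pval outside (0,1]")
    eaf_bad = (~df["eaf"].isna()) & ~((df["eaf"] > 0) & (df["eaf"] < 1))
    reject(eaf_bad.to_numpy(), "eaf outside (0,1)")

    dup = df["snp_id"].duplicated(keep="first").to_numpy()
    reject(dup, "duplicate snp_id (first occurrence kept)")

    return df.loc[keep].reset_index(drop=True), log


def read_sumstats(path, column_map: dict[str, str] | None = None,
                  trait_type: str = "continuous", trait_id: str | None = None,
                  delimiter: str | None = None) -> SumStatsTable:
    """Read a delimited summary-statistics table.

    ``column_map`` maps canonical field names to the file's column headers;
    defaults to the SNP/CHR/BP/EA/OA/BETA/SE/P/EAF/N dialect. The delimiter
    is auto-detected (tab or comma) unless given. Rows violating per-record
    invariants are rejected and reported in ``validation_log`` with their
    1-based data-row numbers.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    if delimiter is None:
        with open(path) as fh:
            header = fh.readline()
        delimiter = "\t" if header.count("\t") >= header.count(",") else ","

    raw = pd.read_csv(path, sep=delimiter, dtype={cmap["snp_id"]: str}, na_values=["NA"])
    missing = [cmap[f] for f in _MANDATORY if cmap[f] not in raw.columns]
    if missing:
        raise ConfigError(f"{path}: missing mandatory column(s) {missing}")

    df = pd.DataFrame()
    for fld in CANONICAL_COLUMNS:
        col = cmap.get(fld)
        df[fld] = raw[col] if col in raw.columns else np.nan
    df["snp_id"] = df["snp_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce").astype("Int64")
    df["n"] = pd.to_numeric(df["n"], errors="coerce")

    df, log = _validate_rows(df)
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no valid rows after validation")
    return SumStatsTable(trait_id or str(path), trait_type, df, log)


def write_sumstats(table: SumStatsTable, path) -> None:
    """Write a table as canonical TSV; missing eaf/n emitted as ``NA``.

    Floats are written with shortest-repr precision so that
    ``read_sumstats(write_sumstats(t))`` reproduces every field exactly.
    """
    out = table.df.copy()
    out.columns = [DEFAULT_COLUMN_MAP[c] for c in CANONICAL_COLUMNS]
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def _is_palindromic(a1: str, a2: str) -> bool:
    return frozenset((a1, a2)) in _PALINDROMIC_SETS


def harmonize(exposure: SumStatsTable, outcome: SumStatsTable,
              palindrome_policy: str = "drop_ambiguous",
              freq_threshold: float = 0.42) -> pd.DataFrame:
    """Align outcome effects onto the exposure's effect-allele frame.

    For each SNP shared by both tables the outcome record is matched to the
    exposure's allele pair directly, after swapping effect/other alleles
    (sign-flipping the outcome beta and complementing its frequency), and/or
    after strand complementation. Palindromic SNPs (A/T or C/G), whose strand
    cannot be resolved from alleles, are handled per ``palindrome_policy``:

    - ``drop_all``: always dropped;
    - ``drop_ambiguous``: orientation inferred from allele frequencies, but
      SNPs with either frequency inside ``[freq_threshold, 1-freq_threshold]``
      (or missing) are dropped as unresolvable;
    - ``infer_by_freq``: orientation always inferred from frequencies
      (missing frequency still drops).

    The exposure beta is never modified: its effect allele defines the frame.

    Returns a DataFrame with columns ``snp_id, chrom, pos, effect_allele,
    other_allele, eaf, beta_exp, se_exp, pval_exp, beta_out, se_out,
    pval_out, eaf_out, action``; rows whose ``action`` begins ``dropped_``
    must be excluded downstream (see :func:`kept_pairs`).
    """
    if palindrome_policy not in ("drop_all", "drop_ambiguous", "infer_by_freq"):
        raise ConfigError(f"unknown palindrome policy {palindrome_policy!r}")

    e = exposure.df.set_index("snp_id")
    o = outcome.df.set_index("snp_id")
    shared = e.index.intersection(o.index)
    if len(shared) == 0:
        raise EmptyOverlapError(
            f"no shared SNPs between {exposure.trait_id} and {outcome.trait_id}")
    # preserve exposure row order
    shared = [s for s in e.index if s in set(shared)]

    lo, hi = freq_threshold, 1.0 - freq_threshold
    rows = []
    for snp in shared:
        er, orow = e.loc[snp], o.loc[snp]
        ea_e, oa_e = er["effect_allele"], er["other_allele"]
        ea_o, oa_o = orow["effect_allele"], orow["other_allele"]
        beta_o, eaf_o = float(orow["beta"]), orow["eaf"]
        action = None

        if _is_palindromic(ea_e, oa_e):
            if {ea_o, oa_o} != {ea_e, oa_e}:
                action = "dropped_mismatch"
            elif palindrome_policy == "drop_all":
                action = "dropped_palindromic"
            else:
                eaf_e = er["eaf"]
                if pd.isna(eaf_e) or pd.isna(eaf_o):
                    action = "dropped_palindromic"
                else:
                    # align textually first (listed alleles may be swapped)
                    flipped = False
                    if ea_o != ea_e:
                        beta_o, eaf_o, flipped = -beta_o, 1.0 - eaf_o, True
                    ambiguous = (lo <= eaf_e <= hi) or (lo <= eaf_o <= hi)
                    if palindrome_policy == "drop_ambiguous" and ambiguous:
                        action = "dropped_palindromic"
                    else:
                        # frequencies on opposite sides of 0.5 => strand flip
                        if (eaf_e - 0.5) * (eaf_o - 0.5) < 0:
                            beta_o, eaf_o, flipped = -beta_o, 1.0 - eaf_o, not flipped
                        action = "flipped" if flipped else "kept_as_is"
        else:
            if (ea_o, oa_o) == (ea_e, oa_e):
                action = "kept_as_is"
            elif (ea_o, oa_o) == (oa_e, ea_e):
                action = "flipped"
                beta_o = -beta_o
                if not pd.isna(eaf_o):
                    eaf_o = 1.0 - eaf_o
            else:
                ca, cb = _COMPLEMENT[ea_o], _COMPLEMENT[oa_o]
                if (ca, cb) == (ea_e, oa_e):
                    action = "kept_as_is"
                elif (ca, cb) == (oa_e, ea_e):
                    action = "flipped"
                    beta_o = -beta_o
                    if not pd.isna(eaf_o):
                        eaf_o = 1.0 - eaf_o
                else:
                    action = "dropped_mismatch"

        rows.append({
            "snp_id": snp, "chrom": er["chrom"], "pos": er["pos"],
            "effect_allele": ea_e, "other_allele": oa_e, "eaf": er["eaf"],
            "beta_exp": float(er["beta"]), "se_exp": float(er["se"]),
            "pval_exp": float(er["pval"]),
            "beta_out": beta_o, "se_out": float(orow["se"]),
            "pval_out": float(orow["pval"]), "eaf_out": eaf_o,
            "action": action,
        })
    return pd.DataFrame(rows)


def kept_pairs(harmonized: pd.DataFrame) -> pd.DataFrame:
    """Rows retained for analysis (action not ``dropped_*``)."""
    keep = ~harmonized["action"].str.startswith("dropped")
    return harmonized.loc[keep].reset_index(drop=True)


def or_ci_to_logscale(or_point: float, ci_low: float, ci_high: float,
                      level: float = 0.95) -> tuple[float, float]:
    """Invert an OR with CI to (log-odds beta, SE).

    ``beta = ln(OR)``; ``se = (ln(hi) - ln(lo)) / (2 z*)`` with ``z*`` the
    exact standard-normal quantile for ``level``.
    """
    if min(or_point, ci_low, ci_high) <= 0:
        raise ValueError("odds ratios must be positive")
    if not (ci_low <= or_point <= ci_high):
        raise ValueError("require ci_low <= or_point <= ci_high")
    zstar = stats.norm.ppf(0.5 + level / 2.0)
    beta = math.log(or_point)
    se = (math.log(ci_high) - math.log(ci_low)) / (2.0 * zstar)
    return beta, se
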