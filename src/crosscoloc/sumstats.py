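"""GWAS summary-statistics IO, validation, filtering and cross-trait harmonization.

A summary-statistics table holds one trait's per-variant association results
(effect size on the log-odds scale, its standard error, p-value, MAF and
imputation info score).  Two traits are compared on their shared variants
after aligning effect alleles, so that the sign of the effect means the same
thing in both tables.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Required columns of the tab-delimited summary-statistics format.
COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pvalue",
    "maf",
    "info",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Smallest positive double; p-values of exactly 0 are clamped here so that
#: downstream log transforms stay finite.
TINY_P = sys.float_info.min


class SumStatsError(ValueError):
    """Fatal problem with a summary-statistics input."""


@dataclass
class SumStatsTable:
    """Validated per-variant association results for one trait.

    ``df`` is sorted by (chrom, pos) and has one row per variant_id.
    """

    trait_name: str
    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise SumStatsError(f"missing required column(s): {', '.join(missing)}")
        self.df = self.df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        if self.df["variant_id"].duplicated().any():
            dups = self.df.loc[self.df["variant_id"].duplicated(), "variant_id"].tolist()
            raise SumStatsError(f"duplicate variant_id(s): {dups[:5]}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def variant_ids(self) -> pd.Series:
        return self.df["variant_id"]


@dataclass
class PairedTable:
    """Two traits' statistics on their shared variants, effect alleles aligned.

    ``beta_b`` has already been sign-flipped wherever trait B reported the
    effect for the opposite allele, so sign(beta_a) and sign(beta_b) are
    directly comparable.  ``n_ambiguous`` counts shared variants dropped
    because their allele pair could not be oriented (palindromic mismatches
    or incompatible allele sets).
    """

    trait_a: str
    trait_b: str
    df: pd.DataFrame = field(repr=False)
    n_ambiguous: int = 0

    def __len__(self) -> int:
        return len(self.df)


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop rows violating the per-variant invariants; return (kept, n_dropped)."""
    n_clamped = int((df["pvalue"] == 0).sum())
    if n_clamped:
        logger.warning("clamping %d zero p-value(s) to %.3e", n_clamped, TINY_P)
        df = df.copy()
        df.loc[df["pvalue"] == 0, "pvalue"] = TINY_P
    ok = (
        (df["pos"] >= 1)
        & (df["se"] > 0)
        & (df["pvalue"] > 0)
        & (df["pvalue"] <= 1)
        & (df["maf"] > 0)
        & (df["maf"] <= 0.5)
        & (df["info"] >= 0)
        & (df["info"] <= 1)
        & (df["effect_allele"] != df["other_allele"])
        & df[COLUMNS].notna().all(axis=1)
    )
    n_dropped = int((~ok).sum())
    return df[ok], n_dropped


def read_sumstats(path, trait_name: str) -> SumStatsTable:
    """Read a tab-delimited summary-statistics file.

    Rows violating the record invariants (non-positive SE, p outside (0,1],
    MAF outside (0,0.5], identical alleles, ...) are dropped with a logged
    count; a missing required column or an empty file is fatal.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            dtype={"chrom": str, "variant_id": str},
            float_precision="round_trip",
        )
    except pd.errors.EmptyDataError:
        raise SumStatsError(f"empty summary-statistics file: {path}") from None
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SumStatsError(f"{path}: missing required column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise SumStatsError(f"{path}: no data rows")
    df, n_dropped = _validate_rows(df)
    if n_dropped:
        logger.info("%s: dropped %d invalid row(s)", path, n_dropped)
    return SumStatsTable(trait_name, df[COLUMNS])


def write_sumstats(table: SumStatsTable, path) -> None:
    """Write the tab-delimited format read by :func:`read_sumstats`.

    Floats are written with 17 significant digits so a write/read cycle
    reproduces every field exactly.
    """
    table.df[COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.17g")


def filter_variants(
    table: SumStatsTable, maf_min: float = 0.01, info_min: float = 0.8
) -> SumStatsTable:
    """Keep variants with MAF strictly above ``maf_min`` and info score
    strictly above ``info_min`` (the usual post-imputation QC)."""
    df = table.df
    kept = df[(df["maf"] > maf_min) & (df["info"] > info_min)]
    return SumStatsTable(table.trait_name, kept.reset_index(drop=True))


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def harmonize(a: SumStatsTable, b: SumStatsTable) -> PairedTable:
    """Intersect two tables on variant_id and align trait B's effect allele
    to trait A's.

    Orientation rules, applied per shared variant:

    * same alleles                          -> keep beta_b;
    * swapped effect/other alleles          -> negate beta_b;
    * strand complement of either pattern   -> as above (non-palindromic only);
    * anything else, or a palindromic SNP whose alleles do not match exactly
      -> dropped and counted as ambiguous (strand cannot be resolved without
      allele-frequency logic).
    """
    da = a.df.set_index("variant_id")
    db = b.df.set_index("variant_id")
    shared = da.index.intersection(db.index)
    if len(shared) == 0:
        raise SumStatsError(
            f"no shared variants between {a.trait_name!r} ({len(a)} variants) "
            f"and {b.trait_name!r} ({len(b)} variants)"
        )
    da = da.loc[shared]
    db = db.loc[shared]

    ea_a = da["effect_allele"].to_numpy()
    oa_a = da["other_allele"].to_numpy()
    ea_b = db["effect_allele"].to_numpy()
    oa_b = db["other_allele"].to_numpy()

    comp = np.vectorize(lambda x: _COMPLEMENT.get(x, "?"))
    ea_b_c = comp(ea_b)
    oa_b_c = comp(oa_b)
    palin = np.array([_is_palindromic(x, y) for x, y in zip(ea_a, oa_a)])

    same = (ea_b == ea_a) & (oa_b == oa_a)
    swap = (ea_b == oa_a) & (oa_b == ea_a)
    same_c = (ea_b_c == ea_a) & (oa_b_c == oa_a)
    swap_c = (ea_b_c == oa_a) & (oa_b_c == ea_a)

    # Palindromic SNPs: only an exact allele match is unambiguous (a swap is
    # indistinguishable from a strand flip).
    keep_sign = same | (same_c & ~palin)
    flip_sign = (~keep_sign) & ((swap & ~palin) | (swap_c & ~palin))
    resolved = keep_sign | flip_sign
    n_ambiguous = int((~resolved).sum())
    if n_ambiguous:
        logger.info(
            "harmonize(%s, %s): dropped %d allele-ambiguous variant(s)",
            a.trait_name,
            b.trait_name,
            n_ambiguous,
        )

    sign = np.where(flip_sign, -1.0, 1.0)
    out = pd.DataFrame(
        {
            "variant_id": shared,
            "chrom": da["chrom"].to_numpy(),
            "pos": da["pos"].to_numpy(),
            "beta_a": da["beta"].to_numpy(),
            "se_a": da["se"].to_numpy(),
            "p_a": da["pvalue"].to_numpy(),
            "beta_b": db["beta"].to_numpy() * sign,
            "se_b": db["se"].to_numpy(),
            "p_b": db["pvalue"].to_numpy(),
            "maf": da["maf"].to_numpy(),
        }
    )
    out = out[resolved].sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return PairedTable(a.trait_name, b.trait_name, out, n_ambiguous=n_ambiguous)
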