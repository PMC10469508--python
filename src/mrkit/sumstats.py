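"""Reading, validating, and pairing GWAS summary-statistics tables.

A summary-statistics table holds one row per SNP: rsid, effect allele,
other allele, effect-allele frequency (EAF), additive effect estimate
(beta; SD units for continuous traits, log odds for binary traits), its
standard error, p-value, and per-SNP sample size.  Rows violating the
type invariants are dropped and logged rather than raising, because
public GWAS downloads routinely contain indels, duplicated rsids, and
missing allele frequencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyInputError, NoOverlapError

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")

#: Canonical internal column order; all intermediate TSVs use it.
CANONICAL_COLUMNS = [
    "rsid",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
]

#: Default header names found in public summary-statistics exports.
DEFAULT_COLUMN_MAP = {
    "rsid": "SNP",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pvalue": "pval",
    "n": "samplesize",
}

_TINY_P = float(np.nextafter(0.0, 1.0))


@dataclass(frozen=True)
class SnpAssociation:
    """One SNP's marginal association with one trait."""

    rsid: str
    effect_allele: str
    other_allele: str
    eaf: float  # NaN when missing (record is flagged, not dropped)
    beta: float
    se: float
    pvalue: float
    n: int

    @property
    def eaf_missing(self) -> bool:
        return not np.isfinite(self.eaf)


@dataclass
class SummaryStatsTable:
    """A validated per-SNP association table for one trait.

    ``df`` holds the canonical columns; rsids are unique.  ``exclusions``
    records every input row that was dropped, as ``(rsid, reason)``.
    """

    trait_name: str
    trait_type: str = "continuous"  # continuous | binary
    n_total: int = 0
    n_cases: int | None = None
    df: pd.DataFrame = field(default_factory=pd.DataFrame)
    exclusions: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ConfigurationError(
                f"trait_type must be continuous or binary, got {self.trait_type!r}"
            )
        if self.n_cases is not None and self.n_cases > self.n_total:
            raise ConfigurationError("n_cases exceeds n_total")
        if len(self.df) and self.df["rsid"].duplicated().any():
            raise ConfigurationError("duplicate rsids in table")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def rsids(self) -> set[str]:
        return set(self.df["rsid"])

    @property
    def records(self) -> Iterator[SnpAssociation]:
        for row in self.df.itertuples(index=False):
            yield SnpAssociation(
                rsid=row.rsid,
                effect_allele=row.effect_allele,
                other_allele=row.other_allele,
                eaf=row.eaf,
                beta=row.beta,
                se=row.se,
                pvalue=row.pvalue,
                n=int(row.n),
            )

    def subset(self, rsids) -> "SummaryStatsTable":
        """New table restricted to ``rsids`` (input order preserved)."""
        keep = self.df[self.df["rsid"].isin(set(rsids))].reset_index(drop=True)
        return replace(self, df=keep, exclusions=[])


def _detect_delimiter(path: Path) -> str:
    header = path.open().readline()
    return "\t" if "\t" in header else ","


def read_sumstats(
    path,
    column_map: dict | None = None,
    trait_meta: dict | None = None,
) -> SummaryStatsTable:
    """Read a delimited summary-statistics file into a validated table.

    Parameters
    ----------
    path
        TSV or CSV file with a header (tab preferred, comma fallback).
    column_map
        Mapping from canonical field name to the file's column name;
        missing keys fall back to :data:`DEFAULT_COLUMN_MAP`.
    trait_meta
        Keys ``trait_name``, ``trait_type``, ``n_total``, ``n_cases``.

    Rows that violate the field invariants (non-ACGT or identical
    alleles, non-positive SE, p outside (0, 1], EAF outside (0, 1),
    non-positive N) are dropped and logged with a reason; duplicate
    rsids keep the first occurrence; p-values of exactly zero are
    clamped to the smallest positive float and logged.  Missing EAF is
    permitted but flagged (NaN), making the record ineligible for
    palindrome resolution and strength computation downstream.
    """
    path = Path(path)
    user_map = column_map or {}
    meta = trait_meta or {}

    raw = pd.read_csv(path, sep=_detect_delimiter(path), dtype=str)
    # resolution order per field: explicit mapping, conventional public
    # header name, canonical name (so our own TSVs read back unmapped)
    cmap, missing = {}, []
    for canon in CANONICAL_COLUMNS:
        if canon in user_map:
            candidates = [user_map[canon]]
        else:
            candidates = [DEFAULT_COLUMN_MAP[canon], canon]
        found = next((c for c in candidates if c in raw.columns), None)
        if found is None:
            missing.append(candidates[0])
        else:
            cmap[canon] = found
    if missing:
        raise ConfigurationError(
            f"{path}: mapped column(s) not found: {', '.join(missing)}"
        )

    df = pd.DataFrame(
        {canon: raw[src].to_numpy() for canon, src in cmap.items()}
    )
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper().str.strip()
    df["other_allele"] = df["other_allele"].astype(str).str.upper().str.strip()
    for col in ("eaf", "beta", "se", "pvalue", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    exclusions: list[tuple[str, str]] = []

    def drop(mask: pd.Series, reason: str) -> None:
        nonlocal df
        for rsid in df.loc[mask, "rsid"]:
            exclusions.append((str(rsid), reason))
            logger.info("%s: dropped %s (%s)", path.name, rsid, reason)
        df = df[~mask]

    bad_allele = (
        ~df["effect_allele"].isin(VALID_ALLELES)
        | ~df["other_allele"].isin(VALID_ALLELES)
        | (df["effect_allele"] == df["other_allele"])
    )
    drop(bad_allele, "invalid_alleles")
    drop(~(df["se"] > 0), "nonpositive_se")
    drop(~np.isfinite(df["beta"]), "invalid_beta")
    drop(~(df["n"] > 0) | ~np.isfinite(df["n"]), "invalid_n")
    # present-but-out-of-range EAF is unusable; absent EAF is only flagged
    eaf_present = np.isfinite(df["eaf"])
    drop(eaf_present & ~((df["eaf"] > 0) & (df["eaf"] < 1)), "invalid_eaf")

    zero_p = df["pvalue"] == 0
    if zero_p.any():
        for rsid in df.loc[zero_p, "rsid"]:
            logger.info("%s: clamped zero p-value for %s", path.name, rsid)
        df.loc[zero_p, "pvalue"] = _TINY_P
    drop(~((df["pvalue"] > 0) & (df["pvalue"] <= 1)), "invalid_pvalue")

    dup = df["rsid"].duplicated(keep="first")
    drop(dup, "duplicate_rsid")

    if df.empty:
        raise EmptyInputError(f"{path}: no valid rows after validation")

    df = df[CANONICAL_COLUMNS].reset_index(drop=True)
    df["n"] = df["n"].round().astype(int)
    return SummaryStatsTable(
        trait_name=meta.get("trait_name", path.stem),
        trait_type=meta.get("trait_type", "continuous"),
        n_total=int(meta.get("n_total", df["n"].max())),
        n_cases=meta.get("n_cases"),
        df=df,
        exclusions=exclusions,
    )


def write_sumstats(table: SummaryStatsTable, path) -> None:
    """Write the canonical TSV (fixed column order, tab-delimited)."""
    table.df[CANONICAL_COLUMNS].to_csv(path, sep="\t", index=False)


def merge_on_rsid(
    exposure: SummaryStatsTable, outcome: SummaryStatsTable
) -> pd.DataFrame:
    """Pair exposure and outcome associations on their rsid intersection.

    Returns one row per shared rsid (sorted by rsid) with suffixes
    ``_exp`` / ``_out``; both allele codings are carried through
    untouched for the harmonization step.
    """
    merged = exposure.df.merge(
        outcome.df, on="rsid", suffixes=("_exp", "_out"), how="inner"
    )
    if merged.empty:
        raise NoOverlapError(
            f"no shared rsids between {exposure.trait_name!r} "
            f"and {outcome.trait_name!r}"
        )
    return merged.sort_values("rsid", kind="mergesort").reset_index(drop=True)
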