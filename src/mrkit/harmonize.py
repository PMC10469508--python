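"""Allele harmonization: align exposure and outcome records to a shared
effect allele before any effects are combined.

Allele pairs are compared with strand complements allowed (A↔T, C↔G).
Palindromic variants (A/T or C/G pairs) are flagged before any same/
flipped verdict, because strand cannot be resolved from the labels
alone; they are aligned by allele-frequency concordance when both EAFs
sit clearly away from 0.5 and dropped as ambiguous otherwise.
Incompatible pairs (alleles that match under neither identity, swap,
complement, nor complement-swap) are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, HarmonizationEmptiedError

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMES = ({"A", "T"}, {"C", "G"})

#: Default EAF window in which a palindromic SNP's strand is unresolvable.
DEFAULT_AMBIGUOUS_EAF_WINDOW = (0.42, 0.58)

HARMONIZED_COLUMNS = [
    "rsid",
    "effect_allele",
    "other_allele",
    "beta_exp",
    "se_exp",
    "eaf_exp",
    "pvalue_exp",
    "beta_out",
    "se_out",
    "eaf_out",
    "pvalue_out",
    "action",
]


def classify_alleles(ea_x: str, oa_x: str, ea_y: str, oa_y: str) -> str:
    """Relationship of the outcome coding (y) to the exposure coding (x):
    ``same`` | ``flipped`` | ``palindromic`` | ``incompatible``."""
    alleles = (ea_x, oa_x, ea_y, oa_y)
    if any(a not in COMPLEMENT for a in alleles):
        raise ConfigurationError(f"non-ACGT allele in {alleles}")
    if ea_x == oa_x or ea_y == oa_y:
        raise ConfigurationError(f"identical alleles in {alleles}")

    if {ea_x, oa_x} in _PALINDROMES:
        # strand-ambiguous regardless of the outcome labels
        return "palindromic" if {ea_y, oa_y} == {ea_x, oa_x} else "incompatible"

    cy = (COMPLEMENT[ea_y], COMPLEMENT[oa_y])
    if (ea_y, oa_y) == (ea_x, oa_x) or cy == (ea_x, oa_x):
        return "same"
    if (oa_y, ea_y) == (ea_x, oa_x) or (cy[1], cy[0]) == (ea_x, oa_x):
        return "flipped"
    return "incompatible"


@dataclass
class HarmonizedSet:
    """Exposure/outcome effect pairs aligned to a common effect allele;
    the unit of all downstream estimation."""

    exposure: str
    outcome: str
    df: pd.DataFrame  # HARMONIZED_COLUMNS, one row per retained SNP
    drop_log: dict[str, str] = field(default_factory=dict)

    @property
    def n_snp(self) -> int:
        return len(self.df)

    @property
    def rsids(self) -> list[str]:
        return list(self.df["rsid"])

    def arrays(self):
        """(beta_exp, se_exp, beta_out, se_out) as float arrays."""
        d = self.df
        return (
            d["beta_exp"].to_numpy(float),
            d["se_exp"].to_numpy(float),
            d["beta_out"].to_numpy(float),
            d["se_out"].to_numpy(float),
        )

    def drop(self, rsids) -> "HarmonizedSet":
        """New set without ``rsids`` (drop log left untouched)."""
        rsids = set(rsids)
        keep = self.df[~self.df["rsid"].isin(rsids)].reset_index(drop=True)
        return replace(self, df=keep, drop_log=dict(self.drop_log))

    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def _in_window(eaf: float, window: tuple[float, float]) -> bool:
    return window[0] <= eaf <= window[1]


def harmonize_set(
    pairs: pd.DataFrame,
    ambiguous_eaf_window: tuple[float, float] = DEFAULT_AMBIGUOUS_EAF_WINDOW,
    exposure: str = "exposure",
    outcome: str = "outcome",
) -> HarmonizedSet:
    """Harmonize merged exposure/outcome rows (from ``merge_on_rsid``).

    Per pair: ``same`` codings are copied; ``flipped`` codings have the
    outcome beta negated and EAF complemented; palindromic pairs are
    dropped when either EAF falls inside ``ambiguous_eaf_window`` (or is
    missing) and otherwise aligned by EAF concordance; incompatible
    pairs are dropped.  Raises if nothing survives.
    """
    lo, hi = ambiguous_eaf_window
    if not 0 <= lo <= hi <= 1:
        raise ConfigurationError("ambiguous_eaf_window must be an interval in [0, 1]")

    rows = []
    drop_log: dict[str, str] = {}
    for row in pairs.itertuples(index=False):
        try:
            verdict = classify_alleles(
                row.effect_allele_exp,
                row.other_allele_exp,
                row.effect_allele_out,
                row.other_allele_out,
            )
        except ConfigurationError:
            verdict = "incompatible"

        beta_out, eaf_out, pval_out = row.beta_out, row.eaf_out, row.pvalue_out
        action = "unchanged"

        if verdict == "incompatible":
            drop_log[row.rsid] = "incompatible"
            continue
        if verdict == "flipped":
            beta_out = -beta_out
            eaf_out = 1.0 - eaf_out if np.isfinite(eaf_out) else eaf_out
            action = "outcome_flipped"
        elif verdict == "palindromic":
            eafs = (row.eaf_exp, row.eaf_out)
            if not all(np.isfinite(e) for e in eafs) or any(
                _in_window(e, ambiguous_eaf_window) for e in eafs
            ):
                drop_log[row.rsid] = "palindromic_ambiguous"
                continue
            if (row.eaf_exp - 0.5) * (row.eaf_out - 0.5) < 0:
                beta_out = -beta_out
                eaf_out = 1.0 - eaf_out
                action = "outcome_flipped"

        rows.append(
            (
                row.rsid,
                row.effect_allele_exp,
                row.other_allele_exp,
                row.beta_exp,
                row.se_exp,
                row.eaf_exp,
                row.pvalue_exp,
                beta_out,
                row.se_out,
                eaf_out,
                pval_out,
                action,
            )
        )

    if not rows:
        raise HarmonizationEmptiedError(
            f"harmonization removed every SNP for {exposure!r} → {outcome!r}"
        )
    df = pd.DataFrame(rows, columns=HARMONIZED_COLUMNS)
    for rsid, reason in drop_log.items():
        logger.info("%s → %s: dropped %s (%s)", exposure, outcome, rsid, reason)
    return HarmonizedSet(exposure=exposure, outcome=outcome, df=df, drop_log=drop_log)


def as_pairs(hset: HarmonizedSet) -> pd.DataFrame:
    """Re-express a harmonized set in the merged-pairs layout, both
    sides sharing the exposure coding (useful for idempotence checks)."""
    d = hset.df
    return pd.DataFrame(
        {
            "rsid": d["rsid"],
            "effect_allele_exp": d["effect_allele"],
            "other_allele_exp": d["other_allele"],
            "eaf_exp": d["eaf_exp"],
            "beta_exp": d["beta_exp"],
            "se_exp": d["se_exp"],
            "pvalue_exp": d["pvalue_exp"],
            "effect_allele_out": d["effect_allele"],
            "other_allele_out": d["other_allele"],
            "eaf_out": d["eaf_out"],
            "beta_out": d["beta_out"],
            "se_out": d["se_out"],
            "pvalue_out": d["pvalue_out"],
        }
    )
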