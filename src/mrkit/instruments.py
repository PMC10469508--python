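"""Genetic-instrument selection from exposure summary statistics.

The filter runs in a fixed order: (1) genome-wide significance
(p < 5e-8 by default); (2) greedy LD clumping at r² < 0.001 so the
retained variants are approximately independent; (3) per-SNP strength
statistics, removing weak instruments with F < 10.  Instruments missing
from the outcome data may be replaced by proxies in LD at r² > 0.8.

The variance a SNP explains in the exposure is

    R² = 2 β² p (1 − p) / [2 β² p (1 − p) + 2 SE² N p (1 − p)]
       = β² / (β² + SE² N),

and its strength F = R² (N − k − 1) / [k (1 − R²)] with k the number of
instruments charged to the statistic.  The weak-instrument filter uses
the per-SNP F (k = 1); the set-level F with k equal to the number of
retained instruments is also reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, NoInstrumentsError, StrengthUnavailableError
from .sumstats import SnpAssociation, SummaryStatsTable

logger = logging.getLogger(__name__)


class LdMatrix:
    """Symmetric r² lookup keyed by rsid pairs.

    Unknown pairs are treated as independent (r² = 0); the diagonal is 1.
    """

    def __init__(self, pairs: dict | None = None):
        self._r2: dict[tuple[str, str], float] = {}
        self._partners: dict[str, set[str]] = {}
        for (a, b), r2 in (pairs or {}).items():
            self.set(a, b, r2)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set(self, a: str, b: str, r2: float) -> None:
        if not 0 <= r2 <= 1:
            raise ConfigurationError(f"r² out of range for ({a}, {b}): {r2}")
        if a == b:
            return
        self._r2[self._key(a, b)] = float(r2)
        self._partners.setdefault(a, set()).add(b)
        self._partners.setdefault(b, set()).add(a)

    def get(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(self._key(a, b), 0.0)

    def partners(self, rsid: str) -> set[str]:
        return set(self._partners.get(rsid, ()))

    def __len__(self) -> int:
        return len(self._r2)

    @classmethod
    def read(cls, path) -> "LdMatrix":
        """Load a 3-column TSV (rsid_a, rsid_b, r2); symmetrized."""
        df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
        if df.shape[1] < 3:
            raise ConfigurationError(f"{path}: LD file needs 3 columns")
        ld = cls()
        a_col, b_col, r_col = df.columns[:3]
        for a, b, r2 in zip(df[a_col], df[b_col], df[r_col]):
            ld.set(str(a), str(b), float(r2))
        return ld

    def write(self, path) -> None:
        rows = sorted((a, b, r2) for (a, b), r2 in self._r2.items())
        pd.DataFrame(rows, columns=["rsid_a", "rsid_b", "r2"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass(frozen=True)
class InstrumentStrength:
    rsid: str
    r2: float  # proportion of exposure variance explained
    f_stat: float


@dataclass
class SelectionConfig:
    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    proxy_r2: float = 0.8
    f_min: float = 10.0

    def validate(self) -> None:
        if not 0 < self.p_threshold <= 1:
            raise ConfigurationError("p_threshold must lie in (0, 1]")
        if not 0 <= self.clump_r2 <= 1:
            raise ConfigurationError("clump_r2 must lie in [0, 1]")
        if not 0 < self.proxy_r2 < 1:
            raise ConfigurationError("proxy_r2 must lie in (0, 1)")
        if self.f_min < 0:
            raise ConfigurationError("f_min must be >= 0")


@dataclass
class InstrumentSet:
    """Selected instruments for one exposure plus a full exclusion log.

    Every input SNP appears exactly once: either in ``df`` or in
    ``exclusions`` (reason ∈ below_threshold | clumped | weak |
    missing_eaf | proxy_unavailable).
    """

    exposure: str
    df: pd.DataFrame  # canonical columns + r2, f_stat (per-SNP, k = 1)
    exclusions: dict[str, str] = field(default_factory=dict)
    k: int = 0  # instruments surviving clumping (set-level k)
    r2_total: float = 0.0
    f_set: float = float("nan")

    @property
    def rsids(self) -> list[str]:
        return list(self.df["rsid"])

    def __len__(self) -> int:
        return len(self.df)


def instrument_strength(assoc: SnpAssociation, k: int = 1) -> InstrumentStrength:
    """R² and F for one SNP given the instrument count ``k``."""
    if assoc.eaf_missing:
        raise StrengthUnavailableError(f"{assoc.rsid}: EAF missing")
    if assoc.n < k + 2:
        raise ConfigurationError(f"{assoc.rsid}: need n >= k + 2")
    r2 = _r2_explained(assoc.beta, assoc.se, assoc.n)
    return InstrumentStrength(rsid=assoc.rsid, r2=r2, f_stat=_f_stat(r2, assoc.n, k))


def _r2_explained(beta: float, se: float, n: float) -> float:
    num = 2.0 * beta**2  # the 2 p (1 − p) factor cancels
    return num / (num + 2.0 * se**2 * n)


def _f_stat(r2: float, n: float, k: int) -> float:
    return r2 * (n - k - 1) / (k * (1.0 - r2))


def clump(candidates: pd.DataFrame, ld: LdMatrix, r2_threshold: float) -> list[str]:
    """Greedy LD clumping: sweep SNPs by ascending p-value (ties broken
    by rsid) and accept each iff its r² with every already-accepted SNP
    stays below ``r2_threshold``.  Output order: p, then rsid."""
    if candidates.empty:
        return []
    ordered = candidates.sort_values(
        ["pvalue", "rsid"], kind="mergesort"
    )["rsid"].tolist()
    kept: list[str] = []
    for rsid in ordered:
        if all(ld.get(rsid, other) < r2_threshold for other in kept):
            kept.append(rsid)
    return kept


def find_proxy(
    rsid: str, ld: LdMatrix, available: set[str], r2_min: float = 0.8
) -> str | None:
    """Best available stand-in for a missing SNP: maximal r² strictly
    above ``r2_min`` (ties resolved to the lexicographically smallest
    rsid); ``None`` when no candidate qualifies."""
    if not 0 < r2_min < 1:
        raise ConfigurationError("r2_min must lie in (0, 1)")
    if rsid in available:
        return rsid
    best: tuple[float, str] | None = None
    for cand in ld.partners(rsid):
        if cand not in available:
            continue
        r2 = ld.get(rsid, cand)
        if r2 <= r2_min:
            continue
        if best is None or r2 > best[0] or (r2 == best[0] and cand < best[1]):
            best = (r2, cand)
    return best[1] if best else None


def select_instruments(
    table: SummaryStatsTable,
    ld: LdMatrix | None = None,
    config: SelectionConfig | None = None,
) -> InstrumentSet:
    """Run the full instrument filter for one exposure.

    Order of operations: significance threshold, LD clumping, strength
    computation (missing-EAF SNPs excluded here), weak-instrument
    removal.  Each dropped SNP is logged with its first failing reason.
    """
    cfg = config or SelectionConfig()
    cfg.validate()
    ld = ld or LdMatrix()

    exclusions: dict[str, str] = {}
    df = table.df

    sig = df[df["pvalue"] < cfg.p_threshold]
    for rsid in df.loc[~df.index.isin(sig.index), "rsid"]:
        exclusions[rsid] = "below_threshold"

    kept_rsids = clump(sig, ld, cfg.clump_r2)
    clumped_out = set(sig["rsid"]) - set(kept_rsids)
    for rsid in clumped_out:
        exclusions[rsid] = "clumped"

    survivors = sig.set_index("rsid").loc[kept_rsids].reset_index()
    k_set = len(survivors)

    rows = []
    for assoc in SummaryStatsTable(
        trait_name=table.trait_name,
        trait_type=table.trait_type,
        n_total=table.n_total,
        n_cases=table.n_cases,
        df=survivors,
    ).records:
        try:
            strength = instrument_strength(assoc, k=1)
        except StrengthUnavailableError:
            exclusions[assoc.rsid] = "missing_eaf"
            continue
        if strength.f_stat < cfg.f_min:
            exclusions[assoc.rsid] = "weak"
            logger.info(
                "%s: %s removed as weak (F = %.2f)",
                table.trait_name, assoc.rsid, strength.f_stat,
            )
            continue
        rows.append((assoc.rsid, strength.r2, strength.f_stat))

    if not rows:
        raise NoInstrumentsError(
            f"no instruments retained for exposure {table.trait_name!r}"
        )

    strength_df = pd.DataFrame(rows, columns=["rsid", "r2", "f_stat"])
    out = survivors.merge(strength_df, on="rsid", how="inner")

    r2_total = float(strength_df["r2"].sum())
    n_med = float(out["n"].median())
    f_set = _f_stat(min(r2_total, 1.0 - 1e-12), n_med, k_set) if k_set else float("nan")

    return InstrumentSet(
        exposure=table.trait_name,
        df=out.reset_index(drop=True),
        exclusions=exclusions,
        k=k_set,
        r2_total=r2_total,
        f_set=f_set,
    )
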