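"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the statistical structure of the public GWAS
tables the pipeline is designed for: per-SNP marginal effects observed
with sampling noise at realistic sample sizes, a subset of genome-wide
significant instruments, optional horizontal pleiotropy (balanced or
directional), palindromic A/T and C/G variants, outcome records emitted
under a swapped allele coding, and exchangeable LD blocks.

Model.  SNP j has minor-allele frequency p_j drawn uniformly from
``maf_range``.  Its true effect on the exposure is
gamma_j ~ Normal(0, gamma_sd^2) for instrument SNPs and 0 otherwise; the
true effect on the outcome is Gamma_j = true_beta * gamma_j + alpha_j,
where alpha_j is the direct (pleiotropic) effect: zero under mode
``none``, Normal(0, sigma_pleiotropy^2) under ``balanced``, and
sign(gamma_j) * mu_pleiotropy + Normal(0, sigma_pleiotropy^2) under
``directional`` (pleiotropy pushes the outcome in the exposure-raising
direction, which is what biases IVW).  Observed betas are the truth plus
Normal noise with the standardized-scale standard error
se_j = 1 / sqrt(2 n p_j (1 - p_j)); binary outcomes use the same form
rescaled by 1 / sqrt(cf (1 - cf)) to a log-odds-like scale.  Exposure
and outcome samples are independent (two-sample design).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .sumstats import CANONICAL_COLUMNS, SummaryStatsTable

_NONPALINDROMIC_PAIRS = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G")]
_PALINDROMIC_PAIRS = [("A", "T"), ("C", "G")]
_TINY_P = float(np.nextafter(0.0, 1.0))


@dataclass
class SimulationConfig:
    """Generator settings; defaults emulate a liver-enzyme-scale GWAS
    (exposure n = 753,010) against a biobank disease outcome."""

    m_snps: int = 1000
    m_instruments: int = 150
    n_exposure: int = 753_010
    n_outcome: int = 400_000
    true_beta: float = 0.3
    pleiotropy_mode: str = "none"  # none | balanced | directional
    sigma_pleiotropy: float = 0.005
    mu_pleiotropy: float = 0.03
    frac_pleiotropic: float = 1.0  # fraction of instruments with direct effects
    gamma_sd: float = 0.1
    maf_range: tuple[float, float] = (0.05, 0.5)
    frac_palindromic: float = 0.15
    frac_flipped: float = 0.1
    ld_block_size: int = 5
    ld_r2_within: float = 0.2
    outcome_type: str = "binary"
    case_fraction: float = 0.25
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"
    seed: int = 0

    def validate(self) -> None:
        if self.m_instruments > self.m_snps:
            raise ConfigurationError("m_instruments exceeds m_snps")
        for name in ("frac_pleiotropic", "frac_palindromic", "frac_flipped"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.sigma_pleiotropy < 0:
            raise ConfigurationError("sigma_pleiotropy must be >= 0")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must sit within (0, 0.5]")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ConfigurationError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.outcome_type not in ("continuous", "binary"):
            raise ConfigurationError(f"unknown outcome_type {self.outcome_type!r}")
        if self.outcome_type == "binary" and not 0 < self.case_fraction < 1:
            raise ConfigurationError("case_fraction must lie in (0, 1)")
        if not 0 <= self.ld_r2_within <= 1:
            raise ConfigurationError("ld_r2_within must lie in [0, 1]")


@dataclass
class SimulationTruth:
    """Ground truth recorded for parameter-recovery tests."""

    true_beta: float
    rsids: list[str]
    gamma: np.ndarray  # per-SNP true exposure effects
    alpha: np.ndarray  # per-SNP direct outcome effects
    instrument_rsids: list[str]
    pleiotropic_rsids: list[str]
    flipped_rsids: list[str]
    palindromic_rsids: list[str]
    block_assignment: np.ndarray = field(default_factory=lambda: np.array([]))

    def to_json(self) -> str:
        d = asdict(self)
        for key in ("gamma", "alpha", "block_assignment"):
            d[key] = np.asarray(d[key]).tolist()
        return json.dumps(d, indent=1, sort_keys=True)


def theoretical_se(n, maf) -> np.ndarray:
    """Standard error of a standardized per-allele effect estimate:
    1 / sqrt(2 n p (1 - p)).  Doubling n divides it by sqrt(2)."""
    maf = np.asarray(maf, dtype=float)
    return 1.0 / np.sqrt(2.0 * n * maf * (1.0 - maf))


def _two_sided_p(beta, se) -> np.ndarray:
    z = np.abs(np.asarray(beta) / np.asarray(se))
    return np.clip(2.0 * stats.norm.sf(z), _TINY_P, 1.0)


def _correlated_noise(rng, blocks: np.ndarray, corr: float) -> np.ndarray:
    """Exchangeable within-block standard-normal noise with pairwise
    correlation ``corr`` (zero between blocks)."""
    e = rng.standard_normal(len(blocks))
    if corr <= 0:
        return e
    n_blocks = int(blocks.max()) + 1
    shared = rng.standard_normal(n_blocks)
    return np.sqrt(corr) * shared[blocks] + np.sqrt(1.0 - corr) * e


def _observed_eaf(rng, n: int, maf: np.ndarray) -> np.ndarray:
    counts = rng.binomial(2 * n, maf)
    eaf = counts / (2.0 * n)
    return np.clip(eaf, 1.0 / (4.0 * n), 1.0 - 1.0 / (4.0 * n))


def simulate_two_sample(config: SimulationConfig):
    """Generate exposure and outcome tables, an LD r² matrix, and truth.

    Returns ``(exposure, outcome, ld, truth)``.  Identical configs
    (including seed) produce byte-identical tables.
    """
    from .instruments import LdMatrix  # local import avoids a cycle

    config.validate()
    rng = np.random.default_rng(config.seed)
    m = config.m_snps

    width = max(6, len(str(m)))
    rsids = np.array([f"rs{j + 1:0{width}d}" for j in range(m)])
    maf = rng.uniform(*config.maf_range, size=m)
    blocks = np.arange(m) // max(1, config.ld_block_size)

    instr_idx = np.sort(rng.choice(m, size=config.m_instruments, replace=False))
    gamma = np.zeros(m)
    gamma[instr_idx] = rng.normal(0.0, config.gamma_sd, size=len(instr_idx))

    alpha = np.zeros(m)
    pleio_idx = np.array([], dtype=int)
    if config.pleiotropy_mode != "none" and len(instr_idx):
        n_pleio = int(round(config.frac_pleiotropic * len(instr_idx)))
        pleio_idx = np.sort(rng.choice(instr_idx, size=n_pleio, replace=False))
        noise = rng.normal(0.0, config.sigma_pleiotropy, size=len(pleio_idx))
        if config.pleiotropy_mode == "balanced":
            alpha[pleio_idx] = noise
        else:  # directional: aligned with the exposure-raising allele
            sgn = np.sign(gamma[pleio_idx])
            sgn[sgn == 0] = 1.0
            alpha[pleio_idx] = sgn * config.mu_pleiotropy + noise

    big_gamma = config.true_beta * gamma + alpha

    se_exp = theoretical_se(config.n_exposure, maf)
    se_out = theoretical_se(config.n_outcome, maf)
    if config.outcome_type == "binary":
        se_out = se_out / np.sqrt(config.case_fraction * (1 - config.case_fraction))

    corr = np.sqrt(config.ld_r2_within)  # beta-noise correlation ~ LD r
    beta_exp = gamma + se_exp * _correlated_noise(rng, blocks, corr)
    beta_out = big_gamma + se_out * _correlated_noise(rng, blocks, corr)

    eaf_exp = _observed_eaf(rng, config.n_exposure, maf)
    eaf_out = _observed_eaf(rng, config.n_outcome, maf)

    n_pal = int(round(config.frac_palindromic * m))
    pal_idx = np.sort(rng.choice(m, size=n_pal, replace=False))
    is_pal = np.zeros(m, dtype=bool)
    is_pal[pal_idx] = True
    pair_choice = rng.integers(0, 4, size=m)  # which allele pair
    order_choice = rng.integers(0, 2, size=m)  # which member is the effect allele
    ea = np.empty(m, dtype=object)
    oa = np.empty(m, dtype=object)
    for j in range(m):
        pair = (
            _PALINDROMIC_PAIRS[pair_choice[j] % 2]
            if is_pal[j]
            else _NONPALINDROMIC_PAIRS[pair_choice[j]]
        )
        ea[j], oa[j] = (pair[0], pair[1]) if order_choice[j] == 0 else (pair[1], pair[0])

    n_flip = int(round(config.frac_flipped * m))
    flip_idx = np.sort(rng.choice(m, size=n_flip, replace=False))
    flip = np.zeros(m, dtype=bool)
    flip[flip_idx] = True

    exp_df = pd.DataFrame(
        {
            "rsid": rsids,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": eaf_exp,
            "beta": beta_exp,
            "se": se_exp,
            "pvalue": _two_sided_p(beta_exp, se_exp),
            "n": np.full(m, config.n_exposure),
        }
    )[CANONICAL_COLUMNS]

    out_df = pd.DataFrame(
        {
            "rsid": rsids,
            "effect_allele": np.where(flip, oa, ea),
            "other_allele": np.where(flip, ea, oa),
            "eaf": np.where(flip, 1.0 - eaf_out, eaf_out),
            "beta": np.where(flip, -beta_out, beta_out),
            "se": se_out,
            "pvalue": _two_sided_p(beta_out, se_out),
            "n": np.full(m, config.n_outcome),
        }
    )[CANONICAL_COLUMNS]

    exposure = SummaryStatsTable(
        trait_name=config.exposure_name,
        trait_type="continuous",
        n_total=config.n_exposure,
        df=exp_df,
    )
    outcome = SummaryStatsTable(
        trait_name=config.outcome_name,
        trait_type=config.outcome_type,
        n_total=config.n_outcome,
        n_cases=(
            int(round(config.case_fraction * config.n_outcome))
            if config.outcome_type == "binary"
            else None
        ),
        df=out_df,
    )

    pairs = {}
    if config.ld_block_size > 1 and config.ld_r2_within > 0:
        for b in range(int(blocks.max()) + 1):
            members = rsids[blocks == b]
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    pairs[(members[i], members[j])] = config.ld_r2_within
    ld = LdMatrix(pairs)

    truth = SimulationTruth(
        true_beta=config.true_beta,
        rsids=list(rsids),
        gamma=gamma,
        alpha=alpha,
        instrument_rsids=list(rsids[instr_idx]),
        pleiotropic_rsids=list(rsids[pleio_idx]),
        flipped_rsids=list(rsids[flip_idx]),
        palindromic_rsids=list(rsids[pal_idx]),
        block_assignment=blocks,
    )
    return exposure, outcome, ld, truth


def corrupt_coding(
    table: SummaryStatsTable,
    frac_flipped: float,
    frac_palindromic_ambiguous: float = 0.0,
    seed: int = 0,
):
    """Deliberately mis-code a table to exercise harmonization.

    A sample of exactly ``round(frac_flipped * m)`` records has its
    allele labels swapped, beta negated, and EAF complemented (applying
    the same corruption twice restores the original).  A disjoint sample
    of ``round(frac_palindromic_ambiguous * m)`` records is rewritten to
    an A/T pair with EAF forced to 0.5 (unresolvable strand).  Returns
    ``(corrupted table, log)`` where the log lists every altered rsid.
    """
    for name, v in (
        ("frac_flipped", frac_flipped),
        ("frac_palindromic_ambiguous", frac_palindromic_ambiguous),
    ):
        if not 0 <= v <= 1:
            raise ConfigurationError(f"{name} must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    df = table.df.copy()
    m = len(df)
    n_flip = int(round(frac_flipped * m))
    flip_idx = np.sort(rng.choice(m, size=n_flip, replace=False))

    remaining = np.setdiff1d(np.arange(m), flip_idx)
    n_pal = min(int(round(frac_palindromic_ambiguous * m)), len(remaining))
    pal_idx = np.sort(rng.choice(remaining, size=n_pal, replace=False))

    ea = df["effect_allele"].to_numpy().copy()
    oa = df["other_allele"].to_numpy().copy()
    df.loc[df.index[flip_idx], "effect_allele"] = oa[flip_idx]
    df.loc[df.index[flip_idx], "other_allele"] = ea[flip_idx]
    df.loc[df.index[flip_idx], "beta"] = -df.loc[df.index[flip_idx], "beta"]
    df.loc[df.index[flip_idx], "eaf"] = 1.0 - df.loc[df.index[flip_idx], "eaf"]

    df.loc[df.index[pal_idx], "effect_allele"] = "A"
    df.loc[df.index[pal_idx], "other_allele"] = "T"
    df.loc[df.index[pal_idx], "eaf"] = 0.5

    log = {
        "flipped": list(df["rsid"].to_numpy()[flip_idx]),
        "palindromic_ambiguous": list(df["rsid"].to_numpy()[pal_idx]),
    }
    return replace(table, df=df, exclusions=[]), log
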