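"""Heterogeneity, pleiotropy, influence, outlier, and power diagnostics.

* Cochran's Q over the per-SNP Wald ratios (weights βx²/se_out², i.e.
  the first-order ratio inverse variances), with
  I² = max(0, (Q − df)/Q) and df = n − 1.
* Leave-one-out: the IVW estimate with each instrument removed in turn;
  a SNP is flagged influential when its exclusion changes the sign of
  the estimate or moves the p-value across α.
* A pleiotropy residual-sum-and-outlier test (MR-PRESSO style): the
  observed weighted residual sum of squares about leave-one-out IVW
  slopes is compared with a parametric-simulation null; per-SNP tails
  give Bonferroni-adjusted outlier p-values, and detected outliers are
  removed once with IVW refit.
* A binary-outcome power approximation based on the normal
  non-centrality parameter |β|·sqrt(n·R²·cf·(1−cf)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InsufficientInstrumentsError
from .estimators import MRResult, ivw
from .harmonize import HarmonizedSet


@dataclass(frozen=True)
class HeterogeneityResult:
    q_stat: float
    df: int
    pvalue: float
    i2: float

    def to_dict(self) -> dict:
        return {"q": self.q_stat, "df": self.df, "pvalue": self.pvalue, "i2": self.i2}


@dataclass
class LooResult:
    """One row per left-out instrument: IVW on the remaining set."""

    table: pd.DataFrame  # rsid, beta, se, pvalue, influential
    full_beta: float
    full_pvalue: float

    @property
    def influential_rsids(self) -> list[str]:
        return list(self.table.loc[self.table["influential"], "rsid"])


@dataclass
class PressoResult:
    rss_obs: float
    global_pvalue: float
    snp_pvalues: pd.DataFrame  # rsid, pvalue (Bonferroni-adjusted)
    outliers: list[str] = field(default_factory=list)
    corrected: MRResult | None = None  # IVW after outlier removal


def i_squared(q: float, df: int) -> float:
    """I² = max(0, (Q − df)/Q); 0 when Q ≤ df (or Q = 0)."""
    if q <= 0:
        return 0.0
    return max(0.0, (q - df) / q)


def _ratio_stats(hset: HarmonizedSet):
    bx, _, by, se_out = hset.arrays()
    ratios = by / bx
    weights = bx**2 / se_out**2
    return ratios, weights


def cochrans_q(hset: HarmonizedSet) -> HeterogeneityResult:
    """Cochran's Q across the per-SNP Wald ratios about the IVW mean."""
    if hset.n_snp < 2:
        raise InsufficientInstrumentsError("Cochran's Q needs at least 2 SNPs")
    ratios, w = _ratio_stats(hset)
    beta = np.sum(w * ratios) / np.sum(w)
    q = float(np.sum(w * (ratios - beta) ** 2))
    df = hset.n_snp - 1
    p = float(stats.chi2.sf(q, df)) if q > 0 else 1.0
    return HeterogeneityResult(q_stat=q, df=df, pvalue=max(p, 0.0) or 1e-300, i2=i_squared(q, df))


def leave_one_out(
    hset: HarmonizedSet,
    alpha: float = 0.05,
    re_mode: str = "multiplicative_random",
) -> LooResult:
    """IVW with each instrument excluded in turn."""
    if hset.n_snp < 3:
        raise InsufficientInstrumentsError("leave-one-out needs at least 3 SNPs")
    full = ivw(hset, re_mode=re_mode)
    rows = []
    for rsid in hset.rsids:
        res = ivw(hset.drop([rsid]), re_mode=re_mode)
        influential = (np.sign(res.beta) != np.sign(full.beta)) or (
            (res.pvalue < alpha) != (full.pvalue < alpha)
        )
        rows.append((rsid, res.beta, res.se, res.pvalue, bool(influential)))
    table = pd.DataFrame(rows, columns=["rsid", "beta", "se", "pvalue", "influential"])
    return LooResult(table=table, full_beta=full.beta, full_pvalue=full.pvalue)


def _loo_slopes(bx, by, w):
    """Vector of IVW slopes each computed without SNP i (closed form)."""
    s_xy = np.sum(w * bx * by)
    s_xx = np.sum(w * bx**2)
    return (s_xy - w * bx * by) / (s_xx - w * bx**2)


def presso(
    hset: HarmonizedSet,
    n_sim: int = 1000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    re_mode: str = "multiplicative_random",
) -> PressoResult:
    """Pleiotropy residual-sum-and-outlier test.

    Observed statistic: RSS = Σ w_i (βy_i − β̂₍₋ᵢ₎ βx_i)² with weights
    w_i = 1/se_out,i² and β̂₍₋ᵢ₎ the leave-one-out IVW slope.  The null
    is built from ``n_sim`` parametric draws (βx* ~ N(βx, se_x²),
    βy* ~ N(β̂₍₋ᵢ₎ βx, se_y²)), recomputing the statistic on each draw.
    Global p = (1 + #{RSS* ≥ RSS})/(n_sim + 1); per-SNP p-values use the
    same tail on each SNP's residual term, Bonferroni-multiplied by n.
    SNPs with adjusted p < ``outlier_alpha`` are removed once and IVW is
    refit on the remainder.
    """
    if hset.n_snp < 4:
        raise InsufficientInstrumentsError("outlier test needs at least 4 SNPs")
    if n_sim < 100:
        raise ConfigurationError("n_sim must be at least 100")

    bx, se_exp, by, se_out = hset.arrays()
    w = 1.0 / se_out**2
    n = hset.n_snp

    b_loo = _loo_slopes(bx, by, w)
    resid_obs = w * (by - b_loo * bx) ** 2
    rss_obs = float(np.sum(resid_obs))

    rng = rng if rng is not None else np.random.default_rng(seed)
    bx_sim = rng.normal(bx, se_exp, size=(n_sim, n))
    by_sim = rng.normal(b_loo * bx, se_out, size=(n_sim, n))

    s_xy = np.sum(w * bx_sim * by_sim, axis=1, keepdims=True)
    s_xx = np.sum(w * bx_sim**2, axis=1, keepdims=True)
    b_loo_sim = (s_xy - w * bx_sim * by_sim) / (s_xx - w * bx_sim**2)
    resid_sim = w * (by_sim - b_loo_sim * bx_sim) ** 2
    rss_sim = resid_sim.sum(axis=1)

    global_p = (1.0 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1.0)
    snp_p_raw = (1.0 + np.sum(resid_sim >= resid_obs[None, :], axis=0)) / (n_sim + 1.0)
    snp_p = np.minimum(1.0, snp_p_raw * n)

    rsids = np.array(hset.rsids)
    outliers = list(rsids[snp_p < outlier_alpha])

    corrected = None
    if outliers and len(outliers) < n:
        corrected = ivw(hset.drop(outliers), re_mode=re_mode)

    return PressoResult(
        rss_obs=rss_obs,
        global_pvalue=float(global_p),
        snp_pvalues=pd.DataFrame({"rsid": rsids, "pvalue": snp_p}),
        outliers=outliers,
        corrected=corrected,
    )


def power_binary(
    n: int,
    case_fraction: float,
    r2_exposure: float,
    beta: float,
    alpha: float = 0.05,
) -> float:
    """Approximate power to detect log-OR ``beta`` with a binary outcome
    of ``n`` samples (case fraction cf) using instruments explaining
    ``r2_exposure`` of the exposure variance:

        power = Φ(|β|·sqrt(n·R²·cf·(1−cf)) − z_{1−α/2}).
    """
    if r2_exposure <= 0:
        raise ConfigurationError("r2_exposure must be positive")
    if not 0 < case_fraction < 1:
        raise ConfigurationError("case_fraction must lie in (0, 1)")
    if not 0 < alpha < 1:
        raise ConfigurationError("alpha must lie in (0, 1)")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    ncp = abs(beta) * np.sqrt(n * r2_exposure * case_fraction * (1.0 - case_fraction))
    return float(stats.norm.cdf(ncp - z))
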