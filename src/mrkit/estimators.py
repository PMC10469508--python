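"""Causal-effect estimators for two-sample MR.

All estimators consume a :class:`~mrkit.harmonize.HarmonizedSet` and
return an :class:`MRResult` carrying the causal log-effect per SD of
exposure, its standard error, a two-sided p-value, and the odds-ratio
scale (OR with 95% CI) the results tables report.

* IVW — inverse-variance-weighted combination of per-SNP Wald ratios,
  algebraically the weighted through-origin regression of outcome betas
  on exposure betas with weights 1/se_out².  The headline mode inflates
  the SE multiplicatively by max(1, sqrt(Q/(n−1))) (random effects with
  a floor at the fixed-effect SE), which keeps the estimator coherent in
  the presence of heterogeneity; a fixed-effect mode is available.
* MR-Egger — the same regression with an unconstrained intercept; a
  nonzero intercept indicates directional horizontal pleiotropy.
  Residual overdispersion φ = max(1, RSS/(n−2)) scales both coefficient
  variances and inference uses t(n−2).
* Weighted median — consistent when instruments carrying at least half
  of the weight are valid; SE from a seeded parametric bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import (
    ConfigurationError,
    InsufficientInstrumentsError,
    NoDataError,
    UndefinedRatioError,
)
from .harmonize import HarmonizedSet


@dataclass(frozen=True)
class MRResult:
    """One method's causal estimate for one exposure–outcome pair."""

    method: str  # IVW | MR-Egger | weighted-median | Wald
    n_snp: int
    beta: float
    se: float
    pvalue: float
    or_value: float
    ci_low: float
    ci_high: float

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "n_snp": self.n_snp,
            "beta": self.beta,
            "se": self.se,
            "pvalue": self.pvalue,
            "or": self.or_value,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        }


@dataclass(frozen=True)
class PleiotropyResult:
    """MR-Egger intercept: estimate, SE, and two-sided p-value."""

    intercept: float
    se: float
    pvalue: float

    def to_dict(self) -> dict:
        return {"intercept": self.intercept, "se": self.se, "pvalue": self.pvalue}


def to_odds_ratio(beta: float, se: float, alpha: float = 0.05):
    """(OR, CI low, CI high) = exp(beta), exp(beta ∓ z_{1−α/2}·se)."""
    if se <= 0:
        raise ConfigurationError("se must be positive")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    return float(np.exp(beta)), float(np.exp(beta - z * se)), float(np.exp(beta + z * se))


def _package(method, n_snp, beta, se, pvalue, alpha) -> MRResult:
    or_value, lo, hi = to_odds_ratio(beta, se, alpha)
    return MRResult(
        method=method,
        n_snp=n_snp,
        beta=float(beta),
        se=float(se),
        pvalue=float(max(pvalue, np.nextafter(0.0, 1.0))),  # p ∈ (0, 1]
        or_value=or_value,
        ci_low=lo,
        ci_high=hi,
    )


def wald_ratio(pair) -> tuple[float, float]:
    """Per-SNP causal estimate: beta_out/beta_exp with the first-order
    SE se_out/|beta_exp|.  ``pair`` needs attributes beta_exp, beta_out,
    se_out (a HarmonizedPair row or any namespace)."""
    if pair.beta_exp == 0:
        raise UndefinedRatioError(f"zero exposure effect for {getattr(pair, 'rsid', '?')}")
    return pair.beta_out / pair.beta_exp, pair.se_out / abs(pair.beta_exp)


def _cochran_q(bx, by, se_out) -> float:
    """Q about the fixed-effect IVW slope, in regression form (equal to
    the ratio form Σ (bx²/se²)(ratio − β̂)²)."""
    w = 1.0 / se_out**2
    beta = np.sum(w * bx * by) / np.sum(w * bx**2)
    return float(np.sum(w * (by - beta * bx) ** 2))


def ivw(
    hset: HarmonizedSet,
    re_mode: str = "multiplicative_random",
    alpha: float = 0.05,
) -> MRResult:
    """Inverse-variance-weighted estimate.

    ``re_mode='fixed'`` uses the fixed-effect SE sqrt(1/Σ w βx²);
    ``'multiplicative_random'`` (default) inflates it by
    max(1, sqrt(Q/(n−1))).  With a single SNP both modes reduce to the
    Wald ratio.
    """
    if re_mode not in ("fixed", "multiplicative_random"):
        raise ConfigurationError(f"unknown re_mode {re_mode!r}")
    if hset.n_snp == 0:
        raise NoDataError("empty harmonized set")
    bx, _, by, se_out = hset.arrays()
    if np.any(bx == 0):
        raise UndefinedRatioError("zero exposure effect in harmonized set")

    w = 1.0 / se_out**2
    s_xx = np.sum(w * bx**2)
    beta = np.sum(w * bx * by) / s_xx
    se = np.sqrt(1.0 / s_xx)
    if re_mode == "multiplicative_random" and hset.n_snp >= 2:
        q = _cochran_q(bx, by, se_out)
        se *= max(1.0, np.sqrt(q / (hset.n_snp - 1)))
    p = 2.0 * stats.norm.sf(abs(beta) / se)
    return _package("IVW", hset.n_snp, beta, se, p, alpha)


def mr_egger(
    hset: HarmonizedSet, alpha: float = 0.05, orient: bool = True
) -> tuple[MRResult, PleiotropyResult]:
    """MR-Egger regression: weighted least squares of outcome on
    exposure betas with an intercept, weights 1/se_out².

    When ``orient`` (default) each SNP is re-signed so its exposure
    effect is non-negative, the conventional orientation for the
    intercept test.  Inference uses t(n−2) with the overdispersion
    factor φ = max(1, RSS/(n−2)).
    """
    if hset.n_snp < 3:
        raise InsufficientInstrumentsError("MR-Egger needs at least 3 SNPs")
    bx, _, by, se_out = hset.arrays()
    if orient:
        sgn = np.where(bx < 0, -1.0, 1.0)
        bx, by = sgn * bx, sgn * by

    w = 1.0 / se_out**2
    x = np.column_stack([np.ones_like(bx), bx])
    xtwx = x.T @ (w[:, None] * x)
    coefs = np.linalg.solve(xtwx, x.T @ (w * by))
    resid = by - x @ coefs
    n = hset.n_snp
    rss = float(np.sum(w * resid**2))
    phi = max(1.0, rss / (n - 2))
    cov = phi * np.linalg.inv(xtwx)
    ses = np.sqrt(np.diag(cov))
    pvals = 2.0 * stats.t.sf(np.abs(coefs) / ses, df=n - 2)

    slope = _package("MR-Egger", n, coefs[1], ses[1], pvals[1], alpha)
    intercept = PleiotropyResult(
        intercept=float(coefs[0]), se=float(ses[0]), pvalue=float(pvals[0])
    )
    return slope, intercept


def wm_estimate(ratios, weights) -> float:
    """Weighted median of ``ratios``: sort, form standardized cumulative
    weights s_i = (cumsum(w)_i − w_i/2)/Σw, and linearly interpolate the
    ratio at s = 0.5."""
    ratios = np.asarray(ratios, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(ratios, kind="stable")
    r, w = ratios[order], weights[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, s, r))


def weighted_median(
    hset: HarmonizedSet,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> MRResult:
    """Weighted-median estimate with a parametric-bootstrap SE.

    Ratio weights are the inverse variances of the first-order Wald
    ratios, βx²/se_out².  The bootstrap redraws both betas from normals
    at their observed means/SEs and recomputes the estimate ``n_boot``
    times; the SE is the SD of those draws (seeded, reproducible).
    """
    if hset.n_snp < 3:
        raise InsufficientInstrumentsError("weighted median needs at least 3 SNPs")
    bx, se_exp, by, se_out = hset.arrays()
    if np.any(bx == 0):
        raise UndefinedRatioError("zero exposure effect in harmonized set")

    beta = wm_estimate(by / bx, bx**2 / se_out**2)

    rng = rng if rng is not None else np.random.default_rng(seed)
    n = hset.n_snp
    draws = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = rng.normal(bx, se_exp)
        by_b = rng.normal(by, se_out)
        bx_b[bx_b == 0] = np.finfo(float).tiny
        draws[b] = wm_estimate(by_b / bx_b, bx_b**2 / se_out**2)
    se = float(np.std(draws, ddof=1))
    if se == 0:
        se = np.finfo(float).tiny
    p = 2.0 * stats.norm.sf(abs(beta) / se)
    return _package("weighted-median", n, beta, se, p, alpha)
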