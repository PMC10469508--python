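"""Replicated simulation studies of the estimators' operating
characteristics: parameter recovery, coverage, type-I-error
calibration, robustness to directional pleiotropy, and outlier
detection.

Each study simulates two-sample summary statistics with the
:mod:`mrkit.synthetic` generator, harmonizes the known instrument SNPs
through the ordinary merge + harmonization path, and applies the
estimators.  Study conditions follow the package's reference scenario:
100 instrument SNPs, 10^5 samples per side, standardized continuous
traits.  Instruments are taken from the generator's ground truth (all
SNPs with a nonzero exposure effect) rather than re-thresholded, so the
measured properties are not confounded by winner's-curse selection —
which the generator deliberately does not model.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import ivw, mr_egger, weighted_median, wm_estimate
from .harmonize import HarmonizedSet, harmonize_set
from .sumstats import merge_on_rsid
from .synthetic import SimulationConfig, simulate_two_sample

#: Reference scenario shared by the studies below.
STUDY_CONFIG = SimulationConfig(
    m_snps=100,
    m_instruments=100,
    n_exposure=100_000,
    n_outcome=100_000,
    true_beta=0.3,
    gamma_sd=0.1,
    maf_range=(0.05, 0.5),
    frac_palindromic=0.0,
    frac_flipped=0.2,
    ld_block_size=1,
    ld_r2_within=0.0,
    outcome_type="continuous",
)


def harmonized_truth_set(
    config: SimulationConfig, f_min: float = 10.0
) -> HarmonizedSet:
    """Simulate one two-sample dataset and harmonize its true
    instrument SNPs (exposure coding) via the standard path.

    Weak instruments (per-SNP F below ``f_min``) are removed, as the
    analysis pipeline always does: estimating with near-null instruments
    would measure weak-instrument attenuation rather than the
    estimators' behaviour on the valid-instrument sets they actually
    receive.
    """
    exposure, outcome, _, truth = simulate_two_sample(config)
    sub = exposure.subset(truth.instrument_rsids)
    if f_min > 0:
        d = sub.df
        f = (d["beta"] / d["se"]) ** 2  # per-SNP F (k = 1), to first order
        sub = exposure.subset(d.loc[f.to_numpy() >= f_min, "rsid"])
    pairs = merge_on_rsid(sub, outcome)
    return harmonize_set(pairs, exposure=config.exposure_name, outcome=config.outcome_name)


def _rep_config(base: SimulationConfig, seed: int, rep: int) -> SimulationConfig:
    return replace(base, seed=(seed * 100_003 + rep) % 2**31)


def recovery_study(
    n_rep: int = 500,
    seed: int = 0,
    true_beta: float = 0.3,
    config: SimulationConfig | None = None,
) -> pd.DataFrame:
    """IVW recovery of a known causal effect: one row per replicate with
    the estimate, SE, and whether the 95% CI covers the truth."""
    base = replace(config or STUDY_CONFIG, true_beta=true_beta, pleiotropy_mode="none")
    rows = []
    for rep in range(n_rep):
        hset = harmonized_truth_set(_rep_config(base, seed, rep))
        res = ivw(hset)
        lo, hi = res.beta - 1.959963984540054 * res.se, res.beta + 1.959963984540054 * res.se
        rows.append((res.beta, res.se, lo <= true_beta <= hi))
    return pd.DataFrame(rows, columns=["beta", "se", "covered"])


def calibration_study(
    n_rep: int = 500,
    seed: int = 0,
    sigma_pleiotropy: float = 0.005,
    alpha: float = 0.05,
    config: SimulationConfig | None = None,
) -> pd.DataFrame:
    """Type-I error under the null (no causal effect) with balanced
    pleiotropy: per replicate, the IVW p-value and the MR-Egger
    intercept p-value."""
    base = replace(
        config or STUDY_CONFIG,
        true_beta=0.0,
        pleiotropy_mode="balanced",
        sigma_pleiotropy=sigma_pleiotropy,
    )
    rows = []
    for rep in range(n_rep):
        hset = harmonized_truth_set(_rep_config(base, seed, rep))
        res = ivw(hset)
        _, intercept = mr_egger(hset)
        rows.append((res.pvalue, intercept.pvalue, res.pvalue < alpha,
                     intercept.pvalue < alpha))
    return pd.DataFrame(
        rows, columns=["ivw_pvalue", "egger_intercept_pvalue", "ivw_reject", "egger_reject"]
    )


def robustness_study(
    n_rep: int = 200,
    seed: int = 0,
    true_beta: float = 0.3,
    frac_pleiotropic: float = 0.4,
    mu_pleiotropy: float = 0.03,
    n_boot: int = 200,
    config: SimulationConfig | None = None,
) -> pd.DataFrame:
    """Weighted-median robustness when a minority of instruments carry
    strong directional pleiotropy: per replicate, the IVW and WM
    estimates (bias = estimate − true_beta)."""
    base = replace(
        config or STUDY_CONFIG,
        true_beta=true_beta,
        pleiotropy_mode="directional",
        frac_pleiotropic=frac_pleiotropic,
        mu_pleiotropy=mu_pleiotropy,
    )
    rows = []
    for rep in range(n_rep):
        hset = harmonized_truth_set(_rep_config(base, seed, rep))
        b_ivw = ivw(hset).beta
        b_wm = weighted_median(hset, n_boot=n_boot, seed=rep).beta
        rows.append((b_ivw, b_wm, b_ivw - true_beta, b_wm - true_beta))
    return pd.DataFrame(rows, columns=["ivw_beta", "wm_beta", "ivw_bias", "wm_bias"])


def planted_outlier_set(
    seed: int = 0,
    n_clean: int = 20,
    true_beta: float = 0.3,
    ratio_factor: float = 10.0,
    se_out: float = 0.005,
) -> tuple[HarmonizedSet, str]:
    """A harmonized set of ``n_clean`` well-behaved instruments plus one
    gross outlier whose Wald ratio is ``ratio_factor`` times the causal
    effect at small SE.  Returns the set and the planted rsid."""
    rng = np.random.default_rng(seed)
    n = n_clean + 1
    bx = rng.uniform(0.03, 0.15, size=n) * rng.choice([-1.0, 1.0], size=n)
    se_exp = np.full(n, 5e-4)
    by = true_beta * bx + rng.normal(0.0, se_out, size=n)
    by[-1] = ratio_factor * true_beta * bx[-1]
    rsids = [f"rs{j + 1:04d}" for j in range(n)]
    df = pd.DataFrame(
        {
            "rsid": rsids,
            "effect_allele": "A",
            "other_allele": "G",
            "beta_exp": bx,
            "se_exp": se_exp,
            "eaf_exp": 0.3,
            "pvalue_exp": 1e-12,
            "beta_out": by,
            "se_out": se_out,
            "eaf_out": 0.3,
            "pvalue_out": 0.5,
            "action": "unchanged",
        }
    )
    return HarmonizedSet(exposure="exposure", outcome="outcome", df=df), rsids[-1]


def outlier_detection_study(
    n_constructions: int = 100, seed: int = 0, n_sim: int = 1000
) -> pd.DataFrame:
    """Fraction of planted-outlier constructions in which the outlier
    test flags the planted SNP."""
    from .sensitivity import presso

    rows = []
    for rep in range(n_constructions):
        hset, planted = planted_outlier_set(seed=(seed * 100_003 + rep) % 2**31)
        result = presso(hset, n_sim=n_sim, seed=rep)
        rows.append((planted, planted in result.outliers, result.global_pvalue))
    return pd.DataFrame(rows, columns=["planted", "detected", "global_pvalue"])


def harmonization_invariance_study(
    n_fixtures: int = 50,
    seed: int = 0,
    frac_flipped: float = 0.5,
    config: SimulationConfig | None = None,
) -> pd.DataFrame:
    """Mis-code a fraction of outcome records and verify harmonization
    restores the IVW / Egger / WM estimates: per fixture, the absolute
    deviation of each estimator from the clean-pipeline value."""
    from .synthetic import corrupt_coding

    base = replace(config or STUDY_CONFIG, m_snps=30, m_instruments=30, frac_flipped=0.0)
    rows = []
    for rep in range(n_fixtures):
        cfg = _rep_config(base, seed, rep)
        exposure, outcome, _, truth = simulate_two_sample(cfg)
        corrupted, _ = corrupt_coding(outcome, frac_flipped=frac_flipped, seed=rep)

        clean = harmonize_set(merge_on_rsid(exposure, outcome))
        restored = harmonize_set(merge_on_rsid(exposure, corrupted))

        diffs = []
        for est in (
            lambda s: ivw(s).beta,
            lambda s: mr_egger(s)[0].beta,
            lambda s: _wm_point(s),
        ):
            diffs.append(abs(est(clean) - est(restored)))
        rows.append(tuple(diffs))
    return pd.DataFrame(rows, columns=["ivw_diff", "egger_diff", "wm_diff"])


def _wm_point(hset: HarmonizedSet) -> float:
    bx, _, by, se_out = hset.arrays()
    return wm_estimate(by / bx, bx**2 / se_out**2)


def binomial_bounds(p: float, n: int, level: float = 0.99) -> tuple[float, float]:
    """Symmetric normal-approximation bounds for an observed proportion
    when the true rate is ``p`` over ``n`` trials."""
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(p * (1 - p) / n)
    return p - half, p + half
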