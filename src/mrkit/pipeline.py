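"""End-to-end orchestration of one or more exposure × outcome analyses.

``run_pair`` executes the full chain for one exposure–outcome pair:
instrument selection → proxy lookup for instruments absent from the
outcome data → merge → harmonization → outlier test (with a single
detect-and-remove pass) → optional confounder-SNP exclusion → IVW
(primary) + weighted median + MR-Egger → Cochran's Q and leave-one-out.
Every SNP's fate is traceable through the per-stage logs, and a report
replayed from the same config and seed serializes byte-for-byte.

Multiple-testing control across an outcome panel uses a Bonferroni
threshold α / n_tests (with 10 outcome traits and α = 0.05 this is
0.005).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import (
    ConfigurationError,
    InsufficientInstrumentsError,
    NoInstrumentsError,
    NoOverlapError,
)
from .estimators import MRResult, PleiotropyResult, ivw, mr_egger, weighted_median
from .harmonize import (
    DEFAULT_AMBIGUOUS_EAF_WINDOW,
    HarmonizedSet,
    harmonize_set,
)
from .instruments import InstrumentSet, LdMatrix, SelectionConfig, find_proxy, select_instruments
from .sensitivity import (
    HeterogeneityResult,
    LooResult,
    PressoResult,
    cochrans_q,
    leave_one_out,
    presso,
)
from .sumstats import SummaryStatsTable, merge_on_rsid

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """Run-level thresholds and seeds for a full analysis."""

    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    proxy_r2: float = 0.8
    f_min: float = 10.0
    ambiguous_eaf_window: tuple[float, float] = DEFAULT_AMBIGUOUS_EAF_WINDOW
    re_mode: str = "multiplicative_random"
    n_boot: int = 1000
    presso_n_sim: int = 1000
    alpha: float = 0.05
    n_tests: int = 10  # outcome traits in the Bonferroni family
    seed: int = 0
    confounder_exclusion_list: list[str] | None = None

    def validate(self) -> None:
        self.selection().validate()
        if self.n_tests < 1:
            raise ConfigurationError("n_tests must be >= 1")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")

    def selection(self) -> SelectionConfig:
        return SelectionConfig(
            p_threshold=self.p_threshold,
            clump_r2=self.clump_r2,
            proxy_r2=self.proxy_r2,
            f_min=self.f_min,
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "ambiguous_eaf_window" in data:
            data["ambiguous_eaf_window"] = tuple(data["ambiguous_eaf_window"])
        return cls(**data)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold α / n_tests."""
    if n_tests < 1:
        raise ConfigurationError("n_tests must be >= 1")
    if not 0 < alpha <= 1:
        raise ConfigurationError("alpha must lie in (0, 1]")
    return alpha / n_tests


@dataclass
class AnalysisReport:
    """Everything computed for one exposure–outcome pair."""

    exposure: str
    outcome: str
    instruments: InstrumentSet
    proxy_substitutions: dict[str, str]
    missing_without_proxy: list[str]
    harmonized: HarmonizedSet  # pre outlier-removal
    presso: PressoResult | None
    presso_skipped_reason: str | None
    confounders_removed: list[str]
    final_set: HarmonizedSet
    results: dict[str, MRResult]
    egger_intercept: PleiotropyResult | None
    heterogeneity: HeterogeneityResult | None
    loo: LooResult | None
    nominal_significant: bool
    bonferroni_significant: bool
    config: PipelineConfig

    def to_dict(self) -> dict:
        d = {
            "exposure": self.exposure,
            "outcome": self.outcome,
            "n_instruments_selected": len(self.instruments),
            "proxy_substitutions": dict(sorted(self.proxy_substitutions.items())),
            "missing_without_proxy": sorted(self.missing_without_proxy),
            "n_harmonized": self.harmonized.n_snp,
            "harmonization_drops": dict(sorted(self.harmonized.drop_log.items())),
            "presso": (
                None
                if self.presso is None
                else {
                    "rss_obs": self.presso.rss_obs,
                    "global_pvalue": self.presso.global_pvalue,
                    "outliers": list(self.presso.outliers),
                }
            ),
            "presso_skipped_reason": self.presso_skipped_reason,
            "confounders_removed": sorted(self.confounders_removed),
            "n_snp_final": self.final_set.n_snp,
            "results": {k: v.to_dict() for k, v in sorted(self.results.items())},
            "egger_intercept": (
                None if self.egger_intercept is None else self.egger_intercept.to_dict()
            ),
            "heterogeneity": (
                None if self.heterogeneity is None else self.heterogeneity.to_dict()
            ),
            "nominal_significant": self.nominal_significant,
            "bonferroni_significant": self.bonferroni_significant,
        }
        return d

    def results_frame(self) -> pd.DataFrame:
        """Results table: method, n_snp, OR, CI, p (one row per method)."""
        rows = [
            (r.method, r.n_snp, r.or_value, r.ci_low, r.ci_high, r.pvalue)
            for r in self.results.values()
        ]
        return pd.DataFrame(
            rows, columns=["method", "n_snp", "or", "ci_low", "ci_high", "pvalue"]
        ).sort_values("method", kind="mergesort").reset_index(drop=True)

    def write(self, out_dir) -> None:
        """Emit the plain-text report bundle into ``out_dir``."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.results_frame().to_csv(out / "results.tsv", sep="\t", index=False)

        sens = {
            "q": self.heterogeneity.q_stat if self.heterogeneity else np.nan,
            "q_pvalue": self.heterogeneity.pvalue if self.heterogeneity else np.nan,
            "i2": self.heterogeneity.i2 if self.heterogeneity else np.nan,
            "egger_intercept": (
                self.egger_intercept.intercept if self.egger_intercept else np.nan
            ),
            "egger_intercept_pvalue": (
                self.egger_intercept.pvalue if self.egger_intercept else np.nan
            ),
        }
        pd.DataFrame([sens]).to_csv(out / "sensitivity.tsv", sep="\t", index=False)

        if self.loo is not None:
            self.loo.table.to_csv(out / "loo.tsv", sep="\t", index=False)
        if self.presso is not None:
            self.presso.snp_pvalues.to_csv(out / "presso.tsv", sep="\t", index=False)
        self.final_set.write(out / "harmonized.tsv")  # per-SNP scatter data

        with open(out / "exclusions.log", "w") as fh:
            for rsid, reason in sorted(self.instruments.exclusions.items()):
                fh.write(f"selection\t{rsid}\t{reason}\n")
            for rsid in sorted(self.missing_without_proxy):
                fh.write(f"proxy\t{rsid}\tproxy_unavailable\n")
            for rsid, reason in sorted(self.harmonized.drop_log.items()):
                fh.write(f"harmonize\t{rsid}\t{reason}\n")
            if self.presso is not None:
                for rsid in self.presso.outliers:
                    fh.write(f"outlier_test\t{rsid}\toutlier\n")
            for rsid in sorted(self.confounders_removed):
                fh.write(f"confounder\t{rsid}\texcluded\n")

        run = {
            "mrkit_version": __version__,
            "config": asdict(self.config),
            "report": self.to_dict(),
        }
        with open(out / "run.json", "w") as fh:
            json.dump(run, fh, indent=1, sort_keys=True, default=str)


def _spawn_rngs(seed: int) -> dict[str, np.random.Generator]:
    """Independent substreams per stochastic stage, so stage order
    cannot perturb the draws."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2)
    return {
        "wm": np.random.default_rng(children[0]),
        "presso": np.random.default_rng(children[1]),
    }


def run_pair(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    ld: LdMatrix | None = None,
    config: PipelineConfig | None = None,
) -> AnalysisReport:
    """Full analysis of one exposure–outcome pair (see module docs)."""
    cfg = config or PipelineConfig()
    cfg.validate()
    ld = ld or LdMatrix()
    rngs = _spawn_rngs(cfg.seed)

    instruments = select_instruments(exposure, ld, cfg.selection())

    outcome_rsids = outcome.rsids
    exposure_rsids = exposure.rsids
    instrument_rsids = list(instruments.rsids)
    kept: list[str] = []
    proxies: dict[str, str] = {}
    missing: list[str] = []
    taken = set(instrument_rsids)
    for rsid in instrument_rsids:
        if rsid in outcome_rsids:
            kept.append(rsid)
            continue
        proxy = find_proxy(rsid, ld, outcome_rsids, cfg.proxy_r2)
        # the proxy must have its own exposure row and not collide with
        # an instrument already in the set
        if proxy is not None and proxy in exposure_rsids and proxy not in taken:
            proxies[rsid] = proxy
            taken.add(proxy)
            kept.append(proxy)
        else:
            missing.append(rsid)

    if not kept:
        raise NoOverlapError(
            f"no instrument of {exposure.trait_name!r} is present "
            f"(or proxied) in {outcome.trait_name!r}"
        )

    exp_subset = exposure.subset(kept)
    pairs = merge_on_rsid(exp_subset, outcome)
    harmonized = harmonize_set(
        pairs,
        ambiguous_eaf_window=cfg.ambiguous_eaf_window,
        exposure=exposure.trait_name,
        outcome=outcome.trait_name,
    )

    # exclusion accounting across stages
    assert len(kept) == harmonized.n_snp + len(harmonized.drop_log)
    assert len(instrument_rsids) == len(kept) + len(missing)

    presso_result: PressoResult | None = None
    presso_skipped = None
    working = harmonized
    if harmonized.n_snp >= 4:
        presso_result = presso(
            harmonized,
            n_sim=cfg.presso_n_sim,
            rng=rngs["presso"],
            outlier_alpha=cfg.alpha,
            re_mode=cfg.re_mode,
        )
        if presso_result.outliers and len(presso_result.outliers) < harmonized.n_snp:
            working = harmonized.drop(presso_result.outliers)
    else:
        presso_skipped = "fewer than 4 SNPs"

    confounders_removed: list[str] = []
    if cfg.confounder_exclusion_list:
        listed = set(cfg.confounder_exclusion_list)
        confounders_removed = [r for r in working.rsids if r in listed]
        if confounders_removed and len(confounders_removed) < working.n_snp:
            working = working.drop(confounders_removed)

    results: dict[str, MRResult] = {}
    results["IVW"] = ivw(working, re_mode=cfg.re_mode, alpha=cfg.alpha)
    egger_intercept = None
    try:
        slope, egger_intercept = mr_egger(working, alpha=cfg.alpha)
        results["MR-Egger"] = slope
    except InsufficientInstrumentsError:
        pass
    try:
        results["weighted-median"] = weighted_median(
            working, n_boot=cfg.n_boot, rng=rngs["wm"], alpha=cfg.alpha
        )
    except InsufficientInstrumentsError:
        pass

    heterogeneity = cochrans_q(working) if working.n_snp >= 2 else None
    loo = (
        leave_one_out(working, alpha=cfg.alpha, re_mode=cfg.re_mode)
        if working.n_snp >= 3
        else None
    )

    p_ivw = results["IVW"].pvalue
    return AnalysisReport(
        exposure=exposure.trait_name,
        outcome=outcome.trait_name,
        instruments=instruments,
        proxy_substitutions=proxies,
        missing_without_proxy=missing,
        harmonized=harmonized,
        presso=presso_result,
        presso_skipped_reason=presso_skipped,
        confounders_removed=confounders_removed,
        final_set=working,
        results=results,
        egger_intercept=egger_intercept,
        heterogeneity=heterogeneity,
        loo=loo,
        nominal_significant=p_ivw < cfg.alpha,
        bonferroni_significant=p_ivw < bonferroni_threshold(cfg.alpha, cfg.n_tests),
        config=cfg,
    )


@dataclass
class DirectionResult:
    """One direction of a bidirectional run: a report or a recorded
    failure (e.g. no genome-wide-significant instruments)."""

    direction: str  # "a_to_b" | "b_to_a"
    report: AnalysisReport | None = None
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.report is not None


def run_bidirectional(
    trait_a: SummaryStatsTable,
    trait_b: SummaryStatsTable,
    ld: LdMatrix | None = None,
    config: PipelineConfig | None = None,
) -> tuple[DirectionResult, DirectionResult]:
    """Forward (a→b) and reverse (b→a) analyses; a direction with no
    instruments records the failure without aborting the other."""
    out = []
    for direction, (x, y) in (
        ("a_to_b", (trait_a, trait_b)),
        ("b_to_a", (trait_b, trait_a)),
    ):
        try:
            out.append(DirectionResult(direction, report=run_pair(x, y, ld, config)))
        except (NoInstrumentsError, NoOverlapError) as exc:
            out.append(DirectionResult(direction, error=str(exc)))
    return out[0], out[1]


def run_matrix(
    exposures: list[SummaryStatsTable],
    outcomes: list[SummaryStatsTable],
    ld: LdMatrix | None = None,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """All exposure × outcome pairs; Bonferroni n_tests defaults to the
    number of outcome traits.  Returns one row per pair with the IVW
    headline and significance flags (failed pairs carry the error)."""
    cfg = config or PipelineConfig()
    if cfg.n_tests == 0 or cfg.n_tests is None:
        cfg.n_tests = len(outcomes)
    rows = []
    for exp in exposures:
        for out in outcomes:
            try:
                rep = run_pair(exp, out, ld, cfg)
                r = rep.results["IVW"]
                rows.append(
                    (
                        exp.trait_name,
                        out.trait_name,
                        r.n_snp,
                        r.or_value,
                        r.ci_low,
                        r.ci_high,
                        r.pvalue,
                        rep.nominal_significant,
                        rep.bonferroni_significant,
                        "",
                    )
                )
            except (NoInstrumentsError, NoOverlapError, InsufficientInstrumentsError) as exc:
                rows.append(
                    (exp.trait_name, out.trait_name, 0, np.nan, np.nan, np.nan,
                     np.nan, False, False, str(exc))
                )
    return pd.DataFrame(
        rows,
        columns=[
            "exposure", "outcome", "n_snp", "or", "ci_low", "ci_high",
            "pvalue", "nominal_significant", "bonferroni_significant", "error",
        ],
    )
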