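"""Causal estimators: Wald ratios, IVW, MR-Egger, weighted median, OR scale."""

from types import SimpleNamespace

import numpy as np
import pytest
import statsmodels.api as sm

from mrkit.errors import (
    ConfigurationError,
    InsufficientInstrumentsError,
    NoDataError,
    UndefinedRatioError,
)
from mrkit.estimators import (
    ivw,
    mr_egger,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
    wm_estimate,
)


class TestWaldRatio:
    def test_direct_arithmetic(self):
        pair = SimpleNamespace(beta_exp=0.1, beta_out=0.05, se_out=0.01)
        beta, se = wald_ratio(pair)
        assert beta == pytest.approx(0.5)
        assert se == pytest.approx(0.1)

    def test_null_numerator(self):
        pair = SimpleNamespace(beta_exp=-0.2, beta_out=0.0, se_out=0.01)
        beta, se = wald_ratio(pair)
        assert beta == 0.0
        assert se == pytest.approx(0.05)

    def test_zero_exposure_effect_guarded(self):
        with pytest.raises(UndefinedRatioError):
            wald_ratio(SimpleNamespace(beta_exp=0.0, beta_out=0.1, se_out=0.01, rsid="rs1"))


class TestIvw:
    def test_hand_computed_weighted_sums(self, make_hset):
        hs = make_hset([0.1, 0.2], [0.05, 0.08], [0.01, 0.02])
        res = ivw(hs, re_mode="fixed")
        assert res.beta == pytest.approx(0.45, rel=1e-12)
        assert res.se == pytest.approx(np.sqrt(1 / 200), rel=1e-12)

    def test_consensus_ratios_make_both_modes_agree(self, make_hset):
        bx = np.array([0.05, 0.1, 0.2, 0.4])
        hs = make_hset(bx, 0.7 * bx, [0.01, 0.03, 0.02, 0.05])
        fixed = ivw(hs, re_mode="fixed")
        random = ivw(hs, re_mode="multiplicative_random")
        assert fixed.beta == pytest.approx(0.7, rel=1e-12)
        assert random.beta == fixed.beta
        assert random.se == fixed.se  # Q = 0, inflation floored at 1

    def test_single_snp_equals_wald_ratio(self, make_hset):
        hs = make_hset([0.1], [0.05], [0.01])
        res = ivw(hs)
        assert res.beta == pytest.approx(0.5, rel=1e-12)
        assert res.se == pytest.approx(0.1, rel=1e-12)

    def test_matches_through_origin_wls_oracle(self, make_hset):
        rng = np.random.default_rng(42)
        for n in (2, 3, 4, 5, 6):
            bx = rng.normal(0.1, 0.05, n)
            by = rng.normal(0.03, 0.02, n)
            se = rng.uniform(0.01, 0.05, n)
            hs = make_hset(bx, by, se)
            res = ivw(hs, re_mode="fixed")
            fit = sm.WLS(by, bx, weights=1 / se**2).fit()
            assert res.beta == pytest.approx(fit.params[0], abs=1e-10)

    def test_empty_set_raises(self, make_hset):
        hs = make_hset([0.1], [0.05], [0.01]).drop(["rs0001"])
        with pytest.raises(NoDataError):
            ivw(hs)

    def test_unknown_mode_rejected(self, make_hset):
        with pytest.raises(ConfigurationError):
            ivw(make_hset([0.1], [0.05], [0.01]), re_mode="bogus")


class TestMrEgger:
    def test_exact_line_recovered(self, make_hset):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        hs = make_hset(bx, 0.1 + 0.5 * bx, 0.02)
        slope, intercept = mr_egger(hs)
        assert intercept.intercept == pytest.approx(0.1, abs=1e-12)
        assert slope.beta == pytest.approx(0.5, abs=1e-12)

    def test_matches_wls_oracle_with_intercept(self, make_hset):
        rng = np.random.default_rng(7)
        for n in (3, 4, 5, 6):
            bx = np.abs(rng.normal(0.1, 0.05, n)) + 0.01
            by = rng.normal(0.03, 0.05, n)
            se = rng.uniform(0.005, 0.02, n)
            hs = make_hset(bx, by, se)
            slope, intercept = mr_egger(hs)
            fit = sm.WLS(by, sm.add_constant(bx), weights=1 / se**2).fit()
            assert intercept.intercept == pytest.approx(fit.params[0], abs=1e-10)
            assert slope.beta == pytest.approx(fit.params[1], abs=1e-10)
            # with overdispersion above 1, the SEs coincide too
            if fit.scale >= 1:
                assert slope.se == pytest.approx(fit.bse[1], abs=1e-10)
                assert intercept.se == pytest.approx(fit.bse[0], abs=1e-10)

    def test_orientation_makes_result_sign_invariant(self, make_hset):
        rng = np.random.default_rng(3)
        bx = rng.normal(0, 0.1, 6)
        by = 0.4 * bx + rng.normal(0, 0.01, 6)
        se = np.full(6, 0.01)
        direct = mr_egger(make_hset(bx, by, se))
        relabeled = mr_egger(make_hset(-bx, -by, se))  # relabel every effect allele
        assert direct[0].beta == pytest.approx(relabeled[0].beta, abs=1e-12)
        assert direct[1].intercept == pytest.approx(relabeled[1].intercept, abs=1e-12)

    def test_needs_three_snps(self, make_hset):
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(make_hset([0.1, 0.2], [0.05, 0.1], 0.01))


class TestWeightedMedian:
    def test_equal_weight_interpolation(self):
        assert wm_estimate([0.2, 0.5, 0.9], [1, 1, 1]) == pytest.approx(0.5)

    def test_unequal_weight_interpolation(self):
        # s = (0.125, 0.625) -> interpolate at 0.5 between 0.1 and 0.3
        assert wm_estimate([0.1, 0.3], [1, 3]) == pytest.approx(0.25)

    def test_order_of_input_irrelevant(self):
        a = wm_estimate([0.9, 0.2, 0.5], [3, 1, 2])
        b = wm_estimate([0.2, 0.5, 0.9], [1, 2, 3])
        assert a == pytest.approx(b)

    def test_consensus_with_tiny_se_gives_tiny_bootstrap_se(self, make_hset):
        bx = np.array([0.1, 0.2, 0.3])
        hs = make_hset(bx, 0.6 * bx, 1e-7, se_exp=1e-8)
        res = weighted_median(hs, n_boot=200, seed=1)
        assert res.beta == pytest.approx(0.6, rel=1e-6)
        assert res.se < 1e-5

    def test_seeded_bootstrap_reproducible(self, make_hset):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        hs = make_hset(bx, 0.5 * bx + [0, 0.01, -0.01, 0.02], 0.01)
        a = weighted_median(hs, n_boot=300, seed=5)
        b = weighted_median(hs, n_boot=300, seed=5)
        assert a.se == b.se and a.beta == b.beta

    def test_needs_three_snps(self, make_hset):
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median(make_hset([0.1, 0.2], [0.05, 0.1], 0.01))


class TestToOddsRatio:
    def test_null_effect_gives_unit_or(self):
        or_value, lo, hi = to_odds_ratio(0.0, 0.1)
        assert or_value == pytest.approx(1.0)
        assert np.log(lo) == pytest.approx(-np.log(hi), rel=1e-12)

    def test_published_scale_reconstruction(self):
        # log-OR 1.834 (SE 0.668) -> OR 6.26, 95% CI 1.69-23.2
        or_value, lo, hi = to_odds_ratio(1.834, 0.668, alpha=0.05)
        assert or_value == pytest.approx(6.259, abs=5e-3)
        assert lo == pytest.approx(1.690, abs=5e-3)
        assert hi == pytest.approx(23.18, abs=5e-2)

    def test_log_round_trip(self):
        or_value, _, _ = to_odds_ratio(0.731, 0.2)
        assert np.log(or_value) == pytest.approx(0.731, abs=1e-12)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ConfigurationError):
            to_odds_ratio(0.1, 0.0)


class TestEstimatorInvariants:
    def test_allele_relabeling_invariance(self, make_hset):
        rng = np.random.default_rng(11)
        bx = rng.normal(0, 0.1, 8)
        by = 0.3 * bx + rng.normal(0, 0.01, 8)
        se = rng.uniform(0.005, 0.02, 8)
        hs = make_hset(bx, by, se)
        flip = rng.random(8) < 0.5
        sgn = np.where(flip, -1.0, 1.0)
        hs_flipped = make_hset(sgn * bx, sgn * by, se)
        assert ivw(hs).beta == pytest.approx(ivw(hs_flipped).beta, abs=1e-12)
        assert mr_egger(hs)[0].beta == pytest.approx(
            mr_egger(hs_flipped)[0].beta, abs=1e-12
        )
        wm_a = wm_estimate(by / bx, bx**2 / se**2)
        wm_b = wm_estimate((sgn * by) / (sgn * bx), bx**2 / se**2)
        assert wm_a == pytest.approx(wm_b, abs=1e-12)

    def test_outcome_scaling_equivariance(self, make_hset):
        rng = np.random.default_rng(13)
        bx = rng.normal(0.1, 0.03, 6)
        by = rng.normal(0.05, 0.02, 6)
        se = rng.uniform(0.01, 0.03, 6)
        c = 2.7
        base, scaled = make_hset(bx, by, se), make_hset(bx, c * by, c * se)
        assert ivw(scaled).beta == pytest.approx(c * ivw(base).beta, rel=1e-12)
        assert mr_egger(scaled)[0].beta == pytest.approx(
            c * mr_egger(base)[0].beta, rel=1e-12
        )
        assert wm_estimate(c * by / bx, bx**2 / (c * se) ** 2) == pytest.approx(
            c * wm_estimate(by / bx, bx**2 / se**2), rel=1e-12
        )
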