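"""Instrument selection: strength statistics, clumping, proxies."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrkit.errors import (
    ConfigurationError,
    NoInstrumentsError,
    StrengthUnavailableError,
)
from mrkit.instruments import (
    LdMatrix,
    SelectionConfig,
    clump,
    find_proxy,
    instrument_strength,
    select_instruments,
)
from mrkit.sumstats import SnpAssociation


def assoc(rsid="rs1", beta=0.1, se=0.01, eaf=0.5, n=1000, p=1e-9):
    return SnpAssociation(
        rsid=rsid, effect_allele="A", other_allele="G",
        eaf=eaf, beta=beta, se=se, pvalue=p, n=n,
    )


class TestInstrumentStrength:
    def test_null_effect_gives_zero_strength(self):
        s = instrument_strength(assoc(beta=0.0))
        assert s.r2 == 0.0 and s.f_stat == 0.0

    def test_strong_instrument_arithmetic(self):
        # R² = 0.005/0.055, F = R²·998/(1−R²) on the printed equations
        s = instrument_strength(assoc(beta=0.1, eaf=0.5, se=0.01, n=1000), k=1)
        assert s.r2 == pytest.approx(0.005 / 0.055, rel=1e-12)
        assert s.f_stat == pytest.approx((0.005 / 0.055) * 998 / (1 - 0.005 / 0.055), rel=1e-12)
        assert s.f_stat == pytest.approx(99.8, rel=1e-3)

    def test_weak_instrument_arithmetic(self):
        s = instrument_strength(assoc(beta=0.02, eaf=0.2, se=0.01, n=50_000), k=1)
        assert s.r2 == pytest.approx(8.0e-5, rel=1e-2)
        assert s.f_stat == pytest.approx(4.0, rel=1e-2)
        assert s.f_stat < 10

    def test_missing_eaf_signals_unavailable(self):
        with pytest.raises(StrengthUnavailableError):
            instrument_strength(assoc(eaf=float("nan")))

    def test_f_monotone_in_r2(self):
        betas = np.linspace(0.01, 0.5, 20)
        stats = [instrument_strength(assoc(beta=b)) for b in betas]
        r2s = [s.r2 for s in stats]
        fs = [s.f_stat for s in stats]
        assert all(np.diff(r2s) > 0) and all(np.diff(fs) > 0)


def cand_df(entries):
    """entries: (rsid, pvalue) tuples."""
    return pd.DataFrame(
        {
            "rsid": [e[0] for e in entries],
            "effect_allele": "A", "other_allele": "G", "eaf": 0.3,
            "beta": 0.1, "se": 0.01,
            "pvalue": [e[1] for e in entries],
            "n": 100_000,
        }
    )


class TestClump:
    def test_single_snp_kept(self):
        assert clump(cand_df([("rs1", 1e-9)]), LdMatrix(), 0.001) == ["rs1"]

    def test_greedy_rule_on_three_snps(self):
        ld = LdMatrix({("rs1", "rs2"): 0.5, ("rs1", "rs3"): 0.0001, ("rs2", "rs3"): 0.0002})
        out = clump(cand_df([("rs1", 1e-10), ("rs2", 1e-9), ("rs3", 1e-8)]), ld, 0.001)
        assert out == ["rs1", "rs3"]

    def test_result_independent_of_input_order(self):
        ld = LdMatrix({("rs1", "rs2"): 0.5, ("rs1", "rs3"): 0.0001})
        entries = [("rs1", 1e-10), ("rs2", 1e-9), ("rs3", 1e-8)]
        a = clump(cand_df(entries), ld, 0.001)
        b = clump(cand_df(entries[::-1]), ld, 0.001)
        assert a == b

    def test_p_ties_broken_by_rsid(self):
        ld = LdMatrix({("rsA", "rsB"): 0.9})
        out = clump(cand_df([("rsB", 1e-9), ("rsA", 1e-9)]), ld, 0.001)
        assert out == ["rsA"]

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.data())
    def test_matches_brute_force_acceptance_oracle(self, data):
        n = data.draw(st.integers(2, 8))
        pvals = data.draw(
            st.lists(st.floats(1e-30, 1e-8), min_size=n, max_size=n, unique=True)
        )
        rsids = [f"rs{j}" for j in range(n)]
        ld = LdMatrix()
        for i in range(n):
            for j in range(i + 1, n):
                ld.set(rsids[i], rsids[j], data.draw(st.sampled_from([0.0, 0.0005, 0.1, 1.0])))
        result = clump(cand_df(list(zip(rsids, pvals))), ld, 0.001)

        # oracle: membership check in sorted sweep order, written naively
        order = sorted(zip(pvals, rsids))
        accepted = []
        for _, rsid in order:
            if not any(ld.get(rsid, a) >= 0.001 for a in accepted):
                accepted.append(rsid)
        assert result == accepted


class TestFindProxy:
    def test_query_present_returns_itself(self):
        assert find_proxy("rs1", LdMatrix(), {"rs1"}) == "rs1"

    def test_boundary_r2_excluded_by_strict_inequality(self):
        ld = LdMatrix({("rs1", "rs2"): 0.8})
        assert find_proxy("rs1", ld, {"rs2"}) is None

    def test_best_r2_wins(self):
        ld = LdMatrix({("rs1", "rs2"): 0.85, ("rs1", "rs3"): 0.95})
        assert find_proxy("rs1", ld, {"rs2", "rs3"}) == "rs3"

    def test_tie_broken_lexicographically(self):
        ld = LdMatrix({("rs1", "rsB"): 0.9, ("rs1", "rsA"): 0.9})
        assert find_proxy("rs1", ld, {"rsA", "rsB"}) == "rsA"

    def test_unavailable_candidates_ignored(self):
        ld = LdMatrix({("rs1", "rs2"): 0.95})
        assert find_proxy("rs1", ld, {"rs9"}) is None


class TestSelectInstruments:
    def strong_row(self, rsid, p):
        return (rsid, "A", "G", 0.5, 0.1, 0.01, p, 100_000)

    def test_significance_threshold_applied(self, make_table):
        table = make_table(
            [self.strong_row("rs1", 1e-9), self.strong_row("rs2", 2e-8),
             self.strong_row("rs3", 1e-7)]
        )
        sel = select_instruments(table)
        assert sorted(sel.rsids) == ["rs1", "rs2"]
        assert sel.exclusions["rs3"] == "below_threshold"
        assert sel.k == 2

    def test_all_below_threshold_raises(self, make_table):
        table = make_table([self.strong_row("rs1", 1e-7)], trait_name="enzyme")
        with pytest.raises(NoInstrumentsError, match="enzyme"):
            select_instruments(table)

    def test_weak_instrument_removed(self, make_table):
        weak = ("rs2", "A", "G", 0.2, 0.02, 0.01, 1e-9, 50_000)  # F ≈ 4
        table = make_table([self.strong_row("rs1", 1e-9), weak])
        sel = select_instruments(table)
        assert sel.rsids == ["rs1"]
        assert sel.exclusions["rs2"] == "weak"

    def test_missing_eaf_logged(self, make_table):
        table = make_table(
            [self.strong_row("rs1", 1e-9),
             ("rs2", "A", "G", float("nan"), 0.1, 0.01, 1e-9, 100_000)]
        )
        sel = select_instruments(table)
        assert sel.exclusions["rs2"] == "missing_eaf"

    def test_clumped_snps_logged(self, make_table):
        table = make_table([self.strong_row("rs1", 1e-10), self.strong_row("rs2", 1e-9)])
        sel = select_instruments(table, LdMatrix({("rs1", "rs2"): 0.9}))
        assert sel.rsids == ["rs1"]
        assert sel.exclusions["rs2"] == "clumped"

    def test_every_snp_retained_or_logged(self, make_table):
        rows = [
            self.strong_row("rs1", 1e-10),
            self.strong_row("rs2", 1e-9),
            self.strong_row("rs3", 1e-6),
            ("rs4", "A", "G", 0.2, 0.02, 0.01, 1e-9, 50_000),
            ("rs5", "A", "G", float("nan"), 0.1, 0.01, 1e-9, 100_000),
        ]
        table = make_table(rows)
        sel = select_instruments(table, LdMatrix({("rs1", "rs2"): 0.9}))
        assert set(sel.rsids) | set(sel.exclusions) == {r[0] for r in rows}
        assert set(sel.rsids).isdisjoint(sel.exclusions)

    def test_config_validation(self):
        with pytest.raises(ConfigurationError):
            SelectionConfig(p_threshold=0).validate()
        with pytest.raises(ConfigurationError):
            SelectionConfig(proxy_r2=1.0).validate()


class TestLdMatrix:
    def test_symmetry_diagonal_and_default(self):
        ld = LdMatrix({("rs2", "rs1"): 0.4})
        assert ld.get("rs1", "rs2") == ld.get("rs2", "rs1") == 0.4
        assert ld.get("rs1", "rs1") == 1.0
        assert ld.get("rs1", "rs9") == 0.0

    def test_round_trip_through_tsv(self, tmp_path):
        ld = LdMatrix({("rs1", "rs2"): 0.25, ("rs1", "rs3"): 0.9})
        path = tmp_path / "ld.tsv"
        ld.write(path)
        again = LdMatrix.read(path)
        assert again.get("rs2", "rs1") == 0.25
        assert again.get("rs3", "rs1") == 0.9

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            LdMatrix({("rs1", "rs2"): 1.5})
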