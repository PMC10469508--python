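import numpy as np
import pandas as pd
import pytest

from mrkit.harmonize import HarmonizedSet
from mrkit.sumstats import CANONICAL_COLUMNS, SummaryStatsTable


@pytest.fixture
def make_table():
    """Factory building a SummaryStatsTable from per-SNP tuples
    (rsid, ea, oa, eaf, beta, se, pvalue, n)."""

    def _make(rows, trait_name="trait", trait_type="continuous", n_cases=None):
        df = pd.DataFrame(rows, columns=CANONICAL_COLUMNS)
        return SummaryStatsTable(
            trait_name=trait_name,
            trait_type=trait_type,
            n_total=int(df["n"].max()),
            n_cases=n_cases,
            df=df,
        )

    return _make


@pytest.fixture
def make_hset():
    """Factory building a HarmonizedSet straight from effect arrays."""

    def _make(bx, by, se_out, se_exp=None, rsids=None,
              exposure="exposure", outcome="outcome"):
        bx = np.asarray(bx, dtype=float)
        by = np.asarray(by, dtype=float)
        se_out = np.asarray(se_out, dtype=float) * np.ones_like(bx)
        se_exp = (
            np.asarray(se_exp, dtype=float) * np.ones_like(bx)
            if se_exp is not None
            else np.full_like(bx, 1e-3)
        )
        n = len(bx)
        rsids = rsids or [f"rs{j + 1:04d}" for j in range(n)]
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
        return HarmonizedSet(exposure=exposure, outcome=outcome, df=df)

    return _make


@pytest.fixture
def write_tsv(tmp_path):
    """Write rows under arbitrary header names to a temp TSV."""

    def _write(header, rows, name="sumstats.tsv", sep="\t"):
        path = tmp_path / name
        lines = [sep.join(header)]
        lines += [sep.join(str(v) for v in row) for row in rows]
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write
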