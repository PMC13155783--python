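import numpy as np
import pandas as pd
import pytest

from mrmediate import HarmonizedSet, SummaryDataset


def make_records(
    n: int,
    seed: int = 0,
    beta_scale: float = 0.1,
    palindromic: bool = False,
) -> pd.DataFrame:
    """Small well-formed summary-statistics frame for I/O and unit tests."""
    rng = np.random.default_rng(seed)
    pairs = [("A", "T"), ("C", "G")] if palindromic else [("A", "G"), ("C", "A"), ("T", "C")]
    ea, oa = zip(*(pairs[i % len(pairs)] for i in range(n)))
    beta = rng.normal(0.0, beta_scale, size=n)
    se = rng.uniform(0.01, 0.05, size=n)
    from scipy import stats

    return pd.DataFrame(
        {
            "snp_id": [f"rs{i + 1}" for i in range(n)],
            "chrom": [str(i % 22 + 1) for i in range(n)],
            "pos": np.arange(1, n + 1) * 1_000_000,
            "effect_allele": list(ea),
            "other_allele": list(oa),
            "eaf": rng.uniform(0.05, 0.95, size=n),
            "beta": beta,
            "se": se,
            "pval": 2 * stats.norm.sf(np.abs(beta) / se),
            "n": 5000,
        }
    )


def make_harmonized(
    beta_exp,
    beta_out,
    se_exp=None,
    se_out=None,
    exposure_id="exp",
    outcome_id="out",
) -> HarmonizedSet:
    """HarmonizedSet straight from beta arrays (unit-test fixture)."""
    beta_exp = np.asarray(beta_exp, dtype=float)
    beta_out = np.asarray(beta_out, dtype=float)
    k = len(beta_exp)
    se_exp = np.full(k, 0.01) if se_exp is None else np.asarray(se_exp, dtype=float)
    se_out = np.full(k, 0.01) if se_out is None else np.asarray(se_out, dtype=float)
    table = pd.DataFrame(
        {
            "snp_id": [f"rs{i + 1}" for i in range(k)],
            "effect_allele": "A",
            "other_allele": "G",
            "beta_exp": beta_exp,
            "se_exp": se_exp,
            "eaf_exp": 0.3,
            "beta_out": beta_out,
            "se_out": se_out,
            "eaf_out": 0.3,
        }
    )
    return HarmonizedSet(exposure_id, outcome_id, table)


@pytest.fixture
def small_dataset() -> SummaryDataset:
    return SummaryDataset("trait", make_records(20, seed=3))


@pytest.fixture
def harmonized_line() -> HarmonizedSet:
    """Ten SNPs lying exactly on beta_out = 0.02 + 0.3 * beta_exp."""
    beta_exp = np.linspace(0.05, 0.5, 10)
    return make_harmonized(beta_exp, 0.02 + 0.3 * beta_exp)
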