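import numpy as np
import pandas as pd
import pytest

from mrmediate.gwas_io import CANONICAL_COLUMNS, SummaryStatTable
from mrmediate.instruments import HarmonizedSet

_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("C", "T"), ("G", "T")]


def random_table(rng: np.random.Generator, n: int = 20,
                 trait_id: str = "trait") -> SummaryStatTable:
    """A valid random summary-stat table for property tests."""
    pairs = [_ALLELE_PAIRS[i] for i in rng.integers(0, len(_ALLELE_PAIRS), n)]
    df = pd.DataFrame({
        "snp_id": [f"rs{i}" for i in range(n)],
        "chrom": rng.integers(1, 23, n).astype(str),
        "pos": rng.integers(1, 10**8, n),
        "effect_allele": [p[0] for p in pairs],
        "other_allele": [p[1] for p in pairs],
        "eaf": rng.uniform(0.05, 0.95, n),
        "beta": rng.normal(0, 0.3, n),
        "se": rng.uniform(0.01, 0.2, n),
        "pvalue": rng.uniform(1e-12, 1, n),
        "n": float(rng.integers(1000, 100000)),
    })
    return SummaryStatTable(trait_id=trait_id, records=df[CANONICAL_COLUMNS])


def random_hset(rng: np.random.Generator, n_snp: int = 10, theta: float = 0.3,
                se_exp_scale: float = 0.02, se_out_scale: float = 0.05
                ) -> HarmonizedSet:
    """Harmonized set with true causal slope ``theta`` and valid instruments."""
    bx_true = rng.uniform(0.1, 0.5, n_snp) * rng.choice([-1, 1], n_snp)
    sx = np.full(n_snp, se_exp_scale)
    sy = np.full(n_snp, se_out_scale)
    bx = bx_true + sx * rng.standard_normal(n_snp)
    by = theta * bx_true + sy * rng.standard_normal(n_snp)
    return HarmonizedSet.from_arrays(bx, sx, by, sy)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def hset(rng):
    return random_hset(rng, n_snp=12)


@pytest.fixture(scope="session")
def clean_study():
    from mrmediate.synthetic import SimConfig, simulate_study
    return simulate_study(SimConfig(seed=42))
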