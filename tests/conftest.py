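import numpy as np
import pandas as pd
import pytest

from polylink.pipeline import make_fixture
from polylink.simulate import SimConfig, build_genome, draw_effects
from polylink.sumstats import SumstatTable


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study with individual-level discovery GWAS."""
    return SimConfig(n_variants=300, n_blocks=60, n_cases=400, n_controls=400,
                     n_confounder=1500, n_cohort=1200, n_outcomes=4,
                     gwas_mode="individual", seed=7)


@pytest.fixture(scope="session")
def small_genome(small_config):
    return build_genome(small_config, np.random.default_rng(small_config.seed))


@pytest.fixture(scope="session")
def small_truth(small_config, small_genome):
    return draw_effects(small_config, small_genome, np.random.default_rng(1))


@pytest.fixture()
def mvr15():
    return make_fixture("mvr-15")


@pytest.fixture()
def clump12():
    return make_fixture("clump-12")


def toy_sumstats(n=8, seed=0, trait="trait", trait_type="quantitative",
                 **overrides) -> SumstatTable:
    """Small valid sumstat table for IO/harmonization tests."""
    rng = np.random.default_rng(seed)
    beta = rng.normal(0, 0.1, n)
    se = np.full(n, 0.05)
    from scipy import stats
    df = pd.DataFrame({
        "variant_id": [f"rs{i}" for i in range(n)],
        "chr": ["1"] * n,
        "pos": 1000 + 10_000 * np.arange(n),
        "effect_allele": ["A"] * n,
        "other_allele": ["G"] * n,
        "beta": beta,
        "se": se,
        "pvalue": 2 * stats.norm.sf(np.abs(beta / se)),
        "eaf": rng.uniform(0.1, 0.9, n),
        "info": rng.uniform(0.81, 1.0, n),
        "n": 5000,
    })
    for k, v in overrides.items():
        df[k] = v
    return SumstatTable(trait=trait, trait_type=trait_type, data=df)
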