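import numpy as np
import pandas as pd
import pytest

from cortasym import compute_cai_table, default_config, generate_cohort
from cortasym.io import build_analysis_table


@pytest.fixture(scope="session")
def barcelona_cohort():
    """Small baseline-only cohort (19 CTR / 22 AMC / 19 SMC)."""
    return generate_cohort(default_config("barcelona_like", seed=11))


@pytest.fixture(scope="session")
def dian_small_cohort():
    """Scaled-down longitudinal cohort for fast model tests."""
    cfg = default_config(
        "dian_like",
        seed=12,
        n_per_group={"CTR": 40, "AMC": 40, "SMC_MCI": 20, "SMC_AD": 20},
        n_visits=4,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def dian_small_table(dian_small_cohort):
    return build_analysis_table(dian_small_cohort, compute_cai_table(dian_small_cohort))


@pytest.fixture(scope="session")
def barcelona_table(barcelona_cohort):
    return build_analysis_table(barcelona_cohort, compute_cai_table(barcelona_cohort))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
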