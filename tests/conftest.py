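import numpy as np
import pandas as pd
import pytest

from mrphescan.synthetic import SimulationConfig, simulate_cohort

SMALL_OUTCOMES = {"continuous": 6, "binary": 6, "ordered": 3, "unordered": 2,
                  "cat_multiple": 1}


@pytest.fixture(scope="session")
def small_cohort():
    """A 3000-participant cohort shared by read-only tests."""
    cfg = SimulationConfig(
        n_participants=3000, seed=11, n_outcomes_per_type=dict(SMALL_OUTCOMES)
    )
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def hand_sumstats():
    """Three-SNP summary-statistics table for closed-form checks."""
    return pd.DataFrame({
        "snp_id": ["rs1", "rs2", "rs3"],
        "beta_exposure": [0.05, 0.08, 0.12],
        "se_exposure": [0.004, 0.005, 0.006],
        "beta_outcome": [0.011, 0.014, 0.027],
        "se_outcome": [0.003, 0.004, 0.005],
    })
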