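import numpy as np
import pandas as pd
import pytest

from landsink import BudgetTable, SyntheticConfig, Uncertain, generate_all


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free study conditions: every round trip must be exact."""
    return SyntheticConfig(seed=7)


@pytest.fixture(scope="session")
def clean_data(clean_config):
    return generate_all(clean_config)


@pytest.fixture(scope="session")
def consensus_budget():
    """2000-2019 consensus budget period means (Pg C/yr, 1-sigma)."""
    return BudgetTable(
        means={
            "fossil": Uncertain(8.6, 0.4),
            "growth": Uncertain(4.6, 0.1),
            "ocean": Uncertain(2.5, 0.4),
            "land": Uncertain(1.6, 0.6),
        },
        period=(2000, 2019),
    )


@pytest.fixture(scope="session")
def weak_sink_budget():
    """Proposed weak-land-sink budget period means (Pg C/yr, 1-sigma)."""
    return BudgetTable(
        means={
            "fossil": Uncertain(8.1, 0.9),
            "growth": Uncertain(4.6, 0.1),
            "ocean": Uncertain(2.7, 0.5),
            "land": Uncertain(0.8, 0.7),
        },
        period=(2000, 2019),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
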