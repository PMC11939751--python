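import numpy as np
import pandas as pd
import pytest

from brskit.survey import default_variable_specs
from brskit.synthetic_data import SimulationConfig, planted_rule


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_binary_features(rng, n=100, k=4, prefix="f"):
    """k base binary columns plus their complements, complement-paired names."""
    probs = rng.uniform(0.2, 0.8, k)
    X = (rng.random((n, k)) < probs).astype(np.uint8)
    cols = {}
    for j in range(k):
        cols[f"{prefix}{j}_high"] = X[:, j]
    for j in range(k):
        cols[f"NOT_{prefix}{j}_high"] = 1 - X[:, j]
    return pd.DataFrame(cols)


@pytest.fixture
def binary_fixture(rng):
    return random_binary_features(rng, n=100, k=4)


def small_specs():
    """Six-variable instrument for fast end-to-end tests."""
    full = default_variable_specs()
    keep = ["Jobs", "workt", "Selfd", "health", "age", "Sleepq"]
    return {k: full[k] for k in keep}


@pytest.fixture
def small_sim():
    return SimulationConfig(
        n=400,
        seed=5,
        variables=small_specs(),
        planted_rules=(planted_rule(("Selfd", "high"), ("workt", "low"),
                                    target_support=0.15),),
        noise_rate=0.0,
    )


def headline_rules():
    """The two planted rule patterns used for recovery studies."""
    return (
        planted_rule(("health", "med_or_high"), ("Selfd", "high"), ("workt", "low"),
                     target_support=0.12),
        planted_rule(("age", "high"), ("Sleepq", "med_or_high"), ("workt", "low"),
                     target_support=0.10),
    )
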