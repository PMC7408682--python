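import numpy as np
import pandas as pd
import pytest

from comorisk import reference
from comorisk.network import CentralityWeights, PartialCorrelationNetwork, eigenvector_centrality
from comorisk.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def reference_network() -> PartialCorrelationNetwork:
    return PartialCorrelationNetwork(
        labels=list(reference.FOOD_GROUPS),
        weights=reference.reference_network_matrix().to_numpy(),
    )


@pytest.fixture(scope="session")
def reference_weights(reference_network) -> CentralityWeights:
    return eigenvector_centrality(reference_network)


def clean_config(**kw) -> SimulationConfig:
    """Simulation config with the exclusion-cascade rates switched off."""
    base = dict(
        energy_bounds_violation_rate=0.0,
        missingness_rate=0.0,
        prior_cancer_rate=0.0,
        early_case_rate=0.0,
    )
    base.update(kw)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def clean_cohort() -> pd.DataFrame:
    """A mid-size clean cohort shared across read-only tests."""
    return generate_cohort(clean_config(n_subjects=5000, seed=101))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
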