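import numpy as np
import pytest

from irdselect import expression, prevalence
from irdselect.simulate import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(seed=3)


@pytest.fixture(scope="session")
def bundle(sim_config):
    """One full synthetic input bundle shared across tests."""
    return simulate_all(sim_config)


@pytest.fixture(scope="session")
def prevalence_table(bundle):
    return prevalence.compute_prevalence(bundle["alleles"], bundle["populations"])


@pytest.fixture(scope="session")
def labeled_counts(bundle) -> expression.LabeledCounts:
    return expression.LabeledCounts(
        matrix=bundle["counts"],
        cell_types=bundle["cells"]["cell_type"].to_numpy(),
        gene_symbols=bundle["count_genes"],
    )


@pytest.fixture(scope="session")
def normalized(labeled_counts):
    return expression.normalize(labeled_counts)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
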