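import numpy as np
import pytest

from pedpop.genotypes import AlleleFrequencyTable, Genotype, LocusPanel
from pedpop.simulate import SimulationParams, simulate_population


@pytest.fixture(scope="session")
def biallelic_table() -> AlleleFrequencyTable:
    return AlleleFrequencyTable({"L1": {1: 0.5, 2: 0.5}})


@pytest.fixture(scope="session")
def small_panel() -> LocusPanel:
    return LocusPanel(("L1", "L2", "L3", "L4"), ("L1", "L2"))


@pytest.fixture(scope="session")
def small_truth():
    """A compact simulated population shared across read-only tests."""
    params = SimulationParams(
        seed=101,
        initial_size=60,
        start_year=2008,
        genotyping_error=0.0,
        locus_missing_prob=0.0,
        monitored_fraction=1.0,
    )
    return simulate_population(params)


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
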