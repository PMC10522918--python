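import numpy as np
import pytest

from prognoscore.datamodel import ScreenCriteria
from prognoscore.simulate import PlantedGene, SimulationConfig, simulate_multicohort


@pytest.fixture(scope="session")
def screen_cohorts():
    """Five small cohorts with two dual-endpoint planted genes, one
    OS-only planted gene and null genes; shared across screening tests."""
    planted = (
        PlantedGene("DUAL_A", 0.9, on_ep2=True),
        PlantedGene("DUAL_B", 0.9, on_ep2=True),
        PlantedGene("OSONLY_C", 0.9, on_ep2=False),
    )
    cfg = SimulationConfig(
        cohort_sizes=(170, 160, 180, 150, 160),
        n_genes=20,
        planted_genes=planted,
        seed=42,
    )
    cohorts, truth = simulate_multicohort(cfg)
    return cohorts, truth


@pytest.fixture(scope="session")
def criteria():
    return ScreenCriteria()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
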