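import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def primate_tree():
    from sfpevol import fixed_primate_tree

    return fixed_primate_tree()


@pytest.fixture(scope="session")
def uniform_pi():
    from sfpevol.codon import uniform_frequencies

    return uniform_frequencies()


@pytest.fixture(scope="session")
def small_quant():
    """A small simulated quant dataset shared by quant/compare tests."""
    from sfpevol import SimulationDesign, simulate_quant_dataset

    design = SimulationDesign(
        seed=11,
        n_proteins=30,
        peptides_per_protein=5,
        fraction_shared=0.5,
        n_responsive=4,
        missing_rate=0.03,
    )
    return simulate_quant_dataset(design)
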