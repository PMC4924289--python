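import hypothesis
import numpy as np
import pytest

hypothesis.settings.register_profile(
    "orthofuzz", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("orthofuzz")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_truth():
    """A small uncorrupted simulation shared across tests (fast, no losses)."""
    from orthofuzz.synthetic_data import SimulationConfig, simulate

    return simulate(
        SimulationConfig(
            seed=11,
            n_species=4,
            n_genes=6,
            loss_rate=0.0,
            duplication_rate=0.0,
            corruption_mix={"intact": 1.0},
            protein_length=(80, 140),
        )
    )
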