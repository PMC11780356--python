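import pytest

from trioquant.synthgen import SynthConfig, make_experiment


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down study configuration for fast unit tests."""
    return SynthConfig(
        seed=42, n_animals_per_target=2, n_L6_cells=450, n_L5_cells=50,
        n_brainwide_inputs=600, n_starter_cells=150, n_sc_cells=120,
    )


@pytest.fixture(scope="session")
def pm_experiment(small_config):
    return make_experiment(small_config, "PM", "PM1")
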