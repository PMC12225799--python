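import pytest

from trefoilkit.simulate import SimulationConfig, evolve_family, make_template_structure


@pytest.fixture(scope="session")
def template():
    return make_template_structure(150, 1)


@pytest.fixture(scope="session")
def default_family(template):
    """One default-config synthetic family (64 taxa, 150 columns)."""
    return evolve_family(template, SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def small_family(template):
    """A small family for the slower structural-alignment tests."""
    return evolve_family(template, SimulationConfig(seed=43, n_taxa=12))
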