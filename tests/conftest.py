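import pytest

from crisprcoev.catalog import build_global_catalog, classify_conserved_variable
from crisprcoev.simulate import SimConfig, make_study_scale_scenario, simulate


@pytest.fixture(scope="session")
def sim():
    """One default-condition synthetic run, shared across tests."""
    return simulate(SimConfig(seed=7))


@pytest.fixture(scope="session")
def sim_catalog(sim):
    cat = build_global_catalog(sim.isolate_arrays())
    return classify_conserved_variable(cat)


@pytest.fixture(scope="session")
def study_sim():
    """A study-scale run: 17 bacteria 2007-2013, 30 phages 2009-2014."""
    return simulate(make_study_scale_scenario(seed=11))
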