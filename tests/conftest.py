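import pytest

from kinopipe import simulate


@pytest.fixture(scope="session")
def stk_layout():
    return simulate.ArrayLayout.stk()


@pytest.fixture(scope="session")
def ptk_layout():
    return simulate.ArrayLayout.ptk()


@pytest.fixture(scope="session")
def stk_map(stk_layout):
    return simulate.make_kinase_map(stk_layout, seed=0)


@pytest.fixture
def noise_free_config(stk_layout, stk_map):
    """Noise-free STK run with planted dead and saturating peptides."""
    return simulate.SimulationConfig(
        layout=stk_layout, kinase_map=stk_map, noise_sd=0.0,
        dead_peptide_frac=0.1, saturating_peptide_frac=0.1, seed=11)


@pytest.fixture
def clean_config(stk_layout, stk_map):
    """Noise-free STK run with no planted failures and no effects."""
    return simulate.SimulationConfig(
        layout=stk_layout, kinase_map=stk_map, noise_sd=0.0, seed=5)
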