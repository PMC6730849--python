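import pytest

from fusedmat.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition simulated panel (3 species x [A1, A2])."""
    return simulate_dataset(SimConfig(seed=11))


@pytest.fixture(scope="session")
def trio_dataset():
    """V. humicola-like trio: one species with one A1 and two A2 strains."""
    cfg = SimConfig(n_species=2,
                    strains_per_species=[["A1", "A2", "A2"], ["A1", "A2"]],
                    seed=23)
    return simulate_dataset(cfg)
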