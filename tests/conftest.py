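import pytest

from capscaffold.kinetics import RateParameterSet, TotalsConfig, default_parameters
from capscaffold.network import add_translation_stage, generate_network


@pytest.fixture(scope="session")
def full_network():
    """The four-ligand assembly network (211 species, 1744 reactions)."""
    return generate_network(4)


@pytest.fixture(scope="session")
def final_network(full_network):
    """Assembly network plus the two translation-stage reactions (215/1746)."""
    return add_translation_stage(generate_network(4))


@pytest.fixture(scope="session")
def toy_network():
    """One-ligand network augmented with the translation stage (10 species)."""
    return add_translation_stage(generate_network(1))


@pytest.fixture(scope="session")
def toy_params():
    return RateParameterSet.symmetric(
        ligands=("A",), kon=1e-4, koff=1.0, kc=10.0, koff_bridge=1.0,
        k_init=5e-6, k_elong=2.0)


@pytest.fixture(scope="session")
def toy_totals():
    return TotalsConfig(totals={"G": 22_000.0, "R": 60_000.0, "A": 25_000.0})


@pytest.fixture(scope="session")
def shipped_params():
    return default_parameters()


@pytest.fixture(scope="session")
def shipped_totals():
    return TotalsConfig()
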