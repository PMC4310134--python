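import pytest

from efmscreen import enumerate_efms, parse_network
from efmscreen.builder import build_core_model, load_main_network

CHAIN = """
R_up: -> A | irrev | exchange
R1: A -> B | irrev | core
R_ex: B -> | irrev | exchange
"""

DIAMOND = """
R_up: -> A | irrev | exchange
R1: A -> B | irrev | core
R2: A -> C | irrev | core
R3: B -> D | irrev | core
R4: C -> D | irrev | core
R_ex: D -> | irrev | exchange
"""


@pytest.fixture(scope="session")
def chain_network():
    return parse_network(CHAIN)


@pytest.fixture(scope="session")
def diamond_network():
    return parse_network(DIAMOND)


@pytest.fixture(scope="session")
def main_network():
    return load_main_network()


def _census_cell(substrate, product, scenario):
    """Condensed screening cell plus its full mode set (cached per session)."""
    uptake = {"glucose": "R61", "glycerol": "R62", "fumarate": "R63"}[substrate]
    net = build_core_model(substrate, product, scenario, condensed=True)
    modes = enumerate_efms(net, substrate_reaction=uptake)
    return net, modes


@pytest.fixture(scope="session")
def pdo_cat1_cell():
    return _census_cell("glucose", "1,3-PDO", "Cat1")


@pytest.fixture(scope="session")
def pa_cat1_cell():
    return _census_cell("glucose", "PA", "Cat1")


@pytest.fixture(scope="session")
def glycerol_pdo_cat1_cell():
    return _census_cell("glycerol", "1,3-PDO", "Cat1")
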