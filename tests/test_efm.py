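"""Enumeration engine: splitting, folding, elementarity, invariances."""

import random
from fractions import Fraction

import pytest

from efmscreen import (EnumerationOverflow, enumerate_efms, is_elementary,
                       parse_network, split_reversible)
from efmscreen.network import MetabolicNetwork, Reaction
from efmscreen.synth import RandomNetworkSpec, random_network


def canon(modes):
    return {m.canonical() for m in modes}


class TestSplitting:
    def test_expanded_column_count(self, main_network):
        expanded, split = split_reversible(main_network)
        # 75 reactions of which 24 reversible -> 99 irreversible columns
        assert len(expanded.reactions) == 99
        assert len(split.columns) == 99
        assert all(not r.reversible for r in expanded.reactions)

    def test_irreversible_network_identity(self, chain_network):
        expanded, split = split_reversible(chain_network)
        assert [r.id for r in expanded.reactions] == chain_network.reaction_ids

    def test_fold_split_round_trip(self, main_network):
        _, split = split_reversible(main_network)
        flux = {"R3": Fraction(-2, 3), "R2": Fraction(1), "R12": Fraction(5)}
        assert split.fold(split.split(flux)) == flux


class TestEnumeration:
    def test_single_path_chain(self, chain_network):
        modes = enumerate_efms(chain_network)
        assert len(modes) == 1
        assert modes[0].flux == {"R_up": 1, "R1": 1, "R_ex": 1}

    def test_diamond_has_two_modes(self, diamond_network):
        modes = enumerate_efms(diamond_network)
        assert len(modes) == 2
        assert {frozenset(m.support) for m in modes} == {
            frozenset({"R_up", "R1", "R3", "R_ex"}),
            frozenset({"R_up", "R2", "R4", "R_ex"})}

    def test_empty_network(self):
        net = MetabolicNetwork([], [])
        assert enumerate_efms(net) == []

    def test_two_cycles_removed(self):
        net = parse_network("""
            R_up: -> A | irrev | exchange
            R1: A -> B | rev | core
            R_ex: B -> | irrev | exchange
        """)
        modes = enumerate_efms(net)
        assert len(modes) == 1  # the forward/backward two-cycle is not a mode

    def test_reversible_only_cycle_has_both_orientations(self):
        net = parse_network("""
            R1: A -> B | rev | core
            R2: B -> A | rev | core
        """)
        modes = enumerate_efms(net)
        assert len(modes) == 2
        assert canon(modes) == {(("R1", Fraction(1)), ("R2", Fraction(1))),
                                (("R1", Fraction(-1)), ("R2", Fraction(-1)))}

    def test_deterministic_output(self, diamond_network):
        a = enumerate_efms(diamond_network)
        b = enumerate_efms(diamond_network)
        assert [m.canonical() for m in a] == [m.canonical() for m in b]

    def test_permutation_invariance(self):
        spec = RandomNetworkSpec(n_internal_metabolites=4, n_reactions=10,
                                 reversible_fraction=0.4, seed=7)
        net = random_network(spec)
        rng = random.Random(1)
        rxns = list(net.reactions)
        mets = list(net.metabolites)
        rng.shuffle(rxns)
        rng.shuffle(mets)
        permuted = MetabolicNetwork(mets, rxns)
        assert canon(enumerate_efms(net)) == canon(enumerate_efms(permuted))

    def test_duplicate_reaction_only_adds_modes(self, diamond_network):
        dup = Reaction(id="R1_copy",
                       stoichiometry=dict(diamond_network.reaction("R1").stoichiometry))
        bigger = diamond_network.with_reactions_added([dup])
        base = canon(enumerate_efms(diamond_network))
        extended = enumerate_efms(bigger)
        kept = {m.canonical() for m in extended if "R1_copy" not in m.support}
        assert kept == base
        assert all("R1_copy" in m.support
                   for m in extended if m.canonical() not in base)

    def test_compression_is_transparent(self):
        for seed in (3, 11):
            net = random_network(RandomNetworkSpec(4, 10, 0.3, 3, seed))
            assert canon(enumerate_efms(net, compress=True)) == \
                   canon(enumerate_efms(net, compress=False))

    def test_overflow_guard(self, main_network):
        from efmscreen.builder import build_core_model
        net = build_core_model("glucose", "1,3-PDO", "Cat1", condensed=True)
        with pytest.raises(EnumerationOverflow):
            enumerate_efms(net, max_rays=50)

    def test_substrate_normalization(self, chain_network):
        modes = enumerate_efms(chain_network, substrate_reaction="R_up")
        assert modes[0].normalized_by == "R_up"
        assert modes[0]["R_up"] == 1


class TestIsElementary:
    def test_chain_flux_is_elementary(self, chain_network):
        assert is_elementary(chain_network,
                             {"R_up": Fraction(2), "R1": Fraction(2), "R_ex": Fraction(2)})

    def test_sum_of_diamond_modes_is_not(self, diamond_network):
        combined = {"R_up": 2, "R1": 1, "R2": 1, "R3": 1, "R4": 1, "R_ex": 2}
        assert not is_elementary(diamond_network,
                                 {k: Fraction(v) for k, v in combined.items()})

    def test_every_enumerated_mode_is_elementary(self):
        net = random_network(RandomNetworkSpec(4, 10, 0.3, 3, seed=5))
        modes = enumerate_efms(net)
        assert modes
        assert all(is_elementary(net, m.flux) for m in modes)

    def test_non_steady_vector_is_an_error(self, diamond_network):
        with pytest.raises(ValueError, match="steady state"):
            is_elementary(diamond_network, {"R1": Fraction(1)})

    def test_irreversibility_violation_is_an_error(self, chain_network):
        with pytest.raises(ValueError, match="irreversible"):
            is_elementary(chain_network, {"R_up": Fraction(-1), "R1": Fraction(-1),
                                          "R_ex": Fraction(-1)})
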