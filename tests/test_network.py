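"""Reaction-table parsing, the packaged core network, and validation."""

from fractions import Fraction

import pytest

from efmscreen import (ElementalComposition, NetworkParseError, parse_network,
                       parse_compositions, serialize_network,
                       serialize_compositions, validate_network)
from efmscreen.builder import build_core_model, load_main_network
from efmscreen.network import Reaction


class TestParsing:
    def test_single_exchange_line(self):
        net = parse_network("R_up: glc_ext -> glc | irrev | exchange")
        assert len(net.reactions) == 1
        rxn = net.reactions[0]
        assert rxn.tag == "exchange" and not rxn.reversible
        assert net.metabolite("glc_ext").external
        assert not net.metabolite("glc").external
        # S is over internal metabolites only
        assert net.S.shape == (1, 1)

    def test_decimal_coefficient_exact(self):
        net = parse_network("R47: nadh + 0.33 atp -> nadph | irrev | core")
        assert net.reactions[0].stoichiometry["atp"] == Fraction(-33, 100)

    def test_fraction_coefficient(self):
        net = parse_network("R: a -> 1/3 b | irrev | core")
        assert net.reactions[0].stoichiometry["b"] == Fraction(1, 3)

    @pytest.mark.parametrize("text, lineno, fragment", [
        ("R1: a -> b | irrev | core\nR1: b -> c | irrev | core", 2, "duplicate"),
        ("R1: a -> b c d | irrev | core", 1, "malformed"),
        ("R1: a -> b | maybe | core", 1, "flag"),
        ("R1: a -> b | irrev", 1, "expected"),
        ("R1: 0.x a -> b | irrev | core", 1, "coefficient"),
    ])
    def test_parse_errors_carry_line_numbers(self, text, lineno, fragment):
        with pytest.raises(NetworkParseError, match=f"line {lineno}") as exc:
            parse_network(text)
        assert fragment in str(exc.value).lower()

    def test_round_trip_preserves_S(self, main_network):
        text = serialize_network(main_network)
        comps = serialize_compositions(main_network)
        again = parse_network(text, comps)
        assert again.stoichiometric_matrix() == main_network.stoichiometric_matrix()
        assert [r.reversible for r in again.reactions] == \
               [r.reversible for r in main_network.reactions]

    def test_compositions_sidecar(self):
        comps = parse_compositions("glc\tC6H12O6\nnh3\tNH3\n")
        assert comps["glc"] == ElementalComposition(carbon=6, hydrogen=12, oxygen=6)
        assert comps["nh3"].nitrogen == 1


class TestPackagedNetwork:
    def test_reported_dimensions(self, main_network):
        assert len(main_network.metabolites) == 57
        assert len(main_network.reactions) == 75
        assert main_network.n_reversible == 24

    def test_core_reactions_carbon_balanced(self, main_network):
        report = validate_network(main_network)
        assert report.carbon_balanced
        assert not report.orphan_metabolites

    def test_biomass_equation(self, main_network):
        eq = main_network.biomass_equation()
        assert eq.atp_cost > 0
        assert eq.nadh_yield > 0
        # 42.56 C-mmol per gram dry weight
        assert abs(float(eq.carbon_content) - 42.56) < 1e-9

    def test_transhydrogenase_atp_equivalents(self, main_network):
        # 0.33 ATP equivalents per transhydrogenation (1 H+ at 3 H+/ATP)
        rxn = main_network.reaction("R47")
        assert rxn.stoichiometry["atp"] == Fraction(-1, 3)


class TestValidation:
    def test_carbon_imbalance_flagged(self):
        net = parse_network("R1: A -> B | irrev | core",
                            {"A": ElementalComposition.from_formula("C6H12O6"),
                             "B": ElementalComposition.from_formula("C3H6O3")})
        report = validate_network(net)
        assert report.carbon_residuals["R1"] == -3
        assert not report.ok

    def test_biomass_reaction_exempt(self):
        net = parse_network("R1: A -> B | irrev | biomass",
                            {"A": ElementalComposition.from_formula("C6H12O6"),
                             "B": ElementalComposition.from_formula("C3H6O3")})
        report = validate_network(net)
        assert "R1" in report.exempt_reactions
        assert report.ok

    def test_dead_end_detection(self):
        net = parse_network("R_up: -> A | irrev | exchange\nR1: A -> B | irrev | core")
        report = validate_network(net)
        assert "R1" in report.dead_end_reactions


class TestBuilder:
    def test_single_substrate_uptake(self):
        net = build_core_model("glucose")
        assert net.has_reaction("R61")
        assert not net.has_reaction("R62") and not net.has_reaction("R63")
        assert not net.has_reaction("R64")  # anaerobic: no oxygen uptake

    def test_aerobic_enables_oxygen(self):
        net = build_core_model("glucose", aerobic=True)
        assert net.has_reaction("R64")

    def test_condensed_pdo_pathway_matches_lumping(self):
        # glucose-based route: DHAP -> glycerol-3-P -> glycerol -> 1,3-PDO,
        # i.e. half a glucose, one high-energy phosphate and two NADH per diol
        net = build_core_model("glucose", "1,3-PDO", "Cat1")
        rxn = net.reaction("R_pdo13")
        internal = {m: c for m, c in rxn.stoichiometry.items()
                    if not net.metabolite(m).external}
        assert internal == {"glyc": Fraction(-1), "nadh": Fraction(-1),
                            "pdo13": Fraction(1), "nad": Fraction(1)}
        assert net.has_reaction("R52") and net.has_reaction("R53")

    def test_unknown_product_rejected(self):
        with pytest.raises(KeyError, match="unobtainium"):
            build_core_model("glucose", "unobtainium")

    def test_aerobic_cathode_rejected(self):
        with pytest.raises(ValueError, match="[Aa]naerobiosis"):
            build_core_model("glucose", "1,3-PDO", "Cat1", aerobic=True)

    def test_unknown_substrate_rejected(self):
        with pytest.raises(ValueError, match="unknown substrate"):
            build_core_model("xylose")

    def test_reaction_requires_nonzero_stoichiometry(self):
        with pytest.raises(ValueError, match="nonzero"):
            Reaction(id="R", stoichiometry={"a": Fraction(0)})
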