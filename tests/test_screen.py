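"""Yield analytics: degree of reduction, carbon yields, censuses, screen."""

from fractions import Fraction

import pytest

from efmscreen import enumerate_efms, parse_network
from efmscreen.efm import ElementaryMode
from efmscreen.network import ElementalComposition
from efmscreen.screen import (by_product_spectrum, carbon_yield,
                              degree_of_reduction, growth_coupled_max_yield,
                              max_yield, mode_census, scatter_table, screen_all,
                              secretes)

C = ElementalComposition.from_formula


class TestDegreeOfReduction:
    @pytest.mark.parametrize("formula, expected", [
        ("C6H12O6", 4),            # glucose
        ("C2H6O", 6),              # ethanol
        ("C4H8O2", 5),             # butyric acid
        ("C4H10O2", Fraction(11, 2)),  # 2,3-butanediol
        ("CO2", 0),                # fully oxidized carbon
        ("C3H8O3", Fraction(14, 3)),   # glycerol: exact value, no rounding
        ("CH4", 8),                # methane: the most reduced carbon
    ])
    def test_closed_forms(self, formula, expected):
        assert degree_of_reduction(C(formula)) == expected

    def test_nitrogen_term(self):
        # lysine C6H14N2O2: (24 + 14 - 4 - 6)/6
        assert degree_of_reduction(C("C6H14N2O2")) == Fraction(14, 3)

    def test_carbon_free_species_rejected(self):
        with pytest.raises(ValueError):
            degree_of_reduction(C("H2O"))


FERMENT = """
R_up: glc_ext -> glc | irrev | exchange
R1: glc -> 2 etoh + 2 co2 | irrev | core
R2: glc -> 3 ac | irrev | core
R_etoh: etoh -> | irrev | exchange
R_co2: co2 -> | irrev | exchange
R_ac: ac -> | irrev | exchange
"""
FERMENT_COMPS = {"glc": C("C6H12O6"), "glc_ext": C("C6H12O6"),
                 "etoh": C("C2H6O"), "co2": C("CO2"), "ac": C("C2H4O2")}


@pytest.fixture(scope="module")
def ferment():
    net = parse_network(FERMENT, FERMENT_COMPS)
    return net, enumerate_efms(net, substrate_reaction="R_up")


class TestCarbonYield:
    def test_ethanol_from_glucose_is_two_thirds(self, ferment):
        net, modes = ferment
        etoh_mode = next(m for m in modes if "R1" in m.support)
        y = carbon_yield(etoh_mode, net, "etoh", "glc")
        assert y == Fraction(200, 3)  # 4 of 6 carbons

    def test_zero_product_flux_gives_zero(self, ferment):
        net, modes = ferment
        ac_mode = next(m for m in modes if "R2" in m.support)
        assert carbon_yield(ac_mode, net, "etoh", "glc") == 0

    def test_non_consuming_mode_is_undefined(self, ferment):
        net, _ = ferment
        fake = ElementaryMode({"R_co2": Fraction(1)})
        with pytest.raises(ValueError, match="consume"):
            carbon_yield(fake, net, "etoh", "glc")

    def test_spectrum_sums_to_100(self, ferment):
        net, modes = ferment
        for m in modes:
            assert sum(by_product_spectrum(m, net, "glc").values()) == 100

    def test_yields_bounded(self, ferment):
        net, modes = ferment
        for m in modes:
            for prod in ("etoh", "ac"):
                assert 0 <= carbon_yield(m, net, prod, "glc") <= 100


class TestMaxYield:
    def test_max_and_top_mode(self, ferment):
        net, modes = ferment
        res = max_yield(modes, net, "ac", "glc")
        assert res.yield_percent == 100
        assert "R2" in res.mode_ref.support

    def test_singleton(self, ferment):
        net, modes = ferment
        res = max_yield(modes[:1], net, "etoh", "glc")
        assert res.yield_percent == carbon_yield(modes[0], net, "etoh", "glc")

    def test_no_consuming_mode_is_infeasible(self, ferment):
        net, _ = ferment
        res = max_yield([ElementaryMode({"R_co2": Fraction(1)})], net, "etoh", "glc")
        assert not res.feasible

    def test_growth_coupled_none_result(self):
        # biomass is exchangeable but no mode can form it
        net = parse_network(FERMENT + "R_bio: biomass -> | irrev | exchange\n",
                            FERMENT_COMPS)
        modes = enumerate_efms(net, substrate_reaction="R_up")
        res = growth_coupled_max_yield(modes, net, "etoh", "glc")
        assert not res.feasible and res.growth_coupled


class TestCensusAndScatter:
    def test_census_counts(self, ferment):
        net, modes = ferment
        count, frac = mode_census(modes, secretes(net, "etoh"))
        assert count == 1 and frac == Fraction(1, 2)

    def test_census_empty_set(self):
        count, frac = mode_census([], lambda m: True)
        assert count == 0 and frac is None

    def test_census_singleton_satisfied(self, ferment):
        net, modes = ferment
        count, frac = mode_census(modes[:1], lambda m: True)
        assert (count, frac) == (1, 1)

    def test_scatter_empty(self, ferment):
        net, _ = ferment
        df = scatter_table([], net, "etoh", "glc")
        assert df.empty
        assert list(df.columns) == ["biomass_yield_percent", "product_yield_percent"]


class TestScreenAll:
    def test_empty_product_list_rejected(self):
        with pytest.raises(ValueError):
            screen_all(["glucose"], [], ["none"])

    def test_small_screen_shape_and_flags(self):
        report = screen_all(["glucose"], ["2,3-BDO", "1,4-BDO"],
                            ["none", "Cat1", "An2"])
        df = report.to_dataframe()
        assert len(df) == 6
        assert report.best_scenario[("glucose", "2,3-butanediol")] == "anode"
        assert report.best_scenario[("glucose", "1,4-butanediol")] == "cathode"

    def test_per_cell_failures_do_not_abort(self):
        report = screen_all(["glucose"], ["2,3-BDO"], ["none", "Cat1"],
                            overrides={"biomass.atp_cost": Fraction(-1)})
        # negative ATP cost breaks the biomass invariant in-cell, not the run
        assert len(report.rows) == 2

    def test_determinism(self, tmp_path):
        r1 = screen_all(["glucose"], ["2,3-BDO"], ["none", "An2"])
        r2 = screen_all(["glucose"], ["2,3-BDO"], ["none", "An2"])
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        r1.write_tsv(p1)
        r2.write_tsv(p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestPlots:
    def test_scatter_and_bar_rendering(self, tmp_path):
        pytest.importorskip("matplotlib")
        import pandas as pd
        from efmscreen.report import plot_scatter, plot_yield_bars
        df = pd.DataFrame({"biomass_yield_percent": [0.0, 10.0, 20.0],
                           "product_yield_percent": [90.0, 50.0, 30.0]})
        out = tmp_path / "scatter.png"
        plot_scatter(df, out, title="toy")
        assert out.stat().st_size > 0
        report = screen_all(["glucose"], ["2,3-BDO"], ["none", "An2"])
        bars = tmp_path / "bars.png"
        plot_yield_bars(report.to_dataframe(), bars, substrate="glucose")
        assert bars.stat().st_size > 0
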