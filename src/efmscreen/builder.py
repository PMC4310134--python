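"""Assembly of screening networks: core model + substrate + product + EET.

``build_core_model`` starts from the packaged anaerobic core network,
enables exactly one substrate uptake, appends the condensed production
pathway of the requested product and the electrode pseudo-reactions of the
requested electron-transport scenario, and enables oxygen exchange only for
the aerobic reference case.
"""

from __future__ import annotations

from fractions import Fraction
from importlib import resources
from typing import Mapping

from .eet import EETScenario, get_scenario, scenario_metabolite, scenario_reactions
from .network import (MetabolicNetwork, Metabolite, Reaction, parse_compositions,
                      parse_network)
from .products import PRODUCTS, ProductPathway, resolve_product

__all__ = ["SUBSTRATES", "load_main_network", "build_core_model",
           "substrate_uptake_reaction", "export_reaction"]

#: substrate name -> (internal metabolite id, uptake reaction id)
SUBSTRATES: dict[str, tuple[str, str]] = {
    "glucose": ("glc", "R61"),
    "glycerol": ("glyc", "R62"),
    "fumarate": ("fum", "R63"),
}

#: composite routes: each of these columns is a non-negative combination of
#: retained reactions (e.g. pyruvate oxidase = PDH + acetate kinase + NADH
#: dehydrogenase II + ATP dissipation), so removing them provably leaves
#: the steady-state flux cone — and every LP yield ceiling — unchanged
#: while shrinking the elementary-mode count for full enumeration.
COMPOSITE_ROUTES = ("R22", "R25", "R51", "R55", "R56", "R57", "R58")

#: additional side branches dropped for the condensed mode-census networks
#: (full enumeration at laptop scale): lactate branch, formate-hydrogen
#: lyase / hydrogenase, glyoxylate shunt, Entner-Doudoroff, pyruvate
#: export.  Unlike COMPOSITE_ROUTES this changes the flux cone; modes of
#: the condensed network are a subset of the full network's modes.
CONDENSED_BRANCHES = ("R24", "R26", "R27", "R36", "R37",
                      "R45", "R46", "R67", "R70", "R74")

_O2_UPTAKE = "R64"
_BIOMASS_EXPORT = "R75"
_CYO = "R59"
_BIOMASS_RXN = "R1"


def _read(name: str) -> str:
    return resources.files("efmscreen.data").joinpath(name).read_text()


def load_main_network() -> MetabolicNetwork:
    """The packaged main network (57 metabolites, 75 reactions, 24 reversible)."""
    return parse_network(_read("ecoli_core.txt"), _read("compositions.tsv"))


def resolve_substrate(substrate: str) -> tuple[str, str]:
    key = substrate.strip().lower()
    if key not in SUBSTRATES:
        raise ValueError(f"unknown substrate {substrate!r}; choose from "
                         + ", ".join(SUBSTRATES))
    return SUBSTRATES[key]


def _with_coefficient_override(net: MetabolicNetwork, rxn_id: str,
                               pairs: Mapping[str, Fraction]) -> MetabolicNetwork:
    rxn = net.reaction(rxn_id)
    stoich = dict(rxn.stoichiometry)
    for met, coeff in pairs.items():
        stoich[met] = coeff
    new = Reaction(id=rxn.id, stoichiometry=stoich, reversible=rxn.reversible,
                   tag=rxn.tag)
    reactions = [new if r.id == rxn_id else r for r in net.reactions]
    return MetabolicNetwork(net.metabolites, reactions)


def build_core_model(substrate: str, product: str | None = None,
                     scenario: "EETScenario | str" = "none",
                     aerobic: bool = False,
                     overrides: Mapping[str, object] | None = None,
                     lean: bool = False,
                     condensed: bool = False,
                     ) -> MetabolicNetwork:
    """Build one screening network.

    Parameters
    ----------
    substrate : one of ``glucose``, ``glycerol``, ``fumarate``.
    product : a screened product (name, alias or metabolite id) or None.
    scenario : EET scenario id (none/Cat1/Cat2/An1/An2) or an
        :class:`~efmscreen.eet.EETScenario` with custom coupling.
    aerobic : enable oxygen uptake.  Anaerobiosis is a technical
        requirement of cathodic operation, so ``aerobic=True`` combined
        with a cathodic scenario is rejected.
    overrides : optional config keys — ``eet.protons_per_electron``,
        ``eet.protons_per_atp``, ``eet.an1_pumping``, ``etc.aerobic_po``
        (ATP per quinol at the terminal oxidase), ``biomass.atp_cost``.
    lean : drop the :data:`COMPOSITE_ROUTES` (cone-preserving reduction
        used for full elementary-mode enumeration).
    condensed : additionally drop the :data:`CONDENSED_BRANCHES`; the
        scaled-down cells used for mode censuses and scatter plots
        (implies ``lean``).
    """
    overrides = dict(overrides or {})
    sc = get_scenario(scenario)
    if "eet.protons_per_electron" in overrides:
        sc = EETScenario(**{**sc.__dict__,
                            "protons_per_electron": Fraction(overrides["eet.protons_per_electron"])})
    if "eet.protons_per_atp" in overrides:
        sc = EETScenario(**{**sc.__dict__,
                            "protons_per_atp": Fraction(overrides["eet.protons_per_atp"])})
    if "eet.an1_pumping" in overrides:
        sc = EETScenario(**{**sc.__dict__,
                            "anode_pumping_protons_per_electron": Fraction(overrides["eet.an1_pumping"])})
    if aerobic and sc.electrode_side == "cathode":
        raise ValueError("aerobic operation is incompatible with a cathodic "
                         "scenario: anaerobiosis is a technical requirement "
                         "of cathodic electro-fermentation")

    net = load_main_network()

    met_id, uptake = resolve_substrate(substrate)
    drop = [rid for _, rid in SUBSTRATES.values() if rid != uptake]
    if not aerobic:
        drop.append(_O2_UPTAKE)
    if lean or condensed:
        drop.extend(COMPOSITE_ROUTES)
    if condensed:
        drop.extend(CONDENSED_BRANCHES)
    net = net.without_reactions(drop)

    if "etc.aerobic_po" in overrides and net.has_reaction(_CYO):
        po = Fraction(overrides["etc.aerobic_po"])
        net = _with_coefficient_override(net, _CYO, {
            "adp": -po, "pi_ext": -po, "atp": po})
    if "biomass.atp_cost" in overrides:
        gam = Fraction(overrides["biomass.atp_cost"])
        net = _with_coefficient_override(net, _BIOMASS_RXN, {
            "atp": -gam, "adp": gam, "pi_ext": gam})

    if product is not None:
        pw = resolve_product(product)
        if pw.reactions:
            comps = parse_compositions(_read("compositions.tsv"))
            sub = parse_network("\n".join(pw.reactions), comps)
            net = net.with_reactions_added(sub.reactions, sub.metabolites)

    eet_rxns = scenario_reactions(sc)
    if eet_rxns:
        net = net.with_reactions_added(eet_rxns, [scenario_metabolite()])
    return net


def substrate_uptake_reaction(network: MetabolicNetwork, substrate: str) -> str:
    """Id of the uptake reaction for a substrate present in the network."""
    _, rid = resolve_substrate(substrate)
    if not network.has_reaction(rid):
        raise ValueError(f"network has no uptake for {substrate!r}")
    return rid


def export_reaction(network: MetabolicNetwork, product: str) -> str:
    """Id of the export reaction for a product (or 'biomass')."""
    if product == "biomass":
        return _BIOMASS_EXPORT
    pw = resolve_product(product)
    if not network.has_reaction(pw.export_reaction):
        raise ValueError(f"network has no export reaction for {product!r}")
    return pw.export_reaction
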