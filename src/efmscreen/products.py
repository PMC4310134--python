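"""Condensed production pathways for the twenty screened products.

Each engineered pathway is condensed to a single lumped reaction from its
core-network precursor(s), with redox and energy cofactors chosen from
standard biochemistry so that carbon and available electrons balance.  The
provenance of every lumping is recorded in ``note``.  Ethanol, succinate
and malate are core fermentation products and need no extra pathway, only
their existing export reaction.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ProductPathway", "PRODUCTS", "resolve_product", "product_ids"]


@dataclass(frozen=True)
class ProductPathway:
    id: str                      # metabolite id of the product
    name: str                    # display name
    aliases: tuple[str, ...]
    formula: str
    reactions: tuple[str, ...]   # reaction-table lines to append
    export_reaction: str         # id of the export (exchange) reaction
    note: str = ""


def _p(id, name, aliases, formula, lump, note):
    reactions = []
    if lump:
        reactions.append(f"R_{id}: {lump} | irrev | product_pathway")
    reactions.append(f"R_{id}ex: {id} -> | irrev | exchange")
    return ProductPathway(id=id, name=name, aliases=tuple(aliases),
                          formula=formula, reactions=tuple(reactions),
                          export_reaction=f"R_{id}ex", note=note)


PRODUCTS: dict[str, ProductPathway] = {p.id: p for p in [
    ProductPathway(id="etoh", name="ethanol", aliases=("ethanol",),
                   formula="C2H6O", reactions=(), export_reaction="R69",
                   note="native fermentation product (alcohol dehydrogenase, core)"),
    ProductPathway(id="succ", name="succinate", aliases=("succinate", "succinic-acid"),
                   formula="C4H6O4", reactions=(), export_reaction="R72",
                   note="native fermentation product (fumarate reductase, core)"),
    ProductPathway(id="mal", name="malate", aliases=("malate", "malic-acid"),
                   formula="C4H6O5", reactions=(), export_reaction="R73",
                   note="TCA intermediate exported directly (core)"),
    _p("btoh", "butanol", ("butanol", "1-butanol"), "C4H10O",
       "2 accoa + 4 nadh -> btoh + 4 nad + h2o_ext",
       "clostridial route: thiolase, 3-HB-CoA/crotonyl-CoA/butyryl-CoA "
       "(2 NADH), butyraldehyde + butanol dehydrogenases (2 NADH)"),
    _p("pdo13", "1,3-propanediol", ("1,3-PDO", "1,3-propanediol", "13pdo"), "C3H8O2",
       "glyc + nadh -> pdo13 + nad + h2o_ext",
       "glycerol dehydratase to 3-HPA then NADH-dependent oxidoreductase; "
       "from glucose the route runs via glycerol-3-P and glycerol "
       "(2 NADH and one high-energy phosphate per product)"),
    _p("pdo12", "1,2-propanediol", ("1,2-PDO", "1,2-propanediol", "12pdo"), "C3H8O2",
       "dhap + 2 nadh -> pdo12 + 2 nad + pi_ext",
       "methylglyoxal synthase then two NADH-dependent reductions"),
    _p("hp3", "3-hydroxypropionic acid", ("3-HP", "3-hydroxypropionic-acid"), "C3H6O3",
       "glyc + nad -> hp3 + nadh",
       "glycerol dehydratase to 3-HPA then NAD+ aldehyde dehydrogenase"),
    _p("bdo23", "2,3-butanediol", ("2,3-BDO", "2,3-butanediol", "23bdo"), "C4H10O2",
       "2 pyr + nadh -> bdo23 + 2 co2 + nad",
       "acetolactate synthase (CO2), acetolactate decarboxylase (CO2), "
       "NADH-dependent acetoin reductase: one NADH per two pyruvate"),
    _p("bdo14", "1,4-butanediol", ("1,4-BDO", "1,4-butanediol", "14bdo"), "C4H10O2",
       "succoa + 4 nadh -> bdo14 + 4 nad + h2o_ext",
       "succinyl-CoA via succinate semialdehyde, 4-hydroxybutyrate and "
       "4-HB-CoA; four NADH-dependent reductions"),
    _p("ppa", "propionic acid", ("PA", "propionic-acid", "propionate"), "C3H6O2",
       "succ -> ppa + co2",
       "methylmalonyl-CoA decarboxylation of succinate; CoA transfer is "
       "energy-neutral, one carbon lost as CO2"),
    _p("but", "butyric acid", ("butyric-acid", "butyrate"), "C4H8O2",
       "2 accoa + 2 nadh + adp + pi_ext -> but + 2 nad + atp",
       "clostridial butyryl-CoA route (2 NADH) with phosphotransbutyrylase "
       "and butyrate kinase (substrate-level ATP)"),
    _p("adi", "adipic acid", ("adipic-acid", "adipate"), "C6H10O4",
       "succoa + accoa + 2 nadh -> adi + 2 nad",
       "reverse beta-oxidation condensation of succinyl-CoA and acetyl-CoA "
       "with two NADH-dependent reductions"),
    _p("lys", "lysine", ("lysine",), "C6H14N2O2",
       "oaa + pyr + 2 nh3 + 4 nadph + 2 atp -> lys + co2 + 4 nadp + 2 adp + 2 pi_ext",
       "aspartate/diaminopimelate route: oxaloacetate + pyruvate, 4 NADPH, "
       "2 ATP, one decarboxylation"),
    _p("dap", "diaminopentane", ("diaminopentane", "cadaverine"), "C5H14N2",
       "oaa + pyr + 2 nh3 + 4 nadph + 2 atp -> dap + 2 co2 + 4 nadp + 2 adp + 2 pi_ext",
       "lysine route plus lysine decarboxylase"),
    _p("ipr", "isoprene", ("isoprene",), "C5H8",
       "pyr + gap + 3 nadph + 2 atp -> ipr + co2 + 3 nadp + 2 adp + 3 pi_ext",
       "methylerythritol-phosphate pathway from pyruvate + GAP with "
       "isoprene synthase; 3 NADPH-equivalent reductions, 2 ATP-equivalents"),
    _p("poh", "propanol", ("propanol", "1-propanol"), "C3H8O",
       "succoa + 2 nadh -> poh + co2 + 2 nad",
       "succinyl-CoA to propionyl-CoA (decarboxylation) then aldehyde and "
       "alcohol dehydrogenases (2 NADH)"),
    _p("asp", "aspartate", ("aspartate", "aspartic-acid"), "C4H7NO4",
       "oaa + nh3 + nadph -> asp + nadp + h2o_ext",
       "glutamate dehydrogenase + transaminase lumped: one NADPH-dependent "
       "reductive amination of oxaloacetate"),
    _p("gaba", "gamma-aminobutyric acid", ("GABA", "gamma-aminobutyric-acid"), "C4H9NO2",
       "akg + nh3 + nadph -> gaba + co2 + nadp",
       "glutamate dehydrogenase then glutamate decarboxylase"),
    _p("paba", "para-aminobenzoic acid", ("pABA", "para-aminobenzoic-acid"), "C7H7NO2",
       "e4p + 2 pep + nh3 + nadph + atp -> paba + pyr + nadp + adp + 4 pi_ext",
       "shikimate pathway to chorismate (E4P + 2 PEP, NADPH, ATP) then "
       "aminodeoxychorismate synthase/lyase (releases pyruvate)"),
    _p("phba", "para-hydroxybenzoic acid", ("pHBA", "para-hydroxybenzoic-acid"), "C7H6O3",
       "e4p + 2 pep + nadph + atp -> phba + pyr + nadp + adp + 4 pi_ext",
       "shikimate pathway to chorismate then chorismate lyase"),
]}


def product_ids() -> list[str]:
    return list(PRODUCTS)


def resolve_product(name: str) -> ProductPathway:
    key = name.strip()
    for p in PRODUCTS.values():
        if key == p.id or key.lower() in {a.lower() for a in p.aliases} \
                or key.lower() == p.name.lower():
            return p
    raise KeyError(f"unknown product {name!r}; known products: "
                   + ", ".join(sorted(p.name for p in PRODUCTS.values())))
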