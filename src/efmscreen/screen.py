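"""Yield analytics: degree of reduction, carbon yields, mode censuses and
the substrate x product x scenario screen.

The central quantity is the carbon yield of a product P from a substrate S
in a steady-state mode v::

    Yield_P [%] = 100 * (flux_P * carbon_P) / (flux_S * carbon_S)

with ``carbon`` the number of carbon atoms per molecule; biomass is
accounted in C-mol via the carbon content of the biomass equation.  For a
single-substrate mode the carbon leaving in all products (including
biomass and CO2) equals the carbon taken up, so yields lie in [0, 100] and
the by-product spectrum of a mode sums to 100%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .efm import ElementaryMode, EnumerationOverflow, enumerate_efms
from .network import ElementalComposition, MetabolicNetwork

__all__ = [
    "degree_of_reduction", "YieldResult", "ScreenReport",
    "carbon_yield", "max_yield", "growth_coupled_max_yield",
    "by_product_spectrum", "mode_census", "scatter_table", "screen_all",
    "secretes", "produces_biomass",
]

BIOMASS = "biomass"


def degree_of_reduction(comp: ElementalComposition) -> Fraction:
    """Available electrons per carbon: (4a + b - 2c - 3d + 6e + 5f) / a
    for composition C_a H_b O_c N_d S_e P_f."""
    if comp.carbon < 1:
        raise ValueError("degree of reduction is undefined for carbon-free species")
    return Fraction(4 * comp.carbon + comp.hydrogen - 2 * comp.oxygen
                    - 3 * comp.nitrogen + 6 * comp.sulfur + 5 * comp.phosphorus,
                    comp.carbon)


# ---------------------------------------------------------------------------
# exchange bookkeeping
# ---------------------------------------------------------------------------

def _exchanged_metabolite(network: MetabolicNetwork, rxn) -> tuple[str, Fraction] | None:
    """(internal metabolite, outward coefficient) of an exchange reaction."""
    internal = [(m, c) for m, c in rxn.stoichiometry.items()
                if not network.metabolite(m).external]
    if len(internal) != 1:
        return None
    met, coeff = internal[0]
    return met, -coeff  # positive flux * positive outward coeff = secretion


def find_uptake(network: MetabolicNetwork, met_id: str) -> str:
    for r in network.reactions:
        if r.tag != "exchange":
            continue
        ex = _exchanged_metabolite(network, r)
        if ex and ex[0] == met_id and (ex[1] < 0 or r.reversible):
            return r.id
    raise KeyError(f"no uptake reaction for metabolite {met_id!r}")


def find_export(network: MetabolicNetwork, met_id: str) -> str:
    for r in network.reactions:
        if r.tag != "exchange":
            continue
        ex = _exchanged_metabolite(network, r)
        if ex and ex[0] == met_id and (ex[1] > 0 or r.reversible):
            return r.id
    raise KeyError(f"no export reaction for metabolite {met_id!r}")


def _carbon(network: MetabolicNetwork, met_id: str) -> Fraction:
    if met_id == BIOMASS:
        eq = network.biomass_equation()
        if eq is None:
            raise ValueError("network has no biomass equation")
        return eq.carbon_content
    met = network.metabolite(met_id)
    return Fraction(met.carbon if met.composition is not None else 1)


def _uptake_flux(network: MetabolicNetwork, flux: Mapping[str, Fraction],
                 met_id: str) -> Fraction:
    rid = find_uptake(network, met_id)
    rxn = network.reaction(rid)
    _, outward = _exchanged_metabolite(network, rxn)
    v = flux.get(rid, Fraction(0))
    return -outward * v  # positive = uptake


def _export_flux(network: MetabolicNetwork, flux: Mapping[str, Fraction],
                 met_id: str) -> Fraction:
    rid = find_export(network, met_id)
    rxn = network.reaction(rid)
    _, outward = _exchanged_metabolite(network, rxn)
    return outward * flux.get(rid, Fraction(0))


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class YieldResult:
    """Carbon yield of one product in one mode or over a mode set."""

    product: str
    substrate: str
    scenario: str = "none"
    yield_percent: Fraction | float | None = None
    mode_ref: ElementaryMode | None = None
    feasible: bool = True
    growth_coupled: bool = False
    flux: dict[str, Fraction] | None = None
    message: str = ""

    def __float__(self):
        return float(self.yield_percent) if self.yield_percent is not None else float("nan")


def carbon_yield(mode: "ElementaryMode | Mapping[str, Fraction]",
                 network: MetabolicNetwork, product: str, substrate: str
                 ) -> Fraction:
    """Carbon yield (percent) of ``product`` in one mode.

    Raises :class:`ValueError` when the mode does not consume the
    substrate (the yield is undefined there).
    """
    flux = mode.flux if isinstance(mode, ElementaryMode) else mode
    up = _uptake_flux(network, flux, substrate)
    if up <= 0:
        raise ValueError(f"mode does not consume substrate {substrate!r}; "
                         "carbon yield undefined")
    out = _export_flux(network, flux, product)
    if out <= 0:
        return Fraction(0)
    return 100 * out * _carbon(network, product) / (up * _carbon(network, substrate))


def _byproduct_count(mode: ElementaryMode, network: MetabolicNetwork,
                     product: str) -> int:
    n = 0
    for r in network.reactions:
        if r.tag != "exchange" or r.id not in mode.flux:
            continue
        ex = _exchanged_metabolite(network, r)
        if ex is None:
            continue
        met, outward = ex
        if met != product and outward * mode.flux[r.id] > 0:
            n += 1
    return n


def _select_best(candidates: list[tuple[Fraction, ElementaryMode]],
                 network: MetabolicNetwork, product: str) -> tuple[Fraction, ElementaryMode]:
    best_y = max(y for y, _ in candidates)
    tied = [m for y, m in candidates if y == best_y]
    tied.sort(key=lambda m: (_byproduct_count(m, network, product),
                             sorted(m.support)))
    return best_y, tied[0]


def max_yield(modes: Iterable[ElementaryMode], network: MetabolicNetwork,
              product: str, substrate: str, scenario: str = "none") -> YieldResult:
    """Maximum carbon yield over a mode set; returns the achieving top mode.

    Ties are broken toward fewer by-product species, then lexicographic
    support.  With no substrate-consuming mode the result is flagged
    infeasible.
    """
    candidates = []
    for m in modes:
        if _uptake_flux(network, m.flux, substrate) > 0:
            candidates.append((carbon_yield(m, network, product, substrate), m))
    if not candidates:
        return YieldResult(product=product, substrate=substrate, scenario=scenario,
                           feasible=False, message="no substrate-consuming mode")
    y, top = _select_best(candidates, network, product)
    return YieldResult(product=product, substrate=substrate, scenario=scenario,
                       yield_percent=y, mode_ref=top)


def produces_biomass(network: MetabolicNetwork) -> Callable[[ElementaryMode], bool]:
    rid = find_export(network, BIOMASS)

    def pred(mode: ElementaryMode) -> bool:
        return mode.flux.get(rid, Fraction(0)) > 0
    return pred


def secretes(network: MetabolicNetwork, met_id: str) -> Callable[[ElementaryMode], bool]:
    rid = find_export(network, met_id)
    rxn = network.reaction(rid)
    _, outward = _exchanged_metabolite(network, rxn)

    def pred(mode: ElementaryMode) -> bool:
        return outward * mode.flux.get(rid, Fraction(0)) > 0
    return pred


def growth_coupled_max_yield(modes: Iterable[ElementaryMode],
                             network: MetabolicNetwork, product: str,
                             substrate: str, scenario: str = "none") -> YieldResult:
    """Maximum yield restricted to modes with biomass flux > 0."""
    pred = produces_biomass(network)
    growing = [m for m in modes if pred(m)]
    if not growing:
        return YieldResult(product=product, substrate=substrate, scenario=scenario,
                           feasible=False, growth_coupled=True,
                           message="no biomass-forming mode")
    res = max_yield(growing, network, product, substrate, scenario)
    res.growth_coupled = True
    return res


def by_product_spectrum(mode: "ElementaryMode | Mapping[str, Fraction]",
                        network: MetabolicNetwork, substrate: str
                        ) -> dict[str, Fraction]:
    """Carbon fraction (percent) of every secreted species plus biomass.

    Fractions are relative to the total carbon entering the network and sum
    to 100% by carbon conservation.
    """
    flux = mode.flux if isinstance(mode, ElementaryMode) else mode
    carbon_in = Fraction(0)
    outflows: dict[str, Fraction] = {}
    for r in network.reactions:
        if r.tag != "exchange" or r.id not in flux or flux[r.id] == 0:
            continue
        ex = _exchanged_metabolite(network, r)
        if ex is None:
            continue
        met, outward = ex
        c = _carbon(network, met) if (met == BIOMASS or network.metabolite(met).carbon) else Fraction(0)
        if c == 0:
            continue
        amount = outward * flux[r.id] * c
        if amount > 0:
            outflows[met] = outflows.get(met, Fraction(0)) + amount
        else:
            carbon_in += -amount
    if carbon_in == 0:
        raise ValueError("mode takes up no carbon")
    return {met: 100 * amt / carbon_in for met, amt in sorted(outflows.items())}


def mode_census(modes: Sequence[ElementaryMode],
                predicate: Callable[[ElementaryMode], bool]
                ) -> tuple[int, Fraction | None]:
    """(count, fraction) of modes satisfying a predicate; fraction is None
    for an empty mode set."""
    modes = list(modes)
    if not modes:
        return 0, None
    count = sum(bool(predicate(m)) for m in modes)
    return count, Fraction(count, len(modes))


def scatter_table(modes: Iterable[ElementaryMode], network: MetabolicNetwork,
                  product: str, substrate: str) -> pd.DataFrame:
    """One row per substrate-consuming mode: biomass yield vs product yield
    (percent), ready for plotting."""
    rows = []
    for m in modes:
        if _uptake_flux(network, m.flux, substrate) <= 0:
            continue
        rows.append({
            "biomass_yield_percent": float(carbon_yield(m, network, BIOMASS, substrate)),
            "product_yield_percent": float(carbon_yield(m, network, product, substrate)),
        })
    return pd.DataFrame(rows, columns=["biomass_yield_percent", "product_yield_percent"])


# ---------------------------------------------------------------------------
# the full screen
# ---------------------------------------------------------------------------

@dataclass
class ScreenReport:
    """Substrate x product x scenario yield matrix plus per-pair electrode calls."""

    rows: list[dict] = field(default_factory=list)
    best_scenario: dict[tuple[str, str], str] = field(default_factory=dict)
    errors: list[dict] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rows)
        if not df.empty:
            df["best_scenario_for_pair"] = [
                self.best_scenario.get((r["substrate"], r["product"]), "")
                for r in self.rows]
        return df

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6g")

    def write_json(self, path) -> None:
        import json
        payload = {
            "rows": [
                {k: (float(v) if isinstance(v, Fraction) else v)
                 for k, v in row.items()} for row in self.rows],
            "best_scenario": {f"{s}/{p}": sc
                              for (s, p), sc in self.best_scenario.items()},
            "errors": self.errors,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


_EPSILON_PP = 0.05  # percentage points regarded as a real yield difference


def _classify(best_by_scenario: dict[str, float]) -> str:
    base = best_by_scenario.get("none", float("nan"))
    cat = max((v for k, v in best_by_scenario.items() if k.startswith("Cat")),
              default=float("-inf"))
    an = max((v for k, v in best_by_scenario.items() if k.startswith("An")),
             default=float("-inf"))
    best = max(cat, an)
    if best <= base + _EPSILON_PP:
        return "no-benefit"
    return "cathode" if cat > an else "anode"


def screen_all(substrates: Sequence[str], products: Sequence[str],
               scenarios: Sequence[str], *, use_efms: bool = False,
               enumerate_ceiling: int = 500_000,
               overrides: Mapping[str, object] | None = None) -> ScreenReport:
    """Run the full substrate x product x scenario yield screen.

    With ``use_efms`` the per-cell networks are enumerated and growth
    coupling, mode counts and top-mode by-product spectra are reported; the
    default uses the LP oracle for the maximum-yield ceilings only (fast).
    Per-cell failures are recorded in the report and do not abort the screen.
    """
    from .builder import build_core_model, resolve_substrate
    from .lp import lp_max_yield
    from .products import resolve_product

    if not substrates or not products or not scenarios:
        raise ValueError("substrates, products and scenarios must be non-empty")

    report = ScreenReport()
    by_pair: dict[tuple[str, str], dict[str, float]] = {}
    for substrate in substrates:
        for product in products:
            pname = resolve_product(product).name if product != BIOMASS else BIOMASS
            for scenario in scenarios:
                row = {"substrate": substrate, "product": pname,
                       "scenario": scenario}
                try:
                    net = build_core_model(substrate, None if product == BIOMASS else product,
                                           scenario, overrides=overrides)
                    met_id, _ = resolve_substrate(substrate)
                    prod_id = BIOMASS if product == BIOMASS else resolve_product(product).id
                    if use_efms:
                        try:
                            modes = enumerate_efms(
                                net, max_rays=enumerate_ceiling,
                                substrate_reaction=find_uptake(net, met_id))
                        except EnumerationOverflow as e:
                            modes = None
                            row["note"] = str(e)
                        if modes is not None:
                            my = max_yield(modes, net, prod_id, met_id, scenario)
                            gy = growth_coupled_max_yield(modes, net, prod_id, met_id, scenario)
                            row["mode_count"] = len(modes)
                            row["max_yield_percent"] = (
                                float(my.yield_percent) if my.feasible else None)
                            row["growth_coupled_max_percent"] = (
                                float(gy.yield_percent) if gy.feasible else None)
                            if my.feasible and my.mode_ref is not None:
                                row["top_mode_byproducts"] = {
                                    k: round(float(v), 2) for k, v in
                                    by_product_spectrum(my.mode_ref, net, met_id).items()
                                    if k != prod_id}
                    lp = lp_max_yield(net, prod_id, met_id)
                    row["lp_max_yield_percent"] = (
                        float(lp.yield_percent) if lp.feasible else None)
                    if "max_yield_percent" not in row:
                        row["max_yield_percent"] = row["lp_max_yield_percent"]
                    if row["max_yield_percent"] is not None:
                        by_pair.setdefault((substrate, pname), {})[scenario] = \
                            row["max_yield_percent"]
                except Exception as e:  # per-cell failure: record, continue
                    report.errors.append({**row, "error": str(e)})
                    row["error"] = str(e)
                report.rows.append(row)
    for pair, vals in by_pair.items():
        report.best_scenario[pair] = _classify(vals)
    return report
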