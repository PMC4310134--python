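"""Electrode electron-transfer (EET) scenarios.

Four mediated electron-transport models connect the metabolism to an
electrode, differing in direction and in whether the transfer is coupled to
energy conservation:

* **Cat1** — cathodic electron supply via membrane-bound carriers onto
  NAD+; the charge imbalance drives one proton per electron into the
  cytosol through the ATP synthase (3 H+ per ATP), so each NADH formed
  comes with 2/3 ATP.
* **Cat2** — the mediator reduces NAD+ directly (diffusion or
  hydrogenase-like transfer of electrons plus protons); no proton-motive
  force, no ATP.
* **An1** — NADH is oxidized through the proton-pumping respiratory chain
  with the anode as terminal acceptor; the pumped protons drive ATP
  synthesis (pumping stoichiometry is a calibrated parameter).
* **An2** — the anode is a plain electron sink for NADH; no membrane
  potential, no ATP.

Electrons are carried by an internal pseudo-species ``e_el`` exchanged
without bound with the electrode (the soluble mediator redox cycle is
collapsed into this exchange); electrons travel in pairs, one NAD(H) per
two electrons.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction
from itertools import product as iproduct
from typing import Callable, Iterable, Sequence

from .network import MetabolicNetwork, Metabolite, Reaction

__all__ = ["EETScenario", "SCENARIOS", "scenario_reactions", "calibrate_energetics"]

ELECTRON = "e_el"

#: reaction ids used by every scenario
EET_EXCHANGE_ID = "R_elec"


@dataclass(frozen=True)
class EETScenario:
    """Parameters of one electron-transport model.

    ``protons_per_electron`` is the Cat1 charge-balancing proton influx;
    ``anode_pumping_protons_per_electron`` the An1 respiratory pumping;
    ``protons_per_atp`` the ATP synthase stoichiometry (3 by default).
    """

    id: str
    electrode_side: str  # cathode | anode | none
    atp_coupled: bool
    protons_per_electron: Fraction = Fraction(1)
    protons_per_atp: Fraction = Fraction(3)
    anode_pumping_protons_per_electron: Fraction = Fraction(2)

    def __post_init__(self):
        if self.electrode_side not in ("cathode", "anode", "none"):
            raise ValueError(f"bad electrode side {self.electrode_side!r}")
        for name in ("protons_per_electron", "protons_per_atp",
                     "anode_pumping_protons_per_electron"):
            v = getattr(self, name)
            object.__setattr__(self, name, Fraction(v))
            if Fraction(v) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.protons_per_atp <= 0:
            raise ValueError("protons_per_atp must be positive")

    @property
    def atp_per_nadh(self) -> Fraction:
        """Net ATP formed (cathode) or conserved (anode) per NAD(H) turned over."""
        if not self.atp_coupled:
            return Fraction(0)
        if self.electrode_side == "cathode":
            return 2 * self.protons_per_electron / self.protons_per_atp
        if self.electrode_side == "anode":
            return 2 * self.anode_pumping_protons_per_electron / self.protons_per_atp
        return Fraction(0)


SCENARIOS: dict[str, EETScenario] = {
    "none": EETScenario(id="none", electrode_side="none", atp_coupled=False),
    "Cat1": EETScenario(id="Cat1", electrode_side="cathode", atp_coupled=True),
    "Cat2": EETScenario(id="Cat2", electrode_side="cathode", atp_coupled=False),
    "An1": EETScenario(id="An1", electrode_side="anode", atp_coupled=True),
    "An2": EETScenario(id="An2", electrode_side="anode", atp_coupled=False),
}


def get_scenario(scenario: "EETScenario | str") -> EETScenario:
    if isinstance(scenario, EETScenario):
        return scenario
    key = str(scenario)
    for sid, sc in SCENARIOS.items():
        if sid.lower() == key.lower():
            return sc
    raise ValueError(f"unknown EET scenario {scenario!r}; "
                     f"choose from {', '.join(SCENARIOS)}")


def scenario_metabolite() -> Metabolite:
    return Metabolite(id=ELECTRON, name="electrode electron")


def scenario_reactions(scenario: "EETScenario | str") -> list[Reaction]:
    """Pseudo-reactions (tag ``eet``) implementing one scenario.

    Cathodes: ``2 e_el + NAD+ -> NADH`` (+ ATP for Cat1) plus an unbounded
    electron influx; anodes: ``NADH -> NAD+ + 2 e_el`` (+ ATP for An1) plus
    an unbounded electron efflux.  Scenario ``none`` contributes nothing.
    """
    sc = get_scenario(scenario)
    if sc.electrode_side == "none":
        return []
    atp = sc.atp_per_nadh
    if sc.electrode_side == "cathode":
        stoich = {ELECTRON: Fraction(-2), "nad": Fraction(-1), "nadh": Fraction(1)}
        exchange = Reaction(id=EET_EXCHANGE_ID, stoichiometry={ELECTRON: Fraction(1)},
                            reversible=False, tag="eet")
    else:
        stoich = {"nadh": Fraction(-1), "nad": Fraction(1), ELECTRON: Fraction(2)}
        exchange = Reaction(id=EET_EXCHANGE_ID, stoichiometry={ELECTRON: Fraction(-1)},
                            reversible=False, tag="eet")
    if atp:
        stoich["adp"] = -atp
        stoich["atp"] = atp
    transfer = Reaction(id=f"R_{sc.id.lower()}", stoichiometry=stoich,
                        reversible=False, tag="eet")
    return [transfer, exchange]


# ---------------------------------------------------------------------------
# energetics calibration
# ---------------------------------------------------------------------------

def _rational_grid(lo: Fraction, hi: Fraction, max_denominator: int) -> list[Fraction]:
    vals = set()
    for q in range(1, max_denominator + 1):
        p = int(lo * q)
        while Fraction(p, q) <= hi:
            if Fraction(p, q) >= lo:
                vals.add(Fraction(p, q))
            p += 1
    return sorted(vals)


@dataclass
class CalibrationResult:
    an1_pumping: Fraction
    aerobic_po: Fraction
    max_deviation: float
    within_tolerance: bool
    deviations: dict[str, float]


def calibrate_energetics(
    evaluate: Callable[[Fraction, Fraction, dict], float],
    targets: Sequence[dict],
    *,
    pumping_range: tuple[Fraction, Fraction] = (Fraction(1), Fraction(4)),
    po_range: tuple[Fraction, Fraction] = (Fraction(1, 6), Fraction(2)),
    max_denominator: int = 6,
    tolerance: float = 1.0,
) -> CalibrationResult:
    """Grid-search the An1 pumping ratio and the aerobic P/O-equivalent.

    ``evaluate(an1_pumping, aerobic_po, target) -> yield percent`` runs the
    model for one anchor target (a dict with at least ``scenario``,
    ``substrate``, ``yield_percent``); the search minimizes the worst
    absolute deviation from the anchors over rationals with denominators up
    to ``max_denominator``.  ``within_tolerance`` is False when no
    parameter pair lands within ``tolerance`` percentage points of every
    anchor (the best pair is still reported).

    With an empty target list the defaults are returned unchanged.
    """
    default = CalibrationResult(
        an1_pumping=SCENARIOS["An1"].anode_pumping_protons_per_electron,
        aerobic_po=Fraction(2), max_deviation=0.0, within_tolerance=True,
        deviations={})
    if not targets:
        return default

    needs_pump = any(t.get("scenario") == "An1" for t in targets)
    needs_po = any(t.get("aerobic") for t in targets)
    pump_grid = (_rational_grid(*pumping_range, max_denominator)
                 if needs_pump else [default.an1_pumping])
    po_grid = (_rational_grid(*po_range, max_denominator)
               if needs_po else [default.aerobic_po])

    best = None
    for pump, po in iproduct(pump_grid, po_grid):
        devs = {}
        for t in targets:
            got = evaluate(pump, po, t)
            key = f"{t.get('scenario', 'none')}/{t.get('substrate', '?')}"
            devs[key] = abs(got - float(t["yield_percent"]))
        worst = max(devs.values())
        if best is None or worst < best[0]:
            best = (worst, pump, po, devs)
    worst, pump, po, devs = best
    return CalibrationResult(an1_pumping=pump, aerobic_po=po,
                             max_deviation=worst,
                             within_tolerance=worst <= tolerance,
                             deviations=devs)
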