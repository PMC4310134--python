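"""Stoichiometric network data model and the reaction-table format.

A :class:`MetabolicNetwork` is an ordered collection of metabolites and
reactions together with the stoichiometric matrix ``S`` over the *internal*
metabolites (rows) and all reactions (columns).  Coefficients are exact
rationals (:class:`fractions.Fraction`) throughout; floating point enters
only in reporting and in the LP oracle.

Networks are stored as plain-text reaction tables, one reaction per line::

    # comment
    R1: glc + pep -> g6p + pyr | irrev | core
    R2: g6p <-> f6p           | rev   | core
    R3: ac ->                 | irrev | exchange

Coefficients may be decimals (``0.33`` is read as the exact rational
``33/100``) or explicit fractions (``1/3``).  Metabolites whose id ends in
``_ext`` are external (environment) species and do not appear in ``S``;
exchange reactions with an empty side ("``ac ->``") are the other way to
exchange matter with the environment.  Elemental compositions live in a
sidecar table (``<id> <TAB> <formula>``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "ElementalComposition",
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "BiomassEquation",
    "NetworkParseError",
    "parse_network",
    "parse_compositions",
    "serialize_network",
    "serialize_compositions",
    "validate_network",
    "NetworkValidation",
]

EXTERNAL_SUFFIX = "_ext"

REACTION_TAGS = ("core", "exchange", "product_pathway", "eet", "biomass")

#: tags whose reactions are exempt from the element-balance check
BALANCE_EXEMPT_TAGS = ("exchange", "biomass", "eet")

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")
_ELEMENT_FIELDS = {"C": "carbon", "H": "hydrogen", "O": "oxygen",
                   "N": "nitrogen", "S": "sulfur", "P": "phosphorus"}
_TOKEN_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_]*$")


class NetworkParseError(ValueError):
    """Raised for malformed reaction-table input; carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class ElementalComposition:
    """Elemental composition C H O N S P of one molecule.

    Counts are non-negative integers.  The degree-of-reduction and carbon
    yield machinery in :mod:`efmscreen.screen` requires ``carbon >= 1``.
    """

    carbon: int = 0
    hydrogen: int = 0
    oxygen: int = 0
    nitrogen: int = 0
    sulfur: int = 0
    phosphorus: int = 0

    def __post_init__(self):
        for name in _ELEMENT_FIELDS.values():
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} count must be a non-negative integer, got {v!r}")

    @classmethod
    def from_formula(cls, formula: str) -> "ElementalComposition":
        """Parse a Hill-style formula such as ``C6H12O6`` or ``CO2``."""
        counts = dict.fromkeys(_ELEMENT_FIELDS.values(), 0)
        pos = 0
        for m in _FORMULA_RE.finditer(formula):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r}")
            pos = m.end()
            sym, num = m.group(1), m.group(2)
            if sym not in _ELEMENT_FIELDS:
                raise ValueError(f"unsupported element {sym!r} in formula {formula!r}")
            counts[_ELEMENT_FIELDS[sym]] += int(num) if num else 1
        if pos != len(formula):
            raise ValueError(f"cannot parse formula {formula!r}")
        return cls(**counts)

    def to_formula(self) -> str:
        parts = []
        for sym, name in _ELEMENT_FIELDS.items():
            n = getattr(self, name)
            if n == 1:
                parts.append(sym)
            elif n > 1:
                parts.append(f"{sym}{n}")
        return "".join(parts)


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    composition: ElementalComposition | None = None
    external: bool = False

    @property
    def carbon(self) -> int:
        return self.composition.carbon if self.composition is not None else 0


@dataclass(frozen=True)
class Reaction:
    """One reaction: metabolite-id -> rational coefficient (negative = consumed)."""

    id: str
    stoichiometry: Mapping[str, Fraction]
    reversible: bool = False
    tag: str = "core"

    def __post_init__(self):
        if self.tag not in REACTION_TAGS:
            raise ValueError(f"unknown reaction tag {self.tag!r}")
        stoich = {m: Fraction(c) for m, c in self.stoichiometry.items() if c != 0}
        if not stoich:
            raise ValueError(f"reaction {self.id!r} has no nonzero coefficients")
        object.__setattr__(self, "stoichiometry", stoich)

    def substrates(self) -> dict[str, Fraction]:
        return {m: -c for m, c in self.stoichiometry.items() if c < 0}

    def products(self) -> dict[str, Fraction]:
        return {m: c for m, c in self.stoichiometry.items() if c > 0}

    def reversed_(self) -> "Reaction":
        return replace(self, stoichiometry={m: -c for m, c in self.stoichiometry.items()})


@dataclass(frozen=True)
class BiomassEquation:
    """Condensed description of the biomass reaction (R1).

    Anaerobic biomass formation drains carbon precursors, consumes ATP and
    NADPH and is a net *producer* of NADH; ``carbon_content`` is the C-mol
    drained per biomass flux unit and is what the carbon-yield bookkeeping
    uses for biomass.
    """

    precursor_drains: Mapping[str, Fraction]
    atp_cost: Fraction
    nadh_yield: Fraction
    carbon_content: Fraction

    def __post_init__(self):
        if self.atp_cost <= 0:
            raise ValueError("biomass ATP cost must be positive")
        if self.nadh_yield <= 0:
            raise ValueError("anaerobic biomass formation must be a net NADH producer")


class MetabolicNetwork:
    """Ordered metabolite and reaction collections plus the exact matrix S."""

    def __init__(self, metabolites: Iterable[Metabolite], reactions: Iterable[Reaction]):
        self.metabolites: list[Metabolite] = list(metabolites)
        self.reactions: list[Reaction] = list(reactions)
        seen = set()
        for m in self.metabolites:
            if m.id in seen:
                raise ValueError(f"duplicate metabolite id {m.id!r}")
            seen.add(m.id)
        seen = set()
        for r in self.reactions:
            if r.id in seen:
                raise ValueError(f"duplicate reaction id {r.id!r}")
            seen.add(r.id)
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        missing = {m for r in self.reactions for m in r.stoichiometry} - set(self._met_index)
        if missing:
            raise ValueError(f"reactions reference undeclared metabolites: {sorted(missing)}")

    # -- lookups ---------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        return self.metabolites[self._met_index[met_id]]

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    def has_reaction(self, rxn_id: str) -> bool:
        return any(r.id == rxn_id for r in self.reactions)

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def internal_metabolites(self) -> list[Metabolite]:
        return [m for m in self.metabolites if not m.external]

    @property
    def n_reversible(self) -> int:
        return sum(r.reversible for r in self.reactions)

    # -- stoichiometric matrix ------------------------------------------
    def stoichiometric_matrix(self) -> list[list[Fraction]]:
        """Exact S: rows follow ``internal_metabolites``, columns ``reactions``."""
        rows = []
        for m in self.internal_metabolites:
            rows.append([r.stoichiometry.get(m.id, Fraction(0)) for r in self.reactions])
        return rows

    @property
    def S(self) -> np.ndarray:
        """S as a numpy object array of exact rationals."""
        return np.array(self.stoichiometric_matrix(), dtype=object)

    def s_float(self) -> np.ndarray:
        return np.array([[float(c) for c in row] for row in self.stoichiometric_matrix()])

    # -- edits (return new networks; instances stay cheap to copy) -------
    def with_reactions_added(self, reactions: Iterable[Reaction],
                             metabolites: Iterable[Metabolite] = ()) -> "MetabolicNetwork":
        new_mets = list(self.metabolites)
        known = set(self._met_index)
        for m in metabolites:
            if m.id not in known:
                new_mets.append(m)
                known.add(m.id)
        return MetabolicNetwork(new_mets, list(self.reactions) + list(reactions))

    def without_reactions(self, rxn_ids: Iterable[str]) -> "MetabolicNetwork":
        drop = set(rxn_ids)
        return MetabolicNetwork(self.metabolites, [r for r in self.reactions if r.id not in drop])

    # -- biomass ---------------------------------------------------------
    def biomass_reaction(self) -> Reaction | None:
        for r in self.reactions:
            if r.tag == "biomass":
                return r
        return None

    def biomass_equation(self) -> BiomassEquation | None:
        """Derive the condensed biomass description from the reaction tagged biomass."""
        r = self.biomass_reaction()
        if r is None:
            return None
        drains: dict[str, Fraction] = {}
        carbon = Fraction(0)
        for met_id, coeff in r.stoichiometry.items():
            met = self.metabolite(met_id)
            c = met.carbon
            if coeff < 0 and c > 0:
                drains[met_id] = -coeff
                carbon += -coeff * c
            elif coeff > 0 and c > 0 and met_id != "biomass":
                carbon -= coeff * c  # carbon released back (e.g. CO2)
        atp = -r.stoichiometry.get("atp", Fraction(0))
        nadh = r.stoichiometry.get("nadh", Fraction(0))
        return BiomassEquation(precursor_drains=drains, atp_cost=atp,
                               nadh_yield=nadh, carbon_content=carbon)

    def __repr__(self):
        return (f"<MetabolicNetwork {len(self.metabolites)} metabolites, "
                f"{len(self.reactions)} reactions ({self.n_reversible} reversible)>")


# ---------------------------------------------------------------------------
# parsing / serialization
# ---------------------------------------------------------------------------

def _parse_coefficient(tok: str, line: int) -> Fraction:
    try:
        return Fraction(tok)
    except (ValueError, ZeroDivisionError):
        raise NetworkParseError(f"bad coefficient {tok!r}", line)


def _parse_side(text: str, line: int, sign: int, stoich: dict[str, Fraction]) -> None:
    text = text.strip()
    if not text:
        return
    for term in text.split("+"):
        parts = term.split()
        if not parts:
            raise NetworkParseError("empty term in equation", line)
        if len(parts) == 1:
            coeff, met = Fraction(1), parts[0]
        elif len(parts) == 2:
            coeff, met = _parse_coefficient(parts[0], line), parts[1]
        else:
            raise NetworkParseError(f"malformed term {' '.join(parts)!r}", line)
        if not _TOKEN_RE.match(met):
            raise NetworkParseError(f"unknown metabolite token {met!r}", line)
        if coeff <= 0:
            raise NetworkParseError(f"non-positive coefficient for {met!r}", line)
        stoich[met] = stoich.get(met, Fraction(0)) + sign * coeff


def parse_network(reaction_table: str,
                  compositions: Mapping[str, ElementalComposition] | str | None = None,
                  ) -> MetabolicNetwork:
    """Parse a reaction-table into a :class:`MetabolicNetwork`.

    ``compositions`` may be a mapping metabolite-id -> composition or the
    text of a sidecar table (see :func:`parse_compositions`).
    """
    if isinstance(compositions, str):
        compositions = parse_compositions(compositions)
    compositions = compositions or {}

    reactions: list[Reaction] = []
    seen_ids: set[str] = set()
    met_order: list[str] = []
    met_seen: set[str] = set()

    for lineno, raw in enumerate(reaction_table.splitlines(), start=1):
        text = raw.split("#", 1)[0].strip()
        if not text:
            continue
        if ":" not in text:
            raise NetworkParseError("missing ':' after reaction id", lineno)
        rid, rest = text.split(":", 1)
        rid = rid.strip()
        if not _TOKEN_RE.match(rid):
            raise NetworkParseError(f"bad reaction id {rid!r}", lineno)
        if rid in seen_ids:
            raise NetworkParseError(f"duplicate reaction id {rid!r}", lineno)
        fields = [f.strip() for f in rest.split("|")]
        if len(fields) != 3:
            raise NetworkParseError("expected '<id>: <eq> | <rev|irrev> | <tag>'", lineno)
        eq, revflag, tag = fields
        if revflag not in ("rev", "irrev"):
            raise NetworkParseError(f"reversibility flag must be 'rev' or 'irrev', got {revflag!r}", lineno)
        if tag not in REACTION_TAGS:
            raise NetworkParseError(f"unknown tag {tag!r}", lineno)
        arrow = "<->" if "<->" in eq else "->"
        if "<->" in eq and revflag != "rev":
            raise NetworkParseError("'<->' equation marked irrev", lineno)
        sides = eq.split(arrow)
        if len(sides) != 2:
            raise NetworkParseError("equation must contain exactly one arrow", lineno)
        stoich: dict[str, Fraction] = {}
        _parse_side(sides[0], lineno, -1, stoich)
        _parse_side(sides[1], lineno, +1, stoich)
        stoich = {m: c for m, c in stoich.items() if c != 0}
        if not stoich:
            raise NetworkParseError("equation has no net conversion", lineno)
        try:
            rxn = Reaction(id=rid, stoichiometry=stoich, reversible=(revflag == "rev"), tag=tag)
        except ValueError as e:
            raise NetworkParseError(str(e), lineno)
        reactions.append(rxn)
        seen_ids.add(rid)
        for m in stoich:
            if m not in met_seen:
                met_seen.add(m)
                met_order.append(m)

    metabolites = [
        Metabolite(id=m, composition=compositions.get(m),
                   external=m.endswith(EXTERNAL_SUFFIX))
        for m in met_order
    ]
    return MetabolicNetwork(metabolites, reactions)


def parse_compositions(text: str) -> dict[str, ElementalComposition]:
    """Parse the composition sidecar: ``<id> <TAB> <formula>`` per line."""
    out: dict[str, ElementalComposition] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise NetworkParseError("expected '<id> <TAB> <formula>'", lineno)
        met, formula = parts
        try:
            out[met] = ElementalComposition.from_formula(formula)
        except ValueError as e:
            raise NetworkParseError(str(e), lineno)
    return out


def _fmt_coeff(c: Fraction) -> str:
    return str(c.numerator) if c.denominator == 1 else f"{c.numerator}/{c.denominator}"


def serialize_network(network: MetabolicNetwork) -> str:
    """Render the network in the reaction-table dialect (round-trip exact)."""
    lines = []
    for r in network.reactions:
        lhs = " + ".join(
            (f"{_fmt_coeff(-c)} {m}" if c != -1 else m)
            for m, c in r.stoichiometry.items() if c < 0)
        rhs = " + ".join(
            (f"{_fmt_coeff(c)} {m}" if c != 1 else m)
            for m, c in r.stoichiometry.items() if c > 0)
        flag = "rev" if r.reversible else "irrev"
        lines.append(f"{r.id}: {lhs} -> {rhs} | {flag} | {r.tag}")
    return "\n".join(lines) + "\n"


def serialize_compositions(network: MetabolicNetwork) -> str:
    lines = []
    for m in network.metabolites:
        if m.composition is not None:
            lines.append(f"{m.id}\t{m.composition.to_formula()}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class NetworkValidation:
    """Report-only structural check of a network.

    ``carbon_residuals`` / ``nitrogen_residuals`` list the per-reaction
    element imbalance for reactions subject to the balance check (core and
    product-pathway reactions whose species all have known composition);
    hydrogen/oxygen/phosphorus are not balanced because water, protons and
    phosphate are implicit environment species.
    """

    carbon_residuals: dict[str, Fraction] = field(default_factory=dict)
    nitrogen_residuals: dict[str, Fraction] = field(default_factory=dict)
    unchecked_reactions: list[str] = field(default_factory=list)
    exempt_reactions: list[str] = field(default_factory=list)
    orphan_metabolites: list[str] = field(default_factory=list)
    dead_end_reactions: list[str] = field(default_factory=list)

    @property
    def carbon_balanced(self) -> bool:
        return all(res == 0 for res in self.carbon_residuals.values())

    @property
    def ok(self) -> bool:
        return self.carbon_balanced

    def summary(self) -> str:
        bad = [rid for rid, res in self.carbon_residuals.items() if res != 0]
        lines = [
            f"checked reactions : {len(self.carbon_residuals)}",
            f"carbon-imbalanced : {len(bad)}" + (f" ({', '.join(bad)})" if bad else ""),
            f"exempt (tag)      : {len(self.exempt_reactions)}",
            f"unknown composition: {len(self.unchecked_reactions)}",
            f"orphan metabolites: {len(self.orphan_metabolites)}",
            f"dead-end reactions: {len(self.dead_end_reactions)}",
        ]
        return "\n".join(lines)


def validate_network(network: MetabolicNetwork) -> NetworkValidation:
    """Element balances, orphan metabolites and dead-end reactions."""
    report = NetworkValidation()
    for r in network.reactions:
        if r.tag in BALANCE_EXEMPT_TAGS:
            report.exempt_reactions.append(r.id)
            continue
        comps = {m: network.metabolite(m).composition for m in r.stoichiometry}
        if any(c is None for c in comps.values()):
            report.unchecked_reactions.append(r.id)
            continue
        report.carbon_residuals[r.id] = sum(
            coeff * comps[m].carbon for m, coeff in r.stoichiometry.items())
        report.nitrogen_residuals[r.id] = sum(
            coeff * comps[m].nitrogen for m, coeff in r.stoichiometry.items())

    used = {m for r in network.reactions for m in r.stoichiometry}
    report.orphan_metabolites = [m.id for m in network.metabolites if m.id not in used]

    # a reaction is dead-ended if it touches an internal metabolite that can
    # only ever be produced or only ever consumed (so no steady flux exists)
    producible: set[str] = set()
    consumable: set[str] = set()
    for r in network.reactions:
        for m, c in r.stoichiometry.items():
            if network.metabolite(m).external:
                continue
            if c > 0 or r.reversible:
                producible.add(m)
            if c < 0 or r.reversible:
                consumable.add(m)
    blocked = {m.id for m in network.internal_metabolites
               if m.id in used and not (m.id in producible and m.id in consumable)}
    report.dead_end_reactions = [
        r.id for r in network.reactions
        if any(m in blocked for m in r.stoichiometry)]
    return report
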