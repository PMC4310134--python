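"""Linear-programming yield oracle.

The maximum carbon yield of a product over the steady-state flux cone with
substrate uptake fixed to 1 is a linear program; by cone theory its optimum
equals the maximum yield over the elementary flux modes, which makes the LP
an independent cross-check of (and fast substitute for) full enumeration.

The LP is solved in floating point (HiGHS); the optimal basis is then
re-solved in exact rational arithmetic where possible, so reported optima
are exact for non-degenerate vertices and float (residuals < 1e-9)
otherwise.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Mapping

import numpy as np
from scipy.optimize import linprog

from .efm import rational_nullspace
from .network import MetabolicNetwork
from .screen import (BIOMASS, YieldResult, _carbon, _exchanged_metabolite,
                     find_export, find_uptake)

__all__ = ["lp_max_yield"]

_TOL = 1e-9


def _exact_vertex(network: MetabolicNetwork, support: list[int],
                  uptake_idx: int) -> dict[str, Fraction] | None:
    """Try to recover the optimal vertex exactly from its support."""
    if uptake_idx not in support:
        return None
    rows = []
    S = network.stoichiometric_matrix()
    for row in S:
        r = [row[j] for j in support]
        if any(x != 0 for x in r):
            rows.append(r)
    basis = rational_nullspace(rows, len(support))
    if len(basis) != 1:
        return None
    gen = basis[0]
    k = support.index(uptake_idx)
    if gen[k] == 0:
        return None
    scale = gen[k]
    vec = [g / scale for g in gen]
    for j, v in zip(support, vec):
        if v < 0 and not network.reactions[j].reversible:
            return None
    return {network.reactions[j].id: v for j, v in zip(support, vec) if v != 0}


def lp_max_yield(network: MetabolicNetwork, product: str, substrate: str,
                 require_biomass: float | Fraction = 0,
                 scenario: str = "none") -> YieldResult:
    """Maximum carbon yield of ``product`` from ``substrate`` by LP.

    Substrate uptake is fixed to 1; with ``require_biomass > 0`` the
    optimization is additionally constrained to at least that biomass flux
    (the growth-coupled ceiling).  An infeasible network (no steady state
    consuming the substrate) yields an explicit infeasibility result, not
    an exception.
    """
    n = len(network.reactions)
    idx = {r.id: j for j, r in enumerate(network.reactions)}
    uptake_id = find_uptake(network, substrate)
    export_id = find_export(network, product)
    uptake_rxn = network.reaction(uptake_id)
    export_rxn = network.reaction(export_id)
    _, up_out = _exchanged_metabolite(network, uptake_rxn)
    _, ex_out = _exchanged_metabolite(network, export_rxn)

    S = network.s_float()
    A_eq = np.vstack([S, np.zeros((1, n))]) if S.size else np.zeros((1, n))
    A_eq[-1, idx[uptake_id]] = -float(up_out)  # uptake flux (inward) = 1
    b_eq = np.zeros(A_eq.shape[0])
    b_eq[-1] = 1.0

    c = np.zeros(n)
    c[idx[export_id]] = -float(ex_out)  # maximize outward product flux

    bounds = [(None, None) if r.reversible else (0, None) for r in network.reactions]
    A_ub = b_ub = None
    if require_biomass and float(require_biomass) > 0:
        bio = np.zeros(n)
        bio[idx[find_export(network, BIOMASS)]] = -1.0
        A_ub, b_ub = bio[None, :], np.array([-float(require_biomass)])

    res = linprog(c, A_eq=A_eq, b_eq=b_eq, A_ub=A_ub, b_ub=b_ub,
                  bounds=bounds, method="highs")
    if not res.success:
        return YieldResult(product=product, substrate=substrate, scenario=scenario,
                           feasible=False, message=res.message)

    cp, cs = _carbon(network, product), _carbon(network, substrate)
    v = res.x
    support = [j for j in range(n) if abs(v[j]) > _TOL]
    exact = None
    if not (require_biomass and float(require_biomass) > 0):
        exact = _exact_vertex(network, support, idx[uptake_id])
    if exact is not None:
        out = exact.get(export_id, Fraction(0)) * ex_out
        y = 100 * max(out, Fraction(0)) * cp / cs
        if abs(float(y) - float(100 * (-res.fun) * cp / cs)) < 1e-6:
            return YieldResult(product=product, substrate=substrate,
                               scenario=scenario, yield_percent=y, flux=exact)
    y = 100 * float(-res.fun) * float(cp) / float(cs)
    flux = {network.reactions[j].id: Fraction(v[j]).limit_denominator(10**9)
            for j in support}
    return YieldResult(product=product, substrate=substrate, scenario=scenario,
                       yield_percent=y, flux=flux)
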