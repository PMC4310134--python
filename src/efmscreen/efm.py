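"""Elementary flux mode enumeration.

An elementary flux mode (EFM) is a steady-state flux vector ``v`` with
``S v = 0``, non-negative flux through every irreversible reaction, and
*minimal support*: no other admissible steady-state vector uses a strict
subset of its reactions.  The EFMs are exactly the extreme rays of the flux
cone after splitting reversible reactions, minus the spurious
forward/backward two-cycles, and together they generate every steady-state
behaviour of the network.

The enumerator is a double description method run in exact integer
arithmetic:

1. reversible reactions are split into forward/backward columns;
2. the network is compressed (enforced-zero column pruning and lumping of
   unbranched metabolites), which preserves the mode set;
3. the stoichiometric equalities are reduced to an independent row set and
   intersected one at a time with the positive orthant, keeping only
   adjacent ray pairs (combinatorial support test with a rank-based
   candidate filter);
4. rays are folded back to the original reaction space, two-cycles are
   dropped, and modes are normalized and sorted deterministically.

Elementarity is a combinatorial property; exact rationals are used end to
end so that no tolerance can corrupt a support.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np

from .network import MetabolicNetwork, Metabolite, Reaction

__all__ = [
    "ElementaryMode",
    "EnumerationOverflow",
    "split_reversible",
    "ReversibleSplit",
    "enumerate_efms",
    "is_elementary",
]


class EnumerationOverflow(RuntimeError):
    """Intermediate ray count exceeded the configured ceiling."""


@dataclass(frozen=True)
class ElementaryMode:
    """One elementary flux mode.

    ``flux`` holds the nonzero rational fluxes by reaction id (negative
    values mean a reversible reaction runs backwards).  ``normalized_by``
    records the scaling convention: a substrate-uptake reaction id when the
    mode consumes that substrate (uptake flux scaled to 1), else
    ``"min-flux"`` (smallest positive flux scaled to 1).
    """

    flux: Mapping[str, Fraction]
    normalized_by: str = "min-flux"

    def __post_init__(self):
        object.__setattr__(self, "flux",
                           {r: Fraction(v) for r, v in self.flux.items() if v != 0})

    @property
    def support(self) -> frozenset[str]:
        return frozenset(self.flux)

    def __getitem__(self, rxn_id: str) -> Fraction:
        return self.flux.get(rxn_id, Fraction(0))

    def canonical(self) -> tuple[tuple[str, Fraction], ...]:
        """Orientation-preserving canonical form: primitive integer scaling."""
        items = sorted(self.flux.items())
        denom_lcm = math.lcm(*(v.denominator for _, v in items))
        ints = [int(v * denom_lcm) for _, v in items]
        g = math.gcd(*(abs(x) for x in ints))
        return tuple((r, Fraction(x, g)) for (r, _), x in zip(items, ints))


# ---------------------------------------------------------------------------
# reversible splitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReversibleSplit:
    """Mapping between a network and its all-irreversible expansion.

    ``columns[j] = (reaction_id, +1|-1)`` for expanded column j.
    """

    columns: tuple[tuple[str, int], ...]

    def fold(self, expanded_flux: Sequence[Fraction]) -> dict[str, Fraction]:
        """Fold an expanded flux vector back to net fluxes per reaction."""
        out: dict[str, Fraction] = {}
        for (rid, sign), v in zip(self.columns, expanded_flux):
            if v:
                out[rid] = out.get(rid, Fraction(0)) + sign * v
        return {r: v for r, v in out.items() if v != 0}

    def split(self, flux: Mapping[str, Fraction]) -> list[Fraction]:
        """Express net fluxes in the expanded space (one direction active)."""
        out = []
        for rid, sign in self.columns:
            v = flux.get(rid, Fraction(0))
            out.append(v * sign if v * sign > 0 else Fraction(0))
        return out


def split_reversible(network: MetabolicNetwork) -> tuple[MetabolicNetwork, ReversibleSplit]:
    """Expand each reversible reaction into forward + backward columns."""
    reactions: list[Reaction] = []
    columns: list[tuple[str, int]] = []
    for r in network.reactions:
        if r.reversible:
            fwd = Reaction(id=r.id + "__f", stoichiometry=dict(r.stoichiometry),
                           reversible=False, tag=r.tag)
            bwd = Reaction(id=r.id + "__b",
                           stoichiometry={m: -c for m, c in r.stoichiometry.items()},
                           reversible=False, tag=r.tag)
            reactions.extend([fwd, bwd])
            columns.extend([(r.id, +1), (r.id, -1)])
        else:
            reactions.append(Reaction(id=r.id, stoichiometry=dict(r.stoichiometry),
                                      reversible=False, tag=r.tag))
            columns.append((r.id, +1))
    expanded = MetabolicNetwork(network.metabolites, reactions)
    return expanded, ReversibleSplit(tuple(columns))


# ---------------------------------------------------------------------------
# exact linear algebra helpers (integer / rational)
# ---------------------------------------------------------------------------

def _primitive(row: Sequence[Fraction]) -> list[int]:
    """Scale a rational vector to coprime integers (orientation preserved)."""
    denom = math.lcm(*(f.denominator for f in row)) if row else 1
    ints = [int(f * denom) for f in row]
    g = math.gcd(*(abs(x) for x in ints))
    if g > 1:
        ints = [x // g for x in ints]
    return ints

def _rref(rows: list[list[Fraction]]) -> list[list[Fraction]]:
    """Reduced row echelon form; returns the nonzero rows."""
    mat = [list(r) for r in rows]
    n_rows, n_cols = len(mat), len(mat[0]) if mat else 0
    pivot_row = 0
    for col in range(n_cols):
        sel = next((i for i in range(pivot_row, n_rows) if mat[i][col] != 0), None)
        if sel is None:
            continue
        mat[pivot_row], mat[sel] = mat[sel], mat[pivot_row]
        pv = mat[pivot_row][col]
        mat[pivot_row] = [x / pv for x in mat[pivot_row]]
        for i in range(n_rows):
            if i != pivot_row and mat[i][col] != 0:
                f = mat[i][col]
                mat[i] = [a - f * b for a, b in zip(mat[i], mat[pivot_row])]
        pivot_row += 1
        if pivot_row == n_rows:
            break
    return [r for r in mat[:pivot_row]]


def rational_nullspace(rows: list[list[Fraction]], n_cols: int) -> list[list[Fraction]]:
    """Basis of the right nullspace of the given rational matrix."""
    if not rows:
        return [[Fraction(i == j) for i in range(n_cols)] for j in range(n_cols)]
    red = _rref(rows)
    pivots = []
    for r in red:
        pivots.append(next(j for j, x in enumerate(r) if x != 0))
    free = [j for j in range(n_cols) if j not in pivots]
    basis = []
    for f in free:
        vec = [Fraction(0)] * n_cols
        vec[f] = Fraction(1)
        for r, p in zip(red, pivots):
            vec[p] = -r[f]
        basis.append(vec)
    return basis


# ---------------------------------------------------------------------------
# network compression (mode-set preserving)
# ---------------------------------------------------------------------------

def _compress(matrix: list[list[Fraction]], columns: list[dict[int, Fraction]],
              same_reaction_pair) -> tuple[list[list[Fraction]], list[dict[int, Fraction]], list[dict[int, Fraction]]]:
    """Dead-end pruning and lumping of unbranched metabolites.

    ``matrix`` is S over the split (all-irreversible) columns; ``columns``
    carries, per working column, its provenance as weights over the original
    split columns.  Returns (reduced matrix rows, reduced columns, isolated
    cycle columns) where an isolated cycle is a locked pair of mutually
    inverse distinct reactions: it is itself a mode but can join no other.
    """
    rows = [list(r) for r in matrix]
    cols = [dict(c) for c in columns]
    cycles: list[dict[int, Fraction]] = []

    def drop_cols(idxs: set[int]):
        nonlocal rows, cols
        keep = [j for j in range(len(cols)) if j not in idxs]
        cols = [cols[j] for j in keep]
        rows = [[r[j] for j in keep] for r in rows]

    changed = True
    while changed:
        changed = False
        rows = [r for r in rows if any(x != 0 for x in r)]
        for ri, row in enumerate(rows):
            pos = [j for j, x in enumerate(row) if x > 0]
            neg = [j for j, x in enumerate(row) if x < 0]
            if not pos and not neg:
                continue
            if not pos or not neg:
                # metabolite only produced or only consumed: all incident
                # reactions are enforced to zero flux
                drop_cols(set(pos) | set(neg))
                del rows[ri]
                changed = True
                break
            if len(pos) == 1 and len(neg) == 1:
                jp, jn = pos[0], neg[0]
                a, b = row[jp], -row[jn]  # a, b > 0
                merged_vec = [b * r[jp] + a * r[jn] for r in rows]
                merged_prov: dict[int, Fraction] = {}
                for k, w in cols[jp].items():
                    merged_prov[k] = merged_prov.get(k, Fraction(0)) + b * w
                for k, w in cols[jn].items():
                    merged_prov[k] = merged_prov.get(k, Fraction(0)) + a * w
                merged_prov = {k: w for k, w in merged_prov.items() if w != 0}
                if all(x == 0 for x in merged_vec):
                    # locked pair that cancels everywhere: an isolated cycle
                    if not same_reaction_pair(cols[jp], cols[jn]) and merged_prov:
                        cycles.append(merged_prov)
                    drop_cols({jp, jn})
                    del rows[ri]
                    changed = True
                    break
                # replace the pair by the lumped column, drop the metabolite
                del rows[ri]
                keep = [j for j in range(len(cols)) if j not in (jp, jn)]
                new_rows = []
                for r_old, mval in zip(rows, merged_vec[:ri] + merged_vec[ri + 1:]):
                    new_rows.append([r_old[j] for j in keep] + [mval])
                rows = new_rows
                cols = [cols[j] for j in keep] + [merged_prov]
                changed = True
                break
    return rows, cols, cycles


# ---------------------------------------------------------------------------
# double description
# ---------------------------------------------------------------------------

def _pack_supports(supports: list[int], n_words: int) -> np.ndarray:
    out = np.zeros((len(supports), n_words), dtype=np.uint64)
    for i, s in enumerate(supports):
        for w in range(n_words):
            out[i, w] = (s >> (64 * w)) & 0xFFFFFFFFFFFFFFFF
    return out


def _adjacent_pairs(packed: np.ndarray, P: list[int], N: list[int],
                    bound: int) -> list[tuple[int, int]]:
    """Adjacent (p, q) pairs by the combinatorial support test.

    Candidates are pre-filtered with the rank bound on the union support
    size (adjacent extreme rays span a 2-face, so their union has at most
    ``bound`` nonzeros), then checked against all current rays in
    vectorized chunks.
    """
    if not P or not N:
        return []
    n_words = packed.shape[1]
    pk, nk = packed[P], packed[N]
    cand_p: list[np.ndarray] = []
    cand_q: list[np.ndarray] = []
    blk = max(1, int(2_000_000 / max(1, len(N))))
    for i0 in range(0, len(P), blk):
        U = pk[i0:i0 + blk, None, :] | nk[None, :, :]
        pops = np.bitwise_count(U).sum(axis=2, dtype=np.int64)
        pi, qi = np.nonzero(pops <= bound)
        cand_p.append(pi + i0)
        cand_q.append(qi)
    cp = np.concatenate(cand_p)
    cq = np.concatenate(cand_q)
    if cp.size == 0:
        return []
    P_arr, N_arr = np.array(P), np.array(N)
    gp, gq = P_arr[cp], N_arr[cq]  # global ray indices

    pairs: list[tuple[int, int]] = []
    k = packed.shape[0]
    chunk = max(16, int(20_000_000 / max(1, k)))
    for j0 in range(0, gp.size, chunk):
        p_idx, q_idx = gp[j0:j0 + chunk], gq[j0:j0 + chunk]
        U = packed[p_idx] | packed[q_idx]  # (m, w)
        # ray r blocks the pair iff supp(r) is inside the union
        inside = np.ones((p_idx.size, k), dtype=bool)
        for w in range(n_words):
            np.logical_and(inside,
                           (packed[:, w][None, :] & ~U[:, w][:, None]) == 0,
                           out=inside)
        rows_m = np.arange(p_idx.size)
        inside[rows_m, p_idx] = False
        inside[rows_m, q_idx] = False
        ok = ~inside.any(axis=1)
        pairs.extend(zip(p_idx[np.nonzero(ok)[0]].tolist(),
                         q_idx[np.nonzero(ok)[0]].tolist()))
    return pairs


def _double_description(rows: list[list[int]], n_cols: int, max_rays: int
                        ) -> list[tuple[int, ...]]:
    """Extreme rays of {v >= 0, R v = 0} for independent integer rows R."""
    rays: list[list[int]] = [[int(i == j) for i in range(n_cols)] for j in range(n_cols)]
    supports: list[int] = [1 << j for j in range(n_cols)]
    n_words = (n_cols + 63) // 64
    remaining = list(range(len(rows)))
    processed = 0

    while remaining:
        # pick the constraint that generates the fewest candidate pairs
        ray_f = np.array(rays, dtype=float)
        best, best_cost = None, None
        for ci in remaining:
            dots = ray_f @ np.array(rows[ci], dtype=float)
            cost = int((dots > 1e-9).sum()) * int((dots < -1e-9).sum())
            if best_cost is None or cost < best_cost:
                best, best_cost = ci, cost
        row = rows[best]
        remaining.remove(best)
        nz = [(j, c) for j, c in enumerate(row) if c != 0]

        dots = [sum(c * ray[j] for j, c in nz) for ray in rays]
        P = [i for i, d in enumerate(dots) if d > 0]
        N = [i for i, d in enumerate(dots) if d < 0]
        Z = [i for i, d in enumerate(dots) if d == 0]

        packed = _pack_supports(supports, n_words)
        bound = processed + 2  # rank argument: adjacent pairs share a 2-face
        new_rays: list[list[int]] = []
        new_supports: list[int] = []
        for p, q in _adjacent_pairs(packed, P, N, bound):
            cp, cq = dots[p], dots[q]
            vec = [cp * rays[q][j] - cq * rays[p][j] for j in range(n_cols)]
            g = math.gcd(*(abs(x) for x in vec))
            if g > 1:
                vec = [x // g for x in vec]
            new_rays.append(vec)
            new_supports.append(supports[p] | supports[q])
        rays = [rays[i] for i in Z] + new_rays
        supports = [supports[i] for i in Z] + new_supports
        if len(rays) > max_rays:
            raise EnumerationOverflow(
                f"intermediate ray count {len(rays)} exceeds ceiling {max_rays}")
        processed += 1
    return [tuple(r) for r in rays]


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def _normalize(flux: dict[str, Fraction], substrate_reaction: str | None
               ) -> ElementaryMode:
    if substrate_reaction is not None and flux.get(substrate_reaction, 0) > 0:
        scale = flux[substrate_reaction]
        return ElementaryMode({r: v / scale for r, v in flux.items()},
                              normalized_by=substrate_reaction)
    positives = [v for v in flux.values() if v > 0]
    scale = min(positives) if positives else min(-v for v in flux.values())
    return ElementaryMode({r: v / scale for r, v in flux.items()},
                          normalized_by="min-flux")


def enumerate_efms(network: MetabolicNetwork, *, max_rays: int = 1_000_000,
                   compress: bool = True,
                   substrate_reaction: str | None = None) -> list[ElementaryMode]:
    """Enumerate the complete set of elementary flux modes.

    Returns modes in the original (unsplit) reaction space, duplicate-free,
    with forward/backward two-cycles of reversible reactions removed, in a
    deterministic order (by support, then lexicographic flux).

    ``max_rays`` guards against combinatorial blow-up of the intermediate
    ray count; :class:`EnumerationOverflow` is raised beyond it.
    ``substrate_reaction`` selects the uptake reaction used for mode
    normalization (uptake flux scaled to 1 where the mode consumes it).
    """
    if not network.reactions:
        return []
    expanded, split = split_reversible(network)
    n_split = len(expanded.reactions)
    matrix = expanded.stoichiometric_matrix()
    columns = [{j: Fraction(1)} for j in range(n_split)]

    col_rxn = [split.columns[j][0] for j in range(n_split)]

    def same_reaction_pair(prov_a: dict[int, Fraction], prov_b: dict[int, Fraction]) -> bool:
        ra = {col_rxn[j] for j in prov_a}
        rb = {col_rxn[j] for j in prov_b}
        return len(ra) == 1 and ra == rb

    cycle_modes: list[dict[int, Fraction]] = []
    if compress:
        matrix, columns, cycle_modes = _compress(matrix, columns, same_reaction_pair)

    n_cols = len(columns)
    raw_fluxes: list[dict[str, Fraction]] = []
    if n_cols:
        rref_rows = _rref(matrix) if matrix else []
        int_rows = [_primitive(r) for r in rref_rows]
        rays = _double_description(int_rows, n_cols, max_rays)
        for ray in rays:
            expanded_flux = [Fraction(0)] * n_split
            for j, val in enumerate(ray):
                if val:
                    for k, w in columns[j].items():
                        expanded_flux[k] += val * w
            folded = split.fold(expanded_flux)
            if folded:
                raw_fluxes.append(folded)
    for prov in cycle_modes:
        expanded_flux = [Fraction(0)] * n_split
        for k, w in prov.items():
            expanded_flux[k] += w
        folded = split.fold(expanded_flux)
        if folded:
            raw_fluxes.append(folded)

    modes = [_normalize(f, substrate_reaction) for f in raw_fluxes]
    unique = {m.canonical(): m for m in modes}
    order = {rid: i for i, rid in enumerate(network.reaction_ids)}
    return sorted(unique.values(),
                  key=lambda m: (len(m.support),
                                 sorted(order[r] for r in m.support),
                                 [(order[r], v) for r, v in sorted(
                                     m.flux.items(), key=lambda kv: order[kv[0]])]))


def is_elementary(network: MetabolicNetwork, flux: Mapping[str, Fraction]) -> bool:
    """Rank test: ``v`` is elementary iff S restricted to supp(v) has nullity 1.

    Raises :class:`ValueError` if the candidate is not a steady-state flux
    (``S v != 0``) or violates an irreversibility constraint — such vectors
    are not modes at all rather than non-elementary ones.
    """
    flux = {r: Fraction(v) for r, v in flux.items() if v != 0}
    if not flux:
        raise ValueError("zero vector is not a flux mode")
    rxn_by_id = {r.id: r for r in network.reactions}
    for rid, v in flux.items():
        if rid not in rxn_by_id:
            raise ValueError(f"unknown reaction {rid!r}")
        if v < 0 and not rxn_by_id[rid].reversible:
            raise ValueError(f"negative flux through irreversible reaction {rid!r}")
    for met in network.internal_metabolites:
        bal = sum(rxn_by_id[rid].stoichiometry.get(met.id, Fraction(0)) * v
                  for rid, v in flux.items())
        if bal != 0:
            raise ValueError(f"steady state violated at metabolite {met.id!r}")
    support_ids = [r.id for r in network.reactions if r.id in flux]
    sub_rows = []
    for met in network.internal_metabolites:
        row = [rxn_by_id[rid].stoichiometry.get(met.id, Fraction(0)) for rid in support_ids]
        if any(x != 0 for x in row):
            sub_rows.append(row)
    nullity = len(rational_nullspace(sub_rows, len(support_ids)))
    return nullity == 1
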