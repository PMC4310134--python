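"""Random small stoichiometric networks with ground-truth mode sets.

These fixtures exercise the enumeration engine and the yield analytics
without the biological network: networks are small enough (<= 14 reactions)
that the complete elementary-mode set can be recovered independently by
exhaustive support enumeration (:func:`brute_force_efms`), which serves as
the oracle the double-description engine is checked against.

Generation uses :class:`random.Random` (pure-Python Mersenne Twister), so a
spec is a bit-stable recipe across platforms.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations

from .efm import ElementaryMode, _normalize, rational_nullspace
from .network import MetabolicNetwork, Metabolite, Reaction

__all__ = ["RandomNetworkSpec", "random_network", "brute_force_efms"]

_BRUTE_FORCE_LIMIT = 14


@dataclass(frozen=True)
class RandomNetworkSpec:
    """Recipe for one random network; generation is a pure function of this."""

    n_internal_metabolites: int = 4
    n_reactions: int = 8
    reversible_fraction: float = 0.0
    max_abs_coefficient: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_internal_metabolites < 1:
            raise ValueError("need at least one internal metabolite")
        if self.n_reactions < 3:
            raise ValueError("need at least 3 reactions (uptake, conversion, secretion)")
        if not 0 <= self.reversible_fraction <= 1:
            raise ValueError("reversible_fraction must be in [0, 1]")
        if self.max_abs_coefficient < 1:
            raise ValueError("max_abs_coefficient must be >= 1")


def _connected(n_mets: int, reactions: list[dict[int, int]]) -> bool:
    # union-find over metabolites, joined through shared reactions
    parent = list(range(n_mets))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for stoich in reactions:
        mets = list(stoich)
        for a, b in zip(mets, mets[1:]):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
    roots = {find(i) for i in range(n_mets)}
    return len(roots) == 1


def random_network(spec: RandomNetworkSpec, max_retries: int = 200) -> MetabolicNetwork:
    """Generate a connected random network; deterministic for a given spec.

    Always contains at least one uptake and one secretion exchange.  Raises
    ``RuntimeError`` if no connected network is found within the retry
    budget (possible for very sparse specs).
    """
    rng = random.Random(spec.seed)
    n = spec.n_internal_metabolites
    for _ in range(max_retries):
        stoichs: list[dict[int, int]] = []
        # one uptake into metabolite 0, one secretion out of the last metabolite
        stoichs.append({0: 1})
        stoichs.append({n - 1: -1})
        for _ in range(spec.n_reactions - 2):
            kind = rng.random()
            if kind < 0.15:  # extra exchange
                met = rng.randrange(n)
                stoichs.append({met: rng.choice([-1, 1])})
                continue
            n_sub = rng.choice([1, 1, 2])
            n_prod = rng.choice([1, 1, 2])
            mets = rng.sample(range(n), min(n, n_sub + n_prod))
            stoich = {}
            for m in mets[:n_sub]:
                stoich[m] = -rng.randint(1, spec.max_abs_coefficient)
            for m in mets[n_sub:]:
                stoich[m] = rng.randint(1, spec.max_abs_coefficient)
            if len(stoich) < 2:
                continue
            stoichs.append(stoich)
        if len(stoichs) != spec.n_reactions or not _connected(n, stoichs):
            continue
        if not all(any(m in s for s in stoichs) for m in range(n)):
            continue
        metabolites = [Metabolite(id=f"M{i}") for i in range(n)]
        reactions = []
        for i, stoich in enumerate(stoichs):
            reversible = i >= 2 and rng.random() < spec.reversible_fraction
            tag = "exchange" if len(stoich) == 1 else "core"
            reactions.append(Reaction(
                id=f"R{i}",
                stoichiometry={f"M{m}": Fraction(c) for m, c in stoich.items()},
                reversible=reversible, tag=tag))
        return MetabolicNetwork(metabolites, reactions)
    raise RuntimeError(f"no connected network found for {spec} within {max_retries} retries")


def brute_force_efms(network: MetabolicNetwork) -> list[ElementaryMode]:
    """Ground-truth mode set by exhaustive support enumeration.

    For every subset T of reactions, the restriction of S to T is elementary
    iff its nullspace is one-dimensional, its generator has full support on
    T, and the generator (or its negation) respects irreversibility.  A
    generator supported only on reversible reactions is admissible in both
    orientations and contributes two modes, matching the orientation
    convention of the enumeration engine.
    """
    n = len(network.reactions)
    if n > _BRUTE_FORCE_LIMIT:
        raise ValueError(
            f"brute force enumeration refused for {n} reactions "
            f"(limit {_BRUTE_FORCE_LIMIT}: subset enumeration is 2^n)")
    rows_full = network.stoichiometric_matrix()
    reversible = [r.reversible for r in network.reactions]
    ids = network.reaction_ids

    modes: dict[tuple, ElementaryMode] = {}
    for size in range(1, n + 1):
        for subset in combinations(range(n), size):
            sub_rows = []
            for row in rows_full:
                r = [row[j] for j in subset]
                if any(x != 0 for x in r):
                    sub_rows.append(r)
            basis = rational_nullspace(sub_rows, size)
            if len(basis) != 1:
                continue
            gen = basis[0]
            if any(x == 0 for x in gen):
                continue  # support smaller than T; T itself is not minimal
            for orient in (1, -1):
                vec = [orient * x for x in gen]
                if all(vec[k] > 0 or reversible[subset[k]] for k in range(size)):
                    flux = {ids[subset[k]]: vec[k] for k in range(size)}
                    mode = _normalize(flux, None)
                    modes[mode.canonical()] = mode
    order = {rid: i for i, rid in enumerate(ids)}
    return sorted(modes.values(),
                  key=lambda m: (len(m.support),
                                 sorted(order[r] for r in m.support),
                                 [(order[r], v) for r, v in sorted(
                                     m.flux.items(), key=lambda kv: order[kv[0]])]))
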