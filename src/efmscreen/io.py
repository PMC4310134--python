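"""Writers for mode sets and screen artefacts (plain TSV / JSON)."""

from __future__ import annotations

import json
from fractions import Fraction
from typing import Iterable, Sequence

from .efm import ElementaryMode
from .network import MetabolicNetwork

__all__ = ["write_modes_tsv", "write_modes_json", "modes_to_json_obj"]


def _render(v: Fraction, rational: bool) -> str:
    if rational:
        return str(v.numerator) if v.denominator == 1 else f"{v.numerator}/{v.denominator}"
    return repr(float(v))


def write_modes_tsv(modes: Sequence[ElementaryMode], network: MetabolicNetwork,
                    path, *, rational: bool = True) -> None:
    """One row per mode, one column per reaction (0 for absent reactions)."""
    ids = network.reaction_ids
    with open(path, "w") as fh:
        fh.write("mode\t" + "\t".join(ids) + "\tnormalized_by\n")
        for i, m in enumerate(modes):
            cells = [_render(m.flux.get(r, Fraction(0)), rational) for r in ids]
            fh.write(f"{i}\t" + "\t".join(cells) + f"\t{m.normalized_by}\n")


def modes_to_json_obj(modes: Sequence[ElementaryMode]) -> list[dict]:
    out = []
    for m in modes:
        out.append({
            "support": sorted(m.support),
            "flux": {r: _render(v, True) for r, v in sorted(m.flux.items())},
            "normalized_by": m.normalized_by,
        })
    return out


def write_modes_json(modes: Sequence[ElementaryMode], path) -> None:
    """Compact JSON: supports plus rational flux values as strings."""
    with open(path, "w") as fh:
        json.dump({"n_modes": len(modes), "modes": modes_to_json_obj(modes)},
                  fh, indent=1)
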