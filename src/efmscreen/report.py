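"""Optional plot rendering: yield bar charts and biomass/product scatters.

Matplotlib is an optional dependency; importing this module without it
raises a clear error only when a plot function is called.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd


def _plt():
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        return plt
    except ImportError as e:  # pragma: no cover
        raise ImportError("plot rendering requires matplotlib "
                          "(install the 'plot' extra)") from e


def plot_yield_bars(df: pd.DataFrame, path, *, substrate: str | None = None) -> None:
    """Grouped bars of max yield per product x scenario (one substrate)."""
    plt = _plt()
    data = df if substrate is None else df[df["substrate"] == substrate]
    pivot = data.pivot_table(index="product", columns="scenario",
                             values="max_yield_percent", aggfunc="first")
    ax = pivot.plot.bar(figsize=(max(6, 0.6 * len(pivot)), 4))
    ax.set_ylabel("max carbon yield [%]")
    ax.set_ylim(0, 105)
    ax.figure.tight_layout()
    ax.figure.savefig(path, dpi=150)


def plot_scatter(scatter_df: pd.DataFrame, path, *, title: str = "") -> None:
    """Biomass vs product yield of every mode (one cell)."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.plot(scatter_df["biomass_yield_percent"],
            scatter_df["product_yield_percent"], ".", ms=4, alpha=0.6)
    ax.set_xlabel("biomass yield [%]")
    ax.set_ylabel("product yield [%]")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
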