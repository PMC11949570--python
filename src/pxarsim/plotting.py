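"""Convenience figures: slope-vs-parameter box plots and importance bars.

Plotting is a presentation layer only; nothing downstream depends on a
rendered figure.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["slope_boxplot", "importance_barplot"]


def slope_boxplot(
    results: pd.DataFrame,
    param: str,
    response: str = "pxar_slope",
    by: str | None = None,
    ax=None,
):
    """Box plots of a fitted slope across the levels of one parameter,
    optionally panelled by a second parameter (e.g. SAD unevenness)."""
    data = results.dropna(subset=[response])
    if by is None:
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        groups = sorted(data[param].unique())
        ax.boxplot(
            [data.loc[data[param] == g, response] for g in groups],
            tick_labels=[str(g) for g in groups],
        )
        ax.axhline(0.0, color="grey", lw=0.8, ls="--")
        ax.set_xlabel(param)
        ax.set_ylabel(response)
        return ax.figure
    panels = sorted(data[by].unique())
    fig, axes = plt.subplots(
        1, len(panels), figsize=(4 * len(panels), 4), sharey=True, squeeze=False
    )
    for axis, level in zip(axes.ravel(), panels):
        slope_boxplot(data[data[by] == level], param, response, ax=axis)
        axis.set_title(f"{by} = {level}")
    fig.tight_layout()
    return fig


def importance_barplot(importance: pd.DataFrame, ax=None):
    """Horizontal bars of random-forest importances, most important on top."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ordered = importance.sort_values("importance")
    ax.barh(ordered["predictor"], ordered["importance"])
    ax.set_xlabel("mean decrease in node impurity")
    response = importance["response"].iloc[0]
    ax.set_title(f"parameter importance for {response}")
    ax.figure.tight_layout()
    return ax.figure
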