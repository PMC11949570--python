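"""Grain scaling of species loss: nested grids, Px, Ex, and slope fits.

The region (unit square) is overlaid with nested k x k grids.  For every
cell we count

* ``s1`` — species present at time 1 (any point of the species in the cell),
* ``ex`` — species present at time 1 with no surviving point in the cell,
* ``px`` — ex / s1 (undefined for empty cells).

The scaling relationships are summarized by two slopes against the natural
log of cell area A = 1/k^2:

* PxAR: ordinary least squares of the per-grain extinction probability Px
  on ln A.  Px at a grain is the ratio of means over occupied cells,
  mean(ex) / mean(s1), which makes the identity Ex = S1 * Px exact at
  every grain.  A mean-of-per-cell-ratios variant is available for
  sensitivity checks.
* ExAR: Poisson GLM (log link) of the per-cell integer counts ``ex``
  (all cells, zeros included) on ln A; the fitted coefficient is the
  ExAR slope d ln E[Ex] / d ln A.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .point_community import PointCommunity

__all__ = [
    "DEFAULT_LEVELS",
    "PxarFit",
    "ExarFit",
    "compute_grain_table",
    "summarize_grains",
    "fit_pxar",
    "fit_exar",
    "extinction_scaling",
]

DEFAULT_LEVELS = (2, 4, 8, 16)

GRAIN_COLUMNS = ["k", "cell_id", "area", "s1", "ex", "px"]


@dataclass(frozen=True)
class PxarFit:
    slope: float
    intercept: float
    residuals: np.ndarray


@dataclass(frozen=True)
class ExarFit:
    slope: float
    intercept: float


def _cell_index(coord: np.ndarray, k: int) -> np.ndarray:
    # half-open cells [i/k, (i+1)/k); a coordinate exactly 1.0 is clamped
    # into the last cell
    return np.minimum((coord * k).astype(np.int64), k - 1)


def compute_grain_table(
    community: PointCommunity,
    levels=DEFAULT_LEVELS,
) -> pd.DataFrame:
    """Per-cell richness and loss counts for each grid resolution.

    Returns a DataFrame with one row per cell per grain (k^2 rows per
    grain, empty cells retained with s1 = 0 and px = NaN), columns
    ``k, cell_id, area, s1, ex, px``.
    """
    levels = [int(k) for k in levels]
    if any(k < 1 for k in levels):
        raise ValueError("grid levels must be positive integers")
    if len(community) == 0:
        return pd.DataFrame(columns=GRAIN_COLUMNS)

    frames = []
    for k in levels:
        cell = _cell_index(community.y, k) * k + _cell_index(community.x, k)
        df = pd.DataFrame(
            {"cell_id": cell, "species": community.species, "alive": community.alive_t2}
        )
        # a species survives in a cell iff any of its points there survive
        surv = df.groupby(["cell_id", "species"])["alive"].any()
        per_cell = surv.groupby(level="cell_id").agg(s1="size", survivors="sum")
        per_cell = per_cell.reindex(range(k * k), fill_value=0)
        s1 = per_cell["s1"].to_numpy(np.int64)
        ex = s1 - per_cell["survivors"].to_numpy(np.int64)
        with np.errstate(invalid="ignore", divide="ignore"):
            px = np.where(s1 > 0, ex / np.maximum(s1, 1), np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "k": k,
                    "cell_id": np.arange(k * k),
                    "area": 1.0 / k**2,
                    "s1": s1,
                    "ex": ex,
                    "px": px,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def summarize_grains(
    table: pd.DataFrame,
    px_mode: str = "ratio_of_means",
) -> pd.DataFrame:
    """Per-grain means of S1 and Ex, and the grain-level Px.

    mean_s1 / mean_ex average over ALL k^2 cells (zeros included).  Px is
    mean(ex)/mean(s1) over occupied cells (``ratio_of_means``, default) or
    the mean of per-cell ex/s1 ratios (``mean_of_ratios``); grains with no
    occupied cell get Px = NaN.
    """
    if table.empty:
        raise ValueError("grain table is empty")
    if px_mode not in ("ratio_of_means", "mean_of_ratios"):
        raise ValueError(f"unknown px_mode {px_mode!r}")

    rows = []
    for (k, area), grp in table.groupby(["k", "area"], sort=True):
        occ = grp[grp["s1"] > 0]
        if occ.empty:
            px = np.nan
        elif px_mode == "ratio_of_means":
            px = occ["ex"].mean() / occ["s1"].mean()
        else:
            px = (occ["ex"] / occ["s1"]).mean()
        rows.append(
            {
                "k": int(k),
                "area": float(area),
                "mean_s1": grp["s1"].mean(),
                "mean_ex": grp["ex"].mean(),
                "px": px,
            }
        )
    return pd.DataFrame(rows).sort_values("area", ignore_index=True)


def fit_pxar(summary: pd.DataFrame) -> PxarFit:
    """OLS of grain-level Px on ln(area); slope is per unit ln A."""
    usable = summary.dropna(subset=["px"])
    if len(usable) < 2:
        raise ValueError(
            "PxAR undefined: need >= 2 grains with a defined Px, "
            f"got {len(usable)}"
        )
    X = sm.add_constant(np.log(usable["area"].to_numpy()))
    res = sm.OLS(usable["px"].to_numpy(), X).fit()
    return PxarFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        residuals=np.asarray(res.resid),
    )


def fit_exar(table: pd.DataFrame) -> ExarFit:
    """Poisson GLM (log link) of per-cell extinct-species counts on ln(area).

    Uses every cell at every grain (zeros included).  If no cell lost any
    species the log-linear mean is unidentified and a ValueError is raised
    rather than returning a spurious 0.
    """
    if table.empty or table["k"].nunique() < 2:
        raise ValueError("ExAR undefined: need >= 2 grains")
    if not (table["ex"] > 0).any():
        raise ValueError("ExAR undefined: no extinctions in any cell")
    X = sm.add_constant(np.log(table["area"].to_numpy()))
    res = sm.GLM(
        table["ex"].to_numpy(float), X, family=sm.families.Poisson()
    ).fit()
    return ExarFit(slope=float(res.params[1]), intercept=float(res.params[0]))


def extinction_scaling(
    community: PointCommunity,
    levels=DEFAULT_LEVELS,
    px_mode: str = "ratio_of_means",
):
    """Grain table + summary + both slope fits for one before/after snapshot.

    Returns ``(table, summary, pxar_fit, exar_fit)``; either fit is None
    when undefined (too few usable grains / no extinctions anywhere).
    """
    table = compute_grain_table(community, levels=levels)
    summary = summarize_grains(table, px_mode=px_mode)
    try:
        pxar = fit_pxar(summary)
    except ValueError:
        pxar = None
    try:
        exar = fit_exar(table)
    except ValueError:
        exar = None
    return table, summary, pxar, exar
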