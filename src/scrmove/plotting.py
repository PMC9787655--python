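"""Plots for fitted SCR-movement models (density surfaces, abundance series)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_density_surface", "plot_abundance_series"]


def plot_density_surface(density: pd.DataFrame, region, ax=None):
    """Heat map of mean daily bears per surveyed trap cell.

    ``density`` is the DataFrame from
    :meth:`SCRMovementResults.density_surface`; ``region`` is a
    :class:`~scrmove.landscape.SurveyRegion` or a trap-cell edge length in km.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    res = region if np.isscalar(region) else region.resolution_km
    vals = density["bears_per_cell_day"]
    sc = ax.scatter(
        density["x_km"],
        density["y_km"],
        c=vals,
        s=(res * 2.2) ** 2,
        marker="s",
        cmap="viridis",
    )
    plt.colorbar(sc, ax=ax, label="bears / cell / day")
    ax.set_xlabel("x (km)")
    ax.set_ylabel("y (km)")
    ax.set_aspect("equal")
    return ax


def plot_abundance_series(abundance: pd.DataFrame, observed_counts=None, ax=None):
    """Daily and cumulative abundance with 95% credible bands.

    ``abundance`` is the DataFrame from
    :meth:`SCRMovementResults.abundance_summary`.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    t = abundance.index.to_numpy()
    for name, color in (("daily", "k"), ("cumulative", "gray")):
        ax.plot(t, abundance[f"{name}_median"], "o-", color=color, label=name)
        ax.fill_between(
            t,
            abundance[f"{name}_q2.5"],
            abundance[f"{name}_q97.5"],
            color=color,
            alpha=0.2,
        )
    if observed_counts is not None:
        ax.plot(t, np.asarray(observed_counts), "s", mfc="none", mec="C0",
                label="observed")
    ax.set_xlabel("occasion (day)")
    ax.set_ylabel("bears in survey region")
    ax.legend()
    return ax
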