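"""Optional matplotlib figures: box plots, fold-change heatmap, 4PL curve."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .stats import DoseResponseFit  # noqa: E402


def boxplot_by_condition(cells: pd.DataFrame, value: str, by: str = "dose_nM", ax=None):
    """Single-cell box plots of one feature grouped by a condition column."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    groups = sorted(cells[by].unique())
    data = [cells.loc[cells[by] == g, value].dropna() for g in groups]
    ax.boxplot(data, tick_labels=[str(g) for g in groups], showfliers=False)
    ax.set_xlabel(by)
    ax.set_ylabel(value)
    return ax


def fold_change_heatmap(summary: pd.DataFrame, value: str = "fold_median_total_lipid_integrated_intensity", ax=None):
    """Dose x time heatmap of fold change over time-matched vehicle."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    pivot = summary.pivot_table(index="dose_nM", columns="time_h", values=value)
    im = ax.imshow(pivot.to_numpy(), cmap="Reds", aspect="auto")
    ax.set_xticks(range(len(pivot.columns)), [f"{t:g} h" for t in pivot.columns])
    ax.set_yticks(range(len(pivot.index)), [f"{d:g} nM" for d in pivot.index])
    ax.figure.colorbar(im, ax=ax, label="fold change vs vehicle")
    return ax


def dose_response_plot(dose_nM, response, fit: DoseResponseFit, ax=None):
    """Scatter of per-condition responses with the fitted 4PL overlaid."""
    from .fourpl import true_response

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    dose = np.asarray(dose_nM, dtype=float)
    pos = dose[dose > 0]
    placeholder = pos.min() / 1000.0
    x = np.where(dose > 0, dose, placeholder)
    ax.semilogx(x, response, "o", color="k")
    if fit.converged and fit.params is not None:
        grid = np.logspace(np.log10(placeholder), np.log10(pos.max() * 2), 200)
        ax.semilogx(grid, true_response(grid, fit.params), "-", color="crimson",
                    label=f"{fit.c50_label} = {fit.c50:.3g} nM")
        ax.legend()
    ax.set_xlabel("dose (nM)")
    ax.set_ylabel("response")
    return ax
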