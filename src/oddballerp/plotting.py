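"""Plots over the model/results objects: ERP traces, group box plots, and
correlation heat maps.  Matplotlib is imported lazily so headless pipelines
never touch a display backend."""

from __future__ import annotations

import numpy as np

from .calibration import ALL_FEATURES
from .erp import ErpTrace, epoch_times


def _plt():
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt


def plot_erp_trace(trace: ErpTrace, ax=None):
    """Standard, target, and difference waveforms on the epoch axis."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    t = epoch_times()
    ax.plot(t, trace.standard_avg, label=f"standard (n={trace.n_standard_trials})")
    ax.plot(t, trace.target_avg, label=f"target (n={trace.n_target_trials})")
    ax.plot(t, trace.difference, label="difference", lw=2, color="k")
    ax.axvspan(300, 600, alpha=0.1, color="grey")
    ax.axhline(0, color="grey", lw=0.5)
    ax.set_xlabel("time from stimulus onset (ms)")
    ax.set_ylabel("amplitude (µV)")
    ax.legend(loc="upper left", fontsize=8)
    return ax


def plot_group_boxplots(table, features=ALL_FEATURES, ncols=5):
    """Per-feature CN-vs-MCI box plots of a cohort table."""
    plt = _plt()
    features = [f for f in features if f in table.columns]
    nrows = int(np.ceil(len(features) / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(3 * ncols, 2.5 * nrows),
                             squeeze=False)
    for ax, feat in zip(axes.ravel(), features):
        data = [table.loc[table["group"] == g, feat].dropna() for g in ("CN", "MCI")]
        ax.boxplot(data, tick_labels=["CN", "MCI"])
        ax.set_title(feat, fontsize=9)
    for ax in axes.ravel()[len(features):]:
        ax.set_visible(False)
    fig.tight_layout()
    return fig


def plot_correlation_matrix(rmat, pmat=None, alpha=0.05, ax=None):
    """Heat map of a correlation matrix; cells with p > alpha are blanked
    when a p-value matrix is supplied."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots(figsize=(0.5 * rmat.shape[1] + 2, 0.5 * rmat.shape[0] + 1))
    values = rmat.to_numpy(dtype=float).copy()
    if pmat is not None:
        values[pmat.to_numpy(dtype=float) > alpha] = np.nan
    im = ax.imshow(values, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(rmat.shape[1]), rmat.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(rmat.shape[0]), rmat.index, fontsize=7)
    ax.figure.colorbar(im, ax=ax, shrink=0.8)
    return ax
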