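"""Static matplotlib views of runs, scans and regime densities.

Presentation layer only: every figure is built from objects the library
already computed; nothing here feeds back into any analysis.
"""

from __future__ import annotations

import numpy as np
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .analysis import RegimeVarianceResult
from .scans import ScanResult
from .timeseries import TimeSeriesTable


def plot_run(table: TimeSeriesTable, path=None):
    """Stacked Active/Jailed/Quiet counts with the forcing levels."""
    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(9, 5),
                                   height_ratios=[2, 1])
    t = table.times
    for col, color in (("Active", "tab:red"), ("Jailed", "tab:gray"),
                       ("Quiet", "tab:blue")):
        ax1.plot(t, table.column(col), lw=0.7, color=color, label=col)
    ax1.set_ylabel("citizens")
    ax1.legend(loc="upper right", fontsize=8)
    ax2.plot(t, table.column("Legitimacy"), lw=0.8, label="Legitimacy")
    ax2.plot(t, table.column("Propaganda"), lw=0.8, label="Propaganda")
    ax2.set_xlabel("step")
    ax2.set_ylim(0, 1)
    ax2.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_scan(result: ScanResult, path=None):
    """Skill curves, one line per column of the scan grid."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for col in result.grid.columns:
        ax.plot(result.grid.index, result.grid[col], marker="o",
                label=f"{result.grid.columns.name}={col}")
    ax.set_xlabel(result.grid.index.name)
    ax.set_ylabel(r"Pearson $\rho$")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_regime_densities(result: RegimeVarianceResult, path=None):
    """Kernel density estimates of the coefficient-variance populations
    in the low- and high-legitimacy regimes."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for sample, kde, label in (
            (result.low_variances, result.low_density,
             f"legitimacy < {result.threshold}"),
            (result.high_variances, result.high_density,
             f"legitimacy > {result.threshold}")):
        if kde is None or sample.size == 0:
            continue
        grid = np.linspace(0, sample.max() * 1.1, 300)
        ax.plot(grid, kde(grid), label=label)
    ax.set_xlabel("dActive/dPropaganda rolling variance")
    ax.set_ylabel("density")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
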