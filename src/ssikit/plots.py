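"""Optional plotting helpers for the kinetics analyses (requires matplotlib)."""

from __future__ import annotations

import numpy as np

from .kinetics import DixonResult, IC50Fit, MMFit


def _axes(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_michaelis_menten(s, v, fit: MMFit, ax=None):
    """Observed rates and the fitted saturation curve."""
    ax = _axes(ax)
    s = np.asarray(s, dtype=float)
    ax.plot(s, v, "o", label="observed")
    grid = np.linspace(0, s.max() * 1.05, 200)
    ax.plot(grid, fit.vmax * grid / (fit.km + grid), "-",
            label=f"fit: Km={fit.km:.3g} µM, Vmax={fit.vmax:.3g} µM/min")
    ax.set_xlabel("[S] (µM)")
    ax.set_ylabel("v (µM/min)")
    ax.legend()
    return ax


def plot_dixon(result: DixonResult, i_max: float, ax=None):
    """Dixon lines (1/v vs [I]) extrapolated through their intersection."""
    ax = _axes(ax)
    left = result.intersection_i if result.intersection_i is not None else 0.0
    grid = np.linspace(min(left * 1.2, 0.0), i_max, 100)
    for line in result.lines:
        ax.plot(grid, line.slope * grid + line.intercept, label=f"S={line.substrate_conc:g} µM")
    if result.intersection_i is not None:
        ax.plot([result.intersection_i], [result.intersection_y], "k*", markersize=10)
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.axvline(0.0, color="grey", lw=0.5)
    ax.set_xlabel("[I] (µM)")
    ax.set_ylabel("1/v (min/µM)")
    ax.set_title(f"implied type: {result.implied_type}")
    ax.legend()
    return ax


def plot_ic50(concs, activities, fit: IC50Fit, ax=None):
    """Dose-response points and the fitted four-parameter logistic."""
    ax = _axes(ax)
    concs = np.asarray(concs, dtype=float)
    ax.semilogx(concs[concs > 0], np.asarray(activities)[concs > 0], "o", label="observed")
    grid = np.logspace(np.log10(concs[concs > 0].min()), np.log10(concs.max()), 200)
    curve = fit.bottom + (fit.top - fit.bottom) / (1 + (grid / fit.ic50) ** fit.hill)
    ax.semilogx(grid, curve, "-", label=f"fit: IC50={fit.ic50:.4g} µM")
    ax.axvline(fit.ic50, color="grey", lw=0.5, ls="--")
    ax.set_xlabel("[I] (µM)")
    ax.set_ylabel("residual activity (%)")
    ax.legend()
    return ax
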