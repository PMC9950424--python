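"""Diagnostic and presentation plots (matplotlib).

Mirrors the standard displays for this model family: velocity maps in
biomarker space, label-probability curves along a forecast, reliability
diagrams and decision curves.  All functions accept and return an Axes.
"""

from __future__ import annotations

import numpy as np

from .prediction import Forecast


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_forecast_probs(forecast: Forecast, ax=None):
    """Label-probability curves along the forecast grid."""
    ax = _ax(ax)
    for j, (name, color) in enumerate(zip(("CN", "MCI", "AD"), ("tab:green", "tab:orange", "tab:red"))):
        ax.plot(forecast.grid, forecast.mean_probs[:, j], label=name, color=color)
        lo = np.percentile(forecast.probs[:, :, j], 5, axis=0)
        hi = np.percentile(forecast.probs[:, :, j], 95, axis=0)
        ax.fill_between(forecast.grid, lo, hi, alpha=0.15, color=color)
    ax.set_xlabel("years from first visit")
    ax.set_ylabel("label probability")
    ax.set_ylim(0, 1)
    ax.legend()
    return ax


def plot_velocity_field(x0_mean: np.ndarray, vel_mean: np.ndarray, dims=(1, 0), years: float = 2.0, ax=None):
    """Per-subject velocity segments in a 2-D slice of biomarker space.

    x0_mean, vel_mean: (n, 5) posterior means of initial states and their
    velocities; dims selects the two plotted components (default abeta-tau).
    """
    ax = _ax(ax)
    i, j = dims
    ax.quiver(
        x0_mean[:, i], x0_mean[:, j],
        years * vel_mean[:, i], years * vel_mean[:, j],
        angles="xy", scale_units="xy", scale=1.0, width=0.003, alpha=0.7,
    )
    from .dynamics import CHANNELS

    ax.set_xlabel(f"{CHANNELS[i]} (latent)")
    ax.set_ylabel(f"{CHANNELS[j]} (latent)")
    return ax


def plot_reliability(table, ax=None, label=None):
    """One reliability diagram (confidence or classwise) with its CIs."""
    ax = _ax(ax)
    mid = (table["bin_low"] + table["bin_high"]) / 2
    ax.plot([0, 1], [0, 1], "k:", lw=1)
    ax.errorbar(
        mid, table["accuracy"],
        yerr=[table["accuracy"] - table["ci_low"], table["ci_high"] - table["accuracy"]],
        marker="o", linestyle="-", capsize=3, label=label,
    )
    ax.set_xlabel("predicted probability")
    ax.set_ylabel("observed accuracy")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    return ax


def plot_decision_curves(nb_table, ax=None):
    """Net-benefit curves for the model, treat-all and treat-none."""
    ax = _ax(ax)
    ax.plot(nb_table["threshold"], nb_table["nb_model"], label="model")
    ax.plot(nb_table["threshold"], nb_table["nb_treat_all"], "--", label="treat all")
    ax.plot(nb_table["threshold"], nb_table["nb_treat_none"], ":", label="treat none")
    ax.set_xlabel("threshold probability")
    ax.set_ylabel("net benefit")
    ax.set_ylim(bottom=-0.05)
    ax.legend()
    return ax
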