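"""Minimal figures: fitted curves with data, and cline scatterplots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .tpc_model import PosteriorDraws, performance_curve_array

_COLORS = {"native": "tab:blue", "invasive": "tab:red"}


def plot_tpcs(draws: PosteriorDraws, scaled=None, path=None):
    """Posterior-mean curves per population, optionally with genotype means."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    mean_params = draws.params.mean(axis=0)
    lo = mean_params[:, 0].min()
    hi = mean_params[:, 1].max()
    x = np.linspace(lo, hi, 400)
    for k, pop in enumerate(draws.populations):
        p = mean_params[k]
        y = performance_curve_array(x, p[0], p[1], p[2], p[3], p[4])
        ax.plot(x, y, color=_COLORS[draws.range_labels[k]], alpha=0.6, lw=1)
    if scaled is not None:
        df = scaled.df
        ax.scatter(
            df["centered_temp"] + scaled.temp_center,
            df["scaled_rgr"] * scaled.grand_mean_rgr,
            s=6,
            c=[_COLORS[l] for l in df["range_label"]],
            alpha=0.4,
        )
    ax.set_xlabel("daytime temperature (\N{DEGREE SIGN}C)")
    ax.set_ylabel("RGR (per day)")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_cline(derived_means, climate, response, predictor, path=None):
    df = derived_means.merge(climate[["population_id", predictor]], on="population_id")
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, grp in df.groupby("range_label"):
        ax.scatter(grp[predictor], grp[response], c=_COLORS[label], label=label)
    ax.set_xlabel(predictor)
    ax.set_ylabel(response)
    ax.legend()
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
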