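"""Matplotlib renderings of the evaluation diagnostics."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .evaluate import ParityResult, RadiusHistograms

__all__ = ["plot_learning_curve", "plot_parity", "plot_radius_histograms"]


def plot_learning_curve(curve: pd.DataFrame, path: str | Path) -> None:
    """Mean out-of-sample MSE vs in-sample size, one-sd error bars."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(
        curve["n_samples"], curve["mean_mse"], yerr=curve["sd_mse"],
        marker="o", capsize=3,
    )
    ax.set_xlabel("in-sample spectra")
    ax.set_ylabel("mean squared error")
    ax.set_xscale("log")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_parity(parity: ParityResult, path: str | Path) -> None:
    """Peak-energy and peak-intensity parity scatter with R^2 annotations."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for ax, (a, b), name, r2 in (
        (axes[0], ("e_target", "e_est"), "peak energy (eV)", parity.r2_energy),
        (axes[1], ("i_target", "i_est"), "peak intensity", parity.r2_intensity),
    ):
        ax.scatter(parity.pairs[a], parity.pairs[b], s=8, alpha=0.5)
        lims = [
            min(parity.pairs[a].min(), parity.pairs[b].min()),
            max(parity.pairs[a].max(), parity.pairs[b].max()),
        ] if len(parity.pairs) else [0, 1]
        ax.plot(lims, lims, "k--", lw=0.8)
        ax.set_xlabel(f"target {name}")
        ax.set_ylabel(f"estimated {name}")
        if r2 is not None:
            ax.set_title(f"$R^2$ = {r2:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_radius_histograms(hists: RadiusHistograms, path: str | Path) -> None:
    """Encoded-radius and required-dimension histograms side by side."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    axes[0].stairs(hists.radius_density, hists.radius_edges, fill=True)
    axes[0].set_xlabel("max encoded radius (A)")
    axes[0].set_ylabel("density")
    axes[0].set_title(f"mode = {hists.radius_mode:.2f} A")
    axes[1].stairs(hists.dimension_density, hists.dimension_edges, fill=True)
    axes[1].set_xlabel("required CM dimension N")
    axes[1].set_title(f"mode = {hists.dimension_mode:.0f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
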