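"""Figures and run manifests for simulation results.

The headline figure is a small-multiples panel of empirical Type I error
against the ICC, faceted by cluster count K (rows) and cluster size N
(columns), one line per inference method, with the nominal alpha reference
and its binomial Monte Carlo noise band.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

__all__ = ["plot_tie_panels", "save_tie_panels", "write_manifest", "read_manifest"]

_METHOD_STYLE = {
    "wald_between_within": ("tab:blue", "between-within"),
    "wald_satterthwaite": ("tab:green", "Satterthwaite"),
    "wald_residual": ("tab:orange", "residual"),
    "wald_z": ("tab:red", "t as z"),
    "lrt": ("tab:purple", "LRT"),
    "cluster_means_ttest": ("tab:gray", "cluster-means t"),
}


def plot_tie_panels(results: pd.DataFrame, alpha: float = 0.05):
    """Small multiples of TIE vs ICC, faceted by K (rows) and N (columns).

    ``results`` follows the results-CSV schema (columns K, N, icc, method,
    tie, replicates).  Methods absent from the data are simply not drawn.
    Returns the matplotlib Figure.
    """
    K_levels = sorted(results["K"].unique())
    N_levels = sorted(results["N"].unique())
    reps = int(results["replicates"].max())
    band = 1.96 * np.sqrt(alpha * (1 - alpha) / reps) if reps > 0 else 0.0

    fig, axes = plt.subplots(
        len(K_levels),
        len(N_levels),
        figsize=(3.0 * len(N_levels), 2.4 * len(K_levels)),
        sharex=True,
        sharey=True,
        squeeze=False,
    )
    for i, K in enumerate(K_levels):
        for j, N in enumerate(N_levels):
            ax = axes[i][j]
            sub = results[(results["K"] == K) & (results["N"] == N)]
            ax.axhspan(alpha - band, alpha + band, color="0.9", zorder=0)
            ax.axhline(alpha, color="0.4", lw=0.8, ls="--", zorder=1)
            for method, g in sub.groupby("method"):
                color, label = _METHOD_STYLE.get(method, ("black", method))
                g = g.sort_values("icc")
                marker = "o" if len(g) == 1 else None
                ax.plot(g["icc"], g["tie"], color=color, label=label,
                        marker=marker or ".", ms=3, lw=1.2)
            ax.set_xscale("log")
            if i == 0:
                ax.set_title(f"N = {N}", fontsize=10)
            if j == 0:
                ax.set_ylabel(f"K = {K}\nType I error", fontsize=9)
            if i == len(K_levels) - 1:
                ax.set_xlabel("ICC", fontsize=9)
            lo = min(results["tie"].min(), alpha)
            hi = max(results["tie"].max(), alpha)
            pad = 0.1 * max(hi - lo, 0.01)
            ax.set_ylim(max(0.0, lo - pad), hi + pad)
    handles, labels = axes[0][0].get_legend_handles_labels()
    if handles:
        fig.legend(handles, labels, loc="lower center", ncol=min(6, len(labels)),
                   frameon=False, fontsize=8)
    fig.tight_layout(rect=(0, 0.06, 1, 1))
    return fig


def save_tie_panels(results: pd.DataFrame, out_dir, alpha: float = 0.05,
                    stem: str = "tie_panels") -> list[Path]:
    """Render the TIE panel figure to vector (PDF) and raster (PNG) files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fig = plot_tie_panels(results, alpha=alpha)
    paths = []
    for ext in ("pdf", "png"):
        path = out_dir / f"{stem}.{ext}"
        fig.savefig(path, dpi=150)
        paths.append(path)
    plt.close(fig)
    return paths


def write_manifest(path, grid, methods: tuple[str, ...]) -> None:
    """Write a machine-readable run manifest sufficient to reproduce a run.

    The manifest doubles as a config file: feeding it back to the simulate
    command reproduces the results CSV byte for byte.
    """
    import crtlmm

    manifest = {
        "grid": {
            "K_values": list(grid.K_values),
            "N_values": list(grid.N_values),
            "sigma_b2_values": list(grid.sigma_b2_values),
            "sigma2": grid.sigma2,
            "replicates": grid.replicates,
            "alpha": grid.alpha,
            "master_seed": grid.master_seed,
        },
        "methods": list(methods),
        "versions": {
            "crtlmm": crtlmm.__version__,
            "numpy": np.__version__,
            "python": platform.python_version(),
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def read_manifest(path) -> dict:
    with open(path) as fh:
        if str(path).endswith(".json"):
            return json.load(fh)
        return yaml.safe_load(fh)
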