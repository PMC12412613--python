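"""Vector-graphics result plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_mode_spectrum(spectra: pd.DataFrame, path: Path | str) -> Path:
    """Log-log per-mode fluctuation spectrum with the 1/(k^2-1) guide line."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(4, 3))
    for cid, group in spectra.groupby("cluster_id"):
        ks = group["k"].to_numpy(dtype=float)
        ax.loglog(ks**2 - 1.0, group["mean_sq_amplitude"], "o-", label=f"cluster {cid}")
    ks = np.asarray(sorted(spectra["k"].unique()), dtype=float)
    ref = spectra["mean_sq_amplitude"].iloc[0] * (ks[0] ** 2 - 1.0) / (ks**2 - 1.0)
    ax.loglog(ks**2 - 1.0, ref, "k--", lw=0.8, label=r"$\propto 1/(k^2-1)$")
    ax.set_xlabel(r"$k^2 - 1$")
    ax.set_ylabel(r"$\langle a_k^2 + b_k^2 \rangle$")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


def plot_angle_density(centers: np.ndarray, density: np.ndarray, path: Path | str) -> Path:
    """False-color interaction-angle probability map, scaled 0..1."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(3.5, 3))
    half = centers[-1] + (centers[1] - centers[0]) / 2.0
    im = ax.imshow(
        density.T, origin="lower", extent=(-half, half, -half, half),
        vmin=0.0, vmax=1.0, cmap="viridis",
    )
    ax.set_xlabel(r"$\alpha$ (deg)")
    ax.set_ylabel(r"$\beta$ (deg)")
    fig.colorbar(im, ax=ax, label="probability")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path
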