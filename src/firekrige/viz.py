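"""Simple diagnostic figures: kriged maps and empirical semivariograms."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .kriging import SpatialObservations

__all__ = ["plot_surface", "empirical_semivariogram", "plot_semivariogram"]


def plot_surface(surface: pd.DataFrame, path, value: str = "pred_mean",
                 title: str | None = None) -> None:
    """Render a regular kriged surface (x_m, y_m, value columns) as a map."""
    grid = surface.pivot(index="y_m", columns="x_m", values=value)
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.pcolormesh(grid.columns, grid.index, grid.to_numpy(), shading="nearest")
    fig.colorbar(im, ax=ax, label=value)
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    ax.set_aspect("equal")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def empirical_semivariogram(
    obs: SpatialObservations, n_bins: int = 12, max_lag: float | None = None
) -> pd.DataFrame:
    """Binned classical (Matheron) semivariance estimate: per lag bin, half
    the mean squared difference of detrended responses over point pairs."""
    d = pdist(obs.coords)
    resid = obs.y - obs.X @ np.linalg.lstsq(obs.X, obs.y, rcond=None)[0]
    i, j = np.triu_indices(obs.n, k=1)
    sq = 0.5 * (resid[i] - resid[j]) ** 2
    if max_lag is None:
        max_lag = float(d.max()) / 2
    edges = np.linspace(0, max_lag, n_bins + 1)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (d > lo) & (d <= hi)
        if sel.sum() == 0:
            continue
        rows.append(
            {"lag_m": float(d[sel].mean()), "semivariance": float(sq[sel].mean()),
             "n_pairs": int(sel.sum())}
        )
    return pd.DataFrame(rows)


def plot_semivariogram(obs: SpatialObservations, path, **kwargs) -> None:
    """Plot the binned empirical semivariogram of (detrended) observations."""
    sv = empirical_semivariogram(obs, **kwargs)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(sv["lag_m"], sv["semivariance"], "o-")
    ax.set_xlabel("lag h (m)")
    ax.set_ylabel("semivariance")
    ax.set_ylim(bottom=0)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
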