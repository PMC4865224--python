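"""Report figures: time-resolved importance curves and group quantile bands."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .features import ma_window_centre
from .kinetics import SimulationProfile

__all__ = ["plot_time_significance", "plot_group_bands"]


def plot_time_significance(time_sig: pd.DataFrame, path: str | Path) -> None:
    """Per-species MDGini versus moving-average window centre time."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    centres = [ma_window_centre(k) for k in range(time_sig.shape[1])]
    for species, row in time_sig.iterrows():
        ax.plot(centres, row.values, marker="o", ms=3, label=species)
    ax.set_xlabel("window centre time (s)")
    ax.set_ylabel("MDGini (run-averaged)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_group_bands(
    profiles: Sequence[SimulationProfile],
    labels: np.ndarray,
    species: str,
    path: str | Path,
    quantiles: tuple[float, float] = (0.05, 0.95),
) -> None:
    """Group means with 5%/95% quantile bands for one species' trajectories."""
    times = profiles[0].times
    stack = np.vstack([p.trajectory(species) for p in profiles])
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for group in pd.unique(labels):
        sub = stack[np.asarray(labels) == group]
        lo, hi = np.quantile(sub, quantiles, axis=0)
        ax.plot(times, sub.mean(axis=0), label=f"{group} mean")
        ax.fill_between(times, lo, hi, alpha=0.25)
    ax.set_xlabel("time (s)")
    ax.set_ylabel(f"[{species}] (M)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
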