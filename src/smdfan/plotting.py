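"""Matplotlib plots for pulling-campaign analysis.

Solid lines are replica means; shaded bands are +-1 SD.  Smoothing, when
requested, is applied at plot time only — rupture forces are always computed
on the unsmoothed series unless the caller opts in explicitly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .forceanalysis import ReplicaEnsemble, running_mean


def plot_force_time(ensemble: ReplicaEnsemble, path: str | Path,
                    smooth_window: int = 51) -> None:
    t = ensemble.common_time
    mean = running_mean(ensemble.mean_force, smooth_window)
    sd = running_mean(ensemble.sd_force, smooth_window)
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.fill_between(t, mean - sd, mean + sd, alpha=0.3, color="lightblue",
                    label="+-1 SD")
    ax.plot(t, mean, lw=1.2, label="mean")
    ax.set_xlabel("time (ps)")
    ax.set_ylabel("pulling force (pN)")
    ax.set_title(ensemble.label or "force vs time")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_force_distance(pairs: np.ndarray, path: str | Path,
                        label: str = "") -> None:
    """pairs: (n, 2) array of (COM distance A, force pN), time-ordered."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(pairs[:, 0], pairs[:, 1], lw=1.0)
    ax.set_xlabel("COM distance (A)")
    ax.set_ylabel("pulling force (pN)")
    ax.set_title(label or "force vs COM distance")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_hbond_series(counts: Sequence[np.ndarray], path: str | Path,
                      labels: Sequence[str] | None = None,
                      smooth_window: int = 0) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.2))
    for k, series in enumerate(counts):
        y = running_mean(np.asarray(series, dtype=float), smooth_window)
        lbl = labels[k] if labels else None
        ax.plot(np.arange(len(y)), y, lw=1.0, label=lbl)
    ax.set_xlabel("frame")
    ax.set_ylabel("hydrogen bonds")
    if labels:
        ax.legend(frameon=False, fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_anisotropy(table: pd.DataFrame, path: str | Path) -> None:
    """Bar chart of mean rupture force +- SD across pulling directions."""
    fig, ax = plt.subplots(figsize=(6, 3.4))
    x = np.arange(len(table))
    ax.bar(x, table["mean_f_max_pN"], yerr=table["sd_f_max_pN"],
           capsize=3, color="steelblue")
    ax.set_xticks(x)
    ax.set_xticklabels(table["label"], rotation=60, ha="right", fontsize=7)
    ax.set_ylabel("max rupture force (pN)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
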