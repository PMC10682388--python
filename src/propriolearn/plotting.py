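"""Minimal plotting helpers for cohort reports (styling is not the point)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .trajectory_similarity import Trajectory

__all__ = ["plot_reproductions", "plot_metric_scatter"]


def plot_reproductions(
    target: Trajectory,
    pre: list[Trajectory],
    post: list[Trajectory],
    path: str,
) -> None:
    """Pre/post reproduction overlays against the target trajectory."""
    fig, axes = plt.subplots(1, 2, figsize=(10, 3.5), sharey=True)
    for ax, reps, title in ((axes[0], pre, "pre-learning"), (axes[1], post, "post-learning")):
        stack = np.vstack([r.samples for r in reps])
        mean = stack.mean(axis=0)
        ax.plot(target.times, target.samples, "g--", lw=1.2, label="target")
        ax.plot(target.times, mean, "k-", lw=1.0, label="mean reproduction")
        ax.fill_between(
            target.times,
            mean - 1.96 * stack.std(axis=0),
            mean + 1.96 * stack.std(axis=0),
            color="0.8",
        )
        ax.set_title(title)
        ax.set_xlabel("time (s)")
    axes[0].set_ylabel("elbow angle (deg)")
    axes[0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_metric_scatter(
    x: np.ndarray, y: np.ndarray, xlabel: str, ylabel: str, path: str
) -> None:
    """Scatter of two per-participant metrics with a least-squares line."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(x, y, s=12, alpha=0.6, edgecolor="none")
    slope, intercept = np.polyfit(x, y, 1)
    grid = np.linspace(x.min(), x.max(), 50)
    ax.plot(grid, slope * grid + intercept, "r-", lw=1)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
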