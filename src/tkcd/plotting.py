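"""Trajectory summary figures.

The panel layout mirrors the standard presentation of these scenarios:
surviving cells (percent of baseline) on top, body burden in the middle,
and the emergent elimination rate with the class-fraction mix below.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers save to file
import matplotlib.pyplot as plt

from .simulate import Trajectory

__all__ = ["plot_trajectory"]


def plot_trajectory(traj: Trajectory, path: str | Path | None = None):
    """Plot cells, body burden and elimination rate against time."""
    fig, axes = plt.subplots(3, 1, figsize=(7, 9), sharex=True)
    t = traj.times
    baseline = traj.params.baseline_cells

    axes[0].plot(t, 100.0 * traj.total / baseline, color="tab:green")
    axes[0].set_ylabel("cells (% of baseline)")
    axes[0].set_ylim(0, 105)

    axes[1].plot(t, traj.c_int, color="tab:red")
    axes[1].set_ylabel("body burden $C_{int}$")

    k = traj.elimination_rate_series()
    axes[2].plot(t, k, color="tab:blue", label="elimination rate $k$")
    q = traj.N / traj.total[:, None]
    for i in range(traj.params.l):
        axes[2].plot(t, q[:, i], alpha=0.4, label=f"$q_{{{i + 1}}}$")
    axes[2].set_ylabel("rate / class fraction")
    axes[2].set_xlabel("time (model units)")
    axes[2].legend(ncol=3, fontsize=8)

    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
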