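"""Matplotlib figure helpers for trajectories, control signals, and the
sensitivity tornado chart."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

from .model import STATE_NAMES
from .sensitivity import SensitivityResult, rank_parameters


def _save_or_return(fig, path):
    if path is not None:
        fig.savefig(Path(path), dpi=150, bbox_inches="tight")
        import matplotlib.pyplot as plt

        plt.close(fig)
        return None
    return fig


def plot_trajectory(traj, path: str | Path | None = None, logy: bool = True):
    """Per-compartment time-series panels (3 x 4 grid)."""
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(3, 4, figsize=(14, 8), sharex=True)
    for ax, name in zip(axes.flat, STATE_NAMES):
        y = traj.component(name)
        ax.plot(traj.times, y, lw=1.2)
        ax.set_title(name)
        if logy and np.any(y > 0):
            ax.set_yscale("symlog", linthresh=max(y.max() * 1e-12, 1e-12))
        ax.grid(alpha=0.3)
    for ax in axes[-1]:
        ax.set_xlabel("time (days)")
    axes.flat[-1].axis("off")
    fig.tight_layout()
    return _save_or_return(fig, path)


def plot_controls(solution, path: str | Path | None = None):
    """Optimal control signals versus time."""
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 1, figsize=(8, 6), sharex=True)
    axes[0].plot(solution.times, solution.controls.uE, lw=1.5, color="tab:blue")
    axes[0].set_ylabel("uE (immunotherapy)")
    axes[1].plot(solution.times, solution.controls.uM, lw=1.5, color="tab:red")
    axes[1].set_ylabel("uM (chemotherapy)")
    axes[1].set_xlabel("time (days)")
    for ax in axes:
        ax.set_ylim(-0.05, 1.05)
        ax.grid(alpha=0.3)
    w = solution.weights
    fig.suptitle(f"A={w.A:g}, B={w.B:g}, C={w.C:g}, tf={w.tf:g}")
    fig.tight_layout()
    return _save_or_return(fig, path)


def plot_sensitivity(
    results: Sequence[SensitivityResult], path: str | Path | None = None, top: int | None = None
):
    """Tornado-style bar chart: percent tumor change per parameter for the
    decreased (-) and increased (+) perturbations."""
    import matplotlib.pyplot as plt

    order = rank_parameters(results)
    if top is not None:
        order = order[:top]
    down = {r.parameter: r.percent_change for r in results if r.factor < 1.0}
    up = {r.parameter: r.percent_change for r in results if r.factor > 1.0}
    ypos = np.arange(len(order))[::-1]
    fig, ax = plt.subplots(figsize=(8, max(4, 0.3 * len(order))))
    ax.barh(ypos + 0.2, [down.get(n, 0.0) for n in order], height=0.38,
            color="tab:red", label="-20%")
    ax.barh(ypos - 0.2, [up.get(n, 0.0) for n in order], height=0.38,
            color="tab:blue", label="+20%")
    ax.set_yticks(ypos, order)
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("tumor change at readout (%)")
    ax.legend()
    ax.grid(alpha=0.3, axis="x")
    fig.tight_layout()
    return _save_or_return(fig, path)
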