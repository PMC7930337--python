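"""Offline figures: kymographs, posture snapshots, fitness histories."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .analysis import Kymograph
from .simulation import SimulationTrace


def plot_kymograph(kym: Kymograph, path: str | Path | None = None, ax=None):
    """Dorsoventral bending over body coordinate (vertical) and time.

    Red = dorsal, blue = ventral curvature (diverging map); a traveling
    wave appears as diagonal bands.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    vmax = np.percentile(np.abs(kym.curvature), 99) or 1.0
    ax.pcolormesh(kym.times, kym.body_coord, kym.curvature,
                  cmap="RdBu_r", vmin=-vmax, vmax=vmax, shading="auto")
    ax.invert_yaxis()
    ax.set_xlabel("time (s)")
    ax.set_ylabel("body coordinate (head → tail)")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_postures(trace: SimulationTrace, n_frames: int = 6,
                  path: str | Path | None = None, ax=None):
    """Midline snapshots at evenly spaced times, labeled in seconds."""
    if trace.midline is None:
        raise ValueError("trace has no midline recording")
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    idx = np.linspace(0, len(trace.times) - 1, n_frames).astype(int)
    for i in idx:
        mid = trace.midline[i] * 1e3  # mm
        ax.plot(mid[:, 0], mid[:, 1], label=f"t = {trace.times[i]:.1f} s")
        ax.plot(mid[0, 0], mid[0, 1], "ko", ms=3)  # head marker
    ax.set_aspect("equal")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.legend(fontsize=7)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_fitness_history(history, path: str | Path | None = None, ax=None):
    """Best and mean fitness per generation of one evolutionary run."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    ax.plot(history["generation"], history["best"], label="best")
    ax.plot(history["generation"], history["mean"], label="mean")
    ax.set_xlabel("generation")
    ax.set_ylabel("fitness")
    ax.set_ylim(0, 1.05)
    ax.legend()
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
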