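"""Figure rendering: kymographs, eccentric-circle polar maps, paths."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .polarity import PolarMap

__all__ = ["plot_kymograph", "plot_polar_map", "plot_movement_path"]


def plot_kymograph(kymo: np.ndarray, frame_interval: float,
                   path: str | Path) -> Path:
    """Time (vertical) x axis-bin (horizontal) heat map; leading edge left."""
    fig, ax = plt.subplots(figsize=(4, 5))
    im = ax.imshow(kymo, aspect="auto", origin="upper", cmap="jet",
                   extent=(0.5, kymo.shape[1] + 0.5,
                           kymo.shape[0] * frame_interval, 0.0))
    ax.set_xlabel("axis bin (1 = leading edge)")
    ax.set_ylabel("time (s)")
    fig.colorbar(im, ax=ax, label="FRET ratio")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_polar_map(pmap: PolarMap, path: str | Path) -> Path:
    """Eccentric-circle plot: first frame at the centre, last at the edge."""
    T, nb = pmap.matrix.shape
    theta = np.linspace(0, 2 * np.pi, nb + 1)
    radius = np.arange(T + 1)
    fig = plt.figure(figsize=(4.5, 4.5))
    ax = fig.add_subplot(projection="polar")
    ax.pcolormesh(theta, radius, pmap.matrix, cmap="jet", shading="flat")
    ax.set_yticklabels([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_movement_path(path_um: np.ndarray, out: str | Path) -> Path:
    """Origin-anchored centroid path."""
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(path_um[:, 0], path_um[:, 1], "-", lw=1.2)
    ax.plot(0, 0, "ko", ms=4)
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return Path(out)
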