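"""Figures: cross-sectional EIT images and per-technique CoM panels."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

ORGAN_COLORS = {"laryngeal": "tab:green", "pulmonary": "tab:blue",
                "cardiac": "tab:red"}


def plot_eit_image(image, nerve_radius: float, path: str | Path,
                   com=None) -> Path:
    """Render a Z-scored cross-sectional image as a voxel map (PNG)."""
    fig, ax = plt.subplots(figsize=(4.2, 4))
    g = np.asarray(image.grid) * 1e6
    vmax = np.abs(image.z).max() or 1.0
    sc = ax.scatter(g[:, 0], g[:, 1], c=image.z, s=38, marker="s",
                    cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    th = np.linspace(0, 2 * np.pi, 200)
    R = nerve_radius * 1e6
    ax.plot(R * np.cos(th), R * np.sin(th), "k-", lw=1)
    if com is not None:
        ax.plot(com.x_um, com.y_um, "k*", ms=14, mew=1.2)
    ax.set_aspect("equal")
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    ax.set_title(f"{image.branch} (|Z| peak {vmax:.2f})")
    fig.colorbar(sc, ax=ax, shrink=0.8, label="Z")
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_com_panels(com_table, nerve_radius_um: float,
                    path: str | Path) -> Path:
    """Clustered CoM scatter per technique over the circular cross-section."""
    techniques = sorted(com_table.technique.unique())
    fig, axes = plt.subplots(1, len(techniques),
                             figsize=(3.4 * len(techniques), 3.6))
    axes = np.atleast_1d(axes)
    th = np.linspace(0, 2 * np.pi, 200)
    R = nerve_radius_um
    for ax, tech in zip(axes, techniques):
        sub = com_table[com_table.technique == tech]
        ax.plot(R * np.cos(th), R * np.sin(th), "k-", lw=1)
        for organ, color in ORGAN_COLORS.items():
            pts = sub[sub.organ == organ]
            ax.scatter(pts.x_um, pts.y_um, c=color, s=30, label=organ)
        ax.plot(0, R, marker=(2, 0, 0), ms=12, c="k")   # cuff opening tick
        ax.set_aspect("equal")
        ax.set_xlim(-1.15 * R, 1.15 * R)
        ax.set_ylim(-1.15 * R, 1.15 * R)
        ax.set_title(tech)
        ax.set_xticks([])
        ax.set_yticks([])
    axes[0].legend(fontsize=7, loc="lower left")
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
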