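"""Presentation-only rendering: LDM heatmaps, allelic profiles, rank curves.

Heatmaps use a fixed 0 -> 1 ND colour scale running deep red (zero
distance) through yellow and green to deep blue (one nuclear diameter).
Nothing here feeds back into any computed statistic.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .analysis import DistanceMap, RankScoreCurve

__all__ = ["plot_ldm", "plot_allelic_profile", "plot_rank_curves"]

_LDM_CMAP = "RdYlBu"  # red (0, close) -> yellow/green -> blue (1 ND apart)


def plot_ldm(dm: DistanceMap, path: str | Path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(5, 4.2))
    im = ax.imshow(dm.values, cmap=_LDM_CMAP, vmin=0.0, vmax=1.0, origin="lower")
    ax.set_xlabel("locus index")
    ax.set_ylabel("locus index")
    ax.set_title(title or f"{dm.kind} LDM")
    fig.colorbar(im, ax=ax, label="mean distance (ND)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_allelic_profile(
    profile: np.ndarray,
    sd: np.ndarray,
    path: str | Path,
    baseline: np.ndarray | None = None,
    title: str = "",
) -> None:
    x = np.arange(profile.size)
    fig, ax = plt.subplots(figsize=(5.5, 3.2))
    ax.fill_between(x, profile - sd, profile + sd, color="black", alpha=0.6, lw=0)
    if baseline is not None:
        ax.plot(x, baseline, color="white", lw=1.5, path_effects=None)
    ax.plot(x, profile, color="gold", lw=1.5)
    ax.set_ylim(0, 1)
    ax.set_xlabel("allelic locus (telomere to telomere)")
    ax.set_ylabel("mean distance (ND)")
    if title:
        ax.set_title(title)
    ax.set_facecolor("#555555")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_rank_curves(
    curves: dict[str, RankScoreCurve], path: str | Path, title: str = ""
) -> None:
    fig, ax = plt.subplots(figsize=(5.5, 3.2))
    for label, curve in curves.items():
        ax.plot(np.arange(curve.binned_means.size), curve.binned_means, label=label)
    ax.set_ylim(0, 1)
    ax.set_xlabel("rank bin")
    ax.set_ylabel("mean distance (ND)")
    ax.legend(fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
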