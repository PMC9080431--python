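"""Optional figure outputs. All plots are side artifacts, never required."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .io import AnnotationSeries, ArenaGeometry, DetectionSeries
from .metrics import Trajectory


def plot_validation_series(detections: DetectionSeries,
                           annotations: AnnotationSeries,
                           tau: float, path: str | Path) -> Path:
    """Manual presence bars with the detector probability overlaid."""
    fig, ax = plt.subplots(figsize=(10, 2.8))
    t = np.arange(len(annotations))
    ax.fill_between(t, 0, annotations.values, step="mid",
                    alpha=0.25, color="C0", label="manual presence")
    n = min(len(detections), len(annotations))
    ax.plot(detections.frame_indices[:n], detections.probabilities[:n],
            ".", ms=2, color="C1", label="detector probability")
    ax.axhline(tau, color="k", lw=0.8, ls="--", label=f"threshold {tau}")
    ax.set_xlabel("frame (s)")
    ax.set_ylabel("presence / probability")
    ax.set_ylim(-0.05, 1.05)
    ax.legend(loc="upper right", fontsize=7)
    ax.set_title(detections.video_id)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_error_vectors(errors: pd.DataFrame, arena: ArenaGeometry,
                       path: str | Path) -> Path:
    """Manual→predicted centroid segments over the arena rectangle."""
    fig, ax = plt.subplots(figsize=(8, 5))
    for _, row in errors.iterrows():
        ax.plot([row["manual_x"], row["pred_x"]],
                [row["manual_y"], row["pred_y"]],
                "-", color="C3", lw=0.6, alpha=0.6)
    ax.plot(errors["manual_x"], errors["manual_y"], ".", ms=2, color="C0")
    ax.set_xlim(0, arena.width)
    ax.set_ylim(arena.height, 0)  # image convention, y down
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    ax.set_title("positioning error vectors (manual → predicted)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_trajectory(traj: Trajectory, arena: ArenaGeometry,
                    path: str | Path,
                    object_centroid: tuple[float, float] | None = None) -> Path:
    """2-D trajectory within the arena, segments drawn separately."""
    fig, ax = plt.subplots(figsize=(8, 5))
    for start, stop in traj.segments:
        ax.plot(traj.x[start:stop], traj.y[start:stop], "-", lw=0.7, alpha=0.8)
    if object_centroid is not None:
        ax.plot(*object_centroid, "k*", ms=12, label="novel object")
        ax.legend(fontsize=7)
    ax.set_xlim(0, arena.width)
    ax.set_ylim(arena.height, 0)
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    ax.set_title(f"trajectory {traj.video_id}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
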