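"""Trajectories and behavioural metrics for activity and exploration tests.

A trajectory is built by thresholding the detector's per-frame score:
a frame is "present" (fish outside the shelter, hence visible) when the
score is at or above the threshold, and its position is the centroid of that
frame's bounding box. Contiguous present frames form segments; metrics never
bridge an absence gap.

Activity (open-field) metrics:
  (i)   time outside the shelter — present frames × frame interval;
  (ii)  time swimming — present-to-present frame pairs whose speed is at or
        above a configurable threshold (default 5 px/s);
  (iii) mean turning angle — mean absolute angle between successive
        displacement vectors, in degrees;
  (iv)  area covered — fraction of arena grid cells (default 32 px) visited.

Exploration (novel-object) metrics:
  (i)   time outside the shelter;
  (ii)  minimum distance of approach to the object centroid;
  (iii) time within a radius (default 100 px) of the object centroid.

Metrics that need data the trajectory lacks (e.g. a turning angle with no
valid triplet of moves) are explicitly ``None``, never silently 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .io import (
    ArenaGeometry,
    DetectionSeries,
    ValidationError,
    bbox_centroid,
)
from .simulate import GroundTruthPath, _runs


@dataclass(frozen=True)
class ActivityConfig:
    speed_threshold: float = 5.0      # px/s separating swimming from stationary
    grid_cell: float = 32.0           # px, cell size for area coverage
    arena: ArenaGeometry = field(default_factory=ArenaGeometry)

    def __post_init__(self) -> None:
        if self.speed_threshold < 0:
            raise ValidationError("speed_threshold must be non-negative")
        if not (0 < self.grid_cell <= min(self.arena.width, self.arena.height)):
            raise ValidationError("grid_cell must fit at least one cell per axis")


@dataclass(frozen=True)
class ExplorationConfig:
    object_centroid: tuple[float, float]
    near_radius: float = 100.0        # px

    def __post_init__(self) -> None:
        if self.near_radius <= 0:
            raise ValidationError("near_radius must be positive")


@dataclass
class Trajectory:
    """Time-ordered centroids with a presence mask.

    ``x``/``y`` are NaN exactly where ``present`` is False. ``segments`` are
    the maximal runs of present frames as half-open [start, stop) ranges.
    """

    video_id: str
    x: np.ndarray
    y: np.ndarray
    present: np.ndarray
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        self.present = np.asarray(self.present, dtype=bool)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.x) == len(self.y) == len(self.present)):
            raise ValidationError("trajectory arrays differ in length")
        if np.isnan(self.x[self.present]).any() or np.isnan(self.y[self.present]).any():
            raise ValidationError("present frames must carry positions")

    def __len__(self) -> int:
        return len(self.present)

    @property
    def segments(self) -> list[tuple[int, int]]:
        return _runs(self.present)

    @property
    def n_present(self) -> int:
        return int(self.present.sum())


def build_trajectory(detections: DetectionSeries, tau: float) -> Trajectory:
    """Threshold a detection series into a trajectory.

    A frame is present iff its probability >= tau (boundary inclusive); its
    position is the bounding-box centroid. Frames without a box are absent
    regardless of score.
    """
    if not (0 < tau < 1):
        raise ValidationError(f"threshold {tau} outside (0, 1)")
    n = len(detections)
    x = np.full(n, np.nan)
    y = np.full(n, np.nan)
    present = np.zeros(n, dtype=bool)
    for i, rec in enumerate(detections):
        if rec.probability >= tau and rec.box is not None:
            cx, cy = bbox_centroid(rec.box)
            x[i], y[i] = cx, cy
            present[i] = True
    return Trajectory(detections.video_id, x, y, present,
                      detections.frame_interval)


def trajectory_from_truth(truth: GroundTruthPath) -> Trajectory:
    """Ground-truth path as a trajectory (the simulator oracle)."""
    return Trajectory(truth.video_id, truth.x.copy(), truth.y.copy(),
                      truth.visible.copy(), truth.frame_interval)


# ---------------------------------------------------------------------------
# Activity metrics
# ---------------------------------------------------------------------------

def time_outside_shelter(traj: Trajectory) -> float:
    """Seconds the fish spent outside the shelter (= visible frames × dt)."""
    return traj.n_present * traj.frame_interval


def _segment_displacements(traj: Trajectory):
    """Yield (dx, dy) arrays of consecutive-present steps, one per segment."""
    for start, stop in traj.segments:
        if stop - start < 2:
            continue
        yield (np.diff(traj.x[start:stop]), np.diff(traj.y[start:stop]))


def time_swimming(traj: Trajectory, cfg: ActivityConfig) -> float:
    """Seconds in motion: frame pairs whose speed >= speed_threshold.

    Pairs never span an absence gap; each qualifying pair contributes one
    frame interval.
    """
    dt = traj.frame_interval
    count = 0
    for dx, dy in _segment_displacements(traj):
        speed = np.hypot(dx, dy) / dt
        count += int((speed >= cfg.speed_threshold).sum())
    return count * dt


def mean_turning_angle(traj: Trajectory) -> Optional[float]:
    """Mean absolute angle (degrees, in [0, 180]) between successive moves.

    Computed over triplets of consecutive present frames whose two
    displacements are both nonzero; triplets spanning gaps or containing a
    zero displacement are skipped. ``None`` when no valid triplet exists.
    """
    angles: list[float] = []
    for dx, dy in _segment_displacements(traj):
        if len(dx) < 2:
            continue
        v1x, v1y = dx[:-1], dy[:-1]
        v2x, v2y = dx[1:], dy[1:]
        n1 = np.hypot(v1x, v1y)
        n2 = np.hypot(v2x, v2y)
        ok = (n1 > 0) & (n2 > 0)
        if not ok.any():
            continue
        cross = v1x[ok] * v2y[ok] - v1y[ok] * v2x[ok]
        dot = v1x[ok] * v2x[ok] + v1y[ok] * v2y[ok]
        angles.extend(np.degrees(np.abs(np.arctan2(cross, dot))).tolist())
    if not angles:
        return None
    return float(np.mean(angles))


def area_covered(traj: Trajectory, cfg: ActivityConfig) -> tuple[int, float]:
    """Grid-occupancy area coverage: (cells visited, fraction of all cells).

    The arena is partitioned into ceil(width/cell) × ceil(height/cell) cells;
    a cell is visited if any present-frame centroid falls in it. A point on a
    cell boundary belongs to the higher-index cell, except at the arena's far
    edge where it belongs to the last cell.
    """
    nx = math.ceil(cfg.arena.width / cfg.grid_cell)
    ny = math.ceil(cfg.arena.height / cfg.grid_cell)
    total = nx * ny
    if traj.n_present == 0:
        return 0, 0.0
    px = traj.x[traj.present]
    py = traj.y[traj.present]
    ix = np.clip(np.floor(px / cfg.grid_cell).astype(int), 0, nx - 1)
    iy = np.clip(np.floor(py / cfg.grid_cell).astype(int), 0, ny - 1)
    visited = len(set(zip(ix.tolist(), iy.tolist())))
    return visited, visited / total


# ---------------------------------------------------------------------------
# Exploration metrics
# ---------------------------------------------------------------------------

def _object_distances(traj: Trajectory, cfg: ExplorationConfig) -> np.ndarray:
    ox, oy = cfg.object_centroid
    return np.hypot(traj.x[traj.present] - ox, traj.y[traj.present] - oy)


def min_object_distance(traj: Trajectory, cfg: ExplorationConfig,
                        ) -> Optional[float]:
    """Minimum distance of approach to the novel object, px; None if never
    present."""
    if traj.n_present == 0:
        return None
    return float(_object_distances(traj, cfg).min())


def time_near_object(traj: Trajectory, cfg: ExplorationConfig) -> float:
    """Seconds spent within near_radius (inclusive) of the object centroid."""
    if traj.n_present == 0:
        return 0.0
    close = _object_distances(traj, cfg) <= cfg.near_radius
    return float(close.sum()) * traj.frame_interval


# ---------------------------------------------------------------------------
# Metric bundles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ActivityMetrics:
    time_outside_s: float
    time_swimming_s: float
    mean_turning_deg: Optional[float]
    cells_visited: int
    area_fraction: float


@dataclass(frozen=True)
class ExplorationMetrics:
    time_outside_s: float
    min_object_distance_px: Optional[float]
    time_near_object_s: float


def activity_metrics(traj: Trajectory, cfg: ActivityConfig) -> ActivityMetrics:
    cells, fraction = area_covered(traj, cfg)
    return ActivityMetrics(
        time_outside_s=time_outside_shelter(traj),
        time_swimming_s=time_swimming(traj, cfg),
        mean_turning_deg=mean_turning_angle(traj),
        cells_visited=cells,
        area_fraction=fraction,
    )


def exploration_metrics(traj: Trajectory,
                        cfg: ExplorationConfig) -> ExplorationMetrics:
    return ExplorationMetrics(
        time_outside_s=time_outside_shelter(traj),
        min_object_distance_px=min_object_distance(traj, cfg),
        time_near_object_s=time_near_object(traj, cfg),
    )


def metrics_table(video_id: str, test_type: str,
                  activity: Optional[ActivityMetrics] = None,
                  exploration: Optional[ExplorationMetrics] = None,
                  config_note: str = "") -> pd.DataFrame:
    """Tidy one-row-per-metric table for CSV output."""
    rows = []

    def add(metric: str, value, units: str) -> None:
        rows.append({"video_id": video_id, "test_type": test_type,
                     "metric": metric, "value": value, "units": units,
                     "config": config_note})

    if activity is not None:
        add("time_outside", activity.time_outside_s, "s")
        add("time_swimming", activity.time_swimming_s, "s")
        add("mean_turning_angle", activity.mean_turning_deg, "deg")
        add("cells_visited", activity.cells_visited, "cells")
        add("area_fraction", activity.area_fraction, "fraction")
    if exploration is not None:
        add("time_outside", exploration.time_outside_s, "s")
        add("min_object_distance", exploration.min_object_distance_px, "px")
        add("time_near_object", exploration.time_near_object_s, "s")
    return pd.DataFrame(rows)
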