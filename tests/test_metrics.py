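"""Trajectory construction and behavioural (activity/exploration) metrics."""

import math

import numpy as np
import pytest

from arenatrack import (
    ActivityConfig,
    ArenaGeometry,
    BoundingBox,
    ExplorationConfig,
    SimulationParams,
    Trajectory,
    ValidationError,
    activity_metrics,
    area_covered,
    build_trajectory,
    exploration_metrics,
    mean_turning_angle,
    min_object_distance,
    simulate_video,
    time_near_object,
    time_outside_shelter,
    time_swimming,
    trajectory_from_truth,
)
from arenatrack.simulate import NOISELESS

from conftest import series_from_probs


def traj_from_points(points, video_id="v"):
    """Trajectory with every frame present at the given (x, y) points."""
    pts = np.asarray(points, dtype=float)
    return Trajectory(video_id, pts[:, 0], pts[:, 1],
                      np.ones(len(pts), dtype=bool))


def square_path(side=50.0, laps=1, origin=(100.0, 100.0)):
    ox, oy = origin
    corners = [(ox, oy), (ox + side, oy), (ox + side, oy + side),
               (ox, oy + side)]
    return [corners[i % 4] for i in range(4 * laps + 1)]


# ---------------------------------------------------------------------------
# trajectory construction
# ---------------------------------------------------------------------------

def test_all_present_is_one_segment(make_series):
    traj = build_trajectory(make_series([1.0, 1.0, 1.0]), 0.5)
    assert traj.segments == [(0, 3)] and traj.n_present == 3


def test_run_decomposition(make_series):
    traj = build_trajectory(make_series([1.0, 1.0, 0.0, 1.0]), 0.5)
    assert traj.segments == [(0, 2), (3, 4)]


def test_noiseless_trajectory_equals_ground_truth(noiseless_video):
    _, occ, truth, det = noiseless_video
    traj = build_trajectory(det, 0.5)
    oracle = trajectory_from_truth(truth)
    assert (traj.present == oracle.present).all()
    assert np.array_equal(traj.x, oracle.x, equal_nan=True)
    assert np.array_equal(traj.y, oracle.y, equal_nan=True)


def test_present_frames_must_have_positions():
    with pytest.raises(ValidationError):
        Trajectory("v", np.array([np.nan]), np.array([1.0]),
                   np.array([True]))


# ---------------------------------------------------------------------------
# activity metrics
# ---------------------------------------------------------------------------

def test_time_outside_counts_present_frames(make_series):
    traj = build_trajectory(make_series([1.0] * 100), 0.5)
    assert time_outside_shelter(traj) == 100.0
    none = build_trajectory(make_series([0.0] * 100), 0.5)
    assert time_outside_shelter(none) == 0.0


def test_time_swimming_stationary_fish_is_zero():
    traj = traj_from_points([(10, 10)] * 50)
    assert time_swimming(traj, ActivityConfig()) == 0.0


def test_time_swimming_zero_threshold_counts_all_transitions():
    traj = traj_from_points([(i * 10.0, 0.0) for i in range(8)])
    cfg = ActivityConfig(speed_threshold=0.0)
    assert time_swimming(traj, cfg) == 7.0


def test_time_swimming_alternating_speeds():
    # steps alternate 10 px and 2 px; at threshold 5 px/s half count
    pts = [(0.0, 0.0)]
    for i in range(10):
        step = 10.0 if i % 2 == 0 else 2.0
        pts.append((pts[-1][0] + step, 0.0))
    traj = traj_from_points(pts)
    assert time_swimming(traj, ActivityConfig(speed_threshold=5.0)) == 5.0


def test_time_swimming_never_spans_absence_gaps():
    x = np.array([0.0, 100.0, np.nan, 300.0, 400.0])
    present = np.array([True, True, False, True, True])
    traj = Trajectory("v", x, np.zeros(5) * x, present)
    # only the two within-segment steps count, not the 200 px gap
    assert time_swimming(traj, ActivityConfig(speed_threshold=5.0)) == 2.0


@pytest.mark.parametrize("points, expected", [
    ([(0, 0), (10, 0), (20, 0), (30, 0)], 0.0),            # collinear
    (square_path(), 90.0),                                  # square corners
    ([(100 + 60 * math.cos(k * math.pi / 3),
       100 + 60 * math.sin(k * math.pi / 3)) for k in range(7)], 60.0),
])
def test_mean_turning_angle_closed_forms(points, expected):
    assert mean_turning_angle(traj_from_points(points)) == pytest.approx(
        expected, abs=1e-9)


def test_mean_turning_angle_skips_zero_displacements():
    # pause in the middle: (10,0)->(10,0) contributes no angle
    traj = traj_from_points([(0, 0), (10, 0), (10, 0), (20, 0), (30, 0)])
    assert mean_turning_angle(traj) == pytest.approx(0.0)


def test_mean_turning_angle_undefined_is_none():
    assert mean_turning_angle(traj_from_points([(0, 0), (1, 0)])) is None
    stationary = traj_from_points([(5, 5)] * 10)
    assert mean_turning_angle(stationary) is None


def test_area_covered_stationary_single_cell():
    traj = traj_from_points([(100, 100)] * 20)
    cells, frac = area_covered(traj, ActivityConfig())
    assert cells == 1 and frac == pytest.approx(1 / 960)


def test_area_covered_empty_presence():
    traj = Trajectory("v", np.array([np.nan]), np.array([np.nan]),
                      np.array([False]))
    assert area_covered(traj, ActivityConfig()) == (0, 0.0)


def test_area_covered_full_grid():
    # centroids at every cell centre of the 40 x 24 grid (32 px on 1280x768)
    centers = [(ix * 32 + 16.0, iy * 32 + 16.0)
               for ix in range(40) for iy in range(24)]
    cells, frac = area_covered(traj_from_points(centers), ActivityConfig())
    assert cells == 960 and frac == 1.0


def test_area_boundary_points_go_to_higher_cell():
    traj = traj_from_points([(32.0, 32.0)])   # exactly on a cell corner
    cfg = ActivityConfig()
    cells, _ = area_covered(traj, cfg)
    assert cells == 1
    both = traj_from_points([(32.0, 32.0), (31.999, 31.999)])
    cells2, _ = area_covered(both, cfg)
    assert cells2 == 2


# ---------------------------------------------------------------------------
# exploration metrics
# ---------------------------------------------------------------------------

OBJ = ExplorationConfig(object_centroid=(640.0, 384.0))


def orbit(radius, n=36, center=(640.0, 384.0)):
    cx, cy = center
    return [(cx + radius * math.cos(2 * math.pi * k / n),
             cy + radius * math.sin(2 * math.pi * k / n)) for k in range(n)]


def test_min_distance_zero_at_object():
    traj = traj_from_points([(0, 0), (640, 384), (100, 100)])
    assert min_object_distance(traj, OBJ) == 0.0


def test_min_distance_constant_orbit():
    assert min_object_distance(traj_from_points(orbit(150)), OBJ) == \
        pytest.approx(150.0)


def test_min_distance_straight_pass():
    # pass from (0,384) to (1280,384), object 100 px off the line at (640,284)
    pts = [(x, 384.0) for x in range(0, 1281, 64)]  # sample lands at x=640
    cfg = ExplorationConfig(object_centroid=(640.0, 284.0))
    assert min_object_distance(traj_from_points(pts), cfg) == pytest.approx(100.0)


def test_min_distance_undefined_without_presence():
    traj = Trajectory("v", np.array([np.nan]), np.array([np.nan]),
                      np.array([False]))
    assert min_object_distance(traj, OBJ) is None


def test_time_near_object_radius_bracketing():
    inside = traj_from_points(orbit(99.0))
    outside = traj_from_points(orbit(101.0))
    assert time_near_object(inside, OBJ) == len(orbit(99.0)) * 1.0
    assert time_near_object(outside, OBJ) == 0.0


def test_time_near_object_counts_inside_frames():
    pts = orbit(50, n=7) + orbit(200, n=13)
    traj = traj_from_points(pts)
    assert time_near_object(traj, OBJ) == 7.0


# ---------------------------------------------------------------------------
# bundles and oracle equivalence
# ---------------------------------------------------------------------------

def test_noiseless_metrics_equal_ground_truth_oracle(noiseless_video):
    _, occ, truth, det = noiseless_video
    cfg = ActivityConfig()
    got = activity_metrics(build_trajectory(det, 0.5), cfg)
    oracle = activity_metrics(trajectory_from_truth(truth), cfg)
    assert got == oracle
    ecfg = ExplorationConfig(object_centroid=(900.0, 400.0))
    assert exploration_metrics(build_trajectory(det, 0.5), ecfg) == \
        exploration_metrics(trajectory_from_truth(truth), ecfg)


def test_empty_presence_metrics_degrade_gracefully(make_series):
    traj = build_trajectory(make_series([0.0] * 10), 0.5)
    am = activity_metrics(traj, ActivityConfig())
    assert am.time_outside_s == 0.0 and am.time_swimming_s == 0.0
    assert am.mean_turning_deg is None and am.cells_visited == 0
    em = exploration_metrics(traj, OBJ)
    assert em.min_object_distance_px is None and em.time_near_object_s == 0.0


def test_swimming_time_never_exceeds_time_outside(noisy_video):
    _, _, _, det = noisy_video
    traj = build_trajectory(det, 0.5)
    cfg = ActivityConfig(speed_threshold=0.0)
    assert time_swimming(traj, cfg) <= time_outside_shelter(traj)


def test_metrics_invariant_under_rigid_translation():
    pts = square_path(side=40, laps=3, origin=(200, 200))
    shifted = [(x + 123.0, y + 77.0) for x, y in pts]
    a, b = traj_from_points(pts), traj_from_points(shifted)
    cfg = ActivityConfig(speed_threshold=1.0)
    assert time_swimming(a, cfg) == time_swimming(b, cfg)
    assert mean_turning_angle(a) == pytest.approx(mean_turning_angle(b))
    obj_a = ExplorationConfig(object_centroid=(220.0, 220.0))
    obj_b = ExplorationConfig(object_centroid=(343.0, 297.0))
    assert min_object_distance(a, obj_a) == pytest.approx(
        min_object_distance(b, obj_b))
    assert time_near_object(a, obj_a) == time_near_object(b, obj_b)
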