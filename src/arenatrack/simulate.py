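"""Synthetic arena: ground-truth behaviour plus noisy detector output.

Stands in for the study's videos so every pipeline stage can be verified by
parameter recovery. Three generative layers, each with known parameters:

1. *Shelter occupancy* — a two-state Markov chain (hidden/visible) with
   per-step exit and entry probabilities; its stationary visible fraction is
   ``p_exit / (p_exit + p_enter)``.
2. *Movement* — a correlated random walk over the visible frames: turning
   angles drawn from a wrapped Cauchy distribution whose concentration is the
   heading persistence (uniform turning at persistence 0), step lengths
   ``|N(0, step_sigma)|``, reflection at arena borders, and re-emergence at
   the shelter anchor at the start of every visible run.
3. *Detector noise* — the per-frame class probability is drawn from a Beta
   law conditioned on true presence (a point mass is available for exact
   noiseless tests), and the emitted box centroid is the true position plus
   per-axis Gaussian jitter, with a small-probability outlier term that
   relocates the box entirely (emulating e.g. the novel object being
   mistaken for a fish). Hidden frames still emit a box at the outlier
   location, as a single-proposal detector does.

All randomness flows from one integer seed; each layer draws from its own
deterministically derived sub-stream so adding one stage never shifts
another's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .io import (
    AnnotationSeries,
    ArenaGeometry,
    BoundingBox,
    DetectionRecord,
    DetectionSeries,
    ValidationError,
)

_STREAM_OCCUPANCY = 11
_STREAM_PATH = 23
_STREAM_NOISE = 37

#: Ground-truth positions are snapped to this dyadic grid (1/65536 px, far
#: below any physical resolution) so that box corners cx±hw and their
#: midpoint are exactly representable: the noiseless detector then reproduces
#: the true position bit-for-bit.
POSITION_GRID = 1.0 / 65536.0


def _quantize(u: np.ndarray) -> np.ndarray:
    return np.round(u / POSITION_GRID) * POSITION_GRID


def _substream(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbabilityLaw:
    """Detector-score law: ``beta(a, b)`` or a degenerate point mass.

    A Beta law models the bounded confidence score of the detector; the point
    mass gives exactly reproducible noiseless runs. ``cdf`` makes
    threshold-dependent error rates analytically available.
    """

    kind: Literal["beta", "point"]
    a: float = 1.0
    b: float = 1.0
    value: float = 1.0

    def __post_init__(self) -> None:
        if self.kind == "beta" and (self.a <= 0 or self.b <= 0):
            raise ValidationError("Beta parameters must be positive")
        if self.kind == "point" and not (0 <= self.value <= 1):
            raise ValidationError("point mass must lie in [0, 1]")

    @staticmethod
    def beta(a: float, b: float) -> "ProbabilityLaw":
        return ProbabilityLaw("beta", a=a, b=b)

    @staticmethod
    def point(value: float) -> "ProbabilityLaw":
        return ProbabilityLaw("point", value=value)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "point":
            return np.full(n, self.value)
        return rng.beta(self.a, self.b, size=n)

    def cdf(self, x: float) -> float:
        """P(score < x); for threshold tau this is the rate of scores under it."""
        if self.kind == "point":
            return float(self.value < x)
        return float(stats.beta.cdf(x, self.a, self.b))


@dataclass(frozen=True)
class SimulationParams:
    """Behavioural ground-truth settings for one synthetic video."""

    duration: float = 3600.0          # seconds of video
    p_exit: float = 0.02              # hidden -> visible, per frame
    p_enter: float = 0.01             # visible -> hidden, per frame
    step_sigma: float = 20.0          # px scale of per-step displacement
    persistence: float = 0.6          # heading correlation in [0, 1)
    start_state: Literal["hidden", "visible"] = "hidden"
    shelter_anchor: tuple[float, float] = (120.0, 120.0)
    arena: ArenaGeometry = field(default_factory=ArenaGeometry)
    frame_interval: float = 1.0       # s between analysed frames
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_exit <= 1 and 0 <= self.p_enter <= 1):
            raise ValidationError("transition probabilities must be in [0, 1]")
        if self.step_sigma < 0:
            raise ValidationError("step_sigma must be non-negative")
        if not (0 <= self.persistence < 1):
            raise ValidationError("persistence must be in [0, 1)")
        if not self.arena.contains(*self.shelter_anchor):
            raise ValidationError("shelter_anchor outside the arena")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.frame_interval))


@dataclass(frozen=True)
class NoiseParams:
    """Detector-error settings.

    Defaults give a competent but imperfect detector: scores near 1 when the
    fish is visible (Beta(8, 2)), near 0 when hidden (Beta(2, 8)), ~5 px
    centroid jitter and a rare relocation outlier producing the
    small-mean / large-SD positioning error structure seen in practice.
    """

    present_prob_dist: ProbabilityLaw = field(
        default_factory=lambda: ProbabilityLaw.beta(8, 2))
    absent_prob_dist: ProbabilityLaw = field(
        default_factory=lambda: ProbabilityLaw.beta(2, 8))
    jitter_sigma: float = 5.0         # px, per-axis Gaussian centroid noise
    outlier_prob: float = 0.01
    outlier_box_source: Literal["random_location", "object_location"] = "random_location"
    box_halfwidth: float = 60.0       # px, emitted boxes are 2*hw x 2*hh
    box_halfheight: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter_sigma < 0:
            raise ValidationError("jitter_sigma must be non-negative")
        if not (0 <= self.outlier_prob <= 1):
            raise ValidationError("outlier_prob must be in [0, 1]")

    def miss_rate(self, tau: float) -> float:
        """P(score < tau | visible): the frame-wise miss rate at threshold tau."""
        return self.present_prob_dist.cdf(tau)

    def false_positive_rate(self, tau: float) -> float:
        """P(score >= tau | hidden)."""
        return 1.0 - self.absent_prob_dist.cdf(tau)


NOISELESS = NoiseParams(
    present_prob_dist=ProbabilityLaw.point(1.0),
    absent_prob_dist=ProbabilityLaw.point(0.0),
    jitter_sigma=0.0,
    outlier_prob=0.0,
)


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthPath:
    """True fish positions per frame; NaN coordinates while hidden."""

    video_id: str
    x: np.ndarray
    y: np.ndarray
    visible: np.ndarray
    frame_interval: float = 1.0

    def __len__(self) -> int:
        return len(self.x)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame_index": np.arange(len(self.x)),
            "visible": self.visible.astype(int),
            "x": self.x,
            "y": self.y,
        })

    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        df = self.to_frame()
        df.insert(0, "video_id", self.video_id)
        df.to_csv(path, index=False)
        return path


def simulate_occupancy(params: SimulationParams,
                       video_id: str = "sim") -> AnnotationSeries:
    """Two-state Markov chain of shelter occupancy, one value per frame.

    Stationary visible fraction is ``p_exit / (p_exit + p_enter)``; mean
    visible run length is ``1 / p_enter`` and mean hidden run length
    ``1 / p_exit``.
    """
    rng = _substream(params.seed, _STREAM_OCCUPANCY)
    n = params.n_frames
    u = rng.random(n)
    states = np.empty(n, dtype=np.int8)
    state = 1 if params.start_state == "visible" else 0
    for t in range(n):
        states[t] = state
        if state == 0:
            state = 1 if u[t] < params.p_exit else 0
        else:
            state = 0 if u[t] < params.p_enter else 1
    return AnnotationSeries(video_id, states, params.frame_interval)


def _reflect(u: np.ndarray, upper: float) -> np.ndarray:
    """Fold unbounded coordinates into [0, upper] by repeated reflection."""
    if upper <= 0:
        return np.zeros_like(u)
    m = np.mod(u, 2.0 * upper)
    return upper - np.abs(m - upper)


def simulate_path(occupancy: AnnotationSeries,
                  params: SimulationParams) -> GroundTruthPath:
    """Correlated random walk over the visible frames of an occupancy series.

    Each maximal visible run starts at the shelter anchor. Within a run the
    heading evolves by turning angles from a wrapped Cauchy with
    concentration ``persistence`` (uniform when 0), the step length is
    ``|N(0, step_sigma)|``, and positions are reflected at the arena borders.
    Hidden frames carry no position.
    """
    if not params.arena.contains(*params.shelter_anchor):
        raise ValidationError("shelter_anchor outside the arena")
    rng = _substream(params.seed, _STREAM_PATH)
    n = len(occupancy)
    x = np.full(n, np.nan)
    y = np.full(n, np.nan)
    vis = occupancy.values.astype(bool)
    ax, ay = params.shelter_anchor
    # maximal runs of visible frames
    for start, stop in _runs(vis):
        length = stop - start
        if params.step_sigma == 0 or length == 1:
            x[start:stop] = ax
            y[start:stop] = ay
            if params.step_sigma == 0:
                continue
        k = length - 1  # number of steps within the run
        if k <= 0:
            continue
        heading0 = rng.uniform(0.0, 2.0 * np.pi)
        if params.persistence == 0.0:
            turns = rng.uniform(-np.pi, np.pi, size=k)
        else:
            turns = stats.wrapcauchy.rvs(
                params.persistence, size=k, random_state=rng)
            turns = np.where(turns > np.pi, turns - 2.0 * np.pi, turns)
        headings = heading0 + np.cumsum(turns)
        steps = np.abs(rng.normal(0.0, params.step_sigma, size=k))
        dx = steps * np.cos(headings)
        dy = steps * np.sin(headings)
        px = ax + np.concatenate(([0.0], np.cumsum(dx)))
        py = ay + np.concatenate(([0.0], np.cumsum(dy)))
        x[start:stop] = _quantize(_reflect(px, params.arena.width))
        y[start:stop] = _quantize(_reflect(py, params.arena.height))
    return GroundTruthPath(occupancy.video_id, x, y, vis,
                           occupancy.frame_interval)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of maximal True runs."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), stops.tolist()))


# ---------------------------------------------------------------------------
# Detector emulation
# ---------------------------------------------------------------------------

def emulate_detections(truth: GroundTruthPath,
                       occupancy: AnnotationSeries,
                       noise: NoiseParams,
                       arena: Optional[ArenaGeometry] = None) -> DetectionSeries:
    """Emit a noisy detection series from a ground-truth path.

    Per frame the class probability is drawn from ``present_prob_dist`` when
    the fish is visible, else ``absent_prob_dist``. The emitted box is
    centred on the true position plus per-axis Gaussian jitter, except with
    probability ``outlier_prob`` (and on every hidden frame) it is placed at
    the outlier source. Boxes are clipped to the arena.
    """
    if len(truth) != len(occupancy):
        raise ValidationError(
            f"truth ({len(truth)}) and occupancy ({len(occupancy)}) differ in length")
    arena = arena or ArenaGeometry()
    rng = _substream(noise.seed, _STREAM_NOISE)
    n = len(truth)
    vis = occupancy.values.astype(bool)
    probs = np.where(
        vis,
        noise.present_prob_dist.sample(rng, n),
        noise.absent_prob_dist.sample(rng, n),
    )
    is_outlier = ~vis | (rng.random(n) < noise.outlier_prob)
    jitter = rng.normal(0.0, noise.jitter_sigma, size=(n, 2))
    if noise.outlier_box_source == "object_location":
        if arena.object_centroid is None:
            raise ValidationError(
                "outlier_box_source='object_location' needs arena.object_centroid")
        ox = np.full(n, arena.object_centroid[0])
        oy = np.full(n, arena.object_centroid[1])
    else:
        ox = rng.uniform(0.0, arena.width, size=n)
        oy = rng.uniform(0.0, arena.height, size=n)
    cx = np.clip(np.where(is_outlier, ox, truth.x + jitter[:, 0]),
                 0.0, arena.width)
    cy = np.clip(np.where(is_outlier, oy, truth.y + jitter[:, 1]),
                 0.0, arena.height)
    # boxes are clipped to the arena by symmetric shrinking so the emitted
    # centroid stays at (cx, cy) even against a border
    hw = np.minimum(noise.box_halfwidth, np.minimum(cx, arena.width - cx))
    hh = np.minimum(noise.box_halfheight, np.minimum(cy, arena.height - cy))
    records = []
    for i in range(n):
        x_min = float(cx[i] - hw[i])
        x_max = float(cx[i] + hw[i])
        y_min = float(cy[i] - hh[i])
        y_max = float(cy[i] + hh[i])
        records.append(DetectionRecord(
            frame_index=i,
            probability=float(np.clip(probs[i], 0.0, 1.0)),
            box=BoundingBox(x_min, y_min, x_max, y_max),
        ))
    return DetectionSeries(truth.video_id, records, truth.frame_interval)


def simulate_video(params: SimulationParams, noise: NoiseParams,
                   video_id: str = "sim",
                   ) -> tuple[AnnotationSeries, GroundTruthPath, DetectionSeries]:
    """Convenience wrapper: occupancy -> path -> detections for one video."""
    occ = simulate_occupancy(params, video_id)
    truth = simulate_path(occ, params)
    det = emulate_detections(truth, occ, noise, params.arena)
    return occ, truth, det


# ---------------------------------------------------------------------------
# Scenario configuration (YAML-friendly dicts)
# ---------------------------------------------------------------------------

def law_from_dict(d) -> ProbabilityLaw:
    if isinstance(d, ProbabilityLaw):
        return d
    if isinstance(d, (int, float)):
        return ProbabilityLaw.point(float(d))
    kind = d.get("kind", "beta")
    if kind == "point":
        return ProbabilityLaw.point(float(d["value"]))
    return ProbabilityLaw.beta(float(d["a"]), float(d["b"]))


def simulation_params_from_dict(d: dict) -> SimulationParams:
    d = dict(d)
    if "arena" in d and isinstance(d["arena"], dict):
        a = d["arena"]
        d["arena"] = ArenaGeometry(
            width=a.get("width", 1280), height=a.get("height", 768),
            shelter_region=(BoundingBox(*a["shelter_region"])
                            if a.get("shelter_region") else None),
            object_centroid=(tuple(a["object_centroid"])
                             if a.get("object_centroid") else None),
        )
    if "shelter_anchor" in d:
        d["shelter_anchor"] = tuple(d["shelter_anchor"])
    return SimulationParams(**d)


def noise_params_from_dict(d: dict) -> NoiseParams:
    d = dict(d)
    for key in ("present_prob_dist", "absent_prob_dist"):
        if key in d:
            d[key] = law_from_dict(d[key])
    return NoiseParams(**d)
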