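"""Detection/classification validation: threshold sweep and accuracy summary.

The detector's continuous per-frame score is thresholded into a binary
presence series and compared frame-by-frame with the manual annotation to
give a matching percentage per video — overall, and split into the manually
present and manually absent parts (separating misses from false positives).
A sweep over thresholds (default 0.5 ... 0.9) aggregates the per-video
percentages across videos into mean, sample SD, a normal-approximation
confidence interval (mean ± z·SD/√n, z = 1.96 by default) and an RMSE,
broken down by behavioural test type and pooled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import (
    AlignmentError,
    AnnotationSeries,
    DetectionSeries,
    ValidationError,
    align,
)

DEFAULT_THRESHOLDS = (0.5, 0.6, 0.7, 0.8, 0.9)


@dataclass(frozen=True)
class ValidationConfig:
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    confidence_z: float = 1.96
    rmse_mode: str = "frame_pooled"       # or "per_video"
    alignment_mode: str = "strict"        # or "truncate"

    def __post_init__(self) -> None:
        t = self.thresholds
        if any(not (0 < tau < 1) for tau in t):
            raise ValidationError("thresholds must lie in (0, 1)")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValidationError("thresholds must be strictly increasing")
        if self.confidence_z <= 0:
            raise ValidationError("confidence_z must be positive")
        if self.rmse_mode not in ("frame_pooled", "per_video"):
            raise ValidationError(f"unknown rmse_mode {self.rmse_mode!r}")


@dataclass(frozen=True)
class VideoMatchResult:
    """Matching percentages for one video at one threshold.

    ``present_pct`` / ``absent_pct`` are the matching percentages among the
    manually-present / manually-absent frames; a part with zero frames has an
    explicitly undefined (None) percentage, never 0 or 100.
    """

    video_id: str
    threshold: float
    n_frames: int
    overall_pct: float
    present_pct: Optional[float]
    absent_pct: Optional[float]
    n_present: int
    n_absent: int


def threshold_series(probabilities: Sequence[float], tau: float) -> np.ndarray:
    """Binarize detector scores: 1 where probability >= tau, else 0.

    The boundary counts as present, so a score exactly at the threshold is a
    detection.
    """
    if not (0 < tau < 1):
        raise ValidationError(f"threshold {tau} outside (0, 1)")
    p = np.asarray(probabilities, dtype=float)
    return (p >= tau).astype(np.int8)


def match_result(predicted: Sequence[int], manual: Sequence[int],
                 video_id: str = "", threshold: float = float("nan"),
                 ) -> VideoMatchResult:
    """Frame-by-frame agreement between a thresholded and a manual series."""
    pred = np.asarray(predicted, dtype=int)
    man = np.asarray(manual, dtype=int)
    if pred.shape != man.shape:
        raise AlignmentError(
            f"length mismatch: {pred.size} predicted vs {man.size} manual")
    n = pred.size
    if n == 0:
        raise ValidationError("cannot score an empty series")
    agree = pred == man
    present = man == 1
    n_present = int(present.sum())
    n_absent = n - n_present
    overall = 100.0 * agree.mean()
    present_pct = (100.0 * agree[present].mean()) if n_present else None
    absent_pct = (100.0 * agree[~present].mean()) if n_absent else None
    return VideoMatchResult(video_id, threshold, n, overall,
                            present_pct, absent_pct, n_present, n_absent)


def ci_of_mean(mean: float, sd: float, n: int, z: float = 1.96,
               ) -> tuple[float, float]:
    """Normal-approximation confidence interval mean ± z·sd/√n.

    This is the interval convention that reproduces the published worked
    examples exactly at two decimals (e.g. 92.79 ± 1.96·6.78/√14 =
    [89.24, 96.34]); a Student-t interval does not.
    """
    if n < 2:
        raise ValidationError("confidence interval needs n >= 2")
    if sd < 0:
        raise ValidationError("sd must be non-negative")
    half = z * sd / math.sqrt(n)
    return (mean - half, mean + half)


def rmse_classification(results: Sequence[VideoMatchResult],
                        mode: str = "frame_pooled") -> float:
    """Root-mean-square error of the thresholded classification.

    ``frame_pooled``: 100·√(mismatched frames / all frames), pooling every
    frame of every video. ``per_video``: √(mean over videos of
    (100 − overall_pct)²).
    """
    if not results:
        raise ValidationError("no results to aggregate")
    if mode == "frame_pooled":
        mismatch = sum(r.n_frames * (100.0 - r.overall_pct) / 100.0
                       for r in results)
        total = sum(r.n_frames for r in results)
        return 100.0 * math.sqrt(mismatch / total)
    if mode == "per_video":
        sq = [(100.0 - r.overall_pct) ** 2 for r in results]
        return math.sqrt(float(np.mean(sq)))
    raise ValidationError(f"unknown rmse_mode {mode!r}")


# ---------------------------------------------------------------------------
# Sweep
# ---------------------------------------------------------------------------

@dataclass
class SweepSummary:
    """Per-threshold accuracy statistics aggregated over videos.

    ``table`` has one row per (test_type, threshold) with columns
    mean_pct, sd_pct, ci_low, ci_high, rmse, present_mean_pct,
    absent_mean_pct, n_videos; test_type includes each observed type plus a
    pooled "Total". ``per_video`` is the long-format per-video table.
    """

    table: pd.DataFrame
    per_video: pd.DataFrame
    n_videos: int
    config: ValidationConfig

    def row(self, test_type: str, threshold: float) -> pd.Series:
        t = self.table
        m = (t["test_type"] == test_type) & np.isclose(t["threshold"], threshold)
        return t[m].iloc[0]


def video_results(detections: DetectionSeries, annotations: AnnotationSeries,
                  tau: float, mode: str = "strict") -> VideoMatchResult:
    pairs = align(detections, annotations, mode=mode)
    pred = threshold_series(pairs["probability"].to_numpy(), tau)
    return match_result(pred, pairs["manual"].to_numpy(),
                        video_id=detections.video_id, threshold=tau)


def _aggregate(group: list[VideoMatchResult], test_type: str, tau: float,
               cfg: ValidationConfig) -> dict:
    overall = np.array([r.overall_pct for r in group])
    n = overall.size
    mean = float(overall.mean())
    sd = float(overall.std(ddof=1)) if n >= 2 else float("nan")
    if n >= 2:
        lo, hi = ci_of_mean(mean, sd, n, cfg.confidence_z)
    else:
        lo = hi = float("nan")
    present = [r.present_pct for r in group if r.present_pct is not None]
    absent = [r.absent_pct for r in group if r.absent_pct is not None]
    return {
        "test_type": test_type,
        "threshold": tau,
        "n_videos": n,
        "mean_pct": mean,
        "sd_pct": sd,
        "ci_low": lo,
        "ci_high": hi,
        "rmse": rmse_classification(group, cfg.rmse_mode),
        "present_mean_pct": float(np.mean(present)) if present else float("nan"),
        "absent_mean_pct": float(np.mean(absent)) if absent else float("nan"),
    }


def sweep(videos: Sequence[tuple[DetectionSeries, AnnotationSeries, str]],
          config: ValidationConfig | None = None) -> SweepSummary:
    """Threshold sweep over a set of annotated videos.

    ``videos`` is a sequence of (detections, annotations, test_type) triples,
    test_type typically "activity" or "exploration". Every video contributes
    equally to the mean regardless of its length; part-wise means skip videos
    whose part is undefined (e.g. no absent frames).
    """
    config = config or ValidationConfig()
    if not videos:
        raise ValidationError("sweep needs at least one video")
    per_video_rows = []
    results: dict[float, list[VideoMatchResult]] = {}
    types: dict[float, dict[str, list[VideoMatchResult]]] = {}
    for tau in config.thresholds:
        results[tau] = []
        types[tau] = {}
        for det, ann, test_type in videos:
            r = video_results(det, ann, tau, config.alignment_mode)
            results[tau].append(r)
            types[tau].setdefault(test_type, []).append(r)
            per_video_rows.append({
                "video_id": r.video_id, "test_type": test_type,
                "threshold": tau, "n_frames": r.n_frames,
                "overall_pct": r.overall_pct,
                "present_pct": r.present_pct, "absent_pct": r.absent_pct,
                "n_present": r.n_present, "n_absent": r.n_absent,
            })
    rows = []
    for tau in config.thresholds:
        for test_type in sorted(types[tau]):
            rows.append(_aggregate(types[tau][test_type], test_type, tau, config))
        rows.append(_aggregate(results[tau], "Total", tau, config))
    return SweepSummary(
        table=pd.DataFrame(rows),
        per_video=pd.DataFrame(per_video_rows),
        n_videos=len(videos),
        config=config,
    )


def total_frames(videos: Sequence[AnnotationSeries] | Sequence[int]) -> int:
    """Number of analysed frames across videos (series or frame counts)."""
    return int(sum(len(v) if not isinstance(v, (int, np.integer)) else int(v)
                   for v in videos))
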