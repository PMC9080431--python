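"""Positioning validation: centroid distance errors against manual boxes.

The detector's localization output — the centroid of its bounding box — is
compared with the centroid of a manually drawn box for the same frame. The
per-frame error is the Euclidean distance in pixels; a localization counts as
a success when the error does not exceed the success threshold, defined as
the mean side length pooled over all manually drawn boxes (each box
contributes its width and its height once). Summary statistics are the mean,
sample SD, normal-approximation CI and RMSE of the error distribution, which
is typically heavy-tailed: a small mean with a much larger SD indicates rare
large relocation errors on top of small jitter.

Frames for manual labelling are sampled proportionally to each video's
manually-present portion (largest-remainder apportionment), which also
mitigates temporal autocorrelation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classification import ci_of_mean
from .io import AnnotationSeries, BoundingBox, ValidationError, bbox_centroid


@dataclass
class PositioningResult:
    errors: np.ndarray                # px, one per sampled frame
    mean_px: float
    sd_px: float                      # sample SD (n-1)
    ci_low: float
    ci_high: float
    rmse_px: float                    # sqrt(mean of squared errors)
    success_threshold_px: float
    success_pct: float

    def moment_identity_gap(self) -> float:
        """Relative gap in RMSE² = mean² + population variance (≈0 always)."""
        pop_var = float(np.var(self.errors))      # ddof=0 by construction
        lhs = self.rmse_px ** 2
        rhs = self.mean_px ** 2 + pop_var
        return abs(lhs - rhs) / max(lhs, 1e-300)


def centroid_error(predicted: BoundingBox, manual: BoundingBox) -> float:
    """Euclidean distance in pixels between the two box centroids."""
    px, py = bbox_centroid(predicted)
    mx, my = bbox_centroid(manual)
    return math.hypot(px - mx, py - my)


def success_threshold(manual_boxes: Sequence[BoundingBox],
                      mode: str = "pooled_sides") -> float:
    """Mean side length of the manually drawn boxes, in pixels.

    ``pooled_sides`` (default): mean over the pooled multiset of all widths
    and all heights, two values per box. ``per_box_mean``: mean of each box's
    own (width+height)/2, then averaged — differs only under unbalanced
    aspect-ratio mixes.
    """
    if not manual_boxes:
        raise ValidationError("success_threshold needs at least one box")
    w = np.array([b.width for b in manual_boxes])
    h = np.array([b.height for b in manual_boxes])
    if mode == "pooled_sides":
        return float(np.concatenate([w, h]).mean())
    if mode == "per_box_mean":
        return float(((w + h) / 2.0).mean())
    raise ValidationError(f"unknown mode {mode!r}")


def summarize_positioning(errors: Sequence[float], threshold: float,
                          z: float = 1.96) -> PositioningResult:
    """Summary statistics of a centroid-error sample.

    Success is inclusive: an error exactly at the threshold counts.
    """
    e = np.asarray(errors, dtype=float)
    if e.size == 0:
        raise ValidationError("no errors to summarize")
    if (e < 0).any():
        raise ValidationError("distance errors cannot be negative")
    if threshold <= 0:
        raise ValidationError("success threshold must be positive")
    mean = float(e.mean())
    sd = float(e.std(ddof=1)) if e.size >= 2 else float("nan")
    if e.size >= 2:
        lo, hi = ci_of_mean(mean, sd, e.size, z)
    else:
        lo = hi = float("nan")
    rmse = float(np.sqrt(np.mean(e ** 2)))
    success = 100.0 * float((e <= threshold).mean())
    return PositioningResult(e, mean, sd, lo, hi, rmse, threshold, success)


def paired_errors(predicted: dict[tuple[str, int], BoundingBox],
                  manual: dict[tuple[str, int], BoundingBox],
                  ) -> tuple[pd.DataFrame, int]:
    """Match predicted and manual boxes on (video_id, frame_index) keys.

    Returns the per-frame error table and the count of unmatched manual keys.
    """
    rows = []
    unmatched = 0
    for key, mbox in manual.items():
        pbox = predicted.get(key)
        if pbox is None:
            unmatched += 1
            continue
        rows.append({
            "video_id": key[0], "frame_index": key[1],
            "error_px": centroid_error(pbox, mbox),
            "pred_x": bbox_centroid(pbox)[0], "pred_y": bbox_centroid(pbox)[1],
            "manual_x": bbox_centroid(mbox)[0], "manual_y": bbox_centroid(mbox)[1],
        })
    return pd.DataFrame(rows), unmatched


def sample_validation_frames(videos: Sequence[tuple[str, AnnotationSeries]],
                             n_total: int, seed: int,
                             ) -> list[tuple[str, int]]:
    """Sample present frames for manual labelling, proportionally per video.

    The per-video quota is the largest-remainder apportionment of ``n_total``
    by each video's manually-present frame count (ties broken in video order
    as given); within a video, frames are drawn uniformly without replacement
    among its present frames. Deterministic under ``seed``.
    """
    counts = [int(np.sum(ann.values)) for _, ann in videos]
    total_present = sum(counts)
    if n_total > total_present:
        raise ValidationError(
            f"requested {n_total} frames but only {total_present} present "
            f"frames exist across {len(videos)} videos")
    if n_total < 0:
        raise ValidationError("n_total must be non-negative")
    exact = [n_total * c / total_present for c in counts]
    quotas = [int(math.floor(q)) for q in exact]
    remainder = n_total - sum(quotas)
    # largest remainders get the leftover units; ties in input order
    order = sorted(range(len(videos)),
                   key=lambda i: (-(exact[i] - quotas[i]), i))
    for i in order[:remainder]:
        quotas[i] += 1
    rng = np.random.default_rng(seed)
    out: list[tuple[str, int]] = []
    for (vid, ann), quota, count in zip(videos, quotas, counts):
        if quota == 0:
            continue
        present_idx = np.flatnonzero(ann.values == 1)
        chosen = rng.choice(present_idx, size=quota, replace=False)
        out.extend((vid, int(f)) for f in np.sort(chosen))
    return out
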