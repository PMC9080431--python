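"""Domain types and readers/writers for detection and annotation tables.

The pipeline's raw input is the per-frame output of a single-object fish
detector run at one frame per second: a class probability in [0, 1] and an
axis-aligned bounding box in pixel coordinates of the video frame
(1,280 x 768 px by default, origin top-left, y increasing downward).
Ground truth for validation is a human-annotated binary presence series
(1 = fish visible, i.e. outside the shelter) and manually drawn bounding
boxes stored as PASCAL VOC XML (the LabelImg dialect).

Tabular formats are plain CSV with a mandatory header, UTF-8, '.' decimal
separator:

* detection table:  video_id, frame_index, probability, x_min, y_min, x_max, y_max
* annotation table: video_id, frame_index, present
"""

from __future__ import annotations

import logging
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("arenatrack")

DETECTION_COLUMNS = [
    "video_id", "frame_index", "probability",
    "x_min", "y_min", "x_max", "y_max",
]
ANNOTATION_COLUMNS = ["video_id", "frame_index", "present"]


class ArenaTrackError(Exception):
    """Base class for all package errors."""


class ParseError(ArenaTrackError):
    """Malformed input file (names the offending line where possible)."""


class ValidationError(ArenaTrackError):
    """A value violates a domain invariant."""


class AlignmentError(ArenaTrackError):
    """Two series that must be compared frame-by-frame do not align."""


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in pixel coordinates, corners inclusive.

    Coordinates follow the image convention (origin top-left, x rightward,
    y downward), matching what LabelImg writes into VOC XML.
    """

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if self.x_min > self.x_max or self.y_min > self.y_max:
            raise ValidationError(
                f"inverted box corners: ({self.x_min},{self.y_min})-"
                f"({self.x_max},{self.y_max})"
            )
        if min(self.x_min, self.y_min) < 0:
            raise ValidationError("box coordinates must be non-negative")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    def centroid(self) -> tuple[float, float]:
        return bbox_centroid(self)


def bbox_centroid(box: BoundingBox) -> tuple[float, float]:
    """Midpoint of a bounding box — the fish's per-frame position."""
    return ((box.x_min + box.x_max) / 2.0, (box.y_min + box.y_max) / 2.0)


@dataclass(frozen=True)
class ArenaGeometry:
    """The recorded aquarium: frame size plus optional shelter and object.

    ``shelter_region`` is an axis-aligned rectangle (a :class:`BoundingBox`)
    where the fish is invisible to the camera; ``object_centroid`` is the
    position of the novel object in exploration tests.
    """

    width: float = 1280.0
    height: float = 768.0
    shelter_region: Optional[BoundingBox] = None
    object_centroid: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValidationError("arena dimensions must be positive")
        if self.shelter_region is not None:
            s = self.shelter_region
            if s.x_max > self.width or s.y_max > self.height:
                raise ValidationError("shelter_region extends outside the arena")
        if self.object_centroid is not None:
            x, y = self.object_centroid
            if not (0 <= x <= self.width and 0 <= y <= self.height):
                raise ValidationError("object_centroid lies outside the arena")

    def contains(self, x: float, y: float) -> bool:
        return 0 <= x <= self.width and 0 <= y <= self.height


# ---------------------------------------------------------------------------
# Series types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DetectionRecord:
    """One frame of detector output.

    The detector always emits its single most confident proposal, so a box
    accompanies even very low probabilities; ``box`` is ``None`` only for
    frames where no proposal at all was produced.
    """

    frame_index: int
    probability: float
    box: Optional[BoundingBox]

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValidationError(f"negative frame_index {self.frame_index}")
        if not (0.0 <= self.probability <= 1.0):
            raise ValidationError(
                f"probability {self.probability} outside [0, 1] "
                f"at frame {self.frame_index}"
            )


@dataclass
class DetectionSeries:
    """Ordered per-frame detections for one video (default 1 frame/s)."""

    video_id: str
    records: list[DetectionRecord]
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        idx = [r.frame_index for r in self.records]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValidationError(
                f"frame_index not strictly increasing in video {self.video_id!r}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[DetectionRecord]:
        return iter(self.records)

    @property
    def probabilities(self) -> np.ndarray:
        return np.array([r.probability for r in self.records], dtype=float)

    @property
    def frame_indices(self) -> np.ndarray:
        return np.array([r.frame_index for r in self.records], dtype=int)


@dataclass
class AnnotationSeries:
    """Human-labelled binary presence per frame (1 = outside the shelter)."""

    video_id: str
    values: np.ndarray
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.size and not np.isin(v, (0, 1)).all():
            bad = v[~np.isin(v, (0, 1))][0]
            raise ValidationError(f"annotation value {bad!r} not in {{0, 1}}")
        object.__setattr__(self, "values", v.astype(np.int8))

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def _read_table(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pandas names the offending line itself
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return df


def read_detections(path: str | Path, video_id: Optional[str] = None,
                    frame_interval: float = 1.0) -> DetectionSeries:
    """Read one video's detection table from CSV.

    If the file holds several videos, ``video_id`` selects one; otherwise the
    file must contain exactly one. Rows with all four box coordinates empty
    are frames without a usable proposal (box stored as ``None``).
    """
    df = _read_table(path, DETECTION_COLUMNS)
    if video_id is not None:
        df = df[df["video_id"].astype(str) == str(video_id)]
    else:
        ids = df["video_id"].astype(str).unique().tolist() if len(df) else []
        if len(ids) > 1:
            raise ParseError(f"{path}: multiple videos {ids}, pass video_id")
        video_id = ids[0] if ids else Path(path).stem
    records = []
    box_cols = ["x_min", "y_min", "x_max", "y_max"]
    for pos, row in enumerate(df.itertuples(index=False), start=2):
        try:
            coords = [getattr(row, c) for c in box_cols]
            if all(pd.isna(c) for c in coords):
                box = None
            else:
                box = BoundingBox(*(float(c) for c in coords))
            records.append(DetectionRecord(
                frame_index=int(row.frame_index),
                probability=float(row.probability),
                box=box,
            ))
        except ValidationError:
            raise
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: malformed row at line {pos}: {exc}") from exc
    try:
        return DetectionSeries(str(video_id), records, frame_interval)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_detections(series: DetectionSeries, path: str | Path) -> Path:
    """Write a detection series as CSV; inverse of :func:`read_detections`.

    Numeric fields are written with ``repr`` precision so that a read/write
    round trip reproduces the series exactly.
    """
    path = Path(path)
    rows = []
    for r in series:
        b = r.box
        rows.append({
            "video_id": series.video_id,
            "frame_index": r.frame_index,
            "probability": np.format_float_positional(r.probability, trim="0"),
            "x_min": "" if b is None else np.format_float_positional(b.x_min, trim="0"),
            "y_min": "" if b is None else np.format_float_positional(b.y_min, trim="0"),
            "x_max": "" if b is None else np.format_float_positional(b.x_max, trim="0"),
            "y_max": "" if b is None else np.format_float_positional(b.y_max, trim="0"),
        })
    pd.DataFrame(rows, columns=DETECTION_COLUMNS).to_csv(path, index=False)
    return path


def read_annotations(path: str | Path, video_id: Optional[str] = None,
                     frame_interval: float = 1.0) -> AnnotationSeries:
    """Read a manual presence/absence series (columns frame_index, present)."""
    df = _read_table(path, ANNOTATION_COLUMNS)
    if video_id is not None:
        df = df[df["video_id"].astype(str) == str(video_id)]
    else:
        ids = df["video_id"].astype(str).unique().tolist() if len(df) else []
        if len(ids) > 1:
            raise ParseError(f"{path}: multiple videos {ids}, pass video_id")
        video_id = ids[0] if ids else Path(path).stem
    idx = df["frame_index"].to_numpy()
    if idx.size and (np.diff(idx) <= 0).any():
        raise ValidationError(f"{path}: frame_index not strictly increasing")
    vals = df["present"].to_numpy()
    try:
        return AnnotationSeries(str(video_id), vals, frame_interval)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_annotations(series: AnnotationSeries, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({
        "video_id": series.video_id,
        "frame_index": np.arange(len(series)),
        "present": series.values,
    }).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# PASCAL VOC XML (LabelImg dialect)
# ---------------------------------------------------------------------------

def parse_voc_boxes(path: str | Path) -> list[tuple[str, BoundingBox]]:
    """Parse manually drawn boxes from one LabelImg PASCAL VOC XML file.

    Returns ``(image_id, box)`` per ``<object>`` element in document order.
    ``image_id`` is the ``<filename>`` stem; VOC stores integer pixel
    coordinates, taken verbatim.
    """
    path = Path(path)
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    fname = root.findtext("filename") or path.stem
    image_id = Path(fname).stem
    out: list[tuple[str, BoundingBox]] = []
    for obj in root.iter("object"):
        bnd = obj.find("bndbox")
        if bnd is None:
            raise ParseError(f"{path}: <object> without <bndbox>")
        try:
            coords = {tag: float(bnd.findtext(tag).strip())
                      for tag in ("xmin", "ymin", "xmax", "ymax")}
        except (TypeError, AttributeError, ValueError) as exc:
            raise ParseError(f"{path}: incomplete <bndbox>") from exc
        out.append((image_id, BoundingBox(
            coords["xmin"], coords["ymin"], coords["xmax"], coords["ymax"],
        )))
    return out


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def align(detections: DetectionSeries, annotations: AnnotationSeries,
          mode: str = "strict") -> pd.DataFrame:
    """Pair detector probabilities with manual presence, frame by frame.

    Returns a frame-indexed DataFrame with columns ``probability`` and
    ``manual``. In ``strict`` mode the two series must have equal length;
    ``truncate`` pairs up to the shorter length with a logged warning.
    Detector frames missing relative to the annotation (shorter detection
    series) are treated in ``truncate`` mode as evidence of absence only via
    truncation — a frame wholly absent from the detection table is filled as
    probability 0 with no box by :func:`read_detections` callers upstream.
    """
    if detections.video_id != annotations.video_id:
        raise AlignmentError(
            f"video_id mismatch: {detections.video_id!r} vs {annotations.video_id!r}"
        )
    n_det, n_ann = len(detections), len(annotations)
    if n_det != n_ann:
        if mode == "strict":
            raise AlignmentError(
                f"length mismatch for {detections.video_id!r}: "
                f"{n_det} detection frames vs {n_ann} annotated frames"
            )
        if mode != "truncate":
            raise ValueError(f"unknown alignment mode {mode!r}")
        logger.warning(
            "truncating %r to %d frames (detections %d, annotations %d)",
            detections.video_id, min(n_det, n_ann), n_det, n_ann,
        )
    n = min(n_det, n_ann)
    return pd.DataFrame({
        "frame_index": detections.frame_indices[:n],
        "probability": detections.probabilities[:n],
        "manual": annotations.values[:n].astype(int),
    }).set_index("frame_index")


def fill_missing_frames(detections: DetectionSeries,
                        n_frames: int) -> DetectionSeries:
    """Insert probability-0, box-less records for frames 0..n_frames-1 that
    the detector skipped: absence of a proposal is evidence of absence."""
    have = {r.frame_index: r for r in detections}
    missing = [i for i in range(n_frames) if i not in have]
    if missing:
        logger.info("video %r: filling %d missing frames with probability 0",
                    detections.video_id, len(missing))
    records = [have.get(i, DetectionRecord(i, 0.0, None))
               for i in range(n_frames)]
    return DetectionSeries(detections.video_id, records,
                           detections.frame_interval)
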