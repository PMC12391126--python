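"""Cross-frame leaf identity tracing.

Leaves are planted in a fixed grid (4x4 by default). In the first frame each
instance gets an ID from its grid position: instances are sorted by centroid
row (Cy), chunked into grid rows, each row sorted left-to-right by Cx, and
IDs 0..rows*cols-1 assigned row-major. In every later frame an instance
inherits the ID of the live track whose most recent mask it best overlaps
(IoU), provided that best IoU exceeds the threshold; otherwise it opens a
new track with a fresh ID beyond the grid range. Conflicts are resolved
greedily in descending IoU. Lost tracks stay live indefinitely, so a leaf
missed in a few frames resumes its identity when it reappears.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime

import numpy as np
import pandas as pd

from .io_formats import FrameObservation
from .merge import InstanceMask, extract_instance_stats


@dataclass(frozen=True)
class MatchConfig:
    iou_threshold: float = 0.5
    rows: int = 4
    cols: int = 4

    def __post_init__(self) -> None:
        if not 0.0 < self.iou_threshold <= 1.0:
            raise ValueError(
                f"iou_threshold must be in (0, 1], got {self.iou_threshold}"
            )
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must have at least one row and column")


@dataclass
class LeafTrack:
    """One leaf's identity: time-ordered (timestamp, instance) observations."""

    leaf_id: int
    observations: list[tuple[datetime, InstanceMask]] = field(default_factory=list)

    @property
    def last_mask(self) -> np.ndarray:
        return self.observations[-1][1].raster

    def append(self, time: datetime, inst: InstanceMask) -> None:
        if self.observations and time <= self.observations[-1][0]:
            raise ValueError(
                f"track {self.leaf_id}: observation times must strictly increase"
            )
        self.observations.append((time, inst))


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two binary masks as pixel sets."""
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    fa = a > 127
    fb = b > 127
    union = np.logical_or(fa, fb).sum()
    if union == 0:
        raise ValueError("IoU undefined: both masks empty")
    inter = np.logical_and(fa, fb).sum()
    return float(inter) / float(union)


def _iou_instances(a: InstanceMask, b: InstanceMask) -> float:
    """IoU between two instances, short-circuited through their bounding
    boxes: disjoint boxes mean disjoint masks, and the pixel comparison is
    restricted to the union box."""
    ax0, ay0, ax1, ay1 = a.bbox
    bx0, by0, bx1, by1 = b.bbox
    if ax1 < bx0 or bx1 < ax0 or ay1 < by0 or by1 < ay0:
        return 0.0
    x0, y0 = min(ax0, bx0), min(ay0, by0)
    x1, y1 = max(ax1, bx1), max(ay1, by1)
    fa = a.raster[y0 : y1 + 1, x0 : x1 + 1] > 127
    fb = b.raster[y0 : y1 + 1, x0 : x1 + 1] > 127
    union = np.logical_or(fa, fb).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(fa, fb).sum()) / float(union)


def assign_initial_ids(
    instances: list[InstanceMask], config: MatchConfig | None = None
) -> dict[int, int]:
    """Grid-based first-frame ID assignment.

    Returns a mapping from instance index (input order) to leaf ID. The
    instance count must equal rows*cols; any other count indicates a faulty
    first frame that needs manual review.
    """
    config = config or MatchConfig()
    expected = config.rows * config.cols
    if len(instances) != expected:
        raise ValueError(
            f"first frame has {len(instances)} instances, expected "
            f"{expected} ({config.rows}x{config.cols} grid); review the "
            "first frame manually"
        )
    order_by_cy = sorted(range(expected), key=lambda i: instances[i].centroid[1])
    mapping: dict[int, int] = {}
    next_id = 0
    for r in range(config.rows):
        row = order_by_cy[r * config.cols : (r + 1) * config.cols]
        for idx in sorted(row, key=lambda i: instances[i].centroid[0]):
            mapping[idx] = next_id
            next_id += 1
    return mapping


def start_tracks(
    frame: FrameObservation, config: MatchConfig | None = None
) -> list[LeafTrack]:
    """Initialize tracks from the first frame via grid assignment."""
    config = config or MatchConfig()
    instances = [extract_instance_stats(m) for m in frame.masks]
    mapping = assign_initial_ids(instances, config)
    tracks = [LeafTrack(leaf_id=mapping[i]) for i in range(len(instances))]
    for i, track in enumerate(tracks):
        track.append(frame.time, instances[i])
    return sorted(tracks, key=lambda t: t.leaf_id)


def match_frame(
    tracks: list[LeafTrack],
    frame: FrameObservation,
    config: MatchConfig | None = None,
) -> list[LeafTrack]:
    """Attach one frame's instances to the live tracks (in place).

    Every instance is compared by IoU against the most recent mask of every
    track; pairs are claimed greedily in descending IoU while the IoU
    exceeds the threshold, one instance per track per frame. Leftover
    instances open new tracks numbered after the current maximum ID.
    """
    config = config or MatchConfig()
    instances = [extract_instance_stats(m) for m in frame.masks]
    if instances and tracks:
        pairs = []
        for j, inst in enumerate(instances):
            for k, track in enumerate(tracks):
                v = _iou_instances(inst, track.observations[-1][1])
                if v > config.iou_threshold:
                    pairs.append((v, j, k))
        pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
        used_inst: set[int] = set()
        used_track: set[int] = set()
        for v, j, k in pairs:
            if j in used_inst or k in used_track:
                continue
            tracks[k].append(frame.time, instances[j])
            used_inst.add(j)
            used_track.add(k)
    else:
        used_inst = set()
    next_id = max((t.leaf_id for t in tracks), default=-1) + 1
    for j, inst in enumerate(instances):
        if j in used_inst:
            continue
        track = LeafTrack(leaf_id=next_id)
        track.append(frame.time, inst)
        tracks.append(track)
        next_id += 1
    return tracks


def track_sequence(
    frames: list[FrameObservation], config: MatchConfig | None = None
) -> list[LeafTrack]:
    """Run grid initialization on the first frame, IoU inheritance on the rest."""
    if not frames:
        return []
    config = config or MatchConfig()
    tracks = start_tracks(frames[0], config)
    for frame in frames[1:]:
        match_frame(tracks, frame, config)
    return tracks


def tracks_to_frame(tracks: list[LeafTrack]) -> pd.DataFrame:
    """Flatten tracks to a table (leaf_id, frame_time, Cx, Cy, pixel_count)."""
    rows = [
        {
            "leaf_id": t.leaf_id,
            "frame_time": time,
            "Cx": inst.centroid[0],
            "Cy": inst.centroid[1],
            "pixel_count": inst.pixel_count,
        }
        for t in tracks
        for time, inst in t.observations
    ]
    df = pd.DataFrame(rows, columns=["leaf_id", "frame_time", "Cx", "Cy", "pixel_count"])
    return df.sort_values(["leaf_id", "frame_time"], ignore_index=True)
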