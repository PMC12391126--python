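"""Reading and writing the formats the phenotyping pipeline touches.

Frames arrive as image files whose names embed a capture timestamp
(``YYYY-MM-DD-HH-MM-SS``); instance annotations arrive either as ISAT-style
per-image polygon JSON documents or as normalized polygon TXT records
(one instance per line: class id followed by alternating normalized x, y).
Masks are 8-bit binary rasters with foreground value 255.

Pixel convention: 0-based, origin at the top-left corner, x rightward,
y downward. Pixel (x, y) covers the half-open square [x, x+1) x [y, y+1);
a polygon claims a pixel when the pixel's center (x+0.5, y+0.5) lies
strictly inside it.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
from PIL import Image
from shapely.geometry import Polygon as ShapelyPolygon

logger = logging.getLogger(__name__)

FOREGROUND = 255

_TIMESTAMP_RE = re.compile(r"(\d{4})-(\d{2})-(\d{2})-(\d{2})-(\d{2})-(\d{2})")

#: Column order of the per-leaf results CSV, frozen for downstream tooling.
RESULT_COLUMNS = [
    "frame_time",
    "leaf_id",
    "Cx",
    "Cy",
    "pixel_count",
    "area_mm2",
    "growth_rate_mm2_per_h",
]


class TimestampParseError(ValueError):
    """Filename lacks a well-formed YYYY-MM-DD-HH-MM-SS token."""


def parse_timestamp(filename: str | Path) -> datetime:
    """Extract the capture time embedded in an image filename.

    Parameters
    ----------
    filename
        Any string containing one ``YYYY-MM-DD-HH-MM-SS`` token, e.g.
        ``box3_2025-03-01-12-30-00.jpg``.

    Returns
    -------
    datetime.datetime
        The parsed calendar time (naive; the incubator clock).

    Raises
    ------
    TimestampParseError
        If no token is present or the fields do not form a valid date-time.
    """
    name = str(filename)
    m = _TIMESTAMP_RE.search(name)
    if m is None:
        raise TimestampParseError(
            f"no YYYY-MM-DD-HH-MM-SS timestamp token in filename {name!r}"
        )
    try:
        return datetime(*(int(g) for g in m.groups()))
    except ValueError as exc:
        raise TimestampParseError(
            f"malformed timestamp token {m.group(0)!r} in filename {name!r}: {exc}"
        ) from exc


def hours_between(earlier: datetime, later: datetime) -> float:
    """Elapsed time from ``earlier`` to ``later`` in fractional hours."""
    return (later - earlier).total_seconds() / 3600.0


@dataclass(frozen=True)
class PolygonRecord:
    """One instance annotation: class id plus normalized vertices in [0, 1]."""

    class_id: int
    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.class_id < 0:
            raise ValueError(f"class_id must be non-negative, got {self.class_id}")
        if len(self.vertices) < 3:
            raise ValueError(
                f"polygon needs >=3 vertices, got {len(self.vertices)}"
            )
        for x, y in self.vertices:
            if not (0.0 <= x <= 1.0 and 0.0 <= y <= 1.0):
                raise ValueError(
                    f"normalized coordinate ({x}, {y}) outside [0, 1]"
                )

    def to_pixels(self, width: int, height: int) -> np.ndarray:
        """Denormalize to an (n, 2) float array of pixel coordinates."""
        v = np.asarray(self.vertices, dtype=float)
        return v * np.array([width, height], dtype=float)


def polygons_to_txt_lines(
    polygons: Sequence[Sequence[tuple[float, float]]],
    image_width: int,
    image_height: int,
    class_id: int = 0,
) -> list[str]:
    """Convert pixel-coordinate polygons to normalized segmentation TXT lines.

    Each output line is ``<class_id> x1 y1 x2 y2 ...`` with x divided by
    ``image_width`` and y by ``image_height``. Vertices outside the image
    rectangle are clipped to it (rotation augmentation can push them out);
    a warning is logged when clipping occurs.

    Raises
    ------
    ValueError
        For non-positive image dimensions, or a degenerate polygon
        (<3 vertices); the error names the offending polygon index.
    """
    if image_width <= 0 or image_height <= 0:
        raise ValueError(
            f"image dimensions must be positive, got {image_width}x{image_height}"
        )
    lines = []
    for i, poly in enumerate(polygons):
        pts = np.asarray(poly, dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 2:
            raise ValueError(
                f"polygon {i} is degenerate: need >=3 (x, y) vertices, "
                f"got shape {pts.shape}"
            )
        clipped = np.clip(pts, [0.0, 0.0], [image_width, image_height])
        if not np.array_equal(clipped, pts):
            logger.warning(
                "polygon %d had out-of-bounds vertices; clipped to image", i
            )
        norm = clipped / [image_width, image_height]
        coords = " ".join(f"{v:.6f}".rstrip("0").rstrip(".") for v in norm.ravel())
        lines.append(f"{class_id} {coords}")
    return lines


def parse_txt_lines(lines: Iterable[str]) -> list[PolygonRecord]:
    """Parse normalized segmentation TXT lines back into PolygonRecords."""
    records = []
    for lineno, raw in enumerate(lines):
        line = raw.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) < 7 or (len(parts) - 1) % 2 != 0:
            raise ValueError(
                f"line {lineno}: expected class id plus >=3 coordinate "
                f"pairs, got {len(parts)} fields"
            )
        cid = int(parts[0])
        vals = [float(p) for p in parts[1:]]
        verts = tuple(zip(vals[0::2], vals[1::2]))
        records.append(PolygonRecord(class_id=cid, vertices=verts))
    return records


def read_polygon_txt(path: str | Path) -> list[PolygonRecord]:
    return parse_txt_lines(Path(path).read_text().splitlines())


def write_polygon_txt(
    path: str | Path,
    polygons: Sequence[Sequence[tuple[float, float]]],
    image_width: int,
    image_height: int,
    class_id: int = 0,
) -> None:
    lines = polygons_to_txt_lines(polygons, image_width, image_height, class_id)
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_isat_json(path: str | Path) -> tuple[list[list[tuple[float, float]]], tuple[int, int]]:
    """Read an ISAT-style per-image annotation document.

    Returns the pixel-coordinate polygons (``segmentation`` field of each
    object) and the declared image size ``(width, height)``. Only the polygon
    path is supported.
    """
    doc = json.loads(Path(path).read_text())
    info = doc.get("info", {})
    width = int(info.get("width"))
    height = int(info.get("height"))
    polys = []
    for obj in doc.get("objects", []):
        seg = obj.get("segmentation")
        if seg is None:
            raise ValueError(f"object without polygon segmentation in {path}")
        polys.append([(float(x), float(y)) for x, y in seg])
    return polys, (width, height)


def rasterize_polygon(
    vertices: Sequence[tuple[float, float]], width: int, height: int
) -> np.ndarray:
    """Fill a pixel-coordinate polygon into a binary {0, 255} uint8 raster.

    A pixel belongs to the mask when its center (x+0.5, y+0.5) lies inside
    the polygon; the test is vectorized through shapely and restricted to
    the polygon's bounding box.
    """
    if width <= 0 or height <= 0:
        raise ValueError(f"raster dimensions must be positive, got {width}x{height}")
    mask = np.zeros((height, width), dtype=np.uint8)
    poly = ShapelyPolygon(vertices)
    if poly.is_empty or poly.area == 0:
        return mask
    poly = shapely.make_valid(poly)
    minx, miny, maxx, maxy = poly.bounds
    x0 = max(int(np.floor(minx)), 0)
    y0 = max(int(np.floor(miny)), 0)
    x1 = min(int(np.ceil(maxx)), width - 1)
    y1 = min(int(np.ceil(maxy)), height - 1)
    if x1 < x0 or y1 < y0:
        return mask
    xs = np.arange(x0, x1 + 1) + 0.5
    ys = np.arange(y0, y1 + 1) + 0.5
    gx, gy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(poly, gx.ravel(), gy.ravel()).reshape(gx.shape)
    mask[y0 : y1 + 1, x0 : x1 + 1] = np.where(inside, FOREGROUND, 0).astype(np.uint8)
    return mask


@dataclass
class FrameObservation:
    """All instance masks of one timestamped frame."""

    time: datetime | None
    width: int
    height: int
    masks: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        for m in self.masks:
            if m.shape != (self.height, self.width):
                raise ValueError(
                    f"mask shape {m.shape} does not match declared frame size "
                    f"{self.height}x{self.width}"
                )

    def __len__(self) -> int:
        return len(self.masks)


def load_instances(
    sources: Sequence[str | Path] | Sequence[PolygonRecord],
    image_size: tuple[int, int],
    time: datetime | None = None,
) -> FrameObservation:
    """Assemble one frame's instances from mask files or polygon records.

    ``sources`` is either a list of mask raster paths (values thresholded at
    127 into {0, 255}) or a list of :class:`PolygonRecord`; polygons are
    denormalized against ``image_size = (width, height)`` and rasterized with
    filled interior. Instances keep source order. Zero sources yield an empty
    frame, not an error.
    """
    width, height = image_size
    masks: list[np.ndarray] = []
    for src in sources:
        if isinstance(src, PolygonRecord):
            masks.append(rasterize_polygon(src.to_pixels(width, height), width, height))
        else:
            arr = np.asarray(Image.open(src).convert("L"))
            if arr.shape != (height, width):
                raise ValueError(
                    f"raster {src} has shape {arr.shape}, declared image size "
                    f"is {height}x{width}"
                )
            masks.append(np.where(arr > 127, FOREGROUND, 0).astype(np.uint8))
    return FrameObservation(time=time, width=width, height=height, masks=masks)


def write_mask_image(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary mask as an 8-bit grayscale image at source resolution."""
    Image.fromarray(mask.astype(np.uint8), mode="L").save(path)


def write_results_csv(path: str | Path, rows: pd.DataFrame) -> None:
    """Write per-leaf results with the frozen column order and fixed
    floating-point formatting (so equal inputs give byte-identical files)."""
    df = rows.loc[:, RESULT_COLUMNS]
    df.to_csv(path, index=False, float_format="%.6f")
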