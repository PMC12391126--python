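"""Calibrated leaf area and growth-rate estimation.

A frame of width ``img_width_px`` pixels images a bench of physical width
``physical_width_mm`` (250 mm at the source setup), so each pixel covers

    PixelArea = (physical_width_mm / img_width_px)^2   [mm^2]

and a leaf whose mask holds SumPixel foreground pixels has

    LeafArea = PixelArea * SumPixel                    [mm^2].

The growth rate between two observations is the forward difference

    GrowthRate = (Area_now - Area_prev) / (t_now - t_prev)   [mm^2/h],

where the elapsed time comes from the frame timestamps; the window is not
restricted to consecutive frames. Small negative rates can occur when the
segmenter jitters and are reported as computed unless clamping is requested.
Pixels are assumed square, so the width calibration applies to both axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime

import numpy as np

from .io_formats import hours_between

GRID_LEAF_COUNT = 16


@dataclass(frozen=True)
class Calibration:
    """Pixel-to-physical scale: image width in pixels vs bench width in mm."""

    img_width_px: int = 1800
    physical_width_mm: float = 250.0

    def __post_init__(self) -> None:
        if self.img_width_px <= 0:
            raise ValueError(f"img_width_px must be positive, got {self.img_width_px}")
        if self.physical_width_mm <= 0:
            raise ValueError(
                f"physical_width_mm must be positive, got {self.physical_width_mm}"
            )


def pixel_area(cal: Calibration) -> float:
    """Physical area of one pixel in mm^2."""
    return (cal.physical_width_mm / cal.img_width_px) ** 2


def leaf_area(sum_pixel: int, cal: Calibration) -> float:
    """Physical area in mm^2 of a mask with ``sum_pixel`` foreground pixels."""
    if sum_pixel < 0:
        raise ValueError(f"pixel count must be non-negative, got {sum_pixel}")
    return pixel_area(cal) * sum_pixel


@dataclass
class AreaSeries:
    """Time-ordered (timestamp, area mm^2) observations of one leaf."""

    leaf_id: int
    points: list[tuple[datetime, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [t for t, _ in self.points]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("AreaSeries times must strictly increase")
        if any(a < 0 for _, a in self.points):
            raise ValueError("areas must be non-negative")


@dataclass
class RateSeries:
    """Time-ordered (timestamp, growth rate mm^2/h); each point is stamped
    with the end of its window."""

    leaf_id: int
    points: list[tuple[datetime, float]] = field(default_factory=list)


def growth_rate(
    series: AreaSeries, window: int = 1, clamp_negative: bool = False
) -> RateSeries:
    """Forward-difference growth rates over a sliding index window.

    ``window=1`` differences consecutive observations; ``window=k`` compares
    each observation with the one k steps earlier (any user-defined span).
    A series with fewer than window+1 points yields an empty result.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    pts = series.points
    rates: list[tuple[datetime, float]] = []
    for i in range(window, len(pts)):
        t0, a0 = pts[i - window]
        t1, a1 = pts[i]
        dt = hours_between(t0, t1)
        if dt <= 0:
            raise ValueError(f"non-positive elapsed time between {t0} and {t1}")
        r = (a1 - a0) / dt
        if clamp_negative and r < 0:
            r = 0.0
        rates.append((t1, r))
    return RateSeries(leaf_id=series.leaf_id, points=rates)


def area_series_from_tracks(tracks, cal: Calibration) -> list[AreaSeries]:
    """Convert tracked pixel counts into physical AreaSeries, one per leaf."""
    out = []
    for t in tracks:
        pts = [
            (time, leaf_area(inst.pixel_count, cal)) for time, inst in t.observations
        ]
        out.append(AreaSeries(leaf_id=t.leaf_id, points=pts))
    return out


def _value_at_or_before(points: list[tuple[datetime, float]], at: datetime):
    best = None
    for t, v in points:
        if t <= at:
            best = v
        else:
            break
    return best


def aggregate_box(
    series: list[AreaSeries] | list[RateSeries],
    at: datetime,
    grid_leaf_count: int = GRID_LEAF_COUNT,
) -> tuple[float, int]:
    """Mean over the planted grid leaves (IDs 0..grid_leaf_count-1) at a time.

    For each grid leaf the value at, or nearest before, ``at`` contributes;
    leaves with no observation yet are skipped. Returns (mean, contributor
    count); raises if no grid leaf has an observation by then. IDs beyond the
    grid range (late spurious tracks) are excluded.
    """
    values = []
    for s in series:
        if not 0 <= s.leaf_id < grid_leaf_count:
            continue
        v = _value_at_or_before(s.points, at)
        if v is not None:
            values.append(v)
    if not values:
        raise ValueError(f"no grid leaf has an observation at or before {at}")
    return float(np.mean(values)), len(values)
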