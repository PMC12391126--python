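"""Dataset construction: retention filtering, 70:20:10 splitting, and
seeded augmentation of images with matched polygon annotations.

The retention filter mirrors how a time-lapse germination dataset is
curated: frames from a leading window (no leaves out of the soil yet) and a
trailing window (heavy leaf overlap) are excluded, together with a flagged
set of quality failures (exposure anomalies, blur, environmental changes);
exclusions are set-union semantics, so a doubly-excluded frame is removed
once. Splitting shuffles with a seed and rounds train/validation sizes to
the nearest integer, with the remainder going to test — the convention that
maps 2707 items at 70:20:10 onto 1895/541/271.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import datetime
from typing import Callable, Sequence

import numpy as np
from PIL import Image
from shapely.geometry import Polygon as ShapelyPolygon, box as shapely_box
from skimage import color, filters

from .io_formats import parse_timestamp

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitRatios:
    train: float = 0.7
    val: float = 0.2
    test: float = 0.1

    def __post_init__(self) -> None:
        if min(self.train, self.val, self.test) < 0:
            raise ValueError("split ratios must be non-negative")
        if abs(self.train + self.val + self.test - 1.0) > 1e-9:
            raise ValueError(
                f"split ratios must sum to 1, got {self.train + self.val + self.test}"
            )


@dataclass(frozen=True)
class AugmentSpec:
    """Uniform sampling ranges for the augmentation transforms.

    rotation_deg : (lo, hi) degrees about the image center, default ±45.
    hue_deg : (lo, hi) hue shift in degrees, default ±180.
    brightness : (lo, hi) fractional brightness change, default ±0.9.
    blur_px : maximum blur kernel radius in pixels (Gaussian sigma is half
        of the sampled radius), default 5.7.
    noise_frac : maximum fraction of pixels hit by salt-and-pepper noise,
        default 0.0826.
    """

    rotation_deg: tuple[float, float] = (-45.0, 45.0)
    hue_deg: tuple[float, float] = (-180.0, 180.0)
    brightness: tuple[float, float] = (-0.9, 0.9)
    blur_px: float = 5.7
    noise_frac: float = 0.0826

    def __post_init__(self) -> None:
        for lo, hi in (self.rotation_deg, self.hue_deg, self.brightness):
            if lo > hi:
                raise ValueError(f"range ({lo}, {hi}) is inverted")
        if self.blur_px < 0 or self.noise_frac < 0:
            raise ValueError("blur_px and noise_frac must be non-negative")

    @classmethod
    def identity(cls) -> "AugmentSpec":
        """Degenerate spec whose transforms are all no-ops."""
        return cls(
            rotation_deg=(0.0, 0.0),
            hue_deg=(0.0, 0.0),
            brightness=(0.0, 0.0),
            blur_px=0.0,
            noise_frac=0.0,
        )


def filter_frames(
    frames: Sequence,
    exclude_before_h: float = 24.0,
    exclude_after_h: float = 48.0,
    quality_flags: set | None = None,
    timestamp: Callable = parse_timestamp,
) -> list:
    """Retain frames outside the exclusion windows and not quality-flagged.

    A frame is excluded when its time is strictly inside the leading window
    (t < t_first + exclude_before_h), strictly inside the trailing window
    (t > t_last - exclude_after_h), or in ``quality_flags``; the three
    exclusion sets are unioned. Survivors are returned in time order. A
    window configuration that excludes everything yields an empty list with
    a warning, not an error.
    """
    if not frames:
        return []
    flags = quality_flags or set()
    times = {f: timestamp(f) for f in frames}
    t0 = min(times.values())
    t1 = max(times.values())
    lead_s = exclude_before_h * 3600.0
    trail_s = exclude_after_h * 3600.0
    kept = [
        f
        for f in frames
        if f not in flags
        and (times[f] - t0).total_seconds() >= lead_s
        and (t1 - times[f]).total_seconds() >= trail_s
    ]
    if not kept:
        logger.warning("exclusion windows removed every frame")
    return sorted(kept, key=lambda f: times[f])


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_dataset(
    items: Sequence, ratios: SplitRatios | None = None, seed: int = 0
) -> tuple[list, list, list]:
    """Seeded shuffle followed by a nearest-integer 70:20:10 partition.

    Train and validation sizes round to the nearest integer; test takes the
    remainder, so the subsets are disjoint and exhaust the input.
    """
    ratios = ratios or SplitRatios()
    n = len(items)
    if n < 3:
        raise ValueError(f"need at least 3 items to split, got {n}")
    n_train = _round_half_up(n * ratios.train)
    n_val = _round_half_up(n * ratios.val)
    if n_train + n_val > n:
        n_val = n - n_train
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    shuffled = [items[i] for i in order]
    return (
        shuffled[:n_train],
        shuffled[n_train : n_train + n_val],
        shuffled[n_train + n_val :],
    )


def rotate_points(
    points: np.ndarray, angle_deg: float, center: tuple[float, float]
) -> np.ndarray:
    """Rotate (n, 2) pixel coordinates about ``center`` by ``angle_deg``."""
    a = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    c = np.asarray(center, dtype=float)
    return (np.asarray(points, dtype=float) - c) @ rot.T + c


def _rotate_image(image: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate an image about its center, same canvas size, matching the
    forward point map of :func:`rotate_points`."""
    h, w = image.shape[:2]
    cx, cy = w / 2.0, h / 2.0
    a = np.deg2rad(angle_deg)
    cos_a, sin_a = np.cos(a), np.sin(a)
    # PIL wants the inverse map: input coords as affine of output coords
    coeffs = (
        cos_a, sin_a, cx - cos_a * cx - sin_a * cy,
        -sin_a, cos_a, cy + sin_a * cx - cos_a * cy,
    )
    img = Image.fromarray(image)
    out = img.transform(
        (w, h), Image.AFFINE, coeffs, resample=Image.BILINEAR, fillcolor=0
    )
    return np.asarray(out)


def augment(
    image: np.ndarray,
    polygons: Sequence[Sequence[tuple[float, float]]],
    spec: AugmentSpec | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """One augmented copy of an image and its pixel-coordinate polygons.

    Rotation is applied identically to the image and the polygon vertices;
    hue, brightness, blur and salt-and-pepper noise touch the image only.
    All parameters are drawn uniformly within the spec ranges from one
    seeded generator. A polygon rotated entirely out of the frame is
    dropped with a warning. Degenerate (zero-width) ranges leave the image
    bit-identical.
    """
    spec = spec or AugmentSpec()
    rng = np.random.default_rng(seed)
    angle = float(rng.uniform(*spec.rotation_deg))
    hue = float(rng.uniform(*spec.hue_deg))
    brightness = float(rng.uniform(*spec.brightness))
    blur = float(rng.uniform(0.0, spec.blur_px))
    noise = float(rng.uniform(0.0, spec.noise_frac))

    out = np.asarray(image)
    h, w = out.shape[:2]
    frame_box = shapely_box(0, 0, w, h)
    center = (w / 2.0, h / 2.0)

    out_polys: list[np.ndarray] = []
    for i, poly in enumerate(polygons):
        pts = np.asarray(poly, dtype=float)
        if angle != 0.0:
            pts = rotate_points(pts, angle, center)
        if not ShapelyPolygon(pts).intersects(frame_box):
            logger.warning("polygon %d rotated fully out of frame; dropped", i)
            continue
        out_polys.append(pts)

    if angle != 0.0:
        out = _rotate_image(out, angle)
    if hue != 0.0 and out.ndim == 3:
        hsv = color.rgb2hsv(out)
        hsv[..., 0] = (hsv[..., 0] + hue / 360.0) % 1.0
        out = (color.hsv2rgb(hsv) * 255).round().clip(0, 255).astype(np.uint8)
    if brightness != 0.0:
        out = np.clip(out.astype(float) * (1.0 + brightness), 0, 255)
        out = out.round().astype(np.uint8)
    if blur > 0.0:
        blurred = filters.gaussian(
            out.astype(float), sigma=blur / 2.0, channel_axis=-1 if out.ndim == 3 else None
        )
        out = np.clip(blurred, 0, 255).round().astype(np.uint8)
    if noise > 0.0:
        n_pix = int(round(noise * h * w))
        ys = rng.integers(0, h, n_pix)
        xs = rng.integers(0, w, n_pix)
        vals = rng.integers(0, 2, n_pix) * 255
        out = out.copy()
        if out.ndim == 3:
            out[ys, xs, :] = vals[:, None]
        else:
            out[ys, xs] = vals
    return out, out_polys


def write_split_manifests(
    out_dir, train: Sequence, val: Sequence, test: Sequence
) -> None:
    """Write the three split manifests as plain text files of item names."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, subset in (("train", train), ("val", val), ("test", test)):
        (out / f"{name}.txt").write_text(
            "\n".join(str(i) for i in subset) + ("\n" if len(subset) else "")
        )
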