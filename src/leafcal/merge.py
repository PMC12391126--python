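"""Mask consolidation and contour refinement (the "Merge" stage).

Per-instance masks coming out of a segmentation model are refined
(edge extraction, periodic B-spline contour smoothing, morphological
closing), merged into one union raster for export, and summarised into
per-instance statistics (centroid, bounding box, pixel count) that the
tracking and calibration stages consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy import interpolate
from skimage import feature, measure, morphology

from .io_formats import FOREGROUND, rasterize_polygon


@dataclass(frozen=True)
class RefineParams:
    """Parameters of the contour-refinement pipeline.

    canny_low, canny_high : gradient thresholds of the Canny edge extractor
        on the 0-255 mask intensity scale (low < high).
    spline_smoothing : dimensionless factor; the periodic cubic spline is fit
        with smoothing proportional to contour length (0 interpolates).
    morph_kernel : odd diameter in pixels of the elliptical closing element.
    max_contour_points : contour is subsampled to at most this many points
        before spline fitting.
    """

    canny_low: float = 50.0
    canny_high: float = 150.0
    spline_smoothing: float = 1.0
    morph_kernel: int = 3
    max_contour_points: int = 200

    def __post_init__(self) -> None:
        if not self.canny_low < self.canny_high:
            raise ValueError("canny_low must be < canny_high")
        if self.morph_kernel < 1 or self.morph_kernel % 2 == 0:
            raise ValueError("morph_kernel must be odd and >= 1")
        if self.spline_smoothing < 0:
            raise ValueError("spline_smoothing must be non-negative")


@dataclass(frozen=True)
class InstanceMask:
    """One leaf instance: raster plus derived statistics.

    centroid is the unweighted mean of foreground pixel coordinates
    (Cx = mean column, Cy = mean row); bbox is the tight axis-aligned
    bound (x_min, y_min, x_max, y_max), inclusive.
    """

    raster: np.ndarray
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]
    pixel_count: int


def _check_binary(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {mask.shape}")
    return mask


def rasterize_and_resize(
    mask: np.ndarray, target_width: int, target_height: int
) -> np.ndarray:
    """Convert a mask to uint8 {0,255} and resize to the original image size.

    Nearest-neighbor interpolation preserves binarity exactly.
    """
    mask = _check_binary(mask)
    if target_width <= 0 or target_height <= 0:
        raise ValueError(
            f"target size must be positive, got {target_width}x{target_height}"
        )
    binary = np.where(mask > 127, FOREGROUND, 0).astype(np.uint8) if mask.dtype != bool \
        else np.where(mask, FOREGROUND, 0).astype(np.uint8)
    if binary.shape == (target_height, target_width):
        return binary
    img = Image.fromarray(binary, mode="L")
    out = img.resize((target_width, target_height), resample=Image.NEAREST)
    return np.asarray(out, dtype=np.uint8)


def merge_masks(instances: list[np.ndarray]) -> np.ndarray:
    """Overlay per-instance masks into one union raster.

    Accumulated values are thresholded so that every output pixel is exactly
    0 or 255; the foreground equals the set union of the input foregrounds.
    """
    if not instances:
        raise ValueError("merge_masks needs at least one mask")
    shape = instances[0].shape
    acc = np.zeros(shape, dtype=np.uint32)
    for m in instances:
        m = _check_binary(m)
        if m.shape != shape:
            raise ValueError(
                f"mask shape {m.shape} differs from first mask {shape}"
            )
        acc += (m > 0).astype(np.uint32)
    return np.where(acc > 0, FOREGROUND, 0).astype(np.uint8)


def _smooth_contour(contour: np.ndarray, params: RefineParams) -> np.ndarray:
    """Resample a closed (row, col) contour and smooth it with a periodic
    cubic spline; returns (x, y) vertices of the smoothed closed curve."""
    pts = contour[:-1] if np.allclose(contour[0], contour[-1]) else contour
    n = len(pts)
    if n > params.max_contour_points:
        idx = np.linspace(0, n - 1, params.max_contour_points).astype(int)
        pts = pts[np.unique(idx)]
        n = len(pts)
    if n < 5:  # too few points for a periodic cubic spline
        return pts[:, ::-1]
    y, x = pts[:, 0], pts[:, 1]
    # smoothing proportional to contour length, as a per-point residual budget
    seg = np.hypot(np.diff(x, append=x[0]), np.diff(y, append=y[0]))
    s = params.spline_smoothing * seg.sum() / max(n, 1)
    try:
        tck, _ = interpolate.splprep([x, y], s=s, per=True, quiet=2)
    except (ValueError, TypeError):
        return pts[:, ::-1]
    u = np.linspace(0, 1, 4 * max(n, 64), endpoint=False)
    xs, ys = interpolate.splev(u, tck)
    return np.column_stack([xs, ys])


def refine_mask(mask: np.ndarray, params: RefineParams | None = None) -> np.ndarray:
    """Refine a binary instance mask's boundary.

    Pipeline: Canny edge extraction locates the boundary; each closed
    contour is resampled and smoothed with a periodic cubic spline; the
    smoothed curves are refilled; finally a morphological closing (one
    dilation then one erosion with an elliptical element) removes pinholes.
    An empty mask is returned unchanged.
    """
    params = params or RefineParams()
    mask = _check_binary(mask)
    binary = mask > 127
    if not binary.any():
        return np.zeros_like(mask, dtype=np.uint8)
    # Canny gates the refinement: no detectable edges (degenerate speck)
    # means there is no contour to smooth.
    edges = feature.canny(
        mask.astype(np.uint8).astype(float),
        low_threshold=params.canny_low,
        high_threshold=params.canny_high,
    )
    contours = measure.find_contours(binary.astype(float), 0.5)
    if not edges.any() or not contours:
        out = binary
    else:
        h, w = mask.shape
        out = np.zeros((h, w), dtype=bool)
        for contour in contours:
            verts = _smooth_contour(contour, params)
            if len(verts) < 3:
                continue
            # find_contours coordinates are pixel indices; shift to the
            # pixel-center frame used by the rasterizer
            filled = rasterize_polygon(verts + 0.5, w, h)
            out |= filled > 0
        if not out.any():
            out = binary
    footprint = morphology.footprint_rectangle((params.morph_kernel,) * 2) \
        if params.morph_kernel <= 3 else morphology.disk(params.morph_kernel // 2)
    # closing = one dilation then one erosion
    out = morphology.closing(out, footprint)
    return np.where(out, FOREGROUND, 0).astype(np.uint8)


def extract_instance_stats(mask: np.ndarray) -> InstanceMask:
    """Compute centroid, tight bounding box and pixel count of one mask.

    Raises ``ValueError`` on an empty mask (no instance present).
    """
    mask = _check_binary(mask)
    ys, xs = np.nonzero(mask > 127)
    if len(xs) == 0:
        raise ValueError("empty mask: no instance present")
    return InstanceMask(
        raster=np.where(mask > 127, FOREGROUND, 0).astype(np.uint8),
        centroid=(float(xs.mean()), float(ys.mean())),
        bbox=(int(xs.min()), int(ys.min()), int(xs.max()), int(ys.max())),
        pixel_count=int(len(xs)),
    )
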