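"""Synthetic growing-leaf scenes with exact analytic ground truth.

The generator emulates an incubator time-lapse experiment: a 4x4 grid of
leaves imaged from above at a fixed interval over a ~156 h window, with
growth following a logistic curve and a salt-stress treatment that scales
both the asymptotic leaf size and the growth rate through a concentration-
dependent inhibition multiplier f(c) in (0, 1], f(0) = 1 for the deionized-
water control (CK) and strictly decreasing in c.

Each leaf is drawn as an analytic closed curve (a jittered ellipse) whose
target area tracks the growth model, so the true area is known exactly and
rasterization is the only source of error. Boundary jitter is a sum of
zero-mean low-order harmonics, which preserves area to first order while
giving the contour-refinement stage something to smooth. Scenes are fully
determined by the spec and its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from .io_formats import FOREGROUND, FrameObservation, rasterize_polygon
from .phenotype import Calibration, pixel_area

#: NaCl treatment levels in mmol/L; 0 is the deionized-water control (CK).
DEFAULT_CONCENTRATIONS = (0, 10, 20, 30, 40, 50, 60)


@dataclass(frozen=True)
class GrowthModel:
    """Logistic leaf growth: area(t) = A_max / (1 + exp(-rate*(t - midpoint)))."""

    a_max_mm2: float = 1200.0
    rate_per_h: float = 0.04
    midpoint_h: float = 120.0

    def __post_init__(self) -> None:
        if self.a_max_mm2 <= 0 or self.rate_per_h <= 0:
            raise ValueError("a_max_mm2 and rate_per_h must be positive")


def inhibition_multiplier(concentration_mmol: float, k: float = 0.008) -> float:
    """Concentration-dependent growth inhibition f(c) = exp(-k*c).

    f(0) = 1 (control) and f is strictly decreasing in c; it scales both the
    asymptotic area and the logistic rate.
    """
    if concentration_mmol < 0 or k <= 0:
        raise ValueError("concentration must be >= 0 and k > 0")
    return math.exp(-k * concentration_mmol)


def leaf_area_at(
    t_h: float, growth: GrowthModel, inhibition: float = 1.0
) -> float:
    """Analytic leaf area (mm^2) at elapsed time ``t_h`` hours.

    Under inhibition f the curve is f*A_max / (1 + exp(-rate*(f*t - midpoint))):
    salt stress caps the final size, slows the effective growth rate
    (d/dt enters as rate*f) and correspondingly delays the midpoint, so the
    stressed curve lies strictly below the control at every time — scaling
    the rate about a fixed midpoint instead would make early stressed leaves
    larger than control, which contradicts the dose response being emulated.
    """
    if not 0.0 < inhibition <= 1.0:
        raise ValueError(f"inhibition multiplier must be in (0, 1], got {inhibition}")
    g = growth
    z = -g.rate_per_h * (inhibition * t_h - g.midpoint_h)
    return inhibition * g.a_max_mm2 / (1.0 + math.exp(z))


def schedule_frames(
    window_h: tuple[float, float],
    interval_min: float,
    start_time: datetime = datetime(2025, 3, 1, 0, 0, 0),
) -> list[datetime]:
    """Capture timestamps on the half-open window [start_h, end_h).

    Frames fall at start_h, start_h + dt, ... strictly before end_h, so a
    156 h window at 15-minute intervals yields exactly 624 frames.
    """
    start_h, end_h = window_h
    if interval_min <= 0:
        raise ValueError(f"interval must be positive, got {interval_min}")
    if not start_h < end_h:
        raise ValueError(f"window start {start_h} must precede end {end_h}")
    n = int(math.ceil((end_h - start_h) * 60.0 / interval_min - 1e-9))
    return [
        start_time + timedelta(hours=start_h, minutes=i * interval_min)
        for i in range(n)
    ]


@dataclass(frozen=True)
class SceneSpec:
    """Description of one synthetic incubator experiment.

    Defaults reproduce the source experiment's geometry and schedule: a 4x4
    grid in an 1800x1850 px frame calibrated at 250 mm physical width,
    imaged every 15 minutes from 36 h to 192 h (156 h, 624 frames), with
    logistic growth reaching ~1.05e3 mm^2 by day 7 for the control.
    """

    rows: int = 4
    cols: int = 4
    img_width_px: int = 1800
    img_height_px: int = 1850
    physical_width_mm: float = 250.0
    frame_interval_min: float = 15.0
    window_h: tuple[float, float] = (36.0, 192.0)
    growth: GrowthModel = field(default_factory=GrowthModel)
    concentration_mmol: float = 0.0
    inhibition_k: float = 0.008
    leaf_param_jitter: float = 0.05
    boundary_jitter: float = 0.02
    n_boundary_points: int = 180
    aspect: float = 0.85
    center_jitter_frac: float = 0.05
    allow_occlusion: bool = False
    start_time: datetime = datetime(2025, 3, 1, 0, 0, 0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must be at least 1x1")
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be positive")
        if not self.window_h[0] < self.window_h[1]:
            raise ValueError("window start must precede end")
        if not 0 < self.aspect <= 1:
            raise ValueError("aspect must be in (0, 1]")

    @property
    def calibration(self) -> Calibration:
        return Calibration(
            img_width_px=self.img_width_px, physical_width_mm=self.physical_width_mm
        )

    @property
    def n_leaves(self) -> int:
        return self.rows * self.cols

    @property
    def inhibition(self) -> float:
        return inhibition_multiplier(self.concentration_mmol, self.inhibition_k)

    def with_concentration(self, c: float) -> "SceneSpec":
        return replace(self, concentration_mmol=c)


@dataclass
class GroundTruth:
    """Analytic per-frame truth emitted alongside the rendered masks.

    ``table`` holds one row per (frame_time, leaf_id) with the analytic area
    in mm^2, the drawn centroid, and the rendered pixel count; ``frame_ids``
    gives, per frame, the true leaf id of each mask in mask order (masks are
    emitted in randomized order to keep tracking honest).
    """

    table: pd.DataFrame
    frame_ids: list[list[int]]


@dataclass
class _LeafParams:
    a_max_mm2: float
    rate_per_h: float
    midpoint_h: float
    center: tuple[float, float]
    orientation: float
    harmonics: np.ndarray  # (k, amplitude, phase) rows


def _draw_leaf_params(spec: SceneSpec, rng: np.random.Generator) -> list[_LeafParams]:
    pitch_x = spec.img_width_px / spec.cols
    pitch_y = spec.img_height_px / spec.rows
    leaves = []
    for r in range(spec.rows):
        for c in range(spec.cols):
            jit = spec.leaf_param_jitter
            a_max = spec.growth.a_max_mm2 * (1 + jit * rng.standard_normal())
            rate = spec.growth.rate_per_h * (1 + jit * rng.standard_normal())
            midpoint = spec.growth.midpoint_h + 12.0 * jit * rng.standard_normal()
            cx = (c + 0.5) * pitch_x + rng.uniform(-1, 1) * spec.center_jitter_frac * pitch_x
            cy = (r + 0.5) * pitch_y + rng.uniform(-1, 1) * spec.center_jitter_frac * pitch_y
            ks = np.arange(3, 7)
            amps = spec.boundary_jitter * rng.uniform(0.3, 1.0, size=len(ks)) / len(ks)
            phases = rng.uniform(0, 2 * np.pi, size=len(ks))
            leaves.append(
                _LeafParams(
                    a_max_mm2=max(a_max, 0.1 * spec.growth.a_max_mm2),
                    rate_per_h=max(rate, 0.1 * spec.growth.rate_per_h),
                    midpoint_h=midpoint,
                    center=(cx, cy),
                    orientation=rng.uniform(0, 2 * np.pi),
                    harmonics=np.column_stack([ks, amps, phases]),
                )
            )
    return leaves


def _check_collisions(spec: SceneSpec, leaves: list[_LeafParams]) -> None:
    px_area = pixel_area(spec.calibration)
    pitch = min(spec.img_width_px / spec.cols, spec.img_height_px / spec.rows)
    margin = 1.0 + spec.boundary_jitter + 2 * spec.center_jitter_frac
    for leaf in leaves:
        final_px = spec.inhibition * leaf.a_max_mm2 / px_area
        semi_major = math.sqrt(final_px / (math.pi * spec.aspect))
        if 2 * semi_major * margin > pitch:
            raise ValueError(
                "leaf asymptote too large for the grid pitch: semi-major axis "
                f"{semi_major:.1f} px cannot fit pitch {pitch:.1f} px without "
                "occlusion; shrink a_max_mm2, enlarge the frame, or set "
                "allow_occlusion=True"
            )


def _render_leaf_mask(
    leaf: _LeafParams,
    area_px: float,
    spec: SceneSpec,
) -> tuple[np.ndarray, tuple[float, float]]:
    n = spec.n_boundary_points
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    aspect = spec.aspect
    # ellipse with area pi*a*b = area_px, b = aspect*a
    a = math.sqrt(area_px / (math.pi * aspect))
    b = aspect * a
    r_ell = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    jitter = np.zeros_like(theta)
    for k, amp, phase in leaf.harmonics:
        jitter += amp * np.cos(k * theta + phase)
    r = r_ell * (1.0 + jitter)
    # exact polygon-area renormalization: scale radii so that the discrete
    # shoelace area of the polygon equals area_px
    phi = theta + leaf.orientation
    xs = r * np.cos(phi)
    ys = r * np.sin(phi)
    shoelace = 0.5 * abs(
        np.sum(xs * np.roll(ys, -1) - np.roll(xs, -1) * ys)
    )
    scale = math.sqrt(area_px / shoelace)
    verts = np.column_stack([xs, ys]) * scale + np.asarray(leaf.center)
    mask = rasterize_polygon(verts, spec.img_width_px, spec.img_height_px)
    return mask, leaf.center


def render_frame_image(
    masks: list[np.ndarray], spec: SceneSpec, rng: np.random.Generator
) -> np.ndarray:
    """RGB frame: soil-like noisy background with green leaves on top.

    The color margin between leaf and background is wide enough for a
    classical threshold-plus-connected-components segmenter to recover the
    masks, enabling detector-free end-to-end tests.
    """
    h, w = spec.img_height_px, spec.img_width_px
    base = np.array([118, 86, 60], dtype=float)
    img = base + rng.normal(0, 8, size=(h, w, 3))
    leaf_color = np.array([46, 142, 52], dtype=float)
    for mask in masks:
        fg = mask > 127
        img[fg] = leaf_color + rng.normal(0, 6, size=(int(fg.sum()), 3))
    return np.clip(img, 0, 255).astype(np.uint8)


def render_scene(
    spec: SceneSpec,
    n_frames: int | None = None,
    include_images: bool = False,
) -> tuple[list[FrameObservation], GroundTruth, list[np.ndarray]]:
    """Render the scene: per-frame instance masks plus analytic ground truth.

    Masks within a frame are emitted in a seeded random order (real
    detectors do not sort their output). ``n_frames`` truncates the
    schedule, which is how tests and demos keep runtimes small; images are
    rendered only on request.

    Returns (frames, ground_truth, images); ``images`` is empty unless
    ``include_images``.
    """
    rng = np.random.default_rng(spec.seed)
    leaves = _draw_leaf_params(spec, rng)
    if not spec.allow_occlusion:
        _check_collisions(spec, leaves)
    times = schedule_frames(
        spec.window_h, spec.frame_interval_min, start_time=spec.start_time
    )
    if n_frames is not None:
        times = times[:n_frames]
    px_area = pixel_area(spec.calibration)
    f = spec.inhibition
    frames: list[FrameObservation] = []
    images: list[np.ndarray] = []
    frame_ids: list[list[int]] = []
    rows = []
    t0 = spec.start_time
    for time in times:
        t_h = (time - t0).total_seconds() / 3600.0
        order = rng.permutation(spec.n_leaves)
        masks = []
        ids = []
        for leaf_id in order:
            leaf = leaves[leaf_id]
            area_mm2 = leaf_area_at(
                t_h,
                GrowthModel(leaf.a_max_mm2, leaf.rate_per_h, leaf.midpoint_h),
                f,
            )
            area_px = area_mm2 / px_area
            mask, center = _render_leaf_mask(leaf, area_px, spec)
            masks.append(mask)
            ids.append(int(leaf_id))
            rows.append(
                {
                    "frame_time": time,
                    "leaf_id": int(leaf_id),
                    "area_mm2": area_mm2,
                    "Cx": center[0],
                    "Cy": center[1],
                    "pixel_count": int((mask > 127).sum()),
                }
            )
        frame = FrameObservation(
            time=time, width=spec.img_width_px, height=spec.img_height_px, masks=masks
        )
        frames.append(frame)
        frame_ids.append(ids)
        if include_images:
            images.append(render_frame_image(masks, spec, rng))
    table = pd.DataFrame(
        rows, columns=["frame_time", "leaf_id", "area_mm2", "Cx", "Cy", "pixel_count"]
    )
    gt = GroundTruth(table=table, frame_ids=frame_ids)
    return frames, gt, images
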