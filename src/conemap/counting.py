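"""Retina-level density estimation: global, counting-frame, and sampled.

Three regimes mirror standard practice for photoreceptor quantification:

* **global** — every accepted field of the full acquisition grid is
  counted and densities averaged (cones per 0.0376 mm² field);
* **automated stereological** — a draughtboard (checkerboard) subset of
  fields, each counted inside an unbiased 30 x 30 µm counting frame with
  two forbidden edges, so each cell is counted exactly once across a
  tiling of frames;
* **systematic random sampling** — 50-80 non-overlapping 1,225 µm² fields
  placed on a randomly offset lattice within 2 mm of the optic nerve
  head, emulating classical manual stereology's sampling scheme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .acquisition import AcquisitionConfig
from .detection import FieldResult, SpotObject

__all__ = [
    "CountingFrame",
    "SamplingPlan",
    "DensitySummary",
    "global_density",
    "frame_count",
    "stereo_automated_density",
    "systematic_random_sample",
]

FRAME_SIDE_UM = 30.0
SRS_FIELD_SIDE_UM = 35.0  # 35 x 35 µm = 1,225 µm²
SRS_RADIUS_UM = 2000.0


@dataclass(frozen=True)
class CountingFrame:
    """Unbiased counting frame: 30 x 30 µm, centered in the field.

    Objects touching the two forbidden edges (left X axis and top Y axis)
    are excluded; objects touching only the permitted right/bottom edges
    are counted. Under a tiling of such frames every object is counted
    exactly once.
    """

    width_um: float = FRAME_SIDE_UM
    height_um: float = FRAME_SIDE_UM

    def pixel_rect(self, acq: AcquisitionConfig) -> tuple[float, float, float, float]:
        """(x0, y0, x1, y1) of the centered frame in field pixel coords."""
        if self.width_um > acq.field_width_um or self.height_um > acq.field_height_um:
            raise ValueError("counting frame larger than the camera field")
        w_px = self.width_um / acq.pixel_size_x_um
        h_px = self.height_um / acq.pixel_size_y_um
        x0 = (acq.width_px - w_px) / 2.0
        y0 = (acq.height_px - h_px) / 2.0
        return (x0, y0, x0 + w_px, y0 + h_px)

    @property
    def area_um2(self) -> float:
        return self.width_um * self.height_um


@dataclass(frozen=True)
class SamplingPlan:
    """Systematic-random-sampling design for manual-style stereology."""

    n_fields_min: int = 50
    n_fields_max: int = 80
    field_side_um: float = SRS_FIELD_SIDE_UM
    sampling_radius_um: float = SRS_RADIUS_UM
    seed: int = 0

    @property
    def field_area_um2(self) -> float:
        return self.field_side_um**2


@dataclass
class DensitySummary:
    """Density estimate over counted fields, with the exclusion tally."""

    n_fields_counted: int
    n_fields_excluded: int
    mean_density: float  # cones per reference area
    total_count: int
    field_area_mm2: float

    def density_per_mm2(self) -> float:
        return self.mean_density / self.field_area_mm2


def global_density(results: list[FieldResult]) -> DensitySummary:
    """Mean per-field count over accepted fields (global automated method).

    Excluded fields contribute to neither the numerator nor the
    denominator. Raises ``ValueError`` when no field was accepted, rather
    than reporting a spurious density of zero.
    """
    accepted = [r for r in results if r.accepted]
    n_excluded = len(results) - len(accepted)
    if not accepted:
        raise ValueError("no accepted fields: cannot estimate a density")
    counts = np.array([r.count for r in accepted], dtype=float)
    return DensitySummary(
        n_fields_counted=len(accepted),
        n_fields_excluded=n_excluded,
        mean_density=float(counts.mean()),
        total_count=int(counts.sum()),
        field_area_mm2=accepted[0].field_area_mm2,
    )


def _object_in_frame(
    coords: np.ndarray, rect: tuple[float, float, float, float]
) -> tuple[bool, bool]:
    """(intersects frame, touches the exclusion line) for a pixel footprint.

    Pixel (r, c) occupies the unit square [c, c+1) x [r, r+1). The
    exclusion line is the classical unbiased-frame polyline built on the
    two forbidden (left X and top Y) axes: the left edge extended
    infinitely downward, the top edge, and the extension rising from the
    top-right corner. Only with these extensions is each object counted
    exactly once across a tiling of frames (a bare two-segment rule
    double-counts corner-crossing objects and misses diagonal
    corner-cutters).
    """
    x0, y0, x1, y1 = rect
    cols = coords[:, 1].astype(float)
    rows = coords[:, 0].astype(float)
    inter = (cols + 1 > x0) & (cols < x1) & (rows + 1 > y0) & (rows < y1)
    if not inter.any():
        return False, False
    straddle_left = (cols < x0) & (cols + 1 > x0)
    straddle_right = (cols < x1) & (cols + 1 > x1)
    straddle_top = (rows < y0) & (rows + 1 > y0)
    touch = (
        bool((straddle_left & (rows + 1 > y0)).any())  # left edge + down ext
        or bool((straddle_top & (cols + 1 > x0) & (cols < x1)).any())  # top edge
        or bool((straddle_right & (rows < y0)).any())  # up ext, top-right
    )
    return True, touch


def frame_count(
    objects: list[SpotObject],
    frame: CountingFrame,
    acq: AcquisitionConfig | None = None,
    rect: tuple[float, float, float, float] | None = None,
) -> int:
    """Count COUNTED objects inside the frame under the forbidden-edge rule.

    An object is counted when its pixel footprint intersects the frame and
    does not touch the left or top (forbidden) edge; objects touching only
    the right or bottom (permitted) edges are counted. Excluded objects
    are marked ``EXCLUDED_FRAME`` in place.
    """
    if rect is None:
        acq = acq or AcquisitionConfig()
        rect = frame.pixel_rect(acq)
    n = 0
    for obj in objects:
        if obj.status != "COUNTED":
            continue
        if obj.coords is None:
            raise ValueError("frame counting requires object pixel footprints")
        inter, forbidden = _object_in_frame(obj.coords, rect)
        if not inter:
            continue
        if forbidden:
            obj.status = "EXCLUDED_FRAME"
        else:
            n += 1
    return n


def stereo_automated_density(
    results: list[FieldResult],
    frame: CountingFrame = CountingFrame(),
    acq: AcquisitionConfig | None = None,
) -> tuple[DensitySummary, DensitySummary]:
    """Automated stereological estimate on draughtboard fields.

    Each accepted field contributes its counting-frame tally. Returns two
    summaries of the same data: densities per frame area (900 µm²) and
    rescaled to per-field-area units, since either convention is found in
    practice.
    """
    acq = acq or AcquisitionConfig()
    accepted = [r for r in results if r.accepted]
    n_excluded = len(results) - len(accepted)
    if not accepted:
        raise ValueError("no accepted fields: cannot estimate a density")
    rect = frame.pixel_rect(acq)
    counts = np.array(
        [frame_count(r.objects, frame, acq=acq, rect=rect) for r in accepted],
        dtype=float,
    )
    per_frame = DensitySummary(
        n_fields_counted=len(accepted),
        n_fields_excluded=n_excluded,
        mean_density=float(counts.mean()),
        total_count=int(counts.sum()),
        field_area_mm2=frame.area_um2 * 1e-6,
    )
    scale = acq.field_area_mm2 / (frame.area_um2 * 1e-6)
    per_field = DensitySummary(
        n_fields_counted=len(accepted),
        n_fields_excluded=n_excluded,
        mean_density=float(counts.mean()) * scale,
        total_count=int(counts.sum()),
        field_area_mm2=acq.field_area_mm2,
    )
    return per_frame, per_field


def systematic_random_sample(
    mask_test,
    optic_center: tuple[float, float],
    plan: SamplingPlan = SamplingPlan(),
) -> list[tuple[float, float, float, float]]:
    """Systematic random sampling of 1,225 µm² fields within 2 mm.

    A square lattice with a seeded random start offset is laid over the
    sampling disc; lattice cells whose 35 x 35 µm field falls entirely
    inside ``mask ∩ disc`` are kept. The stride is chosen so the yield
    lands in [n_fields_min, n_fields_max]; if the mask is too small to fit
    ``n_fields_min`` fields the error names the achievable maximum.

    ``mask_test(x0, y0, x1, y1) -> bool`` decides tissue membership of a
    field rectangle (µm). Returns field rectangles ``(x0, y0, x1, y1)``.
    """
    rng = np.random.default_rng(plan.seed)
    cx, cy = optic_center
    R = plan.sampling_radius_um
    side = plan.field_side_um
    n_target = (plan.n_fields_min + plan.n_fields_max) // 2
    stride = float(math.ceil(math.sqrt(math.pi * R * R / n_target)))
    offset = rng.uniform(0.0, stride, size=2)

    def fields_for(stride: float) -> list[tuple[float, float, float, float]]:
        out = []
        n_steps = int(math.ceil(2 * R / stride)) + 2
        for i in range(-n_steps, n_steps + 1):
            for j in range(-n_steps, n_steps + 1):
                x0 = cx + offset[0] + i * stride - side / 2.0
                y0 = cy + offset[1] + j * stride - side / 2.0
                x1, y1 = x0 + side, y0 + side
                corners = [(x0, y0), (x1, y0), (x0, y1), (x1, y1)]
                if any(
                    (px - cx) ** 2 + (py - cy) ** 2 > R * R for px, py in corners
                ):
                    continue
                if not mask_test(x0, y0, x1, y1):
                    continue
                out.append((x0, y0, x1, y1))
        return out

    best = fields_for(stride)
    # adjust the stride when edge effects push the yield out of range
    for _ in range(20):
        if plan.n_fields_min <= len(best) <= plan.n_fields_max:
            return best
        if len(best) > plan.n_fields_max:
            stride *= 1.08
        else:
            stride /= 1.08
        if stride <= side:
            break
        best = fields_for(stride)
    if plan.n_fields_min <= len(best) <= plan.n_fields_max:
        return best
    if len(best) < plan.n_fields_min:
        raise ValueError(
            f"mask too small for systematic sampling: at most {len(best)} "
            f"fields fit, {plan.n_fields_min} required"
        )
    return best[: plan.n_fields_max]
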