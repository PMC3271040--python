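"""Acquisition geometry: field grids, two-stage autofocus and stack file I/O.

The acquisition model mirrors a motorized epifluorescence stage scanning a
flat-mounted retina: an axis-aligned grid of ~300 camera fields covers the
tissue, each field is focused in two passes (a coarse 6-plane scan at 60 µm
increments, then a fine 8-plane scan at 15 µm), and a 9-plane Z-stack spaced
0.7 µm is captured around the focal position and written as a multi-page
16-bit TIFF.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass, field as _dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "AcquisitionConfig",
    "AutofocusConfig",
    "FieldCoordinate",
    "AcquisitionGrid",
    "ZStack",
    "CAMERA_PRESETS",
    "build_grid",
    "two_stage_autofocus",
    "focus_metric_variance",
    "write_stack",
    "read_stack",
    "write_index",
    "read_index",
]


# CCD field dimensions in µm at the 40X objective, per camera model.
CAMERA_PRESETS = {
    "coolsnap_fx": (217.75, 172.53),
    "coolsnap_hq": (224.46, 167.70),
}


@dataclass(frozen=True)
class AcquisitionConfig:
    """Camera and stack geometry for one acquisition run.

    Defaults describe a CoolSNAP FX frame: 650 x 515 pixels covering
    217.75 x 172.53 µm, nine Z planes spaced 0.7 µm, 16-bit depth.
    """

    n_planes: int = 9
    plane_spacing_um: float = 0.7
    width_px: int = 650
    height_px: int = 515
    field_width_um: float = 217.75
    field_height_um: float = 172.53
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.n_planes % 2 != 1 or self.n_planes < 1:
            raise ValueError("n_planes must be a positive odd integer")
        if self.plane_spacing_um <= 0:
            raise ValueError("plane_spacing_um must be > 0")
        if self.field_width_um <= 0 or self.field_height_um <= 0:
            raise ValueError("field dimensions must be > 0")

    @classmethod
    def from_camera(cls, camera: str, **overrides) -> "AcquisitionConfig":
        try:
            w, h = CAMERA_PRESETS[camera]
        except KeyError:
            raise ValueError(
                f"unknown camera {camera!r}; choose from {sorted(CAMERA_PRESETS)}"
            ) from None
        return cls(field_width_um=w, field_height_um=h, **overrides)

    @property
    def pixel_size_x_um(self) -> float:
        return self.field_width_um / self.width_px

    @property
    def pixel_size_y_um(self) -> float:
        return self.field_height_um / self.height_px

    @property
    def field_area_mm2(self) -> float:
        """Field area in mm² (full precision; display rounds to 4 decimals)."""
        return self.field_width_um * self.field_height_um * 1e-6

    @property
    def plane_offsets_um(self) -> np.ndarray:
        """Symmetric plane offsets about the focal position."""
        half = self.n_planes // 2
        return np.arange(-half, half + 1) * self.plane_spacing_um


@dataclass(frozen=True)
class AutofocusConfig:
    """Two-stage autofocus schedule: coarse scan then fine refinement."""

    coarse_n: int = 6
    coarse_step_um: float = 60.0
    fine_n: int = 8
    fine_step_um: float = 15.0
    focus_metric: str = "variance"

    def __post_init__(self) -> None:
        if self.coarse_step_um <= 0 or self.fine_step_um <= 0:
            raise ValueError("autofocus steps must be > 0")
        if self.coarse_step_um <= self.fine_step_um:
            raise ValueError("coarse_step_um must exceed fine_step_um")


@dataclass(frozen=True)
class FieldCoordinate:
    """Stage position (µm) and grid indices of one camera field.

    ``x_um, y_um`` locate the field's top-left corner; ``z_um`` the recorded
    focal position. Row index grows downward (ventral), column rightward.
    """

    x_um: float
    y_um: float
    z_um: float
    row: int
    col: int

    def center(self, acq: AcquisitionConfig) -> tuple[float, float]:
        return (
            self.x_um + acq.field_width_um / 2.0,
            self.y_um + acq.field_height_um / 2.0,
        )

    def rect(self, acq: AcquisitionConfig) -> tuple[float, float, float, float]:
        """(x0, y0, x1, y1) bounds of the field in µm."""
        return (
            self.x_um,
            self.y_um,
            self.x_um + acq.field_width_um,
            self.y_um + acq.field_height_um,
        )


@dataclass
class AcquisitionGrid:
    fields: list[FieldCoordinate]
    mode: str  # "full" | "draughtboard"
    acq: AcquisitionConfig

    def __len__(self) -> int:
        return len(self.fields)

    @property
    def field_area_mm2(self) -> float:
        return self.acq.field_area_mm2


@dataclass
class ZStack:
    """One field's 9-plane image stack (n_planes x height x width, uint16)."""

    pixels: np.ndarray
    field: FieldCoordinate
    plane_offsets_um: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3:
            raise ValueError("stack pixels must be 3-D (planes, height, width)")
        if self.pixels.dtype != np.uint16:
            raise ValueError("stack pixels must be uint16")
        if self.pixels.shape[0] != len(self.plane_offsets_um):
            raise ValueError("page count must equal number of plane offsets")

    @property
    def n_planes(self) -> int:
        return self.pixels.shape[0]


def build_grid(
    mask_bounds: tuple[float, float, float, float],
    acq: AcquisitionConfig,
    mode: str = "full",
    mask_test=None,
) -> AcquisitionGrid:
    """Construct the acquisition grid over a bounding box.

    Parameters
    ----------
    mask_bounds : (x0, y0, x1, y1) µm bounds of the tissue.
    mode : "full" for every intersecting cell, "draughtboard" for the
        checkerboard subset with (row + col) even.
    mask_test : optional callable ``f(x0, y0, x1, y1) -> bool`` deciding
        whether a grid cell intersects the tissue (e.g. a disk test);
        when omitted every cell within the bounds is kept.
    """
    x0, y0, x1, y1 = mask_bounds
    if not (x1 > x0 and y1 > y0):
        raise ValueError("empty mask bounds")
    if mode not in ("full", "draughtboard"):
        raise ValueError(f"unknown grid mode {mode!r}")

    n_cols = max(1, math.ceil((x1 - x0) / acq.field_width_um - 1e-9))
    n_rows = max(1, math.ceil((y1 - y0) / acq.field_height_um - 1e-9))
    fields = []
    for r in range(n_rows):
        for c in range(n_cols):
            if mode == "draughtboard" and (r + c) % 2 != 0:
                continue
            fx = x0 + c * acq.field_width_um
            fy = y0 + r * acq.field_height_um
            if mask_test is not None and not mask_test(
                fx, fy, fx + acq.field_width_um, fy + acq.field_height_um
            ):
                continue
            fields.append(FieldCoordinate(fx, fy, 0.0, r, c))
    return AcquisitionGrid(fields=fields, mode=mode, acq=acq)


def focus_metric_variance(image: np.ndarray) -> float:
    """Intensity variance as the sharpness score.

    Exactly invariant to adding a constant to all pixels (a stray
    brightness offset must not move the focus), and monotone under the
    simulator's defocus blur. A constant image scores 0.
    """
    img = np.asarray(image, dtype=np.float64)
    return float(img.var())


def two_stage_autofocus(
    render_plane,
    z_start: float,
    af: AutofocusConfig = AutofocusConfig(),
) -> tuple[float, bool]:
    """Recover the focal plane in a coarse-then-fine scan.

    ``render_plane(z)`` must return the image observed at focal position z.
    Stage 1 probes ``coarse_n`` planes spaced ``coarse_step_um`` centered on
    ``z_start`` and keeps the argmax of the focus metric; stage 2 probes
    ``fine_n`` planes spaced ``fine_step_um`` around that position and
    returns its argmax. Ties resolve to the lowest z (deterministic).

    Returns ``(z_best, tie_flag)``; ``tie_flag`` is True when the metric was
    constant across all probed planes (featureless field), in which case
    ``z_best == z_start``.
    """

    def scan(center: float, n: int, step: float) -> tuple[float, bool]:
        lo = -(n // 2)
        zs = [center + (lo + i) * step for i in range(n)]
        scores = [focus_metric_variance(render_plane(z)) for z in zs]
        if max(scores) == min(scores):
            return center, True
        best = int(np.argmax(scores))  # argmax takes first (lowest z) on ties
        return zs[best], False

    z1, tie1 = scan(z_start, af.coarse_n, af.coarse_step_um)
    if tie1:
        return z_start, True
    z2, tie2 = scan(z1, af.fine_n, af.fine_step_um)
    if tie2:
        return z1, False
    return z2, False


def _stack_filename(index: int, date: _dt.date | None = None) -> str:
    d = date or _dt.date.today()
    return f"{d:%Y%m%d}_{index:04d}.tif"


def write_stack(
    stack: ZStack,
    directory: str | Path,
    index: int,
    date: _dt.date | None = None,
) -> Path:
    """Write a stack as a multi-page 16-bit grayscale TIFF.

    Filename is ``YYYYMMDD_<zero-padded index>.tif``; stage coordinates are
    stored in the TIFF description as JSON so ``read_stack`` round-trips
    bit-identically.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / _stack_filename(index, date)
    meta = {
        "x_um": stack.field.x_um,
        "y_um": stack.field.y_um,
        "z_um": stack.field.z_um,
        "row": stack.field.row,
        "col": stack.field.col,
        "plane_offsets_um": [float(o) for o in stack.plane_offsets_um],
    }
    tifffile.imwrite(
        path,
        stack.pixels,
        photometric="minisblack",
        description=json.dumps(meta),
    )
    return path


def read_stack(path: str | Path, expected_planes: int | None = None) -> ZStack:
    """Read a multi-page TIFF stack written by :func:`write_stack`.

    Raises ``ValueError`` naming the file when the page count or bit depth
    violates the stack format.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        pixels = tf.asarray()
        desc = tf.pages[0].description
    if pixels.ndim == 2:
        pixels = pixels[None]
    if pixels.dtype != np.uint16:
        raise ValueError(f"{path}: expected 16-bit pages, got {pixels.dtype}")
    if expected_planes is not None and pixels.shape[0] != expected_planes:
        raise ValueError(
            f"{path}: expected {expected_planes} pages, found {pixels.shape[0]}"
        )
    try:
        meta = json.loads(desc)
    except (TypeError, json.JSONDecodeError):
        raise ValueError(f"{path}: missing or invalid stack metadata") from None
    fc = FieldCoordinate(
        meta["x_um"], meta["y_um"], meta["z_um"], meta["row"], meta["col"]
    )
    offsets = np.asarray(meta["plane_offsets_um"], dtype=float)
    if offsets.shape[0] != pixels.shape[0]:
        raise ValueError(f"{path}: plane offset count does not match page count")
    return ZStack(pixels=pixels, field=fc, plane_offsets_um=offsets)


def write_index(
    fields: list[FieldCoordinate], filenames: list[str], path: str | Path
) -> Path:
    """Write the per-acquisition CSV index of field coordinates."""
    df = pd.DataFrame(
        {
            "field_index": range(len(fields)),
            "row": [f.row for f in fields],
            "col": [f.col for f in fields],
            "x_um": [f.x_um for f in fields],
            "y_um": [f.y_um for f in fields],
            "z_um": [f.z_um for f in fields],
            "filename": filenames,
        }
    )
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_index(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
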