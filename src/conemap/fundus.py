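"""Virtual eye fundus: annular density maps and regional comparisons.

Local per-field densities are projected onto a disk centered on the optic
nerve head: 9 concentric annuli ("rows"), each divided into grid-aligned
angular segments, with densities color-binned at multiples of 45 cones per
field (45, 90, ..., 405) and excluded fields drawn grey. Orientation is
carried as dorsal/ventral/nasal/temporal labels so left and right eyes can
be compared. A dorsal-versus-ventral regional comparison contrasts two
6-row x 11-column blocks of 66 fields (2.48 mm² with the CoolSNAP FX
field) equidistant from the optic nerve and separated by a two-row gap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as _dc_field

import numpy as np
import pandas as pd

from .acquisition import AcquisitionConfig
from .detection import FieldResult
from .stats import paired_t

__all__ = [
    "Orientation",
    "FundusConfig",
    "FundusCell",
    "FundusMap",
    "RegionalGeometry",
    "RegionalComparison",
    "locate_center",
    "build_fundus",
    "radial_profile",
    "regional_comparison",
    "region_area_mm2",
    "row_gap_um",
    "average_field_grids",
    "render_fundus",
]

REGION_ROWS = 6
REGION_COLS = 11
REGION_N_FIELDS = REGION_ROWS * REGION_COLS  # 66
REGION_GAP_ROWS = 2

_AXES = ("+x", "-x", "+y", "-y")


@dataclass(frozen=True)
class Orientation:
    """Anatomical axes of the mounted retina on the image grid.

    ``dorsal`` and ``nasal`` name grid directions (+y is downward, i.e.
    increasing row index); they must be perpendicular.
    """

    dorsal: str = "-y"
    nasal: str = "+x"
    eye: str = "right"

    def __post_init__(self) -> None:
        if self.dorsal not in _AXES or self.nasal not in _AXES:
            raise ValueError(f"axes must be one of {_AXES}")
        if self.dorsal[1] == self.nasal[1]:
            raise ValueError("dorsal and nasal axes must be perpendicular")
        if self.eye not in ("left", "right"):
            raise ValueError("eye must be 'left' or 'right'")


@dataclass(frozen=True)
class FundusConfig:
    n_rows: int = 9
    bin_step: float = 45.0
    n_bins: int = 9  # upper edges 45, 90, ..., 405

    @property
    def bin_edges(self) -> np.ndarray:
        return self.bin_step * np.arange(1, self.n_bins + 1)

    def bin_index(self, density: float) -> int:
        """Left-open color bins: (0,45] → 0, (45,90] → 1, ...; density 0
        maps to the lowest bin, values past the top edge clamp to it."""
        if density <= 0:
            return 0
        return int(min(self.n_bins - 1, math.ceil(density / self.bin_step) - 1))


@dataclass
class FundusCell:
    row: int  # 1..n_rows, 1 innermost
    segment: int
    mean_density: float | None
    bin_index: int | None
    excluded: bool
    angle: float  # radians, for rendering


@dataclass
class FundusMap:
    center_um: tuple[float, float]
    cells: list[FundusCell]
    orientation: Orientation
    config: FundusConfig
    max_radius_um: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "row": c.row,
                    "segment": c.segment,
                    "mean_density": c.mean_density,
                    "bin_index": c.bin_index,
                    "excluded": c.excluded,
                }
                for c in self.cells
            ]
        )


def locate_center(
    results: list[FieldResult],
    acq: AcquisitionConfig | None = None,
    override: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Optic-nerve-head position: centroid of accepted field centers.

    The stage coordinates of the counted fields straddle the optic nerve
    symmetrically, so their centroid estimates its position; an explicit
    operator-supplied center takes precedence.
    """
    if override is not None:
        return override
    acq = acq or AcquisitionConfig()
    centers = [r.field.center(acq) for r in results if r.accepted]
    if not centers:
        raise ValueError("no accepted fields: cannot locate the optic nerve")
    arr = np.asarray(centers)
    return (float(arr[:, 0].mean()), float(arr[:, 1].mean()))


def build_fundus(
    results: list[FieldResult],
    orientation: Orientation = Orientation(),
    cfg: FundusConfig = FundusConfig(),
    acq: AcquisitionConfig | None = None,
    center: tuple[float, float] | None = None,
) -> FundusMap:
    """Assign every field to an annulus row and angular segment.

    A field lands in row ``min(n_rows, ceil(r / r_step))`` by the radial
    distance of its center (``r_step = max radius / n_rows``) and occupies
    one grid-aligned segment of that annulus (segments ordered by angle).
    Accepted fields carry their density's color bin; excluded fields are
    marked for grey rendering.
    """
    acq = acq or AcquisitionConfig()
    cx, cy = locate_center(results, acq, override=center)
    entries = []
    for r in results:
        fx, fy = r.field.center(acq)
        dx, dy = fx - cx, fy - cy
        entries.append((math.hypot(dx, dy), math.atan2(dy, dx), r))
    max_r = max(e[0] for e in entries) if entries else 0.0
    r_step = max_r / cfg.n_rows if max_r > 0 else 1.0

    by_row: dict[int, list] = {}
    for dist, ang, res in entries:
        row = 1 if dist == 0 else min(cfg.n_rows, math.ceil(dist / r_step))
        by_row.setdefault(row, []).append((ang, res))

    cells: list[FundusCell] = []
    for row, members in sorted(by_row.items()):
        members.sort(key=lambda t: t[0])
        for seg, (ang, res) in enumerate(members):
            if res.accepted:
                cells.append(
                    FundusCell(
                        row=row,
                        segment=seg,
                        mean_density=res.density,
                        bin_index=cfg.bin_index(res.density),
                        excluded=False,
                        angle=ang,
                    )
                )
            else:
                cells.append(
                    FundusCell(row, seg, None, None, True, ang)
                )
    return FundusMap(
        center_um=(cx, cy),
        cells=cells,
        orientation=orientation,
        config=cfg,
        max_radius_um=max_r,
    )


def radial_profile(fmap: FundusMap) -> tuple[np.ndarray, list[int]]:
    """Per-annulus mean density, rows 1..n_rows (innermost first).

    Returns ``(profile, empty_rows)``: annuli with no accepted field hold
    NaN and are flagged in ``empty_rows``.
    """
    n = fmap.config.n_rows
    profile = np.full(n, np.nan)
    empty: list[int] = []
    for row in range(1, n + 1):
        vals = [
            c.mean_density
            for c in fmap.cells
            if c.row == row and not c.excluded and c.mean_density is not None
        ]
        if vals:
            profile[row - 1] = float(np.mean(vals))
        else:
            empty.append(row)
    return profile, empty


def region_area_mm2(acq: AcquisitionConfig | None = None, n_fields: int = REGION_N_FIELDS) -> float:
    """Area of one 66-field comparison region (2.48 mm² for the FX frame)."""
    acq = acq or AcquisitionConfig()
    return n_fields * acq.field_area_mm2


def row_gap_um(acq: AcquisitionConfig | None = None, n_rows: int = REGION_GAP_ROWS) -> float:
    """Physical height of the gap separating the dorsal and ventral blocks
    (two rows: 335.4 µm with the CoolSNAP HQ field height of 167.70 µm)."""
    acq = acq or AcquisitionConfig()
    return n_rows * acq.field_height_um


@dataclass(frozen=True)
class RegionalGeometry:
    n_rows: int = REGION_ROWS
    n_cols: int = REGION_COLS
    gap_rows: int = REGION_GAP_ROWS


@dataclass
class RegionalComparison:
    dorsal_means: np.ndarray  # one per retina
    ventral_means: np.ndarray
    differences: np.ndarray  # dorsal - ventral, paired within retina
    t: float
    df: float
    p: float
    region_area_mm2: float
    gap_um: float


def _block_mean(
    results: list[FieldResult], rows: range, cols: range
) -> float:
    vals = [
        r.density
        for r in results
        if r.accepted and r.field.row in rows and r.field.col in cols
    ]
    if not vals:
        raise ValueError("regional block contains no accepted fields")
    return float(np.mean(vals))


def regional_comparison(
    per_retina_results: list[list[FieldResult]],
    orientation: Orientation = Orientation(),
    geometry: RegionalGeometry = RegionalGeometry(),
    acq: AcquisitionConfig | None = None,
) -> RegionalComparison:
    """Dorsal-versus-ventral paired comparison over retinas.

    For each retina two ``n_rows x n_cols`` field blocks are taken,
    centered on the dorso-ventral axis through the optic nerve, separated
    by ``gap_rows`` grid rows straddling the nerve, so both regions are
    equidistant from it. Per-retina region means are compared by a paired
    t-test (pairing within retina).
    """
    acq = acq or AcquisitionConfig()
    if orientation.dorsal not in ("+y", "-y"):
        raise ValueError(
            "regional comparison requires the dorso-ventral axis on the "
            "grid's y axis; rotate the layout or relabel the orientation"
        )
    dorsal_up = orientation.dorsal == "-y"
    dorsal_means, ventral_means = [], []
    for results in per_retina_results:
        cx, cy = locate_center(results, acq)
        rows = sorted({r.field.row for r in results})
        cols = sorted({r.field.col for r in results})
        need = 2 * geometry.n_rows + geometry.gap_rows
        if len(rows) < need:
            raise ValueError(
                f"grid has {len(rows)} rows; at least {need} are required "
                "for the regional comparison"
            )
        # row / col indices nearest the optic nerve
        rc = min(
            rows,
            key=lambda r: abs(
                (r + 0.5) * acq.field_height_um
                + min(res.field.y_um - res.field.row * acq.field_height_um
                      for res in results)
                - cy
            ),
        )
        cc = min(
            cols,
            key=lambda c: abs(
                (c + 0.5) * acq.field_width_um
                + min(res.field.x_um - res.field.col * acq.field_width_um
                      for res in results)
                - cx
            ),
        )
        gap_lo = rc - geometry.gap_rows // 2
        gap_hi = gap_lo + geometry.gap_rows - 1
        upper = range(gap_lo - geometry.n_rows, gap_lo)
        lower = range(gap_hi + 1, gap_hi + 1 + geometry.n_rows)
        half = geometry.n_cols // 2
        cols_r = range(cc - half, cc - half + geometry.n_cols)
        upper_mean = _block_mean(results, upper, cols_r)
        lower_mean = _block_mean(results, lower, cols_r)
        if dorsal_up:
            dorsal_means.append(upper_mean)
            ventral_means.append(lower_mean)
        else:
            dorsal_means.append(lower_mean)
            ventral_means.append(upper_mean)

    dorsal = np.asarray(dorsal_means)
    ventral = np.asarray(ventral_means)
    tt = paired_t(dorsal, ventral)
    return RegionalComparison(
        dorsal_means=dorsal,
        ventral_means=ventral,
        differences=dorsal - ventral,
        t=tt.t,
        df=tt.df,
        p=tt.p,
        region_area_mm2=region_area_mm2(acq, geometry.n_rows * geometry.n_cols),
        gap_um=row_gap_um(acq, geometry.gap_rows),
    )


def average_field_grids(
    per_retina_results: list[list[FieldResult]],
    acq: AcquisitionConfig | None = None,
) -> pd.DataFrame:
    """Cellwise mean density over retinas, grids aligned by center field.

    Each retina's fields are re-indexed relative to the field nearest its
    optic-nerve center; the mean is taken over retinas in which the cell
    was accepted, and a cell is flagged excluded when it was excluded in a
    majority of retinas.
    """
    acq = acq or AcquisitionConfig()
    records: dict[tuple[int, int], list] = {}
    excl: dict[tuple[int, int], int] = {}
    seen: dict[tuple[int, int], int] = {}
    for results in per_retina_results:
        cx, cy = locate_center(results, acq)
        center_field = min(
            results,
            key=lambda r: (r.field.center(acq)[0] - cx) ** 2
            + (r.field.center(acq)[1] - cy) ** 2,
        ).field
        for r in results:
            key = (r.field.row - center_field.row, r.field.col - center_field.col)
            seen[key] = seen.get(key, 0) + 1
            if r.accepted:
                records.setdefault(key, []).append(r.density)
            else:
                excl[key] = excl.get(key, 0) + 1
    rows = []
    for key in sorted(seen):
        vals = records.get(key, [])
        rows.append(
            {
                "d_row": key[0],
                "d_col": key[1],
                "mean_density": float(np.mean(vals)) if vals else np.nan,
                "n_retinas": seen[key],
                "excluded": excl.get(key, 0) * 2 > seen[key],
            }
        )
    return pd.DataFrame(rows)


def render_fundus(fmap: FundusMap, path) -> None:
    """Draw the disk representation (9 annuli, 45-step color scale, grey
    exclusions, D/V/N/T labels) to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib import patches

    cfg = fmap.config
    fig, ax = plt.subplots(figsize=(6, 6))
    colors = plt.get_cmap("jet", cfg.n_bins)
    by_row: dict[int, list[FundusCell]] = {}
    for c in fmap.cells:
        by_row.setdefault(c.row, []).append(c)
    for row, cells in by_row.items():
        cells.sort(key=lambda c: c.angle)
        n = len(cells)
        r0 = (row - 1) / cfg.n_rows
        r1 = row / cfg.n_rows
        for k, cell in enumerate(cells):
            # angular wedge boundaries at midpoints between neighbors
            a0 = math.degrees(
                (cells[k - 1].angle + cell.angle) / 2 if k > 0
                else (cells[-1].angle - 2 * math.pi + cell.angle) / 2
            )
            nxt = cells[(k + 1) % n]
            a1 = math.degrees(
                (cell.angle + nxt.angle) / 2 if k + 1 < n
                else (cell.angle + nxt.angle + 2 * math.pi) / 2
            )
            color = "0.6" if cell.excluded else colors(cell.bin_index)
            ax.add_patch(
                patches.Wedge((0, 0), r1, a0, a1, width=r1 - r0,
                              facecolor=color, edgecolor="white", lw=0.3)
            )
    lab = {"+y": (0, -1.12), "-y": (0, 1.12), "+x": (1.12, 0), "-x": (-1.12, 0)}
    o = fmap.orientation
    dx, dy = lab[o.dorsal]
    ax.text(dx, dy, "D", ha="center", va="center", fontsize=14)
    ax.text(-dx, -dy, "V", ha="center", va="center", fontsize=14)
    nx, ny = lab[o.nasal]
    ax.text(nx, ny, "N", ha="center", va="center", fontsize=14)
    ax.text(-nx, -ny, "T", ha="center", va="center", fontsize=14)
    ax.set_xlim(-1.25, 1.25)
    ax.set_ylim(-1.25, 1.25)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(path, dpi=120)
    plt.close(fig)
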