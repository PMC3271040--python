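"""Synthetic flat-mounted retina: ground-truth scenes and rendered Z-stacks.

The simulator emulates a PNA-labeled flat-mount as seen through a 40X
epifluorescence objective: bright, roughly circular cone outer-segment
profiles 3-8 µm across scattered over a disk-shaped piece of tissue
(flattened by four radial incisions), at densities spanning roughly
45-405 cones per 0.0376 mm² camera field. Nuisance structure includes a
smooth background with a brightness gradient, Poisson photon noise, dark
patches of retinal-pigment-epithelium residue, and cones touching in
pairs. Every scene carries exact ground truth (cone coordinates), so the
entire downstream counting chain is testable without a microscope.

Cones live on a smoothly undulating focal surface z(x, y) (±20 µm), which
makes per-field autofocus a real search rather than a constant lookup.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as _dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import erf

from .acquisition import AcquisitionConfig, FieldCoordinate, ZStack

__all__ = [
    "SyntheticParams",
    "RetinaScene",
    "GroundTruth",
    "generate_scene",
    "render_plane",
    "render_field_stack",
    "make_field_scene",
]

# mean of |y|/R over a half-disk of radius R; used to map the requested
# ventral/dorsal count ratio onto a linear intensity ramp.
_HALFDISK_MEAN_ABS = 4.0 / (3.0 * math.pi)

# densest achievable packing fraction for sequential (dart-throwing)
# placement of hard discs; beyond ~0.54 coverage placement stalls.
_MAX_PACKING = 0.54


@dataclass(frozen=True)
class SyntheticParams:
    """Generator settings; defaults describe a healthy adult mouse retina.

    base_density
        Cones per mm² before gradients. 5300/mm² corresponds to ~200 cones
        per 0.0376 mm² field, mid-range for wild-type tissue.
    radial_gradient
        Multiplicative periphery/center density factor (1 = homogeneous).
    dorsoventral_gradient
        Requested ventral/dorsal total-count ratio (1 = symmetric).
    retina_radius_mm
        Radius of the flattened tissue disk.
    n_incisions
        Radial relaxation cuts made during flat-mounting (wedge-shaped
        notches in the mask).
    dark_patch_fraction
        Fraction of tissue area covered by dark RPE-residue patches.
    cluster_fraction
        Fraction of cones relocated into contact pairs.
    hardcore_radius_um
        Minimum center-to-center spacing between (non-cluster) cones.
    cone_radius_range_um
        Uniform range of cone profile radii (spots 2r across, 3-8 µm).
    cone_intensity_range
        Uniform range of in-focus peak amplitudes above background
        (16-bit counts); free parameters of the emulation.
    background_mean / background_gradient / photon_scale
        Noise model: flat background level, amplitude of a linear
        brightness ramp across the tissue, and the Poisson photon scale
        (variance = photon_scale x signal; 0 disables noise).
    """

    base_density: float = 5300.0
    radial_gradient: float = 1.0
    dorsoventral_gradient: float = 1.0
    retina_radius_mm: float = 1.9
    n_incisions: int = 4
    incision_depth: float = 0.35
    dark_patch_fraction: float = 0.02
    cluster_fraction: float = 0.05
    hardcore_radius_um: float = 3.0
    cone_radius_range_um: tuple[float, float] = (1.5, 4.0)
    cone_intensity_range: tuple[float, float] = (1500.0, 3500.0)
    background_mean: float = 300.0
    background_gradient: float = 60.0
    photon_scale: float = 4.0
    surface_amplitude_um: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_density < 0:
            raise ValueError("base_density must be >= 0")
        for name in ("dark_patch_fraction", "cluster_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.hardcore_radius_um < 0:
            raise ValueError("hardcore_radius_um must be >= 0")
        if self.retina_radius_mm <= 0:
            raise ValueError("retina_radius_mm must be > 0")


# Defocus model: a cone of profile width sigma_c observed at axial distance
# dz renders as a Gaussian of width sqrt(sigma_c² + (SIGMA0 + DEFOCUS_K·|dz|)²)
# with total flux conserved (peak amplitude falls as the square of the
# width ratio). Simplest monotone blur; no claim of optical realism.
SIGMA0_UM = 0.4
DEFOCUS_K = 0.35


@dataclass
class RetinaScene:
    """Ground-truth world model of one flat-mounted retina.

    cones is an (N, 5) float array with columns x_um, y_um, z_um,
    radius_um, intensity; coordinates are centered on the optic nerve at
    (0, 0). dark_patches is an (M, 4) array (x, y, radius, attenuation).
    """

    params: SyntheticParams
    cones: np.ndarray
    dark_patches: np.ndarray
    cluster_members: np.ndarray  # indices exempt from the hard-core check
    _surface_coeffs: np.ndarray = _dc_field(repr=False, default=None)
    _gradient_dir: tuple[float, float] = (1.0, 0.0)

    @property
    def radius_um(self) -> float:
        return self.params.retina_radius_mm * 1000.0

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        r = self.radius_um
        return (-r, -r, r, r)

    # -- tissue mask -----------------------------------------------------
    def contains(self, x, y):
        """Vectorized membership test for the tissue mask (disk minus
        incision wedges)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        r = np.hypot(x, y)
        R = self.radius_um
        inside = r <= R
        p = self.params
        if p.n_incisions > 0 and p.incision_depth > 0:
            theta = np.arctan2(y, x)
            r0 = R * (1.0 - p.incision_depth)
            # wedge half-width grows linearly from 0 at depth r0 to
            # ~2 degrees at the rim
            half_w_rim = math.radians(2.0)
            for k in range(p.n_incisions):
                ang = 2.0 * math.pi * k / p.n_incisions + math.pi / p.n_incisions
                d = np.abs(np.angle(np.exp(1j * (theta - ang))))
                frac = np.clip((r - r0) / max(R - r0, 1e-9), 0.0, 1.0)
                inside &= ~((r > r0) & (d < half_w_rim * frac))
        return inside

    def mask_grid(self, resolution_um: float = 20.0) -> np.ndarray:
        """Rasterize the tissue mask at the given pixel pitch (µm)."""
        r = self.radius_um
        n = int(math.ceil(2 * r / resolution_um))
        xs = -r + (np.arange(n) + 0.5) * resolution_um
        xx, yy = np.meshgrid(xs, xs)
        return self.contains(xx, yy)

    # -- focal surface ---------------------------------------------------
    def surface_z(self, x, y):
        """Smooth focal-depth map z(x, y) in µm (finite everywhere)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        R = self.radius_um
        z = np.zeros(np.broadcast(x, y).shape, dtype=float)
        for ax, ay, phx, phy, amp in self._surface_coeffs:
            z += amp * np.sin(ax * x / R + phx) * np.sin(ay * y / R + phy)
        return z

    # -- nuisance background --------------------------------------------
    def background(self, x, y):
        """Noiseless background level at physical coordinates (µm)."""
        p = self.params
        gx, gy = self._gradient_dir
        R = self.radius_um
        b = p.background_mean + p.background_gradient * (x * gx + y * gy) / R
        if len(self.dark_patches):
            b = np.asarray(b, dtype=float)
            for px, py, pr, att in self.dark_patches:
                inside = (x - px) ** 2 + (y - py) ** 2 <= pr**2
                b = np.where(inside, b * att, b)
        return np.maximum(b, 0.0)

    # -- ground truth ----------------------------------------------------
    def count_in_rect(self, x0: float, y0: float, x1: float, y1: float) -> int:
        """True cone count in the half-open rectangle [x0,x1) x [y0,y1)."""
        c = self.cones
        if len(c) == 0:
            return 0
        m = (c[:, 0] >= x0) & (c[:, 0] < x1) & (c[:, 1] >= y0) & (c[:, 1] < y1)
        return int(m.sum())

    def ground_truth(self, fields: list[FieldCoordinate], acq: AcquisitionConfig):
        counts = [
            self.count_in_rect(*f.rect(acq)) for f in fields
        ]
        return GroundTruth(
            per_field_counts=np.asarray(counts, dtype=int),
            total_count=len(self.cones),
            field_area_mm2=acq.field_area_mm2,
        )

    def export_cones_csv(self, path: str | Path) -> Path:
        df = pd.DataFrame(
            self.cones,
            columns=["x_um", "y_um", "z_um", "radius_um", "intensity"],
        )
        path = Path(path)
        df.to_csv(path, index=False)
        return path


@dataclass
class GroundTruth:
    per_field_counts: np.ndarray
    total_count: int
    field_area_mm2: float

    @property
    def per_field_density(self) -> np.ndarray:
        """True densities in cones per field area (cones per camera field)."""
        return self.per_field_counts.astype(float)


def _intensity_factor(params: SyntheticParams, x, y, R: float):
    """Relative density modulation from the radial and dorso-ventral
    gradients; clipped at zero."""
    r = np.hypot(x, y)
    m = 1.0 + (params.radial_gradient - 1.0) * np.clip(r / R, 0.0, 1.0)
    g = params.dorsoventral_gradient
    if g != 1.0:
        a = (g - 1.0) / ((g + 1.0) * _HALFDISK_MEAN_ABS)
        m = m * (1.0 + a * y / R)  # +y is ventral
    return np.maximum(m, 0.0)


def generate_scene(params: SyntheticParams) -> RetinaScene:
    """Place cones by a hard-core (sequential-inhibition) point process.

    The target total is Poisson with mean equal to the integral of the
    density surface over the mask; points are then placed one at a time by
    rejection sampling, refusing any candidate closer than
    ``hardcore_radius_um`` to an accepted cone. Deterministic given
    ``params.seed``.

    Raises ``ValueError`` when the requested density cannot be packed at
    the requested hard-core spacing.
    """
    rng = np.random.default_rng(params.seed)
    R = params.retina_radius_mm * 1000.0
    lam = params.base_density * 1e-6  # cones per µm²

    # feasibility: peak local intensity vs maximal sequential packing
    h = params.hardcore_radius_um
    peak = lam * float(
        np.max(_intensity_factor(params, np.array([0.0, 0.0, 0.0]),
                                 np.array([0.0, -R, R]), R))
    )
    if h > 0 and peak * math.pi * h * h / 4.0 > _MAX_PACKING:
        raise ValueError(
            "impossible packing: base_density x gradients exceeds the "
            f"hard-core limit (~{_MAX_PACKING * 4 / (math.pi * h * h) * 1e6:.0f}"
            " cones/mm² at this hardcore_radius_um)"
        )

    # surface undulation and gradient direction are scene-level randomness
    n_waves = 3
    coeffs = np.column_stack(
        [
            rng.uniform(2.0, 6.0, n_waves),
            rng.uniform(2.0, 6.0, n_waves),
            rng.uniform(0, 2 * math.pi, n_waves),
            rng.uniform(0, 2 * math.pi, n_waves),
            np.full(n_waves, params.surface_amplitude_um / n_waves),
        ]
    )
    gdir = rng.uniform(0, 2 * math.pi)
    gradient_dir = (math.cos(gdir), math.sin(gdir))

    scene = RetinaScene(
        params=params,
        cones=np.empty((0, 5)),
        dark_patches=np.empty((0, 4)),
        cluster_members=np.empty(0, dtype=int),
        _surface_coeffs=coeffs,
        _gradient_dir=gradient_dir,
    )

    # expected total = integral of the intensity over the mask (MC integral
    # on a fixed grid is exact enough to set the Poisson mean)
    grid_step = max(R / 200.0, 1.0)
    xs = np.arange(-R + grid_step / 2, R, grid_step)
    xx, yy = np.meshgrid(xs, xs)
    inside = scene.contains(xx, yy)
    mean_total = float(
        lam * np.sum(_intensity_factor(params, xx, yy, R) * inside)
        * grid_step**2
    )
    n_target = int(rng.poisson(mean_total)) if mean_total > 0 else 0

    cones_xy = _place_hardcore(rng, scene, params, n_target, R)
    n = len(cones_xy)

    # relocate a fraction of cones into contact pairs (total count is
    # unchanged; partners are exempt from the hard-core invariant)
    cluster_members = np.empty(0, dtype=int)
    radii = rng.uniform(*params.cone_radius_range_um, size=n)
    if params.cluster_fraction > 0 and n >= 4:
        n_pairs = int(round(params.cluster_fraction * n / 2.0))
        if n_pairs > 0:
            idx = rng.choice(n, size=2 * n_pairs, replace=False)
            anchors, movers = idx[:n_pairs], idx[n_pairs:]
            ang = rng.uniform(0, 2 * math.pi, n_pairs)
            d = radii[anchors] + radii[movers]
            cones_xy[movers, 0] = cones_xy[anchors, 0] + d * np.cos(ang)
            cones_xy[movers, 1] = cones_xy[anchors, 1] + d * np.sin(ang)
            keep = scene.contains(cones_xy[movers, 0], cones_xy[movers, 1])
            # partners pushed off-tissue snap back to their anchor side
            bad = movers[~keep]
            cones_xy[bad] = cones_xy[anchors[~keep]] + np.column_stack(
                [-d[~keep] * np.cos(ang[~keep]), -d[~keep] * np.sin(ang[~keep])]
            )
            cluster_members = np.concatenate([anchors, movers])

    z = scene.surface_z(cones_xy[:, 0], cones_xy[:, 1]) + rng.normal(0, 0.5, n)
    intensity = rng.uniform(*params.cone_intensity_range, size=n)
    scene.cones = np.column_stack([cones_xy, z, radii, intensity])
    scene.cluster_members = cluster_members

    # dark RPE-residue patches
    if params.dark_patch_fraction > 0:
        mask_area = math.pi * R * R  # incisions are a small correction
        target = params.dark_patch_fraction * mask_area
        patches = []
        area = 0.0
        while area < target:
            pr = rng.uniform(20.0, 60.0)
            px, py = rng.uniform(-R, R, 2)
            if px * px + py * py > R * R:
                continue
            patches.append((px, py, pr, 0.25))
            area += math.pi * pr * pr
        scene.dark_patches = np.asarray(patches, dtype=float)

    return scene


def _place_hardcore(rng, scene, params, n_target, R) -> np.ndarray:
    """Dart-throwing placement with a spatial-hash neighborhood check."""
    if n_target == 0:
        return np.empty((0, 2))
    h = params.hardcore_radius_um
    cell = max(h, 1e-6)
    grid: dict[tuple[int, int], list[int]] = {}
    pts = np.empty((n_target, 2))
    placed = 0
    attempts = 0
    max_attempts = 60 * n_target + 1000
    lam_peak = 1.0  # rejection envelope for the normalized intensity factor
    while placed < n_target and attempts < max_attempts:
        attempts += 1
        x = rng.uniform(-R, R)
        y = rng.uniform(-R, R)
        f = float(_intensity_factor(params, x, y, R))
        fac_max = max(
            1.0,
            float(_intensity_factor(params, 0.0, R, R)),
            float(_intensity_factor(params, 0.0, -R, R)),
            params.radial_gradient,
        )
        if f < rng.uniform(0, fac_max):
            continue
        if not bool(scene.contains(x, y)):
            continue
        if h > 0:
            ci, cj = int(x // cell), int(y // cell)
            ok = True
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    for k in grid.get((ci + di, cj + dj), ()):
                        dx = pts[k, 0] - x
                        dy = pts[k, 1] - y
                        if dx * dx + dy * dy < h * h:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if not ok:
                continue
            grid.setdefault((ci, cj), []).append(placed)
        pts[placed] = (x, y)
        placed += 1
    if placed < n_target:
        raise ValueError(
            f"impossible packing: placed only {placed} of {n_target} cones "
            "before stalling; lower base_density or hardcore_radius_um"
        )
    return pts


def _render_cones(
    img: np.ndarray,
    cones: np.ndarray,
    x0: float,
    y0: float,
    px_w: float,
    px_h: float,
    plane_z: float,
) -> None:
    """Add analytically pixel-integrated Gaussian cone profiles in place."""
    h, w = img.shape
    sqrt2 = math.sqrt(2.0)
    for cx, cy, cz, radius, intensity in cones:
        sigma_c = radius / 2.0
        dz = abs(plane_z - cz)
        sigma_d = SIGMA0_UM + DEFOCUS_K * dz
        sigma = math.hypot(sigma_c, sigma_d)
        sigma_focus = math.hypot(sigma_c, SIGMA0_UM)
        amp = intensity * (sigma_focus / sigma) ** 2  # flux conserved
        if amp < 0.05:
            continue
        half = 4.0 * sigma
        j0 = max(0, int((cx - half - x0) / px_w))
        j1 = min(w, int((cx + half - x0) / px_w) + 1)
        i0 = max(0, int((cy - half - y0) / px_h))
        i1 = min(h, int((cy + half - y0) / px_h) + 1)
        if j0 >= j1 or i0 >= i1:
            continue
        xe = x0 + np.arange(j0, j1 + 1) * px_w  # pixel edges
        ye = y0 + np.arange(i0, i1 + 1) * px_h
        fx = 0.5 * (erf((xe[1:] - cx) / (sqrt2 * sigma))
                    - erf((xe[:-1] - cx) / (sqrt2 * sigma)))
        fy = 0.5 * (erf((ye[1:] - cy) / (sqrt2 * sigma))
                    - erf((ye[:-1] - cy) / (sqrt2 * sigma)))
        # mean intensity over each pixel of a peak-normalized Gaussian
        scale = amp * 2.0 * math.pi * sigma * sigma / (px_w * px_h)
        img[i0:i1, j0:j1] += scale * np.outer(fy, fx)


def render_plane(
    scene: RetinaScene,
    field: FieldCoordinate,
    acq: AcquisitionConfig,
    plane_z: float,
) -> np.ndarray:
    """Noiseless image (float64) of one focal plane of one field."""
    x0, y0, x1, y1 = field.rect(acq)
    # Grid cells are a ceiling cover of the tissue bounds, so edge fields
    # may overhang them (imaging past the tissue edge); only a field with
    # no overlap at all is an error.
    if (
        x1 <= scene.bounds[0] + 1e-6
        or x0 >= scene.bounds[2] - 1e-6
        or y1 <= scene.bounds[1] + 1e-6
        or y0 >= scene.bounds[3] - 1e-6
    ):
        raise ValueError("field lies outside the scene bounds")
    px_w = acq.pixel_size_x_um
    px_h = acq.pixel_size_y_um
    xs = x0 + (np.arange(acq.width_px) + 0.5) * px_w
    ys = y0 + (np.arange(acq.height_px) + 0.5) * px_h
    xx, yy = np.meshgrid(xs, ys)
    img = scene.background(xx, yy).astype(np.float64)

    c = scene.cones
    if len(c):
        margin = 40.0  # µm; cones just outside still bleed in
        m = (
            (c[:, 0] > x0 - margin)
            & (c[:, 0] < x1 + margin)
            & (c[:, 1] > y0 - margin)
            & (c[:, 1] < y1 + margin)
        )
        _render_cones(img, c[m], x0, y0, px_w, px_h, plane_z)
    return img


def render_field_stack(
    scene: RetinaScene,
    field: FieldCoordinate,
    acq: AcquisitionConfig,
) -> ZStack:
    """Render the 9-plane stack for one field, with photon noise.

    Pure function of (scene, field, acq): the noise stream is seeded from
    the scene seed and the field grid indices, so re-rendering the same
    field is bit-identical.
    """
    offsets = acq.plane_offsets_um
    planes = np.empty((acq.n_planes, acq.height_px, acq.width_px), dtype=np.float64)
    for i, off in enumerate(offsets):
        planes[i] = render_plane(scene, field, acq, field.z_um + off)
    s = scene.params.photon_scale
    if s > 0:
        rng = np.random.default_rng(
            (scene.params.seed, 7919, field.row, field.col)
        )
        planes = rng.poisson(planes / s).astype(np.float64) * s
    pixels = np.clip(np.round(planes), 0, 65535).astype(np.uint16)
    return ZStack(pixels=pixels, field=field, plane_offsets_um=offsets)


def make_field_scene(
    n_cones: int,
    acq: AcquisitionConfig,
    seed: int,
    cone_radius_range_um: tuple[float, float] = (1.5, 2.5),
    hardcore_radius_um: float = 4.0,
    **param_overrides,
) -> tuple[RetinaScene, FieldCoordinate]:
    """Single-field scene with an exact ground-truth cone count.

    Used for controlled recovery experiments: ``n_cones`` are placed
    hard-core-uniformly inside one camera field centered on the origin;
    the surrounding tissue is empty. The tighter default radius range and
    spacing describe the low-clutter condition (well-separated, uniform
    spots) rather than the full nuisance model.
    """
    params = SyntheticParams(
        base_density=0.0,
        cluster_fraction=0.0,
        dark_patch_fraction=0.0,
        n_incisions=0,
        cone_radius_range_um=cone_radius_range_um,
        hardcore_radius_um=hardcore_radius_um,
        surface_amplitude_um=0.0,
        retina_radius_mm=max(
            0.3, 1.2 * math.hypot(acq.field_width_um, acq.field_height_um) / 1000.0
        ),
        seed=seed,
        **param_overrides,
    )
    scene = generate_scene(params)
    fw, fh = acq.field_width_um, acq.field_height_um
    field = FieldCoordinate(-fw / 2.0, -fh / 2.0, 0.0, 0, 0)

    # place exactly n_cones in the field by dart throwing
    rng = np.random.default_rng((seed, 104729))
    h = params.hardcore_radius_um
    pts: list[tuple[float, float]] = []
    attempts = 0
    while len(pts) < n_cones:
        attempts += 1
        if attempts > 400 * max(n_cones, 1) + 1000:
            raise ValueError("impossible packing for requested field count")
        x = rng.uniform(-fw / 2, fw / 2)
        y = rng.uniform(-fh / 2, fh / 2)
        if all((x - px) ** 2 + (y - py) ** 2 >= h * h for px, py in pts):
            pts.append((x, y))
    n = len(pts)
    xy = np.asarray(pts).reshape(n, 2)
    z = rng.normal(0.0, 0.5, n)
    radii = rng.uniform(*cone_radius_range_um, size=n)
    intensity = rng.uniform(*params.cone_intensity_range, size=n)
    scene.cones = np.column_stack([xy, z, radii, intensity])
    return scene, field
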