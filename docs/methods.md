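# Methods

This note records the models and deliberate numerical choices behind
`conemap`. Everything here is implemented in `src/conemap/` and exercised
by `tests/`.

## 1. Synthetic retina

The simulator is the package's ground-truth source; its scope is the
geometry and photometry that the counting pipeline is sensitive to, not
biological realism.

**Point process.** Cone positions follow a hard-core (sequential
inhibition) process: candidate points are drawn from the target intensity
surface and rejected within `hardcore_radius_um` (default 3 µm) of an
accepted point, using a spatial hash for neighbor lookups. The target
count is Poisson with mean equal to the integral of the density surface
over the tissue mask; a packing-feasibility check rejects parameter sets
whose implied disc packing exceeds a 0.54 area fraction, well below the
jamming limit, so generation always terminates.

**Density surface.** A radial linear ramp (`radial_gradient` = edge/center
ratio) times a dorsoventral linear ramp. For a requested dorsal/ventral
count ratio *g* the ramp slope is `a = (g − 1) / ((g + 1) · 4/(3π))`,
since 4/(3π) is the mean |y|/R over a half-disc; the test suite checks the
resulting count ratio directly.

**Tissue geometry.** The retina is a disc with `n_incisions` (default 4)
wedge-shaped cuts emulating the flattening incisions, a smooth focal
surface z(x, y) built from low-order sinusoids (±20 µm default, the scale
that makes the two-stage autofocus necessary), dark circular patches
(RPE residue; intensity attenuation 0.25) and count-preserving relocation
of a fraction of cones into touching pairs ("clusters"), so the
watershed-dissociation code path is exercised with known totals.

**Rendering.** Each cone is an integrated Gaussian: per-pixel values are
computed analytically with the error function, so the image is exact for
any pixel pitch, and flux is conserved under defocus (amplitude ∝ 1/σ²).
The blur width is `σ = sqrt(σ_c² + (σ₀ + k·|Δz|)²)` with `σ₀ = 0.4` µm and
`k = 0.35` per µm of defocus `Δz` between the imaging plane and the cone's
z position — a linearized defocus model, monotone in |Δz|, which is all
the autofocus metric requires. Photon noise is Poisson with
variance = `photon_scale` × signal (default 4, i.e. a gain-like
overdispersion); the noise stream is seeded from
`(scene seed, 7919, field row, field col)`, making every stack a pure
function of (scene, field, camera) and bit-reproducible. Output is
clipped to 16 bits.

**Problem sizes.** Default scene radius 1.9 mm at 5,300 cones/mm²
(≈ 60,000 cones, ≈ 8 s to generate) reflects a mouse retina; tests use
smaller radii and a reduced 160 × 128 px camera frame with the same
0.335 µm pixel pitch so pixel-denominated detection defaults remain
meaningful. These sizes are package choices for desk-scale runs, not
claims about instrument throughput.

## 2. Acquisition model

Camera presets: CoolSNAP FX 217.75 × 172.53 µm (0.0376 mm² per field) and
CoolSNAP HQ 224.46 × 167.70 µm, both 650 × 515 px, 16-bit, 9 planes at
0.7 µm spacing. Grids are axis-aligned ceiling covers of the tissue
bounding box ("full") or their checkerboard subset ("draughtboard");
edge fields may overhang the tissue — the stage images past the specimen
edge, and QC later excludes mostly-empty fields.

**Autofocus** is a two-stage scan: 6 planes at 60 µm, then 8 planes at
15 µm around the coarse optimum, keeping the argmax of the focus metric
(ties resolve to the lowest z; a metric constant across all probed planes
is reported as a tie flag and leaves the stage at its starting position).

**Focus metric.** Plain intensity variance. A mean-normalized variance
(var/mean) was considered and rejected: adding a constant brightness
offset changes var/mean and can move the argmax, violating the basic
requirement that a stray background offset must not refocus the stage.
Plain variance is exactly offset-invariant and monotone under the
simulator's defocus blur; the recovery test checks the autofocus lands
within one fine step of an exhaustive 1 µm scan.

**Stack files** are multi-page 16-bit grayscale TIFFs named
`YYYYMMDD_NNNN.tif`; stage coordinates and plane offsets are stored as
JSON in the TIFF description so stacks round-trip bit-identically, and a
CSV index maps grid positions to filenames.

## 3. Detection

Per field: pixelwise-maximum projection through the 9 planes → field QC →
tile-local threshold enhancement → spot detection and filtering.

**Auto-threshold** is Otsu's criterion computed exhaustively over every
candidate gray level of the 16-bit histogram (vectorized cumulative
sums; ties take the lowest level; foreground is strictly `> level`). A
constant image is flagged degenerate. The test suite compares it against
a brute-force scan of the between-class variance.

**Field QC** evaluates five gates in a fixed order, recording *all*
failures: TOO_DARK (mean below `dark_max`, or a pixel-fraction variant),
LOW_AVG_INTENSITY (`best_focus_avg_intensity_min`),
AREA_PCT_OUT_OF_RANGE (foreground percentage outside
`autothreshold_area_pct_range`, or a degenerate threshold),
TOO_FEW_PRELIM_OBJECTS (`prelim_cells_min` / `n_objects_min`), and
BACKGROUND_TOO_BRIGHT (mean outside preliminary objects above
`fond_max`). Excluded fields carry `count = None` — never 0 — so they can
be dropped from density averages without biasing them.

**Tile-local enhancement** splits the projection into a
`tile_grid × tile_grid` (default 4 × 4) grid; each tile is thresholded by
its own Otsu level and sub-threshold pixels are zeroed, so a brightness
gradient within one field cannot swallow dim cones. A tile falls back to
the global level when its own threshold is degenerate **or would retain
more than `_TILE_MAX_FG` = 0.25 of its pixels**: cones never cover a
quarter of a tile (measured ≤ ~4 % at low densities), so such a level is
splitting background noise in a cone-free tile — without this guard a
single empty tile can contribute hundreds of speckle objects.

**Spot detection.** White top-hat with a disc of `tophat_radius` = 15 px
(≈ the largest cone radius at 0.335 µm/px; rotation-invariant), component
labeling, then watershed dissociation of components larger than
`spot_size_max` px using markers from the peak set of the Euclidean
distance transform smoothed with a σ = 1 px Gaussian (smoothing collapses
discretization plateaus so convex bodies yield one marker and stay
whole); marker spacing is 5 px. Objects below 5 px are discretization
debris and dropped. Filters run in the order cluster → surface →
intensity → shape: area > `cluster_size` → REJECTED_CLUSTER,
area > `surf_spot_max` → REJECTED_SURFACE, mean < `int_min` →
REJECTED_INTENSITY, circularity `4πA/P²` < `spot_cutoff` →
REJECTED_SHAPE. (Cluster precedes surface because a cluster-sized blob
necessarily exceeds the single-object footprint cap; the reverse order
could never label anything a cluster.) Objects are returned sorted by
(y, x) centroid, deterministically.

**The eleven empirical variables and their defaults.**

| Variable | Default | Role |
| --- | --- | --- |
| `dark_max` | 120 | minimal projection mean (dark-field gate) |
| `best_focus_avg_intensity_min` | 150 | minimal projection mean (dim-field gate) |
| `autothreshold_area_pct_range` | (0.2, 40) | acceptable foreground percentage |
| `prelim_cells_min` | 10 | minimal preliminary component count |
| `n_objects_min` | 10 | minimal object count per image |
| `fond_max` | 800 | maximal between-object background mean |
| `spot_size_max` | 120 px | area above which a blob is dissociated |
| `surf_spot_max` | 2500 px | maximal single-object footprint |
| `cluster_size` | 6000 px | area above which an object is a rejected cluster |
| `int_min` | 100 | minimal object mean intensity |
| `spot_cutoff` | 0.3 | minimal circularity |

These variables are empirical by design. The defaults were fixed in a
single tuning pass against the simulator's default intensity model
(backgrounds ≈ 300, cone peaks 1,500–3,500, photon scale 4) and then
frozen; the acceptance suite (50 fields, 45–405 cones/field) measures
per-field error ≤ 2.9 % and mean error ≤ 1.2 % with them. All are
overridable via the `[detection]` config section, which also accepts the
original variable spellings (`spot_size`, `surf_spot`, `cluster`,
`nb_objects_min`, …). `tile_grid` and `tophat_radius` are additional
implementation knobs, not part of the eleven.

## 4. Density estimation

**Global:** mean count over accepted fields, reported per field area and
per mm². No accepted fields is an error, not a zero.

**Counting frame:** a 30 × 30 µm frame centered in each draughtboard
field. The exclusion rule is the classical unbiased-frame polyline: an
object is rejected when its pixel footprint touches the left frame edge
extended infinitely downward, the top edge, or the line rising from the
top-right corner; objects touching only the right/bottom edges are
counted. Two simpler readings were tested and rejected empirically — the
bare two-edge-segment rule double-counts corner-crossing objects under a
tiling of frames, and two full infinite lines miss diagonal
corner-cutters; only the polyline counts every disc exactly once in a
brute-force tiling experiment, and a 10⁴-placement Monte-Carlo run shows
≤ 0.2 % bias against density × frame area. Densities are reported both
per frame area (900 µm²) and rescaled to per-field units, since both
conventions occur in practice.

**Systematic random sampling:** 35 × 35 µm (1,225 µm²) fields on a
square lattice with a seeded random offset inside a 2 mm radius around
the optic nerve head; the stride is adjusted geometrically (× / ÷ 1.08)
until the yield lands in [50, 80] fields, and an over-small mask raises
an error naming the achievable maximum.

## 5. Fundus mapping and regional statistics

Field centers are mapped to polar coordinates about the optic nerve head
(centroid of accepted field centers, operator-overridable). The disk has
9 equal-width annuli (`row = min(9, ceil(r / r_step))`), each holding its
fields as grid-aligned segments ordered by angle. Densities are binned on
a left-open 45-step scale — (0, 45] → bin 0 up to (360, 405] → bin 8,
clamped above — and excluded fields render grey. Radial profiles are
per-annulus means with empty annuli flagged rather than imputed.

The dorsal-versus-ventral comparison takes two 6 × 11 field blocks
(66 fields, 2.48 mm² with the FX frame) separated by a 2-row gap
straddling the optic nerve (335.4 µm with the HQ field height), so both
regions are equidistant from it, and compares per-retina block means with
a paired t-test across retinas. Cross-retina averaging aligns per-field
grids on the field nearest each retina's center and takes cellwise means,
flagging cells excluded in a majority of retinas.

## 6. Statistics

`welch_t` and `paired_t` wrap scipy with documented degenerate cases:
zero-variance equal samples give t = 0, p = 1; a constant nonzero
(paired) difference gives p = 0 with a `zero_variance` flag rather than a
NaN. `two_way_anova` fits an OLS model with type-II sums of squares
(exact for balanced designs, standard for mildly unbalanced ones),
includes the day × method interaction automatically when cells are
replicated, raises on empty design cells naming the cell, returns
F = 0 / p = 1 for factors with (numerically) zero sum of squares, and
handles an all-constant response as p = 1 for every factor.

`quantile_equalize` implements rank-wise quantile-quantile
normalization: stable argsort per dataset, replacement of each rank's
values by their across-dataset mean, inverse permutation. It preserves
the grand sum exactly and makes all sorted vectors identical — hence the
certifying identity that a subsequent two-way ANOVA's method factor has
exactly zero sum of squares and p = 1, independent of the data.
`enumerate_equalizations` enumerates every way of trimming oversized
datasets to the common size (cartesian product of deletion choices, with
a combinatorial guard), for exhaustive sensitivity analyses of the
trimming step.

## 7. Scope and limitations

- The simulator models labeled cones as isotropic Gaussian spots on a
  smooth background; it does not model rods, vasculature, mounting
  artifacts other than dark patches, or label variability beyond a
  uniform intensity range.
- Detection defaults are tuned to the simulator's intensity model; real
  micrographs would need a fresh single-pass calibration of the eleven
  variables (the config file exists for exactly that).
- Headline biological results from degeneration models depend on real
  specimens and are out of scope; what is reproduced is the platform's
  geometry, counting rules and statistics, each validated against an
  independent oracle in `tests/`.
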