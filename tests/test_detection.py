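"""Detection chain: projection, Otsu threshold, QC gates, find_spots."""

import numpy as np
import pytest

from conemap.acquisition import AcquisitionConfig, FieldCoordinate, ZStack
from conemap.detection import (
    MIN_SPOT_AREA_PX,
    DetectionParams,
    auto_threshold,
    best_focus_projection,
    count_field,
    field_qc,
    find_spots,
    local_threshold_enhance,
)
from conemap.synthetic import make_field_scene, render_field_stack


def _disc(img, cy, cx, r, value):
    yy, xx = np.ogrid[: img.shape[0], : img.shape[1]]
    img[(yy - cy) ** 2 + (xx - cx) ** 2 <= r * r] = value


def _brute_otsu(img):
    """Exhaustive between-class-variance maximization, lowest level on ties."""
    flat = img.ravel().astype(float)
    best_level, best_score = None, -np.inf
    for t in range(int(flat.min()), int(flat.max())):
        lo, hi = flat[flat <= t], flat[flat > t]
        if lo.size == 0 or hi.size == 0:
            continue
        score = lo.size * hi.size * (lo.mean() - hi.mean()) ** 2
        if score > best_score:
            best_level, best_score = t, score
    return best_level


class TestAutoThreshold:
    def test_two_population_separation(self):
        img = np.full((40, 40), 100, np.uint16)
        img[:10, :10] = 1000
        level, degenerate = auto_threshold(img)
        assert not degenerate
        assert 100 <= level < 1000
        assert (img > level).sum() == 100

    def test_constant_image_is_degenerate(self):
        level, degenerate = auto_threshold(np.full((5, 5), 42, np.uint16))
        assert degenerate and level == 42

    def test_matches_exhaustive_otsu(self):
        rng = np.random.default_rng(3)
        img = np.concatenate(
            [rng.normal(80, 10, 600), rng.normal(200, 20, 200)]
        ).clip(0, 255).astype(np.uint16).reshape(20, 40)
        level, _ = auto_threshold(img)
        assert level == _brute_otsu(img)

    def test_empty_image_raises(self):
        with pytest.raises(ValueError):
            auto_threshold(np.empty((0, 0), np.uint16))


class TestFieldQC:
    def test_all_zero_field_is_too_dark(self):
        qc = field_qc(np.zeros((100, 100), np.uint16), DetectionParams())
        assert not qc.accepted
        assert "TOO_DARK" in qc.reasons
        assert "LOW_AVG_INTENSITY" in qc.reasons
        assert "AREA_PCT_OUT_OF_RANGE" in qc.reasons

    def test_bright_background_rejected_for_that_reason_only(self):
        img = np.full((200, 200), 1000, np.uint16)
        rng = np.random.default_rng(0)
        for _ in range(20):
            _disc(img, rng.integers(10, 190), rng.integers(10, 190), 3, 3000)
        qc = field_qc(img, DetectionParams())
        assert qc.reasons == ["BACKGROUND_TOO_BRIGHT"]
        assert qc.measures["background_mean"] == pytest.approx(1000.0, abs=1.0)

    def test_few_objects_rejected(self):
        img = np.full((200, 200), 300, np.uint16)
        _disc(img, 100, 100, 5, 3000)  # a single object
        qc = field_qc(img, DetectionParams())
        assert "TOO_FEW_PRELIM_OBJECTS" in qc.reasons

    def test_rendered_field_is_accepted(self, field200):
        _scene, _field, stack = field200
        qc = field_qc(best_focus_projection(stack), DetectionParams())
        assert qc.accepted and qc.reasons == []

    def test_all_failures_recorded_in_gate_order(self):
        qc = field_qc(np.zeros((50, 50), np.uint16), DetectionParams())
        order = [
            "TOO_DARK",
            "LOW_AVG_INTENSITY",
            "AREA_PCT_OUT_OF_RANGE",
            "TOO_FEW_PRELIM_OBJECTS",
            "BACKGROUND_TOO_BRIGHT",
        ]
        assert qc.reasons == [r for r in order if r in qc.reasons]

    def test_fraction_dark_metric(self):
        img = np.full((100, 100), 500, np.uint16)
        img[:60] = 50  # 60 % of pixels below dark_max
        params = DetectionParams(dark_metric="fraction", dark_fraction=0.5)
        assert "TOO_DARK" in field_qc(img, params).reasons
        img[:] = 500
        assert "TOO_DARK" not in field_qc(img, params).reasons


class TestLocalThreshold:
    def test_uniform_image_zeroes_out(self):
        out = local_threshold_enhance(
            np.full((80, 80), 700, np.uint16), DetectionParams()
        )
        assert (out == 0).all()

    def test_single_tile_equals_global_threshold(self):
        rng = np.random.default_rng(1)
        img = rng.normal(300, 30, (64, 64)).clip(0, 65535).astype(np.uint16)
        _disc(img, 20, 20, 4, 2000)
        _disc(img, 45, 50, 4, 2000)
        params = DetectionParams(tile_grid=1)
        level, _ = auto_threshold(img)
        expected = np.where(img > level, img, 0)
        assert np.array_equal(local_threshold_enhance(img, params), expected)

    def test_rescues_dim_spots_under_brightness_gradient(self):
        """Spots on the dim half are lost to a global threshold but kept by
        tile-local thresholding."""
        img = np.zeros((128, 128), np.uint16)
        img[:, :64] = 200
        img[:, 64:] = 1000
        spots_dim = [(20, 20), (50, 40), (90, 25), (110, 50)]
        for cy, cx in spots_dim:
            _disc(img, cy, cx, 3, 400)
        for cy, cx in [(30, 90), (70, 110), (100, 80)]:
            _disc(img, cy, cx, 3, 1300)
        global_level, _ = auto_threshold(img)
        assert all(400 <= global_level for _ in [0])  # dim spots below global
        enhanced = local_threshold_enhance(img, DetectionParams(tile_grid=4))
        for cy, cx in spots_dim:
            assert enhanced[cy, cx] == 400
        assert (np.where(img > global_level, img, 0)[20, 20]) == 0

    def test_output_is_zero_or_original(self):
        rng = np.random.default_rng(7)
        img = rng.integers(0, 4000, (96, 96)).astype(np.uint16)
        out = local_threshold_enhance(img, DetectionParams())
        assert ((out == 0) | (out == img)).all()


class TestFindSpots:
    def test_empty_field_yields_no_objects(self):
        assert find_spots(np.zeros((64, 64), np.uint16), DetectionParams()) == []

    def test_counts_k_separated_discs(self):
        img = np.zeros((200, 200), np.uint16)
        centers = [(30, 30), (30, 100), (30, 170), (100, 60), (100, 140), (170, 100)]
        for cy, cx in centers:
            _disc(img, cy, cx, 4, 1500)
        objects = find_spots(img, DetectionParams())
        counted = [o for o in objects if o.status == "COUNTED"]
        assert len(counted) == len(centers)
        got = sorted((round(o.centroid_xy[1]), round(o.centroid_xy[0])) for o in counted)
        assert got == sorted(centers)

    def test_objects_sorted_by_y_then_x(self):
        img = np.zeros((120, 120), np.uint16)
        for cy, cx in [(90, 20), (30, 90), (30, 20), (90, 90)]:
            _disc(img, cy, cx, 4, 1500)
        objects = find_spots(img, DetectionParams())
        keys = [(o.centroid_xy[1], o.centroid_xy[0]) for o in objects]
        assert keys == sorted(keys)

    def test_cluster_rejection(self):
        """A uniform disc (single distance-transform peak, so the splitter
        keeps it whole) above cluster_size is rejected as a cell cluster."""
        img = np.zeros((120, 120), np.uint16)
        _disc(img, 60, 60, 30, 1500)  # area ~ 2800 px
        params = DetectionParams(
            cluster_size=2000, spot_size_max=2000, tophat_radius=50
        )
        objects = find_spots(img, params)
        assert [o.status for o in objects] == ["REJECTED_CLUSTER"]
        assert objects[0].area > 2000

    def test_surface_rejection(self):
        img = np.zeros((120, 120), np.uint16)
        _disc(img, 60, 60, 30, 1500)
        params = DetectionParams(surf_spot_max=2000, tophat_radius=50)
        assert [o.status for o in find_spots(img, params)] == ["REJECTED_SURFACE"]

    def test_dim_object_rejected_by_intensity(self):
        img = np.zeros((64, 64), np.uint16)
        _disc(img, 32, 32, 4, 50)  # below int_min = 100
        objects = find_spots(img, DetectionParams())
        assert [o.status for o in objects] == ["REJECTED_INTENSITY"]

    def test_elongated_object_rejected_by_shape(self):
        img = np.zeros((64, 64), np.uint16)
        img[30:32, 10:54] = 1500  # 2 x 44 bar, circularity << 0.3
        objects = find_spots(img, DetectionParams())
        assert [o.status for o in objects] == ["REJECTED_SHAPE"]
        assert objects[0].circularity < 0.3

    def test_touching_pair_is_dissociated(self):
        img = np.zeros((80, 80), np.uint16)
        _disc(img, 40, 34, 7, 1500)
        _disc(img, 40, 46, 7, 1500)
        counted = [
            o for o in find_spots(img, DetectionParams()) if o.status == "COUNTED"
        ]
        assert len(counted) == 2

    def test_translation_equivariance(self):
        img = np.zeros((160, 160), np.uint16)
        for cy, cx in [(50, 50), (50, 90), (90, 70), (80, 110)]:
            _disc(img, cy, cx, 4, 1500)
        shifted = np.roll(np.roll(img, 13, axis=0), 9, axis=1)
        a = find_spots(img, DetectionParams())
        b = find_spots(shifted, DetectionParams())
        assert [o.status for o in a] == [o.status for o in b]
        assert [o.area for o in a] == [o.area for o in b]

    def test_debris_below_min_area_ignored(self):
        img = np.zeros((64, 64), np.uint16)
        img[10, 10] = 1500
        img[30, 30:32] = 1500  # 1- and 2-pixel specks
        assert find_spots(img, DetectionParams()) == []
        assert MIN_SPOT_AREA_PX == 5

    def test_params_validation(self):
        with pytest.raises(ValueError):
            DetectionParams(spot_size_max=7000, cluster_size=6000)
        with pytest.raises(ValueError):
            DetectionParams(tile_grid=0)
        with pytest.raises(ValueError):
            DetectionParams(dark_metric="median")


class TestCountField:
    def test_dark_stack_is_excluded_with_none_count(self, small_acq):
        pixels = np.zeros(
            (9, small_acq.height_px, small_acq.width_px), np.uint16
        )
        stack = ZStack(
            pixels=pixels,
            field=FieldCoordinate(0, 0, 0, 0, 0),
            plane_offsets_um=small_acq.plane_offsets_um,
        )
        result = count_field(stack, acq=small_acq)
        assert not result.accepted
        assert result.count is None and result.density is None
        assert "TOO_DARK" in result.qc.reasons

    def test_recovers_forty_cones_within_tolerance(self, small_acq):
        scene, field = make_field_scene(40, small_acq, seed=17)
        stack = render_field_stack(scene, field, small_acq)
        result = count_field(stack, acq=small_acq)
        assert result.accepted
        assert abs(result.count - 40) <= 4  # within 10 %

    def test_recovers_two_hundred_cones_on_full_frame(self, field200, acq):
        _scene, _field, stack = field200
        result = count_field(stack, acq=acq)
        assert result.accepted
        assert abs(result.count - 200) <= 20
        assert result.field_area_mm2 == pytest.approx(0.0376, abs=5e-4)

    def test_more_cones_never_fewer_counts(self, small_acq):
        """Exclusion-free monotonicity spot check: 10 vs 60 cones."""
        lo_scene, lo_field = make_field_scene(10, small_acq, seed=23)
        hi_scene, hi_field = make_field_scene(60, small_acq, seed=23)
        lo = count_field(
            render_field_stack(lo_scene, lo_field, small_acq),
            DetectionParams(prelim_cells_min=1, n_objects_min=1),
            acq=small_acq,
        )
        hi = count_field(
            render_field_stack(hi_scene, hi_field, small_acq),
            DetectionParams(prelim_cells_min=1, n_objects_min=1),
            acq=small_acq,
        )
        assert lo.count < hi.count
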