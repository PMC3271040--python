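"""Shared fixtures: acquisition geometries and pre-rendered synthetic fields.

Rendering full 650 x 515 px stacks is the slow part of the suite, so the
expensive scenes are session-scoped and most tests use a reduced camera
frame with the same 0.335 µm pixel pitch (so the pixel-denominated
detection defaults stay meaningful).
"""

from __future__ import annotations

import numpy as np
import pytest

from conemap.acquisition import AcquisitionConfig, FieldCoordinate
from conemap.detection import FieldResult, QCDecision
from conemap.synthetic import (
    SyntheticParams,
    generate_scene,
    make_field_scene,
    render_field_stack,
)


@pytest.fixture(scope="session")
def acq() -> AcquisitionConfig:
    """Full CoolSNAP FX frame: 650 x 515 px, 217.75 x 172.53 µm."""
    return AcquisitionConfig()


@pytest.fixture(scope="session")
def small_acq() -> AcquisitionConfig:
    """Reduced frame with the FX pixel pitch (0.335 µm/px)."""
    return AcquisitionConfig(
        width_px=160,
        height_px=128,
        field_width_um=160 * 0.335,
        field_height_um=128 * 0.335,
    )


@pytest.fixture(scope="session")
def field200(acq):
    """One full-size field holding exactly 200 well-separated cones."""
    scene, field = make_field_scene(200, acq, seed=11)
    stack = render_field_stack(scene, field, acq)
    return scene, field, stack


@pytest.fixture(scope="session")
def quiet_scene():
    """Small nuisance-free homogeneous scene for geometry/gradient checks."""
    params = SyntheticParams(
        base_density=3000.0,
        retina_radius_mm=0.5,
        dark_patch_fraction=0.0,
        cluster_fraction=0.0,
        n_incisions=0,
        seed=5,
    )
    return generate_scene(params)


def make_result(
    row: int,
    col: int,
    density: float | None,
    acq: AcquisitionConfig,
    accepted: bool = True,
) -> FieldResult:
    """Construct a FieldResult directly (no imaging) for aggregation tests."""
    fc = FieldCoordinate(
        col * acq.field_width_um, row * acq.field_height_um, 0.0, row, col
    )
    if accepted:
        qc = QCDecision(True, [], {})
        count = int(round(density))
    else:
        qc = QCDecision(False, ["TOO_DARK"], {})
        count = None
        density = None
    return FieldResult(
        field=fc,
        qc=qc,
        objects=[],
        count=count,
        density=density,
        field_area_mm2=acq.field_area_mm2,
    )
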