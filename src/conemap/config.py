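"""Run configuration: a single YAML file with one section per module.

Every variable ships with a default; unknown keys are rejected so a typo
in a threshold name cannot silently fall back to the default. CLI flags
override file values (flag > file > default).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .acquisition import AcquisitionConfig, AutofocusConfig, CAMERA_PRESETS
from .detection import DetectionParams
from .synthetic import SyntheticParams

__all__ = ["RunConfig", "load_config", "default_config_dict"]

_SECTIONS = ("acquisition", "autofocus", "detection", "synthetic", "run")

_RUN_DEFAULTS = {
    "mode": "global",  # global | stereo | sample
    "grid": "full",  # full | draughtboard
    "camera": "coolsnap_fx",
    "seed": 0,
    "verbosity": "info",
}


@dataclasses.dataclass
class RunConfig:
    acquisition: AcquisitionConfig
    autofocus: AutofocusConfig
    detection: DetectionParams
    synthetic: SyntheticParams
    mode: str = "global"
    grid: str = "full"
    camera: str = "coolsnap_fx"
    seed: int = 0
    verbosity: str = "info"


_FIELD_ALIASES = {
    # legacy variable spellings accepted in the [detection] section
    "dark_max": "dark_max",
    "fond_max": "fond_max",
    "int_min": "int_min",
    "nb_objects_min": "n_objects_min",
    "spot_cutoff": "spot_cutoff",
    "spot_size": "spot_size_max",
    "surf_spot": "surf_spot_max",
    "cluster": "cluster_size",
    "best_focus_avg_intensity": "best_focus_avg_intensity_min",
    "autothreshold_area_pct": "autothreshold_area_pct_range",
    "prelim_cells_min": "prelim_cells_min",
}


def _build(cls, section: dict, aliases: dict[str, str] | None = None):
    fields = {f.name for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, val in (section or {}).items():
        name = (aliases or {}).get(key, key)
        if name not in fields:
            raise ValueError(f"unknown {cls.__name__} key: {key!r}")
        if isinstance(val, list):
            val = tuple(val)
        kwargs[name] = val
    return cls(**kwargs)


def default_config_dict() -> dict:
    return {s: {} for s in _SECTIONS[:-1]} | {"run": dict(_RUN_DEFAULTS)}


def load_config(
    path: str | Path | None = None, overrides: dict | None = None
) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus overrides.

    ``overrides`` is a flat dict of run-level keys (mode, grid, camera,
    seed, verbosity); ``None`` values are ignored.
    """
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    run = dict(_RUN_DEFAULTS) | (raw.get("run") or {})
    bad = set(run) - set(_RUN_DEFAULTS)
    if bad:
        raise ValueError(f"unknown run keys: {sorted(bad)}")
    for key, val in (overrides or {}).items():
        if val is not None:
            run[key] = val

    acq_section = dict(raw.get("acquisition") or {})
    camera = run["camera"]
    if camera not in CAMERA_PRESETS:
        raise ValueError(f"unknown camera preset {camera!r}")
    w, h = CAMERA_PRESETS[camera]
    acq_section.setdefault("field_width_um", w)
    acq_section.setdefault("field_height_um", h)

    syn_section = dict(raw.get("synthetic") or {})
    syn_section.setdefault("seed", run["seed"])

    return RunConfig(
        acquisition=_build(AcquisitionConfig, acq_section),
        autofocus=_build(AutofocusConfig, raw.get("autofocus")),
        detection=_build(DetectionParams, raw.get("detection"), _FIELD_ALIASES),
        synthetic=_build(SyntheticParams, syn_section),
        mode=run["mode"],
        grid=run["grid"],
        camera=camera,
        seed=int(run["seed"]),
        verbosity=run["verbosity"],
    )
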