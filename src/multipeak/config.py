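"""Tracking configuration files and shipped parameter presets.

Config files are flat YAML with the parameter names of the interactive
panel: ``threshold``, ``max_angle`` (degrees), ``step_size`` (mm) or
``step_size_vox`` (voxel multiples, resolved against the tracked field),
``g``, ``min_length``/``max_length`` (mm), ``seeds_per_axis``,
``rng_seed``.  Alternatively ``curvature_mm`` may replace ``max_angle``:
it is a radius of curvature converted through
``theta = min(2 asin(step / 2R), 90)`` so curvature-based and angle-based
parameter grids share one internal representation.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .tracking import TrackingConfig, theta_from_radius

PRESET_NAMES = ("default", "fx", "cst", "ifof", "cc")


def load_preset(name: str) -> dict:
    """Raw parameter dict of a shipped preset."""
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    text = resources.files("multipeak.presets").joinpath(f"{name}.yaml").read_text()
    return yaml.safe_load(text)


def load_config_file(path: str | Path) -> dict:
    with open(path) as fh:
        params = yaml.safe_load(fh)
    if not isinstance(params, dict):
        raise ValueError(f"{path}: expected a mapping of parameters")
    return params


def tracking_config(params: dict, voxel_size: float | None = None) -> TrackingConfig:
    """Build a TrackingConfig from a flat parameter dict.

    ``voxel_size`` (mm) is required when the dict uses ``step_size_vox``.
    ``curvature_mm`` takes precedence over ``max_angle`` when both appear.
    """
    params = dict(params)
    if "step_size_vox" in params:
        if voxel_size is None:
            raise ValueError("step_size_vox given but no voxel size to resolve it")
        step = float(params["step_size_vox"]) * float(voxel_size)
    else:
        step = float(params.get("step_size", 1.0))
    if "curvature_mm" in params:
        theta = theta_from_radius(step, float(params["curvature_mm"]))
    else:
        theta = float(params.get("max_angle", 35.0))
    return TrackingConfig(
        f_threshold=float(params.get("threshold", 0.1)),
        theta_max=theta,
        step_size=step,
        g=float(params.get("g", 0.20)),
        min_length=float(params.get("min_length", 0.0)),
        max_length=float(params.get("max_length", 300.0)),
        rng_seed=int(params.get("rng_seed", 0)),
    )
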