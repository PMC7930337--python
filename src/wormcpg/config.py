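"""Configuration loading for parameter ranges, body constants, and runs.

Two versioned YAML files shipped with the package define the defaults:
``data/ranges.yaml`` (search ranges of the 44 evolvable parameters) and
``data/body.yaml`` (mechanical constants of the body and environment).
User-supplied files with the same schema override them.
"""
from __future__ import annotations

import dataclasses
import functools
from importlib import resources
from pathlib import Path

import yaml

_RANGE_KEYS = (
    "bias",
    "time_constant",
    "self_weight",
    "nmj_weight",
    "chemical_weight",
    "gap_conductance",
    "muscle_gain",
)


class ConfigError(ValueError):
    """Raised when a configuration file is missing entries or malformed."""


@dataclasses.dataclass(frozen=True)
class ParameterRanges:
    """Linear decode ranges, one ``(lo, hi)`` pair per parameter kind."""

    bias: tuple[float, float]
    time_constant: tuple[float, float]
    self_weight: tuple[float, float]
    nmj_weight: tuple[float, float]
    chemical_weight: tuple[float, float]
    gap_conductance: tuple[float, float]
    muscle_gain: tuple[float, float]

    def __post_init__(self):
        for key in _RANGE_KEYS:
            lo, hi = getattr(self, key)
            if not (lo < hi):
                raise ConfigError(f"range {key!r} must satisfy lo < hi, got {(lo, hi)}")
        if self.time_constant[0] <= 0:
            raise ConfigError("time constants must be positive")
        if self.gap_conductance[0] < 0 or self.nmj_weight[0] < 0:
            raise ConfigError("gap conductances and NMJ magnitudes must be non-negative")


@dataclasses.dataclass(frozen=True)
class BodyConstants:
    """Mechanical constants of the rod-spring body and agar drag."""

    n_seg: int
    body_length: float
    half_width_max: float
    half_width_taper: float
    drag_tangential: float
    drag_normal: float
    k_lateral: float
    c_lateral: float
    k_diagonal: float
    c_diagonal: float
    n_muscles_per_side: int
    muscle_span_elements: int
    muscle_stagger: int
    f_max: float
    fl_width: float
    fv_vmax: float
    fv_curvature: float
    tau_muscle: float

    def __post_init__(self):
        if self.n_seg < 1:
            raise ConfigError("n_seg must be >= 1")
        for key in ("body_length", "half_width_max", "drag_tangential", "drag_normal",
                    "k_lateral", "c_lateral", "k_diagonal", "c_diagonal",
                    "f_max", "fv_vmax", "tau_muscle"):
            if getattr(self, key) <= 0:
                raise ConfigError(f"{key} must be positive")


def _read_yaml(path: str | Path | None, default_name: str) -> dict:
    if path is None:
        text = resources.files("wormcpg.data").joinpath(default_name).read_text()
    else:
        text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"expected a mapping in {path or default_name}")
    data.pop("schema", None)
    return data


@functools.lru_cache(maxsize=8)
def _load_ranges_cached(path) -> ParameterRanges:
    return _build_ranges(path)


def _build_ranges(path) -> ParameterRanges:
    data = _read_yaml(path, "ranges.yaml")
    missing = [k for k in _RANGE_KEYS if k not in data]
    if missing:
        raise ConfigError(f"range table missing entries: {missing}")
    return ParameterRanges(**{k: tuple(map(float, data[k])) for k in _RANGE_KEYS})


def load_ranges(path: str | Path | None = None) -> ParameterRanges:
    return _load_ranges_cached(None if path is None else str(path))


@functools.lru_cache(maxsize=8)
def _load_body_cached(path) -> BodyConstants:
    return _build_body_constants(path)


def load_body_constants(path: str | Path | None = None) -> BodyConstants:
    return _load_body_cached(None if path is None else str(path))


def _build_body_constants(path) -> BodyConstants:
    data = _read_yaml(path, "body.yaml")
    fields = {f.name for f in dataclasses.fields(BodyConstants)}
    missing = fields - data.keys()
    if missing:
        raise ConfigError(f"body constants missing entries: {sorted(missing)}")
    kwargs = {}
    for f in dataclasses.fields(BodyConstants):
        cast = int if f.type == "int" else float
        kwargs[f.name] = cast(data[f.name])
    return BodyConstants(**kwargs)


def dump_yaml(obj, path: str | Path) -> None:
    """Serialize a dataclass config to YAML (round-trip lossless)."""
    data = dataclasses.asdict(obj)
    data["schema"] = 1
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
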