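"""Pipeline configuration: defaults, YAML loading, strict validation.

The YAML schema mirrors the stage structure::

    global:    t_abs, t_soft, s_max, bg_window, rel_factor, max_area_frac,
               peak_override, sigma, ring_width, falloff_sigma, cutoff
    local:     k, omega, dilate_px, y_global_scope
    exemplar:  patch_size
    integrate: hue_mode            # literal_max | dominant_v
    io:        resize, save_intermediates
    seed:      integer

Unknown keys anywhere are rejected with a message naming the key, so typos
fail loudly instead of silently running with defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from .global_stage import GlobalParams
from .local_stage import LocalParams

__all__ = ["PipelineConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass(frozen=True)
class PipelineConfig:
    global_params: GlobalParams = field(default_factory=GlobalParams)
    local_params: LocalParams = field(default_factory=LocalParams)
    k: int = 3                      # blocks per side (k² blocks)
    patch_size: int = 9             # exemplar patch side, odd >= 3
    hue_mode: str = "literal_max"
    resize: int = 224               # working size, input resized to resize×resize
    save_intermediates: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.k <= 5):
            raise ConfigError("local.k must lie in 1..5")
        if self.patch_size < 3 or self.patch_size % 2 == 0:
            raise ConfigError("exemplar.patch_size must be an odd integer >= 3")
        if self.hue_mode not in ("literal_max", "dominant_v"):
            raise ConfigError("integrate.hue_mode must be literal_max or dominant_v")
        if self.resize < 16:
            raise ConfigError("io.resize must be >= 16")


def _take(section: str, data: dict[str, Any], allowed: dict[str, str]) -> dict[str, Any]:
    out = {}
    for key, value in data.items():
        if key not in allowed:
            raise ConfigError(f"unknown config key '{section}.{key}'")
        out[allowed[key]] = value
    return out


def config_from_dict(data: dict[str, Any]) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a nested mapping."""
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    data = dict(data)
    kwargs: dict[str, Any] = {}

    g = data.pop("global", {}) or {}
    g_allowed = {f.name: f.name for f in fields(GlobalParams)}
    try:
        kwargs["global_params"] = GlobalParams(**_take("global", g, g_allowed))
    except ValueError as exc:
        raise ConfigError(f"global: {exc}") from exc

    loc = data.pop("local", {}) or {}
    l_allowed = {"omega": "omega", "dilate_px": "dilate_px", "y_global_scope": "y_global_scope"}
    k = loc.pop("k", 3)
    try:
        kwargs["local_params"] = LocalParams(**_take("local", loc, l_allowed))
    except ValueError as exc:
        raise ConfigError(f"local: {exc}") from exc
    kwargs["k"] = k

    ex = data.pop("exemplar", {}) or {}
    kwargs.update(_take("exemplar", ex, {"patch_size": "patch_size"}))

    integ = data.pop("integrate", {}) or {}
    kwargs.update(_take("integrate", integ, {"hue_mode": "hue_mode"}))

    io_sec = data.pop("io", {}) or {}
    kwargs.update(
        _take("io", io_sec, {"resize": "resize", "save_intermediates": "save_intermediates"})
    )

    if "seed" in data:
        kwargs["seed"] = int(data.pop("seed"))
    if data:
        raise ConfigError(f"unknown config section(s): {', '.join(sorted(data))}")
    return PipelineConfig(**kwargs)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config file; ``None`` yields all defaults."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)
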