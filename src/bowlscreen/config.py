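"""Run configuration: YAML loading, schema validation, seed substreams.

Every CLI run resolves its configuration (user file merged over
defaults), validates it against the known schema, and writes the
resolved values as a JSON sidecar next to the outputs so every artifact
is traceable to a config + seed.  User-facing angles are degrees.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

__all__ = ["SCHEMA", "RunConfig", "load_config", "ConfigError", "substream_seed"]


class ConfigError(ValueError):
    pass


# field name -> (type, default); None default means required when used
SCHEMA = {
    "d_proj": (float, 1.0),
    "throw_ratio": (float, 1.4),
    "aspect_ratio": (float, 16.0 / 9.0),
    "image_width_px": (int, 1280),
    "image_height_px": (int, 720),
    "alpha_min_deg": (float, 15.0),
    "alpha_max_deg": (float, 140.0),
    "beta_span_deg": (float, 180.0),
    "n_alpha": (int, 200),
    "n_beta": (int, 90),
    "scale_mm": (float, 100.0),
    "texture_px_per_deg": (float, 2.0),
    "frame_rate": (float, 60.0),
    "noise_cell_deg": (float, 5.0),
    "noise_az_extent": (float, 180.0),
    "noise_el_extent": (float, 140.0),
    "seed": (int, 0),
    "max_lag": (int, 25),
    "camera_rate": (float, 120.0),
    "closed_loop_rate": (float, 50.0),
    "closed_loop_gain": (float, 35.0),
    "max_yaw_rate": (float, 140.0),
    "trial_duration_s": (float, 60.0),
    "density_bin_deg": (float, 3.6),
}


class RunConfig(dict):
    """Validated configuration mapping with attribute access."""

    def __getattr__(self, name):
        try:
            return self[name]
        except KeyError as exc:
            raise AttributeError(name) from exc

    def write_sidecar(self, out_dir, name: str = "resolved_config.json") -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / name
        with open(path, "w") as fh:
            json.dump(dict(self), fh, indent=2, sort_keys=True)
        return path


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Merge user YAML and CLI overrides over the schema defaults."""
    data = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError("config file must contain a mapping")
        data.update(loaded)
    for key, value in (overrides or {}).items():
        if value is not None:
            data[key] = value
    cfg = RunConfig()
    for key, value in data.items():
        if key not in SCHEMA:
            raise ConfigError(f"unknown config field: {key}")
        typ, _ = SCHEMA[key]
        try:
            cfg[key] = typ(value)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid value for field {key}: {value!r}") from exc
    for key, (_, default) in SCHEMA.items():
        if key not in cfg:
            if default is None:
                raise ConfigError(f"missing required config field: {key}")
            cfg[key] = default
    return cfg


_SUBSTREAMS = {
    "noise": 0,
    "photodiode": 1,
    "neuron": 2,
    "behavior": 3,
    "schedule": 4,
    "wingbeat": 5,
}


def substream_seed(seed: int, name: str) -> int:
    """Deterministic per-module child seed (< 2**31) from one global seed."""
    try:
        key = _SUBSTREAMS[name]
    except KeyError:
        raise ConfigError(f"unknown seed substream: {name}")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(key,))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)
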