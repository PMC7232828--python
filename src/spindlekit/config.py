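"""Pipeline configuration: defaults, YAML loading, strict key validation.

Every tunable mirrors the detector and scoring defaults; the effective
configuration (defaults merged with file and CLI overrides) is echoed into
each output directory so runs are reproducible.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

DEFAULTS: dict = {
    "sleep": {
        "jerk_threshold": 1.0,       # m/s^3
        "emg_threshold": None,       # tone units; None -> quantile rule
        "emg_quantile": 0.6,
        "speed_threshold": 2.0,      # cm/s
        "min_duration_s": 40.0,      # strict > persistence
        "bin_s": 1.0,
    },
    "window": {
        # analysis window per rest epoch; desk-scale sessions use the scaled
        # values so the window occupies the same fraction of the epoch
        "offset_s": 300.0,
        "duration_s": 6600.0,
    },
    "spindle": {
        "sigma_band": [9.0, 16.0],
        "filter_order": 12,
        "smooth_window_ms": 20.0,
        "peak_z": 2.5,
        "edge_z": 1.7,
        "min_dur_s": 0.5,
        "max_dur_s": 2.0,
        "winsor_limits": [10.0, 90.0],
        "burg_order": 40,
        "burg_input": "raw",
    },
    "stats": {
        "alpha": 0.05,
        # metric family sharing one Holm correction in cohort reports
        "family": ["pct_time_asleep", "bouts_per_min", "mean_bout_dur_s",
                   "spindle_density", "mean_spindle_dur_s"],
    },
    "sim": {
        "preset": "wt",
        "scale": "desk",
        "seed": 0,
    },
}

# desk-scale rest epochs are 600 s; keep the window the same fraction
DESK_WINDOW = {"offset_s": 30.0, "duration_s": 540.0}


class ConfigError(ValueError):
    pass


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigError(f"unknown config key: {here}")
        if isinstance(base[key], dict) and isinstance(value, dict):
            out[key] = _merge(base[key], value, here)
        else:
            out[key] = value
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Defaults merged with an optional YAML file and a nested override dict.

    Unknown keys at any level are rejected.
    """
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        cfg = _merge(cfg, loaded)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def window_for_scale(cfg: dict, scale: str) -> tuple[float, float]:
    if scale == "desk" and cfg["window"] == DEFAULTS["window"]:
        return DESK_WINDOW["offset_s"], DESK_WINDOW["duration_s"]
    return cfg["window"]["offset_s"], cfg["window"]["duration_s"]


def dump_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def spindle_params_from_config(cfg: dict):
    from .spindles import SpindleParams

    s = cfg["spindle"]
    return SpindleParams(
        sigma_band=tuple(s["sigma_band"]), filter_order=s["filter_order"],
        smooth_window_ms=s["smooth_window_ms"], peak_z=s["peak_z"], edge_z=s["edge_z"],
        min_dur_s=s["min_dur_s"], max_dur_s=s["max_dur_s"],
        winsor_limits=tuple(s["winsor_limits"]), burg_order=s["burg_order"],
        burg_input=s["burg_input"],
    )


def sleep_criteria_from_config(cfg: dict):
    from .sleep import SleepCriteria

    s = cfg["sleep"]
    return SleepCriteria(
        jerk_threshold=s["jerk_threshold"], emg_threshold=s["emg_threshold"],
        emg_quantile=s["emg_quantile"], speed_threshold=s["speed_threshold"],
        min_sleep_duration_s=s["min_duration_s"], bin_s=s["bin_s"],
    )
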