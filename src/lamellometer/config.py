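"""Run configuration: YAML files with strict (unknown-key-rejecting) schema."""
from __future__ import annotations

import copy
import json
from pathlib import Path

import yaml

DEFAULTS: dict = {
    "seed": 0,
    "log_level": "INFO",
    "optics": {
        "na": 0.85,
        "n1": 1.0,
        "n2": 1.28,
        "linear_limit_um": 9.0,
        "bottom_margin_um": 0.3,
    },
    "rlm": {
        "fib_incidence_deg": 10.0,
        "sem_incidence_deg": 52.0,
        "mill_rate_nm_s": 2.4,
        "k_sigma": 3.0,
        "peak_fraction": 0.5,
    },
    "tfi": {
        "wavelengths_nm": [463.0, 542.0, 632.0],
        "L_nm": 500.0,
        "envelope": "exponential",
        "temperature_K": 109.0,
        "max_fit_thickness_nm": 1500.0,
    },
    "q4stem": {
        "beam_energy_keV": 30.0,
        "specimen_to_scintillator_um": 300.0,
        "max_angle_mrad": 218.0,
        "bf_cutoff_mrad": 30.0,
        "incidence_deg": 52.0,
        "n_electrons": 20000,
    },
    "eftem": {
        "lambda_inel_nm": 320.0,
        "pre_tilt_deg": 10.0,
    },
    "synth": {
        "length_um": 30.0,
        "width_um": 10.0,
        "center_thickness_nm": 600.0,
        "theta_deg": 10.0,
        "ramp_nm": 0.0,
        "pixel_size_um": 0.1,
        "mill_rate_nm_s": 2.4,
        "frame_interval_s": 10.0,
        "n_frames": 20,
        "noise_sigma_frac": 0.02,
    },
}


def _merge(defaults: dict, overrides: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in overrides.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise KeyError(f"unknown config key: {here}")
        if isinstance(defaults[key], dict):
            if not isinstance(value, dict):
                raise TypeError(f"config key {here} must be a mapping")
            out[key] = _merge(defaults[key], value, here)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Defaults, updated from a YAML file and explicit overrides.

    Unknown keys at any nesting level are rejected, so typos fail loudly.
    """
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        cfg = _merge(cfg, loaded)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def echo_config(cfg: dict, out_path: str | Path) -> Path:
    """Write the effective configuration next to a run's outputs."""
    out_path = Path(out_path)
    out_path.write_text(json.dumps(cfg, indent=1, sort_keys=True))
    return out_path
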