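"""Run configuration: YAML parsing, validation, defaults, run manifests.

A single structured config file drives every pipeline stage; command-line
flags override file values.  Defaults are the standard study conditions:
Wilson-Cowan constants c1=16, c2=12, c3=15, c4=3, a_e=1.3, a_i=2, theta_e=4,
theta_i=3.7, tau=8 ms, noise sigma=1e-5; stimulation amplitude 1.25 over
[2 s, 3 s); coupling sweep 1.0:0.05:1.5; FC window 1 s with 250 ms max lag;
activation threshold 0.6.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .dynamics import WCParams

__all__ = ["RunConfig", "validate_config", "write_manifest"]

_MODEL_KEYS = {
    "tau", "c1", "c2", "c3", "c4", "c5", "a_e", "a_i",
    "theta_e", "theta_i", "sigma", "s_e_max", "s_i_max", "noise_mode",
}
_SCHEMA = {
    "paths": {"network", "regions", "out_dir"},
    "model": _MODEL_KEYS,
    "stimulation": {"amplitude", "onset_ms", "offset_ms"},
    "sweep": {"c5_start", "c5_stop", "c5_step", "jump_factor", "rate_floor",
              "sim_seconds"},
    "fc": {"window_ms", "max_lag_ms", "threshold"},
    "generator": {"n_regions", "n_systems", "weight_scale"},
    "seeds": {"network", "simulation"},
    "dt_ms": None,
    "verbosity": None,
}


@dataclass
class RunConfig:
    """Fully validated configuration with defaults filled in."""

    network_path: str | None = None
    regions_path: str | None = None
    out_dir: str = "."
    model: WCParams = field(default_factory=WCParams)
    stim_amplitude: float = 1.25
    stim_onset_ms: float = 2000.0
    stim_offset_ms: float = 3000.0
    c5_grid: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(1.0, 1.5001, 0.05), 10)
    )
    jump_factor: float = 3.0
    rate_floor: float = 0.05
    sweep_sim_seconds: float = 1.0
    fc_window_ms: float = 1000.0
    fc_max_lag_ms: float = 250.0
    fc_threshold: float = 0.6
    gen_n_regions: int = 83
    gen_n_systems: int = 4
    gen_weight_scale: float | None = None
    seed_network: int = 0
    seed_simulation: int = 0
    dt_ms: float = 0.1
    verbosity: int = 1
    source_path: str | None = None


def _check_unknown(section: str, given: dict, allowed: set[str]) -> None:
    unknown = sorted(set(given) - allowed)
    if unknown:
        raise ValueError(f"unknown key(s) in {section!r}: {unknown}")


def validate_config(path) -> RunConfig:
    """Parse and validate a YAML config file, filling in the defaults.

    Unknown keys are rejected by name; out-of-range values are rejected with
    their bounds.  An empty file yields the full default configuration.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root in {path} must be a mapping")
    _check_unknown("config", raw, set(_SCHEMA))
    for section, allowed in _SCHEMA.items():
        if allowed is not None and section in raw:
            if not isinstance(raw[section], dict):
                raise ValueError(f"section {section!r} must be a mapping")
            _check_unknown(section, raw[section], allowed)

    cfg = RunConfig(source_path=str(path))
    paths = raw.get("paths", {})
    cfg.network_path = paths.get("network", cfg.network_path)
    cfg.regions_path = paths.get("regions", cfg.regions_path)
    cfg.out_dir = paths.get("out_dir", cfg.out_dir)
    for p in (cfg.network_path, cfg.regions_path):
        if p is not None and not Path(p).exists():
            raise ValueError(f"configured path does not exist: {p}")

    if "model" in raw:
        cfg.model = WCParams(**raw["model"])  # WCParams enforces its bounds

    stim = raw.get("stimulation", {})
    cfg.stim_amplitude = float(stim.get("amplitude", cfg.stim_amplitude))
    cfg.stim_onset_ms = float(stim.get("onset_ms", cfg.stim_onset_ms))
    cfg.stim_offset_ms = float(stim.get("offset_ms", cfg.stim_offset_ms))
    if cfg.stim_onset_ms >= cfg.stim_offset_ms:
        raise ValueError(
            f"stimulation onset ({cfg.stim_onset_ms}) must precede offset "
            f"({cfg.stim_offset_ms})"
        )

    sweep = raw.get("sweep", {})
    start = float(sweep.get("c5_start", 1.0))
    stop = float(sweep.get("c5_stop", 1.5))
    step = float(sweep.get("c5_step", 0.05))
    if step <= 0 or stop <= start:
        raise ValueError(
            f"invalid sweep grid: start={start}, stop={stop}, step={step}"
        )
    cfg.c5_grid = np.round(np.arange(start, stop + step / 2, step), 10)
    cfg.jump_factor = float(sweep.get("jump_factor", cfg.jump_factor))
    cfg.rate_floor = float(sweep.get("rate_floor", cfg.rate_floor))
    cfg.sweep_sim_seconds = float(sweep.get("sim_seconds", cfg.sweep_sim_seconds))
    if cfg.jump_factor <= 1:
        raise ValueError(f"jump_factor must exceed 1, got {cfg.jump_factor}")

    fc = raw.get("fc", {})
    cfg.fc_window_ms = float(fc.get("window_ms", cfg.fc_window_ms))
    cfg.fc_max_lag_ms = float(fc.get("max_lag_ms", cfg.fc_max_lag_ms))
    cfg.fc_threshold = float(fc.get("threshold", cfg.fc_threshold))
    if cfg.fc_threshold < 0:
        raise ValueError(f"fc threshold must be >= 0, got {cfg.fc_threshold}")
    if not 0 < cfg.fc_max_lag_ms < cfg.fc_window_ms:
        raise ValueError(
            f"need 0 < max_lag ({cfg.fc_max_lag_ms}) < window "
            f"({cfg.fc_window_ms})"
        )

    gen = raw.get("generator", {})
    cfg.gen_n_regions = int(gen.get("n_regions", cfg.gen_n_regions))
    cfg.gen_n_systems = int(gen.get("n_systems", cfg.gen_n_systems))
    if "weight_scale" in gen:
        cfg.gen_weight_scale = float(gen["weight_scale"])
    if cfg.gen_n_regions < 2:
        raise ValueError(f"n_regions must be >= 2, got {cfg.gen_n_regions}")

    seeds = raw.get("seeds", {})
    for key in seeds:
        if not isinstance(seeds[key], int):
            raise ValueError(f"seed {key!r} must be an integer")
    cfg.seed_network = seeds.get("network", cfg.seed_network)
    cfg.seed_simulation = seeds.get("simulation", cfg.seed_simulation)

    cfg.dt_ms = float(raw.get("dt_ms", cfg.dt_ms))
    if cfg.dt_ms <= 0:
        raise ValueError(f"dt_ms must be positive, got {cfg.dt_ms}")
    cfg.verbosity = int(raw.get("verbosity", cfg.verbosity))
    return cfg


def write_manifest(path, config: RunConfig | None, seeds: dict, extra: dict | None = None) -> None:
    """Write a JSON run manifest (parameters, seeds, version, config hash)."""
    from . import __version__

    manifest = {
        "netstim_version": __version__,
        "seeds": seeds,
    }
    if config is not None:
        d = asdict(config)
        d["c5_grid"] = [float(v) for v in config.c5_grid]
        manifest["config"] = d
        if config.source_path and Path(config.source_path).exists():
            manifest["config_sha256"] = hashlib.sha256(
                Path(config.source_path).read_bytes()
            ).hexdigest()
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
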