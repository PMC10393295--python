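"""Run configuration: flat YAML with schema validation.

``RunConfig.default()`` loads the packaged ``defaults.yaml``;
``RunConfig.from_yaml(path)`` overlays a user file on top of the defaults
and validates every key against the schema (unknown keys are rejected).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields
from importlib import resources
from pathlib import Path

import yaml

from .core import InvalidArgumentError


def _pair(x) -> tuple[float, float]:
    lo, hi = (float(v) for v in x)
    if hi <= lo:
        raise InvalidArgumentError(f"window [{lo}, {hi}] must be increasing")
    return (lo, hi)


@dataclass
class RunConfig:
    config_version: int = 1
    seed: int = 0

    n_animals: int = 58
    n_missing_lfp: int = 5
    n_bad_probe: int = 9
    n_no_units: int = 2
    n_trials: int = 75

    electrode_pitch_um: float = 20.0
    depth_span_um: float = 860.0
    lfp_fs_hz: float = 1250.0
    lowpass_cutoff_hz: float = 500.0
    filter_order: int = 5
    target_pitch_um: float = 40.0
    baseline_subtract: bool = True

    grid_m: int = 30
    grid_k: int = 100
    analysis_window_ms: tuple[float, float] = (0.0, 100.0)
    baseline_window_ms: tuple[float, float] = (-250.0, 0.0)
    peak_window_ms: tuple[float, float] = (35.0, 60.0)
    sustained_window_ms: tuple[float, float] = (60.0, 100.0)

    icsd_context: str = "experiment"
    icsd_radius_model_um: float = 400.0
    icsd_radius_experiment_um: float = 800.0
    conductivity_s_per_m: float = 0.3

    depth_weight: float = 1.0

    rate_bin_ms: float = 1.0
    rate_smooth_sigma_bins: float = 2.0
    min_cells: int = 10
    cutoff_cortex_ms: float = 0.4
    cutoff_lgn_ms: float = 0.3

    animal_latency_sd_ms: float = 3.0
    animal_depth_sd_um: float = 40.0
    animal_amplitude_cv: float = 0.2
    trial_noise_sd_uv: float = 8.0
    gamma_period_ms: float = 20.0
    gamma_amplitude_uv: float = 4.0

    lgn_pool_units: int = 1263
    lgn_pool_trials: int = 75
    lgn_n_subsets: int = 10
    lgn_target_units: int = 17400
    sim_trials: int = 10
    lm_pool_units: int = 1823

    spike_units_per_population: int = 30

    pipeline_csd_trials: int = 20
    pipeline_trial_wd_subset: int = 8
    pipeline_spike_animals: int = 12

    def __post_init__(self) -> None:
        self.analysis_window_ms = _pair(self.analysis_window_ms)
        self.baseline_window_ms = _pair(self.baseline_window_ms)
        self.peak_window_ms = _pair(self.peak_window_ms)
        self.sustained_window_ms = _pair(self.sustained_window_ms)
        self.validate()

    def validate(self) -> None:
        if self.n_animals < 1 or self.n_trials < 1:
            raise InvalidArgumentError("cohort sizes must be positive")
        if self.grid_m < 2 or self.grid_k < 2:
            raise InvalidArgumentError("analysis grid must be at least 2 x 2")
        if self.lowpass_cutoff_hz >= self.lfp_fs_hz / 2:
            raise InvalidArgumentError("low-pass cutoff must be below Nyquist")
        if self.icsd_context not in ("experiment", "model"):
            raise InvalidArgumentError("icsd_context must be 'experiment' or 'model'")
        if self.depth_weight <= 0:
            raise InvalidArgumentError("depth_weight must be positive")
        for name in ("conductivity_s_per_m", "icsd_radius_model_um",
                     "icsd_radius_experiment_um", "electrode_pitch_um"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be positive")

    @property
    def icsd_radius_um(self) -> float:
        return (self.icsd_radius_experiment_um if self.icsd_context == "experiment"
                else self.icsd_radius_model_um)

    def electrode_depths(self) -> "np.ndarray":
        import numpy as np

        return np.arange(0.0, self.depth_span_um + self.electrode_pitch_um / 2,
                         self.electrode_pitch_um)

    @classmethod
    def default(cls) -> "RunConfig":
        with resources.files("lamcsd").joinpath("defaults.yaml").open() as f:
            return cls._from_mapping(yaml.safe_load(f))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with resources.files("lamcsd").joinpath("defaults.yaml").open() as f:
            data = yaml.safe_load(f)
        user = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(user, dict):
            raise InvalidArgumentError("config file must be a mapping of keys")
        data.update(user)
        return cls._from_mapping(data)

    @classmethod
    def _from_mapping(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = list(v) if isinstance(v, tuple) else v
        return out

    def digest(self) -> str:
        """Content hash recorded in every pipeline output."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
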