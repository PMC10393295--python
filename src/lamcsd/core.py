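"""Shared domain types: grid patterns, laminar recordings, spike tables."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd


class LamcsdError(Exception):
    """Base class for package errors."""


class InvalidArgumentError(LamcsdError, ValueError):
    """A precondition on an operation's arguments was violated."""


class DegeneratePatternError(LamcsdError, ValueError):
    """A CSD pattern lacks one polarity, so sink/source masses are undefined."""


class NumericalFailureError(LamcsdError, RuntimeError):
    """A numerical routine failed (ill-conditioning, divergence, ...)."""


@dataclass
class GridPattern:
    """A depth x time grid of values with physical axes.

    ``values[i, j]`` is the sample at depth ``depth_axis[i]`` (µm) and time
    ``time_axis[j]`` (ms relative to stimulus onset).
    """

    values: np.ndarray
    depth_axis: np.ndarray
    time_axis: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.depth_axis = np.asarray(self.depth_axis, dtype=float)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        if self.values.ndim != 2:
            raise InvalidArgumentError("values must be 2-D (depth x time)")
        if self.values.shape != (self.depth_axis.size, self.time_axis.size):
            raise InvalidArgumentError(
                f"values shape {self.values.shape} inconsistent with axes "
                f"({self.depth_axis.size}, {self.time_axis.size})"
            )
        for name, ax in (("depth_axis", self.depth_axis), ("time_axis", self.time_axis)):
            d = np.diff(ax)
            if ax.size >= 2 and not (np.all(d > 0) or np.all(d < 0)):
                raise InvalidArgumentError(f"{name} must be strictly monotone")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "GridPattern":
        return GridPattern(
            self.values.copy(), self.depth_axis.copy(), self.time_axis.copy(), self.units
        )

    def flatten(self) -> np.ndarray:
        """Depth-major flattening: all time samples of depth 0 first."""
        return self.values.ravel(order="C")


# CSD patterns share the grid layout; the alias marks intent at call sites.
CSDPattern = GridPattern


@dataclass
class LaminarRecording:
    """Multichannel LFP with electrode geometry and trial structure.

    lfp is channels x samples in µV; depths are µm per channel (strictly
    monotone); fs in Hz; trial_onsets in seconds from recording start.
    """

    lfp: np.ndarray
    depths: np.ndarray
    fs: float
    trial_onsets: np.ndarray
    area: str = "V1"
    layers: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.lfp = np.asarray(self.lfp, dtype=float)
        self.depths = np.asarray(self.depths, dtype=float)
        self.trial_onsets = np.asarray(self.trial_onsets, dtype=float)
        if self.lfp.ndim != 2:
            raise InvalidArgumentError("lfp must be channels x samples")
        if self.lfp.shape[0] != self.depths.size:
            raise InvalidArgumentError("one depth per LFP channel required")
        if self.fs <= 0:
            raise InvalidArgumentError("fs must be positive")
        d = np.diff(self.depths)
        if self.depths.size >= 2 and not (np.all(d > 0) or np.all(d < 0)):
            raise InvalidArgumentError("depths must be strictly monotone")
        if np.isnan(self.lfp).any():
            raise InvalidArgumentError("NaN channels must be dropped at ingest")

    @property
    def n_channels(self) -> int:
        return self.lfp.shape[0]

    @property
    def n_trials(self) -> int:
        return self.trial_onsets.size

    def with_lfp(self, lfp: np.ndarray) -> "LaminarRecording":
        return replace(self, lfp=np.asarray(lfp, dtype=float))


SPIKE_COLUMNS = ["unit_id", "animal_id", "area", "layer", "duration_ms", "trial", "spike_time_s"]


@dataclass
class UnitTable:
    """Spike times per unit/trial plus per-unit metadata.

    units: one row per unit with columns unit_id, animal_id, area, layer,
    duration_ms (and cls once classified).
    spikes: long table with columns unit_id, trial, spike_time_s (seconds
    relative to trial onset).
    """

    units: pd.DataFrame
    spikes: pd.DataFrame
    n_trials: int

    def __post_init__(self) -> None:
        if (self.units["duration_ms"] <= 0).any():
            raise InvalidArgumentError("waveform durations must be positive")

    def to_long(self) -> pd.DataFrame:
        """Single long table, the CSV external interface."""
        meta = self.units[["unit_id", "animal_id", "area", "layer", "duration_ms"]]
        return self.spikes.merge(meta, on="unit_id", how="left")[SPIKE_COLUMNS]

    @classmethod
    def from_long(cls, df: pd.DataFrame, n_trials: int | None = None) -> "UnitTable":
        units = (
            df[["unit_id", "animal_id", "area", "layer", "duration_ms"]]
            .drop_duplicates("unit_id")
            .reset_index(drop=True)
        )
        spikes = df[["unit_id", "trial", "spike_time_s"]].reset_index(drop=True)
        if n_trials is None:
            n_trials = int(df["trial"].max()) + 1 if len(df) else 0
        return cls(units=units, spikes=spikes, n_trials=n_trials)

    def select(self, mask: pd.Series) -> "UnitTable":
        units = self.units[mask].reset_index(drop=True)
        spikes = self.spikes[self.spikes["unit_id"].isin(units["unit_id"])].reset_index(
            drop=True
        )
        return UnitTable(units=units, spikes=spikes, n_trials=self.n_trials)

    @property
    def n_units(self) -> int:
        return len(self.units)


def derive_rng(seed: int, *keys: int) -> np.random.Generator:
    """Independent child generator for (seed, keys...) on the seed ladder."""
    return np.random.default_rng([int(seed), *map(int, keys)])
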