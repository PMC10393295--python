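"""Surrogate flash-experiment generator.

Produces cohorts of animals with laminar LFP, population spike trains,
thalamic/cortical input pools and QC metadata that carry the statistical
structure the downstream analyses assume (canonical sink/source components,
trial noise with a gamma-band oscillation, trapezoid population rates with
bimodal waveform durations), so that the whole pipeline runs without any
external recordings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    CSDPattern,
    InvalidArgumentError,
    LaminarRecording,
    UnitTable,
    derive_rng,
)
from .icsd import ForwardOperator

# --------------------------------------------------------------------------
# cohort manifests and QC filtering
# --------------------------------------------------------------------------

MANIFEST_COLUMNS = [
    "animal_id", "has_v1_lfp", "probe_recoverable", "has_v1_units", "n_trials", "seed",
]


@dataclass(frozen=True)
class CohortManifest:
    animal_id: str
    has_v1_lfp: bool
    probe_recoverable: bool
    has_v1_units: bool
    n_trials: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise InvalidArgumentError("n_trials must be >= 1")


def generate_cohort_manifest(
    n_animals: int,
    n_missing_lfp: int,
    n_bad_probe: int,
    n_no_units: int,
    n_trials: int,
    seed: int,
    allow_overlap: bool = False,
) -> list[CohortManifest]:
    """Cohort manifest with exclusion flags drawn without replacement.

    By default the three flag sets are disjoint, so the retained counts are
    additive (e.g. 58 - 5 - 9 CSD-retained, 58 - 9 - 2 spike-retained).  Set
    ``allow_overlap`` to draw each flag set independently.
    """
    for name, k in (
        ("n_missing_lfp", n_missing_lfp),
        ("n_bad_probe", n_bad_probe),
        ("n_no_units", n_no_units),
    ):
        if k < 0 or k > n_animals:
            raise InvalidArgumentError(f"{name}={k} outside [0, {n_animals}]")
    if not allow_overlap and n_missing_lfp + n_bad_probe + n_no_units > n_animals:
        raise InvalidArgumentError("disjoint flag counts exceed cohort size")

    rng = derive_rng(seed, 0)
    if allow_overlap:
        missing = set(rng.choice(n_animals, n_missing_lfp, replace=False).tolist())
        bad = set(rng.choice(n_animals, n_bad_probe, replace=False).tolist())
        nounits = set(rng.choice(n_animals, n_no_units, replace=False).tolist())
    else:
        flagged = rng.choice(
            n_animals, n_missing_lfp + n_bad_probe + n_no_units, replace=False
        ).tolist()
        missing = set(flagged[:n_missing_lfp])
        bad = set(flagged[n_missing_lfp : n_missing_lfp + n_bad_probe])
        nounits = set(flagged[n_missing_lfp + n_bad_probe :])

    return [
        CohortManifest(
            animal_id=f"animal_{i:03d}",
            has_v1_lfp=i not in missing,
            probe_recoverable=i not in bad,
            has_v1_units=i not in nounits,
            n_trials=n_trials,
            seed=int(derive_rng(seed, 1, i).integers(0, 2**31 - 1)),
        )
        for i in range(n_animals)
    ]


def filter_cohort(manifest: list[CohortManifest], modality: str) -> list[str]:
    """Animal ids retained for a modality after QC exclusion.

    ``csd`` requires a recoverable probe and V1 LFP; ``spikes`` requires a
    recoverable probe and recorded V1 units.  Order is preserved.
    """
    if modality == "csd":
        keep = lambda m: m.probe_recoverable and m.has_v1_lfp
    elif modality == "spikes":
        keep = lambda m: m.probe_recoverable and m.has_v1_units
    else:
        raise InvalidArgumentError(f"unknown modality {modality!r}")
    return [m.animal_id for m in manifest if keep(m)]


def manifest_to_frame(manifest: list[CohortManifest]) -> pd.DataFrame:
    return pd.DataFrame([vars(m) for m in manifest], columns=MANIFEST_COLUMNS)


def manifest_from_frame(df: pd.DataFrame) -> list[CohortManifest]:
    return [
        CohortManifest(
            animal_id=str(r.animal_id),
            has_v1_lfp=bool(r.has_v1_lfp),
            probe_recoverable=bool(r.probe_recoverable),
            has_v1_units=bool(r.has_v1_units),
            n_trials=int(r.n_trials),
            seed=int(r.seed),
        )
        for r in df.itertuples()
    ]


# --------------------------------------------------------------------------
# ground-truth CSD patterns
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CanonicalComponentSpec:
    """One sink or source building block of the evoked pattern.

    Profiles are compact: the depth profile is a Gaussian truncated at
    3 sigma and the temporal profile is a raised-cosine bump (transient) or
    a rise-then-plateau (sustained) confined to [onset, onset + duration].
    """

    name: str
    polarity: str  # {"sink", "source"}
    depth_center: float  # µm
    depth_sigma: float  # µm
    onset: float  # ms
    duration: float  # ms
    peak_amplitude: float  # signed CSD units
    temporal_shape: str  # {"transient", "sustained"}

    def __post_init__(self) -> None:
        if self.polarity not in ("sink", "source"):
            raise InvalidArgumentError(f"bad polarity {self.polarity!r}")
        if self.temporal_shape not in ("transient", "sustained"):
            raise InvalidArgumentError(f"bad temporal_shape {self.temporal_shape!r}")
        if self.depth_sigma <= 0:
            raise InvalidArgumentError("depth_sigma must be positive")
        if self.duration <= 0:
            raise InvalidArgumentError("duration must be positive")
        if self.polarity == "sink" and self.peak_amplitude >= 0:
            raise InvalidArgumentError("sink amplitude must be negative")
        if self.polarity == "source" and self.peak_amplitude <= 0:
            raise InvalidArgumentError("source amplitude must be positive")


#: Canonical four-component flash response: early transient L4 sink (~40 ms),
#: sustained L4 source (~60 ms), sustained L5/6 sink (~50 ms) and sustained
#: L2/3 sink (~60 ms).  Depths/amplitudes are package defaults, not measured.
DEFAULT_COMPONENTS: tuple[CanonicalComponentSpec, ...] = (
    CanonicalComponentSpec("l4_sink", "sink", 420.0, 55.0, 40.0, 25.0, -1.0, "transient"),
    CanonicalComponentSpec("l4_source", "source", 390.0, 70.0, 60.0, 40.0, 0.85, "sustained"),
    CanonicalComponentSpec("l56_sink", "sink", 680.0, 80.0, 50.0, 50.0, -0.7, "sustained"),
    CanonicalComponentSpec("l23_sink", "sink", 160.0, 75.0, 60.0, 40.0, -0.6, "sustained"),
)


@dataclass(frozen=True)
class VariabilitySpec:
    """Animal- and trial-level variability knobs."""

    animal_latency_sd: float = 0.0  # ms
    animal_depth_sd: float = 0.0  # µm
    animal_amplitude_cv: float = 0.0
    trial_noise_sd: float = 0.0  # µV on the LFP
    gamma_period: float = 20.0  # ms
    gamma_amplitude: float = 0.0  # µV on the LFP
    gamma_depth_center: float = 300.0  # µm (L2/3 to upper L5 band)
    gamma_depth_sigma: float = 150.0  # µm

    def __post_init__(self) -> None:
        for name in ("animal_latency_sd", "animal_depth_sd", "animal_amplitude_cv",
                     "trial_noise_sd", "gamma_amplitude"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be >= 0")
        if self.gamma_period <= 0:
            raise InvalidArgumentError("gamma_period must be positive")


DEFAULT_VARIABILITY = VariabilitySpec(
    animal_latency_sd=3.0,
    animal_depth_sd=40.0,
    animal_amplitude_cv=0.2,
    trial_noise_sd=8.0,
    gamma_amplitude=4.0,
)


def _depth_profile(z: np.ndarray, center: float, sigma: float) -> np.ndarray:
    prof = np.exp(-((z - center) ** 2) / (2.0 * sigma**2))
    prof[np.abs(z - center) > 3.0 * sigma] = 0.0
    return prof


def _time_profile(t: np.ndarray, comp: CanonicalComponentSpec, onset: float) -> np.ndarray:
    end = onset + comp.duration
    x = (t - onset) / comp.duration
    inside = (x >= 0.0) & (x <= 1.0)
    prof = np.zeros_like(t)
    if comp.temporal_shape == "transient":
        prof[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * x[inside]))
    else:
        rise = min(10.0, comp.duration / 4.0)
        xr = (t - onset) / rise
        ramp = np.where(xr < 1.0, 0.5 * (1.0 - np.cos(np.pi * np.clip(xr, 0, 1))), 1.0)
        prof[inside] = ramp[inside]  # plateau runs to onset+duration or window end
    return prof


def synth_ground_truth_csd(
    components: list[CanonicalComponentSpec] | tuple[CanonicalComponentSpec, ...],
    depth_axis: np.ndarray,
    time_axis: np.ndarray,
    animal_jitter: VariabilitySpec | None = None,
    seed: int = 0,
) -> CSDPattern:
    """Per-animal ground-truth CSD: sum of jittered compact components.

    Jitter shifts each component's latency and depth and scales its
    amplitude (log-normal with the requested CV); components pushed off the
    grid are clipped back to the grid edge with a warning.
    """
    depth_axis = np.asarray(depth_axis, dtype=float)
    time_axis = np.asarray(time_axis, dtype=float)
    rng = derive_rng(seed, 11)
    jit = animal_jitter or VariabilitySpec()

    values = np.zeros((depth_axis.size, time_axis.size))
    for comp in components:
        dz = rng.normal(0.0, jit.animal_depth_sd) if jit.animal_depth_sd else 0.0
        dt = rng.normal(0.0, jit.animal_latency_sd) if jit.animal_latency_sd else 0.0
        if jit.animal_amplitude_cv:
            s = np.sqrt(np.log1p(jit.animal_amplitude_cv**2))
            amp_fac = rng.lognormal(-0.5 * s**2, s)
        else:
            amp_fac = 1.0
        center = comp.depth_center + dz
        onset = comp.onset + dt
        lo, hi = depth_axis.min(), depth_axis.max()
        if center < lo or center > hi:
            warnings.warn(
                f"component {comp.name!r} jittered off the depth grid; clipping",
                stacklevel=2,
            )
            center = float(np.clip(center, lo, hi))
        if onset < time_axis.min() or onset >= time_axis.max():
            warnings.warn(
                f"component {comp.name!r} jittered outside the time window; clipping",
                stacklevel=2,
            )
            onset = float(np.clip(onset, time_axis.min(), time_axis.max() - comp.duration))
        prof = np.outer(
            _depth_profile(depth_axis, center, comp.depth_sigma),
            _time_profile(time_axis, comp, onset),
        )
        values += comp.peak_amplitude * amp_fac * prof

    return CSDPattern(values=values, depth_axis=depth_axis, time_axis=time_axis, units="a.u.")


# --------------------------------------------------------------------------
# LFP trials
# --------------------------------------------------------------------------


def synth_lfp_trials(
    truth: CSDPattern,
    electrode_depths: np.ndarray,
    n_trials: int,
    noise: VariabilitySpec,
    forward: ForwardOperator,
    seed: int = 0,
    fs: float = 1250.0,
    trial_spacing_s: float = 1.0,
    pre_s: float = 0.5,
) -> LaminarRecording:
    """Forward-consistent surrogate LFP recording.

    Every trial slot contains ``F @ truth`` (linearly interpolated onto the
    sample grid) plus a gamma-band sinusoid with an L2/3-to-upper-L5 depth
    envelope and a fresh phase per trial, plus white noise.  The
    trial-averaged LFP therefore converges to the forward-projected truth.
    """
    electrode_depths = np.asarray(electrode_depths, dtype=float)
    if electrode_depths.size != truth.depth_axis.size or not np.allclose(
        electrode_depths, truth.depth_axis
    ):
        raise InvalidArgumentError("truth must be sampled on the electrode depths")
    if forward.depths.size != electrode_depths.size or not np.allclose(
        forward.depths, electrode_depths
    ):
        raise InvalidArgumentError("forward operator depths do not match electrodes")
    if n_trials < 1:
        raise InvalidArgumentError("n_trials must be >= 1")

    n_ch = electrode_depths.size
    n_samples = int(round((pre_s + n_trials * trial_spacing_s) * fs))
    lfp = np.zeros((n_ch, n_samples))
    onsets = pre_s + np.arange(n_trials) * trial_spacing_s

    evoked = forward.matrix @ truth.values  # µV, channels x truth samples
    # evoked waveform resampled onto integer sample offsets from trial onset,
    # so trial extraction windows line up sample-exactly with the truth grid
    k0 = int(np.ceil(truth.time_axis[0] / 1e3 * fs))
    k1 = int(np.floor(truth.time_axis[-1] / 1e3 * fs))
    offs = np.arange(k0, k1 + 1)
    rel_ms = offs / fs * 1e3
    evoked_rs = np.vstack(
        [np.interp(rel_ms, truth.time_axis, evoked[c]) for c in range(n_ch)]
    )
    slot = int(round(trial_spacing_s * fs))
    env = np.exp(
        -((electrode_depths - noise.gamma_depth_center) ** 2)
        / (2.0 * noise.gamma_depth_sigma**2)
    )

    for trial in range(n_trials):
        rng = derive_rng(seed, 21, trial)
        onset_sample = int(round(onsets[trial] * fs))
        lo = max(onset_sample + k0, 0)
        hi = min(onset_sample + k1 + 1, n_samples)
        lfp[:, lo:hi] += evoked_rs[:, lo - (onset_sample + k0) : hi - (onset_sample + k0)]
        # noise slot covers the trial from 350 ms pre-onset onward
        s0 = max(onset_sample - int(round(0.35 * fs)), 0)
        s1 = min(s0 + slot, n_samples)
        seg_t_ms = (np.arange(s0, s1) - onset_sample) / fs * 1e3
        seg = lfp[:, s0:s1]
        if noise.gamma_amplitude > 0:
            phase = rng.uniform(0, 2 * np.pi)
            osc = np.sin(2 * np.pi * seg_t_ms / noise.gamma_period + phase)
            seg += noise.gamma_amplitude * env[:, None] * osc[None, :]
        if noise.trial_noise_sd > 0:
            seg += rng.normal(0.0, noise.trial_noise_sd, size=seg.shape)

    return LaminarRecording(
        lfp=lfp, depths=electrode_depths, fs=fs, trial_onsets=onsets, area="V1"
    )


# --------------------------------------------------------------------------
# spikes
# --------------------------------------------------------------------------

#: Waveform-duration mixture modes (ms): the cortex pair straddles the
#: 0.4 ms RS/FS cutoff, the LGN pair straddles 0.3 ms.
WAVEFORM_MODES = {
    ("V1", "RS"): 0.55, ("V1", "FS"): 0.25,
    ("LM", "RS"): 0.55, ("LM", "FS"): 0.25,
    ("LGN", "RS"): 0.42, ("LGN", "FS"): 0.20,
}
WAVEFORM_SD = 0.04  # ms, keeps the mixture modes well separated
SPIKE_RESOLUTION_S = 1e-4  # 0.1 ms spike-time resolution


@dataclass(frozen=True)
class PopulationRateSpec:
    """Trapezoid rate profile and unit counts for one population."""

    population: str  # e.g. "RS L4" or "FS"
    baseline_rate: float  # spikes/s
    peak_rate: float  # spikes/s
    sustained_rate: float  # spikes/s
    peak_latency: float  # ms
    n_units: int
    waveform_duration_mode: float  # ms
    area: str = "V1"
    layer: str = "none"
    cls: str = "RS"

    def __post_init__(self) -> None:
        for name in ("baseline_rate", "peak_rate", "sustained_rate"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be >= 0")
        if self.n_units < 1:
            raise InvalidArgumentError("n_units must be >= 1")


def default_population_specs(n_units: int = 30) -> list[PopulationRateSpec]:
    """Default V1 populations: L5 > L4 ~ L6 > L2/3 among RS; FS baseline more
    than twice every RS baseline."""
    mk = lambda pop, b, p, s, lat, layer, cls: PopulationRateSpec(
        pop, b, p, s, lat, n_units, WAVEFORM_MODES[("V1", cls)], "V1", layer, cls
    )
    return [
        mk("RS L2/3", 1.2, 7.0, 2.5, 50.0, "2/3", "RS"),
        mk("RS L4", 3.0, 16.0, 5.0, 45.0, "4", "RS"),
        mk("RS L5", 4.5, 19.0, 7.5, 47.0, "5", "RS"),
        mk("RS L6", 3.0, 12.0, 5.0, 48.0, "6", "RS"),
        mk("FS", 10.0, 38.0, 16.0, 45.0, "none", "FS"),
    ]


def rate_profile(spec: PopulationRateSpec, t_ms: np.ndarray) -> np.ndarray:
    """Piecewise-linear (trapezoid) rate in spikes/s on a ms time grid."""
    rise_start = spec.peak_latency - 12.0
    fall_end = 62.0 if spec.peak_latency < 60.0 else spec.peak_latency + 15.0
    pts_t = [t_ms[0], rise_start, spec.peak_latency, fall_end, 250.0, 300.0, max(t_ms[-1], 301.0)]
    pts_r = [spec.baseline_rate, spec.baseline_rate, spec.peak_rate,
             spec.sustained_rate, spec.sustained_rate, spec.baseline_rate, spec.baseline_rate]
    return np.interp(t_ms, pts_t, pts_r)


def _sample_inhomogeneous(
    rng: np.random.Generator, t_ms: np.ndarray, rate: np.ndarray, n_draws: int
) -> list[np.ndarray]:
    """Inhomogeneous-Poisson samples (seconds) via inverse-CDF of the rate."""
    dt_s = (t_ms[1] - t_ms[0]) / 1e3
    cum = np.concatenate([[0.0], np.cumsum(rate) * dt_s])
    total = cum[-1]
    edges_s = np.concatenate([[t_ms[0] / 1e3], (t_ms + (t_ms[1] - t_ms[0])) / 1e3])
    counts = rng.poisson(total, size=n_draws)
    out = []
    for c in counts:
        if c == 0 or total <= 0:
            out.append(np.empty(0))
            continue
        u = np.sort(rng.uniform(0.0, total, size=c))
        times = np.interp(u, cum, edges_s)
        out.append(np.round(times / SPIKE_RESOLUTION_S) * SPIKE_RESOLUTION_S)
    return out


def synth_spike_cohort(
    specs: list[PopulationRateSpec],
    n_trials: int,
    seed: int = 0,
    animal_id: str = "synthetic",
    window_ms: tuple[float, float] = (-250.0, 350.0),
) -> UnitTable:
    """Inhomogeneous-Poisson spike tables for one animal.

    Waveform durations are drawn from the population's mixture mode so that
    duration-threshold classification recovers the intended RS/FS labels for
    the bulk of units.
    """
    if not specs:
        raise InvalidArgumentError("specs must be non-empty")
    t_ms = np.arange(window_ms[0], window_ms[1], 1.0)
    unit_rows = []
    spike_rows = {"unit_id": [], "trial": [], "spike_time_s": []}
    uid = 0
    fs_layers = ["2/3", "4", "5", "6"]
    for si, spec in enumerate(specs):
        rate = rate_profile(spec, t_ms)
        rng = derive_rng(seed, 31, si)
        for u in range(spec.n_units):
            unit_id = f"{animal_id}_u{uid:04d}"
            layer = spec.layer if spec.layer != "none" or spec.cls != "FS" else fs_layers[u % 4]
            duration = max(0.08, rng.normal(spec.waveform_duration_mode, WAVEFORM_SD))
            unit_rows.append(
                {"unit_id": unit_id, "animal_id": animal_id, "area": spec.area,
                 "layer": layer, "duration_ms": round(float(duration), 4),
                 "population": spec.population}
            )
            trains = _sample_inhomogeneous(rng, t_ms, rate, n_trials)
            for trial, times in enumerate(trains):
                spike_rows["unit_id"].extend([unit_id] * times.size)
                spike_rows["trial"].extend([trial] * times.size)
                spike_rows["spike_time_s"].extend(times.tolist())
            uid += 1
    units = pd.DataFrame(unit_rows)
    spikes = pd.DataFrame(spike_rows)
    return UnitTable(units=units, spikes=spikes, n_trials=n_trials)


# --------------------------------------------------------------------------
# input pools (LGN / LM)
# --------------------------------------------------------------------------


@dataclass
class SpikeTrainPool:
    """Flat pool of spike trains stored as a ragged array."""

    times: np.ndarray  # concatenated spike times (s)
    offsets: np.ndarray  # len n_trains + 1

    @property
    def n_trains(self) -> int:
        return self.offsets.size - 1

    def __len__(self) -> int:
        return self.n_trains

    def train(self, i: int) -> np.ndarray:
        return self.times[self.offsets[i] : self.offsets[i + 1]]


def build_lgn_input_pool(
    n_units: int,
    n_trials_recorded: int,
    rate_template: PopulationRateSpec,
    seed: int = 0,
    window_ms: tuple[float, float] = (-250.0, 350.0),
) -> SpikeTrainPool:
    """Pool of ``n_units x n_trials_recorded`` spike trains.

    Mirrors pairing every recorded unit with every recorded flash trial
    (e.g. 1263 units x 75 trials -> 94,725 trains).
    """
    if n_units < 1 or n_trials_recorded < 1:
        raise InvalidArgumentError("pool dimensions must be >= 1")
    n_trains = n_units * n_trials_recorded
    t_ms = np.arange(window_ms[0], window_ms[1], 1.0)
    rate = rate_profile(rate_template, t_ms)
    dt_s = 1e-3
    cum = np.concatenate([[0.0], np.cumsum(rate) * dt_s])
    total = cum[-1]
    edges_s = np.concatenate([[t_ms[0] / 1e3], (t_ms + 1.0) / 1e3])

    rng = derive_rng(seed, 41)
    counts = rng.poisson(total, size=n_trains)
    offsets = np.concatenate([[0], np.cumsum(counts)])
    u = rng.uniform(0.0, total, size=int(offsets[-1]))
    times = np.interp(u, cum, edges_s)
    times = np.round(times / SPIKE_RESOLUTION_S) * SPIKE_RESOLUTION_S
    # sort within each train
    for i in range(n_trains):
        sl = slice(offsets[i], offsets[i + 1])
        times[sl] = np.sort(times[sl])
    return SpikeTrainPool(times=times, offsets=offsets)


def assign_input_trains(
    pool: SpikeTrainPool,
    n_target_units: int,
    n_sim_trials: int,
    n_subsets: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Assign a pool train to every target unit in every simulated trial.

    The pool is split into ``n_subsets`` random, near-equal subsets; each
    simulated trial draws (with replacement across target units) from one
    distinct subset until all targets are covered.  Returns an integer array
    of pool indices with shape ``(n_sim_trials, n_target_units)``.
    """
    if pool.n_trains < 1:
        raise InvalidArgumentError("input pool is empty")
    if n_subsets < n_sim_trials:
        raise InvalidArgumentError("need at least one subset per simulated trial")
    rng = derive_rng(seed, 42)
    perm = rng.permutation(pool.n_trains)
    subsets = np.array_split(perm, n_subsets)
    order = rng.permutation(n_subsets)
    assignment = np.empty((n_sim_trials, n_target_units), dtype=np.int64)
    for trial in range(n_sim_trials):
        subset = subsets[order[trial]]
        if subset.size == 0:
            raise InvalidArgumentError(
                f"subset {order[trial]} is empty; reduce n_subsets"
            )
        assignment[trial] = rng.choice(subset, size=n_target_units, replace=True)
    return assignment
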