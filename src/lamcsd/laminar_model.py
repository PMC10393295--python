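"""Desk-scale laminar rate network with depth-resolved synaptic current
bookkeeping.

Each projection drives its target population's threshold-linear rate
dynamics and simultaneously deposits membrane current on the depth grid: an
inward current over the synapse-placement kernel and an equal-magnitude
return current over a soma-centered kernel (polarity reversed for
inhibitory sources).  Distal placements attenuate the *drive* delivered to
the rate equation but not the deposited current — which is what decouples
synaptic placement (strong CSD effect, weak rate effect) from synaptic
weight (strong rate effect, weak normalized-CSD effect).

The network is a deliberate caricature of a layered cortical circuit: one
excitatory and one inhibitory population per layer, feedforward thalamic
drive to L4/L6, an optional higher-area feedback stream onto upper-layer
apical dendrites, and a constant background drive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    CSDPattern,
    GridPattern,
    InvalidArgumentError,
    NumericalFailureError,
)
from .icsd import build_forward

DEPTH_STEP_UM = 20.0
DEPTH_MAX_UM = 860.0
SOMA_KERNEL_SIGMA_UM = 30.0


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    n_neurons: int
    soma_depth: float  # µm below the pia
    basal_extent: float  # µm around/below the soma
    apical_extent: float  # µm above the soma toward the pia (0 = none)
    sign: str  # {"excitatory", "inhibitory"}
    tau_ms: float = 10.0

    def __post_init__(self) -> None:
        if self.n_neurons <= 0:
            raise InvalidArgumentError("n_neurons must be positive")
        if self.sign not in ("excitatory", "inhibitory"):
            raise InvalidArgumentError(f"bad sign {self.sign!r}")


@dataclass(frozen=True)
class ProjectionSpec:
    source: str  # population name or external input {"LGN", "BKG", "LM"}
    target: str
    weight: float
    placement: str  # {"basal", "apical", "both", "soma"}
    min_dist: float = 0.0  # µm along the dendrite from the soma
    max_dist: float = 150.0
    attenuation: float = 0.85  # drive multiplier per 100 µm of distance
    delay_ms: float = 2.0

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise InvalidArgumentError("weights are nonnegative (sign from source)")
        if self.placement not in ("basal", "apical", "both", "soma"):
            raise InvalidArgumentError(f"bad placement {self.placement!r}")
        if self.min_dist < 0 or self.max_dist < self.min_dist:
            raise InvalidArgumentError("invalid placement distance bounds")
        if not 0.0 <= self.attenuation <= 1.0:
            raise InvalidArgumentError("attenuation must lie in [0, 1]")

    @property
    def name(self) -> str:
        return f"{self.source}->{self.target}"


@dataclass
class LaminarNetwork:
    populations: dict[str, PopulationSpec]
    projections: list[ProjectionSpec]
    depth_axis: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, DEPTH_MAX_UM + DEPTH_STEP_UM / 2, DEPTH_STEP_UM)
    )

    def copy(self) -> "LaminarNetwork":
        return LaminarNetwork(
            populations=dict(self.populations),
            projections=list(self.projections),
            depth_axis=self.depth_axis.copy(),
        )

    def validate(self) -> None:
        for proj in self.projections:
            if proj.target not in self.populations:
                raise InvalidArgumentError(f"unknown target {proj.target!r}")
            tgt = self.populations[proj.target]
            if proj.placement in ("apical", "both") and tgt.apical_extent <= 0:
                raise InvalidArgumentError(
                    f"{proj.name}: apical placement on a population without "
                    "apical dendrites"
                )


@dataclass
class SimResult:
    rates: dict[str, np.ndarray]
    csd_by_population: dict[str, np.ndarray]
    csd_total: np.ndarray
    lfp_total: np.ndarray
    depth_axis: np.ndarray
    time_axis: np.ndarray  # ms relative to stimulus onset

    def csd_pattern(self) -> CSDPattern:
        return CSDPattern(
            values=self.csd_total, depth_axis=self.depth_axis,
            time_axis=self.time_axis, units="a.u.",
        )

    def lfp_pattern(self) -> GridPattern:
        return GridPattern(
            values=self.lfp_total, depth_axis=self.depth_axis,
            time_axis=self.time_axis, units="a.u.",
        )


# --------------------------------------------------------------------------
# default network
# --------------------------------------------------------------------------

_LAYER_SOMA = {"2/3": 210.0, "4": 370.0, "5": 540.0, "6": 750.0}
_APICAL_EXTENT = {"2/3": 190.0, "4": 180.0, "5": 460.0, "6": 250.0}

#: Weight-scaling presets named after the study stages they caricature:
#: "original" (raw weights, no feedback), "intermediate" (recurrent weights
#: adjusted to fix rates), "final" (feedback added, L6 recurrent placement
#: restricted, background compensated).
PRESETS = ("original", "intermediate", "final")


def _default_populations() -> dict[str, PopulationSpec]:
    pops: dict[str, PopulationSpec] = {}
    for layer, soma in _LAYER_SOMA.items():
        pops[f"E{layer}"] = PopulationSpec(
            name=f"E{layer}", n_neurons=1000, soma_depth=soma,
            basal_extent=120.0, apical_extent=_APICAL_EXTENT[layer],
            sign="excitatory",
        )
        pops[f"I{layer}"] = PopulationSpec(
            name=f"I{layer}", n_neurons=250, soma_depth=soma,
            basal_extent=100.0, apical_extent=0.0, sign="inhibitory",
        )
    return pops


def _default_projections(with_feedback: bool) -> list[ProjectionSpec]:
    P = ProjectionSpec
    projs = [
        # thalamocortical: basal+apical within 150 µm on excitatory targets,
        # soma/basal on inhibitory targets
        P("LGN", "E4", 1.0, "both", 0.0, 150.0),
        P("LGN", "I4", 0.7, "basal", 0.0, 100.0),
        P("LGN", "E6", 0.45, "both", 0.0, 150.0),
        # recurrent excitatory; L2/3 and L4 targets within 200 µm
        P("E4", "E2/3", 0.55, "both", 0.0, 200.0),
        P("E4", "E5", 0.35, "both", 0.0, 250.0),
        P("E4", "I4", 0.45, "basal", 0.0, 100.0),
        P("E2/3", "E5", 0.45, "both", 0.0, 250.0),
        P("E2/3", "I2/3", 0.45, "basal", 0.0, 100.0),
        P("E5", "E6", 0.40, "both", 0.0, 300.0),
        P("E5", "I5", 0.45, "basal", 0.0, 100.0),
        P("E6", "I6", 0.40, "basal", 0.0, 100.0),
        # inhibitory, soma-targeting within layer
        P("I2/3", "E2/3", 0.9, "soma", 0.0, 50.0),
        P("I4", "E4", 0.9, "soma", 0.0, 50.0),
        P("I5", "E5", 0.9, "soma", 0.0, 50.0),
        P("I6", "E6", 0.9, "soma", 0.0, 50.0),
        # background drive to every population
        *[P("BKG", pop, 0.30, "basal", 0.0, 100.0)
          for pop in ("E2/3", "E4", "E5", "E6", "I2/3", "I4", "I5", "I6")],
    ]
    if with_feedback:
        projs += [
            # higher-area feedback: L2/3 apical within 150 µm, L5 apical
            # tufts (>300 µm) plus basal, inhibitory somata/basal dendrites
            P("LM", "E2/3", 0.55, "apical", 0.0, 150.0),
            P("LM", "E5", 0.40, "apical", 300.0, 460.0),
            P("LM", "E5", 0.20, "basal", 0.0, 150.0),
            P("LM", "I2/3", 0.30, "basal", 0.0, 150.0),
            P("LM", "I5", 0.30, "basal", 0.0, 150.0),
        ]
    return projs


def build_default_network(preset: str = "original") -> LaminarNetwork:
    """V1-like laminar network in one of the three named configurations."""
    if preset not in PRESETS:
        raise InvalidArgumentError(f"unknown preset {preset!r}; expected one of {PRESETS}")
    net = LaminarNetwork(
        populations=_default_populations(),
        projections=_default_projections(with_feedback=(preset == "final")),
    )
    if preset in ("intermediate", "final"):
        # fix rates: weaken E->I (then compensate), weaken E->E, strengthen I->E
        factors = {}
        for proj in net.projections:
            src, tgt = proj.source, proj.target
            if src.startswith("E") and tgt.startswith("I"):
                factors[proj.name] = 0.7
            elif src.startswith("E") and tgt.startswith("E"):
                factors[proj.name] = 0.8
            elif src.startswith("I"):
                factors[proj.name] = 1.15
        net = scale_weights(net, factors)
    if preset == "final":
        # background compensation on feedback-targeted populations
        factors = {
            f"BKG->{pop}": 0.4 for pop in ("E2/3", "E5", "I2/3", "I5")
        }
        net = scale_weights(net, factors)
        # restrict recurrent synapses onto L6 excitatory cells to 150 µm,
        # shrinking the deep sink/source separation
        net.projections = [
            replace(p, max_dist=150.0)
            if p.target == "E6" and p.source.startswith("E")
            else p
            for p in net.projections
        ]
    net.validate()
    return net


# --------------------------------------------------------------------------
# placement kernels
# --------------------------------------------------------------------------


def _gaussian_kernel(depth_axis: np.ndarray, center: float, sigma: float) -> np.ndarray:
    k = np.exp(-((depth_axis - center) ** 2) / (2.0 * sigma**2))
    s = k.sum()
    if s <= 0:
        raise InvalidArgumentError("placement kernel falls outside the depth grid")
    return k / s


def _segment_kernel(
    depth_axis: np.ndarray, soma: float, direction: int, lo: float, hi: float
) -> np.ndarray:
    """Kernel over a dendritic segment from ``lo`` to ``hi`` µm from the soma.

    ``direction`` +1 places below the soma (basal, deeper), -1 above
    (apical, toward the pia).
    """
    mid = soma + direction * 0.5 * (lo + hi)
    sigma = max((hi - lo) / 4.0, 10.0)
    return _gaussian_kernel(depth_axis, mid, sigma)


def placement_kernel(
    net: LaminarNetwork, proj: ProjectionSpec
) -> tuple[np.ndarray, float]:
    """Depth kernel of the synaptic deposit and its mean soma distance (µm)."""
    tgt = net.populations[proj.target]
    ax = net.depth_axis
    if proj.placement == "soma":
        return _gaussian_kernel(ax, tgt.soma_depth, 15.0), 0.0
    basal_hi = min(proj.max_dist, tgt.basal_extent)
    apical_hi = min(proj.max_dist, tgt.apical_extent)
    if proj.placement == "basal":
        lo, hi = min(proj.min_dist, basal_hi), basal_hi
        return _segment_kernel(ax, tgt.soma_depth, +1, lo, hi), 0.5 * (lo + hi)
    if proj.placement == "apical":
        if tgt.apical_extent <= 0:
            raise InvalidArgumentError(
                f"{proj.name}: apical placement on {tgt.name} (no apical dendrite)"
            )
        lo, hi = min(proj.min_dist, apical_hi), apical_hi
        return _segment_kernel(ax, tgt.soma_depth, -1, lo, hi), 0.5 * (lo + hi)
    # both: equal split between basal and apical segments
    blo, bhi = min(proj.min_dist, basal_hi), basal_hi
    alo, ahi = min(proj.min_dist, apical_hi), apical_hi
    kb = _segment_kernel(ax, tgt.soma_depth, +1, blo, bhi)
    ka = _segment_kernel(ax, tgt.soma_depth, -1, alo, ahi)
    return 0.5 * (kb + ka), 0.25 * (blo + bhi + alo + ahi)


def drive_attenuation(proj: ProjectionSpec, mean_dist_um: float) -> float:
    """Multiplicative drive attenuation for a placement distance."""
    return proj.attenuation ** (mean_dist_um / 100.0)


# --------------------------------------------------------------------------
# inputs and simulation
# --------------------------------------------------------------------------


def default_inputs(
    duration_ms: float = 150.0, dt_ms: float = 0.5, t_start_ms: float = -50.0
) -> dict[str, np.ndarray]:
    """External drives on the simulation grid: LGN ramp peaking ~40 ms,
    sustained LM feedback from ~55 ms, constant background."""
    t = np.arange(t_start_ms, duration_ms, dt_ms)
    lgn = np.interp(t, [0.0, 30.0, 40.0, 55.0, 150.0, 250.0],
                    [0.0, 0.0, 1.0, 0.55, 0.45, 0.45]) * (t >= 0)
    lm = np.interp(t, [0.0, 45.0, 60.0, 150.0, 250.0],
                   [0.0, 0.0, 1.0, 0.9, 0.9]) * (t >= 0)
    bkg = np.ones_like(t) * 0.5
    return {"t_ms": t, "LGN": lgn, "LM": lm, "BKG": bkg}


def feedback_switch(
    inputs: dict[str, np.ndarray], off_time_ms: float
) -> dict[str, np.ndarray]:
    """Zero the feedback drive after ``off_time_ms``."""
    t = inputs["t_ms"]
    if off_time_ms < t[0] or off_time_ms > t[-1] + (t[1] - t[0]):
        raise InvalidArgumentError(
            f"off_time {off_time_ms} ms outside the simulation window "
            f"[{t[0]}, {t[-1]}] ms"
        )
    out = dict(inputs)
    out["LM"] = np.where(t >= off_time_ms, 0.0, inputs["LM"])
    return out


MAX_RATE = 1e6


def simulate(
    net: LaminarNetwork,
    inputs: dict[str, np.ndarray] | None = None,
    duration_ms: float = 150.0,
    dt_ms: float = 0.5,
    seed: int = 0,
    somatic_active_gain: float = 0.0,
) -> SimResult:
    """Integrate the rate network and accumulate depth-resolved deposits.

    Threshold-linear dynamics per population:
    ``tau dr/dt = -r + [sum_proj w * attenuation * r_src(t - delay) + 0]_+``.
    Each projection deposits ``w * r_src`` inward current over its placement
    kernel and the same amount outward at the soma (reversed for inhibitory
    sources), so the depth integral of the total CSD is zero by construction.

    ``somatic_active_gain`` toggles a caricature of somatic active
    conductances: each excitatory population adds an extra rate-proportional
    dipole with outward (source) current at the soma balanced by inward
    current over its dendritic span.
    """
    net.validate()
    if dt_ms <= 0:
        raise InvalidArgumentError("dt must be positive")
    if inputs is None:
        inputs = default_inputs(duration_ms, dt_ms)
    t = inputs["t_ms"]
    if t[-1] < duration_ms - dt_ms - 1e-9:
        raise InvalidArgumentError("inputs do not cover the simulation window")
    n_t = t.size
    ax = net.depth_axis
    pops = list(net.populations)
    rates = {p: np.zeros(n_t) for p in pops}

    # precompute kernels, attenuations, signs, lags
    pinfo = []
    for proj in net.projections:
        kern, dist = placement_kernel(net, proj)
        soma_kern = _gaussian_kernel(
            ax, net.populations[proj.target].soma_depth, SOMA_KERNEL_SIGMA_UM
        )
        src_pop = net.populations.get(proj.source)
        inhibitory = src_pop is not None and src_pop.sign == "inhibitory"
        lag = int(round(proj.delay_ms / dt_ms))
        pinfo.append(
            (proj, kern, soma_kern, drive_attenuation(proj, dist), inhibitory, lag)
        )

    ext = {k: v for k, v in inputs.items() if k != "t_ms"}

    def lagged_source(proj, lag):
        src = ext[proj.source] if proj.source in ext else rates[proj.source]
        if lag == 0:
            return src
        pad = src[0] if proj.source in ext else 0.0
        return np.concatenate([np.full(lag, pad), src[: n_t - lag]])

    drive = np.zeros(len(pops))
    pop_index = {p: i for i, p in enumerate(pops)}
    for it in range(1, n_t):
        drive[:] = 0.0
        for proj, _, _, atten, inhibitory, lag in pinfo:
            i_src = max(0, it - 1 - lag)
            if proj.source in ext:
                r_src = ext[proj.source][i_src]
            else:
                r_src = rates[proj.source][i_src]
            s = -1.0 if inhibitory else 1.0
            drive[pop_index[proj.target]] += s * atten * proj.weight * r_src
        for p in pops:
            tau = net.populations[p].tau_ms
            r_prev = rates[p][it - 1]
            r_new = r_prev + dt_ms / tau * (-r_prev + max(drive[pop_index[p]], 0.0))
            if not np.isfinite(r_new) or r_new > MAX_RATE:
                raise NumericalFailureError(f"rate divergence in population {p!r}")
            rates[p][it] = max(r_new, 0.0)

    # deposits: inward current on the placement kernel, equal return current
    # at the soma; polarity reversed for inhibitory sources
    csd = {p: np.zeros((ax.size, n_t)) for p in pops}
    for proj, kern, soma_kern, _, inhibitory, lag in pinfo:
        current = proj.weight * lagged_source(proj, lag)
        profile = (soma_kern - kern) if not inhibitory else (kern - soma_kern)
        csd[proj.target] += np.outer(profile, current)

    if somatic_active_gain:
        for p in pops:
            spec = net.populations[p]
            if spec.sign != "excitatory":
                continue
            soma_kern = _gaussian_kernel(ax, spec.soma_depth, 15.0)
            span = max(spec.basal_extent, spec.apical_extent)
            dend_kern = _gaussian_kernel(
                ax, spec.soma_depth - 0.25 * spec.apical_extent, span / 2.0
            )
            csd[p] += somatic_active_gain * np.outer(
                soma_kern - dend_kern, rates[p]
            )

    csd_total = sum(csd.values())
    op = build_forward(ax, context="model")
    lfp = op.matrix @ csd_total
    return SimResult(
        rates=rates,
        csd_by_population=csd,
        csd_total=csd_total,
        lfp_total=lfp,
        depth_axis=ax.copy(),
        time_axis=t.copy(),
    )


# --------------------------------------------------------------------------
# network surgery
# --------------------------------------------------------------------------


def _match(proj: ProjectionSpec, selector) -> bool:
    """Selector: projection name "SRC->TGT", source name, or callable."""
    if callable(selector):
        return bool(selector(proj))
    if "->" in str(selector):
        return proj.name == selector
    return proj.source == selector or proj.target == selector


def set_placement(
    net: LaminarNetwork, selector, scheme: str
) -> LaminarNetwork:
    """Replace the placement scheme of matching projections; weights untouched."""
    if scheme not in ("basal", "apical", "both"):
        raise InvalidArgumentError(f"bad placement scheme {scheme!r}")
    out = net.copy()
    changed = []
    for i, proj in enumerate(out.projections):
        if _match(proj, selector):
            tgt = out.populations[proj.target]
            if scheme in ("apical", "both") and tgt.apical_extent <= 0:
                raise InvalidArgumentError(
                    f"{proj.name}: cannot place {scheme!r} on {tgt.name} "
                    "(no apical dendrite)"
                )
            out.projections[i] = replace(proj, placement=scheme)
            changed.append(proj.name)
    if not changed:
        raise InvalidArgumentError(f"selector matched no projection: {selector!r}")
    return out


def scale_weights(net: LaminarNetwork, factors: dict[str, float]) -> LaminarNetwork:
    """Scale projection weights by name; placements untouched."""
    for name, f in factors.items():
        if f <= 0:
            raise InvalidArgumentError(f"factor for {name!r} must be positive")
    out = net.copy()
    seen = set()
    for i, proj in enumerate(out.projections):
        if proj.name in factors:
            out.projections[i] = replace(proj, weight=proj.weight * factors[proj.name])
            seen.add(proj.name)
    missing = set(factors) - seen
    if missing:
        raise InvalidArgumentError(f"unknown projections in factor map: {sorted(missing)}")
    return out


def ablate(net: LaminarNetwork, which: str) -> LaminarNetwork:
    """Remove a class of projections: recurrent, inhibitory, feedback or lgn."""
    preds = {
        "recurrent": lambda p: p.source in net.populations,
        "inhibitory": lambda p: net.populations.get(p.source) is not None
        and net.populations[p.source].sign == "inhibitory",
        "feedback": lambda p: p.source == "LM",
        "lgn": lambda p: p.source == "LGN",
    }
    if which not in preds:
        raise InvalidArgumentError(
            f"unknown ablation {which!r}; expected one of {sorted(preds)}"
        )
    out = net.copy()
    out.projections = [p for p in out.projections if not preds[which](p)]
    return out


def population_csd_contribution(result: SimResult, population: str) -> np.ndarray:
    """One population's deposit grid; contributions sum to ``csd_total``."""
    try:
        return result.csd_by_population[population]
    except KeyError:
        raise InvalidArgumentError(
            f"unknown population {population!r}; have {list(result.csd_by_population)}"
        ) from None
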