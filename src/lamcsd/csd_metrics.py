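"""Wasserstein-distance statistics between CSD patterns.

Sinks and sources are normalized to unit mass separately, compared with an
exact W1 under the grid-index Euclidean ground metric, and the two costs
are summed into a total pattern distance.  Cohort machinery computes the
pairwise distance matrix and compares inter-trial against inter-animal
variability with two-sample KS tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .core import CSDPattern, DegeneratePatternError, InvalidArgumentError
from .transport import wasserstein_2d


@dataclass(frozen=True)
class NormalizedMassPair:
    """Sink and source components as separately normalized mass distributions."""

    sink_mass: np.ndarray  # nonnegative, sums to 1 (sign-flipped negative part)
    source_mass: np.ndarray  # nonnegative, sums to 1 (positive part)
    depth_axis: np.ndarray
    time_axis: np.ndarray

    def signed(self) -> np.ndarray:
        """Signed pattern whose sinks sum to -1 and sources to +1."""
        return self.source_mass - self.sink_mass


@dataclass(frozen=True)
class WDResult:
    wd_sinks: float
    wd_sources: float
    normalized_total: float | None = None

    @property
    def wd_total(self) -> float:
        return self.wd_sinks + self.wd_sources


def split_normalize(pattern: CSDPattern) -> NormalizedMassPair:
    """Split a signed CSD pattern into unit-mass sink and source components."""
    v = pattern.values
    neg = np.maximum(-v, 0.0)
    pos = np.maximum(v, 0.0)
    sneg, spos = neg.sum(), pos.sum()
    if sneg <= 0 or spos <= 0:
        raise DegeneratePatternError(
            "pattern must contain both sinks and sources "
            f"(sink mass {sneg:.3g}, source mass {spos:.3g})"
        )
    return NormalizedMassPair(
        sink_mass=neg / sneg,
        source_mass=pos / spos,
        depth_axis=pattern.depth_axis.copy(),
        time_axis=pattern.time_axis.copy(),
    )


def wd_csd(p1: CSDPattern, p2: CSDPattern, depth_weight: float = 1.0) -> WDResult:
    """Total WD between two CSD patterns: sink WD plus source WD."""
    if p1.shape != p2.shape:
        raise InvalidArgumentError(f"patterns must share a grid: {p1.shape} vs {p2.shape}")
    m1 = split_normalize(p1)
    m2 = split_normalize(p2)
    return WDResult(
        wd_sinks=wasserstein_2d(m1.sink_mass, m2.sink_mass, depth_weight),
        wd_sources=wasserstein_2d(m1.source_mass, m2.source_mass, depth_weight),
    )


def pairwise_wd(
    patterns: dict[str, CSDPattern] | list[CSDPattern], depth_weight: float = 1.0
) -> tuple[pd.DataFrame, np.ndarray]:
    """Pairwise total WDs between patterns.

    Returns the symmetric distance matrix (labelled DataFrame) and the
    condensed upper-triangle vector (n(n-1)/2 entries, row-major).
    Degenerate (single-signed) patterns are excluded with a warning.
    """
    if isinstance(patterns, dict):
        items = list(patterns.items())
    else:
        items = [(str(i), p) for i, p in enumerate(patterns)]
    if len(items) < 2:
        raise InvalidArgumentError("need at least two patterns")

    masses = {}
    dropped = []
    for name, p in items:
        try:
            masses[name] = split_normalize(p)
        except DegeneratePatternError:
            dropped.append(name)
    if dropped:
        warnings.warn(f"excluding degenerate patterns: {dropped}", stacklevel=2)
    names = list(masses)
    n = len(names)
    mat = np.zeros((n, n))
    condensed = []
    for i in range(n):
        for j in range(i + 1, n):
            mi, mj = masses[names[i]], masses[names[j]]
            d = wasserstein_2d(mi.sink_mass, mj.sink_mass, depth_weight) + wasserstein_2d(
                mi.source_mass, mj.source_mass, depth_weight
            )
            mat[i, j] = mat[j, i] = d
            condensed.append(d)
    return (
        pd.DataFrame(mat, index=names, columns=names),
        np.asarray(condensed, dtype=float),
    )


def normalize_wd(values: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Divide WD values by the maximum of the reference set."""
    reference = np.asarray(reference, dtype=float)
    if reference.size == 0:
        raise InvalidArgumentError("reference set is empty")
    ref = reference.max()
    if ref <= 0:
        raise InvalidArgumentError("reference maximum must be positive")
    return np.asarray(values, dtype=float) / ref


def trial_vs_animal_variability(
    trial_wds_per_animal: dict[str, np.ndarray], animal_wds: np.ndarray
) -> pd.DataFrame:
    """Two-sample KS tests of each animal's inter-trial WDs against the
    inter-animal WD distribution.

    Returns one row per animal with the KS statistic, asymptotic p-value and
    a flag for animals whose inter-trial distribution is stochastically
    larger (median above the inter-animal median and significant KS).
    A final row labelled ``pooled`` tests all inter-trial WDs together.
    """
    animal_wds = np.asarray(animal_wds, dtype=float)
    if animal_wds.size < 2:
        raise InvalidArgumentError("need at least two inter-animal WDs")
    rows = []
    pooled = []
    for animal, wds in trial_wds_per_animal.items():
        wds = np.asarray(wds, dtype=float)
        if wds.size < 2:
            raise InvalidArgumentError(f"animal {animal!r} has fewer than two trial WDs")
        res = scipy.stats.ks_2samp(wds, animal_wds, method="asymp")
        larger = bool(
            np.median(wds) > np.median(animal_wds) and res.pvalue < 0.001
        )
        rows.append(
            {"animal_id": animal, "ks_statistic": float(res.statistic),
             "p_value": float(res.pvalue), "trials_more_variable": larger}
        )
        pooled.append(wds)
    res = scipy.stats.ks_2samp(np.concatenate(pooled), animal_wds, method="asymp")
    rows.append(
        {"animal_id": "pooled", "ks_statistic": float(res.statistic),
         "p_value": float(res.pvalue), "trials_more_variable": False}
    )
    return pd.DataFrame(rows)
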