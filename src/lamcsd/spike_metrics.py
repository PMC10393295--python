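"""Spiking statistics: RS/FS classification, population rates, KS similarity,
rate correlations, leave-one-out cohort comparison and unit-level moments."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage
import scipy.stats

from .core import InvalidArgumentError, LamcsdError, UnitTable

#: Trough-to-peak duration cutoffs (ms): FS strictly below, RS at/above.
CLASSIFICATION_CUTOFFS_MS = {"V1": 0.4, "LM": 0.4, "LGN": 0.3}

RATE_BIN_MS = 1.0
RATE_SMOOTH_SIGMA_BINS = 2.0
MIN_CELLS = 10

#: Standard analysis populations: RS split by layer, FS pooled across layers.
POPULATIONS = ("RS L2/3", "RS L4", "RS L5", "RS L6", "FS")


@dataclass(frozen=True)
class WindowSet:
    """Analysis windows in ms relative to flash onset (half-open)."""

    baseline: tuple[float, float] = (-250.0, 0.0)
    peak: tuple[float, float] = (35.0, 60.0)
    sustained: tuple[float, float] = (60.0, 100.0)

    def items(self):
        return (("baseline", self.baseline), ("peak", self.peak),
                ("sustained", self.sustained))


@dataclass(frozen=True)
class PopulationRate:
    population: str
    t_ms: np.ndarray  # uniform 1 ms grid (bin centers)
    rate: np.ndarray  # spikes/s, Gaussian-smoothed


class UndefinedCorrelationError(LamcsdError, ValueError):
    """Pearson correlation undefined for zero-variance input."""


def classify_rs_fs(duration_ms: float, area: str) -> str:
    """RS/FS by trough-to-peak duration: FS below the area cutoff, ties -> RS."""
    if duration_ms <= 0:
        raise InvalidArgumentError("duration must be positive")
    try:
        cutoff = CLASSIFICATION_CUTOFFS_MS[area]
    except KeyError:
        raise InvalidArgumentError(
            f"unknown area {area!r}; expected one of {sorted(CLASSIFICATION_CUTOFFS_MS)}"
        ) from None
    return "FS" if duration_ms < cutoff else "RS"


def classify_units(table: UnitTable) -> UnitTable:
    """Add (or refresh) the ``cls`` column on the unit table."""
    units = table.units.copy()
    units["cls"] = [
        classify_rs_fs(d, a) for d, a in zip(units["duration_ms"], units["area"])
    ]
    return UnitTable(units=units, spikes=table.spikes, n_trials=table.n_trials)


def population_label(cls: str, layer: str) -> str | None:
    """Map a unit's class/layer to an analysis population (None = unused)."""
    if cls == "FS":
        return "FS"
    return {"2/3": "RS L2/3", "4": "RS L4", "5": "RS L5", "6": "RS L6"}.get(layer)


def _bin_edges(window_ms: tuple[float, float]) -> np.ndarray:
    t0, t1 = window_ms
    return np.arange(t0, t1 + RATE_BIN_MS / 2, RATE_BIN_MS)


def _spike_counts(
    table: UnitTable, unit_ids: pd.Series, window_ms: tuple[float, float]
) -> np.ndarray:
    """Summed per-bin spike counts over the given units, all trials."""
    edges = _bin_edges(window_ms)
    sp = table.spikes[table.spikes["unit_id"].isin(unit_ids)]
    times_ms = sp["spike_time_s"].to_numpy() * 1e3
    counts, _ = np.histogram(times_ms, bins=edges)
    return counts.astype(float)


def population_rate(
    table: UnitTable,
    unit_ids: pd.Series | list[str],
    population: str = "",
    window_ms: tuple[float, float] = (-250.0, 250.0),
    sigma_bins: float = RATE_SMOOTH_SIGMA_BINS,
) -> PopulationRate:
    """Per-bin spike count averaged over units and trials, in spikes/s,
    Gaussian-smoothed along time."""
    unit_ids = pd.Series(list(unit_ids))
    n_units = unit_ids.nunique()
    if n_units == 0:
        raise InvalidArgumentError("population is empty")
    if table.n_trials < 1:
        raise InvalidArgumentError("no trials recorded")
    counts = _spike_counts(table, unit_ids, window_ms)
    rate = counts / (n_units * table.n_trials * RATE_BIN_MS * 1e-3)
    smoothed = scipy.ndimage.gaussian_filter1d(rate, sigma=sigma_bins)
    edges = _bin_edges(window_ms)
    centers = edges[:-1] + RATE_BIN_MS / 2
    return PopulationRate(population=population, t_ms=centers, rate=smoothed)


def per_cell_mean_rates(
    table: UnitTable, unit_ids: pd.Series | list[str], window_ms: tuple[float, float]
) -> np.ndarray:
    """Mean firing rate (spikes/s) per cell in a window, averaged over trials."""
    unit_ids = list(dict.fromkeys(unit_ids))
    t0, t1 = window_ms
    dur_s = (t1 - t0) * 1e-3
    sp = table.spikes
    in_win = (sp["spike_time_s"] * 1e3 >= t0) & (sp["spike_time_s"] * 1e3 < t1)
    counts = sp[in_win].groupby("unit_id").size()
    return np.array(
        [counts.get(u, 0) / (table.n_trials * dur_s) for u in unit_ids], dtype=float
    )


def ks_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """1 minus the two-sample KS statistic; 1 = identical, 0 = disjoint."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidArgumentError("samples must be non-empty")
    return 1.0 - float(scipy.stats.ks_2samp(a, b).statistic)


def rate_correlation(
    a: PopulationRate, b: PopulationRate, window_ms: tuple[float, float] = (0.0, 100.0)
) -> float:
    """Pearson correlation between two population rates over a window."""
    if a.t_ms.size != b.t_ms.size or not np.allclose(a.t_ms, b.t_ms):
        raise InvalidArgumentError("population rates must share a time grid")
    mask = (a.t_ms >= window_ms[0]) & (a.t_ms <= window_ms[1])
    x, y = a.rate[mask], b.rate[mask]
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("zero-variance rate in correlation window")
    return float(scipy.stats.pearsonr(x, y).statistic)


def _population_units(table: UnitTable) -> pd.DataFrame:
    units = table.units
    if "cls" not in units.columns:
        raise InvalidArgumentError("classify_units must run before population grouping")
    pops = units.apply(lambda r: population_label(r["cls"], r["layer"]), axis=1)
    out = units.assign(population=pops)
    return out[out["population"].notna()]


def leave_one_out_compare(
    cohort: dict[str, UnitTable],
    metric: str,
    windows: WindowSet | None = None,
    min_cells: int = MIN_CELLS,
    corr_window_ms: tuple[float, float] = (0.0, 100.0),
) -> pd.DataFrame:
    """Each animal vs the pooled rest of the cohort, per population.

    ``metric="ks"`` compares per-cell mean-rate distributions per window
    (columns ks_baseline/ks_peak/ks_sustained); ``metric="corr"`` correlates
    population rate time courses over ``corr_window_ms``.  Populations with
    ``min_cells`` cells or fewer in an animal are skipped.
    """
    if metric not in ("ks", "corr"):
        raise InvalidArgumentError(f"unknown metric {metric!r}")
    if len(cohort) < 2:
        raise InvalidArgumentError("cohort must contain at least two animals")
    windows = windows or WindowSet()

    per_animal = {a: _population_units(t) for a, t in cohort.items()}
    rows = []
    for animal, table in cohort.items():
        units_a = per_animal[animal]
        for pop in POPULATIONS:
            ids_a = units_a.loc[units_a["population"] == pop, "unit_id"]
            if len(ids_a) <= min_cells:
                continue
            rest_tables = [
                (other, cohort[other], per_animal[other]) for other in cohort if other != animal
            ]
            row: dict[str, object] = {"animal_id": animal, "population": pop,
                                      "n_cells": len(ids_a)}
            if metric == "ks":
                for wname, win in windows.items():
                    own = per_cell_mean_rates(table, ids_a, win)
                    rest = np.concatenate(
                        [
                            per_cell_mean_rates(
                                t, u.loc[u["population"] == pop, "unit_id"], win
                            )
                            for _, t, u in rest_tables
                        ]
                    )
                    if rest.size == 0:
                        row[f"ks_{wname}"] = np.nan
                    else:
                        row[f"ks_{wname}"] = ks_similarity(own, rest)
            else:
                own_rate = population_rate(table, ids_a, pop)
                pooled = _pooled_rate(rest_tables, pop)
                if pooled is None:
                    row["r"] = np.nan
                else:
                    row["r"] = rate_correlation(own_rate, pooled, corr_window_ms)
            rows.append(row)
    if not rows:
        warnings.warn("no animal/population met the cell-count criterion", stacklevel=2)
        return pd.DataFrame(columns=["animal_id", "population"])
    return pd.DataFrame(rows)


def _pooled_rate(rest_tables, pop: str) -> PopulationRate | None:
    """Cell-weighted pooled population rate over the rest of the cohort."""
    rates, weights = [], []
    for _, table, units in rest_tables:
        ids = units.loc[units["population"] == pop, "unit_id"]
        if len(ids) == 0:
            continue
        rates.append(population_rate(table, ids, pop))
        weights.append(len(ids))
    if not rates:
        return None
    total = sum(weights)
    avg = sum(w * r.rate for w, r in zip(weights, rates)) / total
    return PopulationRate(population=pop, t_ms=rates[0].t_ms, rate=avg)


def outlier_assessment(model_score: float, cohort_scores: np.ndarray) -> dict:
    """Locate a score relative to the cohort's boxplot.

    ``within_whiskers`` uses Tukey whiskers (most extreme cohort points
    within 1.5 IQR of the quartiles); ``within_range`` uses the raw
    min-to-max span.  The headline verdict follows the whisker convention.
    """
    scores = np.asarray(cohort_scores, dtype=float)
    if scores.size == 0:
        raise InvalidArgumentError("cohort scores must be non-empty")
    q1, q3 = np.percentile(scores, [25, 75])
    iqr = q3 - q1
    in_fence = scores[(scores >= q1 - 1.5 * iqr) & (scores <= q3 + 1.5 * iqr)]
    lo, hi = in_fence.min(), in_fence.max()
    within_whiskers = bool(lo <= model_score <= hi)
    within_range = bool(scores.min() <= model_score <= scores.max())
    return {
        "verdict": "within" if within_whiskers else "outlier",
        "within_whiskers": within_whiskers,
        "within_range": within_range,
        "whisker_lo": float(lo),
        "whisker_hi": float(hi),
        "raw_min": float(scores.min()),
        "raw_max": float(scores.max()),
    }


def unit_feature_moments(
    table: UnitTable,
    feature: str,
    window_ms: tuple[float, float] = (0.0, 100.0),
    sigma_bins: float = RATE_SMOOTH_SIGMA_BINS,
) -> pd.DataFrame:
    """First four moments of a per-unit rate feature, per population.

    Features are computed on each unit's smoothed 1 ms rate in the window:
    ``peak_rate`` (max), ``peak_latency`` (ms of max), ``max_curvature``
    (max second finite difference).  Moments are mean, SD, skewness and
    excess kurtosis (bias-uncorrected); degenerate samples yield NaN with a
    warning.
    """
    if feature not in ("peak_rate", "peak_latency", "max_curvature"):
        raise InvalidArgumentError(f"unknown feature {feature!r}")
    units = _population_units(table)
    rows = []
    for pop in POPULATIONS:
        ids = units.loc[units["population"] == pop, "unit_id"]
        if len(ids) < 2:
            continue
        feats = []
        for uid in ids:
            r = population_rate(table, [uid], pop, window_ms=window_ms,
                                sigma_bins=sigma_bins)
            if feature == "peak_rate":
                feats.append(r.rate.max())
            elif feature == "peak_latency":
                feats.append(r.t_ms[int(np.argmax(r.rate))])
            else:
                feats.append(np.diff(r.rate, n=2).max() if r.rate.size > 2 else 0.0)
        x = np.asarray(feats)
        sd = float(np.std(x))
        if sd == 0:
            warnings.warn(
                f"constant {feature} sample in {pop}; higher moments undefined",
                stacklevel=2,
            )
            skew = kurt = float("nan")
        else:
            skew = float(scipy.stats.skew(x, bias=True))
            kurt = float(scipy.stats.kurtosis(x, bias=True))
        rows.append(
            {"population": pop, "feature": feature, "n_units": len(ids),
             "mean": float(np.mean(x)), "sd": sd, "skewness": skew,
             "excess_kurtosis": kurt}
        )
    return pd.DataFrame(rows)
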