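"""Shared fixtures and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import sparse
from scipy.optimize import linprog

from lamcsd.config import RunConfig
from lamcsd.core import CSDPattern


def lp_transport_oracle(a: np.ndarray, b: np.ndarray, cost: np.ndarray) -> float:
    """Brute-force transportation LP over all feasible plans (scipy HiGHS).

    Independent of the package's network-simplex path.
    """
    na, nb = len(a), len(b)
    row_idx = np.repeat(np.arange(na), nb)
    col_idx = np.tile(np.arange(nb), na) + na
    var = np.arange(na * nb)
    A = sparse.coo_matrix(
        (
            np.ones(2 * na * nb),
            (np.concatenate([row_idx, col_idx]), np.concatenate([var, var])),
        ),
        shape=(na + nb, na * nb),
    ).tocsr()
    res = linprog(
        cost.ravel(), A_eq=A, b_eq=np.concatenate([a, b]),
        bounds=(0, None), method="highs",
    )
    assert res.status == 0, f"oracle LP failed: {res.message}"
    return float(res.fun)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_config() -> RunConfig:
    """Desk-scale pilot configuration for pipeline-level tests."""
    cfg = RunConfig.default()
    cfg.n_animals = 8
    cfg.n_missing_lfp = 1
    cfg.n_bad_probe = 1
    cfg.n_no_units = 1
    cfg.n_trials = 6
    cfg.pipeline_csd_trials = 4
    cfg.pipeline_trial_wd_subset = 3
    cfg.pipeline_spike_animals = 3
    cfg.spike_units_per_population = 8
    cfg.seed = 7
    return cfg


def make_pattern(values: np.ndarray) -> CSDPattern:
    """CSD pattern with unit-spaced axes around the given values."""
    values = np.asarray(values, dtype=float)
    M, K = values.shape
    return CSDPattern(
        values=values,
        depth_axis=np.arange(M, dtype=float),
        time_axis=np.arange(K, dtype=float),
    )


@pytest.fixture
def two_blob_pattern() -> CSDPattern:
    """16 x 28 pattern with compactly supported interior sink and source.

    Blobs are truncated at 3 sigma so rigid shifts of a few bins stay fully
    interior (no mass wraps or leaves the grid).
    """
    z = np.arange(16)[:, None]
    t = np.arange(28)[None, :]

    def blob(zc, tc, sz=1.0, st=1.5):
        g = np.exp(-((z - zc) ** 2) / (2 * sz**2) - ((t - tc) ** 2) / (2 * st**2))
        g[(np.abs(z - zc) > 3 * sz) | (np.abs(t - tc) > 3 * st)] = 0.0
        return g

    return make_pattern(-blob(5, 8) + blob(10, 18))
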