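"""Cohort-level canonical CSD pattern: PC 1 over animals, plus the plain mean."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .core import CSDPattern, GridPattern, InvalidArgumentError, LamcsdError


class DegenerateCohortError(LamcsdError, ValueError):
    """Cohort has no variance after centering; PCA is undefined."""


@dataclass(frozen=True)
class CanonicalPattern:
    pc1: GridPattern  # unit-norm first principal component, reshaped
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray  # per-animal projections onto PC1
    cohort_mean: GridPattern


def stack_cohort(patterns: dict[str, CSDPattern] | list[CSDPattern]) -> np.ndarray:
    """Stack flattened per-animal patterns into an N x (M*K) matrix.

    Flattening is depth-major (all time samples of the first depth first),
    i.e. row-major over the (depth, time) grid.
    """
    if isinstance(patterns, dict):
        items = list(patterns.items())
    else:
        items = [(str(i), p) for i, p in enumerate(patterns)]
    if not items:
        raise InvalidArgumentError("no patterns to stack")
    ref_name, ref = items[0]
    rows = []
    for name, p in items:
        if p.shape != ref.shape or not (
            np.allclose(p.depth_axis, ref.depth_axis)
            and np.allclose(p.time_axis, ref.time_axis)
        ):
            raise InvalidArgumentError(
                f"pattern {name!r} is not on the common grid of {ref_name!r}"
            )
        rows.append(p.flatten())
    return np.vstack(rows)


def unflatten(vector: np.ndarray, template: GridPattern) -> GridPattern:
    """Inverse of the depth-major flattening, onto the template's axes."""
    M, K = template.shape
    return GridPattern(
        values=np.asarray(vector, dtype=float).reshape(M, K),
        depth_axis=template.depth_axis.copy(),
        time_axis=template.time_axis.copy(),
        units=template.units,
    )


def mean_pattern(matrix: np.ndarray, template: GridPattern) -> GridPattern:
    """Element-wise cohort mean reshaped onto the grid."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 1:
        raise InvalidArgumentError("matrix must have at least one row")
    return unflatten(matrix.mean(axis=0), template)


def pca_canonical(matrix: np.ndarray, template: GridPattern) -> CanonicalPattern:
    """Feature-centered PCA over animals; PC 1 is the canonical pattern.

    The PC 1 sign is fixed so that its correlation with the cohort mean is
    nonnegative.  Explained-variance ratios cover all retained components
    (min(N, M*K), capped by the data rank).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise InvalidArgumentError("PCA needs at least two animals")
    centered = matrix - matrix.mean(axis=0, keepdims=True)
    if not np.any(np.abs(centered) > 0):
        raise DegenerateCohortError("cohort has zero variance after centering")

    pca = PCA(n_components=min(matrix.shape))
    scores = pca.fit_transform(matrix)
    pc1 = pca.components_[0]
    loadings = scores[:, 0]
    mean_vec = matrix.mean(axis=0)
    mc = mean_vec - mean_vec.mean()
    pc = pc1 - pc1.mean()
    corr = float(pc @ mc)
    if corr < 0:
        pc1 = -pc1
        loadings = -loadings

    return CanonicalPattern(
        pc1=unflatten(pc1, template),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        loadings=loadings,
        cohort_mean=mean_pattern(matrix, template),
    )
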