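"""Preprocessing chain: standardization, correlation screening, seasonal
clustering, collinearity pruning, rotated PCA, and the train/validation split.

The intended workflow mirrors a common bioassessment screening recipe:
min-max rescale everything to [0, 1]; inspect the Pearson correlation matrix
of indices and water chemistry; cluster samples into two groups with K-means
(winter separates from the rest of the year in strongly seasonal rivers) and
keep only the non-winter cluster; drop one member of any (near-)perfectly
correlated predictor pair (TDS vs EC being the canonical case); summarise the
remaining predictors with a varimax-rotated PCA; and split 80/20 for the
symbolic-regression step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from statsmodels.multivariate.factor_rotation import rotate_factors

from .errors import (
    AmbiguousSeasonError,
    InsufficientDataError,
    InvalidKError,
    InvalidSplitError,
    RiverbioError,
    UndefinedCorrelationError,
)

__all__ = [
    "StandardizedMatrix",
    "ClusterAssignment",
    "PcaResult",
    "minmax_standardize",
    "pearson_correlation_matrix",
    "drop_collinear",
    "kmeans_cluster",
    "exclude_winter_cluster",
    "pca_varimax",
    "train_validation_split",
    "WINTER_MONTHS",
]

WINTER_MONTHS = (12, 1, 2)


@dataclass(frozen=True)
class StandardizedMatrix:
    """A [0,1] min-max rescaled matrix plus the bounds needed to invert it."""

    values: pd.DataFrame  # indexed by sample key, columns = variables
    mins: pd.Series
    maxs: pd.Series

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        """Apply the stored bounds to new data (values may leave [0,1])."""
        span = (self.maxs - self.mins).replace(0.0, 1.0)
        return (table[self.values.columns] - self.mins) / span

    def inverse(self, table: pd.DataFrame | pd.Series):
        span = (self.maxs - self.mins).replace(0.0, 1.0)
        if isinstance(table, pd.Series) and table.name in self.values.columns:
            return table * span[table.name] + self.mins[table.name]
        return table * span + self.mins

    def inverse_column(self, values: np.ndarray, column: str) -> np.ndarray:
        lo, hi = self.mins[column], self.maxs[column]
        span = hi - lo if hi > lo else 1.0
        return np.asarray(values) * span + lo


def minmax_standardize(table: pd.DataFrame) -> StandardizedMatrix:
    """Rescale each numeric column to [0, 1]; constant columns map to 0."""
    if len(table) < 2:
        raise InsufficientDataError("min-max standardization needs >= 2 rows")
    numeric = table.apply(pd.to_numeric)  # raises on non-numeric cells
    mins = numeric.min()
    maxs = numeric.max()
    span = (maxs - mins).replace(0.0, 1.0)
    values = (numeric - mins) / span
    return StandardizedMatrix(values=values, mins=mins, maxs=maxs)


def pearson_correlation_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations; errors on constant columns."""
    if len(table) < 3:
        raise InsufficientDataError("correlation needs >= 3 rows")
    stds = table.std(ddof=0)
    constant = stds[stds == 0.0].index.tolist()
    if constant:
        raise UndefinedCorrelationError(
            f"correlation undefined for constant column(s): {constant}"
        )
    corr = table.corr(method="pearson")
    return corr


def drop_collinear(
    corr: pd.DataFrame, threshold: float, keep_priority: Sequence[str]
) -> list[str]:
    """Greedily remove the lower-priority member of every |r| >= threshold pair.

    ``keep_priority`` orders variables from most to least preferred; variables
    absent from it rank below all listed ones, in matrix order.
    """
    if not (0.0 < threshold <= 1.0):
        raise RiverbioError("collinearity threshold must be in (0, 1]")
    names = list(corr.columns)
    rank = {v: i for i, v in enumerate(keep_priority)}
    order = sorted(names, key=lambda v: rank.get(v, len(rank) + names.index(v)))
    kept: list[str] = []
    for var in order:
        if any(abs(corr.loc[var, k]) >= threshold for k in kept):
            continue
        kept.append(var)
    return [v for v in names if v in kept]


@dataclass(frozen=True)
class ClusterAssignment:
    labels: pd.Series  # indexed by sample key, values in {0..k-1}
    centroids: np.ndarray  # (k, n_features)
    inertia: float


def kmeans_cluster(
    features: StandardizedMatrix | pd.DataFrame, k: int, seed: int, n_restarts: int = 10
) -> ClusterAssignment:
    """Lloyd's K-means from k-means++ starts, best of ``n_restarts`` by SSE."""
    table = features.values if isinstance(features, StandardizedMatrix) else features
    if k < 1 or k > len(table):
        raise InvalidKError(f"k={k} invalid for {len(table)} samples")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(table.to_numpy())
    return ClusterAssignment(
        labels=pd.Series(labels, index=table.index),
        centroids=km.cluster_centers_,
        inertia=float(km.inertia_),
    )


def exclude_winter_cluster(
    assignment: ClusterAssignment,
    months: pd.Series,
    winter_months: Sequence[int] = WINTER_MONTHS,
) -> pd.Index:
    """Drop the cluster holding the majority of winter samples; keep the rest.

    Requires a two-cluster assignment. ``months`` must share the assignment's
    sample index.
    """
    labels = assignment.labels
    if set(labels.unique()) - {0, 1} or assignment.centroids.shape[0] != 2:
        raise RiverbioError("winter exclusion requires a k=2 cluster assignment")
    months = months.loc[labels.index]
    is_winter = months.isin(list(winter_months))
    winter_in_0 = int((labels[is_winter] == 0).sum())
    winter_in_1 = int((labels[is_winter] == 1).sum())
    if winter_in_0 == winter_in_1:
        raise AmbiguousSeasonError(
            f"winter samples split evenly across clusters ({winter_in_0} each)"
        )
    winter_cluster = 0 if winter_in_0 > winter_in_1 else 1
    return labels.index[labels != winter_cluster]


@dataclass(frozen=True)
class PcaResult:
    loadings: pd.DataFrame  # unrotated, variables x components
    rotated_loadings: pd.DataFrame  # varimax-rotated
    explained_variance_ratio: np.ndarray  # per unrotated component

    @property
    def cumulative_explained(self) -> np.ndarray:
        return np.cumsum(self.explained_variance_ratio)


def pca_varimax(
    features: StandardizedMatrix | pd.DataFrame, n_components: int
) -> PcaResult:
    """PCA on the correlation matrix with varimax rotation of the loadings.

    Loadings are eigenvectors scaled by the square root of their eigenvalues
    (the convention of rotated-component tables in statistical packages), so
    each variable's squared loadings sum to its communality, which varimax
    preserves.
    """
    table = features.values if isinstance(features, StandardizedMatrix) else features
    if len(table) < 3:
        raise InsufficientDataError("PCA needs >= 3 rows")
    if n_components > table.shape[1]:
        raise RiverbioError("n_components exceeds number of variables")
    corr = pearson_correlation_matrix(table)
    eigval, eigvec = np.linalg.eigh(corr.to_numpy())
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0.0, None)
    ratio = eigval / eigval.sum()

    comps = [f"PC{i + 1}" for i in range(n_components)]
    load = eigvec[:, :n_components] * np.sqrt(eigval[:n_components])
    # fix sign so each component's largest-magnitude loading is positive
    for j in range(load.shape[1]):
        if load[np.argmax(np.abs(load[:, j])), j] < 0:
            load[:, j] = -load[:, j]
    loadings = pd.DataFrame(load, index=corr.columns, columns=comps)

    if n_components >= 2:
        rotated_arr, _ = rotate_factors(load, "varimax")
    else:
        rotated_arr = load.copy()
    for j in range(rotated_arr.shape[1]):
        if rotated_arr[np.argmax(np.abs(rotated_arr[:, j])), j] < 0:
            rotated_arr[:, j] = -rotated_arr[:, j]
    rotated = pd.DataFrame(rotated_arr, index=corr.columns, columns=comps)
    return PcaResult(
        loadings=loadings,
        rotated_loadings=rotated,
        explained_variance_ratio=ratio[:n_components],
    )


def train_validation_split(
    keys: Sequence[Hashable], fraction: float, seed: int
) -> tuple[list, list]:
    """Seeded uniform split; train size = round(fraction * n)."""
    keys = list(keys)
    n = len(keys)
    if not (0.0 < fraction < 1.0):
        raise InvalidSplitError("fraction must lie strictly between 0 and 1")
    if n < 2:
        raise InvalidSplitError("need at least 2 samples to split")
    n_train = int(round(fraction * n))
    if n_train == 0 or n_train == n:
        raise InvalidSplitError(
            f"fraction {fraction} leaves an empty part for n={n}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train = [keys[i] for i in sorted(perm[:n_train])]
    valid = [keys[i] for i in sorted(perm[n_train:])]
    return train, valid
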