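"""Multivariate phenotype profiling.

Per-cell feature tables from multiple images are combined, standardized by
robust z-scores (``(x - median) / IQR``, outlier-resistant), optionally
embedded in 2D for visualisation, and clustered by density (DBSCAN-style:
dense regions become clusters, sparse points noise with label -1).
Subpopulations can be split at a reference group's feature median, and
per-image cilia/nuclei counts aggregate into ciliated fractions.

``RobustZScaler`` and ``DensityClusterer`` follow the scikit-learn estimator
protocol (``fit``/``transform``/``fit_predict``, fitted attributes with a
trailing underscore) and compose with sklearn pipelines; the module-level
functions are thin wrappers over them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from sklearn.utils.validation import check_array, check_is_fitted

from .features import METADATA_COLUMNS

__all__ = [
    "ScaledTable",
    "ClusterResult",
    "RobustZScaler",
    "DensityClusterer",
    "assemble",
    "robust_scale",
    "embed",
    "dbscan",
    "choose_eps",
    "cluster_summary",
    "median_split",
    "ciliated_fraction",
]

logger = logging.getLogger(__name__)


@dataclass
class ScaledTable:
    """Robust z-scored feature values plus the fit statistics."""

    values: pd.DataFrame
    center: pd.Series
    scale: pd.Series
    dropped: list[str] = field(default_factory=list)


@dataclass
class ClusterResult:
    """Density-clustering labels (-1 = noise), relabeled so cluster 0 is the
    largest."""

    labels: np.ndarray
    eps: float
    min_samples: int

    @property
    def n_clusters(self) -> int:
        return int((np.unique(self.labels) >= 0).sum())


class RobustZScaler(BaseEstimator, TransformerMixin):
    """Robust z-score standardization: ``z = (x - median) / (Q3 - Q1)``.

    Quartiles use linear interpolation.  Columns with zero IQR carry no
    usable variation and are dropped with a warning (``dropped_`` lists
    them).  On the fitting data every retained column has median 0 and
    IQR 1.
    """

    def fit(self, X, y=None):
        X = self._as_frame(X)
        q1 = X.quantile(0.25, interpolation="linear")
        q2 = X.quantile(0.50, interpolation="linear")
        q3 = X.quantile(0.75, interpolation="linear")
        iqr = q3 - q1
        keep = iqr > 0
        self.dropped_ = list(X.columns[~keep])
        if self.dropped_:
            warnings.warn(f"dropping zero-IQR columns: {self.dropped_}")
        self.columns_ = list(X.columns[keep])
        self.center_ = q2[keep]
        self.scale_ = iqr[keep]
        return self

    def transform(self, X):
        check_is_fitted(self, "center_")
        X = self._as_frame(X)
        return (X[self.columns_] - self.center_) / self.scale_

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X.astype(float)
        return pd.DataFrame(np.asarray(X, dtype=float))


class DensityClusterer(BaseEstimator, ClusterMixin):
    """Deterministic density clustering (DBSCAN semantics).

    A core point has at least ``min_samples`` points (itself included)
    within Euclidean radius ``eps`` (inclusive); clusters are the connected
    components of core points, border points join the cluster of their
    lowest-index core neighbor, and unreachable points get label -1.
    With ``eps=None`` the radius is chosen by the k-distance elbow heuristic
    (k = min_samples) and logged.
    """

    def __init__(self, eps: float | None = None, min_samples: int = 5):
        self.eps = eps
        self.min_samples = min_samples

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")
        eps = self.eps if self.eps is not None else choose_eps(X, self.min_samples)
        if eps <= 0:
            raise ValueError("eps must be positive")
        n = X.shape[0]
        nn = NearestNeighbors(radius=eps).fit(X)
        neigh = nn.radius_neighbors(X, return_distance=False)
        counts = np.array([len(a) for a in neigh])  # self included
        core = counts >= self.min_samples

        parent = np.arange(n)

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in np.flatnonzero(core):
            for j in neigh[i]:
                if core[j]:
                    ri, rj = find(i), find(int(j))
                    if ri != rj:
                        parent[max(ri, rj)] = min(ri, rj)

        labels = np.full(n, -1, dtype=int)
        roots = {}
        for i in np.flatnonzero(core):
            r = find(i)
            if r not in roots:
                roots[r] = len(roots)
            labels[i] = roots[r]
        for i in np.flatnonzero(~core):
            core_neighbors = sorted(int(j) for j in neigh[i] if core[j])
            if core_neighbors:
                labels[i] = labels[core_neighbors[0]]

        self.labels_ = _relabel_by_size(labels)
        self.eps_ = float(eps)
        self.core_sample_mask_ = core
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters contiguously from 0 in order of descending size
    (ties by first occurrence); noise stays -1."""
    out = np.full_like(labels, -1)
    ids, counts = np.unique(labels[labels >= 0], return_counts=True)
    first = {k: int(np.argmax(labels == k)) for k in ids}
    order = sorted(ids, key=lambda k: (-counts[list(ids).index(k)], first[k]))
    for new, old in enumerate(order):
        out[labels == old] = new
    return out


def choose_eps(X: np.ndarray, k: int) -> float:
    """k-distance elbow heuristic for the DBSCAN radius.

    Sorts each point's distance to its k-th neighbor and takes the point of
    maximum deviation from the chord of the curve (kneedle-style).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    k = min(k, n - 1)
    if k < 1:
        raise ValueError("need at least 2 points to choose eps")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    dists, _ = nn.kneighbors(X)
    kd = np.sort(dists[:, -1])
    if kd[-1] <= 0:
        return 1e-12
    x = np.arange(n, dtype=float)
    chord = kd[0] + (kd[-1] - kd[0]) * x / (n - 1)
    # the sorted k-distance curve is convex (flat, then a sharp tail): the
    # knee is the point of maximum deviation below the chord
    elbow = int(np.argmax(chord - kd))
    eps = float(kd[elbow])
    if eps <= 0:
        eps = float(kd[kd > 0][0]) if np.any(kd > 0) else 1e-12
    logger.info("k-distance elbow: eps=%.4g (k=%d)", eps, k)
    return eps


def _numeric_columns(table: pd.DataFrame) -> list[str]:
    return [
        c
        for c in table.columns
        if c not in METADATA_COLUMNS and pd.api.types.is_numeric_dtype(table[c])
    ]


def assemble(
    tables: Iterable[pd.DataFrame], max_missing_frac: float = 0.5
) -> pd.DataFrame:
    """Concatenate per-image feature tables and impute missing values.

    Feature columns missing in more than ``max_missing_frac`` of cells are
    dropped (logged); remaining missing values are imputed with the
    per-column median, with a ``<col>_imputed`` flag column per affected
    feature so imputation stays auditable.
    """
    tables = list(tables)
    if not tables or all(len(t) == 0 for t in tables):
        raise ValueError("no rows to assemble")
    df = pd.concat(tables, ignore_index=True, sort=False)
    for col in _numeric_columns(df):
        frac = df[col].isna().mean()
        if frac > max_missing_frac:
            logger.info("dropping column %s: %.0f%% missing", col, 100 * frac)
            df = df.drop(columns=[col])
        elif frac > 0:
            df[f"{col}_imputed"] = df[col].isna().astype(int)
            df[col] = df[col].fillna(df[col].median())
    return df


def robust_scale(table: pd.DataFrame, columns: Sequence[str] | None = None) -> ScaledTable:
    """Robust z-score the numeric feature columns of a table.

    Columns carrying an ``<col>_imputed`` flag (from :func:`assemble`) have
    their median/IQR fitted on the observed values only: imputed entries all
    equal the median, and letting them into the quartiles would collapse the
    IQR of any column with substantial missingness.
    """
    cols = list(columns) if columns is not None else _numeric_columns(table)
    fit_data = table[cols].astype(float).copy()
    for col in cols:
        flag = f"{col}_imputed"
        if flag in table.columns:
            fit_data.loc[table[flag].astype(bool), col] = np.nan
    scaler = RobustZScaler().fit(fit_data)
    return ScaledTable(
        values=scaler.transform(table[cols]),
        center=scaler.center_,
        scale=scaler.scale_,
        dropped=scaler.dropped_,
    )


def embed(
    scaled: pd.DataFrame | np.ndarray,
    method: str = "pca",
    seed: int = 0,
    **kwargs,
) -> np.ndarray:
    """Map an N x d scaled table to N x 2 coordinates.

    Backends: ``pca`` (exact classical PCA, deterministic sign convention)
    and ``umap`` (when umap-learn is importable).  Any backend is
    deterministic under a fixed seed.
    """
    X = np.asarray(scaled, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("embedding needs at least 2 rows")
    if method == "pca":
        pca = PCA(n_components=2, svd_solver="full", random_state=seed)
        coords = pca.fit_transform(X)
        # fix sign: largest-magnitude loading positive per component
        for j in range(coords.shape[1]):
            load = pca.components_[j]
            if load[np.argmax(np.abs(load))] < 0:
                coords[:, j] *= -1
        return coords
    if method == "umap":
        try:
            import umap
        except ImportError as exc:  # pragma: no cover
            raise ValueError("umap backend requested but umap-learn is not installed") from exc
        reducer = umap.UMAP(n_components=2, random_state=seed, **kwargs)
        return np.asarray(reducer.fit_transform(X))
    raise ValueError(f"unknown embedding method {method!r}; available: pca, umap")


def dbscan(
    data: pd.DataFrame | np.ndarray, eps: float | None = None, min_samples: int = 5
) -> ClusterResult:
    """Density-cluster scaled features or embedded coordinates."""
    clusterer = DensityClusterer(eps=eps, min_samples=min_samples)
    labels = clusterer.fit_predict(np.asarray(data, dtype=float))
    return ClusterResult(labels=labels, eps=clusterer.eps_, min_samples=min_samples)


def cluster_summary(
    scaled: pd.DataFrame,
    labels: np.ndarray,
    group_by: pd.Series | None = None,
) -> pd.DataFrame:
    """Mean scaled value per (cluster x condition) stratum, plus counts.

    Noise (-1) is reported as its own stratum.
    """
    df = scaled.copy()
    df["cluster"] = np.asarray(labels)
    keys = ["cluster"]
    if group_by is not None:
        df["condition"] = np.asarray(group_by)
        keys.append("condition")
    grouped = df.groupby(keys, dropna=False)
    out = grouped.mean()
    out.insert(0, "n_cells", grouped.size())
    return out.reset_index()


def median_split(
    table: pd.DataFrame,
    feature: str,
    reference_mask: np.ndarray | pd.Series,
) -> tuple[np.ndarray, float]:
    """Split cells into subclusters 1/2 at a reference group's median.

    The threshold is the median of ``feature`` over the reference subset;
    values <= threshold get label 1, the rest label 2.
    """
    if feature not in table.columns:
        raise ValueError(f"feature {feature!r} not in table")
    ref = table.loc[np.asarray(reference_mask, bool), feature].dropna()
    if ref.empty:
        raise ValueError("reference subset is empty")
    vals = table[feature]
    if vals.isna().all():
        raise ValueError(f"feature {feature!r} is all-missing")
    threshold = float(ref.median())
    labels = np.where(vals <= threshold, 1, 2)
    return labels, threshold


def ciliated_fraction(
    per_image_counts: pd.DataFrame,
    by: Sequence[str] = ("condition",),
) -> pd.DataFrame:
    """Ciliated fraction per stratum from per-image cilia/nuclei counts.

    Expects columns ``cilia`` and ``nuclei`` plus the stratum keys; the
    fraction is sum(cilia)/sum(nuclei) with absolute counts retained.  Zero
    nuclei give a missing fraction.
    """
    df = per_image_counts.copy()
    if (df[["cilia", "nuclei"]] < 0).any().any():
        raise ValueError("counts must be non-negative")
    grouped = df.groupby(list(by), dropna=False)[["cilia", "nuclei"]].sum()
    grouped["fraction"] = np.where(
        grouped["nuclei"] > 0, grouped["cilia"] / grouped["nuclei"], np.nan
    )
    return grouped.reset_index()
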