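"""Sample-wide quality computations.

PCA and hierarchical clustering of samples expose outliers and systematic
effects before any cross-dataset comparison; per-sample distribution
summaries feed boxplots/density plots; single-feature condition profiles
back the feature-check view.

Both PCA and the dendrogram use complete-case feature filtering: features
with any missing value among the selected samples are removed (no
imputation). PCA always centers per feature; unit-variance scaling is on by
default.
"""

from __future__ import annotations

import difflib
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from scipy.stats import gaussian_kde

from .datamodel import ConfigurationError, ExpressionDataset, ValidationError

__all__ = [
    "PCAResult",
    "TreeResult",
    "FeatureProfile",
    "SampleSummaries",
    "pca",
    "dendrogram",
    "sample_summaries",
    "feature_profile",
]


@dataclass
class PCAResult:
    """Principal components of samples over complete-case features."""

    scores: pd.DataFrame           # sample x component
    loadings: pd.DataFrame         # feature x component, orthonormal columns
    variance_explained: np.ndarray  # fraction per component, non-increasing
    n_features_used: int
    dropped_zero_variance: list = field(default_factory=list)


@dataclass
class TreeResult:
    """Agglomerative (average-linkage) clustering of samples.

    ``merges`` lists (cluster_i, cluster_j, height) in merge order; clusters
    0..n-1 are the leaves (in ``labels`` order), cluster n+k is the cluster
    created by merge k — scipy's linkage numbering.
    """

    merges: list[tuple[int, int, float]]
    labels: list[str]
    linkage_matrix: np.ndarray  # full scipy Z for plotting


@dataclass
class FeatureProfile:
    """Distribution of one feature's values across the levels of a grouping."""

    feature_id: object
    group_column: str
    groups: pd.DataFrame  # per group: n, n_missing, mean, median, q1, q3
    raw_points: dict      # group -> observed values (missing removed)


@dataclass
class SampleSummaries:
    """Per-sample distribution summaries plus a shared density grid."""

    table: pd.DataFrame
    density_grid: np.ndarray
    densities: dict  # sample -> density values on the grid
    degenerate_samples: list


def _complete_case(ds: ExpressionDataset, samples: Sequence[str] | None) -> tuple[np.ndarray, list, np.ndarray]:
    samples = list(samples) if samples is not None else ds.sample_names
    if len(samples) < 2:
        raise ValidationError("need at least 2 samples")
    X = ds.values_for_samples(samples)           # features x samples
    keep = ~np.isnan(X).any(axis=1)
    return X[keep], samples, np.flatnonzero(keep)


def pca(
    ds: ExpressionDataset,
    samples: Sequence[str] | None = None,
    n_components: int | None = None,
    scale: bool = True,
) -> PCAResult:
    """PCA of samples after complete-case feature filtering.

    Features with any missing value among the selected samples are removed;
    the rest are centered and, if ``scale``, divided by their (ddof=1)
    standard deviation. Zero-variance features are dropped with a warning
    when scaling. Each loading vector is oriented so its largest-magnitude
    element is positive (component signs are otherwise arbitrary).
    """
    X, samples, kept_rows = _complete_case(ds, samples)
    ids = ds.feature_ids.to_numpy()[kept_rows]
    dropped: list = []
    if scale:
        sd = X.std(axis=1, ddof=1)
        zero = sd == 0
        if zero.any():
            dropped = list(ids[zero])
            warnings.warn(
                f"dropping {int(zero.sum())} zero-variance feature(s) before scaling",
                stacklevel=2,
            )
            X, ids = X[~zero], ids[~zero]
    if X.shape[0] < 2:
        raise ValidationError(
            f"only {X.shape[0]} complete feature(s) after filtering; need >= 2 for PCA"
        )

    centered = X - X.mean(axis=1, keepdims=True)
    if scale:
        centered = centered / centered.std(axis=1, ddof=1, keepdims=True)
    data = centered.T  # samples x features
    U, S, Vt = np.linalg.svd(data, full_matrices=False)
    total = float((S**2).sum())
    ve = S**2 / total if total > 0 else np.zeros_like(S)

    k = min(n_components or len(S), len(S))
    scores = U[:, :k] * S[:k]
    loadings = Vt[:k].T
    # deterministic sign: largest-|.| loading element positive per component
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    comp_names = [f"PC{j + 1}" for j in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=samples, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=ids, columns=comp_names),
        variance_explained=ve[:k],
        n_features_used=X.shape[0],
        dropped_zero_variance=dropped,
    )


def dendrogram(
    ds: ExpressionDataset,
    distance: str = "euclidean",
    samples: Sequence[str] | None = None,
) -> TreeResult:
    """Average-linkage (UPGMA) clustering of samples.

    ``distance`` is ``euclidean`` or ``correlation`` (1 - Pearson), computed
    over complete-case features.
    """
    if distance not in ("euclidean", "correlation"):
        raise ConfigurationError(
            f"unknown distance {distance!r}; use 'euclidean' or 'correlation'"
        )
    X, samples, _ = _complete_case(ds, samples)
    if X.shape[0] < 1:
        raise ValidationError("no complete features left for clustering")
    condensed = pdist(X.T, metric=distance)
    Z = linkage(condensed, method="average")
    merges = [(int(i), int(j), float(h)) for i, j, h, _ in Z]
    return TreeResult(merges=merges, labels=samples, linkage_matrix=Z)


def sample_summaries(ds: ExpressionDataset) -> SampleSummaries:
    """Per-sample summary statistics and Gaussian kernel densities.

    Quantiles use linear interpolation (type 7). Densities use Silverman's
    bandwidth on a shared 512-point grid spanning the pooled data range
    extended by three times the largest bandwidth; samples with fewer than
    two observed values or zero spread are flagged degenerate and get no
    density.
    """
    rows = []
    degenerate: list = []
    values_by_sample: dict = {}
    for s in ds.sample_names:
        v = ds.matrix[s].to_numpy(dtype=float)
        obs = v[~np.isnan(v)]
        values_by_sample[s] = obs
        if obs.size == 0:
            degenerate.append(s)
            rows.append({"sample": s, "n_observed": 0, "n_missing": int(v.size)})
            continue
        q1, med, q3 = np.quantile(obs, [0.25, 0.5, 0.75])
        sd = float(obs.std(ddof=1)) if obs.size > 1 else 0.0
        if obs.size < 2 or sd == 0:
            degenerate.append(s)
        rows.append(
            {
                "sample": s,
                "n_observed": int(obs.size),
                "n_missing": int(v.size - obs.size),
                "min": float(obs.min()),
                "q1": float(q1),
                "median": float(med),
                "q3": float(q3),
                "max": float(obs.max()),
                "mean": float(obs.mean()),
                "sd": sd,
            }
        )
    table = pd.DataFrame(rows).set_index("sample")

    pooled = np.concatenate([v for v in values_by_sample.values() if v.size]) if any(
        v.size for v in values_by_sample.values()
    ) else np.array([0.0])
    bandwidths = {}
    for s, obs in values_by_sample.items():
        if s in degenerate:
            continue
        kde = gaussian_kde(obs, bw_method="silverman")
        bandwidths[s] = (kde, kde.factor * obs.std(ddof=1))
    max_bw = max((bw for _, bw in bandwidths.values()), default=1.0)
    grid = np.linspace(pooled.min() - 3 * max_bw, pooled.max() + 3 * max_bw, 512)
    densities = {s: kde(grid) for s, (kde, _) in bandwidths.items()}
    return SampleSummaries(
        table=table, density_grid=grid, densities=densities, degenerate_samples=degenerate
    )


def feature_profile(
    ds: ExpressionDataset, feature_id: object, group_column: str
) -> FeatureProfile:
    """Per-group distribution of one feature (the feature-check view)."""
    if group_column not in ds.design.columns:
        raise ConfigurationError(
            f"group column {group_column!r} not in design; "
            f"available: {list(ds.design.columns)}"
        )
    ids = ds.feature_ids
    hits = np.flatnonzero(ids.to_numpy() == feature_id)
    if hits.size == 0:
        candidates = difflib.get_close_matches(
            str(feature_id), [str(x) for x in ids.unique()], n=5
        )
        raise ConfigurationError(
            f"feature {feature_id!r} not found in {ds.id_column!r}"
            + (f"; did you mean {candidates}?" if candidates else "")
        )
    row = int(hits[0])  # first listed entry, consistent with merge policy

    groups = ds.design[group_column]
    rows = []
    raw_points: dict = {}
    for level in pd.unique(groups):
        members = [s for s in ds.sample_names if groups.loc[s] == level]
        v = ds.matrix.loc[row, members].to_numpy(dtype=float)
        obs = v[~np.isnan(v)]
        raw_points[level] = obs
        entry = {
            "group": level,
            "n": len(members),
            "n_missing": int(v.size - obs.size),
        }
        if obs.size:
            q1, med, q3 = np.quantile(obs, [0.25, 0.5, 0.75])
            entry.update(
                mean=float(obs.mean()), median=float(med), q1=float(q1), q3=float(q3)
            )
        rows.append(entry)
    return FeatureProfile(
        feature_id=feature_id,
        group_column=group_column,
        groups=pd.DataFrame(rows).set_index("group"),
        raw_points=raw_points,
    )
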