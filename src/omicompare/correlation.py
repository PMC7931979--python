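"""Per-feature correlation between two data layers on the same samples.

For multiomics designs (e.g. transcript vs protein per gene) the question
is how well abundance varies together across samples, feature by feature.
Pearson correlation is computed on the values, Spearman as Pearson on
average-ranked values (midranks for ties). Missing data are handled by
pairwise-complete deletion per feature; a correlation is reported only when
at least ``min_pairs`` complete sample pairs remain and both sides vary
(the correlation of a constant vector is undefined, and two points always
give |r| = 1, hence the default minimum of 3).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datamodel import ConfigurationError, MergedPair

__all__ = [
    "CorrelationResult",
    "CorrelationSummary",
    "feature_correlations",
    "correlation_summary",
]


@dataclass
class CorrelationResult:
    """Per-shared-feature cross-layer correlations."""

    table: pd.DataFrame  # id, pearson_r, spearman_r, n_pairs
    min_pairs: int


@dataclass
class CorrelationSummary:
    """Distribution summary of per-feature correlations."""

    stats: pd.DataFrame        # per method: n, median, q1, q3, fraction_negative
    bin_edges: np.ndarray
    histograms: dict           # method -> counts over [-1, 1]
    all_missing: bool = False


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    return float((xc * yc).sum() / denom)


def feature_correlations(
    m: MergedPair,
    sample_map: Sequence[tuple[str, str]],
    min_pairs: int = 3,
) -> CorrelationResult:
    """Pearson and Spearman correlation per shared feature across layers.

    ``sample_map`` pairs each sample of dataset a with its counterpart in
    dataset b (same biological sample measured in both layers). For each
    shared feature only sample pairs with both values observed enter the
    computation; ``r`` is missing when fewer than ``min_pairs`` remain or
    either side has zero variance.
    """
    if len(sample_map) == 0:
        raise ConfigurationError("sample_map is empty")
    samples_a = [s for s, _ in sample_map]
    samples_b = [s for _, s in sample_map]
    A = m.a.values_for_samples(samples_a)[m.rows_a]  # shared features x pairs
    B = m.b.values_for_samples(samples_b)[m.rows_b]

    n_feat = A.shape[0]
    pearson = np.full(n_feat, np.nan)
    spearman = np.full(n_feat, np.nan)
    n_pairs = np.zeros(n_feat, dtype=int)
    for i in range(n_feat):
        ok = ~np.isnan(A[i]) & ~np.isnan(B[i])
        n = int(ok.sum())
        n_pairs[i] = n
        if n < min_pairs:
            continue
        x, y = A[i, ok], B[i, ok]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue  # zero variance: r undefined, left missing
        pearson[i] = _pearson(x, y)
        spearman[i] = _pearson(rankdata(x), rankdata(y))
    table = pd.DataFrame(
        {
            "id": m.shared_ids,
            "pearson_r": pearson,
            "spearman_r": spearman,
            "n_pairs": n_pairs,
        }
    )
    return CorrelationResult(table=table, min_pairs=min_pairs)


def correlation_summary(c: CorrelationResult, n_bins: int = 40) -> CorrelationSummary:
    """Median/quartiles, fraction negative and histograms of the r values."""
    if n_bins < 1:
        raise ConfigurationError(f"n_bins must be >= 1, got {n_bins}")
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    rows = []
    histograms = {}
    any_present = False
    for method in ("pearson_r", "spearman_r"):
        r = c.table[method].to_numpy(dtype=float)
        r = r[~np.isnan(r)]
        histograms[method] = np.histogram(r, bins=edges)[0]
        if r.size == 0:
            rows.append({"method": method, "n": 0})
            continue
        any_present = True
        q1, med, q3 = np.quantile(r, [0.25, 0.5, 0.75])
        rows.append(
            {
                "method": method,
                "n": int(r.size),
                "median": float(med),
                "q1": float(q1),
                "q3": float(q3),
                "fraction_negative": float((r < 0).mean()),
            }
        )
    return CorrelationSummary(
        stats=pd.DataFrame(rows).set_index("method"),
        bin_edges=edges,
        histograms=histograms,
        all_missing=not any_present,
    )
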