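"""Cross-comparison analytics between two statistical contrasts.

The two contrasts may come from the same dataset (e.g. two time points) or
from two datasets joined on shared IDs. The central outputs are

* a per-feature classification into ``both_same`` / ``both_contra`` /
  ``a_only`` / ``b_only`` / ``neither`` given significance thresholds,
* plot-ready volcano / MA / p-value-histogram tables with selection
  propagation between them, and
* the direction-concordance profile: the fraction of shared features whose
  fold-change directions agree, stratified by p-value bins. Under
  independent null contrasts this fraction sits at 0.5 in every bin;
  genuinely shared signal pushes the low-p bins toward 1.

Significance uses strict inequalities on both the p/FDR cutoff and the
absolute log2-fold cutoff; missing statistics are never significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import ConfigurationError, ContrastStats, MergedPair

__all__ = [
    "Thresholds",
    "ClassificationTable",
    "ConcordanceProfile",
    "PlotTable",
    "DEFAULT_CONCORDANCE_EDGES",
    "is_significant",
    "classify_features",
    "volcano_table",
    "ma_table",
    "pvalue_histogram",
    "select_features",
    "concordance_profile",
]

CATEGORIES = ("both_same", "both_contra", "a_only", "b_only", "neither")

#: default p-value bin edges of the concordance profile
DEFAULT_CONCORDANCE_EDGES = (0.0, 0.001, 0.01, 0.05, 0.1, 0.5, 1.0)


@dataclass(frozen=True)
class Thresholds:
    """Significance cutoffs: ``stat < alpha`` and ``|log2fc| > lfc_min``."""

    alpha: float = 0.05
    stat_column: str = "fdr"
    lfc_min: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ConfigurationError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.stat_column not in ("fdr", "p"):
            raise ConfigurationError(
                f"stat_column must be 'fdr' or 'p', got {self.stat_column!r}"
            )
        if self.lfc_min < 0:
            raise ConfigurationError(f"lfc_min must be >= 0, got {self.lfc_min}")


@dataclass
class ClassificationTable:
    """Per-shared-feature cross-comparison categories."""

    table: pd.DataFrame  # id, category, sig_a, sig_b, dir_a, dir_b + stats
    thresholds: Thresholds
    n_zero_lfc_significant: int = 0

    def counts(self) -> pd.Series:
        return self.table["category"].value_counts().reindex(CATEGORIES, fill_value=0)


@dataclass
class ConcordanceProfile:
    """Direction agreement by p-value bin."""

    bin_edges: np.ndarray
    n_features: np.ndarray
    n_same_direction: np.ndarray
    fraction_same: np.ndarray  # NaN where a bin is empty
    bin_statistic: str = "max_p"


@dataclass
class PlotTable:
    """Plot-ready coordinates; excluded + plotted always equals the input."""

    data: pd.DataFrame  # id, x, y (+ clipped flag for volcano)
    n_excluded: int
    x_label: str
    y_label: str


def is_significant(stats: ContrastStats, t: Thresholds) -> np.ndarray:
    """Boolean per-feature significance flags (strict inequalities).

    A feature with a missing test statistic or missing log2 fold change is
    not significant.
    """
    stat = (stats.fdr if t.stat_column == "fdr" else stats.p).to_numpy(dtype=float)
    lfc = stats.log2fc.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        flags = (stat < t.alpha) & (np.abs(lfc) > t.lfc_min)
    return np.where(np.isnan(stat) | np.isnan(lfc), False, flags)


def _significant_aligned(stat: np.ndarray, lfc: np.ndarray, t: Thresholds) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        flags = (stat < t.alpha) & (np.abs(lfc) > t.lfc_min)
    return np.where(np.isnan(stat) | np.isnan(lfc), False, flags)


def classify_features(
    m: MergedPair,
    stats_a: ContrastStats,
    stats_b: ContrastStats,
    t: Thresholds,
) -> ClassificationTable:
    """Classify each shared feature by joint significance and fold direction.

    ``both_same``: significant in both contrasts with the same nonzero
    fold direction; ``both_contra``: significant in both with opposite
    nonzero directions; ``a_only`` / ``b_only``: significant in exactly
    one; ``neither`` otherwise. A feature significant in both but with a
    fold change of exactly zero on either side cannot be assigned a
    direction and falls into ``neither`` (with a warning tally).
    """
    df = m.stats_frame(stats_a, stats_b)
    stat_a = df["fdr_a" if t.stat_column == "fdr" else "p_a"].to_numpy(dtype=float)
    stat_b = df["fdr_b" if t.stat_column == "fdr" else "p_b"].to_numpy(dtype=float)
    lfc_a = df["lfc_a"].to_numpy(dtype=float)
    lfc_b = df["lfc_b"].to_numpy(dtype=float)
    sig_a = _significant_aligned(stat_a, lfc_a, t)
    sig_b = _significant_aligned(stat_b, lfc_b, t)
    dir_a = np.sign(np.nan_to_num(lfc_a))
    dir_b = np.sign(np.nan_to_num(lfc_b))

    category = np.full(len(df), "neither", dtype=object)
    both = sig_a & sig_b
    same = both & (dir_a == dir_b) & (dir_a != 0)
    contra = both & (dir_a * dir_b < 0)
    category[sig_a & ~sig_b] = "a_only"
    category[~sig_a & sig_b] = "b_only"
    category[same] = "both_same"
    category[contra] = "both_contra"

    zero_lfc_sig = int(np.sum(both & ((dir_a == 0) | (dir_b == 0))))
    if zero_lfc_sig:
        warnings.warn(
            f"{zero_lfc_sig} feature(s) significant in both contrasts with a "
            "zero log2 fold change; classified as 'neither' (no direction)",
            stacklevel=2,
        )
        category[both & ((dir_a == 0) | (dir_b == 0))] = "neither"

    def dir_label(d: np.ndarray) -> np.ndarray:
        return np.where(d > 0, "up", np.where(d < 0, "down", "zero"))

    out = df.copy()
    out.insert(1, "category", category)
    out.insert(2, "sig_a", sig_a)
    out.insert(3, "sig_b", sig_b)
    out.insert(4, "dir_a", dir_label(dir_a))
    out.insert(5, "dir_b", dir_label(dir_b))
    return ClassificationTable(
        table=out, thresholds=t, n_zero_lfc_significant=zero_lfc_sig
    )


def volcano_table(stats: ContrastStats, ids: Sequence | None = None) -> PlotTable:
    """Volcano coordinates: x = log2 fold change, y = -log10 p.

    Rows missing p or log2fc are excluded (tallied). p = 0 cannot be drawn
    on the -log10 scale and is clipped 5% above the largest finite y in the
    table, with a ``clipped`` flag; the underlying statistics are untouched.
    """
    p = stats.p.to_numpy(dtype=float)
    lfc = stats.log2fc.to_numpy(dtype=float)
    ids = np.asarray(ids if ids is not None else np.arange(len(p)), dtype=object)
    ok = ~np.isnan(p) & ~np.isnan(lfc)
    p_ok, lfc_ok, ids_ok = p[ok], lfc[ok], ids[ok]
    with np.errstate(divide="ignore"):
        y = -np.log10(p_ok)
    clipped = np.isinf(y)
    if clipped.any():
        pos = p_ok[p_ok > 0]
        if pos.size:
            y_clip = -np.log10(pos.min()) * 1.05
        else:  # every p is zero; arbitrary finite ceiling
            y_clip = 1.0
        y = np.where(clipped, y_clip, y)
    data = pd.DataFrame({"id": ids_ok, "x": lfc_ok, "y": y, "clipped": clipped})
    return PlotTable(
        data=data,
        n_excluded=int((~ok).sum()),
        x_label="log2 fold change",
        y_label="-log10 p",
    )


def ma_table(stats: ContrastStats, ids: Sequence | None = None) -> PlotTable:
    """MA coordinates: x = average level, y = log2 fold change."""
    ave = stats.ave.to_numpy(dtype=float)
    lfc = stats.log2fc.to_numpy(dtype=float)
    ids = np.asarray(ids if ids is not None else np.arange(len(ave)), dtype=object)
    ok = ~np.isnan(ave) & ~np.isnan(lfc)
    data = pd.DataFrame({"id": ids[ok], "x": ave[ok], "y": lfc[ok]})
    return PlotTable(
        data=data,
        n_excluded=int((~ok).sum()),
        x_label="average level",
        y_label="log2 fold change",
    )


def pvalue_histogram(stats: ContrastStats, n_bins: int = 20) -> np.ndarray:
    """Counts of p-values in equal-width bins over [0, 1].

    Bins are left-closed with a right-closed last bin; missing p-values are
    excluded. A flat histogram indicates well-behaved null p-values; an
    excess in the first bin reflects true effects (or miscalibration).
    """
    if n_bins < 1:
        raise ConfigurationError(f"n_bins must be >= 1, got {n_bins}")
    p = stats.p.to_numpy(dtype=float)
    p = p[~np.isnan(p)]
    counts, _ = np.histogram(p, bins=np.linspace(0.0, 1.0, n_bins + 1))
    return counts


def select_features(
    table: PlotTable | pd.DataFrame,
    region: tuple[float, float, float, float] | None = None,
    ids: Sequence | None = None,
) -> list:
    """Select feature IDs from a plot table, by rectangle or by ID list.

    ``region`` is ``(x_min, x_max, y_min, y_max)`` in the table's plot
    coordinates; containment is closed on all edges. In ID-list mode the
    IDs present in the table pass through, preserving table order — this is
    how a selection made on one comparison is re-applied as a highlight set
    on another. An empty selection is an empty list, not an error.
    """
    data = table.data if isinstance(table, PlotTable) else table
    if (region is None) == (ids is None):
        raise ConfigurationError("provide exactly one of region= or ids=")
    if region is not None:
        x0, x1, y0, y1 = region
        inside = (
            (data["x"] >= x0) & (data["x"] <= x1) & (data["y"] >= y0) & (data["y"] <= y1)
        )
        return data.loc[inside, "id"].tolist()
    wanted = set(ids)
    return [i for i in data["id"] if i in wanted]


def _bin_index(x: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Left-closed bins over ``edges``; the last bin is right-closed."""
    idx = np.searchsorted(edges, x, side="right") - 1
    return np.clip(idx, 0, len(edges) - 2)


def concordance_profile(
    m: MergedPair,
    stats_a: ContrastStats,
    stats_b: ContrastStats,
    bin_edges: Sequence[float] = DEFAULT_CONCORDANCE_EDGES,
    bin_statistic: str = "max_p",
) -> ConcordanceProfile:
    """Fraction of shared features changing in the same direction, by p bin.

    With ``bin_statistic="max_p"`` (default) each shared feature with both
    p-values present is assigned to the bin containing ``max(p_a, p_b)`` —
    a feature only counts as low-p if it is low-p in *both* contrasts. With
    ``"per_comparison"`` each feature contributes twice, once per contrast's
    own p-value. Agreement means ``sign(lfc_a) == sign(lfc_b) != 0``;
    zero-fold features count toward bin sizes but never toward agreement.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if (
        edges.ndim != 1
        or len(edges) < 2
        or edges[0] != 0.0
        or edges[-1] != 1.0
        or np.any(np.diff(edges) <= 0)
    ):
        raise ConfigurationError(
            "bin_edges must start at 0, end at 1 and be strictly ascending"
        )
    if bin_statistic not in ("max_p", "per_comparison"):
        raise ConfigurationError(
            f"bin_statistic must be 'max_p' or 'per_comparison', got {bin_statistic!r}"
        )

    p_a = m.take_a(stats_a.p).astype(float)
    p_b = m.take_b(stats_b.p).astype(float)
    lfc_a = m.take_a(stats_a.log2fc).astype(float)
    lfc_b = m.take_b(stats_b.log2fc).astype(float)
    ok = ~np.isnan(p_a) & ~np.isnan(p_b)
    same = (
        (np.sign(lfc_a) == np.sign(lfc_b))
        & (np.sign(np.nan_to_num(lfc_a)) != 0)
        & ~np.isnan(lfc_a)
        & ~np.isnan(lfc_b)
    )

    n_bins = len(edges) - 1
    n = np.zeros(n_bins, dtype=int)
    n_same = np.zeros(n_bins, dtype=int)
    if bin_statistic == "max_p":
        assignments = [_bin_index(np.maximum(p_a[ok], p_b[ok]), edges)]
        sames = [same[ok]]
    else:
        assignments = [_bin_index(p_a[ok], edges), _bin_index(p_b[ok], edges)]
        sames = [same[ok], same[ok]]
    for idx, s in zip(assignments, sames):
        np.add.at(n, idx, 1)
        np.add.at(n_same, idx[s], 1)
    with np.errstate(invalid="ignore"):
        frac = np.where(n > 0, n_same / np.maximum(n, 1), np.nan)
    return ConcordanceProfile(
        bin_edges=edges,
        n_features=n,
        n_same_direction=n_same,
        fraction_same=frac,
        bin_statistic=bin_statistic,
    )
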