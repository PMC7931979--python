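"""Set analytics across comparisons or datasets.

Membership matrices (feature x set booleans) are the common substrate for
Venn counts, UpSet-style exclusive intersections, fold-direction-split
overlaps and qualitative presence/absence analysis. An *exclusive*
intersection assigns every feature to the single subset key matching its
full membership pattern — the quantity UpSet bar plots display, so the
counts over all keys always sum to the number of features in at least one
set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    ConfigurationError,
    ExpressionDataset,
    ValidationError,
)
from .compare import Thresholds, _significant_aligned

__all__ = [
    "MembershipMatrix",
    "IntersectionCounts",
    "significance_membership",
    "direction_split_membership",
    "presence_membership",
    "exclusive_intersections",
    "venn_counts",
    "subset_export",
]


@dataclass
class MembershipMatrix:
    """Boolean feature x set membership."""

    data: pd.DataFrame  # index = feature ids (unique), columns = set labels, bool
    n_zero_lfc_excluded: int = 0  # direction splitting only

    def __post_init__(self) -> None:
        if self.data.shape[1] < 1:
            raise ValidationError("membership matrix needs at least one set")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()[:10]
            raise ValidationError(f"membership feature ids not unique: {dups}")

    @property
    def set_labels(self) -> list[str]:
        return list(self.data.columns)

    @property
    def feature_ids(self) -> list:
        return list(self.data.index)


@dataclass
class IntersectionCounts:
    """Exclusive intersection counts keyed by frozenset of set labels."""

    counts: dict  # frozenset[str] -> int, zero-count keys omitted
    none_count: int  # features in no set
    set_labels: list[str] = field(default_factory=list)

    def sorted_items(self) -> list[tuple[frozenset, int]]:
        """Decreasing count, ties by degree then lexicographic key."""
        return sorted(
            self.counts.items(),
            key=lambda kv: (-kv[1], len(kv[0]), tuple(sorted(kv[0]))),
        )

    def total(self) -> int:
        return sum(self.counts.values())


def significance_membership(
    specs: Sequence[tuple[str, np.ndarray | pd.Series, np.ndarray | pd.Series, Thresholds]],
    feature_ids: Sequence,
) -> MembershipMatrix:
    """Membership by significance under per-comparison thresholds.

    ``specs`` is a list of ``(label, stat_values, lfc_values, thresholds)``
    where the value vectors are already aligned to the shared
    ``feature_ids`` universe (e.g. via :meth:`MergedPair.take_a`);
    ``stat_values`` holds the column named by each spec's
    ``thresholds.stat_column``. Features with missing statistics in a
    comparison are simply not members there; a feature in no set stays in
    the universe but contributes to no intersection.
    """
    if len(specs) < 2:
        raise ConfigurationError("need at least 2 comparison specs")
    cols = {}
    for label, stat, lfc, t in specs:
        stat = np.asarray(stat, dtype=float)
        lfc = np.asarray(lfc, dtype=float)
        if len(stat) != len(feature_ids) or len(lfc) != len(feature_ids):
            raise ValidationError(
                f"spec {label!r}: stat vectors not aligned to the feature universe"
            )
        if label in cols:
            raise ConfigurationError(f"duplicate set label {label!r}")
        cols[label] = _significant_aligned(stat, lfc, t)
    return MembershipMatrix(data=pd.DataFrame(cols, index=pd.Index(feature_ids)))


def direction_split_membership(
    specs: Sequence[tuple[str, np.ndarray | pd.Series, np.ndarray | pd.Series, Thresholds]],
    feature_ids: Sequence,
) -> MembershipMatrix:
    """Significance membership split by fold direction.

    Each comparison contributes two sets, ``<label>_up`` and
    ``<label>_down``. Overlaps between an up-set of one comparison and a
    down-set of another expose features that are significant in both but
    change in opposing directions. Features significant with a fold change
    of exactly zero join neither set and are tallied.
    """
    base = significance_membership(specs, feature_ids)
    cols = {}
    zero_excluded = 0
    for label, stat, lfc, t in specs:
        lfc = np.asarray(lfc, dtype=float)
        sig = base.data[label].to_numpy()
        up = sig & (lfc > 0)
        down = sig & (lfc < 0)
        zero_excluded += int(np.sum(sig & (np.nan_to_num(lfc) == 0)))
        cols[f"{label}_up"] = up
        cols[f"{label}_down"] = down
    return MembershipMatrix(
        data=pd.DataFrame(cols, index=pd.Index(feature_ids)),
        n_zero_lfc_excluded=zero_excluded,
    )


def presence_membership(
    datasets: Sequence[ExpressionDataset] | ExpressionDataset,
    *,
    group_column: str | None = None,
    min_obs: int = 1,
    id_column: str | None = None,
) -> MembershipMatrix:
    """Qualitative presence/absence membership.

    Two modes: (1) a list of datasets — each dataset is one set over the
    union of their deduplicated IDs; a feature is *present* in a dataset if
    it has at least ``min_obs`` non-missing values there, and features
    entirely absent from a dataset are absent (membership false) rather
    than dropped from the universe; (2) a single dataset with
    ``group_column`` — one set per condition level, presence counted over
    that level's samples. This surfaces features below the detection limit
    in some conditions or datasets.
    """
    if min_obs < 1:
        raise ConfigurationError(f"min_obs must be >= 1, got {min_obs}")
    if isinstance(datasets, ExpressionDataset):
        ds = datasets
        if group_column is None:
            raise ConfigurationError("single-dataset mode requires group_column")
        if group_column not in ds.design.columns:
            raise ConfigurationError(
                f"group column {group_column!r} not in design; "
                f"available: {list(ds.design.columns)}"
            )
        ids, rows = _dedup_ids(ds, id_column or ds.id_column)
        groups = ds.design[group_column]
        cols = {}
        for level in pd.unique(groups):
            members = [s for s in ds.sample_names if groups.loc[s] == level]
            vals = ds.matrix.loc[rows, members].to_numpy(dtype=float)
            cols[str(level)] = (~np.isnan(vals)).sum(axis=1) >= min_obs
        return MembershipMatrix(data=pd.DataFrame(cols, index=pd.Index(ids)))

    if len(datasets) < 2:
        raise ConfigurationError("need at least 2 datasets for presence analysis")
    id_column = id_column or datasets[0].id_column
    per_ds = []
    universe: list = []
    seen = set()
    for ds in datasets:
        ids, rows = _dedup_ids(ds, id_column)
        vals = ds.matrix.loc[rows].to_numpy(dtype=float)
        present = (~np.isnan(vals)).sum(axis=1) >= min_obs
        per_ds.append((ds.name, dict(zip(ids, present))))
        for i in ids:
            if i not in seen:
                seen.add(i)
                universe.append(i)
    cols = {
        name: np.array([present.get(i, False) for i in universe], dtype=bool)
        for name, present in per_ds
    }
    return MembershipMatrix(data=pd.DataFrame(cols, index=pd.Index(universe)))


def _dedup_ids(ds: ExpressionDataset, id_column: str) -> tuple[list, list]:
    if id_column not in ds.feature_annotations.columns:
        raise ConfigurationError(
            f"dataset {ds.name!r}: id column {id_column!r} not found"
        )
    ids_all = ds.feature_annotations[id_column]
    seen: set = set()
    ids, rows = [], []
    for row, value in enumerate(ids_all):
        if value not in seen:
            seen.add(value)
            ids.append(value)
            rows.append(row)
    return ids, rows


def exclusive_intersections(m: MembershipMatrix) -> IntersectionCounts:
    """Count features by their exact membership pattern (UpSet semantics)."""
    labels = m.set_labels
    arr = m.data.to_numpy(dtype=bool)
    counts: dict = {}
    none_count = 0
    # pattern id per feature via bit packing (k <= 62 sets in practice)
    weights = 1 << np.arange(arr.shape[1], dtype=np.int64)
    codes = arr @ weights
    for code, n in zip(*np.unique(codes, return_counts=True)):
        if code == 0:
            none_count = int(n)
            continue
        key = frozenset(labels[i] for i in range(len(labels)) if code >> i & 1)
        counts[key] = int(n)
    return IntersectionCounts(counts=counts, none_count=none_count, set_labels=labels)


def venn_counts(m: MembershipMatrix) -> tuple[int, int, int]:
    """Pairwise counts (only_a, only_b, both) for a two-set membership."""
    if m.data.shape[1] != 2:
        raise ConfigurationError(
            f"venn_counts needs exactly 2 sets, got {m.data.shape[1]}"
        )
    a = m.data.iloc[:, 0].to_numpy()
    b = m.data.iloc[:, 1].to_numpy()
    return int((a & ~b).sum()), int((~a & b).sum()), int((a & b).sum())


def subset_export(
    m: MembershipMatrix,
    key: Sequence[str] | frozenset,
    annotations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Rows of features whose exclusive pattern equals ``key``.

    ``annotations`` (indexed by feature id, or with an ``id`` column) is
    joined on; row order follows the membership matrix (stable). A key with
    no matching feature yields an empty table.
    """
    key = frozenset(key)
    unknown = key - set(m.set_labels)
    if unknown:
        raise ConfigurationError(f"unknown set labels in key: {sorted(unknown)}")
    pattern = np.array([c in key for c in m.set_labels], dtype=bool)
    match = (m.data.to_numpy(dtype=bool) == pattern).all(axis=1)
    out = pd.DataFrame({"id": np.asarray(m.feature_ids, dtype=object)[match]})
    for c in m.set_labels:
        out[c] = m.data[c].to_numpy()[match]
    if annotations is not None:
        ann = annotations
        if "id" in ann.columns:
            ann = ann.set_index("id")
        out = out.join(ann, on="id")
    return out
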