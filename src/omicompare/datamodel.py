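"""Core data model and I/O.

Expression data arrive as flat tables: a matrix file with features per row
(sample intensity columns mixed with annotation and per-contrast statistics
columns) and a design file with one row per sample. Two datasets are joined
on a shared feature-ID column, keeping the first listed entry for duplicated
IDs, so that downstream cross-comparison analytics can align features.

Analysis settings round-trip through a canonical JSON snapshot so that any
run can be replayed exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OmicompareError",
    "ValidationError",
    "ConfigurationError",
    "ExpressionDataset",
    "ContrastStats",
    "MergedPair",
    "SettingsSnapshot",
    "read_dataset",
    "write_dataset",
    "contrast_from_columns",
    "merge_on_id",
    "save_settings",
    "load_settings",
]

#: tokens treated as missing in matrix cells, compared case-insensitively
MISSING_TOKENS = frozenset({"", "na", "nan", "null"})


class OmicompareError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(OmicompareError):
    """Input data violate a structural invariant."""


class ConfigurationError(OmicompareError):
    """A requested column, contrast or parameter does not exist / is invalid."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionDataset:
    """A feature x sample expression matrix with annotations and a design.

    Parameters
    ----------
    name : str
        Dataset label used in figure titles and set labels.
    matrix : pandas.DataFrame
        Numeric values (log-scale intensities or transformed counts), one
        row per feature, one column per sample. Missing values are NaN.
    feature_annotations : pandas.DataFrame
        Per-feature columns; must contain ``id_column``. Row-aligned with
        ``matrix`` (same length, same order).
    design : pandas.DataFrame
        One row per sample, indexed by sample name, with >= 1 grouping
        column.
    id_column : str
        Name of the shared-ID column inside ``feature_annotations``.
    """

    name: str
    matrix: pd.DataFrame
    feature_annotations: pd.DataFrame
    design: pd.DataFrame
    id_column: str

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        if len(self.matrix) != len(self.feature_annotations):
            raise ValidationError(
                f"dataset {self.name!r}: matrix has {len(self.matrix)} rows but "
                f"annotations have {len(self.feature_annotations)}"
            )
        if self.id_column not in self.feature_annotations.columns:
            raise ConfigurationError(
                f"dataset {self.name!r}: id column {self.id_column!r} not found; "
                f"available columns: {list(self.feature_annotations.columns)}"
            )
        dup_samples = self.design.index[self.design.index.duplicated()].tolist()
        if dup_samples:
            raise ValidationError(
                f"dataset {self.name!r}: duplicate sample names in design: {dup_samples}"
            )
        unknown = [c for c in self.matrix.columns if c not in self.design.index]
        if unknown:
            raise ValidationError(
                f"dataset {self.name!r}: matrix samples missing from design: {unknown}"
            )

    # -- conveniences ------------------------------------------------------
    @property
    def n_features(self) -> int:
        return len(self.matrix)

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    @property
    def sample_names(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def feature_ids(self) -> pd.Series:
        return self.feature_annotations[self.id_column]

    def values_for_samples(self, samples: Sequence[str]) -> np.ndarray:
        """Matrix values restricted to ``samples``, as a float array."""
        missing = [s for s in samples if s not in self.matrix.columns]
        if missing:
            raise ConfigurationError(
                f"dataset {self.name!r}: unknown samples {missing}"
            )
        return self.matrix.loc[:, list(samples)].to_numpy(dtype=float)


@dataclass
class ContrastStats:
    """Per-feature statistics of one named contrast.

    All series are positionally aligned with the owning dataset's feature
    rows. ``log2fc`` is the difference of group means on the log2 scale;
    its sign convention comes from the upstream contrast and is never
    altered here.
    """

    contrast_name: str
    p: pd.Series
    fdr: pd.Series
    log2fc: pd.Series
    ave: pd.Series

    def __post_init__(self) -> None:
        n = {len(self.p), len(self.fdr), len(self.log2fc), len(self.ave)}
        if len(n) != 1:
            raise ValidationError(
                f"contrast {self.contrast_name!r}: stat columns have unequal lengths {sorted(n)}"
            )
        for label, s in (("p", self.p), ("fdr", self.fdr)):
            vals = s.to_numpy(dtype=float)
            bad = (vals < 0) | (vals > 1)
            if np.any(bad & ~np.isnan(vals)):
                raise ValidationError(
                    f"contrast {self.contrast_name!r}: {label} values outside [0, 1]"
                )
        both = self.p.notna() & self.fdr.notna()
        if (self.fdr[both] < self.p[both] - 1e-12).any():
            warnings.warn(
                f"contrast {self.contrast_name!r}: some FDR values are below "
                "their p-values; upstream adjustment looks inconsistent",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.p)


@dataclass
class MergedPair:
    """Two datasets joined on a shared-ID column.

    ``rows_a`` / ``rows_b`` are positional row indices into each dataset
    (after the first-entry duplicate rule), one per shared ID, in
    dataset-``a`` order.
    """

    a: ExpressionDataset
    b: ExpressionDataset
    id_column: str
    shared_ids: list
    rows_a: np.ndarray
    rows_b: np.ndarray
    dropped_duplicates_a: int
    dropped_duplicates_b: int
    duplicate_examples_a: list = field(default_factory=list)
    duplicate_examples_b: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.shared_ids)) != len(self.shared_ids):
            raise ValidationError("merged pair: shared IDs are not unique")
        if not (len(self.shared_ids) == len(self.rows_a) == len(self.rows_b)):
            raise ValidationError("merged pair: id/row index lengths differ")

    @property
    def n_shared(self) -> int:
        return len(self.shared_ids)

    def take_a(self, values: pd.Series | np.ndarray) -> np.ndarray:
        """Align a per-feature vector of dataset a to the shared rows."""
        arr = values.to_numpy() if isinstance(values, pd.Series) else np.asarray(values)
        return arr[self.rows_a]

    def take_b(self, values: pd.Series | np.ndarray) -> np.ndarray:
        arr = values.to_numpy() if isinstance(values, pd.Series) else np.asarray(values)
        return arr[self.rows_b]

    def stats_frame(self, stats_a: ContrastStats, stats_b: ContrastStats) -> pd.DataFrame:
        """Aligned per-shared-feature statistics of both contrasts."""
        return pd.DataFrame(
            {
                "id": self.shared_ids,
                "p_a": self.take_a(stats_a.p),
                "fdr_a": self.take_a(stats_a.fdr),
                "lfc_a": self.take_a(stats_a.log2fc),
                "ave_a": self.take_a(stats_a.ave),
                "p_b": self.take_b(stats_b.p),
                "fdr_b": self.take_b(stats_b.fdr),
                "lfc_b": self.take_b(stats_b.log2fc),
                "ave_b": self.take_b(stats_b.ave),
            }
        )


@dataclass
class SettingsSnapshot:
    """Parameter snapshot of a run; save -> load -> save is byte-identical."""

    tool_version: str
    params: dict

    def __eq__(self, other: object) -> bool:  # value semantics
        if not isinstance(other, SettingsSnapshot):
            return NotImplemented
        return self.tool_version == other.tool_version and self.params == other.params


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------


def _sniff_delimiter(path: Path) -> str:
    """Choose between tab and comma from the header line.

    Only these two delimiters are supported; a header containing both (or
    neither) is ambiguous and requires an explicit ``delimiter`` argument.
    """
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    has_tab, has_comma = "\t" in header, "," in header
    if has_tab and not has_comma:
        return "\t"
    if has_comma and not has_tab:
        return ","
    raise ConfigurationError(
        f"{path}: cannot auto-detect delimiter (tab vs comma ambiguous); "
        "pass delimiter explicitly"
    )


def _coerce_missing(column: pd.Series) -> pd.Series:
    """Numeric coercion with the package-wide missing-token policy.

    Parsing goes through Python's float(), which is correctly rounded —
    pandas' fast to_numeric parser can be off by one ulp, breaking exact
    write/read round-trips.
    """
    if column.dtype != object:
        return pd.to_numeric(column, errors="coerce")

    def parse(v: object) -> float:
        s = str(v).strip()
        if s.lower() in MISSING_TOKENS:
            return np.nan
        try:
            return float(s)
        except ValueError:
            return np.nan

    return column.map(parse).astype(float)


def read_dataset(
    matrix_path: str | Path,
    design_path: str | Path,
    id_column: str,
    *,
    name: str | None = None,
    sample_column: str | None = None,
    sample_columns: Sequence[str] | None = None,
    delimiter: str | None = None,
    zero_as_missing: bool = False,
) -> ExpressionDataset:
    """Read a matrix + design table pair into an :class:`ExpressionDataset`.

    The design table's sample-identifier column (``sample_column``, default
    its first column) defines which matrix columns hold sample values; all
    other matrix columns become feature annotations. Non-numeric cells,
    empty strings and NA/NaN/null tokens in sample columns become missing.

    Parameters
    ----------
    sample_columns : sequence of str, optional
        Explicit list of matrix columns that are samples. Any listed column
        absent from the design raises a validation error naming it — useful
        to catch a design table that silently lacks a sample.
    zero_as_missing : bool
        Treat exact zeros as missing (for upstream pipelines that encode
        below-detection-limit values as 0).
    """
    matrix_path, design_path = Path(matrix_path), Path(design_path)
    for p in (matrix_path, design_path):
        if not p.exists():
            raise ConfigurationError(f"input file does not exist: {p}")
    sep_m = delimiter or _sniff_delimiter(matrix_path)
    sep_d = delimiter or _sniff_delimiter(design_path)

    raw = pd.read_csv(matrix_path, sep=sep_m, dtype=object, keep_default_na=False)
    design = pd.read_csv(design_path, sep=sep_d)
    if design.empty:
        raise ValidationError(f"{design_path}: design table is empty")
    sample_column = sample_column or design.columns[0]
    if sample_column not in design.columns:
        raise ConfigurationError(
            f"{design_path}: sample column {sample_column!r} not found; "
            f"available columns: {list(design.columns)}"
        )
    design = design.set_index(design[sample_column].astype(str))
    design.index.name = sample_column

    if id_column not in raw.columns:
        raise ConfigurationError(
            f"{matrix_path}: id column {id_column!r} not found; "
            f"available columns: {list(raw.columns)}"
        )

    if sample_columns is not None:
        samples = list(sample_columns)
        not_in_design = [c for c in samples if c not in design.index]
        if not_in_design:
            raise ValidationError(
                f"{design_path}: design table lacks matrix sample columns: "
                f"{not_in_design}"
            )
    else:
        samples = list(design.index)
    absent = [s for s in samples if s not in raw.columns]
    if absent:
        raise ValidationError(
            f"{matrix_path}: design samples missing from the matrix: {absent}"
        )

    matrix = pd.DataFrame({s: _coerce_missing(raw[s]) for s in samples})
    if zero_as_missing:
        matrix = matrix.mask(matrix == 0)
    annotations = raw[[c for c in raw.columns if c not in set(samples)]].copy()
    # annotation stat columns stay numeric where they can be
    for c in annotations.columns:
        if c == id_column:
            continue
        coerced = _coerce_missing(annotations[c])
        non_missing = annotations[c].astype(str).str.strip().str.lower()
        non_missing = ~non_missing.isin(MISSING_TOKENS)
        if coerced.notna().eq(non_missing).all():  # purely numeric column
            annotations[c] = coerced

    design = design.loc[samples]
    return ExpressionDataset(
        name=name or matrix_path.stem,
        matrix=matrix,
        feature_annotations=annotations,
        design=design,
        id_column=id_column,
    )


def write_dataset(ds: ExpressionDataset, matrix_path: str | Path, design_path: str | Path) -> None:
    """Write a dataset back to the TSV matrix/design layout (full precision)."""
    out = pd.concat(
        [ds.feature_annotations.reset_index(drop=True), ds.matrix.reset_index(drop=True)],
        axis=1,
    )
    # %.17g round-trips doubles exactly
    out.to_csv(matrix_path, sep="\t", index=False, float_format="%.17g")
    ds.design.to_csv(design_path, sep="\t", index=False)


def contrast_from_columns(
    ds: ExpressionDataset,
    contrast_name: str,
    *,
    p: str,
    fdr: str,
    log2fc: str,
    ave: str,
) -> ContrastStats:
    """Build :class:`ContrastStats` from annotation columns of ``ds``."""
    cols = {"p": p, "fdr": fdr, "log2fc": log2fc, "ave": ave}
    missing = [c for c in cols.values() if c not in ds.feature_annotations.columns]
    if missing:
        raise ConfigurationError(
            f"dataset {ds.name!r}: contrast columns not found: {missing}; "
            f"available: {list(ds.feature_annotations.columns)}"
        )
    get = lambda c: pd.to_numeric(ds.feature_annotations[c], errors="coerce")
    return ContrastStats(
        contrast_name=contrast_name,
        p=get(p),
        fdr=get(fdr),
        log2fc=get(log2fc),
        ave=get(ave),
    )


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------


def _first_occurrences(ids: pd.Series, fold_case: bool) -> tuple[dict, int, list]:
    """Map each ID to the row index of its first occurrence (file order)."""
    first: dict = {}
    dropped = 0
    examples: list = []
    for row, value in enumerate(ids):
        key = value.lower() if fold_case and isinstance(value, str) else value
        if key in first:
            dropped += 1
            if len(examples) < 10:
                examples.append(value)
        else:
            first[key] = row
    return first, dropped, examples


def merge_on_id(
    a: ExpressionDataset,
    b: ExpressionDataset,
    id_column: str | None = None,
    *,
    dup_policy: str = "first",
    fold_case: bool = False,
) -> MergedPair:
    """Join two datasets on a shared-ID column.

    With ``dup_policy="first"`` the first listed entry per ID (file row
    order) is kept within each dataset; the ID sets are then intersected,
    preserving dataset-``a`` order. ID matching is case-sensitive unless
    ``fold_case`` is set.
    """
    if dup_policy not in ("first", "error"):
        raise ConfigurationError(f"unknown dup_policy {dup_policy!r}; use 'first' or 'error'")
    id_column = id_column or a.id_column
    for ds in (a, b):
        if id_column not in ds.feature_annotations.columns:
            raise ConfigurationError(
                f"dataset {ds.name!r}: id column {id_column!r} not found; "
                f"available: {list(ds.feature_annotations.columns)}"
            )
    ids_a = a.feature_annotations[id_column]
    ids_b = b.feature_annotations[id_column]
    first_a, dropped_a, ex_a = _first_occurrences(ids_a, fold_case)
    first_b, dropped_b, ex_b = _first_occurrences(ids_b, fold_case)
    if dup_policy == "error" and (dropped_a or dropped_b):
        raise ValidationError(
            "duplicate IDs present with dup_policy='error'; first duplicates: "
            f"a={ex_a} b={ex_b}"
        )

    shared_keys = [k for k in first_a if k in first_b]  # dict preserves a order
    if not shared_keys:
        raise ValidationError(
            f"datasets {a.name!r} and {b.name!r} share no IDs in column {id_column!r}"
        )
    rows_a = np.array([first_a[k] for k in shared_keys], dtype=int)
    rows_b = np.array([first_b[k] for k in shared_keys], dtype=int)
    # report IDs as they appear in dataset a
    shared_ids = [ids_a.iloc[r] for r in rows_a]
    return MergedPair(
        a=a,
        b=b,
        id_column=id_column,
        shared_ids=shared_ids,
        rows_a=rows_a,
        rows_b=rows_b,
        dropped_duplicates_a=dropped_a,
        dropped_duplicates_b=dropped_b,
        duplicate_examples_a=ex_a,
        duplicate_examples_b=ex_b,
    )


# ---------------------------------------------------------------------------
# Settings snapshots
# ---------------------------------------------------------------------------


def _snapshot_to_json(s: SettingsSnapshot) -> str:
    payload = {"tool_version": s.tool_version, "params": s.params}
    return json.dumps(payload, sort_keys=True, indent=2, ensure_ascii=False) + "\n"


def save_settings(s: SettingsSnapshot, path: str | Path) -> None:
    """Serialize a snapshot as canonical JSON (stable key order, UTF-8)."""
    Path(path).write_text(_snapshot_to_json(s), encoding="utf-8")


def load_settings(path: str | Path) -> SettingsSnapshot:
    """Load a snapshot; malformed files raise with line context."""
    text = Path(path).read_text(encoding="utf-8")
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as e:
        raise ConfigurationError(
            f"{path}: malformed settings JSON at line {e.lineno}, column {e.colno}: {e.msg}"
        ) from e
    if not isinstance(payload, Mapping) or "params" not in payload:
        raise ConfigurationError(f"{path}: not a settings snapshot (missing 'params')")
    return SettingsSnapshot(
        tool_version=str(payload.get("tool_version", "")),
        params=dict(payload["params"]),
    )
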