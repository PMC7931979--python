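"""Static figure rendering (matplotlib, Agg backend).

All figures are written as both PNG and SVG. UpSet-style plots are drawn
directly with matplotlib: an intersection-size bar chart over a membership
dot matrix; the 2-set Venn is a fixed (non-proportional) two-circle layout
with counts.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .compare import ClassificationTable, ConcordanceProfile, PlotTable
from .correlation import CorrelationSummary
from .overlap import IntersectionCounts
from .quality import FeatureProfile, PCAResult, SampleSummaries, TreeResult

__all__ = [
    "save_figure",
    "plot_pca",
    "plot_dendrogram",
    "plot_densities",
    "plot_boxplots",
    "plot_feature_profile",
    "plot_volcano_pair",
    "plot_pvalue_histogram",
    "plot_concordance",
    "plot_upset",
    "plot_venn2",
    "plot_correlation_summary",
]

_CATEGORY_COLORS = {
    "both_same": "#1f77b4",
    "both_contra": "#2ca02c",
    "a_only": "#ff7f0e",
    "b_only": "#9467bd",
    "neither": "#bbbbbb",
}


def save_figure(fig: plt.Figure, path_stem: str | Path) -> list[Path]:
    """Write ``<stem>.png`` and ``<stem>.svg``; returns the paths."""
    stem = Path(path_stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    paths = []
    for ext in ("png", "svg"):
        p = stem.with_suffix(f".{ext}")
        fig.savefig(p, dpi=150, bbox_inches="tight", metadata=_stable_metadata(ext))
        paths.append(p)
    plt.close(fig)
    return paths


def _stable_metadata(ext: str) -> dict:
    # strip timestamps so re-runs produce comparable files
    return {"Date": None} if ext == "svg" else {}


def plot_pca(res: PCAResult, color_by: dict | None = None, title: str = "PCA") -> plt.Figure:
    fig, ax = plt.subplots(figsize=(5, 4))
    xs = res.scores.iloc[:, 0]
    ys = res.scores.iloc[:, 1] if res.scores.shape[1] > 1 else np.zeros(len(xs))
    if color_by:
        levels = sorted({color_by.get(s) for s in res.scores.index}, key=str)
        cmap = plt.get_cmap("tab10")
        for i, level in enumerate(levels):
            sel = [s for s in res.scores.index if color_by.get(s) == level]
            ax.scatter(xs.loc[sel], ys.loc[sel], s=30, color=cmap(i % 10), label=str(level))
        ax.legend(fontsize=8)
    else:
        ax.scatter(xs, ys, s=30)
    for s in res.scores.index:
        ax.annotate(str(s), (xs.loc[s], ys.loc[s]), fontsize=6, alpha=0.7)
    ve = res.variance_explained
    ax.set_xlabel(f"PC1 ({ve[0] * 100:.1f}%)")
    ax.set_ylabel(f"PC2 ({ve[1] * 100:.1f}%)" if len(ve) > 1 else "PC2")
    ax.set_title(title)
    return fig


def plot_dendrogram(tree: TreeResult, title: str = "Sample clustering") -> plt.Figure:
    from scipy.cluster.hierarchy import dendrogram as scipy_dendrogram

    fig, ax = plt.subplots(figsize=(max(4, 0.5 * len(tree.labels)), 4))
    scipy_dendrogram(tree.linkage_matrix, labels=tree.labels, ax=ax, leaf_rotation=90)
    ax.set_ylabel("height (average linkage)")
    ax.set_title(title)
    return fig


def plot_densities(summ: SampleSummaries, title: str = "Per-sample densities") -> plt.Figure:
    fig, ax = plt.subplots(figsize=(6, 4))
    for s, dens in summ.densities.items():
        ax.plot(summ.density_grid, dens, label=str(s), lw=1)
    if len(summ.densities) <= 12:
        ax.legend(fontsize=7)
    ax.set_xlabel("value")
    ax.set_ylabel("density")
    ax.set_title(title)
    return fig


def plot_boxplots(summ: SampleSummaries, title: str = "Per-sample distributions") -> plt.Figure:
    fig, ax = plt.subplots(figsize=(max(4, 0.4 * len(summ.table)), 4))
    t = summ.table.dropna(subset=["median"]) if "median" in summ.table else summ.table
    pos = np.arange(len(t))
    stats = [
        {
            "med": row["median"],
            "q1": row["q1"],
            "q3": row["q3"],
            "whislo": row["min"],
            "whishi": row["max"],
            "label": str(idx),
        }
        for idx, row in t.iterrows()
    ]
    ax.bxp(stats, positions=pos, showfliers=False)
    ax.set_xticklabels([s["label"] for s in stats], rotation=90, fontsize=7)
    ax.set_ylabel("value")
    ax.set_title(title)
    return fig


def plot_feature_profile(profile: FeatureProfile) -> plt.Figure:
    fig, ax = plt.subplots(figsize=(5, 4))
    groups = list(profile.raw_points)
    for i, g in enumerate(groups):
        pts = profile.raw_points[g]
        ax.scatter(np.full(len(pts), i) + np.linspace(-0.1, 0.1, max(len(pts), 1)), pts, s=20)
        row = profile.groups.loc[g]
        if "median" in row and not np.isnan(row.get("median", np.nan)):
            ax.hlines(row["median"], i - 0.2, i + 0.2, color="black")
    ax.set_xticks(range(len(groups)), [str(g) for g in groups])
    ax.set_xlabel(profile.group_column)
    ax.set_ylabel("value")
    ax.set_title(f"Feature {profile.feature_id}")
    return fig


def plot_volcano_pair(
    table_a: PlotTable,
    table_b: PlotTable,
    classification: ClassificationTable | None = None,
    highlight: Sequence | None = None,
    titles: tuple[str, str] = ("comparison A", "comparison B"),
) -> plt.Figure:
    """Side-by-side volcano (or MA) panels sharing category colors and a
    highlight set."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=False)
    cat_by_id = {}
    if classification is not None:
        cat_by_id = dict(
            zip(classification.table["id"], classification.table["category"])
        )
    highlight = set(highlight or [])
    for ax, table, title in zip(axes, (table_a, table_b), titles):
        colors = [
            _CATEGORY_COLORS.get(cat_by_id.get(i, "neither"), "#bbbbbb")
            for i in table.data["id"]
        ]
        ax.scatter(table.data["x"], table.data["y"], s=8, c=colors, alpha=0.6, lw=0)
        if highlight:
            sel = table.data["id"].isin(highlight)
            ax.scatter(
                table.data.loc[sel, "x"],
                table.data.loc[sel, "y"],
                s=40,
                facecolors="none",
                edgecolors="red",
            )
        ax.set_xlabel(table.x_label)
        ax.set_ylabel(table.y_label)
        ax.set_title(title)
    if cat_by_id:
        handles = [
            plt.Line2D([], [], marker="o", ls="", color=c, label=l)
            for l, c in _CATEGORY_COLORS.items()
        ]
        fig.legend(handles=handles, fontsize=7, loc="upper center", ncol=5)
    fig.tight_layout()
    return fig


def plot_pvalue_histogram(counts: np.ndarray, title: str = "p-value histogram") -> plt.Figure:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    edges = np.linspace(0, 1, len(counts) + 1)
    ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge", edgecolor="white")
    ax.set_xlabel("p-value")
    ax.set_ylabel("features")
    ax.set_title(title)
    return fig


def plot_concordance(profile: ConcordanceProfile) -> plt.Figure:
    fig, ax = plt.subplots(figsize=(6, 4))
    centers = np.arange(len(profile.n_features))
    ax.bar(centers, profile.fraction_same, color="#1f77b4")
    ax.axhline(0.5, color="grey", ls="--", lw=1, label="independent null (0.5)")
    labels = [
        f"[{a:g}, {b:g}{']' if i == len(profile.n_features) - 1 else ')'}\nn={n}"
        for i, (a, b, n) in enumerate(
            zip(profile.bin_edges[:-1], profile.bin_edges[1:], profile.n_features)
        )
    ]
    ax.set_xticks(centers, labels, fontsize=7)
    ax.set_ylim(0, 1.05)
    ax.set_xlabel(f"p-value bin ({profile.bin_statistic})")
    ax.set_ylabel("fraction same direction")
    ax.legend(fontsize=8)
    return fig


def plot_upset(counts: IntersectionCounts, max_bars: int = 25, title: str = "UpSet") -> plt.Figure:
    """Exclusive-intersection bar chart over a membership dot matrix."""
    items = counts.sorted_items()[:max_bars]
    labels = counts.set_labels
    n_bars, n_sets = len(items), len(labels)
    fig, (ax_bars, ax_dots) = plt.subplots(
        2,
        1,
        figsize=(max(4, 0.45 * n_bars + 2), 3.5 + 0.3 * n_sets),
        sharex=True,
        height_ratios=[3, max(1, 0.45 * n_sets)],
    )
    xs = np.arange(n_bars)
    ax_bars.bar(xs, [n for _, n in items], color="#333333")
    for x, (_, n) in zip(xs, items):
        ax_bars.text(x, n, str(n), ha="center", va="bottom", fontsize=7)
    ax_bars.set_ylabel("exclusive\nintersection size")
    ax_bars.set_title(title)

    for y in range(n_sets):
        ax_dots.scatter(xs, np.full(n_bars, y), s=30, color="#dddddd", zorder=1)
    for x, (key, _) in zip(xs, items):
        ys = [i for i, l in enumerate(labels) if l in key]
        ax_dots.scatter(np.full(len(ys), x), ys, s=30, color="#333333", zorder=2)
        if len(ys) > 1:
            ax_dots.plot([x, x], [min(ys), max(ys)], color="#333333", lw=1.5, zorder=2)
    ax_dots.set_yticks(range(n_sets), labels, fontsize=8)
    ax_dots.set_xticks([])
    ax_dots.invert_yaxis()
    fig.tight_layout()
    return fig


def plot_venn2(
    only_a: int, only_b: int, both: int, labels: tuple[str, str] = ("A", "B")
) -> plt.Figure:
    """Standard (non-proportional) two-circle Venn with counts."""
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    for cx, color in ((-0.45, "#1f77b4"), (0.45, "#ff7f0e")):
        ax.add_patch(plt.Circle((cx, 0), 1.0, alpha=0.35, color=color))
    ax.text(-0.95, 0, str(only_a), ha="center", va="center", fontsize=12)
    ax.text(0.95, 0, str(only_b), ha="center", va="center", fontsize=12)
    ax.text(0, 0, str(both), ha="center", va="center", fontsize=12)
    ax.text(-0.75, 1.1, labels[0], ha="center", fontsize=10)
    ax.text(0.75, 1.1, labels[1], ha="center", fontsize=10)
    ax.set_xlim(-1.8, 1.8)
    ax.set_ylim(-1.4, 1.5)
    ax.set_aspect("equal")
    ax.axis("off")
    return fig


def plot_correlation_summary(summ: CorrelationSummary) -> plt.Figure:
    fig, ax = plt.subplots(figsize=(6, 4))
    centers = (summ.bin_edges[:-1] + summ.bin_edges[1:]) / 2
    width = np.diff(summ.bin_edges)
    for method, counts in summ.histograms.items():
        ax.bar(centers, counts, width=width, alpha=0.5, label=method.replace("_r", ""))
    ax.set_xlabel("per-feature correlation")
    ax.set_ylabel("features")
    ax.legend(fontsize=8)
    ax.set_title("Cross-layer correlation distributions")
    return fig
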