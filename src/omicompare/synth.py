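"""Self-contained statistics helpers and synthetic-data generators.

The cross-comparison analytics never fit statistical models to real data —
that is upstream work (limma/DESeq2-style pipelines). For testing the whole
stack end-to-end without downloads, this module provides

* Benjamini–Hochberg step-up FDR adjustment,
* a plain Welch two-group test producing the per-contrast statistics
  (p, FDR, log2 fold change, average level) the comparison modules expect,
* a spike-in-style simulator: two conditions, a null background plus
  known up/down features at a fixed true log2 fold — mimicking benchmark
  designs where proteins of two organisms are spiked at reversed
  concentrations (30%/3% w/w gives an expected log2 fold of
  log2(10) ~ 3.3),
* a paired two-layer multiomics simulator with controllable per-feature
  cross-layer correlation and same/opposite-direction group effects.

All generators take a mandatory seed and are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datamodel import ConfigurationError, ContrastStats, ExpressionDataset

__all__ = [
    "SpikeinDesign",
    "MultiomicsDesign",
    "bh_adjust",
    "two_group_stats",
    "simulate_spikein",
    "simulate_multiomics",
    "attach_contrast",
    "expected_spikein_log2fc",
]


def expected_spikein_log2fc(high_fraction: float = 30.0, low_fraction: float = 3.0) -> float:
    """Analytic log2 fold implied by reversed spike-in concentrations.

    Two conditions contain a spiked organism at ``high_fraction`` and
    ``low_fraction`` (w/w percent); the expected abundance ratio is their
    quotient, so e.g. 30%/3% gives log2(10) ~ 3.32.
    """
    if high_fraction <= 0 or low_fraction <= 0:
        raise ConfigurationError("spike-in fractions must be positive")
    return float(np.log2(high_fraction / low_fraction))


# ---------------------------------------------------------------------------
# Statistics helpers
# ---------------------------------------------------------------------------


def bh_adjust(p: Sequence[float] | np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    Sort the m observed p-values ascending, set q_(i) = min_{j>=i}
    p_(j) * m / j, clip at 1. Missing values are excluded from m and
    returned as missing.
    """
    arr = np.asarray(pd.Series(p, dtype=float).to_numpy(), dtype=float)
    ok = ~np.isnan(arr)
    vals = arr[ok]
    if np.any((vals < 0) | (vals > 1)):
        raise ConfigurationError("p-values must lie in [0, 1]")
    out = np.full(arr.shape, np.nan)
    m = vals.size
    if m:
        order = np.argsort(vals, kind="stable")
        scaled = vals[order] * m / np.arange(1, m + 1)
        q = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
        adj = np.empty(m)
        adj[order] = q
        out[ok] = adj
    return out


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone, convex)."""
    from scipy.special import polygamma

    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(polygamma(1, y))
        step = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += step
        if abs(step) < 1e-10 * y:
            break
    return y


def _moderate_variances(s2: np.ndarray, df: np.ndarray) -> tuple[np.ndarray, float]:
    """Empirical-Bayes shrinkage of per-feature variances.

    Assuming s2 ~ s0^2 * chi2_df / df, the prior (s0^2, d0) is estimated by
    method of moments on log s2 (matching the mean and excess variance of
    the log-chi-square distribution); the posterior variance is the
    df-weighted blend (d0*s0^2 + df*s2) / (d0 + df). Borrowing strength
    across features this way rescues power at very small replicate counts,
    where a per-feature variance estimate with 2-4 degrees of freedom is
    too unstable for meaningful t-tests.
    """
    from scipy.special import digamma, polygamma

    ok = (df >= 1) & (s2 > 0) & ~np.isnan(s2)
    if ok.sum() < 2:
        return s2, 0.0  # nothing to borrow: degenerate, leave untouched
    e = np.log(s2[ok]) - digamma(df[ok] / 2.0) + np.log(df[ok] / 2.0)
    evar = e.var(ddof=1) - float(np.mean(polygamma(1, df[ok] / 2.0)))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
    else:
        d0 = 1e6  # variances essentially exchangeable: near-infinite prior df
    d0 = min(d0, 1e6)
    s0_sq = float(np.exp(e.mean() + digamma(d0 / 2.0) - np.log(d0 / 2.0))) if np.isfinite(d0) else float(np.exp(e.mean()))
    post = (d0 * s0_sq + df * s2) / (d0 + df)
    post = np.where(np.isnan(s2), np.nan, post)
    return post, d0


def two_group_stats(
    ds: ExpressionDataset,
    group_column: str,
    level_a: str,
    level_b: str,
    contrast_name: str | None = None,
    moderate: bool = True,
) -> ContrastStats:
    """Per-feature two-group t-test between two condition levels.

    log2fc is mean(level_a) - mean(level_b) (data are assumed log2 scale),
    ``ave`` the overall mean over both groups' observed values, FDR by
    Benjamini–Hochberg over the features with a p-value.

    With ``moderate=True`` (default) the test is a pooled-variance t with
    empirical-Bayes variance shrinkage across features (prior degrees of
    freedom estimated from the variance distribution), matching the
    moderated models omics pipelines use at few replicates. With
    ``moderate=False`` a plain Welch unequal-variance t is used instead.

    Features with fewer than two observed values in either group get
    missing p/FDR; so do features whose observed within-group variance is
    exactly zero in both groups (e.g. noiseless or imputed data) — the fold
    change is still reported.
    """
    if group_column not in ds.design.columns:
        raise ConfigurationError(
            f"group column {group_column!r} not in design; "
            f"available: {list(ds.design.columns)}"
        )
    groups = ds.design[group_column].astype(str)
    samples_a = [s for s in ds.sample_names if groups.loc[s] == str(level_a)]
    samples_b = [s for s in ds.sample_names if groups.loc[s] == str(level_b)]
    for level, members in ((level_a, samples_a), (level_b, samples_b)):
        if not members:
            raise ConfigurationError(
                f"no samples with {group_column}=={level!r}; "
                f"levels present: {sorted(groups.unique())}"
            )
    A = ds.values_for_samples(samples_a)
    B = ds.values_for_samples(samples_b)

    def moments(X: np.ndarray):
        n = (~np.isnan(X)).sum(axis=1).astype(float)
        mean = np.where(n > 0, np.nanmean(np.where(n[:, None] > 0, X, 0.0), axis=1), np.nan)
        var = np.full(X.shape[0], np.nan)
        enough = n >= 2
        if enough.any():
            var[enough] = np.nanvar(X[enough], axis=1, ddof=1)
        return n, mean, var

    import warnings as _warnings

    with np.errstate(all="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        n_a, mean_a, var_a = moments(A)
        n_b, mean_b, var_b = moments(B)
        log2fc = mean_a - mean_b
        both = np.concatenate([A, B], axis=1)
        ave = np.where(
            (~np.isnan(both)).any(axis=1), np.nanmean(both, axis=1), np.nan
        )
        if moderate:
            df_pool = n_a + n_b - 2.0
            s2_pool = ((n_a - 1) * var_a + (n_b - 1) * var_b) / df_pool
            s2_post, d0 = _moderate_variances(s2_pool, df_pool)
            se2 = s2_post * (1.0 / n_a + 1.0 / n_b)
            t = log2fc / np.sqrt(se2)
            p = 2.0 * sps.t.sf(np.abs(t), df_pool + min(d0, 1e6))
            raw_se2 = var_a / n_a + var_b / n_b
        else:
            se2 = var_a / n_a + var_b / n_b
            t = log2fc / np.sqrt(se2)
            df = se2**2 / (
                (var_a / n_a) ** 2 / (n_a - 1) + (var_b / n_b) ** 2 / (n_b - 1)
            )
            p = 2.0 * sps.t.sf(np.abs(t), df)
            raw_se2 = se2
    usable = (n_a >= 2) & (n_b >= 2) & (raw_se2 > 0)
    p = np.where(usable, p, np.nan)
    fdr = bh_adjust(p)
    return ContrastStats(
        contrast_name=contrast_name or f"{level_a}_vs_{level_b}",
        p=pd.Series(p),
        fdr=pd.Series(fdr),
        log2fc=pd.Series(log2fc),
        ave=pd.Series(ave),
    )


def attach_contrast(ds: ExpressionDataset, stats: ContrastStats, prefix: str) -> None:
    """Append contrast columns ``<prefix>_{p,fdr,lfc,ave}`` to the feature table."""
    ann = ds.feature_annotations
    ann[f"{prefix}_p"] = stats.p.to_numpy()
    ann[f"{prefix}_fdr"] = stats.fdr.to_numpy()
    ann[f"{prefix}_lfc"] = stats.log2fc.to_numpy()
    ann[f"{prefix}_ave"] = stats.ave.to_numpy()


# ---------------------------------------------------------------------------
# Simulators
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpikeinDesign:
    """Two-condition benchmark with known up/down features.

    Defaults mirror a proteomics spike-in benchmark: a large null
    background, a block of features shifted up and one shifted down by a
    true log2 fold of 3.3 (reversed 30%/3% w/w spike levels), measured in
    triplicate per condition with log2-scale replicate noise of 0.5.
    ``baseline_mean``/``baseline_sd`` place per-feature baselines on a
    realistic log2-intensity scale.
    """

    n_background: int = 1800
    n_up: int = 100
    n_down: int = 100
    true_lfc: float = 3.3
    noise_sd: float = 0.5
    n_replicates: int = 3
    missing_rate: float = 0.0
    seed: int = 0
    baseline_mean: float = 20.0
    baseline_sd: float = 2.0

    def __post_init__(self) -> None:
        if min(self.n_background, self.n_up, self.n_down) < 0:
            raise ConfigurationError("feature counts must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.n_replicates < 2:
            raise ConfigurationError("need >= 2 replicates per condition")
        if not (0 <= self.missing_rate < 1):
            raise ConfigurationError("missing_rate must be in [0, 1)")


def simulate_spikein(d: SpikeinDesign) -> tuple[ExpressionDataset, pd.DataFrame]:
    """Simulate a two-condition spike-in-style dataset with ground truth.

    Returns the dataset (conditions ``level1`` / ``level2``; the contrast
    convention is level1 - level2) and a truth table with each feature's
    class (``background``/``up``/``down``) and true log2 fold.
    """
    rng = np.random.default_rng(d.seed)
    n_feat = d.n_background + d.n_up + d.n_down
    classes = np.array(
        ["background"] * d.n_background + ["up"] * d.n_up + ["down"] * d.n_down
    )
    true_lfc = np.where(
        classes == "up", d.true_lfc, np.where(classes == "down", -d.true_lfc, 0.0)
    )
    baseline = rng.normal(d.baseline_mean, d.baseline_sd, size=n_feat)
    samples = [f"level{c}_r{r + 1}" for c in (1, 2) for r in range(d.n_replicates)]
    condition = ["level1"] * d.n_replicates + ["level2"] * d.n_replicates
    # level1 mean = baseline + true_lfc, level2 mean = baseline
    means = np.empty((n_feat, len(samples)))
    means[:, : d.n_replicates] = (baseline + true_lfc)[:, None]
    means[:, d.n_replicates:] = baseline[:, None]
    values = means + rng.normal(0.0, d.noise_sd, size=means.shape)
    if d.missing_rate > 0:
        mask = rng.random(values.shape) < d.missing_rate
        values = np.where(mask, np.nan, values)

    ids = [f"feat{i + 1:05d}" for i in range(n_feat)]
    ds = ExpressionDataset(
        name="spikein_sim",
        matrix=pd.DataFrame(values, columns=samples),
        feature_annotations=pd.DataFrame({"feature_id": ids}),
        design=pd.DataFrame(
            {"sample": samples, "condition": condition}
        ).set_index(pd.Index(samples, name="sample_name")),
        id_column="feature_id",
    )
    truth = pd.DataFrame({"feature_id": ids, "class": classes, "true_lfc": true_lfc})
    return ds, truth


@dataclass(frozen=True)
class MultiomicsDesign:
    """Paired two-layer design on the same samples.

    Each feature's two layers are drawn as a bivariate normal across
    samples with correlation ``target_rho``. ``n_same``/``n_contra``
    features additionally get a two-group effect of ``effect_lfc`` applied
    with equal / opposite signs in the two layers, supporting
    concordant-vs-contra classification tests; the remainder are null.
    """

    n_features: int = 2000
    n_samples: int = 50
    target_rho: float = 0.5
    n_same: int = 0
    n_contra: int = 0
    effect_lfc: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0
    baseline_mean: float = 20.0
    baseline_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ConfigurationError("need >= 3 samples")
        if not (-1 <= self.target_rho <= 1):
            raise ConfigurationError("target_rho must be in [-1, 1]")
        if self.n_same + self.n_contra > self.n_features:
            raise ConfigurationError("effect features exceed n_features")


def simulate_multiomics(
    d: MultiomicsDesign,
) -> tuple[ExpressionDataset, ExpressionDataset, pd.DataFrame]:
    """Simulate two expression layers sharing IDs and samples.

    Returns (layer_x, layer_y, truth); truth labels each feature
    ``same`` / ``contra`` / ``null``. Samples are split into two equal-ish
    groups (design column ``group``: g1/g2) and group effects are applied
    to g1, so the g1-vs-g2 contrast has log2fc +effect in layer x for both
    effect classes and +/-effect in layer y for same/contra respectively.
    """
    rng = np.random.default_rng(d.seed)
    n, s = d.n_features, d.n_samples
    rho = d.target_rho
    z1 = rng.standard_normal((n, s))
    z2 = rng.standard_normal((n, s))
    y_corr = rho * z1 + np.sqrt(max(0.0, 1 - rho**2)) * z2

    baseline = rng.normal(d.baseline_mean, d.baseline_sd, size=n)
    X = baseline[:, None] + d.noise_sd * z1
    Y = baseline[:, None] + d.noise_sd * y_corr

    labels = np.array(
        ["same"] * d.n_same
        + ["contra"] * d.n_contra
        + ["null"] * (n - d.n_same - d.n_contra)
    )
    half = s // 2
    group = np.array(["g1"] * half + ["g2"] * (s - half))
    g1 = group == "g1"
    eff_x = np.where(labels == "null", 0.0, d.effect_lfc)
    eff_y = np.where(
        labels == "same", d.effect_lfc, np.where(labels == "contra", -d.effect_lfc, 0.0)
    )
    X[:, g1] += eff_x[:, None]
    Y[:, g1] += eff_y[:, None]

    ids = [f"feat{i + 1:05d}" for i in range(n)]
    samples = [f"s{i + 1:03d}" for i in range(s)]
    design = pd.DataFrame({"sample": samples, "group": group}).set_index(
        pd.Index(samples, name="sample_name")
    )

    def layer(name: str, values: np.ndarray) -> ExpressionDataset:
        return ExpressionDataset(
            name=name,
            matrix=pd.DataFrame(values, columns=samples),
            feature_annotations=pd.DataFrame({"feature_id": ids}),
            design=design.copy(),
            id_column="feature_id",
        )

    truth = pd.DataFrame({"feature_id": ids, "class": labels, "eff_x": eff_x, "eff_y": eff_y})
    return layer("layer_x", X), layer("layer_y", Y), truth
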