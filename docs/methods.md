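# Methods

This note documents the models, conventions and numerical choices behind
`omicompare`, and what the synthetic benchmarks do and do not demonstrate.

## Data model and merging

A dataset is a feature × sample matrix of log-scale intensities (or
transformed counts) with row-aligned feature annotations and a per-sample
design table. Missing values are first-class: the tokens `NA`, `NaN`,
`null` and the empty string (case-insensitive), and any non-numeric cell,
parse to missing. Zeros are *not* missing by default; pipelines that
encode below-detection-limit values as 0 can set `zero_as_missing`.
Numeric parsing goes through correctly rounded `float()` so that a
written dataset reads back bit-identically.

Two datasets are joined on a shared-ID annotation column. When an ID
occurs several times (e.g. multiple transcripts per gene), the first
listed entry in file row order is kept — a deliberate, deterministic
convention rather than any abundance-based pick — and dropped-duplicate
counts are recorded. The shared-ID order follows the first dataset, which
makes every downstream table deterministic. ID matching is case-sensitive
by default (`fold_case` folds both sides to lower case); the merge is
idempotent.

## Significance and classification

Thresholds are strict on both sides: `stat < α` and `|log2FC| > λ`. The
strictness matters only for boundary values but must be fixed once;
features with missing statistics are never significant, so "not
significant" conflates "tested and null" with "not testable" — the
presence/absence module exists precisely to separate those cases.

Classification of a shared feature into `both_same` / `both_contra` /
`a_only` / `b_only` / `neither` is a pure function of the two significance
flags and the two fold-change signs, and partitions the shared features.
The fold-change sign convention comes from the upstream contrasts: the
package never flips signs, and nothing in the data can verify that both
contrasts used the same group ordering — this is an assumption the user
must guarantee (it is stated in the CLI help and here).

## Concordance profile

Shared features with both p-values present are assigned to p-value bins
(default edges 0, 0.001, 0.01, 0.05, 0.1, 0.5, 1; left-closed, last bin
closed). The default bin statistic is `max(p_A, p_B)`: a feature only
counts as low-p when it is low-p in *both* comparisons, which is the
conservative reading for a cross-comparison reliability statistic. The
alternative `per_comparison` mode lets each feature contribute twice, once
per comparison's own p-value, for users who want marginal rather than
joint stratification. Direction agreement requires equal *nonzero* signs;
exact-zero fold changes count toward bin sizes but never toward agreement,
so they dilute rather than inflate concordance. Empty bins report a
missing fraction rather than 0.

## Overlap analytics

Membership matrices are boolean feature × set tables. UpSet-style
*exclusive* intersections assign each feature to its exact membership
pattern, so pattern counts sum to the union size; features in no set are
reported as a separate tally, and features entirely absent from a dataset
count as absent (membership false) rather than being dropped from the
universe. Intersection ordering is decreasing count, ties broken by degree
then lexicographic key — deterministic output for tests and diffs.
Direction splitting replaces each comparison's set by an up-set and a
down-set (significant features with positive/negative fold); a pattern
joining one comparison's up-set with another's down-set is exactly the
"contra" phenomenon. Presence/absence membership means ≥ `min_obs`
observed values (default 1, i.e. "not missing in all samples") within a
dataset or condition group.

## Quality computations

PCA and dendrograms use complete-case feature filtering over the selected
samples — no imputation, so the feature universe shrinks with
missingness; `n_features_used` is always reported. PCA centers per
feature, scales to unit variance by default (zero-variance features are
dropped with a warning when scaling), and is computed by SVD, so loadings
are orthonormal by construction. Component signs are fixed by orienting
each loading vector so its largest-magnitude element is positive.
Dendrograms use average linkage (UPGMA) over euclidean (default) or
correlation (1 − Pearson) sample distances; the linkage itself is scipy's,
verified in tests against a naive O(n³) UPGMA.

Summary quantiles use linear interpolation (type 7, the numpy/R default).
Densities use a Gaussian kernel with Silverman's bandwidth on a shared
512-point grid spanning the pooled range ± 3 bandwidths; constant or
single-value samples are flagged degenerate instead of producing a
degenerate kernel.

## Two-group test and FDR

`bh_adjust` implements the Benjamini–Hochberg step-up exactly (missing
p-values are excluded from m and returned missing); it is cross-checked in
tests against both a double-loop oracle and statsmodels.

`two_group_stats` produces the per-contrast statistics the comparison
modules consume. The default test is a pooled-variance t with
empirical-Bayes variance moderation: per-feature variances s² (d degrees
of freedom) are shrunk toward a prior (s₀², d₀) estimated by method of
moments on log s² (trigamma inversion for d₀), and the t statistic uses
the posterior variance with d + d₀ degrees of freedom. At the 3 + 3
replicates typical of benchmark designs, an unmoderated test has ~4
degrees of freedom per feature and essentially no power after FDR
control even for 3.3 log2-fold effects; borrowing variance information
across features is what the field's upstream tools (limma and
descendants) do, and is required for the simulated benchmarks to behave
like their real counterparts. `moderate=False` gives a plain Welch
unequal-variance t for users who want no sharing across features.
Degenerate features keep explicit missing statistics: fewer than two
observations in either group, or exactly zero observed variance in both
groups (noiseless or imputed data), yield missing p/FDR while the fold
change is still reported — a moderated variance is deliberately *not*
substituted there, since zero observed variance usually signals an
artifact rather than true precision.

## Synthetic data

The generators define the benchmark conditions; they are not tuning
knobs.

**Spike-in benchmark** (`SpikeinDesign`): two conditions × 3 replicates,
1800 null background features and 100 + 100 features shifted up/down by a
true log2 fold of 3.3 — the fold implied by reversing 30%/3% w/w spike
levels between conditions (log2(30/3) ≈ 3.32). Per-feature baselines are
drawn N(20, 2²) on the log2-intensity scale (typical of proteomics
intensities) and replicate noise is N(0, 0.5²) in log2 units, a realistic
between-replicate spread for such designs; optional missingness is
missing-completely-at-random at a configurable rate. What this emulates:
known-truth fold recovery and power/FDR behavior. What it does not:
intensity-dependent missingness, correlated features, heteroscedasticity
across the intensity range — so passing benchmarks here show the
machinery is correct, not that any particular real dataset will reach the
same power.

**Paired multiomics** (`MultiomicsDesign`): per feature, the two layers'
sample vectors are bivariate normal with correlation `target_rho`; an
optional two-group effect is added with equal (`same`) or opposite
(`contra`) signs in the two layers. This supports correlation-recovery
tests and end-to-end classification tests. Real cross-layer data have
feature-dependent correlations and shared technical structure that this
generator deliberately omits.

All generators take a mandatory seed (numpy `default_rng`) and are
bit-reproducible.

## Reporting and reproducibility

Every CLI run writes a canonical-JSON settings snapshot (sorted keys,
UTF-8, trailing newline) whose save → load → save cycle is
byte-identical; replaying a snapshot reproduces byte-identical TSV
outputs. The output directory is excluded from the snapshot, as a
destination rather than an analysis setting. Figures are static PNG + SVG
(SVG metadata dates stripped); HTML reports embed PNGs base64 so the
report is a single self-contained file.

## Problem sizes

The test suite and the acceptance script run entirely on simulated data
at moderate sizes chosen to make sampling error negligible relative to
the tolerances checked: 2000-feature spike-in and multiomics instances
(50 samples for correlation recovery), 5000-feature null calibration,
10000-feature concordance null, and a few hundred randomized instances
per oracle-equivalence check (up to 6 sets / 500 features for set logic,
up to 12 samples for UPGMA). The whole suite completes in well under a
minute of compute.

## Known limitations

* Contrast orientation across datasets cannot be verified from the data.
* No imputation, batch correction or count-model simulation; upstream
  tools own normalization and model fitting.
* Correlation p-values / multiple testing over correlations are out of
  scope; the module reports effect sizes and distributions only.
* Venn rendering is the standard two-circle layout; counts, not
  proportional areas.
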