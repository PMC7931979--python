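"""Cross-comparison classification, plot tables and concordance profiles."""

import numpy as np
import pandas as pd
import pytest

from omicompare import (
    ConfigurationError,
    Thresholds,
    classify_features,
    concordance_profile,
    is_significant,
    ma_table,
    pvalue_histogram,
    select_features,
    volcano_table,
)
from conftest import make_contrast, make_pair


def classify_oracle(sig_a, sig_b, lfc_a, lfc_b):
    """Brute-force truth table for a single feature's category."""
    da, db = np.sign(lfc_a), np.sign(lfc_b)
    if sig_a and sig_b:
        if da == db and da != 0:
            return "both_same"
        if da * db < 0:
            return "both_contra"
        return "neither"  # zero direction on either side
    if sig_a:
        return "a_only"
    if sig_b:
        return "b_only"
    return "neither"


class TestIsSignificant:
    @pytest.mark.parametrize(
        "fdr,lfc,expected",
        [
            (0.01, 2.0, True),
            (0.05, 2.0, False),   # boundary: strict inequality on alpha
            (0.01, 1.0, False),   # boundary: strict inequality on lfc
            (0.01, -2.0, True),   # absolute fold
            (np.nan, 2.0, False),
            (0.01, np.nan, False),
        ],
    )
    def test_threshold_semantics(self, fdr, lfc, expected):
        stats = make_contrast(p=[0.001], fdr=[fdr], lfc=[lfc])
        t = Thresholds(alpha=0.05, stat_column="fdr", lfc_min=1.0)
        assert is_significant(stats, t)[0] == expected

    def test_p_column_selectable(self):
        stats = make_contrast(p=[0.01], fdr=[0.2], lfc=[2.0])
        assert not is_significant(stats, Thresholds(0.05, "fdr", 1.0))[0]
        assert is_significant(stats, Thresholds(0.05, "p", 1.0))[0]

    @pytest.mark.parametrize("alpha,stat,lfc_min", [(0, "fdr", 0), (1.5, "fdr", 0), (0.05, "q", 0), (0.05, "fdr", -1)])
    def test_invalid_thresholds_rejected(self, alpha, stat, lfc_min):
        with pytest.raises(ConfigurationError):
            Thresholds(alpha=alpha, stat_column=stat, lfc_min=lfc_min)


class TestClassifyFeatures:
    def test_definition_examples(self):
        m = make_pair(4)
        t = Thresholds(alpha=0.05, stat_column="fdr", lfc_min=1.0)
        stats_a = make_contrast(p=[0.001] * 4, fdr=[0.01, 0.01, 0.01, 0.5], lfc=[2.0, 2.0, 2.0, 0.1])
        stats_b = make_contrast(p=[0.001] * 4, fdr=[0.01, 0.02, 0.2, 0.6], lfc=[1.5, -1.2, 2.0, -0.1])
        cls = classify_features(m, stats_a, stats_b, t)
        assert list(cls.table["category"]) == ["both_same", "both_contra", "a_only", "neither"]

    def test_zero_lfc_cannot_carry_a_direction(self):
        # strict |lfc| > 0 keeps an exactly-zero fold change non-significant,
        # so it can never land in a both_* category
        m = make_pair(2)
        t = Thresholds(alpha=0.05, stat_column="fdr", lfc_min=0.0)
        stats_a = make_contrast(fdr=[0.01, 0.01], lfc=[2.0, 2.0])
        stats_b = make_contrast(fdr=[0.01, 0.01], lfc=[0.0, 1.0])
        cls = classify_features(m, stats_a, stats_b, t)
        assert list(cls.table["category"]) == ["a_only", "both_same"]

    def test_partition_matches_truth_table(self, rng):
        """Categories partition every random instance exactly as the
        brute-force per-feature truth table dictates."""
        t = Thresholds(alpha=0.05, stat_column="fdr", lfc_min=0.5)
        for _ in range(50):
            n = int(rng.integers(1, 60))
            fdr_a = rng.choice([0.01, 0.2, np.nan], size=n)
            fdr_b = rng.choice([0.01, 0.2, np.nan], size=n)
            lfc_a = rng.choice([-2.0, -0.1, 0.0, 0.1, 2.0, np.nan], size=n)
            lfc_b = rng.choice([-2.0, -0.1, 0.0, 0.1, 2.0, np.nan], size=n)
            m = make_pair(n)
            cls = classify_features(
                m,
                make_contrast(p=fdr_a, fdr=fdr_a, lfc=lfc_a),
                make_contrast(p=fdr_b, fdr=fdr_b, lfc=lfc_b),
                t,
            )
            sig = lambda f, l: bool(
                not np.isnan(f) and not np.isnan(l) and f < t.alpha and abs(l) > t.lfc_min
            )
            expected = [
                classify_oracle(
                    sig(fdr_a[i], lfc_a[i]),
                    sig(fdr_b[i], lfc_b[i]),
                    0.0 if np.isnan(lfc_a[i]) else lfc_a[i],
                    0.0 if np.isnan(lfc_b[i]) else lfc_b[i],
                )
                for i in range(n)
            ]
            assert list(cls.table["category"]) == expected
            assert cls.counts().sum() == n  # partition


class TestPlotTables:
    def test_volcano_basic_and_p1(self):
        stats = make_contrast(p=[0.01, 1.0], lfc=[2.0, 0.5])
        table = volcano_table(stats, ids=["g1", "g2"])
        assert table.data.loc[0, "x"] == 2.0
        assert table.data.loc[0, "y"] == pytest.approx(2.0)
        assert table.data.loc[1, "y"] == pytest.approx(0.0)

    def test_volcano_p_zero_clipped(self):
        stats = make_contrast(p=[0.0, 1e-4], lfc=[1.0, 1.0])
        table = volcano_table(stats)
        assert table.data.loc[0, "clipped"]
        assert table.data.loc[0, "y"] == pytest.approx(4 * 1.05)

    def test_volcano_missing_excluded_with_tally(self):
        stats = make_contrast(p=[0.01, np.nan], lfc=[1.0, 1.0])
        table = volcano_table(stats)
        assert len(table.data) == 1 and table.n_excluded == 1

    def test_ma_table(self):
        stats = make_contrast(lfc=[1.0, 2.0], ave=[10.0, np.nan])
        table = ma_table(stats)
        assert (table.data.loc[0, "x"], table.data.loc[0, "y"]) == (10.0, 1.0)
        assert table.n_excluded == 1

    def test_counts_conserved(self, rng):
        n = 200
        p = rng.uniform(size=n)
        p[rng.choice(n, 30, replace=False)] = np.nan
        stats = make_contrast(p=p, lfc=rng.normal(size=n))
        for table in (volcano_table(stats), ma_table(stats)):
            assert len(table.data) + table.n_excluded == n

    def test_all_missing_empty_no_crash(self):
        stats = make_contrast(p=[np.nan] * 3, lfc=[np.nan] * 3, ave=[np.nan] * 3)
        assert len(ma_table(stats).data) == 0
        assert len(volcano_table(stats).data) == 0


class TestPvalueHistogram:
    def test_two_bins(self):
        counts = pvalue_histogram(make_contrast(p=[0.01, 0.02, 0.99]), n_bins=2)
        assert list(counts) == [2, 1]

    def test_uniform_within_binomial_error(self, rng):
        p = rng.uniform(size=10_000)
        counts = pvalue_histogram(make_contrast(p=p), n_bins=20)
        sd = np.sqrt(10_000 * 0.05 * 0.95)
        assert np.all(np.abs(counts - 500) < 5 * sd)
        assert counts.sum() == 10_000

    def test_empty_input_all_zero(self):
        counts = pvalue_histogram(make_contrast(p=[np.nan]), n_bins=5)
        assert counts.sum() == 0 and len(counts) == 5


class TestSelectFeatures:
    def test_rectangle_containment(self):
        data = pd.DataFrame({"id": ["g1", "g2"], "x": [2.0, -1.0], "y": [3.0, 0.5]})
        assert select_features(data, region=(0, 3, 1, 4)) == ["g1"]
        assert select_features(data, region=(-5, 5, 0, 5)) == ["g1", "g2"]

    def test_id_list_passthrough_preserves_table_order(self):
        data = pd.DataFrame({"id": ["g1", "g2", "g3"], "x": [0, 0, 0], "y": [0, 0, 0]})
        assert select_features(data, ids=["g3", "g1", "gX"]) == ["g1", "g3"]

    def test_empty_selection_is_empty_list(self):
        data = pd.DataFrame({"id": ["g1"], "x": [5.0], "y": [5.0]})
        assert select_features(data, region=(0, 1, 0, 1)) == []


class TestConcordanceProfile:
    def test_direct_count(self):
        m = make_pair(4)
        stats_a = make_contrast(p=[0.5] * 4, lfc=[1, 1, 1, -1])
        stats_b = make_contrast(p=[0.5] * 4, lfc=[1, 1, -1, -1])
        prof = concordance_profile(m, stats_a, stats_b, bin_edges=[0, 1])
        assert prof.n_features[0] == 4
        assert prof.fraction_same[0] == pytest.approx(0.75)

    def test_max_p_rule(self):
        m = make_pair(1)
        prof = concordance_profile(
            m,
            make_contrast(p=[0.001], lfc=[1.0]),
            make_contrast(p=[0.2], lfc=[1.0]),
            bin_edges=[0, 0.05, 1],
        )
        assert list(prof.n_features) == [0, 1]

    def test_per_comparison_binning(self):
        m = make_pair(1)
        prof = concordance_profile(
            m,
            make_contrast(p=[0.001], lfc=[1.0]),
            make_contrast(p=[0.2], lfc=[1.0]),
            bin_edges=[0, 0.05, 1],
            bin_statistic="per_comparison",
        )
        assert list(prof.n_features) == [1, 1]

    def test_independent_null_fraction_half(self, rng):
        n = 10_000
        m = make_pair(n)
        lfc_a = rng.choice([-1.0, 1.0], size=n)
        lfc_b = rng.choice([-1.0, 1.0], size=n)
        prof = concordance_profile(
            m,
            make_contrast(p=rng.uniform(size=n), lfc=lfc_a),
            make_contrast(p=rng.uniform(size=n), lfc=lfc_b),
        )
        for frac, cnt in zip(prof.fraction_same, prof.n_features):
            if cnt > 50:
                assert abs(frac - 0.5) < 4 * np.sqrt(0.25 / cnt)

    def test_shared_effects_raise_low_p_concordance_above_null(self, rng):
        """True shared signal gives higher agreement in low-p bins than an
        independent-null simulation at matched size."""
        n = 4000
        m = make_pair(n)
        effect = rng.choice([-3.0, 3.0], size=n)
        noise = lambda: rng.normal(0, 0.5, size=n)
        lfc_a, lfc_b = effect + noise(), effect + noise()
        p_shared = np.minimum(rng.uniform(size=n) * 0.01, 1.0)  # strong effects: low p
        prof_shared = concordance_profile(
            m, make_contrast(p=p_shared, lfc=lfc_a), make_contrast(p=p_shared, lfc=lfc_b)
        )
        prof_null = concordance_profile(
            m,
            make_contrast(p=p_shared, lfc=rng.choice([-1.0, 1.0], size=n)),
            make_contrast(p=p_shared, lfc=rng.choice([-1.0, 1.0], size=n)),
        )
        low_bins = prof_shared.n_features > 100
        assert np.all(
            prof_shared.fraction_same[low_bins] > prof_null.fraction_same[low_bins]
        )

    def test_bin_counts_conserved(self, rng):
        n = 500
        m = make_pair(n)
        p_a, p_b = rng.uniform(size=n), rng.uniform(size=n)
        p_a[:20] = np.nan
        prof = concordance_profile(
            m, make_contrast(p=p_a, lfc=np.ones(n)), make_contrast(p=p_b, lfc=np.ones(n))
        )
        assert prof.n_features.sum() == n - 20

    @pytest.mark.parametrize("edges", [[0.1, 1], [0, 0.9], [0, 0.5, 0.5, 1], [1, 0]])
    def test_invalid_edges_rejected(self, edges):
        m = make_pair(1)
        s = make_contrast(p=[0.5], lfc=[1.0])
        with pytest.raises(ConfigurationError):
            concordance_profile(m, s, s, bin_edges=edges)
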