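"""Membership matrices, exclusive intersections, Venn and presence analysis."""

import numpy as np
import pandas as pd
import pytest

from omicompare import (
    ConfigurationError,
    MembershipMatrix,
    Thresholds,
    direction_split_membership,
    exclusive_intersections,
    presence_membership,
    significance_membership,
    subset_export,
    venn_counts,
)
from conftest import make_dataset


def membership_from_sets(universe, sets):
    data = pd.DataFrame(
        {label: [f in members for f in universe] for label, members in sets.items()},
        index=pd.Index(universe),
    )
    return MembershipMatrix(data=data)


def brute_force_exclusive(universe, sets):
    """Enumerate every feature's exact pattern (oracle)."""
    counts = {}
    none = 0
    for f in universe:
        key = frozenset(l for l, members in sets.items() if f in members)
        if key:
            counts[key] = counts.get(key, 0) + 1
        else:
            none += 1
    return counts, none


T = Thresholds(alpha=0.05, stat_column="fdr", lfc_min=0.0)


class TestExclusiveIntersections:
    def test_enumerated_example(self):
        sets = {"A": {1, 2, 3}, "B": {2, 3, 4}, "C": {3}}
        m = membership_from_sets([1, 2, 3, 4], sets)
        counts = exclusive_intersections(m).counts
        assert counts == {
            frozenset({"A"}): 1,
            frozenset({"B"}): 1,
            frozenset({"A", "B"}): 1,
            frozenset({"A", "B", "C"}): 1,
        }

    def test_disjoint_sets(self):
        m = membership_from_sets(range(5), {"A": {0, 1}, "B": {2, 3, 4}})
        counts = exclusive_intersections(m).counts
        assert counts == {frozenset({"A"}): 2, frozenset({"B"}): 3}

    def test_counts_sum_to_union(self, rng):
        for _ in range(30):
            k = int(rng.integers(1, 7))
            n = int(rng.integers(1, 100))
            universe = list(range(n))
            sets = {
                f"S{i}": set(rng.choice(n, size=rng.integers(0, n + 1), replace=False))
                for i in range(k)
            }
            m = membership_from_sets(universe, sets)
            res = exclusive_intersections(m)
            union = set().union(*sets.values())
            assert res.total() == len(union)
            assert res.none_count == n - len(union)
            expected, none = brute_force_exclusive(universe, sets)
            assert res.counts == expected and res.none_count == none

    def test_sorted_items_deterministic_order(self):
        m = membership_from_sets(
            range(6), {"B": {0, 1}, "A": {2, 3}, "C": {4, 5}}
        )
        items = exclusive_intersections(m).sorted_items()
        # equal counts: ties broken by degree then lexicographic label tuple
        assert [tuple(sorted(k)) for k, _ in items] == [("A",), ("B",), ("C",)]


class TestVennCounts:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({1, 2}, {2}, (1, 0, 1)),
            ({1, 2}, {1, 2}, (0, 0, 2)),
            ({1, 2, 3}, set(), (3, 0, 0)),
        ],
    )
    def test_pairwise_counts(self, a, b, expected):
        m = membership_from_sets(sorted(a | b | {99}), {"A": a, "B": b})
        assert venn_counts(m) == expected

    def test_matches_exclusive_intersections(self, rng):
        for _ in range(20):
            n = 40
            a = set(rng.choice(n, size=15, replace=False))
            b = set(rng.choice(n, size=15, replace=False))
            m = membership_from_sets(range(n), {"A": a, "B": b})
            only_a, only_b, both = venn_counts(m)
            counts = exclusive_intersections(m).counts
            assert only_a == counts.get(frozenset({"A"}), 0)
            assert only_b == counts.get(frozenset({"B"}), 0)
            assert both == counts.get(frozenset({"A", "B"}), 0)

    def test_wrong_set_count_rejected(self):
        m = membership_from_sets(range(3), {"A": {0}, "B": {1}, "C": {2}})
        with pytest.raises(ConfigurationError):
            venn_counts(m)


class TestSignificanceMembership:
    def test_flags_follow_thresholds(self):
        ids = ["g1", "g2", "g3"]
        specs = [
            ("c1", [0.01, 0.2, np.nan], [1.0, 1.0, 1.0], T),
            ("c2", [0.01, 0.01, 0.01], [1.0, 1.0, 1.0], T),
        ]
        m = significance_membership(specs, ids)
        assert list(m.data.loc["g1"]) == [True, True]
        assert list(m.data.loc["g2"]) == [False, True]
        assert list(m.data.loc["g3"]) == [False, True]  # missing stat -> not member

    def test_all_false_row_stays_in_universe(self):
        specs = [
            ("c1", [0.5], [1.0], T),
            ("c2", [0.5], [1.0], T),
        ]
        m = significance_membership(specs, ["g1"])
        res = exclusive_intersections(m)
        assert res.total() == 0 and res.none_count == 1


class TestDirectionSplit:
    def test_up_down_sets_and_contra_pattern(self):
        specs = [
            ("A", [0.01, 0.01], [2.0, -1.0], T),
            ("B", [0.01, 0.01], [-2.0, -1.5], T),
        ]
        m = direction_split_membership(specs, ["g1", "g2"])
        assert set(m.data.columns) == {"A_up", "A_down", "B_up", "B_down"}
        counts = exclusive_intersections(m).counts
        # g1: up in A, down in B -> the contra pattern pairs an up-set with a down-set
        assert counts[frozenset({"A_up", "B_down"})] == 1
        assert counts[frozenset({"A_down", "B_down"})] == 1

    def test_zero_lfc_excluded_and_tallied(self):
        t0 = Thresholds(alpha=0.05, stat_column="p", lfc_min=0.0)
        specs = [("A", [0.01], [0.0], t0), ("B", [0.01], [1.0], t0)]
        m = direction_split_membership(specs, ["g1"])
        assert not m.data[["A_up", "A_down"]].any().any()
        # strict |lfc|>0 already makes lfc=0 non-significant; tally stays 0
        assert m.n_zero_lfc_excluded == 0

    def test_split_union_equals_significant_nonzero(self, rng):
        for _ in range(20):
            n = 100
            stat = rng.uniform(size=n)
            lfc = rng.normal(size=n) * (rng.random(n) > 0.1)
            specs = [("A", stat, lfc, T), ("B", rng.uniform(size=n), rng.normal(size=n), T)]
            base = significance_membership(specs, list(range(n)))
            split = direction_split_membership(specs, list(range(n)))
            for label in ("A", "B"):
                sig_nonzero = base.data[label].to_numpy() & (
                    np.nan_to_num(dict(A=lfc, B=specs[1][2])[label]) != 0
                )
                union = (
                    split.data[f"{label}_up"] | split.data[f"{label}_down"]
                ).to_numpy()
                np.testing.assert_array_equal(union, sig_nonzero)


class TestPresence:
    def test_observed_in_one_of_three_samples_is_present(self):
        ds1 = make_dataset([[1.0, np.nan, np.nan]], ids=["g1"], name="d1")
        ds2 = make_dataset([[np.nan, np.nan, np.nan]], ids=["g1"], name="d2")
        m = presence_membership([ds1, ds2])
        assert bool(m.data.loc["g1", "d1"]) is True
        assert bool(m.data.loc["g1", "d2"]) is False

    def test_min_obs_threshold(self):
        ds1 = make_dataset([[1.0, 2.0, np.nan]], ids=["g1"], name="d1")
        ds2 = make_dataset([[1.0, 2.0, 3.0]], ids=["g1"], name="d2")
        m = presence_membership([ds1, ds2], min_obs=3)
        assert bool(m.data.loc["g1", "d1"]) is False
        assert bool(m.data.loc["g1", "d2"]) is True

    def test_feature_absent_from_dataset_counts_absent(self):
        ds1 = make_dataset([[1.0, 1.0]], ids=["g1"], name="d1")
        ds2 = make_dataset([[1.0, 1.0], [2.0, 2.0]], ids=["g1", "g2"], name="d2")
        m = presence_membership([ds1, ds2])
        assert list(m.data.index) == ["g1", "g2"]
        assert bool(m.data.loc["g2", "d1"]) is False

    def test_condition_split_mode(self):
        ds = make_dataset(
            [[1.0, np.nan, np.nan, np.nan]], ids=["g1"], groups=["x", "x", "y", "y"]
        )
        m = presence_membership(ds, group_column="group")
        assert bool(m.data.loc["g1", "x"]) is True
        assert bool(m.data.loc["g1", "y"]) is False


class TestSubsetExport:
    def test_export_matches_enumeration(self):
        sets = {"A": {1, 2, 3}, "B": {2, 3, 4}, "C": {3}}
        m = membership_from_sets([1, 2, 3, 4], sets)
        out = subset_export(m, {"A", "B"})
        assert list(out["id"]) == [2]

    def test_nonexistent_pattern_empty(self):
        m = membership_from_sets([1], {"A": {1}, "B": set()})
        assert len(subset_export(m, {"B"})) == 0

    def test_row_counts_equal_intersection_counts(self, rng):
        n, k = 80, 4
        sets = {
            f"S{i}": set(rng.choice(n, size=20, replace=False)) for i in range(k)
        }
        m = membership_from_sets(range(n), sets)
        res = exclusive_intersections(m)
        for key, count in res.counts.items():
            assert len(subset_export(m, key)) == count

    def test_annotations_joined(self):
        m = membership_from_sets(["g1", "g2"], {"A": {"g1"}, "B": set()})
        ann = pd.DataFrame({"id": ["g1", "g2"], "desc": ["x", "y"]})
        out = subset_export(m, {"A"}, annotations=ann)
        assert out.loc[0, "desc"] == "x"
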