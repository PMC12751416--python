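"""Occupancy table, Bray-Curtis contribution curve, elbow, core selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import distance

from bacfilter.core import (
    bc_contribution_curve,
    bray_curtis_similarity,
    compare_cores,
    find_elbow,
    occupancy_table,
    select_core,
)
from bacfilter.io import CountMatrix, rarefy


def _meta(samples, days, reps):
    return pd.DataFrame(
        {
            "compartment": "filter",
            "day": days,
            "depth_cm": 0.0,
            "replicate": reps,
            "size_fraction": "none",
        },
        index=samples,
    )


class TestOccupancyTable:
    def test_ubiquitous_taxon_scores_one(self):
        cm = CountMatrix(
            pd.DataFrame({"a": [3], "b": [1], "c": [9], "d": [2]}, index=["t"])
        )
        meta = _meta(list("abcd"), [1, 1, 2, 2], [1, 2, 1, 2])
        occ = occupancy_table(cm, meta, "day")
        assert occ.loc["t", ["occupancy", "time_specific_occupancy",
                            "replication_consistency", "composite_index"]].eq(1.0).all()

    def test_absent_taxon_scores_zero(self):
        cm = CountMatrix(pd.DataFrame({"a": [0], "b": [0]}, index=["t"]))
        meta = _meta(["a", "b"], [1, 2], [1, 1])
        occ = occupancy_table(cm, meta, "day")
        assert occ.loc["t"].drop("mean_rel").eq(0.0).all()

    def test_half_time_groups_hand_enumeration(self):
        # detected in all samples of day 1, absent on day 2
        cm = CountMatrix(
            pd.DataFrame({"a": [4], "b": [2], "c": [0], "d": [0]}, index=["t"])
        )
        meta = _meta(list("abcd"), [1, 1, 2, 2], [1, 2, 1, 2])
        occ = occupancy_table(cm, meta, "day")
        assert occ.loc["t", "time_specific_occupancy"] == pytest.approx(0.5)
        assert occ.loc["t", "replication_consistency"] == pytest.approx(0.5)
        assert occ.loc["t", "composite_index"] == pytest.approx(0.5)

    def test_missing_grouping_field_rejected(self, toy_counts):
        meta = _meta(["s1", "s2"], [1, 2], [1, 1])
        with pytest.raises(KeyError, match="epoch"):
            occupancy_table(toy_counts, meta, "epoch")


class TestBrayCurtis:
    def test_identical_vectors(self):
        assert bray_curtis_similarity([3, 1, 2], [3, 1, 2]) == 1.0

    def test_hand_case(self):
        assert bray_curtis_similarity([3, 1], [1, 3]) == pytest.approx(0.5)

    def test_disjoint_supports(self):
        assert bray_curtis_similarity([2, 0], [0, 5]) == 0.0

    def test_both_zero_convention(self):
        assert bray_curtis_similarity([0, 0], [0, 0]) == 1.0

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis_similarity([-1, 2], [1, 2])

    def test_matches_scipy_on_positive_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x, y = rng.integers(0, 50, 8), rng.integers(1, 50, 8)
            assert bray_curtis_similarity(x, y) == pytest.approx(
                1 - distance.braycurtis(x, y)
            )


def brute_force_curve(table: pd.DataFrame, ranked):
    """Independent double-loop computation of the contribution curve."""
    cols = list(table.columns)
    pairs = list(itertools.combinations(cols, 2))
    out = []
    for n in range(1, len(ranked) + 1):
        top = set(ranked[:n])
        sims = []
        for a, b in pairs:
            denom = table[a].sum() + table[b].sum()
            if denom == 0:
                sims.append(1.0)
                continue
            shared = sum(
                2 * min(table.loc[t, a], table.loc[t, b]) for t in ranked[:n]
            )
            sims.append(shared / denom)
        out.append(np.mean(sims))
    out = np.array(out)
    return out / out[-1]


class TestContributionCurve:
    def test_full_ranking_ends_at_one(self, toy_counts):
        curve = bc_contribution_curve(toy_counts, toy_counts.taxa)
        assert curve[-1] == pytest.approx(1.0)

    def test_single_dominant_taxon_saturates_at_one(self):
        cm = CountMatrix(
            pd.DataFrame({"a": [10, 0], "b": [7, 0]}, index=["t1", "t2"])
        )
        curve = bc_contribution_curve(cm, ["t1", "t2"])
        assert curve[0] == pytest.approx(1.0)

    def test_matches_brute_force_on_toy(self):
        rng = np.random.default_rng(9)
        table = pd.DataFrame(
            rng.integers(0, 30, (5, 3)),
            index=[f"t{i}" for i in range(5)],
            columns=list("abc"),
        )
        ranked = [f"t{i}" for i in rng.permutation(5)]
        curve = bc_contribution_curve(CountMatrix(table), ranked)
        assert np.allclose(curve, brute_force_curve(table, ranked), atol=1e-12)

    def test_non_decreasing(self, filter_counts):
        rel = filter_counts.relative_abundance()
        ranked = rel.mean(axis=1).sort_values(ascending=False).index.tolist()
        curve = bc_contribution_curve(filter_counts, ranked)
        assert (np.diff(curve) >= -1e-12).all()
        assert curve[-1] == pytest.approx(1.0)

    def test_empty_ranking_rejected(self, toy_counts):
        with pytest.raises(ValueError, match="empty"):
            bc_contribution_curve(toy_counts, [])


class TestElbow:
    def test_perfect_knee(self):
        assert find_elbow([0.0, 1.0, 1.0, 1.0, 1.0]) == 2

    def test_linear_curve_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert find_elbow(np.linspace(0, 1, 10)) == 1

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            find_elbow([0.0, 1.0])

    def test_chord_matches_exhaustive_search_on_random_concave_curves(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            n = int(rng.integers(5, 60))
            gains = np.sort(rng.random(n))[::-1]
            y = np.cumsum(gains)
            y = y / y[-1]
            x = np.arange(1, n + 1, dtype=float)
            dx, dy = x[-1] - x[0], y[-1] - y[0]
            dist_ = np.abs(dy * (x - x[0]) - dx * (y - y[0])) / np.hypot(dx, dy)
            assert find_elbow(y) == int(np.argmax(dist_)) + 1

    def test_last_gain_method(self):
        curve = [0.0, 0.5, 0.8, 0.95, 0.96, 0.97, 1.0]
        assert find_elbow(curve, method="last-gain", gain_fraction=0.1) == 4


class TestSelectCore:
    def test_invariant_to_sample_permutation(self, filter_counts, experiment):
        rare = rarefy(filter_counts, seed=1)
        meta = experiment.meta.loc[rare.samples]
        sel_a = select_core(rare, meta)
        shuffled = rare.subset_samples(list(reversed(rare.samples)))
        sel_b = select_core(shuffled, meta)
        assert sel_a.ranked == sel_b.ranked
        assert sel_a.elbow_index == sel_b.elbow_index
        assert sel_a.core_set == sel_b.core_set

    def test_engineered_high_occupancy_taxa_recovered(self, experiment):
        meta = experiment.meta
        top_ids = meta.index[(meta["compartment"] == "filter") & (meta["depth_cm"] < 15)]
        cm = experiment.counts.subset_samples(
            [s for s in experiment.counts.samples if s in top_ids]
        )
        cm = rarefy(cm, seed=7)
        sel = select_core(cm, meta.loc[cm.samples])
        engineered = set(experiment.truth["engineered_core"])
        recall = len(engineered & set(sel.core_set)) / len(engineered)
        assert recall >= 0.9

    def test_identical_taxa_degenerate_warning(self):
        cm = CountMatrix(
            pd.DataFrame(
                {"a": [5, 5, 5], "b": [5, 5, 5]}, index=["t1", "t2", "t3"]
            )
        )
        meta = _meta(["a", "b"], [1, 2], [1, 1])
        with pytest.warns(UserWarning):
            sel = select_core(cm, meta)
        assert sel.elbow_index >= 1


class TestCompareCores:
    def test_identical_sets(self):
        out = compare_cores({"a", "b"}, {"a", "b"})
        assert out["n_shared"] == 2 and not out["only_a"] and not out["only_b"]

    def test_disjoint_sets(self):
        assert compare_cores({"a"}, {"b"})["n_shared"] == 0

    def test_planted_overlap_recovered(self):
        shared = [f"s{i}" for i in range(119)]
        core_a = shared + [f"a{i}" for i in range(383 - 119)]
        core_b = shared + [f"b{i}" for i in range(302 - 119)]
        out = compare_cores(core_a, core_b)
        assert out["n_shared"] == 119
        assert out["n_only_a"] == 383 - 119
        assert out["n_only_b"] == 302 - 119
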