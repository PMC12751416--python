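"""Dominant/rare partition, richness, change metrics, depth stratification."""

import numpy as np
import pandas as pd
import pytest

from bacfilter.io import BedProfile, DEFAULT_BED, rarefy
from bacfilter.partition import (
    PartitionConfig,
    depth_stratification,
    fold_change,
    group_dynamics,
    partition_taxa,
    percent_change,
    richness,
)
from bacfilter.quantitation import absolute_abundance


class TestPartitionTaxa:
    def test_top_n_counting(self):
        rng = np.random.default_rng(0)
        rel = pd.DataFrame(
            rng.dirichlet(np.arange(1, 26), size=4).T,
            index=[f"t{i}" for i in range(25)],
        )
        part = partition_taxa(rel, PartitionConfig(top_n=20))
        assert len(part.dominant) == 20
        assert len(part.rare) == 5
        ranks = part.table["rank"]
        assert ranks[part.table["group"] == "dominant"].max() < ranks[
            part.table["group"] == "rare"
        ].min()

    def test_equal_abundances_tie_broken_lexicographically(self):
        rel = pd.DataFrame(
            np.full((4, 3), 0.25), index=["d", "b", "a", "c"], columns=list("xyz")
        )
        with pytest.warns(UserWarning, match="tie"):
            part = partition_taxa(rel, PartitionConfig(top_n=2))
        assert part.dominant == ["a", "b"]

    def test_top_n_exceeding_taxa_rejected(self):
        rel = pd.DataFrame({"s": [0.6, 0.4]}, index=["a", "b"])
        with pytest.raises(ValueError, match="top_n"):
            partition_taxa(rel, PartitionConfig(top_n=5))

    def test_invariant_to_sample_order(self):
        rng = np.random.default_rng(1)
        rel = pd.DataFrame(
            rng.dirichlet(np.ones(30), size=6).T, index=[f"t{i}" for i in range(30)]
        )
        a = partition_taxa(rel, PartitionConfig(top_n=10))
        b = partition_taxa(rel[rel.columns[::-1]], PartitionConfig(top_n=10))
        assert a.dominant == b.dominant

    def test_designed_abundant_taxa_recovered(self, experiment, filter_counts):
        rel = filter_counts.relative_abundance()
        part = partition_taxa(rel, PartitionConfig(top_n=20))
        designed = set(
            experiment.truth["taxa"].index[experiment.truth["taxa"]["role"] == "abundant"]
        )
        agreement = len(designed & set(part.dominant)) / len(designed)
        assert agreement >= 0.95


class TestRichness:
    def test_counts_nonzero_taxa(self, toy_counts):
        r = richness(toy_counts)
        assert r["s1"] == 2 and r["s2"] == 2

    def test_all_zero_column_is_zero(self):
        from bacfilter.io import CountMatrix

        cm = CountMatrix(pd.DataFrame({"s": [0, 0]}, index=["a", "b"]))
        assert richness(cm)["s"] == 0

    def test_rarefaction_never_increases_richness(self, filter_counts):
        rare = rarefy(filter_counts, seed=5)
        assert (richness(rare) <= richness(filter_counts)).all()


class TestChangeMetrics:
    @pytest.mark.parametrize(
        "start,end,expected",
        [
            (2.0e10, 8.4e10, 4.2),
            (8.7e8, 2.3e9, 2.64),
            (1.0, 1.0, 1.0),
        ],
    )
    def test_fold_change_reference_values(self, start, end, expected):
        assert fold_change(start, end) == pytest.approx(expected, rel=5e-3)

    @pytest.mark.parametrize(
        "start,end,expected",
        [
            (6.98e9, 6.24e10, 794.0),
            (3.27e10, 7.11e10, 117.0),
            (1.04e11, 7.79e10, -25.0),
        ],
    )
    def test_percent_change_reference_values(self, start, end, expected):
        assert percent_change(start, end) == pytest.approx(expected, rel=5e-3)

    def test_fold_and_percent_consistent(self):
        assert fold_change(3.0, 7.5) == pytest.approx(1 + percent_change(3.0, 7.5) / 100)

    def test_non_positive_start_rejected(self):
        with pytest.raises(ValueError):
            fold_change(0.0, 1.0)


class TestDepthStratification:
    def _meta(self, profile):
        rows = []
        for i, top in enumerate(profile.top_cm):
            rows.append(
                {
                    "sample_id": f"s{i}",
                    "compartment": "filter",
                    "day": 162,
                    "depth_cm": float(top),
                    "replicate": 1,
                    "size_fraction": "none",
                }
            )
        return pd.DataFrame(rows).set_index("sample_id")

    def test_all_biomass_in_top_section(self):
        profile = BedProfile(("top", "bot"), (0.0, 15.0), (15.0, 90.0), (10.0, 10.0))
        meta = self._meta(profile)
        totals = pd.Series({"s0": 5e10, "s1": 0.0})
        out = depth_stratification(totals, meta, profile, cutoff_cm=15.0)
        assert out.loc[162, "fraction_above_cutoff"] == pytest.approx(1.0)

    def test_equal_mass_nine_to_one(self):
        profile = BedProfile(("top", "bot"), (0.0, 15.0), (15.0, 90.0), (20.0, 20.0))
        meta = self._meta(profile)
        out = depth_stratification(
            pd.Series({"s0": 9e9, "s1": 1e9}), meta, profile, cutoff_cm=15.0
        )
        assert out.loc[162, "fraction_above_cutoff"] == pytest.approx(0.9)

    def test_reference_top_bottom_ratio(self):
        out = depth_stratification(
            pd.Series(
                {"s0": 8.4e10, "s1": 3e10, "s2": 2e10, "s3": 1e10, "s4": 2.3e9}
            ),
            self._meta(DEFAULT_BED),
            DEFAULT_BED,
            cutoff_cm=15.0,
        )
        assert out.loc[162, "top_bottom_ratio"] == pytest.approx(36.5, rel=2e-3)

    def test_cutoff_off_boundary_rejected(self):
        with pytest.raises(ValueError, match="boundary"):
            depth_stratification(
                pd.Series({"s0": 1.0}), self._meta(DEFAULT_BED), DEFAULT_BED, cutoff_cm=10.0
            )

    def test_synthetic_share_near_target(self, experiment, filter_counts):
        out = depth_stratification(
            experiment.qpcr.reindex(filter_counts.samples),
            experiment.meta,
            experiment.bed,
            cutoff_cm=15.0,
        )
        target = experiment.truth["top_biomass_fraction_target"]
        assert np.allclose(out["fraction_above_cutoff"], target, atol=0.05)


class TestGroupDynamics:
    def test_two_taxon_hand_oracle(self):
        profile = BedProfile(("top",), (0.0,), (15.0,), (10.0,))
        meta = pd.DataFrame(
            {
                "compartment": ["filter", "filter"],
                "day": [34, 62],
                "depth_cm": [0.0, 0.0],
                "replicate": [1, 1],
                "size_fraction": ["none", "none"],
            },
            index=["sA", "sB"],
        )
        absolute = pd.DataFrame(
            {"sA": [6.0e9, 4.0e9], "sB": [9.0e9, 12.0e9]}, index=["dom", "rar"]
        )
        rel = absolute / absolute.sum(axis=0)
        part = partition_taxa(rel, PartitionConfig(top_n=1))
        out = group_dynamics(absolute, part, meta, profile)
        totals = out["totals"]
        assert totals.loc[34, "dominant"] == pytest.approx(6.0e10)  # x10 g bed mass
        assert totals.loc[62, "rare"] == pytest.approx(1.2e11)
        row = out["changes"].query("group == 'dominant' and from_day == 34").iloc[0]
        assert row["fold_change"] == pytest.approx(1.5)
        assert row["percent_change"] == pytest.approx(50.0)

    def test_conservation_of_group_totals(self, experiment, filter_counts):
        rel = filter_counts.relative_abundance()
        absolute = absolute_abundance(rel, experiment.qpcr)
        part = partition_taxa(rel, PartitionConfig(top_n=20))
        dom = absolute.loc[part.dominant].sum(axis=0)
        rare = absolute.loc[part.rare].sum(axis=0)
        assert np.allclose(dom + rare, experiment.qpcr.reindex(absolute.columns), rtol=1e-12)

    def test_truth_stability_and_rare_growth(self, experiment, filter_counts):
        rel = filter_counts.relative_abundance()
        absolute = absolute_abundance(rel, experiment.qpcr)
        part = partition_taxa(rel, PartitionConfig(top_n=20))
        out = group_dynamics(absolute, part, experiment.meta, experiment.bed)
        totals = out["totals"]
        assert totals["rare"].is_monotonic_increasing
        cv = totals["dominant"].std(ddof=0) / totals["dominant"].mean()
        assert cv <= 0.10  # stable by design; only measurement noise remains
        # per-taxon bed totals: averaged over taxa, stability within the design CV
        meta = experiment.meta.loc[absolute.columns]
        sect = meta["depth_cm"].map(experiment.bed.section_for_depth)
        mass = pd.Series(experiment.bed.mass_g, index=experiment.bed.labels)
        cvs = []
        for taxon in part.dominant:
            df = pd.DataFrame({"day": meta["day"], "sect": sect, "v": absolute.loc[taxon]})
            dens = df.groupby(["day", "sect"])["v"].mean().unstack()
            tot = (dens * mass).sum(axis=1)
            cvs.append(tot.std(ddof=0) / tot.mean())
        assert np.mean(cvs) <= 0.10
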