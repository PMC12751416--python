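"""Dominant/rare partitioning, richness, depth stratification and dynamics.

Taxa are ranked by unweighted mean relative abundance across all samples;
the top ``top_n`` (default 20) are the dominant group and the rest rare.
The alternative threshold definition (mean relative abundance >= 0.5%) is
tracked as a diagnostic: a warning is emitted when the two rules disagree
about membership. Group totals are mass-weighted bed totals by default
(per-gram densities are available via ``per_gram=True``), and the
fold-change / percent-change helpers are the exact ratios the rendered
report later rounds to the published precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import BedProfile, CountMatrix

__all__ = [
    "PartitionConfig",
    "TaxonPartition",
    "partition_taxa",
    "richness",
    "fold_change",
    "percent_change",
    "depth_stratification",
    "group_dynamics",
]


@dataclass(frozen=True)
class PartitionConfig:
    top_n: int = 20
    mean_rel_threshold: float = 0.005

    def __post_init__(self):
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if not 0 < self.mean_rel_threshold < 1:
            raise ValueError("mean_rel_threshold must be in (0, 1)")


@dataclass(frozen=True)
class TaxonPartition:
    """Ranked taxa with dominant/rare labels.

    ``table`` is indexed by taxon id with columns ``mean_rel`` (unweighted
    mean relative abundance over samples), ``rank`` (1 = most abundant) and
    ``group`` ('dominant' or 'rare').
    """

    table: pd.DataFrame
    config: PartitionConfig = field(default_factory=PartitionConfig)

    @property
    def dominant(self) -> list[str]:
        return self.table.index[self.table["group"] == "dominant"].tolist()

    @property
    def rare(self) -> list[str]:
        return self.table.index[self.table["group"] == "rare"].tolist()


def partition_taxa(rel: pd.DataFrame, cfg: PartitionConfig | None = None) -> TaxonPartition:
    """Rank taxa by mean relative abundance; label the top ``top_n`` dominant.

    Ties are broken deterministically by lexicographic taxon id (with a
    warning when a tie straddles the cut). A consistency warning is also
    emitted when the top-n rule and the mean-abundance threshold disagree.
    """
    cfg = cfg or PartitionConfig()
    if rel.empty:
        raise ValueError("empty relative-abundance matrix")
    if cfg.top_n > rel.shape[0]:
        raise ValueError(f"top_n={cfg.top_n} exceeds the {rel.shape[0]} available taxa")
    mean_rel = rel.mean(axis=1)
    order = (
        pd.DataFrame({"mean_rel": mean_rel, "taxon": mean_rel.index.astype(str)})
        .sort_values(["mean_rel", "taxon"], ascending=[False, True])
        .index
    )
    ranked = mean_rel.loc[order]
    if ranked.duplicated(keep=False).any():
        cut_val = ranked.iloc[cfg.top_n - 1]
        n_at_cut = int((ranked == cut_val).sum())
        if n_at_cut > 1:
            warnings.warn(
                "abundance tie at the dominant/rare cut; broken by taxon id"
            )
    group = np.where(np.arange(len(ranked)) < cfg.top_n, "dominant", "rare")
    table = pd.DataFrame(
        {"mean_rel": ranked, "rank": np.arange(1, len(ranked) + 1), "group": group}
    )
    # diagnostic: top-n rule vs >= threshold rule
    by_threshold = set(ranked.index[ranked >= cfg.mean_rel_threshold])
    by_rank = set(ranked.index[: cfg.top_n])
    if by_threshold != by_rank:
        warnings.warn(
            f"top-{cfg.top_n} rule and mean>={cfg.mean_rel_threshold:g} rule disagree: "
            f"{len(by_rank - by_threshold)} ranked-in below threshold, "
            f"{len(by_threshold - by_rank)} above threshold ranked out"
        )
    return TaxonPartition(table=table, config=cfg)


def richness(counts: CountMatrix) -> pd.Series:
    """Observed richness: taxa with at least one read, per sample."""
    return (counts.counts >= 1).sum(axis=0).rename("richness")


def fold_change(start: float, end: float) -> float:
    """Exact ratio ``end / start`` (start must be positive)."""
    if not start > 0:
        raise ValueError("fold change undefined for non-positive start value")
    return float(end) / float(start)


def percent_change(start: float, end: float) -> float:
    """Signed percent change ``(end/start - 1) * 100``."""
    return (fold_change(start, end) - 1.0) * 100.0


def depth_stratification(
    totals: pd.Series,
    meta: pd.DataFrame,
    profile: BedProfile,
    cutoff_cm: float = 15.0,
) -> pd.DataFrame:
    """Biomass share above ``cutoff_cm`` and top:bottom density ratio, per day.

    ``totals`` maps filter sample id -> per-gram biomass (16S copies or
    cells per g wet GAC). Samples are averaged over replicates within each
    day x section, weighted by section wet mass, and the mass-weighted
    share of biomass in sections above the cutoff is reported together with
    the ratio of the top section's density to the bottom section's.
    """
    if cutoff_cm not in profile.bottom_cm:
        raise ValueError(
            f"cutoff {cutoff_cm} cm is not a section boundary {profile.bottom_cm}"
        )
    filt = meta[meta["compartment"] == "filter"]
    shared = totals.index.intersection(filt.index)
    if len(shared) == 0:
        raise ValueError("no filter samples with biomass totals")
    df = pd.DataFrame(
        {
            "day": filt.loc[shared, "day"],
            "section": filt.loc[shared, "depth_cm"].map(profile.section_for_depth),
            "density": totals.loc[shared].astype(float),
        }
    )
    dens = df.groupby(["day", "section"])["density"].mean().unstack("section")
    dens = dens.reindex(columns=list(profile.labels))
    if dens.isna().any().any():
        missing = dens.columns[dens.isna().any()].tolist()
        raise ValueError(f"missing density for bed section(s): {missing}")
    mass = np.asarray(profile.mass_g, dtype=float)
    above = np.asarray(profile.bottom_cm) <= cutoff_cm
    weighted = dens * mass
    frac = weighted.loc[:, above].sum(axis=1) / weighted.sum(axis=1)
    ratio = dens.iloc[:, 0] / dens.iloc[:, -1]
    return pd.DataFrame({"fraction_above_cutoff": frac, "top_bottom_ratio": ratio})


def group_dynamics(
    absolute: pd.DataFrame,
    partition: TaxonPartition,
    meta: pd.DataFrame,
    profile: BedProfile | None = None,
    per_gram: bool = False,
) -> dict:
    """Dominant vs rare group totals per timepoint, with pairwise changes.

    ``absolute`` is the taxa x samples absolute-abundance matrix (copies
    per g wet GAC). Per day, sample columns are averaged over replicates
    within each bed section and combined into a bed total weighted by
    section wet mass (``per_gram=True`` skips the mass weighting and
    reports the mean per-gram density instead). Returns a dict with a
    ``totals`` DataFrame (index day, columns dominant/rare/total) and a
    ``changes`` DataFrame of fold/percent changes between consecutive and
    first-vs-last timepoints.
    """
    filt = meta[meta["compartment"] == "filter"]
    shared = [s for s in absolute.columns if s in filt.index]
    if not shared:
        raise ValueError("no filter samples in the absolute-abundance matrix")
    sub = absolute[shared]
    dom = partition.dominant
    dom_tot = sub.loc[[t for t in dom if t in sub.index]].sum(axis=0)
    all_tot = sub.sum(axis=0)
    rare_tot = all_tot - dom_tot

    frames = {}
    for name, series in (("dominant", dom_tot), ("rare", rare_tot), ("total", all_tot)):
        df = pd.DataFrame(
            {
                "day": filt.loc[series.index, "day"],
                "value": series,
            }
        )
        if per_gram or profile is None:
            per_day = df.groupby("day")["value"].mean()
        else:
            df["section"] = filt.loc[series.index, "depth_cm"].map(
                profile.section_for_depth
            )
            dens = df.groupby(["day", "section"])["value"].mean().unstack("section")
            dens = dens.reindex(columns=list(profile.labels))
            mass = np.asarray(profile.mass_g, dtype=float)
            per_day = (dens * mass).sum(axis=1, min_count=1)
        frames[name] = per_day
    totals = pd.DataFrame(frames)
    if len(totals) < 2:
        raise ValueError("need at least two timepoints for group dynamics")

    days = totals.index.tolist()
    pairs = [(days[i], days[i + 1]) for i in range(len(days) - 1)]
    if (days[0], days[-1]) not in pairs:
        pairs.append((days[0], days[-1]))
    rows = []
    for a, b in pairs:
        for grp in ("dominant", "rare", "total"):
            start, end = totals.loc[a, grp], totals.loc[b, grp]
            if start > 0:
                fc, pc = fold_change(start, end), percent_change(start, end)
            else:
                fc = pc = np.nan
                warnings.warn(f"{grp} total is zero on day {a}; change undefined")
            rows.append(
                {"from_day": a, "to_day": b, "group": grp, "start": start,
                 "end": end, "fold_change": fc, "percent_change": pc}
            )
    return {"totals": totals, "changes": pd.DataFrame(rows)}
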