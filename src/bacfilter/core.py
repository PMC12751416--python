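"""Occupancy-abundance core-microbiome selection.

Taxa are ranked by a composite occupancy index (the mean of time-specific
occupancy and replication consistency), a Bray-Curtis contribution curve is
accumulated along the ranking, and the curve's elbow defines the core set.

The contribution curve measures, for each prefix of the ranking, how much
of the community's pairwise Bray-Curtis similarity structure the prefix
already captures: per sample pair, the shared abundance of the top-n taxa
``2 * sum_{i<=n} min(x_i, y_i)`` over the full-table denominator
``sum_i (x_i + y_i)``, averaged over pairs and normalised by the value at
the full ranking. The curve is therefore non-decreasing in n and ends at
exactly 1.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix

__all__ = [
    "CoreSelection",
    "occupancy_table",
    "bray_curtis_similarity",
    "bc_contribution_curve",
    "find_elbow",
    "select_core",
    "compare_cores",
]


def occupancy_table(
    counts: CountMatrix,
    meta: pd.DataFrame,
    grouping: str | list[str] = "day",
    detection_threshold: int = 1,
) -> pd.DataFrame:
    """Per-taxon occupancy statistics.

    Columns: ``occupancy`` (proportion of samples with detection),
    ``mean_rel`` (mean relative abundance), ``time_specific_occupancy``
    (mean over groups of within-group occupancy), ``replication_consistency``
    (proportion of groups where the taxon is detected in every sample of
    the group) and ``composite_index`` (mean of the last two).
    """
    if isinstance(grouping, str):
        grouping = [grouping]
    for g in grouping:
        if g not in meta.columns:
            raise KeyError(f"grouping field {g!r} not in metadata")
    # canonical sample order so statistics (and float summation) are
    # invariant to the input column ordering
    samples = sorted(s for s in counts.samples if s in meta.index)
    if not samples:
        raise ValueError("no overlap between count matrix samples and metadata")
    sub = counts.subset_samples(samples)
    detected = sub.counts >= detection_threshold
    rel = sub.relative_abundance()

    groups = meta.loc[samples, grouping].astype(str).agg("|".join, axis=1)
    per_group_occ = []
    per_group_all = []
    for _, members in groups.groupby(groups).groups.items():
        d = detected[list(members)]
        per_group_occ.append(d.mean(axis=1))
        per_group_all.append(d.all(axis=1).astype(float))
    tso = pd.concat(per_group_occ, axis=1).mean(axis=1)
    rc = pd.concat(per_group_all, axis=1).mean(axis=1)
    return pd.DataFrame(
        {
            "occupancy": detected.mean(axis=1),
            "mean_rel": rel.mean(axis=1),
            "time_specific_occupancy": tso,
            "replication_consistency": rc,
            "composite_index": (tso + rc) / 2.0,
        }
    )


def bray_curtis_similarity(x, y) -> float:
    """``1 - sum|x-y| / sum(x+y)`` on non-negative abundance vectors.

    A pair of all-zero vectors is defined to have similarity 1: restricted
    tables can zero out whole samples, and penalising shared absence would
    distort the contribution curve.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("Bray-Curtis requires non-negative abundances")
    denom = float((x + y).sum())
    if denom == 0:
        return 1.0
    return 1.0 - float(np.abs(x - y).sum()) / denom


def bc_contribution_curve(counts: CountMatrix | pd.DataFrame, ranked: list[str]) -> np.ndarray:
    """Per-n similarity contribution of the top-n ranked taxa (ends at 1)."""
    table = counts.counts if isinstance(counts, CountMatrix) else counts
    if len(ranked) == 0:
        raise ValueError("empty ranking")
    missing = [t for t in ranked if t not in table.index]
    if missing:
        raise KeyError(f"ranked taxa missing from the table: {missing}")
    X = table.loc[list(ranked)].to_numpy(float)  # ranked taxa x samples
    n_samples = X.shape[1]
    pairs = list(itertools.combinations(range(n_samples), 2))
    if not pairs:
        raise ValueError("need at least two samples")
    full_col = table.to_numpy(float)
    num = np.empty((len(pairs), X.shape[0]))  # per-pair per-rank 2*min
    denom = np.empty(len(pairs))
    for k, (i, j) in enumerate(pairs):
        num[k] = 2.0 * np.minimum(X[:, i], X[:, j])
        denom[k] = full_col[:, i].sum() + full_col[:, j].sum()
    cum = np.cumsum(num, axis=1)  # per-pair shared abundance of top-n
    sims = np.empty_like(cum)
    zero = denom == 0
    sims[~zero] = cum[~zero] / denom[~zero, None]
    sims[zero] = 1.0  # both-zero pair convention
    mean_sim = sims.mean(axis=0)
    full = mean_sim[-1]
    if full == 0:
        warnings.warn("no shared abundance among ranked taxa; flat curve")
        return np.ones_like(mean_sim)
    return mean_sim / full


def find_elbow(curve, method: str = "chord", gain_fraction: float = 0.02) -> int:
    """Elbow of a saturating curve; returns n* (1-based rank count).

    ``chord``: the point of maximum perpendicular distance to the chord
    joining the first and last point (ties -> smallest n; a degenerate flat
    or linear curve returns 1 with a warning). ``last-gain``: the largest n
    whose marginal gain is at least ``gain_fraction`` of the curve's total
    range.
    """
    y = np.asarray(curve, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 curve points to locate an elbow")
    x = np.arange(1, n + 1, dtype=float)
    if method == "chord":
        dx, dy = x[-1] - x[0], y[-1] - y[0]
        norm = np.hypot(dx, dy)
        dist = np.abs(dy * (x - x[0]) - dx * (y - y[0])) / norm
        if np.allclose(dist, 0):
            warnings.warn("degenerate (linear or flat) contribution curve; elbow set to 1")
            return 1
        return int(np.argmax(dist)) + 1
    if method == "last-gain":
        total = y[-1] - y[0]
        if total <= 0:
            warnings.warn("degenerate flat curve; elbow set to 1")
            return 1
        gains = np.diff(y)
        ok = np.where(gains >= gain_fraction * total)[0]
        return int(ok[-1]) + 2 if len(ok) else 1
    raise ValueError(f"unknown elbow method {method!r}")


@dataclass(frozen=True)
class CoreSelection:
    """Result of the occupancy-abundance core selection."""

    ranked: list[str]
    bc_curve: np.ndarray
    elbow_index: int
    core_set: list[str]
    occupancy: pd.DataFrame
    method: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_ranked": len(self.ranked),
            "elbow_index": self.elbow_index,
            "core_set": list(self.core_set),
            "bc_curve": [float(v) for v in self.bc_curve],
            "method": dict(self.method),
        }


def select_core(
    counts: CountMatrix,
    meta: pd.DataFrame,
    grouping: str | list[str] = "day",
    detection_threshold: int = 1,
    elbow_method: str = "chord",
    gain_fraction: float = 0.02,
) -> CoreSelection:
    """occupancy table -> composite ranking -> contribution curve -> elbow.

    Ranking is by composite index, ties broken by mean relative abundance
    and then lexicographic taxon id, so the selection is invariant to
    sample and taxon ordering. Detection conventions assume the caller has
    already rarefied the table if desired.
    """
    occ = occupancy_table(counts, meta, grouping, detection_threshold)
    ranked = (
        occ.assign(_id=occ.index.astype(str))
        .sort_values(
            ["composite_index", "mean_rel", "_id"], ascending=[False, False, True]
        )
        .index.tolist()
    )
    samples = sorted(s for s in counts.samples if s in meta.index)
    curve = bc_contribution_curve(counts.subset_samples(samples), ranked)
    if occ["composite_index"].nunique() == 1:
        warnings.warn("all taxa have identical composite index; core is degenerate")
    n_star = find_elbow(curve, method=elbow_method, gain_fraction=gain_fraction)
    return CoreSelection(
        ranked=ranked,
        bc_curve=curve,
        elbow_index=n_star,
        core_set=ranked[:n_star],
        occupancy=occ,
        method={
            "elbow": elbow_method,
            "gain_fraction": gain_fraction,
            "detection_threshold": detection_threshold,
            "grouping": grouping,
        },
    )


def compare_cores(core_a, core_b) -> dict:
    """Set overlap between two core selections."""
    a, b = set(core_a), set(core_b)
    return {
        "shared": sorted(a & b),
        "only_a": sorted(a - b),
        "only_b": sorted(b - a),
        "n_shared": len(a & b),
        "n_only_a": len(a - b),
        "n_only_b": len(b - a),
    }
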