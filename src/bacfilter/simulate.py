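"""Synthetic biofilter experiments with the structure the analysis assumes.

The generator emulates a depth-stratified, time-resolved GAC biofilter
community sampled at a small number of takedown days, together with the
measurements the pipeline consumes: an ASV count table, sample metadata,
16S qPCR totals, ATP series, influent/effluent total cell counts and a bed
profile. Its statistical skeleton:

* a fixed source (influent) community of ``n_abundant`` high-abundance
  taxa, a few persistent mid-abundance taxa and a long tail of rare taxa;
* neutral assembly of the filter community from that source: per sample,
  rare-taxon presence follows the Sloan beta/binomial detection process at
  migration ``m``, optionally tilted by per-taxon detection-odds
  multipliers (>1 advantaged, <1 disadvantaged) for classifier testing;
* biomass that decays exponentially with bed depth, calibrated so a target
  share of total biomass sits above the 15 cm boundary;
* abundant taxa whose absolute abundance is stable across takedowns while
  the rare fraction's total grows, within a prescribed trajectory of total
  standing stocks;
* two biomass proxies (qPCR copies, ATP-derived cells) measured from the
  same true field with independent lognormal noise, so they correlate
  strongly by construction.

True standing stocks default to the magnitudes a lab-scale drinking-water
biofilter reaches over six months, and the influent/effluent cell counts
to a realistic surface-water step profile; the noise-free mass balance of
these defaults lands in the +1e8..-2e9 cells/day transformation-rate
regime. All randomness flows from one seed through named
``numpy.random.SeedSequence`` spawns, so sub-streams are independently
reproducible and the whole experiment is bit-identical given the seed.

The generator targets statistical structure only: no hydraulics,
adsorption or nutrient mechanics. The lognormal form of rare-taxon
within-sample noise and the exponential depth profile are stand-ins chosen
for plausibility, not mechanism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from scipy import optimize, special

from .io import (
    DEFAULT_BED,
    BedProfile,
    CountMatrix,
    FlowSpec,
    TCCSeries,
    parse_flow,
    validate_sample_metadata,
    write_atp,
    write_bed_profile,
    write_count_matrix,
    write_qpcr,
    write_sample_metadata,
    write_tcc,
)

__all__ = [
    "SimConfig",
    "Experiment",
    "generate_experiment",
    "generate_neutral_occupancy",
    "neutral_detection_prob",
    "write_experiment",
]


def _lognormal_factor(rng, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with coefficient of variation cv."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=size)


def neutral_detection_prob(p, m: float, N: int) -> np.ndarray:
    """P(count >= 1) under the Sloan beta/binomial detection process.

    Local abundance x ~ Beta(N*m*p, N*m*(1-p)), count ~ Binomial(N, x); the
    zero-count probability is the beta-binomial mass at zero,
    B(a, b+N)/B(a, b), evaluated in log space.
    """
    p = np.asarray(p, dtype=float)
    a = N * m * p
    b = N * m * (1.0 - p)
    with np.errstate(invalid="ignore"):
        log_p0 = special.betaln(a, b + N) - special.betaln(a, b)
    pi = 1.0 - np.exp(log_p0)
    return np.clip(np.where(p <= 0, 0.0, pi), 0.0, 1.0)


def _tilt_odds(pi: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Multiply detection odds by ``s``: pi' = s*pi / (1 - pi + s*pi)."""
    return s * pi / (1.0 - pi + s * pi)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic experiment.

    Defaults mirror the emulated system: four takedown days, a 90 cm bed in
    five sections, triplicate sampling, 20 abundant taxa over a rare tail,
    79% of biomass above 15 cm, migration 0.1 and ~20k reads per sample.
    """

    seed: int = 0
    takedown_days: tuple = (34, 62, 83, 162)
    stocks_cells: tuple = (5.3e10, 1.2e11, 1.307e11, 1.8e11)
    bed: BedProfile = field(default_factory=lambda: DEFAULT_BED)
    replicates: int = 3
    n_abundant: int = 20
    n_rare: int = 280
    n_persistent_rare: int = 10
    top_biomass_fraction: float = 0.79
    top_cutoff_cm: float = 15.0
    abundant_source_share: float = 0.55
    persistent_source_share: float = 0.04
    migration: float = 0.1
    n_reads: int = 20000
    n_advantaged: int = 20
    advantage: float = 8.0
    n_disadvantaged: int = 20
    disadvantage: float = 0.25
    abundant_fraction: float = 0.7
    abundant_stability_cv: float = 0.10
    rare_growth_rate: float | None = None
    rare_sample_cv: float = 0.3
    cv_qpcr: float = 0.10
    cv_atp: float = 0.12
    cv_tcc: float = 0.05
    copies_per_cell: float = 1.0
    influent_tcc: tuple = (1.5e6, 1.9e6)
    influent_step_day: float = 83.0
    effluent_tcc: float = 2.925e5
    tcc_interval_days: int = 7
    flow: str = "1 mL/min"
    water_sample_days: tuple = (7, 14, 21, 28, 34)

    def validate(self) -> None:
        if len(self.takedown_days) != len(self.stocks_cells):
            raise ValueError("takedown_days and stocks_cells must align")
        if len(self.takedown_days) < 2 or any(
            b <= a for a, b in zip(self.takedown_days, self.takedown_days[1:])
        ):
            raise ValueError("takedown_days must be >= 2 strictly increasing values")
        if not 0 < self.top_biomass_fraction < 1:
            raise ValueError("top_biomass_fraction must be in (0, 1)")
        mass = np.asarray(self.bed.mass_g)
        above = np.asarray(self.bed.bottom_cm) <= self.top_cutoff_cm
        if not above.any() or above.all():
            raise ValueError("top_cutoff_cm must split the bed sections")
        base_share = mass[above].sum() / mass.sum()
        if self.top_biomass_fraction <= base_share:
            raise ValueError(
                f"top_biomass_fraction {self.top_biomass_fraction} not above the "
                f"uniform-density share {base_share:.3f}; no decay profile can hit it"
            )
        if self.n_persistent_rare > self.n_rare:
            raise ValueError("n_persistent_rare cannot exceed n_rare")
        if not 0 < self.migration <= 1:
            raise ValueError("migration must be in (0, 1]")
        for name in ("advantage", "disadvantage"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} multiplier must be positive")
        if not 0 < self.abundant_fraction < 1:
            raise ValueError("abundant_fraction must be in (0, 1)")
        share_sum = self.abundant_source_share + self.persistent_source_share
        if not 0 < share_sum < 1:
            raise ValueError("source shares must leave room for the rare tail")
        if min(self.n_abundant, self.n_rare, self.replicates, self.n_reads) < 1:
            raise ValueError("counts must be >= 1")


@dataclass(frozen=True)
class Experiment:
    """Everything one synthetic run produces, plus the truth bundle."""

    counts: CountMatrix
    meta: pd.DataFrame
    qpcr: pd.Series
    atp: pd.Series
    tcc_influent: TCCSeries
    tcc_effluent: TCCSeries
    bed: BedProfile
    flow: FlowSpec
    truth: dict


def _depth_weights(cfg: SimConfig) -> np.ndarray:
    """Exponential-decay section weights hitting the top biomass share."""
    mid = cfg.bed.midpoints_cm
    mass = np.asarray(cfg.bed.mass_g)
    above = np.asarray(cfg.bed.bottom_cm) <= cfg.top_cutoff_cm

    def share(k):
        w = np.exp(-k * mid)
        return (mass[above] * w[above]).sum() / (mass * w).sum() - cfg.top_biomass_fraction

    k = optimize.brentq(share, 0.0, 5.0)
    return np.exp(-k * mid)


def _cap_and_redistribute(x: np.ndarray, cap: float, total: float) -> np.ndarray:
    """Scale ``x`` to ``total`` with no element above ``cap``."""
    if cap * len(x) < total:
        raise ValueError("cap too low to hold the requested total")
    x = x / x.sum() * total
    for _ in range(50):
        over = x > cap
        if not over.any():
            break
        excess = (x[over] - cap).sum()
        x[over] = cap
        room = ~over
        x[room] += excess * x[room] / x[room].sum()
    return np.minimum(x, cap)


def _source_community(cfg: SimConfig, rng) -> np.ndarray:
    """Source relative abundances: abundant head, persistent shelf, rare tail.

    The abundant group mixes a uniform floor with a lognormal spread so its
    weakest member keeps a guaranteed share; individual rare-tail taxa are
    capped at the persistent-taxon share so that, even once the rare
    fraction dominates total biomass late in the run, no single rare taxon
    overtakes the designed abundant group in mean relative abundance (real
    rare fractions spread their biomass over far more taxa than a compact
    simulation carries, so the cap stands in for that dilution).
    """
    ab_raw = np.sort(rng.lognormal(0.0, 0.8, cfg.n_abundant))[::-1]
    ab = 0.5 / cfg.n_abundant + 0.5 * ab_raw / ab_raw.sum()
    ab = ab / ab.sum() * cfg.abundant_source_share
    p_pers = cfg.persistent_source_share / cfg.n_persistent_rare
    pers = np.full(cfg.n_persistent_rare, p_pers)
    n_tail = cfg.n_rare - cfg.n_persistent_rare
    tail_total = 1.0 - cfg.abundant_source_share - cfg.persistent_source_share
    tail = _cap_and_redistribute(rng.lognormal(0.0, 1.5, n_tail), p_pers, tail_total)
    return np.concatenate([ab, pers, tail])


def generate_experiment(config: SimConfig) -> Experiment:
    """Deterministically generate one complete synthetic experiment."""
    cfg = config
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("source", "selection", "occupancy", "counts", "measure", "tcc", "water"),
            ss.spawn(7),
        )
    }

    n_taxa = cfg.n_abundant + cfg.n_rare
    taxa = [f"ASV_{i + 1}" for i in range(n_taxa)]
    roles = np.array(
        ["abundant"] * cfg.n_abundant
        + ["persistent_rare"] * cfg.n_persistent_rare
        + ["rare"] * (cfg.n_rare - cfg.n_persistent_rare)
    )
    p = _source_community(cfg, streams["source"])

    # --- selection design: odds multipliers on taxa in the informative range
    pi_neutral = neutral_detection_prob(p, cfg.migration, cfg.n_reads)
    mult = np.ones(n_taxa)
    tail_idx = np.where(roles == "rare")[0]
    # informative windows: outside them a 95% band at ~30 samples cannot
    # register the odds shift (closed-form binomial power calculation)
    adv_pool = tail_idx[(pi_neutral[tail_idx] >= 0.22) & (pi_neutral[tail_idx] <= 0.64)]
    dis_pool = tail_idx[(pi_neutral[tail_idx] >= 0.40) & (pi_neutral[tail_idx] <= 0.95)]
    rng_sel = streams["selection"]
    adv = rng_sel.choice(adv_pool, size=min(cfg.n_advantaged, len(adv_pool)), replace=False)
    dis_pool = np.setdiff1d(dis_pool, adv)
    dis = rng_sel.choice(dis_pool, size=min(cfg.n_disadvantaged, len(dis_pool)), replace=False)
    mult[adv] = cfg.advantage
    mult[dis] = cfg.disadvantage
    pi_tilted = _tilt_odds(pi_neutral, mult)

    # --- biomass skeleton
    w = _depth_weights(cfg)
    mass = np.asarray(cfg.bed.mass_g)
    mw = float((mass * w).sum())
    days = np.asarray(cfg.takedown_days, dtype=float)
    stocks = np.asarray(cfg.stocks_cells, dtype=float)
    ab_total = cfg.abundant_fraction * stocks[0]
    if cfg.rare_growth_rate is not None:
        rare0 = stocks[0] - ab_total
        rare_totals = rare0 * np.exp(cfg.rare_growth_rate * (days - days[0]))
        stocks = ab_total + rare_totals
    else:
        rare_totals = stocks - ab_total
    if (rare_totals <= 0).any():
        raise ValueError("stock trajectory leaves no room for the rare fraction")

    ab_mask = roles == "abundant"
    rare_mask = ~ab_mask
    ab_shares = p[ab_mask] / p[ab_mask].sum()
    rare_shares = p[rare_mask] / p[rare_mask].sum()

    rng_occ, rng_cnt, rng_meas = streams["occupancy"], streams["counts"], streams["measure"]
    records, count_cols = [], {}
    sample_truth = []
    for t_idx, day in enumerate(days.astype(int)):
        for f_idx, label in enumerate(cfg.bed.labels):
            for rep in range(1, cfg.replicates + 1):
                sid = f"F_d{day}_{label}cm_r{rep}"
                depth_factor = w[f_idx] / mw  # cells/g per unit total stock
                ab_dens = (
                    ab_shares
                    * ab_total
                    * depth_factor
                    * _lognormal_factor(rng_meas, cfg.abundant_stability_cv, ab_mask.sum())
                )
                present = rng_occ.random(rare_mask.sum()) < pi_tilted[rare_mask]
                rare_dens = (
                    rare_shares
                    * present
                    * _lognormal_factor(rng_meas, cfg.rare_sample_cv, rare_mask.sum())
                )
                tot = rare_dens.sum()
                if tot > 0:  # renormalise so the rare fraction carries its budget
                    rare_dens = rare_dens / tot * rare_totals[t_idx] * depth_factor
                dens = np.empty(n_taxa)
                dens[ab_mask] = ab_dens
                dens[rare_mask] = rare_dens
                true_cells = float(dens.sum())
                comp = dens / true_cells
                depth_reads = int(rng_cnt.poisson(cfg.n_reads))
                count_cols[sid] = rng_cnt.multinomial(depth_reads, comp)
                records.append(
                    {
                        "sample_id": sid,
                        "compartment": "filter",
                        "day": int(day),
                        "depth_cm": float(cfg.bed.top_cm[f_idx]),
                        "replicate": rep,
                        "size_fraction": "none",
                    }
                )
                sample_truth.append(
                    {
                        "sample_id": sid,
                        "true_cells_per_g": true_cells,
                        "true_copies_per_g": true_cells * cfg.copies_per_cell,
                        "seq_depth": depth_reads,
                    }
                )

    # --- influent water community samples (seeding community)
    rng_wat = streams["water"]
    for day in cfg.water_sample_days:
        for frac in ("glass_fibre_1.2um", "sterivex_0.22um"):
            sid = f"W_d{day}_{frac}"
            depth_reads = int(rng_wat.poisson(cfg.n_reads))
            count_cols[sid] = rng_wat.multinomial(depth_reads, p)
            records.append(
                {
                    "sample_id": sid,
                    "compartment": "influent",
                    "day": int(day),
                    "depth_cm": np.nan,
                    "replicate": 1,
                    "size_fraction": frac,
                }
            )
            sample_truth.append(
                {"sample_id": sid, "true_cells_per_g": np.nan,
                 "true_copies_per_g": np.nan, "seq_depth": depth_reads}
            )

    counts = CountMatrix(
        pd.DataFrame(count_cols, index=taxa, dtype=np.int64)
    )
    meta = validate_sample_metadata(
        pd.DataFrame(records).set_index("sample_id")
    )

    # --- measurements: qPCR copies/g and ATP g/g from the same true field
    st = pd.DataFrame(sample_truth).set_index("sample_id")
    filter_ids = meta.index[meta["compartment"] == "filter"]
    true_cells = st.loc[filter_ids, "true_cells_per_g"].to_numpy()
    qpcr_vals = (
        true_cells
        * cfg.copies_per_cell
        * _lognormal_factor(rng_meas, cfg.cv_qpcr, len(filter_ids))
    )
    atp_vals = (
        true_cells * 8.9e-17 * _lognormal_factor(rng_meas, cfg.cv_atp, len(filter_ids))
    )
    qpcr = pd.Series(qpcr_vals, index=filter_ids, name="copies")
    atp = pd.Series(atp_vals, index=filter_ids, name="atp_g_per_g")

    # --- TCC series and flow
    rng_tcc = streams["tcc"]
    grid = np.arange(0, days[-1] + 1, cfg.tcc_interval_days, dtype=float)
    if grid[-1] < days[-1]:
        grid = np.append(grid, days[-1])
    in_true = np.where(grid < cfg.influent_step_day, cfg.influent_tcc[0], cfg.influent_tcc[1])
    eff_true = np.full_like(grid, cfg.effluent_tcc)
    tcc_in = TCCSeries(
        "influent", grid, in_true * _lognormal_factor(rng_tcc, cfg.cv_tcc, len(grid))
    )
    tcc_eff = TCCSeries(
        "effluent", grid, eff_true * _lognormal_factor(rng_tcc, cfg.cv_tcc, len(grid))
    )
    flow = parse_flow(cfg.flow)

    # --- truth bundle (noise-free bookkeeping)
    q_day = flow.q_ml_per_day
    phases = []
    bounds = [0.0, *days]
    stocks_b = [0.0, *stocks]
    for i in range(len(bounds) - 1):
        t0, t1 = bounds[i], bounds[i + 1]
        # noise-free step integral of the influent/effluent difference
        seg = np.clip(np.minimum(cfg.influent_step_day, t1) - t0, 0, None)
        lo_part = seg * (cfg.influent_tcc[0] - cfg.effluent_tcc)
        hi_part = max(t1 - max(t0, cfg.influent_step_day), 0) * (
            cfg.influent_tcc[1] - cfg.effluent_tcc
        )
        net = (lo_part + hi_part) * q_day
        delta = (stocks_b[i + 1] - stocks_b[i]) - net
        rate = delta / (t1 - t0)
        phases.append(
            {
                "t_start": t0,
                "t_end": t1,
                "net_input_true": net,
                "delta_true": delta,
                "rate_true": rate,
                "phase": "growth" if rate > 0 else ("decay" if rate < 0 else "balanced"),
            }
        )

    selection = np.where(mult > 1, "advantaged", np.where(mult < 1, "disadvantaged", "neutral"))
    taxa_truth = pd.DataFrame(
        {
            "taxon": taxa,
            "role": roles,
            "selection": selection,
            "multiplier": mult,
            "source_p": p,
            "neutral_detection_prob": pi_neutral,
            "tilted_detection_prob": pi_tilted,
        }
    ).set_index("taxon")
    truth = {
        "taxa": taxa_truth,
        "engineered_core": [t for t, r in zip(taxa, roles) if r != "rare"],
        "sample_truth": st,
        "stocks_true": dict(zip((int(d) for d in days), stocks.tolist())),
        "phases": phases,
        "depth_weights": w.tolist(),
        "top_biomass_fraction_target": cfg.top_biomass_fraction,
        "config": asdict(replace(cfg, bed=None)) | {"bed_labels": list(cfg.bed.labels)},
    }
    return Experiment(
        counts=counts,
        meta=meta,
        qpcr=qpcr,
        atp=atp,
        tcc_influent=tcc_in,
        tcc_effluent=tcc_eff,
        bed=cfg.bed,
        flow=flow,
        truth=truth,
    )


def generate_neutral_occupancy(
    p,
    m: float,
    N: int,
    n_samples: int,
    seed: int = 0,
    selection_multipliers=None,
) -> CountMatrix:
    """Taxon counts under the Sloan detection process, for recovery tests.

    Per sample and taxon, a local relative abundance is drawn from
    Beta(N*m*p, N*m*(1-p)) and thinned to ``N`` reads with a binomial;
    detection is count >= 1. Optional per-taxon detection-odds multipliers
    tilt occupancy away from neutrality without changing the conditional
    abundance: the tilted detection probability is ``s*pi/(1-pi+s*pi)``,
    realised by flipping a matching fraction of detections/non-detections.
    """
    p = np.asarray(p, dtype=float)
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("source abundances p must lie in (0, 1)")
    if p.sum() > 1 + 1e-9:
        raise ValueError("source abundances must sum to at most 1")
    if not 0 < m <= 1:
        raise ValueError(f"migration m must be in (0, 1], got {m}")
    if N < 10:
        raise ValueError("community size N must be >= 10")
    rng = np.random.default_rng(seed)
    a = N * m * p
    b = N * m * (1.0 - p)
    x = rng.beta(a[:, None], b[:, None], size=(len(p), n_samples))
    counts = rng.binomial(N, x)

    if selection_multipliers is not None:
        s = np.asarray(selection_multipliers, dtype=float)
        if s.shape != p.shape:
            raise ValueError("selection_multipliers must match p in length")
        if (s <= 0).any():
            raise ValueError("selection multipliers must be positive")
        pi = neutral_detection_prob(p, m, N)
        pi_t = _tilt_odds(pi, s)
        u = rng.random(counts.shape)
        for i in range(len(p)):
            if s[i] > 1 and pi[i] < 1:
                flip = (counts[i] == 0) & (u[i] < (pi_t[i] - pi[i]) / (1 - pi[i]))
                counts[i, flip] = 1
            elif s[i] < 1 and pi[i] > 0:
                drop = (counts[i] >= 1) & (u[i] < (pi[i] - pi_t[i]) / pi[i])
                counts[i, drop] = 0

    df = pd.DataFrame(
        counts,
        index=[f"taxon_{i}" for i in range(len(p))],
        columns=[f"sample_{j}" for j in range(n_samples)],
        dtype=np.int64,
    )
    return CountMatrix(df)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.reset_index().to_dict(orient="list"))
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def write_experiment(exp: Experiment, outdir) -> dict:
    """Write all input files in the formats the loaders read, plus truth.json.

    Returns a mapping of artefact name -> path.
    """
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "asv_counts.tsv",
        "metadata": out / "sample_metadata.csv",
        "qpcr": out / "qpcr.csv",
        "atp": out / "atp.csv",
        "tcc_influent": out / "tcc_influent.csv",
        "tcc_effluent": out / "tcc_effluent.csv",
        "bed": out / "bed_profile.csv",
        "truth": out / "truth.json",
    }
    write_count_matrix(exp.counts, paths["counts"])
    write_sample_metadata(exp.meta, paths["metadata"])
    write_qpcr(exp.qpcr, paths["qpcr"])
    write_atp(exp.atp, paths["atp"])
    write_tcc(exp.tcc_influent, paths["tcc_influent"])
    write_tcc(exp.tcc_effluent, paths["tcc_effluent"])
    write_bed_profile(exp.bed, paths["bed"])
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(_jsonable(exp.truth), fh, indent=1)
    return {k: str(v) for k, v in paths.items()}
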