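"""End-to-end orchestration: inputs -> all analyses -> results bundle.

``run_pipeline`` executes the full analysis in stage order — quantitation,
mass balance, dominant/rare partitioning and dynamics, core-microbiome
selection, neutral-model classification — on either a synthetic experiment
(default) or user-supplied files, and returns a JSON-serialisable bundle
together with a manifest recording the configuration snapshot, seeds,
input digests and per-stage status. ``render_report`` turns a bundle into
a human-readable markdown report; stored values keep full precision and
only the report rounds.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import select_core
from .io import (
    CountMatrix,
    parse_flow,
    rarefy,
    read_atp,
    read_bed_profile,
    read_count_matrix,
    read_qpcr,
    read_sample_metadata,
    read_tcc,
)
from .massbalance import budget_series
from .ncm import NeutralCommunityModel, summarize_classes
from .partition import (
    PartitionConfig,
    depth_stratification,
    group_dynamics,
    partition_taxa,
)
from .quantitation import absolute_abundance, correlate_biomass, depth_cell_density
from .simulate import Experiment, SimConfig, generate_experiment, _jsonable

__all__ = ["run_pipeline", "render_report", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "mode": "synthetic",
    "seed": 0,
    "sim": {},
    "inputs": {},
    "top_n": 20,
    "rarefy": "min",
    "core_grouping": "day",
    "core_depth_cutoff_cm": 15.0,
    "elbow_method": "chord",
    "ncm_level": 0.95,
    "epsilon_cells_per_day": 0.0,
    "eq1_literal": False,
}


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _load_inputs(config: dict) -> tuple[Experiment, dict]:
    digests = {}
    if config["mode"] == "synthetic":
        sim = SimConfig(**({"seed": config["seed"]} | dict(config.get("sim") or {})))
        return generate_experiment(sim), digests
    if config["mode"] != "files":
        raise ValueError(f"unknown mode {config['mode']!r}")
    paths = config.get("inputs") or {}
    required = ("counts", "metadata", "qpcr", "atp", "tcc_influent", "tcc_effluent", "bed")
    missing = [k for k in required if k not in paths or not Path(paths[k]).exists()]
    if missing:
        raise FileNotFoundError(f"missing input file(s): {missing}")
    for k in required:
        digests[k] = _digest(paths[k])
    exp = Experiment(
        counts=read_count_matrix(paths["counts"]),
        meta=read_sample_metadata(paths["metadata"]),
        qpcr=read_qpcr(paths["qpcr"]),
        atp=read_atp(paths["atp"]),
        tcc_influent=read_tcc(paths["tcc_influent"], "influent"),
        tcc_effluent=read_tcc(paths["tcc_effluent"], "effluent"),
        bed=read_bed_profile(paths["bed"]),
        flow=parse_flow(paths.get("flow", "1 mL/min")),
        truth={},
    )
    return exp, digests


def _filter_subset(exp: Experiment, max_depth_cm: float | None = None) -> CountMatrix:
    meta = exp.meta
    keep = meta["compartment"] == "filter"
    if max_depth_cm is not None:
        keep &= meta["depth_cm"] < max_depth_cm
    ids = [s for s in exp.counts.samples if s in meta.index[keep]]
    return exp.counts.subset_samples(ids)


def run_pipeline(config: dict | None = None, outdir=None) -> dict:
    """Run every stage; returns the results bundle (JSON-serialisable)."""
    config = DEFAULT_CONFIG | (config or {})
    manifest = {
        "version": __version__,
        "config": _jsonable({k: v for k, v in config.items() if k != "inputs"}
                            | {"inputs": {k: str(v) for k, v in (config.get("inputs") or {}).items()}}),
        "seed": config["seed"],
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": [],
    }
    bundle: dict = {"manifest": manifest}

    def stage(name):
        manifest["stages"].append({"name": name, "status": "ok"})

    try:
        exp, digests = _load_inputs(config)
        manifest["input_digests"] = digests
        stage("load_inputs")

        # ---- quantitation -------------------------------------------------
        filter_counts = _filter_subset(exp)
        rel = filter_counts.relative_abundance()
        absolute = absolute_abundance(rel, exp.qpcr)
        dens = depth_cell_density(exp.atp, exp.meta, exp.bed)
        atp_cells = pd.Series(
            exp.atp.loc[filter_counts.samples] / 8.9e-17, index=filter_counts.samples
        )
        r, pval = correlate_biomass(atp_cells, exp.qpcr)
        bundle["quantitation"] = {
            "biomass_pearson_r": r,
            "biomass_pearson_p": pval,
            "depth_cell_density": dens,
        }
        stage("quantitation")

        # ---- mass balance -------------------------------------------------
        takedowns = sorted(dens.index)
        stocks = [
            float(np.dot(np.asarray(exp.bed.mass_g), dens.loc[d].to_numpy()))
            for d in takedowns
        ]
        budgets = budget_series(
            takedowns,
            stocks,
            exp.tcc_influent,
            exp.tcc_effluent,
            exp.flow,
            start_day=0.0,
            epsilon=config["epsilon_cells_per_day"],
            eq1_literal=config["eq1_literal"],
        )
        bundle["mass_balance"] = {
            "takedown_days": takedowns,
            "stocks": stocks,
            "budgets": [b.as_dict() for b in budgets],
        }
        stage("mass_balance")

        # ---- partition & dynamics ----------------------------------------
        part = partition_taxa(rel, PartitionConfig(top_n=config["top_n"]))
        dyn = group_dynamics(absolute, part, exp.meta, exp.bed)
        strat = depth_stratification(
            exp.qpcr.reindex(filter_counts.samples),
            exp.meta,
            exp.bed,
            cutoff_cm=config["core_depth_cutoff_cm"],
        )
        bundle["partition"] = {
            "table": part.table,
            "dominant": part.dominant,
            "group_totals": dyn["totals"],
            "group_changes": dyn["changes"],
            "depth_stratification": strat,
        }
        stage("partition_dynamics")

        # ---- core microbiome (top of the bed, rarefied) -------------------
        top_counts = _filter_subset(exp, max_depth_cm=config["core_depth_cutoff_cm"])
        depth = config["rarefy"]
        if depth == "min":
            rare_counts = rarefy(top_counts, seed=config["seed"])
        elif depth is None:
            rare_counts = top_counts
        else:
            rare_counts = rarefy(top_counts, depth=int(depth), seed=config["seed"])
        meta_top = exp.meta.loc[rare_counts.samples]
        core = select_core(
            rare_counts,
            meta_top,
            grouping=config["core_grouping"],
            elbow_method=config["elbow_method"],
        )
        bundle["core"] = core.as_dict()
        stage("core_microbiome")

        # ---- neutral model ------------------------------------------------
        model = NeutralCommunityModel.from_counts(rare_counts)
        fit = model.fit(level=config["ncm_level"])
        labels = fit.table["ncm_class"]
        groups = part.table["group"].reindex(labels.index).fillna("rare")
        class_by_group = summarize_classes(labels, groups)
        core_groups = pd.Series(
            np.where(labels.index.isin(core.core_set), "core", "non_core"),
            index=labels.index,
        )
        class_by_core = summarize_classes(labels, core_groups)
        bundle["ncm"] = {
            "m": fit.m,
            "m_stderr": fit.m_stderr,
            "r_squared": fit.r_squared,
            "N": fit.N,
            "d": fit.d,
            "n_samples": fit.n_samples,
            "table": fit.table,
            "summary": fit.summary(),
            "class_by_group": class_by_group,
            "class_by_core": class_by_core,
        }
        stage("neutral_model")
    except Exception as exc:
        failed = len(manifest["stages"])
        names = [
            "load_inputs", "quantitation", "mass_balance",
            "partition_dynamics", "core_microbiome", "neutral_model",
        ]
        name = names[failed] if failed < len(names) else "unknown"
        manifest["stages"].append({"name": name, "status": f"error: {exc}"})
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    if outdir is not None:
        _write_bundle(bundle, outdir)
    return bundle


def _write_bundle(bundle: dict, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "results.json", "w", encoding="utf-8") as fh:
        json.dump(_jsonable(bundle), fh, indent=1)
    bundle["partition"]["table"].to_csv(out / "taxon_partition.tsv", sep="\t")
    bundle["partition"]["group_changes"].to_csv(
        out / "group_changes.tsv", sep="\t", index=False
    )
    pd.DataFrame(bundle["mass_balance"]["budgets"]).to_csv(
        out / "cell_budgets.tsv", sep="\t", index=False
    )
    bundle["ncm"]["table"].to_csv(out / "ncm_taxa.tsv", sep="\t")
    with open(out / "report.md", "w", encoding="utf-8") as fh:
        fh.write(render_report(bundle))


def _fmt(x, sig=3):
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return "-"
    return f"{x:.{sig}g}"


def render_report(bundle: dict) -> str:
    """Markdown report mirroring the analyses; rounds to ~3 significant figures."""
    missing = [k for k in ("manifest", "quantitation", "mass_balance", "partition",
                           "core", "ncm") if k not in bundle]
    if missing:
        raise ValueError(f"incomplete bundle, missing stage(s): {missing}")
    lines = ["# Biofilter community analysis report", ""]
    man = bundle["manifest"]
    lines += [f"Pipeline version {man['version']}, seed {man['seed']}.", ""]

    lines += ["## Biomass quantitation", ""]
    q = bundle["quantitation"]
    lines += [
        f"ATP-derived cells vs qPCR totals: Pearson r = {_fmt(q['biomass_pearson_r'])} "
        f"(p = {_fmt(q['biomass_pearson_p'], 2)})",
        "",
    ]

    lines += ["## Cell mass balance", "",
              "| interval (d) | net input | stock start | stock end | delta | rate (cells/d) | phase |",
              "|---|---|---|---|---|---|---|"]
    for b in bundle["mass_balance"]["budgets"]:
        lines.append(
            f"| {b['t_start']:g}-{b['t_end']:g} | {_fmt(b['net_input'])} | "
            f"{_fmt(b['stock_start'])} | {_fmt(b['stock_end'])} | "
            f"{_fmt(b['delta_cells'])} | {_fmt(b['rate_cells_per_day'])} | {b['phase']} |"
        )
    lines.append("")

    lines += ["## Dominant vs rare dynamics", "",
              "| from day | to day | group | start | end | fold | percent |",
              "|---|---|---|---|---|---|---|"]
    ch = bundle["partition"]["group_changes"]
    for _, row in ch.iterrows():
        lines.append(
            f"| {row['from_day']} | {row['to_day']} | {row['group']} | "
            f"{_fmt(row['start'])} | {_fmt(row['end'])} | {_fmt(row['fold_change'])} | "
            f"{_fmt(row['percent_change'])}% |"
        )
    strat = bundle["partition"]["depth_stratification"]
    lines += ["", "Depth stratification (share of biomass above the cutoff, top:bottom ratio):", ""]
    for day, row in strat.iterrows():
        lines.append(
            f"- day {day}: fraction {_fmt(row['fraction_above_cutoff'])}, "
            f"ratio {_fmt(row['top_bottom_ratio'])}"
        )
    lines.append("")

    core = bundle["core"]
    lines += ["## Core microbiome", ""]
    if core["elbow_index"] <= 1 and len(core["core_set"]) <= 1:
        lines.append("Degenerate core: the contribution curve has no usable elbow.")
    lines += [
        f"{core['n_ranked']} ranked taxa; elbow at n = {core['elbow_index']}; "
        f"core set of {len(core['core_set'])} taxa "
        f"(elbow method: {core['method']['elbow']}).",
        "",
    ]

    lines += ["## Neutral community model", "", "```", bundle["ncm"]["summary"], "```", ""]
    lines += ["Class counts by dominant/rare group:", ""]
    cg = bundle["ncm"]["class_by_group"]
    lines += [cg.to_markdown() if hasattr(cg, "to_markdown") else str(cg), ""]
    return "\n".join(lines)
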