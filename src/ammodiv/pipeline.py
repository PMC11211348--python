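"""End-to-end orchestration: simulate -> clean -> standardize -> bds -> mbd -> mte.

Each stage reads/writes plain CSV/TSV files in an output directory so stages
can be re-run independently (from the CLI or programmatically).  Every run
echoes its configuration and seed into ``run.log`` together with row-count
accounting.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bds, mbd, mte, occurrences, simulate, spatial

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 1,
    "simulate": {
        "n_initial": 2,
        "lam": 0.12,
        "mu": 0.1,
        "q": 1.5,
        "accept_range": [80, 400],
        "localities_per_stage": 12,
        "n_decoy_drivers": 2,
        "dispersion_km": 400.0,
    },
    "clean": {
        "max_age_uncertainty": 10.0,
        "tail_proportion": 0.35,
        "drop_outliers": True,
    },
    "standardize": {
        "grid_frequency": 8,
        "window": [60.0, 40.0],
        "target_quantile": 0.25,
        "sqs_quorum": 0.5,
    },
    "bds": {
        "n_replicates": 2,
        "iterations": 20000,
        "sampling_interval": 50,
        "edge_window": [113.2, 66.0],
    },
    "mbd": {"iterations": 2000, "sampling_interval": 5, "link": "exponential"},
    "mte": {"iterations": 4000, "sampling_interval": 5},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_config(path=None, overrides=None) -> dict:
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            cfg = _merge(cfg, yaml.safe_load(fh) or {})
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def _setup_run(outdir, config) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "config_echo.yaml", "w") as fh:
        yaml.safe_dump(config, fh)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("ammodiv")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    logger.info("config: %s", json.dumps(config, default=str))
    return outdir


def stage_simulate(config: dict, outdir) -> dict:
    outdir = Path(outdir)
    sim = config["simulate"]
    cfg = simulate.SimulationConfig(
        seed=config["seed"],
        n_initial=sim["n_initial"],
        lam=sim["lam"],
        mu=sim["mu"],
        q=sim["q"],
        accept_range=tuple(sim["accept_range"]),
        localities_per_stage=sim["localities_per_stage"],
        n_decoy_drivers=sim["n_decoy_drivers"],
        driver_effects=sim.get("driver_effects", {}),
        trait_multipliers=sim.get("trait_multipliers", {}),
        dispersion_km=sim["dispersion_km"],
    )
    table, drivers, traits, truth = simulate.simulate_full(cfg)
    occurrences.write_occurrences(table, outdir / "occurrences.csv")
    traits.to_csv(outdir / "traits.csv", index=False)
    (outdir / "truth.json").write_text(truth.to_json())
    ddir = outdir / "drivers"
    ddir.mkdir(exist_ok=True)
    for name, (ages, values) in drivers.items():
        pd.DataFrame({"age_ma": ages, "value": values}).to_csv(
            ddir / f"{name}.csv", index=False
        )
    logger.info("simulated %d occurrences, %d lineages", len(table), len(truth.times))
    return {"n_occurrences": len(table), "n_lineages": len(truth.times)}


def stage_clean(config: dict, outdir) -> pd.DataFrame:
    outdir = Path(outdir)
    cln = config["clean"]
    table = occurrences.read_occurrences(outdir / "occurrences.csv")
    n0 = len(table)
    table = occurrences.filter_age_uncertainty(table, cln["max_age_uncertainty"])
    # reference ranges derived from observed stratigraphic extremes per genus
    ranges = (
        table.groupby("genus")
        .agg(oldest_ma=("max_ma", "max"), youngest_ma=("min_ma", "min"))
        .reset_index()
        .rename(columns={"genus": "taxon"})
    )
    out_flags = occurrences.flag_range_outliers(table, ranges)
    genus_flags, tail_flags = occurrences.flag_range_tails(
        table, cln["tail_proportion"]
    )
    flags = out_flags.merge(tail_flags, on="occurrence_id", suffixes=("_range", "_tail"))
    flags.to_csv(outdir / "flags.tsv", sep="\t", index=False)
    if cln["drop_outliers"]:
        bad = (flags["flag_range"].isin(["older_than_range", "younger_than_range"])
               | (flags["flag_tail"] == "tail"))
        table = table.loc[~bad.to_numpy()].reset_index(drop=True)
    occurrences.write_occurrences(table, outdir / "occurrences_clean.csv")
    logger.info("clean: %d -> %d rows", n0, len(table))
    return table


def stage_standardize(config: dict, outdir) -> pd.DataFrame:
    outdir = Path(outdir)
    std = config["standardize"]
    table = occurrences.read_occurrences(outdir / "occurrences_clean.csv")
    grid = spatial.build_grid(std["grid_frequency"])
    track, masks = spatial.slide_windows(table, tuple(std["window"]))
    kept = np.zeros(len(table), bool)
    for mask in masks.values():
        kept |= mask
    table = table.loc[kept].reset_index(drop=True)

    occ_rows, report_rows, keep_rows = [], [], []
    stage_info = []
    for stage, sub in table.groupby("stage", sort=False):
        occ = spatial.assign_cells(sub["plon"], sub["plat"], grid, stage=stage)
        tree = spatial.mst_length(occ, grid)
        stage_info.append((stage, sub, occ, tree))
    lengths = [t.total_length_km for _, _, _, t in stage_info]
    target = float(np.quantile(lengths, std["target_quantile"])) if lengths else 0.0
    for stage, sub, occ, tree in stage_info:
        pruned, ptree = spatial.prune_to_target(occ, grid, target)
        kept_cells = set(pruned.cell_ids)
        cell_of = spatial.assign_cells(sub["plon"], sub["plat"], grid)
        # recompute per-row cell assignment to filter occurrences
        v = spatial._unit_vectors(sub["plon"], sub["plat"])
        nearest = np.argmax(v @ grid._vectors.T, axis=1)
        row_keep = np.isin(nearest, list(kept_cells))
        keep_rows.append(sub.loc[row_keep])
        for cid in pruned.cell_ids:
            c = grid.centroids.iloc[cid]
            occ_rows.append((stage, "all", cid, c["lon"], c["lat"],
                             int(pruned.counts[cid])))
        report_rows.append(
            (stage, "all", tree.total_length_km, ptree.total_length_km, target,
             len(occ.counts) - len(pruned.counts), int((~row_keep).sum()))
        )
    pd.DataFrame(
        occ_rows,
        columns=["stage", "region", "cell_id", "centroid_lon", "centroid_lat",
                 "n_occurrences"],
    ).to_csv(outdir / "occupancy.tsv", sep="\t", index=False)
    pd.DataFrame(
        report_rows,
        columns=["stage", "region", "mst_before_km", "mst_after_km", "target_km",
                 "cells_dropped", "occurrences_dropped"],
    ).to_csv(outdir / "standardization.tsv", sep="\t", index=False)

    std_table = pd.concat(keep_rows, ignore_index=True)
    occurrences.write_occurrences(std_table, outdir / "occurrences_std.csv")

    # coverage-standardised diversity per stage + extent correlations
    sqs_rows = []
    for stage, sub in std_table.groupby("stage", sort=False):
        ab = sub.groupby("genus")["occurrence_id"].count().to_numpy()
        res = spatial.sqs_diversity(ab, std["sqs_quorum"])
        occ = spatial.assign_cells(sub["plon"], sub["plat"], grid, stage=stage)
        tree = spatial.mst_length(occ, grid)
        sqs_rows.append(
            (stage, res.richness, res.extrapolated,
             float(np.ptp(sub["plon"])), float(np.ptp(sub["plat"])),
             tree.total_length_km)
        )
    sqs = pd.DataFrame(
        sqs_rows,
        columns=["stage", "sqs_richness", "extrapolated", "lon_range",
                 "lat_range", "mst_km"],
    )
    sqs.to_csv(outdir / "sqs.tsv", sep="\t", index=False)
    if len(sqs) >= 3:
        try:
            corr = spatial.extent_correlations(
                sqs["sqs_richness"],
                {"lon_range": sqs["lon_range"], "lat_range": sqs["lat_range"],
                 "mst_km": sqs["mst_km"]},
            )
            corr.to_csv(outdir / "extent_correlations.tsv", sep="\t", index=False)
        except ValueError as exc:
            logger.warning("extent correlations skipped: %s", exc)
    logger.info("standardize: retained %d rows", len(std_table))
    return std_table


def stage_bds(config: dict, outdir) -> pd.DataFrame:
    outdir = Path(outdir)
    bcfg = config["bds"]
    table = occurrences.read_occurrences(outdir / "occurrences_std.csv")
    reps = occurrences.randomize_ages(
        table, n_replicates=bcfg["n_replicates"], seed=config["seed"]
    )
    stage_bounds = simulate.DEFAULT_STAGE_BOUNDS
    ml = bds.fit_preservation_ml(table["genus"], reps[0].point_age, stage_bounds)
    ml.to_csv(outdir / "preservation_model_test.tsv", sep="\t", index=False)
    logs = []
    for rep in reps:
        data = bds.BDSData.from_replicate(table, rep.point_age, stage_bounds)
        cfg = bds.BDSConfig(
            iterations=bcfg["iterations"],
            sampling_interval=bcfg["sampling_interval"],
            edge_window=tuple(bcfg["edge_window"]),
            stage_bounds=tuple(stage_bounds),
            seed=config["seed"] * 100 + rep.replicate_index,
        )
        log = bds.run_rjmcmc(data, cfg)
        log.to_csv(outdir / f"bds_chain_{rep.replicate_index}.tsv", sep="\t",
                   index=False)
        logs.append(log)
    chain = bds.combine_logs(logs)
    chain.to_csv(outdir / "bds_chain_combined.tsv", sep="\t", index=False)
    # ESS is a per-chain notion; replicates differ in likelihood level
    ess = min(bds.chain_ess(log.iloc[len(log) // 10:]) for log in logs)
    logger.info("bds: combined chain %d samples, min replicate ESS %.0f",
                len(chain), ess)

    w_hi, w_lo = bcfg["edge_window"]
    grid = np.arange(w_lo, w_hi + 0.25, 0.5)[::-1]
    bins = list(zip(stage_bounds[:-1], stage_bounds[1:]))
    rtt = bds.rates_through_time(chain, grid, edge_window=tuple(bcfg["edge_window"]),
                                 boundary_bins=bins)
    rtt.summary.to_csv(outdir / "rtt.tsv", sep="\t", index=False)
    rtt.shift_support.to_csv(outdir / "shift_support.tsv", sep="\t", index=False)
    curve = bds.diversity_curve(chain)
    curve.summary.to_csv(outdir / "diversity.tsv", sep="\t", index=False)
    return chain


def _times_from_chain(chain: pd.DataFrame) -> pd.DataFrame:
    """Posterior-mean lineage times from a combined chain."""
    ts_cols = [c for c in chain.columns if c.startswith("ts_")]
    rows = []
    for c in ts_cols:
        name = c[3:]
        rows.append((name, float(chain[c].mean()), float(chain["te_" + name].mean())))
    return pd.DataFrame(rows, columns=["lineage", "ts", "te"])


def stage_mbd(config: dict, outdir, chain=None) -> pd.DataFrame:
    outdir = Path(outdir)
    mcfg = config["mbd"]
    if chain is None:
        chain = pd.read_csv(outdir / "bds_chain_combined.tsv", sep="\t")
    times = _times_from_chain(chain)
    drivers = []
    for path in sorted((outdir / "drivers").glob("*.csv")):
        raw = pd.read_csv(path)
        drivers.append(
            mbd.prepare_driver(raw[["age_ma", "value"]].to_numpy(), name=path.stem)
        )
    cfg = mbd.MBDConfig(
        link=mcfg["link"],
        iterations=mcfg["iterations"],
        sampling_interval=mcfg["sampling_interval"],
        seed=config["seed"] + 31,
    )
    mbd_chain, summary = mbd.run_mbd_mcmc([times], drivers, cfg)
    summary.table.to_csv(outdir / "mbd_summary.tsv", sep="\t", index=False)
    mbd_chain.to_csv(outdir / "mbd_chain.tsv", sep="\t", index=False)
    logger.info("mbd: %d drivers, %d samples", len(drivers), len(mbd_chain))
    return summary.table


def stage_mte(config: dict, outdir, chain=None) -> pd.DataFrame:
    outdir = Path(outdir)
    tcfg = config["mte"]
    if chain is None:
        chain = pd.read_csv(outdir / "bds_chain_combined.tsv", sep="\t")
    times = _times_from_chain(chain)
    traits = pd.read_csv(outdir / "traits.csv")
    traits = traits[traits["lineage"].isin(times["lineage"])]
    cfg = mte.MTEConfig(
        iterations=tcfg["iterations"],
        sampling_interval=tcfg["sampling_interval"],
        seed=config["seed"] + 77,
    )
    mte_chain, summary = mte.run_mte_mcmc([times], traits, cfg)
    out = summary.trait_table.merge(summary.category_table, on="trait")
    out = out[["trait", "category", "posterior_mean_multiplier",
               "inclusion_frequency", "significant"]]
    out.to_csv(outdir / "mte_summary.tsv", sep="\t", index=False)
    logger.info("mte: %d traits", len(summary.trait_table))
    return out


def run_pipeline(config: dict, outdir) -> dict:
    """Run every stage in order; returns a dict of stage outputs."""
    outdir = _setup_run(outdir, config)
    results = {}
    results["simulate"] = stage_simulate(config, outdir)
    results["clean"] = stage_clean(config, outdir)
    results["standardize"] = stage_standardize(config, outdir)
    chain = stage_bds(config, outdir)
    results["bds_chain"] = chain
    results["mbd"] = stage_mbd(config, outdir, chain)
    results["mte"] = stage_mte(config, outdir, chain)
    return results
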