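"""End-to-end drivers: simulate -> write, and load -> normalize -> filter ->
vote -> score -> null -> call -> summarize -> report."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aucell import build_null, ranking_positions, score_signature
from .config import config_hash, load_config
from .io import read_counts, read_spot_table, write_counts, write_spot_table
from .matrix import filter_observations, normalize
from .modules import GeneModule, match_modules
from .signatures import read_gene_list, read_gmt
from .simulate import ConcentricLayout, simulate_spatial
from .spatial import call_darg_high, niche_summary, patient_summary, quantile_bin_test
from .voting import SignatureVoter

logger = logging.getLogger(__name__)


def run_simulate(config_path: str | Path | None, out_dir: str | Path, seed: int | None = None) -> dict:
    """Simulate a spatial section and write the standard triplet + metadata."""
    cfg = load_config(config_path)
    if seed is not None:
        cfg["seed"] = int(seed)
    out_dir = Path(out_dir)
    if not out_dir.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {out_dir.parent}")
    out_dir.mkdir(exist_ok=True)
    layout = ConcentricLayout(
        lc_radius=cfg["sim.lc_radius"],
        lr_width=cfg["sim.lr_width"],
        plwm_width=cfg["sim.plwm_width"],
    )
    matrix, spots, truth = simulate_spatial(
        grid_w=cfg["sim.grid_w"],
        grid_h=cfg["sim.grid_h"],
        layout=layout,
        darg_rate_per_niche={
            n: cfg[f"sim.darg_rate.{n}"] for n in ("LC", "LR", "PLWM", "NAWM")
        },
        n_rg_genes=cfg["sim.n_rg_genes"],
        n_infl_genes=cfg["sim.n_infl_genes"],
        log2_fold_change=cfg["sim.log2_fold_change"],
        n_genes=cfg["sim.n_genes"],
        sample_id=cfg["sim.sample_id"],
        group=cfg["sim.group"],
        seed=cfg["seed"],
    )
    write_counts(matrix, out_dir)
    write_spot_table(spots, out_dir / "spots.csv")
    truth.darg_truth.rename("darg_truth").to_frame().rename_axis("obs_id").to_csv(
        out_dir / "truth.csv"
    )
    (out_dir / "rg_genes.txt").write_text(
        "".join(f"{g}\n" for g in truth.parameters["rg_genes"])
    )
    (out_dir / "inflammatory_genes.txt").write_text(
        "".join(f"{g}\n" for g in truth.parameters["infl_genes"])
    )
    manifest = {
        "artifact_version": __version__,
        "seed": cfg["seed"],
        "config_hash": config_hash(cfg),
        "parameters": {k: v for k, v in truth.parameters.items()
                       if k not in ("rg_genes", "infl_genes")},
        "n_spots": matrix.n_obs,
        "n_genes": matrix.n_genes,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    logger.info("simulated %d spots x %d genes -> %s", matrix.n_obs, matrix.n_genes, out_dir)
    return manifest


def run_pipeline(
    config_path: str | Path | None,
    data_dir: str | Path,
    out_dir: str | Path,
    seed: int | None = None,
) -> dict:
    """Full DARG-high calling pipeline on a dataset directory.

    ``data_dir`` must contain matrix.mtx, features.tsv, barcodes.tsv,
    spots.csv, rg_genes.txt and inflammatory_genes.txt.  Writes stage outputs
    and a report JSON to ``out_dir``; returns the report dict.
    """
    cfg = load_config(config_path)
    if seed is not None:
        cfg["seed"] = int(seed)
    data_dir, out_dir = Path(data_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    logger.info("stage read: loading triplet from %s", data_dir)
    matrix = read_counts(
        data_dir / "matrix.mtx", data_dir / "features.tsv", data_dir / "barcodes.tsv"
    )
    spots = read_spot_table(data_dir / "spots.csv")
    rg_genes = read_gene_list(data_dir / "rg_genes.txt")
    infl_genes = read_gene_list(data_dir / "inflammatory_genes.txt")

    logger.info("stage filter: %d spots in", matrix.n_obs)
    filtered = filter_observations(matrix, cfg["filter.min_unique_genes"])
    spots = spots[spots["obs_id"].isin(filtered.obs_ids)].reset_index(drop=True)
    logger.info("stage filter: %d spots kept", filtered.n_obs)
    norm = normalize(
        filtered, cfg["normalize.scale_factor"], cfg["normalize.log_base"]
    )
    frame = norm.to_frame()

    logger.info("stage vote: counting signature genes per spot")
    vote_mode = cfg["darg.vote_mode"]
    votes = {}
    for name, genes in (("rg", rg_genes), ("inflammatory", infl_genes)):
        voter = SignatureVoter(genes=genes, min_genes=1, mode=vote_mode).fit(frame)
        votes[name] = voter.vote_counts(frame)

    logger.info("stage score: recovery AUC for the combined DARG signature")
    darg_genes = rg_genes + [g for g in infl_genes if g not in set(rg_genes)]
    positions = ranking_positions(frame, seed=cfg["seed"])
    scores = score_signature(
        frame, darg_genes, top_fraction=cfg["auc.top_fraction"],
        seed=cfg["seed"], positions=positions,
    )

    logger.info("stage null: %d permutations", cfg["null.n_perm"])
    present = [g for g in darg_genes if g in set(norm.gene_ids)]
    null = build_null(
        frame,
        sig_length=len(present),
        n_perm=cfg["null.n_perm"],
        quantile_q=cfg["null.quantile"],
        seed=cfg["seed"],
        top_fraction=cfg["auc.top_fraction"],
        positions=positions,
    )
    null.save(out_dir / "null.json")

    logger.info("stage call: threshold %.4f", null.threshold)
    calls = call_darg_high(
        scores, null, votes["rg"], votes["inflammatory"], spots,
        gene_count_thresholds={
            "WM": cfg["darg.wm_gene_threshold"],
            "GM": cfg["darg.gm_gene_threshold"],
        },
    )
    calls.to_csv(out_dir / "darg_calls.csv", index=False)
    scores.to_csv(out_dir / "scores.csv")

    niches = niche_summary(calls, spots)
    niches.to_csv(out_dir / "niche_summary.csv", index=False)

    report: dict = {
        "artifact_version": __version__,
        "seed": cfg["seed"],
        "config_hash": config_hash(cfg),
        "n_spots": int(len(calls)),
        "n_genes": int(norm.n_genes),
        "normalization": {"scale_factor": cfg["normalize.scale_factor"],
                          "log_base": cfg["normalize.log_base"]},
        "auc_threshold": float(null.threshold),
        "null": null.summary(),
        "n_darg_high": int(calls["darg_high"].sum()),
        "darg_high_fraction": float(calls["darg_high"].mean()),
        "niche_summary": niches.to_dict(orient="records"),
    }

    if spots["group"].nunique() == 2:
        per_sample, p = patient_summary(scores, spots)
        per_sample.to_csv(out_dir / "patient_summary.csv", index=False)
        report["patient_test"] = {"p_two_sided": p,
                                  "per_sample": per_sample.to_dict(orient="records")}

    n_bins = int(cfg["stats.n_bins"])
    high = calls.loc[calls["darg_high"], "auc"].to_numpy()
    low = calls.loc[~calls["darg_high"], "auc"].to_numpy()
    if len(high) >= n_bins and len(low) >= n_bins:
        t, df, p, _, _ = quantile_bin_test(high, low, n_bins=n_bins)
        report["darg_high_vs_low_auc"] = {
            "t": t, "df": df, "p_two_sided": p, "n_bins": n_bins,
        }

    (out_dir / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    logger.info("report written: %d/%d DARG-high spots", report["n_darg_high"], len(calls))
    return report


def run_match_modules(
    baseline_gmt: str | Path,
    query_gmt: str | Path,
    out_csv: str | Path,
    universe_file: str | Path | None = None,
    alpha: float = 0.05,
    scaling: str = "ochiai",
) -> pd.DataFrame:
    """Match two GMT module collections; writes long-format and best-match CSVs."""
    baseline = [GeneModule(n, frozenset(g)) for n, g in read_gmt(baseline_gmt).items()]
    query = [GeneModule(n, frozenset(g)) for n, g in read_gmt(query_gmt).items()]
    universe = set(read_gene_list(universe_file)) if universe_file else None
    results, best = match_modules(baseline, query, universe=universe,
                                  alpha=alpha, scaling=scaling)
    out_csv = Path(out_csv)
    results.to_csv(out_csv, index=False)
    best.to_csv(out_csv.with_name(out_csv.stem + "_best" + out_csv.suffix), index=False)
    return results
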