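"""End-to-end pipeline orchestration.

Runs simulate -> normalize -> structure -> dynamics -> noise -> network ->
modules -> motif in order, writing every intermediate artifact under one
run directory and a JSON manifest with the seed, config hash and per-stage
summaries.  Every stage is also runnable standalone from files; the
orchestration adds nothing numeric.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import coexpression, dynamics, io, noise, normalization, population, regulation, synthetic
from .config import PipelineConfig

log = logging.getLogger("ctnet")

STAGES = ("simulate", "normalize", "structure", "dynamics", "noise", "network", "modules", "motif")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.save(out / "config.yaml")
    manifest: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }

    def record(stage: str, summary: dict) -> None:
        manifest["stages"][stage] = {"status": "ok", **_jsonable(summary)}
        log.info("stage %s done: %s", stage, summary)

    try:
        # --- simulate (or load) -------------------------------------------
        if config.simulate or not config.ct_table:
            truth = synthetic.make_truth(seed=config.seed)
            ct = synthetic.generate_ct_table(truth)
            net = truth.network
            motif_table = synthetic.generate_motif_table(
                truth.gene_names,
                ["AP1", "SP1", "NFKB", "ETS", "CREB", "GATA", "IRF", "STAT"],
                truth.module_genes(config.enriched_module),
                "AP1",
                enrichment=truth.motif_truth["AP1"],
                seed=config.seed,
            )
            io.write_ct_table(ct, out / "ct_table.tsv")
            io.write_network(net, out / "network.tsv")
            motif_table.to_csv(out / "motif_table.tsv", sep="\t")
            record("simulate", {"n_cells": ct.n_cells, "n_assays": len(ct.assay_names)})
        else:
            ct = io.read_ct_table(config.ct_table)
            net = io.read_network(config.network) if config.network else None
            motif_table = io.read_motif_table(config.motif_table) if config.motif_table else None
            record("simulate", {"loaded": config.ct_table, "n_cells": ct.n_cells})

        # --- normalize ----------------------------------------------------
        ct_c = normalization.CtTable(normalization.censor_ct(ct.values), ct.cell_meta)
        ct_qc, qc_report = normalization.qc_filter(
            ct_c, config.ref_gene, config.anchor_gene, config.qc_k_sd
        )
        n_avail = ct_qc.cell_meta["time_h"].value_counts().min()
        n_take = min(config.n_per_time, int(n_avail))
        ct_fix = normalization.subsample_cells(ct_qc, n_take, config.seed)
        expr = normalization.normalize(ct_fix, config.ref_gene, config.scale_factor)
        io.write_expression(expr, out / "expression.tsv")
        with open(out / "qc_report.json", "w") as fh:
            json.dump(_jsonable(qc_report), fh, indent=2)
        record(
            "normalize",
            {"n_cells": len(expr.expr), "n_genes": len(expr.genes), "qc_removed": qc_report["n_removed"]},
        )

        # --- structure ----------------------------------------------------
        mds = population.mds_embed(expr)
        pca_res = population.pca(expr, k=3)
        cod_series = population.dispersion_by_time(pca_res)
        mds.coords.to_csv(out / "mds_coords.tsv", sep="\t")
        mds.centroids.to_csv(out / "mds_centroids.tsv", sep="\t")
        pca_res.coords.to_csv(out / "pca_scores.tsv", sep="\t")
        pca_res.loadings.to_csv(out / "pca_loadings.tsv", sep="\t")
        cod_series.to_csv(out / "cod_by_time.tsv", sep="\t")
        record(
            "structure",
            {"var_explained": [round(float(v), 6) for v in pca_res.var_explained]},
        )

        # --- dynamics -----------------------------------------------------
        profiles = dynamics.detection_profiles(expr)
        labels = dynamics.classify_trajectories(profiles, k=config.kmeans_k, seed=config.seed)
        rate_table = dynamics.rates(profiles)
        profiles.f.to_csv(out / "detection_fractions.tsv", sep="\t")
        profiles.mean_detected.to_csv(out / "mean_detected.tsv", sep="\t")
        labels.to_csv(out / "trajectory_classes.tsv", sep="\t")
        rate_table.to_csv(out / "rates.tsv", sep="\t", index=False)
        record("dynamics", {"class_counts": labels.value_counts().to_dict()})

        # --- noise --------------------------------------------------------
        noise_table = noise.noise_strength(expr)
        noise_table.eta.to_csv(out / "noise_strength.tsv", sep="\t")
        noise_table.z.to_csv(out / "noise_z.tsv", sep="\t")
        summary: dict = {}
        if net is not None:
            layers = noise.classify_layers(net)
            layers.to_csv(out / "layers.tsv", sep="\t")
            test = noise.layer_noise_test(noise_table, net)
            with open(out / "layer_noise_test.json", "w") as fh:
                json.dump(_jsonable(test), fh, indent=2)
            summary = {"layer_test_p": test["p"], "layer_counts": layers.value_counts().to_dict()}
        record("noise", summary)

        # --- network ------------------------------------------------------
        nets = coexpression.spearman_networks(expr, fdr=config.fdr)
        counts_q = coexpression.count_edges(nets, "q")
        counts_p = coexpression.count_edges(nets, "p")
        counts_q.to_csv(out / "edge_counts_fdr.tsv", sep="\t")
        counts_p.to_csv(out / "edge_counts_pval.tsv", sep="\t")
        for t in nets.time_points:
            nets[t].edges("q").to_csv(out / f"edges_t{int(t):03d}h.tsv", sep="\t", index=False)
        record("network", {"total_edges_fdr": int(counts_q.to_numpy().sum())})

        # --- modules ------------------------------------------------------
        modules = coexpression.detect_modules(nets, config.module_time_h, config.n_modules)
        modules.modules.to_csv(out / "modules.tsv", sep="\t")
        traj = coexpression.module_trajectories(expr, modules)
        traj["mean_expression"].to_csv(out / "module_mean_expression.tsv", sep="\t")
        traj["mean_noise"].to_csv(out / "module_mean_noise.tsv", sep="\t")
        hinges = coexpression.hinge_genes(nets, modules, config.module_time_h)
        hinges.to_csv(out / "hinge_genes.tsv", sep="\t", index=False)
        mod_summary: dict = {
            "module_sizes": modules.modules.value_counts().to_dict(),
            "top_hinge": hinges["gene"].iloc[0] if len(hinges) else None,
        }
        if net is not None:
            balance = regulation.module_edge_balance(net, modules)
            balance.drop(columns=["missing"]).to_csv(out / "module_edge_balance.tsv", sep="\t")
        record("modules", mod_summary)

        # --- motif --------------------------------------------------------
        if motif_table is not None:
            module_genes = modules.genes_in(config.enriched_module)
            res = regulation.motif_enrichment_all(motif_table, module_genes)
            res.to_csv(out / "motif_enrichment.tsv", sep="\t")
            top = res.sort_values("p").iloc[0]
            record("motif", {"top_motif": res["p"].idxmin(), "top_p": float(top["p"])})
        else:
            record("motif", {"skipped": "no motif table"})
    except Exception as exc:  # noqa: BLE001 - abort names the failing stage
        failed = STAGES[len(manifest["stages"])] if len(manifest["stages"]) < len(STAGES) else "?"
        raise RuntimeError(f"pipeline stage {failed!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def compare_conditions(
    control: "normalization.ExpressionMatrix",
    treated: "normalization.ExpressionMatrix",
) -> dict:
    """Knockdown-vs-control comparison of two expression matrices.

    Per shared gene: change in detection fraction, in mean expression, and
    in noise strength (treated minus control, pooled over cells), plus the
    per-gene KDE inputs for density overlays.
    """
    genes = [g for g in control.genes if g in set(treated.genes)]
    rows = []
    densities = {}
    for g in genes:
        c = control.unit_scale()[g].to_numpy()
        t = treated.unit_scale()[g].to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            eta_c = c.var(ddof=1) / c.mean() if c.mean() > 0 else np.nan
            eta_t = t.var(ddof=1) / t.mean() if t.mean() > 0 else np.nan
        rows.append(
            {
                "gene": g,
                "delta_detection": float((t >= 0.5).mean() - (c >= 0.5).mean()),
                "delta_mean": float(t.mean() - c.mean()),
                "delta_noise": float(eta_t - eta_c),
            }
        )
        if c.std() > 0 and t.std() > 0:
            densities[g] = {
                "control": dynamics.kde_density(c),
                "treated": dynamics.kde_density(t),
            }
    return {"deltas": pd.DataFrame(rows).set_index("gene"), "densities": densities}
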