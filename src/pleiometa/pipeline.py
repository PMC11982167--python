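"""End-to-end workflow: simulate/load -> QC -> BLUEs -> GRM -> GREML ->
univariate scans -> three meta-analyses -> QTL clusters -> LD summary.

`run_pipeline` drives the stages from one configuration mapping (typically
parsed from TOML) and writes every stage's tables plus a JSON manifest with
parameters, seed, and per-file checksums; reruns with the same config are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time


import pandas as pd

from . import __version__
from .blues import blues_all

from .greml import BivariateGREML, GREML, average_rg, group_elements
from .grm import compute_grm, stabilize
from .gwas import MLMScan
from .io import read_genotypes, read_tsv, write_dosage_tsv, write_tsv
from .ld import ld_summary
from .meta import build_t_matrix, cluster_qtl, run_meta_design
from .qc import run_qc
from .simulate import (default_env_plan, simulate_architecture,
                       simulate_genotypes, simulate_trials)

log = logging.getLogger("pleiometa")

__all__ = ["run_pipeline", "simulate_dataset", "default_config"]


def default_config() -> dict:
    """Demo configuration: a small fully synthetic dataset."""
    return {
        "seed": 1,
        "out_dir": "pleiometa_run",
        "simulate": {
            "n_lines": 200,
            "n_chrom": 3,
            "snps_per_chrom": 250,
            "length_bp": 120_000_000,
            "missing_rate": 0.03,
            "n_subset": 80,
            "elements": ["Ca", "K", "Fe", "Zn", "Mg", "P"],
            "group1": ["Ca", "K"],
            "n_shared": 8,
            "n_private": 1,
            "n_antagonistic": 1,
            "h2_target": 0.42,
            "rg_within": 0.45,
            "rg_between": -0.20,
            "n_envs": 4,
        },
        "qc": {"max_missing": 0.40, "min_call_rate": 0.60, "min_maf": 0.05,
               "knn_k": 5, "knn_l": 30},
        "gwas": {"mode": "null_lambda"},
        "greml": {"pairs": "between"},
        "meta": {"alpha": 0.05, "r2_cluster": 0.5, "overrides": {}},
        "ld": {"span": 0.5, "quantile": 0.99, "max_pairs": 200_000,
               "n_inter_pairs": 50_000},
    }


def simulate_dataset(cfg: dict, seed: int):
    """Generate genotypes, architecture and plot data from a config block."""
    from .simulate import EnvSpec, default_chrom_plan

    plan = default_chrom_plan(cfg.get("n_chrom", 3),
                              cfg.get("snps_per_chrom", 250),
                              cfg.get("length_bp", 120_000_000))
    geno = simulate_genotypes(cfg.get("n_lines", 200), plan,
                              missing_rate=cfg.get("missing_rate", 0.03),
                              seed=seed)
    arch = simulate_architecture(
        geno,
        elements=cfg.get("elements"),
        group1=cfg.get("group1"),
        n_shared=cfg.get("n_shared", 8),
        n_private=cfg.get("n_private", 1),
        n_antagonistic=cfg.get("n_antagonistic", 1),
        h2_target=cfg.get("h2_target", 0.42),
        rg_within=cfg.get("rg_within", 0.45),
        rg_between=cfg.get("rg_between", -0.20),
        seed=seed,
    )
    envs = default_env_plan(geno, n_subset=cfg.get("n_subset", 80), seed=seed)
    envs = envs[: cfg.get("n_envs", 4)]
    plots = simulate_trials(geno, arch, envs, seed=seed)
    return geno, arch, plots


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()[:16]


def run_pipeline(config: dict) -> str:
    """Execute the full workflow; returns the output directory path."""
    cfg = default_config()
    for k, v in config.items():
        if isinstance(v, dict) and k in cfg:
            cfg[k].update(v)
        else:
            cfg[k] = v
    seed = int(cfg["seed"])
    out = cfg["out_dir"]
    os.makedirs(out, exist_ok=True)
    manifest = {"version": __version__, "seed": seed, "config": cfg,
                "stages": {}, "files": {}}
    t0 = time.time()

    def stage_done(name, **info):
        manifest["stages"][name] = {"elapsed_s": round(time.time() - t0, 2), **info}
        log.info("stage %s done (%.1fs)", name, time.time() - t0)

    def emit(name, df):
        path = os.path.join(out, name)
        write_tsv(df, path)
        manifest["files"][name] = _checksum(path)

    # 1. data ---------------------------------------------------------------
    if "genotype_path" in cfg:
        geno = read_genotypes(cfg["genotype_path"], cfg.get("genotype_format"))
        plots = read_tsv(cfg["phenotype_path"])
        arch = None
    else:
        geno, arch, plots = simulate_dataset(cfg["simulate"], seed)
        write_dosage_tsv(geno, os.path.join(out, "genotypes_raw.tsv"))
        emit("qtl_truth.tsv", arch.qtl_effects.reset_index(names="snp_id")
             .merge(arch.qtl_flags.reset_index(names="snp_id"), on="snp_id"))
        emit("genetic_values_truth.tsv",
             arch.genetic_values.reset_index(names="line_id"))
    emit("plots.tsv", plots)
    stage_done("data", n_lines=geno.n_lines, n_snps=geno.n_snps)

    # 2. QC -----------------------------------------------------------------
    qcc = cfg["qc"]
    geno_qc, report = run_qc(geno, qcc["max_missing"], qcc["min_call_rate"],
                             qcc["min_maf"], qcc["knn_k"], qcc["knn_l"], seed=seed)
    emit("qc_report.tsv", report.as_frame())
    write_dosage_tsv(geno_qc, os.path.join(out, "genotypes_qc.tsv"))
    stage_done("qc", n_snps=geno_qc.n_snps, n_lines=geno_qc.n_lines)

    # 3. BLUEs --------------------------------------------------------------
    plots = plots[plots["line_id"].isin(set(geno_qc.lines))]
    blue_table, trial_fits = blues_all(plots)
    emit("blues.tsv", blue_table)
    emit("trial_fits.tsv", trial_fits)
    stage_done("blues", n_trials=len(trial_fits))

    # 4. GRM ----------------------------------------------------------------
    grm = stabilize(compute_grm(geno_qc))
    emit("grm.tsv", grm.as_frame().reset_index(names="line_id"))
    stage_done("grm")

    # 5. GREML + grouping ---------------------------------------------------
    envs = sorted(blue_table["env"].unique())
    elements = sorted(blue_table["element"].unique())
    pivot = {env: blue_table[blue_table["env"] == env]
             .pivot(index="line_id", columns="element", values="blue")
             for env in envs}
    h2_rows, rg_rows = [], []
    for env in envs:
        for element in elements:
            if element not in pivot[env]:
                continue
            y = pivot[env][element].reindex(grm.lines).to_numpy()
            r = GREML(y, grm).fit()
            h2_rows.append({"env": env, "element": element, "vg": r.vg,
                            "ve": r.ve, "h2": r.h2, "se_h2": r.se_h2,
                            "loglik": r.loglik, "converged": r.converged})
    for env in envs:
        cols = [e for e in elements if e in pivot[env]]
        for i, a in enumerate(cols):
            for b in cols[i + 1:]:
                ya = pivot[env][a].reindex(grm.lines).to_numpy()
                yb = pivot[env][b].reindex(grm.lines).to_numpy()
                r = BivariateGREML(ya, yb, grm).fit()
                rg_rows.append({"element_a": a, "element_b": b, "env_a": env,
                                "env_b": env, "rg": r.rg,
                                "n_lines_used": r.n, "converged": r.converged})
    h2_table = pd.DataFrame(h2_rows)
    rg_table = pd.DataFrame(rg_rows)
    emit("h2.tsv", h2_table)
    emit("rg.tsv", rg_table)
    avg = average_rg(rg_table, mode="between_element")
    emit("rg_avg.tsv", avg.reset_index(names="element"))
    grouping = group_elements(avg, overrides=cfg["meta"].get("overrides", {}))
    emit("groups.tsv", pd.DataFrame(
        {"element": list(grouping.groups), "group": list(grouping.groups.values())}))
    stage_done("greml", n_h2=len(h2_table), n_rg=len(rg_table))

    # 6. univariate scans ---------------------------------------------------
    assoc = {}
    for env in envs:
        for element in elements:
            if element not in pivot[env]:
                continue
            y = pivot[env][element]
            tab = MLMScan(y.to_numpy(), geno_qc, grm, lines=list(y.index)
                          ).scan(mode=cfg["gwas"]["mode"])
            label = f"{element}:{env}"
            assoc[label] = tab
            emit(f"assoc_{element}_{env}.tsv", tab)
    stage_done("gwas", n_analyses=len(assoc))

    # 7. meta ---------------------------------------------------------------
    tmat = build_t_matrix(assoc)
    results, comparison = run_meta_design(
        tmat, grouping, alpha=cfg["meta"]["alpha"])
    for label, res in results.items():
        emit(f"meta_{label}.tsv", res.table)
        qtl = cluster_qtl(res.table, geno_qc,
                          r2_threshold=cfg["meta"]["r2_cluster"])
        emit(f"qtl_{label}.tsv", qtl)
    emit("meta_comparison.tsv", comparison)
    stage_done("meta", n_meta_analyses=len(results),
               n_significant={k: r.n_significant for k, r in results.items()})

    # 8. LD -----------------------------------------------------------------
    ldc = cfg["ld"]
    pairs, curve = ld_summary(geno_qc, span=ldc["span"], quantile=ldc["quantile"],
                              max_pairs_per_chrom=ldc["max_pairs"],
                              n_inter_pairs=ldc["n_inter_pairs"], seed=seed)
    emit("ld_curve.tsv", curve.as_frame())
    emit("ld_summary.tsv", pd.DataFrame([{
        "background_r2": curve.background,
        "block_size_bp": curve.block_size_bp,
        "n_intra_pairs": len(pairs),
    }]))
    stage_done("ld", background=curve.background,
               block_size_bp=curve.block_size_bp)

    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str, sort_keys=True)
    return out
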