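"""Pipeline orchestration: simulate -> qc -> de -> cluster -> bias -> enrich.

One YAML config drives every stage; every threshold the analysis uses
(expressed-gene FPKM, DEG p and fold change, enrichment alphas, the
triad Low threshold) is surfaced in the config, never hidden.  Each
stage reads its declared inputs from the run directory and writes its
declared TSV outputs there, so a deleted downstream artifact can be
regenerated byte-identically by rerunning just that stage.  A manifest
records SHA-256 checksums of all outputs plus the effective config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib

import numpy as np
import pandas as pd
import yaml

from . import coexpress, diffexpr, enrich, quantify, triad_bias
from .containers import (ExpressionMatrix, read_annotation, read_counts, read_fpkm,
                         read_lengths, read_triads, write_matrix, write_tsv)
from .synthetic import SimulationConfig, simulate_dataset, write_dataset

log = logging.getLogger("triadyn")

STAGES = ("simulate", "qc", "de", "cluster", "bias", "enrich")

DEFAULT_THRESHOLDS = {
    "expressed_fpkm": 1.0,
    "de_p": 0.05,
    "de_lfc": 1.0,
    "tf_alpha": 0.01,
    "pathway_alpha": 0.05,
    "triad_low": 1.0,
}

DEFAULT_CLUSTER = {"k_min": 2, "k_max": 10, "n_init": 25}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return normalize_config(cfg)


def normalize_config(cfg: dict) -> dict:
    cfg = dict(cfg)
    cfg.setdefault("outdir", "triadyn_run")
    cfg.setdefault("seed", 0)
    cfg.setdefault("stages", list(STAGES))
    unknown = set(cfg["stages"]) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    thresholds = {**DEFAULT_THRESHOLDS, **cfg.get("thresholds", {})}
    for key, val in thresholds.items():
        if not (0 <= float(val)) or (key in ("de_p", "tf_alpha", "pathway_alpha") and val > 1):
            raise ValueError(f"threshold {key}={val} outside its valid domain")
    cfg["thresholds"] = thresholds
    cfg["cluster"] = {**DEFAULT_CLUSTER, **cfg.get("cluster", {})}
    cfg.setdefault("simulate", {})
    cfg.setdefault("inputs", {})
    if "simulate" not in cfg["stages"]:
        for key, p in cfg["inputs"].items():
            if not pathlib.Path(p).exists():
                raise FileNotFoundError(f"configured input {key!r} not found: {p}")
    return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _need(outdir: pathlib.Path, name: str, stage: str) -> pathlib.Path:
    p = outdir / name
    if not p.exists():
        raise FileNotFoundError(f"stage {stage!r}: missing upstream output {name}")
    return p


def _read_fpkm(outdir, stage) -> ExpressionMatrix:
    return read_fpkm(_need(outdir, "fpkm.tsv", stage), _need(outdir, "samples.tsv", stage))


def run_pipeline(config: dict | str | pathlib.Path) -> dict:
    """Execute the enabled stages in dependency order.

    Returns the manifest dict (also written to ``manifest.json`` in the
    run directory): per-file SHA-256 checksums, the effective config
    and per-stage row-count log lines.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        config = normalize_config(config)
    outdir = pathlib.Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    enabled = [s for s in STAGES if s in config["stages"]]
    stage_log = []

    def run_stage(name, fn):
        try:
            info = fn(config, outdir)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        line = f"stage {name}: " + ", ".join(f"{k}={v}" for k, v in info.items())
        log.info(line)
        stage_log.append(line)

    dispatch = {
        "simulate": _stage_simulate,
        "qc": _stage_qc,
        "de": _stage_de,
        "cluster": _stage_cluster,
        "bias": _stage_bias,
        "enrich": _stage_enrich,
    }
    for name in enabled:
        run_stage(name, dispatch[name])

    files = sorted(p for p in outdir.iterdir() if p.suffix == ".tsv")
    manifest = {
        "config": _jsonable(config),
        "stages": enabled,
        "log": stage_log,
        "files": {p.name: _sha256(p) for p in files},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in sorted(obj.items())}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pathlib.Path):
        return str(obj)
    return obj


# ---------------------------------------------------------------------------
# stages

def _stage_simulate(cfg, outdir):
    sim_cfg = dict(cfg.get("simulate", {}))
    sim_cfg.pop("enabled", None)
    sim_cfg.setdefault("seed", cfg["seed"])
    ds = simulate_dataset(SimulationConfig.from_dict(sim_cfg))
    write_dataset(ds, outdir)
    return {"triads": len(ds.triads), "genes": len(ds.counts.gene_ids),
            "samples": ds.counts.values.shape[1]}


def _input_path(cfg, outdir, key, default_name, stage):
    if key in cfg["inputs"]:
        return pathlib.Path(cfg["inputs"][key])
    return _need(outdir, default_name, stage)


def _stage_qc(cfg, outdir):
    counts = read_counts(_input_path(cfg, outdir, "counts", "counts.tsv", "qc"),
                         _input_path(cfg, outdir, "samples", "samples.tsv", "qc"))
    lengths = read_lengths(_input_path(cfg, outdir, "lengths", "lengths.tsv", "qc"))
    if "samples" in cfg["inputs"]:
        write_tsv(counts.samples, outdir / "samples.tsv", index=True)
    fpkm = quantify.fpkm(counts, lengths)
    write_matrix(fpkm, outdir / "fpkm.tsv")

    sets = quantify.expressed_genes(fpkm, threshold=cfg["thresholds"]["expressed_fpkm"])
    rows = [{"timepoint": tp, "gene_id": g}
            for tp, genes in sets.per_timepoint.items() for g in sorted(genes)]
    rows += [{"timepoint": "overall", "gene_id": g} for g in sorted(sets.overall)]
    write_tsv(pd.DataFrame(rows, columns=["timepoint", "gene_id"]),
              outdir / "expressed_sets.tsv")

    qc = quantify.sample_qc(fpkm)
    scc = qc.scc.copy()
    scc.index.name = "sample_id"
    write_tsv(scc, outdir / "qc_scc.tsv", index=True)
    pca = qc.pca_coords.copy()
    pca.index.name = "sample_id"
    pca["explained_pc1"] = qc.explained_variance[0]
    pca["explained_pc2"] = qc.explained_variance[1] if len(qc.explained_variance) > 1 else np.nan
    write_tsv(pca, outdir / "qc_pca.tsv", index=True)
    return {"genes": len(fpkm.gene_ids), "expressed_overall": len(sets.overall)}


def _read_expressed(outdir, stage):
    df = pd.read_csv(_need(outdir, "expressed_sets.tsv", stage), sep="\t",
                     dtype={"timepoint": str})
    per_tp = {tp: set(sub["gene_id"]) for tp, sub in df.groupby("timepoint") if tp != "overall"}
    overall = set(df.loc[df["timepoint"] == "overall", "gene_id"])
    return per_tp, overall


def _stage_de(cfg, outdir):
    counts = read_counts(_input_path(cfg, outdir, "counts", "counts.tsv", "de"),
                         _need(outdir, "samples.tsv", "de"))
    per_tp, _ = _read_expressed(outdir, "de")
    th = cfg["thresholds"]
    results, summary = diffexpr.run_de(counts, expressed_per_timepoint=per_tp,
                                       p_threshold=th["de_p"], lfc_threshold=th["de_lfc"])
    write_tsv(results, outdir / "de_results.tsv")
    summary = summary.reset_index().rename(columns={"index": "contrast"})
    write_tsv(summary, outdir / "de_summary.tsv")
    n_union = int(summary.loc[summary["contrast"] == "union", "n_degs"].iloc[0])
    return {"tests": len(results), "degs_union": n_union}


def _stage_cluster(cfg, outdir):
    fpkm = _read_fpkm(outdir, "cluster")
    de = pd.read_csv(_need(outdir, "de_results.tsv", "cluster"), sep="\t")
    degs = sorted(set(de.loc[de["is_deg"], "gene_id"]))
    if not degs:
        raise ValueError("no DEGs available for clustering")
    means = fpkm.timepoint_means()
    profiles, excluded = coexpress.zscore_profiles(means, genes=degs)
    cc = cfg["cluster"]
    k_max = min(cc["k_max"], len(profiles) - 1)
    best_k, table, assignment = coexpress.select_k(
        profiles, range(cc["k_min"], k_max + 1), seed=cfg["seed"], n_init=cc["n_init"]
    )
    lab = assignment.labels.to_frame().reset_index()
    write_tsv(lab, outdir / "clusters.tsv")
    write_tsv(table, outdir / "silhouette_by_k.tsv")
    cm = assignment.cluster_means.copy()
    cm.index.name = "cluster"
    write_tsv(cm, outdir / "cluster_means.tsv", index=True)
    return {"degs_clustered": len(profiles), "constant_excluded": len(excluded),
            "best_k": best_k, "silhouette": round(assignment.silhouette, 4)}


def _stage_bias(cfg, outdir):
    fpkm = _read_fpkm(outdir, "bias")
    triads = read_triads(_input_path(cfg, outdir, "triads", "triads.tsv", "bias"))
    assignments = triad_bias.classify_all(fpkm, triads,
                                          threshold=cfg["thresholds"]["triad_low"])
    write_tsv(assignments, outdir / "bias_assignments.tsv")
    for include_low, name in ((True, "category_proportions.tsv"),
                              (False, "category_proportions_expressed.tsv")):
        props = triad_bias.category_proportions(assignments, include_low=include_low)
        props = props.reset_index()
        write_tsv(props, outdir / name)
    expressed = assignments.dropna(subset=["fA"])
    coords = triad_bias.ternary_coordinates(expressed[["fA", "fB", "fD"]].to_numpy())
    tern = expressed[["triad_id", "timepoint"]].copy()
    tern["x"] = coords[:, 0]
    tern["y"] = coords[:, 1]
    write_tsv(tern, outdir / "ternary_coords.tsv")
    tables, stability = triad_bias.transitions(assignments)
    for (t1, t2), tab in tables.items():
        write_tsv(tab.reset_index(), outdir / f"transitions_{t1}_{t2}.tsv")
    write_tsv(stability.reset_index(), outdir / "stability.tsv")
    n_cat = assignments.groupby("category").size().to_dict()
    return {"triads": triads.shape[0], "low_cells": n_cat.get(triad_bias.LOW, 0)}


def _stage_enrich(cfg, outdir):
    th = cfg["thresholds"]
    _, overall = _read_expressed(outdir, "enrich")
    clusters = pd.read_csv(_need(outdir, "clusters.tsv", "enrich"), sep="\t")
    tf = read_annotation(_input_path(cfg, outdir, "tf_families", "tf_families.tsv", "enrich"))
    member_sets = {c: set(sub["gene_id"]) & overall
                   for c, sub in clusters.groupby("cluster")}
    tf_res = enrich.fisher_enrichment(member_sets, tf, overall, alpha=th["tf_alpha"])
    write_tsv(tf_res, outdir / "enrichment_tf.tsv")
    mat = enrich.enrichment_matrix(tf_res)
    if len(mat):
        write_tsv(mat.reset_index(), outdir / "enrichment_tf_matrix.tsv")

    assignments = pd.read_csv(_need(outdir, "bias_assignments.tsv", "enrich"), sep="\t",
                              dtype={"timepoint": str})
    triads = read_triads(_input_path(cfg, outdir, "triads", "triads.tsv", "enrich"))
    pathways = read_annotation(_input_path(cfg, outdir, "pathways", "pathways.tsv", "enrich"))
    gene_cols = ["gene_A", "gene_B", "gene_D"]
    expressed_triads = set(
        assignments.loc[assignments["category"] != triad_bias.LOW, "triad_id"]
    )
    background = set(triads.loc[sorted(expressed_triads), gene_cols].to_numpy().ravel())
    cat_sets = {}
    for cat in triad_bias.CATEGORIES:
        tri = set(assignments.loc[assignments["category"] == cat, "triad_id"])
        if tri:
            cat_sets[cat] = set(triads.loc[sorted(tri), gene_cols].to_numpy().ravel())
    pw_res = enrich.fisher_enrichment(cat_sets, pathways, background,
                                      alpha=th["pathway_alpha"])
    write_tsv(pw_res, outdir / "enrichment_pathways.tsv")
    mat = enrich.enrichment_matrix(pw_res)
    if len(mat):
        write_tsv(mat.reset_index(), outdir / "enrichment_pathways_matrix.tsv")
    return {"tf_tests": len(tf_res), "tf_significant": int(tf_res["significant"].sum()),
            "pathway_tests": len(pw_res),
            "pathway_significant": int(pw_res["significant"].sum())}
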