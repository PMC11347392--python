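"""Config-driven orchestration of the full analysis.

Stages run in order: IO/QC -> clustering + two-phase malignancy ->
DEG signatures -> co-localization -> communication, with optional
survival stratification when a cohort file is configured. All stage
randomness derives from one global seed (per-stage seed = seed + stage
index) so stages are reproducible independently.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from sttme import coloc as coloc_mod
from sttme import communication as comm_mod
from sttme import malignancy as mal_mod
from sttme import signatures as sig_mod
from sttme.cluster import normalize
from sttme.errors import ConfigError
from sttme.genome import read_bed
from sttme.io import qc_filter, read_spot_matrix

logger = logging.getLogger(__name__)

DEFAULTS = {
    "seed": 0,
    "out_dir": "sttme_out",
    "inputs": {
        "matrix": None, "features": None, "barcodes": None, "positions": None,
        "genome_bed": None, "gene_sets": None, "regulons": None,
        "lr_db": None, "survival": None, "truth": None,
    },
    "qc": {"min_numi": 500, "min_ngene": 250, "max_mito_frac": 0.05,
           "min_spots_per_gene": 3, "drop_mito_ribo": True,
           "require_in_tissue": True},
    "cluster": {"n_hvg": 3000, "n_pcs": 30, "k_neighbors": 20,
                "resolution": 1.0},
    "malignancy": {"window": 101, "clip": 3.0, "k_phase2": 8,
                   "alpha": 0.01, "min_effect": 1.5},
    "signatures": {"min_pct": 0.1, "logfc_threshold": 0.25, "top_k": 50},
    "coloc": {"gene_a": "MMP7", "gene_b": "APOE", "hi_quantile": 0.75,
              "n_perm": 1000},
    "communication": {"n_perm": 100, "trim": 0.1, "K": 0.5, "n_hill": 1.0},
}

REQUIRED_INPUTS = ["matrix", "features", "barcodes", "positions", "genome_bed"]


@dataclass
class PipelineConfig:
    """Validated, fully-defaulted pipeline configuration."""

    data: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.data[key]

    def hash(self) -> str:
        # out_dir does not affect the analysis, only where it lands
        payload = {k: v for k, v in self.data.items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()


def _merge(defaults: dict, user: dict, path: str = "") -> tuple[dict, list]:
    out = {}
    violations = []
    for key, dv in defaults.items():
        if isinstance(dv, dict):
            sub, v = _merge(dv, user.get(key, {}) or {}, f"{path}{key}.")
            out[key] = sub
            violations += v
        else:
            out[key] = user.get(key, dv)
    for key in user:
        if key not in defaults:
            violations.append(f"unknown key {path}{key}")
    return out, violations


def _range_checks(cfg: dict) -> list:
    v = []
    qc = cfg["qc"]
    if not 0 <= qc["max_mito_frac"] <= 1:
        v.append("qc.max_mito_frac must be in [0, 1]")
    for k in ("min_numi", "min_ngene", "min_spots_per_gene"):
        if qc[k] < 0:
            v.append(f"qc.{k} must be nonnegative")
    mal = cfg["malignancy"]
    if mal["window"] < 1 or mal["window"] % 2 == 0:
        v.append("malignancy.window must be a positive odd integer")
    if not 0 < mal["alpha"] < 1:
        v.append("malignancy.alpha must be in (0, 1)")
    if mal["k_phase2"] < 1:
        v.append("malignancy.k_phase2 must be >= 1")
    cl = cfg["cluster"]
    if cl["resolution"] <= 0:
        v.append("cluster.resolution must be > 0")
    if cl["n_pcs"] < 1 or cl["n_hvg"] < 1 or cl["k_neighbors"] < 1:
        v.append("cluster sizes must be >= 1")
    co = cfg["coloc"]
    if not 0 < co["hi_quantile"] < 1:
        v.append("coloc.hi_quantile must be in (0, 1)")
    cm = cfg["communication"]
    if cm["n_perm"] < 20:
        v.append("communication.n_perm must be >= 20")
    if cm["K"] <= 0:
        v.append("communication.K must be > 0")
    return v


def validate_config(path) -> PipelineConfig:
    """Parse, default, and range-check a YAML config; raise ConfigError
    with the full list of violations otherwise."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg, violations = _merge(DEFAULTS, user)
    violations += _range_checks(cfg)
    for key in REQUIRED_INPUTS:
        if cfg["inputs"][key] is None:
            violations.append(f"inputs.{key} is required")
        elif not Path(cfg["inputs"][key]).exists():
            violations.append(f"inputs.{key}: file not found: {cfg['inputs'][key]}")
    if violations:
        raise ConfigError("; ".join(violations))
    return PipelineConfig(data=cfg)


def _report_hash(report: dict) -> str:
    payload = {k: v for k, v in report.items()
               if k not in ("report_hash", "parameters")}
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the run report (also written to disk)."""
    from sttme import __version__

    cfg = config.data
    seed = int(cfg["seed"])
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "config_hash": config.hash(),
                    "parameters": cfg, "stages": {}}

    inputs = cfg["inputs"]
    m = read_spot_matrix(inputs["matrix"], inputs["features"],
                         inputs["barcodes"], inputs["positions"])
    genome = read_bed(inputs["genome_bed"])
    m, qc_report = qc_filter(m, **cfg["qc"])
    qc_report.to_json(out_dir / "qc_report.json")
    report["stages"]["qc"] = {"spots": [qc_report.spots_in, qc_report.spots_out],
                              "genes": [qc_report.genes_in, qc_report.genes_out]}

    res = mal_mod.two_phase_identify(
        m, genome,
        n_hvg=cfg["cluster"]["n_hvg"], n_pcs=cfg["cluster"]["n_pcs"],
        k_neighbors=min(cfg["cluster"]["k_neighbors"], m.n_spots - 1),
        resolution=cfg["cluster"]["resolution"],
        window=cfg["malignancy"]["window"], clip=cfg["malignancy"]["clip"],
        k_phase2=cfg["malignancy"]["k_phase2"], alpha=cfg["malignancy"]["alpha"],
        min_effect=cfg["malignancy"]["min_effect"], seed=seed + 1)
    cr = res.cnv_result
    calls = cr.calls_frame()
    calls["immune_score"] = res.immune_scores
    calls["epithelial_score"] = res.epithelial_scores
    calls.to_csv(out_dir / "malignant_calls.csv", index=False)
    call_counts = calls["call"].value_counts().to_dict()
    report["stages"]["malignancy"] = {
        "reference_cluster": int(res.reference_cluster),
        "n_phase1_clusters": int(res.phase1.n_clusters),
        "call_counts": {k: int(v) for k, v in sorted(call_counts.items())},
        "epithelial_median_by_call": {k: round(v, 6) for k, v in
                                      sorted(res.epithelial_by_call.items())},
    }
    if inputs.get("truth"):
        truth = pd.read_csv(inputs["truth"]).set_index("barcode")
        truth = truth.reindex(calls["barcode"])
        pred = (calls["call"] == "malignant").to_numpy()
        actual = truth["malignant"].to_numpy(bool)
        tp = int((pred & actual).sum())
        prec = tp / max(int(pred.sum()), 1)
        rec = tp / max(int(actual.sum()), 1)
        report["stages"]["malignancy"]["precision_vs_truth"] = round(prec, 6)
        report["stages"]["malignancy"]["recall_vs_truth"] = round(rec, 6)

    nm = normalize(m, method="log_cpm")
    deg = sig_mod.wilcoxon_deg(nm, res.phase1,
                               min_pct=cfg["signatures"]["min_pct"],
                               logfc_threshold=cfg["signatures"]["logfc_threshold"])
    deg.to_csv(out_dir / "deg_table.csv", index=False)
    signatures = {}
    for c in range(res.phase1.n_clusters):
        sig = sig_mod.top_signature(deg, c, k=cfg["signatures"]["top_k"])
        signatures[c] = sig.genes
    report["stages"]["signatures"] = {
        "n_deg_rows": int(len(deg)),
        "signature_sizes": {int(c): len(g) for c, g in signatures.items()},
    }

    survival = inputs.get("survival")
    if survival and Path(survival).exists():
        cohort = sig_mod.SurvivalCohort.read_csv(survival)
        cohort_genes = set(cohort.expression.index)
        best_sig = max(signatures.items(),
                       key=lambda kv: len(cohort_genes & set(kv[1])))
        try:
            score = sig_mod.score_bulk_signature(
                cohort, sig_mod.Signature(name=f"cluster{best_sig[0]}",
                                          genes=best_sig[1]))
            km = sig_mod.km_logrank(cohort, score)
            report["stages"]["survival"] = {
                "signature_cluster": int(best_sig[0]),
                "logrank_statistic": round(km.statistic, 6),
                "logrank_p": round(km.p_value, 8),
            }
        except Exception as exc:  # optional stage: log and continue
            logger.warning("survival stage skipped: %s", exc)
            report["stages"]["survival"] = {"skipped": str(exc)}

    gene_set = set(m.gene_ids)
    ga, gb = cfg["coloc"]["gene_a"], cfg["coloc"]["gene_b"]
    if ga in gene_set and gb in gene_set:
        graph = coloc_mod.hex_neighbor_graph(m.positions)
        obs, z, p = coloc_mod.neighborhood_coloc(
            nm, graph, ga, gb, hi_quantile=cfg["coloc"]["hi_quantile"],
            n_perm=cfg["coloc"]["n_perm"], seed=seed + 2)
        rho, rho_p = coloc_mod.expression_correlation(nm, ga, gb)
        report["stages"]["coloc"] = {
            "pair": [ga, gb], "observed_edges": int(obs),
            "z": round(z, 6), "p": round(p, 8),
            "spearman_rho": round(rho, 6), "spearman_p": round(rho_p, 8),
        }
    else:
        report["stages"]["coloc"] = {"skipped": f"{ga}/{gb} not in matrix"}

    db = comm_mod.LRDatabase.read_csv(inputs["lr_db"]) if inputs.get("lr_db") \
        else comm_mod.LRDatabase.builtin()
    try:
        ct = comm_mod.permutation_significance(
            nm, res.phase1, db, n_perm=cfg["communication"]["n_perm"],
            seed=seed + 3, trim=cfg["communication"]["trim"],
            K=cfg["communication"]["K"], n_hill=cfg["communication"]["n_hill"])
        agg = comm_mod.aggregate(ct)
        report["stages"]["communication"] = {
            "ranked_pathways": agg["ranked_pathways"],
            "outgoing_strength": [round(float(x), 6)
                                  for x in agg["outgoing_strength"]],
            "incoming_strength": [round(float(x), 6)
                                  for x in agg["incoming_strength"]],
            "top_sender": int(np.argmax(agg["outgoing_strength"])),
            "top_receiver": int(np.argmax(agg["incoming_strength"])),
        }
    except Exception as exc:
        logger.warning("communication stage skipped: %s", exc)
        report["stages"]["communication"] = {"skipped": str(exc)}

    report["report_hash"] = _report_hash(report)
    (out_dir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=str))
    _write_markdown(report, out_dir / "report.md")
    return report


def _write_markdown(report: dict, path: Path) -> None:
    lines = [f"# sttme run report", "",
             f"- version: {report['version']}",
             f"- config hash: `{report['config_hash']}`",
             f"- report hash: `{report['report_hash']}`", ""]
    for stage, body in report["stages"].items():
        lines.append(f"## {stage}")
        lines.append("```json")
        lines.append(json.dumps(body, indent=2, sort_keys=True, default=str))
        lines.append("```")
        lines.append("")
    path.write_text("\n".join(lines))
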