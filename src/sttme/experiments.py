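"""Reproducible validation experiments on synthetic data.

Each function generates its own data with the study's default
conditions, runs the corresponding analysis end to end, and returns the
summary quantity (a recovery rate, a type-I error, a power estimate,
...). They back both the validation test suite and the reproduction
script, so the numbers reported anywhere are always recomputed from
scratch.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from sttme import coloc as coloc_mod
from sttme import communication as comm_mod
from sttme import malignancy as mal_mod
from sttme import signatures as sig_mod
from sttme.cluster import (ClusterAssignment, NormalizedMatrix, cluster_graph,
                           embed_pca, normalize, select_hvg)
from sttme.synth import (make_section, simulate_bulk_cohort, simulate_if_cells)

# analysis operating point for the bundled synthetic tissue: the planted
# arm-level fold-2 gain puts malignant clusters at >7x the reference
# CNV-score median while cell-type pseudo-signal stays below ~2x, so the
# malignancy effect threshold sits between the two bands
SECTION_PARAMS = dict(n_spots=500, n_genes=2000, n_chroms=10, tumour_frac=0.3,
                      cnv_genes=200, cnv_fold=2.0)
MIN_EFFECT = 3.0


def _seeds(seed: int, n: int, salt: int) -> list[int]:
    ss = np.random.SeedSequence([seed, salt])
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(n)]


def malignant_recovery(n_seeds: int = 10, seed: int = 0) -> dict:
    """Spot-level precision/recall of two-phase identification vs truth."""
    precs, recs = [], []
    for s in _seeds(seed, n_seeds, salt=1):
        m, genome, truth = make_section(seed=s, **SECTION_PARAMS)
        res = mal_mod.two_phase_identify(m, genome, seed=s, k_phase2=8,
                                         min_effect=MIN_EFFECT)
        pred = res.cnv_result.call == "malignant"
        tp = int((pred & truth.malignant).sum())
        precs.append(tp / max(int(pred.sum()), 1))
        recs.append(tp / max(int(truth.malignant.sum()), 1))
    return {"precision_mean": float(np.mean(precs)),
            "recall_mean": float(np.mean(recs)),
            "precision_min": float(np.min(precs)),
            "recall_min": float(np.min(recs)), "n": n_seeds}


def false_positive_control(n_sims: int = 100, seed: int = 0) -> dict:
    """Fraction of no-CNV simulations with zero malignant calls (k=4)."""
    params = dict(SECTION_PARAMS, cnv_fold=1.0)
    clean = 0
    for s in _seeds(seed, n_sims, salt=2):
        m, genome, _ = make_section(seed=s, **params)
        res = mal_mod.two_phase_identify(m, genome, seed=s, k_phase2=4,
                                         min_effect=MIN_EFFECT)
        clean += int((res.cnv_result.call == "malignant").sum() == 0)
    return {"fraction_zero_calls": clean / n_sims, "n": n_sims}


def reference_selection(n_sims: int = 100, seed: int = 0) -> dict:
    """How often the planted immune region supplies the reference cluster."""
    hits = 0
    for s in _seeds(seed, n_sims, salt=3):
        m, genome, truth = make_section(seed=s, **SECTION_PARAMS)
        nm = normalize(m, method="log_cpm")
        hvg = select_hvg(nm, n=1000)
        scores = embed_pca(nm, n_pcs=30, hvg_mask=hvg)
        ca = cluster_graph(scores, seed=s)
        imm = mal_mod.panel_score(nm, mal_mod.immune_panel())
        ref = mal_mod.select_reference_cluster(imm, ca)
        regions = truth.region[ca.labels == ref]
        hits += int(pd.Series(regions).mode()[0] == "immune_infiltrate")
    return {"fraction_immune_selected": hits / n_sims, "n": n_sims}


def naive_window_smooth(E: np.ndarray, chroms: np.ndarray, window: int) -> np.ndarray:
    """Literal O(n*w) loop implementation of per-chromosome truncated
    moving-average smoothing — the reference oracle for infer_cnv."""
    out = np.empty_like(E)
    h = window // 2
    for chrom in dict.fromkeys(chroms):
        cols = np.flatnonzero(chroms == chrom)
        for ji, j in enumerate(cols):
            lo, hi = max(ji - h, 0), min(ji + h, len(cols) - 1)
            out[:, j] = E[:, cols[lo:hi + 1]].mean(axis=1)
    return out


def smoothing_oracle_deviation(n_spots: int = 20, n_genes: int = 500,
                               window: int = 101, seed: int = 0) -> float:
    """Max |difference| between the fast smoother and the naive loop."""
    from sttme.malignancy import _truncated_moving_average

    rng = np.random.default_rng(seed)
    E = rng.normal(size=(n_spots, n_genes))
    n_chrom = 3
    chroms = np.repeat([f"chr{i}" for i in range(n_chrom)],
                       np.diff(np.linspace(0, n_genes, n_chrom + 1).astype(int)))
    fast = np.empty_like(E)
    for chrom in dict.fromkeys(chroms):
        sel = chroms == chrom
        fast[:, sel] = _truncated_moving_average(E[:, sel], window)
    slow = naive_window_smooth(E, chroms, window)
    return float(np.max(np.abs(fast - slow)))


def wilcoxon_type1(n_spots: int = 200, n_genes: int = 1000, n_reps: int = 5,
                   seed: int = 0) -> dict:
    """Fraction of raw DEG p-values below .05 under label-shuffled nulls.

    Pooled over independent datasets/shuffles: within one shuffle the
    per-gene tests share the same labels and are weakly correlated.
    """
    import scipy.sparse as sp
    from sttme.io import SpotMatrix

    below, total = 0, 0
    for s in _seeds(seed, n_reps, salt=10):
        rng = np.random.default_rng(s)
        counts = rng.negative_binomial(5, 0.2, size=(n_spots, n_genes))
        counts[:, 0] += 1  # guard against zero-count spots
        barcodes = [f"S{i}" for i in range(n_spots)]
        pos = pd.DataFrame({"in_tissue": 1, "array_row": np.arange(n_spots),
                            "array_col": np.arange(n_spots) % 2},
                           index=pd.Index(barcodes, name="barcode"))
        m = SpotMatrix(counts=sp.csr_matrix(counts),
                       barcodes=np.array(barcodes, object),
                       gene_ids=np.array([f"G{j}" for j in range(n_genes)], object),
                       positions=pos)
        nm = normalize(m, method="log_cpm")
        labels = rng.permutation(np.arange(n_spots) % 2)
        ca = ClusterAssignment(labels=labels, method="graph")
        deg = sig_mod.wilcoxon_deg(nm, ca, min_pct=0.0, logfc_threshold=0.0)
        one_side = deg[deg["cluster"] == 0]
        below += int((one_side["p_value"] < 0.05).sum())
        total += int(len(one_side))
    return {"fraction_p_below_05": below / total, "n": total}


def logrank_type1(n_reps: int = 500, n_patients: int = 60, seed: int = 0) -> dict:
    """Log-rank rejection rate at alpha=.05 when the hazard ratio is 1."""
    rejections = 0
    for s in _seeds(seed, n_reps, salt=4):
        cohort = simulate_bulk_cohort(n_patients, ["SIG1", "SIG2"],
                                      log_hazard_ratio=0.0, censor_rate=0.2,
                                      seed=s, n_noise_genes=0)
        sc = sig_mod.SurvivalCohort.from_bulk(cohort)
        score = sig_mod.score_bulk_signature(
            sc, sig_mod.Signature(name="sig", genes=["SIG1", "SIG2"]))
        km = sig_mod.km_logrank(sc, score)
        rejections += int(km.p_value < 0.05)
    return {"rejection_rate": rejections / n_reps, "n": n_reps}


def logrank_power(n_reps: int = 200, n_patients: int = 200, seed: int = 0) -> dict:
    """Log-rank rejection rate at HR=2, and how often high fares worse."""
    rejections, high_worse = 0, 0
    for s in _seeds(seed, n_reps, salt=5):
        cohort = simulate_bulk_cohort(n_patients, ["SIG1", "SIG2", "SIG3"],
                                      log_hazard_ratio=np.log(2.0),
                                      censor_rate=0.2, seed=s, n_noise_genes=0)
        sc = sig_mod.SurvivalCohort.from_bulk(cohort)
        score = sig_mod.score_bulk_signature(
            sc, sig_mod.Signature(name="sig", genes=["SIG1", "SIG2", "SIG3"]))
        km = sig_mod.km_logrank(sc, score)
        rejections += int(km.p_value < 0.05)
        high_worse += int(km.km_high.median_survival_time_
                          < km.km_low.median_survival_time_)
    return {"rejection_rate": rejections / n_reps,
            "high_group_worse_rate": high_worse / n_reps, "n": n_reps}


def _two_cluster_expression(n_spots: int, seed: int, boost: float = 0.0):
    """Small two-cluster dataset over the built-in LR genes: cluster 0
    overexpresses MIF (sender), cluster 1 overexpresses CD74/CXCR4
    (receiver) when ``boost`` > 0."""
    rng = np.random.default_rng(seed)
    genes = sorted({g for _, _, ls, rs in comm_mod.BUILTIN_LR for g in ls + rs})
    labels = np.arange(n_spots) % 2
    values = rng.lognormal(mean=0.0, sigma=0.3, size=(n_spots, len(genes)))
    gi = {g: j for j, g in enumerate(genes)}
    if boost > 0:
        values[labels == 0, gi["MIF"]] *= boost
        values[labels == 1, gi["CD74"]] *= boost
        values[labels == 1, gi["CXCR4"]] *= boost
    nm = NormalizedMatrix(values=values,
                          barcodes=np.array([f"S{i}" for i in range(n_spots)], object),
                          gene_ids=np.array(genes, object), method="log_cpm")
    return nm, ClusterAssignment(labels=labels, method="graph")


def communication_uniformity(n_spots: int = 120, n_perm: int = 100,
                             n_reps: int = 20, seed: int = 0) -> dict:
    """Fraction of permutation p-values below .05 on exchangeable labels.

    Pooled over independent replicate datasets: within one dataset the
    tensor cells share permutations and are correlated, so a single
    dataset estimates the null rate too coarsely.
    """
    below, total = 0, 0
    for s in _seeds(seed, n_reps, salt=9):
        nm, ca = _two_cluster_expression(n_spots, s, boost=0.0)
        ct = comm_mod.permutation_significance(
            nm, ca, comm_mod.LRDatabase.builtin(), n_perm=n_perm, seed=s)
        below += int((ct.pval < 0.05).sum())
        total += int(ct.pval.size)
    return {"fraction_p_below_05": below / total, "n": total}


def mif_power(n_reps: int = 50, n_spots: int = 120, n_perm: int = 100,
              seed: int = 0) -> dict:
    """How often the planted MIF sender->receiver pair attains the minimal
    permutation p-value for both MIF interactions."""
    hits = 0
    for s in _seeds(seed, n_reps, salt=6):
        nm, ca = _two_cluster_expression(n_spots, s, boost=10.0)
        ct = comm_mod.permutation_significance(
            nm, ca, comm_mod.LRDatabase.builtin(), n_perm=n_perm, seed=s)
        p_min = 1.0 / (n_perm + 1)
        mif_idx = [i for i, pw in enumerate(ct.pathways) if pw == "MIF"]
        hits += int(all(ct.pval[0, 1, i] <= p_min + 1e-12 for i in mif_idx))
    return {"minimal_p_rate": hits / n_reps, "n": n_reps}


def roi_power(n_reps: int = 200, n_rois: int = 10, cells_per_roi: int = 500,
              coloc_effect: float = 3.0, seed: int = 0) -> dict:
    """Rejection rate of the one-sided ROI comparison at the planted effect."""
    rejections = 0
    for s in _seeds(seed, n_reps, salt=7):
        ds = simulate_if_cells(n_rois, cells_per_roi, coloc_effect, seed=s)
        rule = coloc_mod.otsu_rule(ds.cells)
        res = coloc_mod.roi_compare(ds.cells, rule, ds.roi_class)
        rejections += int(res["CD14+APOE+"]["p"] < 0.05)
    return {"rejection_rate": rejections / n_reps, "n": n_reps}


def coloc_recovery(n_reps: int = 50, seed: int = 0) -> dict:
    """Spatial co-localization of the planted MMP7/APOE pair: rejection
    rate of the edge-count permutation test on the default tissue."""
    hits = 0
    zs = []
    for s in _seeds(seed, n_reps, salt=8):
        m, genome, _ = make_section(seed=s, **SECTION_PARAMS)
        nm = normalize(m, method="log_cpm")
        graph = coloc_mod.hex_neighbor_graph(m.positions)
        _, z, p = coloc_mod.neighborhood_coloc(nm, graph, "MMP7", "APOE",
                                               n_perm=200, seed=s)
        hits += int(p < 0.05)
        zs.append(z)
    return {"rejection_rate": hits / n_reps, "mean_z": float(np.mean(zs)),
            "n": n_reps}


def write_demo_fixture(out_dir, seed: int = 0) -> Path:
    """Write a complete synthetic fixture + pipeline config; returns the
    config path."""
    import yaml

    from sttme.genome import write_bed
    from sttme.io import write_spot_matrix
    from sttme.synth import write_truth

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    m, genome, truth = make_section(seed=seed, **SECTION_PARAMS)
    write_spot_matrix(m, out)
    write_bed(genome, out / "genome.bed")
    write_truth(truth, m.barcodes, out / "truth.csv")
    cohort = simulate_bulk_cohort(200, truth.signature_genes,
                                  log_hazard_ratio=np.log(2.0),
                                  censor_rate=0.2, seed=seed)
    cohort.to_csv(out / "cohort.csv")
    config = {
        "seed": seed,
        "out_dir": str(out / "results"),
        "inputs": {
            "matrix": str(out / "matrix.mtx"),
            "features": str(out / "features.tsv"),
            "barcodes": str(out / "barcodes.tsv"),
            "positions": str(out / "tissue_positions.csv"),
            "genome_bed": str(out / "genome.bed"),
            "truth": str(out / "truth.csv"),
            "survival": str(out / "cohort.csv"),
        },
        "qc": {"min_numi": 500, "min_ngene": 250},
        "malignancy": {"min_effect": MIN_EFFECT},
    }
    cfg_path = out / "config.yaml"
    cfg_path.write_text(yaml.safe_dump(config))
    return cfg_path


def pipeline_determinism(workdir, seed: int = 0) -> dict:
    """Run the pipeline twice on the bundled fixture; compare report hashes."""
    from sttme.pipeline import run_pipeline, validate_config

    workdir = Path(workdir)
    cfg_path = write_demo_fixture(workdir / "fixture", seed=seed)
    hashes = []
    for run in (1, 2):
        cfg = validate_config(cfg_path)
        cfg.data["out_dir"] = str(workdir / f"run{run}")
        report = run_pipeline(cfg)
        hashes.append(report["report_hash"])
    return {"identical": int(hashes[0] == hashes[1]), "hashes": hashes,
            "n": 2}
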