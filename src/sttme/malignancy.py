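"""Two-phase malignant-spot identification via immune-score-guided CNV inference.

Phase 1 clusters spots on expression and picks the cluster with the
highest immune score as the copy-number-neutral reference. Phase 2
infers a smoothed copy-number profile for every spot against that
reference (log expression, reference centering, clipping, per-chromosome
moving average, spot re-centering, reference re-baselining), summarizes
it as a per-spot CNV score (mean of squares), hierarchically clusters
the non-reference spots on the CNV matrix, and calls a cluster malignant
when its CNV scores are both significantly and substantially elevated
over the reference.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from sttme.cluster import (ClusterAssignment, NormalizedMatrix, cluster_graph,
                           cluster_hierarchical, embed_pca, normalize, select_hvg)
from sttme.errors import InvalidArgumentError, SttmeError
from sttme.genome import GenomeModel
from sttme.io import SpotMatrix

logger = logging.getLogger(__name__)

IMMUNE_PANEL_GENES = ["PTPRC", "CD2", "CD3D", "CD3E", "CD3G",
                      "CD79A", "MS4A1", "CD79B", "CD68", "CD14"]
EPITHELIAL_PANEL_GENES = ["EPCAM", "KRT8", "KRT19"]


@dataclass
class MarkerPanel:
    """A named, non-empty set of marker gene symbols."""

    name: str
    genes: list

    def __post_init__(self) -> None:
        if not self.genes:
            raise InvalidArgumentError("panel must be non-empty")
        if len(set(self.genes)) != len(self.genes):
            raise InvalidArgumentError("panel genes must be unique")


def immune_panel() -> MarkerPanel:
    """Pan-immune, T-, B- and myeloid-cell markers used for the immune score."""
    return MarkerPanel(name="immune", genes=list(IMMUNE_PANEL_GENES))


def epithelial_panel() -> MarkerPanel:
    """Tumour-related epithelial markers (EPCAM/KRT8/KRT19)."""
    return MarkerPanel(name="epithelial", genes=list(EPITHELIAL_PANEL_GENES))


@dataclass
class CNVResult:
    """Smoothed CNV matrix with per-spot scores and malignancy calls."""

    cnv: np.ndarray                   # spots x ordered genes
    gene_ids: np.ndarray              # genome order
    barcodes: np.ndarray
    reference_spots: np.ndarray       # boolean mask over spots
    reference_cluster: int | None = None
    cnv_scores: np.ndarray | None = None
    call: np.ndarray | None = None    # {"reference","malignant","other"}
    phase2: ClusterAssignment | None = None

    def calls_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"barcode": self.barcodes, "call": self.call,
                             "cnv_score": self.cnv_scores})


def panel_score(nm: NormalizedMatrix, panel: MarkerPanel) -> np.ndarray:
    """Per-spot arithmetic mean of normalized expression over panel genes.

    Genes absent from the matrix are logged and skipped; at least one
    must be present.
    """
    present = [g for g in panel.genes if g in set(nm.gene_ids)]
    missing = sorted(set(panel.genes) - set(present))
    if missing:
        logger.warning("panel %s: %d genes absent, skipped: %s",
                       panel.name, len(missing), missing)
    if not present:
        raise SttmeError(f"no gene of panel {panel.name!r} present in matrix")
    idx = [nm.gene_index(g) for g in present]
    return nm.values[:, idx].mean(axis=1)


def compare_scores_across_clusters(scores: np.ndarray, ca: ClusterAssignment,
                                   ) -> tuple[float, float, dict]:
    """Kruskal-Wallis comparison of a per-spot score across clusters."""
    groups = [scores[ca.spots_in(c)] for c in range(ca.n_clusters)]
    groups = [g for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise SttmeError("need >= 2 non-empty clusters")
    if np.ptp(np.concatenate(groups)) == 0:  # scipy rejects all-identical data
        h, p = 0.0, 1.0
    else:
        h, p = scipy.stats.kruskal(*groups)
    medians = {c: float(np.median(scores[ca.spots_in(c)]))
               for c in range(ca.n_clusters)}
    return float(h), float(p), medians


def select_reference_cluster(scores: np.ndarray, ca: ClusterAssignment) -> int:
    """Cluster with the highest mean spot score; ties -> lowest cluster id."""
    if ca.n_clusters < 2:
        raise SttmeError("need >= 2 clusters to select a reference")
    means = np.array([scores[ca.spots_in(c)].mean() for c in range(ca.n_clusters)])
    return int(np.argmax(means))  # argmax returns first (lowest id) on ties


def _truncated_moving_average(X: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along columns with truncated edge windows.

    For column j the window covers columns [j-h, j+h] intersected with
    the valid range (h = window//2); edge means use the genes actually
    available rather than reflected or zero padding.
    """
    n = X.shape[1]
    h = window // 2
    cs = np.cumsum(X, axis=1)
    cs = np.concatenate([np.zeros((X.shape[0], 1)), cs], axis=1)
    lo = np.maximum(np.arange(n) - h, 0)
    hi = np.minimum(np.arange(n) + h, n - 1)
    sums = cs[:, hi + 1] - cs[:, lo]
    return sums / (hi - lo + 1)


def infer_cnv(m: SpotMatrix, genome: GenomeModel, reference_spots,
              window: int = 101, clip: float = 3.0) -> CNVResult:
    """Windowed expression-based CNV inference against a reference spot set.

    Pipeline: log2(count/nUMI*1e4 + 1) -> subtract per-gene reference
    mean -> clip to +/-clip -> per-chromosome centered moving average of
    width ``window`` (truncated at chromosome edges; smoothing never
    crosses a chromosome boundary) -> subtract per-spot median ->
    subtract the per-gene reference mean of the smoothed values.
    Genes without genome annotation are dropped with a warning.
    """
    if window < 1 or window % 2 == 0:
        raise InvalidArgumentError("window must be a positive odd integer")
    reference_spots = np.asarray(reference_spots)
    if reference_spots.dtype == bool:
        if len(reference_spots) != m.n_spots:
            raise InvalidArgumentError("boolean reference mask has wrong length")
        ref = reference_spots.copy()
    else:
        ref = np.zeros(m.n_spots, bool)
        ref[reference_spots] = True
    if not ref.any():
        raise InvalidArgumentError("reference spot set is empty")
    if ref.all():
        raise InvalidArgumentError("reference must be a strict subset of spots")

    ordered, chroms = genome.genome_order(m.gene_ids)
    dropped = m.n_genes - len(ordered)
    if dropped:
        warnings.warn(f"{dropped} genes lack genome annotation and were dropped")
    if len(ordered) < window:
        raise SttmeError(f"only {len(ordered)} annotated genes for window={window}")
    col = {g: i for i, g in enumerate(m.gene_ids)}
    idx = [col[g] for g in ordered]
    X = np.asarray(m.counts[:, idx].todense(), dtype=float)
    n_umi = m.n_umi
    if (n_umi == 0).any():
        raise InvalidArgumentError("zero-count spot present")

    E = np.log2(X / n_umi[:, None] * 1e4 + 1.0)
    E -= E[ref].mean(axis=0)
    np.clip(E, -clip, clip, out=E)

    smooth = np.empty_like(E)
    for chrom in dict.fromkeys(chroms):
        sel = chroms == chrom
        smooth[:, sel] = _truncated_moving_average(E[:, sel], window)

    smooth -= np.median(smooth, axis=1, keepdims=True)
    smooth -= smooth[ref].mean(axis=0)
    return CNVResult(cnv=smooth, gene_ids=ordered, barcodes=m.barcodes,
                     reference_spots=ref)


def cnv_score(cr: CNVResult) -> np.ndarray:
    """Per-spot mean of squared smoothed CNV values (filled into ``cr``)."""
    scores = np.mean(cr.cnv ** 2, axis=1)
    cr.cnv_scores = scores
    return scores


def call_malignant(cr: CNVResult, k: int, alpha: float = 0.01,
                   min_effect: float = 1.5) -> CNVResult:
    """Cluster non-reference spots on the CNV matrix and call malignancy.

    A phase-2 cluster is called malignant iff a one-sided Mann-Whitney
    test of its CNV scores against the reference scores is significant at
    ``alpha`` after Bonferroni correction over the ``k`` clusters AND its
    median score is at least ``min_effect`` times the reference median.
    """
    if cr.cnv_scores is None:
        cnv_score(cr)
    nonref = ~cr.reference_spots
    if not nonref.any():
        raise SttmeError("all spots are reference; nothing to call")
    n_nonref = int(nonref.sum())
    if n_nonref < k:
        raise InvalidArgumentError(f"k={k} exceeds {n_nonref} non-reference spots")

    phase2 = cluster_hierarchical(cr.cnv[nonref], k=k, provenance="phase-2")
    ref_scores = cr.cnv_scores[cr.reference_spots]
    ref_median = np.median(ref_scores)
    call = np.array(["reference"] * len(cr.barcodes), dtype=object)
    nonref_idx = np.flatnonzero(nonref)
    for c in range(phase2.n_clusters):
        spots = nonref_idx[phase2.spots_in(c)]
        scores = cr.cnv_scores[spots]
        if len(scores) == 0:
            continue
        _, p = scipy.stats.mannwhitneyu(scores, ref_scores, alternative="greater")
        significant = p * k < alpha
        ratio = np.median(scores) / ref_median if ref_median > 0 else np.inf
        call[spots] = "malignant" if (significant and ratio >= min_effect) else "other"
    cr.call = call
    cr.phase2 = phase2
    return cr


@dataclass
class TwoPhaseResult:
    """All intermediates of the two-phase identification."""

    cnv_result: CNVResult
    phase1: ClusterAssignment
    immune_scores: np.ndarray
    epithelial_scores: np.ndarray
    reference_cluster: int
    kruskal: tuple = field(default_factory=tuple)
    epithelial_by_call: dict = field(default_factory=dict)


def two_phase_identify(m: SpotMatrix, genome: GenomeModel,
                       immune: MarkerPanel | None = None,
                       epithelial: MarkerPanel | None = None,
                       n_hvg: int = 1000, n_pcs: int = 30,
                       k_neighbors: int = 20, resolution: float = 1.0,
                       window: int = 101, clip: float = 3.0,
                       k_phase2: int = 8, alpha: float = 0.01,
                       min_effect: float = 1.5, seed: int = 0,
                       ) -> TwoPhaseResult:
    """Run the full two-phase malignant-spot identification.

    Composes normalization -> HVG -> PCA -> SNN graph clustering ->
    immune panel scoring -> reference cluster selection -> CNV inference
    -> CNV scoring -> phase-2 hierarchical clustering -> malignancy
    calling, and reports the epithelial score per call group.
    """
    immune = immune or immune_panel()
    epithelial = epithelial or epithelial_panel()

    nm = normalize(m, method="log_cpm")
    hvg = select_hvg(nm, n=min(n_hvg, nm.n_genes))
    scores = embed_pca(nm, n_pcs=min(n_pcs, min(m.n_spots, int(hvg.sum()))), hvg_mask=hvg)
    phase1 = cluster_graph(scores, k_neighbors=k_neighbors,
                           resolution=resolution, seed=seed)

    imm = panel_score(nm, immune)
    epi = panel_score(nm, epithelial)
    kw = compare_scores_across_clusters(imm, phase1) if phase1.n_clusters > 1 else ()
    ref_cluster = select_reference_cluster(imm, phase1)
    ref_mask = phase1.labels == ref_cluster

    cr = infer_cnv(m, genome, ref_mask, window=window, clip=clip)
    cr.reference_cluster = ref_cluster
    cnv_score(cr)
    k_eff = min(k_phase2, int((~ref_mask).sum()))
    call_malignant(cr, k=k_eff, alpha=alpha, min_effect=min_effect)

    epithelial_by_call = {grp: float(np.median(epi[cr.call == grp]))
                          for grp in np.unique(cr.call)}
    return TwoPhaseResult(cnv_result=cr, phase1=phase1, immune_scores=imm,
                          epithelial_scores=epi, reference_cluster=ref_cluster,
                          kruskal=kw, epithelial_by_call=epithelial_by_call)
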