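"""Normalization, variable-gene selection, embedding and spot clustering.

Phase-1 clustering of the malignancy workflow operates on expression
(log-CPM or Pearson residuals -> HVGs -> PCA -> shared-nearest-neighbour
graph with modularity communities); phase 2 reuses the hierarchical
clustering here on smoothed CNV matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.cluster.hierarchy as sch
import scipy.sparse as sp
import igraph as ig
import leidenalg
from sklearn.neighbors import NearestNeighbors

from sttme.errors import InvalidArgumentError
from sttme.io import SpotMatrix


@dataclass
class NormalizedMatrix:
    """Dense normalized spot x gene matrix, same ordering as its source."""

    values: np.ndarray
    barcodes: np.ndarray
    gene_ids: np.ndarray
    method: str
    hvg_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise InvalidArgumentError("normalized matrix contains non-finite values")

    @property
    def n_spots(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene: str) -> int:
        idx = np.flatnonzero(self.gene_ids == gene)
        if len(idx) == 0:
            raise KeyError(gene)
        return int(idx[0])


@dataclass
class ClusterAssignment:
    """Per-spot integer labels, contiguous from 0, with provenance."""

    labels: np.ndarray
    method: str                    # "graph" | "hierarchical"
    parameters: dict = field(default_factory=dict)
    provenance: str = "phase-1"    # "phase-1" | "phase-2"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        uniq = np.unique(self.labels)
        if len(uniq) and not np.array_equal(uniq, np.arange(len(uniq))):
            raise InvalidArgumentError("labels must be contiguous from 0")

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))

    def spots_in(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)


def _relabel_contiguous(labels: np.ndarray) -> np.ndarray:
    """Relabel to 0..k-1 in order of first occurrence (deterministic)."""
    mapping: dict[int, int] = {}
    out = np.empty(len(labels), int)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def normalize(m: SpotMatrix, method: str = "log_cpm",
              theta: float = 100.0) -> NormalizedMatrix:
    """Variance-stabilize counts.

    ``log_cpm``: log1p(count / nUMI * 1e4). ``pearson_residual``:
    (x - mu) / sqrt(mu + mu^2/theta) under a constant-overdispersion NB
    null with gene-wise mu proportional to the spot's nUMI, clipped to
    +/- sqrt(n_spots).
    """
    n_umi = m.n_umi
    if (n_umi == 0).any():
        raise InvalidArgumentError("zero-count spot present; run QC first")
    X = np.asarray(m.counts.todense(), dtype=float)
    if method == "log_cpm":
        values = np.log1p(X / n_umi[:, None] * 1e4)
    elif method == "pearson_residual":
        gene_tot = X.sum(axis=0)
        total = n_umi.sum()
        mu = np.outer(n_umi, gene_tot) / total
        with np.errstate(invalid="ignore", divide="ignore"):
            resid = (X - mu) / np.sqrt(mu + mu ** 2 / theta)
        resid = np.where(mu > 0, resid, 0.0)
        clip = np.sqrt(m.n_spots)
        values = np.clip(resid, -clip, clip)
    else:
        raise InvalidArgumentError(f"unknown normalization method {method!r}")
    return NormalizedMatrix(values=values, barcodes=m.barcodes,
                            gene_ids=m.gene_ids, method=method)


def select_hvg(nm: NormalizedMatrix, n: int = 3000, n_bins: int = 20) -> np.ndarray:
    """Mask of the ``n`` most variable genes.

    Genes are binned (quantile bins on their mean normalized expression,
    up to ``n_bins`` bins with at least 10 genes per bin) and the
    variance of each gene is z-scored within its bin, so selection is
    not driven by the mean-variance trend. Top ``n`` by z-scored
    variance; ties broken by gene order.
    """
    if n <= 0:
        raise InvalidArgumentError("n must be positive")
    if n > nm.n_genes:
        raise InvalidArgumentError("n exceeds number of genes")
    means = nm.values.mean(axis=0)
    variances = nm.values.var(axis=0)
    n_bins = max(1, min(n_bins, nm.n_genes // 10))
    edges = np.unique(np.quantile(means, np.linspace(0, 1, n_bins + 1)))
    bins = np.clip(np.searchsorted(edges, means, side="right") - 1, 0, len(edges) - 2) \
        if len(edges) > 1 else np.zeros(len(means), int)
    z = np.zeros_like(variances)
    for b in np.unique(bins):
        sel = bins == b
        sd = variances[sel].std()
        if sd > 0:
            z[sel] = (variances[sel] - variances[sel].mean()) / sd
    # stable sort: descending z, ties by ascending gene index
    order = np.lexsort((np.arange(len(z)), -z))
    mask = np.zeros(nm.n_genes, bool)
    mask[order[:n]] = True
    return mask


def embed_pca(nm: NormalizedMatrix, n_pcs: int = 30,
              hvg_mask: np.ndarray | None = None) -> np.ndarray:
    """PCA scores of the centered (HVG-restricted) matrix.

    Signs are fixed so the largest-magnitude loading of each component is
    positive, making the embedding deterministic.
    """
    mask = hvg_mask if hvg_mask is not None else nm.hvg_mask
    X = nm.values[:, mask] if mask is not None else nm.values
    if n_pcs > min(X.shape):
        raise InvalidArgumentError(f"n_pcs={n_pcs} exceeds min(n_spots, n_genes)={min(X.shape)}")
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    U, S, Vt = U[:, :n_pcs], S[:n_pcs], Vt[:n_pcs]
    signs = np.sign(Vt[np.arange(n_pcs), np.abs(Vt).argmax(axis=1)])
    signs[signs == 0] = 1.0
    return U * S * signs


def snn_graph(scores: np.ndarray, k_neighbors: int = 20) -> sp.csr_matrix:
    """Shared-nearest-neighbour graph with Jaccard edge weights.

    Each spot's neighbourhood is itself plus its k nearest neighbours in
    the embedding; edges between spots whose neighbourhoods overlap get
    the Jaccard index of the two sets as weight.
    """
    n = scores.shape[0]
    if k_neighbors >= n:
        raise InvalidArgumentError("k_neighbors must be < n_spots")
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(scores)
    _, idx = nn.kneighbors(scores)
    rows = np.repeat(np.arange(n), k_neighbors + 1)
    cols = idx.ravel()
    A = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    A.data[:] = 1.0
    # |N(i) & N(j)| via the gram matrix; Jaccard from set sizes
    inter = (A @ A.T).tocoo()
    size = k_neighbors + 1
    jac = inter.data / (2 * size - inter.data)
    W = sp.csr_matrix((jac, (inter.row, inter.col)), shape=(n, n))
    W.setdiag(0)
    W.eliminate_zeros()
    return W


def cluster_graph(scores: np.ndarray, k_neighbors: int = 20,
                  resolution: float = 1.0, seed: int = 0) -> ClusterAssignment:
    """Cluster spots by modularity communities of the SNN graph."""
    W = snn_graph(scores, k_neighbors)
    coo = sp.triu(W, k=1).tocoo()
    g = ig.Graph(n=W.shape[0], edges=list(zip(coo.row, coo.col)),
                 edge_attrs={"weight": coo.data})
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition, weights="weight",
        resolution_parameter=resolution, seed=seed)
    labels = _relabel_contiguous(np.asarray(part.membership))
    return ClusterAssignment(labels=labels, method="graph",
                             parameters=dict(k_neighbors=k_neighbors,
                                             resolution=resolution, seed=seed))


def cluster_hierarchical(values: np.ndarray, k: int, linkage: str = "ward",
                         provenance: str = "phase-2") -> ClusterAssignment:
    """Agglomerative clustering on Euclidean distances, cut at k clusters."""
    if k <= 0:
        raise InvalidArgumentError("k must be positive")
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if k > n:
        raise InvalidArgumentError("k exceeds number of observations")
    if linkage not in ("ward", "average"):
        raise InvalidArgumentError(f"unsupported linkage {linkage!r}")
    if k == n:
        labels = np.arange(n)
    else:
        Z = sch.linkage(values, method=linkage)
        labels = _relabel_contiguous(sch.fcluster(Z, t=k, criterion="maxclust") - 1)
    return ClusterAssignment(labels=labels, method="hierarchical",
                             parameters=dict(k=k, linkage=linkage),
                             provenance=provenance)


def linkage_matrix(values: np.ndarray, linkage: str = "ward") -> np.ndarray:
    """Expose the dendrogram for inspection (merge heights etc.)."""
    return sch.linkage(np.asarray(values, dtype=float), method=linkage)
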