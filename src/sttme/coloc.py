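"""Spatial co-localization of marker pairs and multiplex-IF quantification.

The spatial statistic operationalizes co-location on the array grid:
spots above a per-gene quantile are "high", and the observed number of
lattice edges joining a high-A spot to a high-B spot is compared with a
permutation null that relabels the high-B set at random. The cell-table
side reproduces the ROI counting workflow: per-channel positivity
thresholds (Otsu by default), phenotype flags requiring a nuclear
signal, and one-sided rank tests of double-positive counts between
high- and low-MMP7 ROIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from skimage.filters import threshold_otsu

from sttme.cluster import NormalizedMatrix
from sttme.errors import FormatError, InvalidArgumentError, SttmeError

CHANNELS = ["DAPI", "PanCK", "MMP7", "CD14", "APOE"]

# Visium even-lattice hex neighbourhood: array_row and array_col share
# parity, and each interior spot has six neighbours.
HEX_OFFSETS = [(0, -2), (0, 2), (-1, -1), (-1, 1), (1, -1), (1, 1)]


@dataclass
class NeighborGraph:
    """Symmetric spot adjacency on the array grid (no self loops)."""

    adjacency: sp.csr_matrix
    barcodes: np.ndarray

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz // 2)


def hex_neighbor_graph(positions: pd.DataFrame) -> NeighborGraph:
    """Build the 6-neighbour hex adjacency from array_row/array_col.

    Positions follow the Visium convention where row and column parity
    match; neighbours are at offsets (0, +/-2) and (+/-1, +/-1).
    """
    coords = list(zip(positions["array_row"].astype(int),
                      positions["array_col"].astype(int)))
    index = {rc: i for i, rc in enumerate(coords)}
    rows, cols = [], []
    for i, (r, c) in enumerate(coords):
        for dr, dc in HEX_OFFSETS:
            j = index.get((r + dr, c + dc))
            if j is not None:
                rows.append(i)
                cols.append(j)
    n = len(coords)
    A = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    A = ((A + A.T) > 0).astype(np.int8)
    A.setdiag(0)
    A.eliminate_zeros()
    return NeighborGraph(adjacency=A.tocsr(),
                         barcodes=positions.index.to_numpy())


def marker_correlation(values_a, values_b, method: str = "spearman",
                       ) -> tuple[float, float]:
    """Spearman correlation with tie-corrected ranks.

    Two-sided p uses the t approximation; for n <= 9 the exact
    permutation distribution of rho is enumerated instead.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if method != "spearman":
        raise InvalidArgumentError("only spearman is supported")
    if len(a) != len(b) or len(a) < 3:
        raise InvalidArgumentError("need >= 3 paired observations")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise SttmeError("constant vector; correlation undefined")
    rho, p = scipy.stats.spearmanr(a, b)
    n = len(a)
    if n <= 9:
        ra = scipy.stats.rankdata(a)
        rb = scipy.stats.rankdata(b)
        obs = abs(np.corrcoef(ra, rb)[0, 1])
        count = 0
        total = 0
        for perm in permutations(rb):
            r = np.corrcoef(ra, np.asarray(perm))[0, 1]
            count += abs(r) >= obs - 1e-12
            total += 1
        p = count / total
    return float(rho), float(p)


def expression_correlation(nm: NormalizedMatrix, gene_a: str, gene_b: str,
                           ) -> tuple[float, float]:
    """Spearman correlation of two genes across spots."""
    return marker_correlation(nm.values[:, nm.gene_index(gene_a)],
                              nm.values[:, nm.gene_index(gene_b)])


def neighborhood_coloc(nm: NormalizedMatrix, graph: NeighborGraph,
                       gene_a: str, gene_b: str, hi_quantile: float = 0.75,
                       n_perm: int = 1000, seed: int = 0,
                       ) -> tuple[int, float, float]:
    """Edge-count co-localization statistic with a permutation null.

    Spots above the per-gene ``hi_quantile`` are "high"; the statistic is
    the number of adjacency edges joining a high-A spot to a high-B
    spot. The null relabels the high-B set uniformly at random over
    spots. Returns (observed, z, one-sided p with add-one correction).
    """
    if graph.n_edges == 0:
        raise SttmeError("neighbour graph has no edges")
    a = nm.values[:, nm.gene_index(gene_a)]
    b = nm.values[:, nm.gene_index(gene_b)]
    hi_a = a > np.quantile(a, hi_quantile)
    hi_b = b > np.quantile(b, hi_quantile)
    if not hi_a.any() or not hi_b.any():
        raise SttmeError("no high spots for one of the genes")
    A = graph.adjacency

    def stat(mask_b):
        # each qualifying unordered edge counted once per direction pair
        return int(hi_a @ (A @ mask_b.astype(np.int64)))

    observed = stat(hi_b)
    rng = np.random.default_rng(seed)
    n = len(a)
    k = int(hi_b.sum())
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm_b = np.zeros(n, bool)
        perm_b[rng.choice(n, size=k, replace=False)] = True
        null[i] = stat(perm_b)
    sd = null.std()
    z = (observed - null.mean()) / sd if sd > 0 else 0.0
    p = (1 + int((null >= observed).sum())) / (n_perm + 1)
    return observed, float(z), float(p)


@dataclass
class PositivityRule:
    """Per-channel intensity thresholds; positivity also requires DAPI."""

    thresholds: dict = field(default_factory=dict)
    require_dapi: bool = True

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.thresholds.values()):
            raise InvalidArgumentError("thresholds must be >= 0")


def otsu_rule(cells: pd.DataFrame, channels=None, require_dapi: bool = True,
              ) -> PositivityRule:
    """Default rule: per-channel Otsu threshold on the intensity histogram."""
    channels = channels or [c for c in CHANNELS if c != "DAPI"] + ["DAPI"]
    thresholds = {}
    for ch in channels:
        vals = cells[ch].to_numpy(float)
        thresholds[ch] = float(threshold_otsu(vals)) if np.ptp(vals) > 0 else 0.0
    return PositivityRule(thresholds=thresholds, require_dapi=require_dapi)


def classify_cells(cells: pd.DataFrame, rule: PositivityRule) -> pd.DataFrame:
    """Phenotype flags per cell: a marker is positive iff the cell has a
    DAPI signal above threshold AND the marker channel exceeds its
    threshold; CD14+APOE+ requires both single flags."""
    for ch in CHANNELS:
        if ch not in cells.columns:
            raise FormatError(f"missing channel {ch!r}")
    dapi_thr = rule.thresholds.get("DAPI", 0.0)
    has_nucleus = cells["DAPI"].to_numpy(float) > dapi_thr \
        if rule.require_dapi else np.ones(len(cells), bool)
    flags = pd.DataFrame(index=cells.index)
    for ch in ("PanCK", "MMP7", "CD14", "APOE"):
        thr = rule.thresholds.get(ch, 0.0)
        flags[f"{ch}+"] = has_nucleus & (cells[ch].to_numpy(float) > thr)
    flags["CD14+APOE+"] = flags["CD14+"] & flags["APOE+"]
    return flags


def roi_compare(cells: pd.DataFrame, rule: PositivityRule,
                roi_class: pd.Series) -> dict:
    """Compare CD14+ / CD14+APOE+ cell counts between ROI classes.

    One-sided Mann-Whitney (high_MMP7 > low_MMP7); exact when both
    classes have <= 8 ROIs, normal approximation with tie correction
    otherwise. Returns per-ROI counts and the U/p for both phenotypes.
    """
    classes = set(roi_class)
    if classes != {"high_MMP7", "low_MMP7"}:
        raise InvalidArgumentError("roi_class must label high_MMP7 and low_MMP7")
    for cls in classes:
        if (roi_class == cls).sum() < 2:
            raise SttmeError(f"need >= 2 ROIs of class {cls}")
    flags = classify_cells(cells, rule)
    counts = pd.DataFrame({
        "roi_id": cells["roi_id"],
        "CD14+": flags["CD14+"].astype(int),
        "CD14+APOE+": flags["CD14+APOE+"].astype(int),
    }).groupby("roi_id").sum()
    counts["class"] = roi_class.reindex(counts.index)
    out = {"counts": counts}
    hi = counts[counts["class"] == "high_MMP7"]
    lo = counts[counts["class"] == "low_MMP7"]
    for pheno in ("CD14+", "CD14+APOE+"):
        x, y = hi[pheno].to_numpy(float), lo[pheno].to_numpy(float)
        method = "exact" if (len(x) <= 8 and len(y) <= 8
                             and len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)) \
            else "asymptotic"
        u, p = scipy.stats.mannwhitneyu(x, y, alternative="greater", method=method)
        out[pheno] = {"U": float(u), "p": float(p)}
    return out


def ihc_score(intensity: int, proportion_bin: int) -> int:
    """Product IHC score: staining intensity (0-3) x positive-area bin (0-4)."""
    if intensity not in range(4):
        raise InvalidArgumentError("intensity must be an integer 0-3")
    if proportion_bin not in range(5):
        raise InvalidArgumentError("proportion_bin must be an integer 0-4")
    return intensity * proportion_bin


def group_compare(values_a, values_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U, exact for small tie-free samples."""
    x = np.asarray(values_a, float)
    y = np.asarray(values_b, float)
    if len(x) == 0 or len(y) == 0:
        raise InvalidArgumentError("both groups must be non-empty")
    tie_free = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and tie_free) else "asymptotic"
    u, p = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(u), float(p)
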