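"""Reading, writing and QC of Visium-style spot-by-gene matrices.

The on-disk dialect is the Space Ranger output triplet (MatrixMarket
``matrix.mtx`` with genes as rows, ``features.tsv``, ``barcodes.tsv``)
plus a ``tissue_positions.csv`` with the spot array coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from sttme.errors import EmptyResultError, FormatError, InvalidArgumentError

MITO_PREFIX = "MT-"
RIBO_PREFIXES = ("RPL", "RPS")

POSITION_COLUMNS = ["barcode", "in_tissue", "array_row", "array_col",
                    "pxl_row_in_fullres", "pxl_col_in_fullres"]


@dataclass
class SpotMatrix:
    """Sparse spot-by-gene counts with grid positions and QC covariates.

    ``counts`` is spots x genes (CSR, nonnegative integers); ``positions``
    is indexed by barcode and carries ``array_row``, ``array_col`` and the
    ``in_tissue`` flag for every barcode in the matrix.
    """

    counts: sp.csr_matrix
    barcodes: np.ndarray
    gene_ids: np.ndarray
    positions: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        n_spots, n_genes = self.counts.shape
        if len(self.barcodes) != n_spots:
            raise FormatError(f"{len(self.barcodes)} barcodes for {n_spots} matrix rows")
        if len(self.gene_ids) != n_genes:
            raise FormatError(f"{len(self.gene_ids)} gene ids for {n_genes} matrix columns")
        if len(set(self.barcodes)) != n_spots:
            raise FormatError("duplicate barcode")
        if len(set(self.gene_ids)) != n_genes:
            raise FormatError("duplicate gene id")
        missing = set(self.barcodes) - set(self.positions.index)
        if missing:
            raise FormatError(f"{len(missing)} barcodes missing positions, "
                              f"e.g. {sorted(missing)[0]!r}")
        self.positions = self.positions.loc[list(self.barcodes)]
        if self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError("negative counts")

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def n_umi(self) -> np.ndarray:
        """Total counts per spot."""
        return np.asarray(self.counts.sum(axis=1)).ravel()

    @property
    def n_gene(self) -> np.ndarray:
        """Number of genes detected (count > 0) per spot."""
        return np.asarray((self.counts > 0).sum(axis=1)).ravel()

    @property
    def mito_frac(self) -> np.ndarray:
        """Fraction of each spot's counts on ``MT-`` genes (0 where nUMI=0)."""
        is_mito = np.array([g.startswith(MITO_PREFIX) for g in self.gene_ids])
        mito_counts = np.asarray(self.counts[:, is_mito].sum(axis=1)).ravel()
        total = self.n_umi
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, mito_counts / np.maximum(total, 1), 0.0)
        return frac

    def subset(self, spot_mask=None, gene_mask=None) -> "SpotMatrix":
        spot_mask = np.ones(self.n_spots, bool) if spot_mask is None else np.asarray(spot_mask)
        gene_mask = np.ones(self.n_genes, bool) if gene_mask is None else np.asarray(gene_mask)
        return SpotMatrix(
            counts=self.counts[spot_mask][:, gene_mask],
            barcodes=self.barcodes[spot_mask],
            gene_ids=self.gene_ids[gene_mask],
            positions=self.positions.loc[self.barcodes[spot_mask]].copy(),
        )


@dataclass
class QCReport:
    """Per-filter removal accounting for one qc_filter call."""

    spots_in: int
    spots_out: int
    genes_in: int
    genes_out: int
    thresholds: dict
    spot_removals: dict = field(default_factory=dict)
    gene_removals: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))


def read_spot_matrix(matrix_path, features_path, barcodes_path, positions_path) -> SpotMatrix:
    """Read the Space Ranger triplet + tissue positions into a SpotMatrix.

    The MTX stores genes as rows and barcodes as columns; it is transposed
    into spot-major orientation. Every barcode must appear in the
    positions table (exact string match) or a FormatError is raised.
    """
    mat = scipy.io.mmread(str(matrix_path))
    counts = sp.csr_matrix(mat.T)
    if not np.issubdtype(counts.dtype, np.integer):
        data = counts.data
        if not np.allclose(data, np.round(data)):
            raise FormatError("matrix contains non-integer counts")
        counts = counts.astype(np.int64)
    features = pd.read_csv(features_path, sep="\t", header=None)
    gene_ids = features.iloc[:, 0].astype(str).to_numpy()
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None).iloc[:, 0].astype(str).to_numpy()
    if counts.shape != (len(barcodes), len(gene_ids)):
        raise FormatError(
            f"matrix is {mat.shape} but features={len(gene_ids)}, barcodes={len(barcodes)}")
    positions = pd.read_csv(positions_path)
    if list(positions.columns) != POSITION_COLUMNS:
        raise FormatError(f"tissue positions must have columns {POSITION_COLUMNS}")
    if positions["barcode"].duplicated().any():
        raise FormatError("duplicate barcode in positions")
    positions = positions.set_index("barcode")
    return SpotMatrix(counts=counts, barcodes=barcodes, gene_ids=gene_ids, positions=positions)


def write_spot_matrix(m: SpotMatrix, out_dir) -> None:
    """Write matrix.mtx / features.tsv / barcodes.tsv / tissue_positions.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(out / "matrix.mtx"), sp.coo_matrix(m.counts.T.astype(np.int64)))
    with open(out / "features.tsv", "w") as fh:
        for g in m.gene_ids:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    with open(out / "barcodes.tsv", "w") as fh:
        for b in m.barcodes:
            fh.write(f"{b}\n")
    pos = m.positions.reset_index()
    pos.columns = ["barcode"] + list(pos.columns[1:])
    for col in POSITION_COLUMNS[4:]:
        if col not in pos.columns:
            pos[col] = 0
    pos[POSITION_COLUMNS].to_csv(out / "tissue_positions.csv", index=False)


def qc_filter(m: SpotMatrix, min_numi: int = 500, min_ngene: int = 250,
              max_mito_frac: float = 0.05, min_spots_per_gene: int = 3,
              drop_mito_ribo: bool = True, require_in_tissue: bool = True,
              ) -> tuple[SpotMatrix, QCReport]:
    """Apply the standard spot and gene QC filters.

    Spots must satisfy nUMI/nGene/mito-fraction/in-tissue predicates;
    genes must then (evaluated after spot filtering) be expressed in at
    least ``min_spots_per_gene`` surviving spots, and mitochondrial
    (``MT-``) and ribosomal (``RPL``/``RPS``) genes are removed when
    ``drop_mito_ribo`` is set. Spot/gene order is preserved.
    """
    for name, v in [("min_numi", min_numi), ("min_ngene", min_ngene),
                    ("max_mito_frac", max_mito_frac),
                    ("min_spots_per_gene", min_spots_per_gene)]:
        if v < 0:
            raise InvalidArgumentError(f"{name} must be nonnegative")

    n_umi, n_gene, mito = m.n_umi, m.n_gene, m.mito_frac
    keep = np.ones(m.n_spots, bool)
    spot_removals = {}
    for label, pred in [
        ("low_numi", n_umi >= min_numi),
        ("low_ngene", n_gene >= min_ngene),
        ("high_mito", mito <= max_mito_frac),
    ]:
        spot_removals[label] = int((keep & ~pred).sum())
        keep &= pred
    if require_in_tissue:
        in_tissue = m.positions["in_tissue"].to_numpy().astype(bool)
        spot_removals["not_in_tissue"] = int((keep & ~in_tissue).sum())
        keep &= in_tissue

    thresholds = dict(min_numi=min_numi, min_ngene=min_ngene,
                      max_mito_frac=max_mito_frac,
                      min_spots_per_gene=min_spots_per_gene,
                      drop_mito_ribo=drop_mito_ribo,
                      require_in_tissue=require_in_tissue)

    if not keep.any():
        report = QCReport(spots_in=m.n_spots, spots_out=0, genes_in=m.n_genes,
                          genes_out=0, thresholds=thresholds,
                          spot_removals=spot_removals)
        raise EmptyResultError("all spots removed by QC", report=report)

    sub = m.counts[keep]
    gene_keep = np.ones(m.n_genes, bool)
    gene_removals = {}
    if drop_mito_ribo:
        named = np.array([g.startswith(MITO_PREFIX) or g.startswith(RIBO_PREFIXES)
                          for g in m.gene_ids])
        gene_removals["mito_ribo"] = int(named.sum())
        gene_keep &= ~named
    spots_per_gene = np.asarray((sub > 0).sum(axis=0)).ravel()
    sparse_genes = spots_per_gene < min_spots_per_gene
    gene_removals["too_few_spots"] = int((gene_keep & sparse_genes).sum())
    gene_keep &= ~sparse_genes

    filtered = m.subset(keep, gene_keep)
    report = QCReport(spots_in=m.n_spots, spots_out=filtered.n_spots,
                      genes_in=m.n_genes, genes_out=filtered.n_genes,
                      thresholds=thresholds, spot_removals=spot_removals,
                      gene_removals=gene_removals)
    return filtered, report
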