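"""Gene genomic annotation: chromosome assignment and ordering.

The genome model drives CNV inference: genes are laid out along each
chromosome in coordinate order so that a moving-average window over
adjacent genes approximates a chromosomal segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sttme.errors import FormatError, InvalidArgumentError

MITO_PREFIX = "MT-"


@dataclass
class GenomeModel:
    """Per-gene chromosome/start/end plus an explicit chromosome order.

    Coordinates are 0-based half-open. Gene ids are unique and, within
    each chromosome, starts are strictly increasing. Mitochondrial genes
    are identifiable by the ``MT-`` symbol prefix.
    """

    genes: pd.DataFrame  # columns: gene_id, chrom, start, end
    chrom_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        required = {"gene_id", "chrom", "start", "end"}
        if not required.issubset(self.genes.columns):
            raise FormatError(f"genome table requires columns {sorted(required)}")
        if self.genes["gene_id"].duplicated().any():
            dup = self.genes.loc[self.genes["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise FormatError(f"duplicate gene_id in genome: {dup!r}")
        if not self.chrom_order:
            self.chrom_order = list(dict.fromkeys(self.genes["chrom"]))
        for chrom, sub in self.genes.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            if not np.all(np.diff(starts) > 0):
                raise FormatError(f"starts not strictly increasing on {chrom}")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def gene_ids(self) -> np.ndarray:
        return self.genes["gene_id"].to_numpy()

    def genome_order(self, gene_ids) -> tuple[np.ndarray, np.ndarray]:
        """Order a set of gene ids along the genome.

        Returns ``(ordered_gene_ids, chrom_of_each)`` restricted to genes
        present in the annotation, sorted by ``chrom_order`` then start.
        """
        rank = {c: i for i, c in enumerate(self.chrom_order)}
        sub = self.genes[self.genes["gene_id"].isin(set(gene_ids))].copy()
        sub["_crank"] = sub["chrom"].map(rank)
        sub = sub.sort_values(["_crank", "start"], kind="stable")
        return sub["gene_id"].to_numpy(), sub["chrom"].to_numpy()


def make_genome(n_genes: int, n_chroms: int, seed: int,
                named_genes: list[str] | None = None) -> GenomeModel:
    """Generate a synthetic genome annotation.

    Genes are distributed across ``n_chroms`` chromosomes (each gets at
    least one), with strictly increasing starts inside each chromosome
    and ~1% of gene symbols carrying the mitochondrial ``MT-`` prefix.
    ``named_genes`` optionally replaces the symbols of randomly chosen
    non-mitochondrial slots (used to plant real marker genes).
    """
    if n_chroms < 1 or n_genes < n_chroms:
        raise InvalidArgumentError("need n_genes >= n_chroms >= 1")
    rng = np.random.default_rng(seed)
    # one gene guaranteed per chromosome, remainder multinomial
    extra = rng.multinomial(n_genes - n_chroms, np.full(n_chroms, 1.0 / n_chroms))
    counts = extra + 1
    rows = []
    gene_idx = 0
    n_mito = max(1, int(round(0.01 * n_genes)))
    mito_slots = set(rng.choice(n_genes, size=n_mito, replace=False).tolist())
    for ci in range(n_chroms):
        chrom = f"chr{ci + 1}"
        starts = np.sort(rng.choice(np.arange(1, 250_000_000, 1000), size=counts[ci],
                                    replace=False))
        for s in starts:
            if gene_idx in mito_slots:
                name = f"MT-G{gene_idx:05d}"
            else:
                name = f"G{gene_idx:05d}"
            rows.append((name, chrom, int(s), int(s) + 500))
            gene_idx += 1
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])
    if named_genes:
        candidates = np.flatnonzero(~genes["gene_id"].str.startswith(MITO_PREFIX))
        if len(named_genes) > len(candidates):
            raise InvalidArgumentError("more named genes than available slots")
        slots = rng.choice(candidates, size=len(named_genes), replace=False)
        genes.loc[np.sort(slots), "gene_id"] = list(named_genes)
    chrom_order = [f"chr{ci + 1}" for ci in range(n_chroms)]
    return GenomeModel(genes=genes, chrom_order=chrom_order)


def write_bed(genome: GenomeModel, path) -> None:
    """Write the annotation as 4-column BED (chrom, start, end, gene_id)."""
    genome.genes[["chrom", "start", "end", "gene_id"]].to_csv(
        path, sep="\t", header=False, index=False)


def read_bed(path) -> GenomeModel:
    """Read a 4-column BED (chrom, start, end, gene_id) annotation."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "gene_id"])
    df = df[["gene_id", "chrom", "start", "end"]]
    chrom_order = list(dict.fromkeys(df["chrom"]))
    return GenomeModel(genes=df.reset_index(drop=True), chrom_order=chrom_order)
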