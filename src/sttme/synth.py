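"""Synthetic spatial, bulk-survival and cell-table data with ground truth.

The generator emulates the statistical structure of a Visium NSCLC
section: spots are multicellular mixtures of cell-type expression
profiles, counts are negative binomial, tumour regions carry planted
chromosome-segment copy-number gains, immune regions are enriched for a
10-gene immune marker panel, a myeloid marker pair is spatially
co-located with a tumour marker, and a bulk cohort has
signature-dependent survival hazard. Ground-truth labels are returned
for every planted feature so recovery can be measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from sttme.errors import InvalidArgumentError
from sttme.genome import GenomeModel, make_genome
from sttme.io import SpotMatrix

# marker panels used throughout the analysis
IMMUNE_PANEL = ["PTPRC", "CD2", "CD3D", "CD3E", "CD3G",
                "CD79A", "MS4A1", "CD79B", "CD68", "CD14"]
EPITHELIAL_PANEL = ["EPCAM", "KRT8", "KRT19"]

# ligand/receptor genes for the built-in communication pathways
LR_GENES = ["MIF", "CD74", "CXCR4", "CD44",
            "SEMA3A", "SEMA3B", "SEMA3C", "NRP1", "NRP2", "PLXNA4",
            "MDK", "SDC1", "SDC4", "NCL", "ITGA4", "ITGA6", "ITGB1"]

OTHER_MARKERS = ["MMP7", "APOE", "JCHAIN", "COL1A1", "FAP", "PECAM1", "VWF"]

PLANTED_GENES = IMMUNE_PANEL + EPITHELIAL_PANEL + LR_GENES + OTHER_MARKERS

CELL_TYPES = ["tumour", "normal_epithelial", "immune_plasma",
              "immune_myeloid", "fibroblast", "endothelial"]

REGIONS = ["tumour_core", "immune_infiltrate", "normal", "stroma"]

# base mixture weights per region over CELL_TYPES (Dirichlet-perturbed per
# spot). The tumour core carries a substantial myeloid component: the
# immune-exclusion phenotype this emulates has CD14+/APOE+ myeloid cells
# co-located with MMP7+ tumour cells inside the tumour area.
REGION_WEIGHTS = {
    "tumour_core":       [0.62, 0.02, 0.02, 0.22, 0.08, 0.04],
    "immune_infiltrate": [0.05, 0.05, 0.50, 0.25, 0.10, 0.05],
    "normal":            [0.02, 0.73, 0.05, 0.05, 0.10, 0.05],
    "stroma":            [0.02, 0.05, 0.05, 0.08, 0.60, 0.20],
}

# marker boosts per cell type (fold on the baseline relative abundance)
TYPE_MARKERS = {
    "tumour": {**{g: 8.0 for g in EPITHELIAL_PANEL},
               "MMP7": 8.0, "MDK": 6.0, "MIF": 6.0,
               "SEMA3A": 5.0, "SEMA3B": 5.0, "SEMA3C": 5.0},
    "normal_epithelial": {**{g: 4.0 for g in EPITHELIAL_PANEL}},
    "immune_plasma": {"PTPRC": 8.0, "CD79A": 8.0, "MS4A1": 8.0, "CD79B": 8.0,
                      "JCHAIN": 8.0, "CD2": 3.0, "CD3D": 3.0, "CD3E": 3.0,
                      "CD3G": 3.0},
    "immune_myeloid": {"PTPRC": 8.0, "CD68": 8.0, "CD14": 8.0, "APOE": 8.0,
                       "CD74": 6.0, "CXCR4": 6.0, "CD44": 5.0,
                       "SDC1": 4.0, "SDC4": 4.0, "NCL": 4.0,
                       "ITGA4": 4.0, "ITGA6": 4.0, "ITGB1": 4.0},
    "fibroblast": {"COL1A1": 8.0, "FAP": 8.0, "NRP1": 4.0, "NRP2": 4.0,
                   "PLXNA4": 4.0},
    "endothelial": {"PECAM1": 8.0, "VWF": 8.0, "NRP1": 4.0},
}


@dataclass
class CellTypeProfile:
    """Relative per-gene expression of one cell type (sums to one)."""

    name: str
    mean_expr: pd.Series
    marker_genes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = float(self.mean_expr.sum())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise InvalidArgumentError(f"profile {self.name}: mean_expr sums to {total}")
        if any(b < 1 for b in self.marker_genes.values()):
            raise InvalidArgumentError("marker boost must be >= 1")


@dataclass
class CNVProfile:
    """Planted multiplicative copy-number segments on the tumour component.

    Segment gene indices refer to positions in the genome-ordered gene
    list; segments must not overlap within a chromosome.
    """

    segments: list  # (chrom, start_gene_index, end_gene_index, fold)

    def __post_init__(self) -> None:
        by_chrom: dict[str, list] = {}
        for chrom, s, e, fold in self.segments:
            if fold < 0:
                raise InvalidArgumentError("fold must be >= 0")
            if e <= s:
                raise InvalidArgumentError("empty segment")
            by_chrom.setdefault(chrom, []).append((s, e))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise InvalidArgumentError(f"overlapping segments on {chrom}")

    def fold_vector(self, genome: GenomeModel) -> pd.Series:
        """Per-gene fold (genome order), 1 outside all segments."""
        ordered, chroms = genome.genome_order(genome.gene_ids)
        fold = pd.Series(1.0, index=ordered)
        pos_in_order = pd.Series(np.arange(len(ordered)), index=ordered)
        for chrom, s, e, f in self.segments:
            in_chrom = ordered[chroms == chrom]
            sel = pos_in_order[in_chrom]
            seg = sel[(sel >= s) & (sel < e)].index
            fold[seg] = f
        return fold


@dataclass
class TissueLayout:
    """Spot grid with region labels and per-spot cell-type mixture weights."""

    spots: pd.DataFrame          # barcode, array_row, array_col, region_label
    weights: np.ndarray          # n_spots x len(cell_types), rows sum to 1
    cell_types: list = field(default_factory=lambda: list(CELL_TYPES))

    def __post_init__(self) -> None:
        if not np.allclose(self.weights.sum(axis=1), 1.0):
            raise InvalidArgumentError("mixture weights must sum to 1 per spot")
        if (self.weights < 0).any():
            raise InvalidArgumentError("mixture weights must be nonnegative")
        coords = list(zip(self.spots["array_row"], self.spots["array_col"]))
        if len(set(coords)) != len(coords):
            raise InvalidArgumentError("grid positions must be unique")


@dataclass
class SyntheticTruth:
    """Ground-truth labels for one simulated section."""

    malignant: np.ndarray            # per-spot bool (tumour weight > 0.5)
    dominant_type: np.ndarray        # per-spot cell type name
    region: np.ndarray               # per-spot region label
    signature_genes: list
    coloc_pair: tuple = ("MMP7", "APOE")
    log_hazard_ratio: float | None = None

    def to_frame(self, barcodes) -> pd.DataFrame:
        return pd.DataFrame({"barcode": barcodes, "malignant": self.malignant,
                             "dominant_type": self.dominant_type,
                             "region": self.region})


def default_profiles(genome: GenomeModel, seed: int = 0) -> dict[str, CellTypeProfile]:
    """Cell-type profiles over the genome's genes with planted marker boosts.

    The baseline is a shared log-normal abundance landscape; cell types
    differ through a mild global jitter plus a stronger fold change on a
    small random "program" gene subset (``program_frac`` of genes, fold
    sd ``program_sigma`` on the log scale), mirroring how real cell
    types share housekeeping expression and diverge on localized
    transcriptional programs rather than uniformly across the genome.
    """
    rng = np.random.default_rng(seed)
    gene_ids = genome.gene_ids
    n = len(gene_ids)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n)
    program_frac, program_sigma = 0.05, 0.8
    # random programs never touch the planted markers, whose cell-type
    # assignment is part of the generator's ground-truth contract
    candidates = np.flatnonzero(~np.isin(gene_ids, PLANTED_GENES))
    profiles = {}
    for name in CELL_TYPES:
        perturb = rng.lognormal(mean=0.0, sigma=0.1, size=n)
        program = rng.choice(candidates, size=int(program_frac * n), replace=False)
        perturb[program] *= rng.lognormal(0.0, program_sigma, size=len(program))
        expr = pd.Series(base * perturb, index=gene_ids)
        markers = {g: b for g, b in TYPE_MARKERS[name].items() if g in expr.index}
        for g, boost in markers.items():
            expr[g] *= boost
        expr /= expr.sum()
        profiles[name] = CellTypeProfile(name=name, mean_expr=expr, marker_genes=markers)
    return profiles


def make_layout(n_spots: int = 500, tumour_frac: float = 0.3,
                immune_frac: float = 0.2, seed: int = 0,
                concentration: float = 60.0) -> TissueLayout:
    """Lay spots on a Visium-style lattice with concentric regions.

    Spots sit on the even sub-lattice (array_row + array_col even), the
    hexagonal-equivalent integer grid of the positions file. The tumour
    core is the central disk containing ``tumour_frac`` of spots, ringed
    by an immune infiltrate; the periphery splits into normal epithelium
    and stroma by row. Mixture weights are Dirichlet draws around the
    region's base composition.
    """
    rng = np.random.default_rng(seed)
    n_rows = max(4, int(np.ceil(np.sqrt(n_spots))))
    coords = []
    r = 0
    while len(coords) < n_spots:
        for c in range(r % 2, 2 * n_rows, 2):
            coords.append((r, c))
            if len(coords) >= n_spots:
                break
        r += 1
    coords = np.array(coords[:n_spots], dtype=float)
    # euclidean geometry: column units are half row units on this lattice
    xy = np.column_stack([coords[:, 0], coords[:, 1] / 2.0])
    center = xy.mean(axis=0)
    dist = np.linalg.norm(xy - center, axis=1)
    order = np.argsort(dist, kind="stable")
    region = np.empty(n_spots, dtype=object)
    n_tum = int(round(tumour_frac * n_spots))
    n_imm = int(round(immune_frac * n_spots))
    region[order[:n_tum]] = "tumour_core"
    region[order[n_tum:n_tum + n_imm]] = "immune_infiltrate"
    outer = order[n_tum + n_imm:]
    median_row = np.median(coords[outer, 0]) if len(outer) else 0
    for i in outer:
        region[i] = "normal" if coords[i, 0] <= median_row else "stroma"

    weights = np.empty((n_spots, len(CELL_TYPES)))
    for i in range(n_spots):
        base = np.asarray(REGION_WEIGHTS[region[i]])
        weights[i] = rng.dirichlet(concentration * base)
    spots = pd.DataFrame({
        "barcode": [f"SPOT-{i:05d}" for i in range(n_spots)],
        "array_row": coords[:, 0].astype(int),
        "array_col": coords[:, 1].astype(int),
        "region_label": region,
    })
    return TissueLayout(spots=spots, weights=weights)


def default_cnv(genome: GenomeModel, n_genes_gained: int = 200,
                fold: float = 2.0) -> CNVProfile:
    """One contiguous fold-gain covering the first genes of the longest chromosome."""
    ordered, chroms = genome.genome_order(genome.gene_ids)
    uniq, counts = np.unique(chroms, return_counts=True)
    chrom = uniq[np.argmax(counts)]
    pos = np.flatnonzero(chroms == chrom)
    if len(pos) < n_genes_gained:
        n_genes_gained = len(pos)
    start = int(pos[0])
    return CNVProfile(segments=[(str(chrom), start, start + n_genes_gained, fold)])


def simulate_spots(layout: TissueLayout, profiles: dict[str, CellTypeProfile],
                   cnv: CNVProfile | None, library_size_mean: int = 20000,
                   nb_dispersion: float = 10.0, seed: int = 0, genome:
                   GenomeModel | None = None,
                   ) -> tuple[SpotMatrix, SyntheticTruth]:
    """Draw negative-binomial counts for a tissue layout.

    The expected count of gene g in spot s is
    ``L_s * sum_t w_st * p_tg * c_g(t)`` where ``c_g(t)`` is the CNV fold
    for the tumour component inside a planted segment and 1 otherwise.
    Counts are NB with a single global dispersion (gamma-Poisson mixture).
    """
    if nb_dispersion <= 0:
        raise InvalidArgumentError("dispersion must be > 0")
    for t in layout.cell_types:
        if t not in profiles:
            raise InvalidArgumentError(f"no profile for cell type {t!r}")
    if cnv is not None and genome is None:
        raise InvalidArgumentError("genome required to place CNV segments")

    rng = np.random.default_rng(seed)
    gene_ids = profiles[layout.cell_types[0]].mean_expr.index.to_numpy()
    n_spots, n_genes = len(layout.spots), len(gene_ids)

    # per-type expression, with CNV fold applied to the tumour component
    P = np.vstack([profiles[t].mean_expr.reindex(gene_ids).to_numpy()
                   for t in layout.cell_types])
    if cnv is not None:
        fold = cnv.fold_vector(genome).reindex(gene_ids).fillna(1.0).to_numpy()
        ti = layout.cell_types.index("tumour")
        P = P.copy()
        P[ti] = P[ti] * fold

    lib = rng.gamma(shape=10.0, scale=library_size_mean / 10.0, size=n_spots)
    mean = (layout.weights @ P) * lib[:, None]
    lam = rng.gamma(shape=nb_dispersion, scale=mean / nb_dispersion)
    counts = rng.poisson(lam)

    barcodes = layout.spots["barcode"].to_numpy()
    positions = pd.DataFrame({
        "in_tissue": 1,
        "array_row": layout.spots["array_row"].to_numpy(),
        "array_col": layout.spots["array_col"].to_numpy(),
        "pxl_row_in_fullres": layout.spots["array_row"].to_numpy() * 100,
        "pxl_col_in_fullres": layout.spots["array_col"].to_numpy() * 100,
    }, index=pd.Index(barcodes, name="barcode"))
    m = SpotMatrix(counts=sp.csr_matrix(counts), barcodes=barcodes,
                   gene_ids=gene_ids, positions=positions)
    ti = layout.cell_types.index("tumour")
    truth = SyntheticTruth(
        malignant=layout.weights[:, ti] > 0.5,
        dominant_type=np.asarray(layout.cell_types, dtype=object)[
            layout.weights.argmax(axis=1)],
        region=layout.spots["region_label"].to_numpy(),
        signature_genes=[g for g in TYPE_MARKERS["tumour"] if g in set(gene_ids)],
    )
    return m, truth


def make_section(n_spots: int = 500, n_genes: int = 2000, n_chroms: int = 10,
                 tumour_frac: float = 0.3, cnv_genes: int = 200,
                 cnv_fold: float = 2.0, library_size_mean: int = 20000,
                 nb_dispersion: float = 10.0, seed: int = 0,
                 ) -> tuple[SpotMatrix, GenomeModel, SyntheticTruth]:
    """Convenience wrapper: genome + layout + profiles + counts in one call.

    This is the default study condition used by the recovery experiments:
    30% tumour spots carrying a fold-2 gain over a contiguous block of
    genes, an immune infiltrate enriched for the immune panel, and marker
    genes planted for the co-localization and communication analyses.
    """
    ss = np.random.SeedSequence(seed)
    s_genome, s_layout, s_prof, s_counts = [int(c.generate_state(1)[0] % (2**31))
                                            for c in ss.spawn(4)]
    genome = make_genome(n_genes, n_chroms, seed=s_genome, named_genes=PLANTED_GENES)
    layout = make_layout(n_spots=n_spots, tumour_frac=tumour_frac, seed=s_layout)
    profiles = default_profiles(genome, seed=s_prof)
    cnv = default_cnv(genome, n_genes_gained=cnv_genes, fold=cnv_fold) \
        if cnv_fold != 1.0 and cnv_genes > 0 else None
    m, truth = simulate_spots(layout, profiles, cnv, library_size_mean,
                              nb_dispersion, seed=s_counts, genome=genome)
    return m, genome, truth


@dataclass
class BulkCohort:
    """Bulk expression with survival follow-up and the latent group truth."""

    expression: pd.DataFrame     # genes x patients
    time: np.ndarray             # days
    event: np.ndarray            # 1 = death observed
    group: np.ndarray            # latent "high" flag used for the hazard

    @property
    def patients(self):
        return self.expression.columns.to_numpy()

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"patient_id": self.patients, "time": self.time,
                           "event": self.event})
        df = pd.concat([df, self.expression.T.reset_index(drop=True)], axis=1)
        df.to_csv(path, index=False)


def simulate_bulk_cohort(n_patients: int, signature: list, log_hazard_ratio: float,
                         censor_rate: float = 0.2, seed: int = 0,
                         n_noise_genes: int = 100) -> BulkCohort:
    """Bulk cohort with a signature-dependent exponential hazard.

    Half the patients form a latent "high" group whose signature genes are
    shifted up by two standard units (a clear separation, so a median
    split on the signature score recovers the latent groups) and whose
    hazard is multiplied by
    ``exp(log_hazard_ratio)``. Censoring times are independent
    exponentials calibrated so each record is censored with probability
    ``censor_rate``.
    """
    if n_patients < 10:
        raise InvalidArgumentError("need n_patients >= 10")
    if not signature:
        raise InvalidArgumentError("signature must be non-empty")
    if not 0 <= censor_rate < 1:
        raise InvalidArgumentError("censor_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    genes = list(signature) + [f"NOISE{i:04d}" for i in range(n_noise_genes)]
    patients = [f"PT{i:04d}" for i in range(n_patients)]
    expr = rng.normal(size=(len(genes), n_patients))
    group = np.zeros(n_patients, bool)
    group[rng.permutation(n_patients)[: n_patients // 2]] = True
    expr[: len(signature), group] += 2.0

    base_rate = 1.0 / 365.0
    rate = base_rate * np.where(group, np.exp(log_hazard_ratio), 1.0)
    t_event = rng.exponential(1.0 / rate)
    if censor_rate > 0:
        # for exponential T~rate and C~c*rate/(1-c), P(C < T) = c exactly
        c_rate = rate * censor_rate / (1.0 - censor_rate)
        t_cens = rng.exponential(1.0 / c_rate)
        event = (t_event <= t_cens).astype(int)
        time = np.minimum(t_event, t_cens)
    else:
        event = np.ones(n_patients, int)
        time = t_event
    expression = pd.DataFrame(expr, index=genes, columns=patients)
    return BulkCohort(expression=expression, time=time, event=event, group=group)


@dataclass
class IFDataset:
    """Multiplex-IF cell table plus the per-ROI MMP7 class labels."""

    cells: pd.DataFrame
    roi_class: pd.Series  # roi_id -> {"high_MMP7", "low_MMP7"}


def simulate_if_cells(n_rois: int, cells_per_roi: int, coloc_effect: float = 1.0,
                      seed: int = 0, base_dp_frac: float = 0.05) -> IFDataset:
    """Simulate per-cell stain intensities across regions of interest.

    Half the ROIs are "high MMP7" (their tumour cells stain for MMP7);
    in those ROIs the density of CD14+APOE+ double-positive cells is
    multiplied by ``coloc_effect``. Every cell has a positive DAPI
    (nuclear) signal; positive and negative marker intensities are drawn
    from well-separated distributions.
    """
    if n_rois < 2 or n_rois % 2:
        raise InvalidArgumentError("n_rois must be even and >= 2")
    if coloc_effect < 1:
        raise InvalidArgumentError("coloc_effect must be >= 1")
    rng = np.random.default_rng(seed)

    def neg(n):
        return rng.exponential(1.0, n)

    def pos(n):
        return 15.0 + rng.exponential(5.0, n)

    rows = []
    roi_class = {}
    for roi in range(n_rois):
        high = roi < n_rois // 2
        roi_id = f"ROI{roi:02d}"
        roi_class[roi_id] = "high_MMP7" if high else "low_MMP7"
        n = cells_per_roi
        tumour = rng.random(n) < 0.5
        dp_frac = min(base_dp_frac * (coloc_effect if high else 1.0), 0.9)
        double_pos = (~tumour) & (rng.random(n) < dp_frac / 0.5)
        df = pd.DataFrame({
            "cell_id": [f"{roi_id}-C{i:05d}" for i in range(n)],
            "roi_id": roi_id,
            "x": rng.uniform(0, 1000, n),
            "y": rng.uniform(0, 1000, n),
            "DAPI": 5.0 + rng.exponential(3.0, n),
            "PanCK": np.where(tumour, pos(n), neg(n)),
            "MMP7": np.where(tumour & high, pos(n), neg(n)),
            "CD14": np.where(double_pos, pos(n), neg(n)),
            "APOE": np.where(double_pos, pos(n), neg(n)),
        })
        rows.append(df)
    cells = pd.concat(rows, ignore_index=True)
    return IFDataset(cells=cells, roi_class=pd.Series(roi_class))


def write_truth(truth: SyntheticTruth, barcodes, path) -> None:
    truth.to_frame(barcodes).to_csv(path, index=False)
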