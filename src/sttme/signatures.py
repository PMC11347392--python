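"""Differential expression, gene signatures, enrichment, regulon activity
and survival stratification.

The one-vs-rest Wilcoxon DEG test mirrors the standard single-cell
marker-detection convention: genes are pre-filtered on detection
fraction and log2 fold change of pseudocounted back-transformed means,
tested with a tie-corrected rank-sum statistic, and Bonferroni-adjusted
over the genes that entered the test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from statsmodels.stats.multitest import multipletests

from sttme.cluster import ClusterAssignment, NormalizedMatrix
from sttme.errors import FormatError, InvalidArgumentError, SttmeError
from sttme.synth import BulkCohort

logger = logging.getLogger(__name__)

CONFIDENCE_LEVELS = "ABCDE"


@dataclass
class Signature:
    """An ordered gene list (top DEGs of a cluster, by avg_log2FC)."""

    name: str
    genes: list

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise InvalidArgumentError("signature genes must be unique")


def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p: exact for tiny tie-free groups,
    tie-corrected normal approximation otherwise."""
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < n1 + n2
    if n1 <= 12 and n2 <= 12 and not has_ties:
        _, p = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        _, p = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(p)


def _rank_sum_p_vectorized(X: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Tie-corrected normal-approximation rank-sum p for every column of X
    comparing rows in ``mask`` against the rest."""
    n1 = int(mask.sum())
    n2 = X.shape[0] - n1
    ranks = scipy.stats.rankdata(X, axis=0)
    R1 = ranks[mask].sum(axis=0)
    U = R1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    # tie correction per gene
    n = n1 + n2
    tie_term = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        _, counts = np.unique(X[:, j], return_counts=True)
        tie_term[j] = (counts ** 3 - counts).sum()
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sigma = np.sqrt(np.maximum(sigma2, 0))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (U - mu - 0.5 * np.sign(U - mu)) / sigma
    p = 2 * scipy.stats.norm.sf(np.abs(z))
    p = np.where(sigma > 0, p, 1.0)
    return np.minimum(p, 1.0)


def wilcoxon_deg(nm: NormalizedMatrix, ca: ClusterAssignment,
                 min_pct: float = 0.1, logfc_threshold: float = 0.25,
                 min_cluster_size: int = 3) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum DEGs per cluster.

    A gene enters the test for a cluster when max(pct_in, pct_out) >=
    ``min_pct`` and |avg_log2FC| >= ``logfc_threshold`` where avg_log2FC
    = log2((mean(expm1(in)) + 1) / (mean(expm1(out)) + 1)). Bonferroni
    correction is applied over the genes entering the test per cluster.
    """
    if ca.n_clusters < 2:
        raise SttmeError("need >= 2 clusters")
    rows = []
    X = nm.values
    for c in range(ca.n_clusters):
        mask = ca.labels == c
        if mask.sum() < min_cluster_size:
            logger.warning("cluster %d has < %d spots; skipped", c, min_cluster_size)
            continue
        Xin, Xout = X[mask], X[~mask]
        pct_in = (Xin > 0).mean(axis=0)
        pct_out = (Xout > 0).mean(axis=0)
        mean_in = np.expm1(Xin).mean(axis=0)
        mean_out = np.expm1(Xout).mean(axis=0)
        lfc = np.log2((mean_in + 1.0) / (mean_out + 1.0))
        enter = (np.maximum(pct_in, pct_out) >= min_pct) & \
                (np.abs(lfc) >= logfc_threshold)
        idx = np.flatnonzero(enter)
        if len(idx) == 0:
            continue
        n_tested = len(idx)
        n_in, n_out = int(mask.sum()), int((~mask).sum())
        if n_in <= 12 and n_out <= 12:
            pvals = np.array([_rank_sum_p(Xin[:, j], Xout[:, j]) for j in idx])
        else:
            pvals = _rank_sum_p_vectorized(X[:, idx], mask)
        for j, p in zip(idx, pvals):
            rows.append((nm.gene_ids[j], c, lfc[j], pct_in[j], pct_out[j],
                         p, min(1.0, p * n_tested)))
    return pd.DataFrame(rows, columns=["gene", "cluster", "avg_log2FC",
                                       "pct_in", "pct_out", "p_value",
                                       "p_adj_bonferroni"])


def top_signature(deg: pd.DataFrame, cluster: int, k: int = 50,
                  name: str | None = None) -> Signature:
    """Top-k genes of a cluster by positive avg_log2FC among p_adj < .05."""
    if k == 0:
        logger.warning("k=0 requested; returning empty signature")
        return Signature(name=name or f"cluster{cluster}", genes=[])
    sub = deg[(deg["cluster"] == cluster) & (deg["p_adj_bonferroni"] < 0.05)
              & (deg["avg_log2FC"] > 0)]
    sub = sub.sort_values("avg_log2FC", ascending=False, kind="stable")
    return Signature(name=name or f"cluster{cluster}",
                     genes=sub["gene"].head(k).tolist())


def tumor_specific_genes(deg_tables: list, lfc: float = 0.25,
                         p: float = 0.05) -> set:
    """Genes upregulated (avg_log2FC > lfc, p < p, strict) in every table."""
    if len(deg_tables) == 0 or any(t.empty for t in deg_tables):
        raise InvalidArgumentError("all DEG tables must be non-empty")
    sets = []
    for t in deg_tables:
        passing = t[(t["avg_log2FC"] > lfc) & (t["p_value"] < p)]
        sets.append(set(passing["gene"]))
    result = set.intersection(*sets)
    if not result:
        logger.warning("tumour-specific intersection is empty")
    return result


def read_gmt(path) -> dict[str, list]:
    """Read a GMT gene-set collection (name, description, genes...)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def enrich_hypergeometric(hits: set, gene_sets: dict, universe: set) -> pd.DataFrame:
    """Over-representation by upper-tail hypergeometric test, BH-adjusted.

    p = P(X >= overlap) for X ~ Hypergeom(N=|universe|, K=|set in
    universe|, n=|hits|). Gene sets are intersected with the universe.
    """
    if not universe:
        raise InvalidArgumentError("universe must be non-empty")
    hits = set(hits)
    if not hits <= universe:
        raise InvalidArgumentError("hits must be a subset of the universe")
    N, n = len(universe), len(hits)
    rows = []
    for name, genes in gene_sets.items():
        in_uni = set(genes) & universe
        K = len(in_uni)
        overlap = len(in_uni & hits)
        pv = float(scipy.stats.hypergeom.sf(overlap - 1, N, K, n))
        rows.append((name, overlap, K, pv))
    df = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "p"])
    if len(df):
        df["p_adj_bh"] = multipletests(df["p"], method="fdr_bh")[1]
    else:
        df["p_adj_bh"] = []
    return df


def read_regulons(path) -> pd.DataFrame:
    """Read a regulon TSV (tf, target, mode, confidence)."""
    df = pd.read_csv(path, sep="\t")
    required = {"tf", "target", "mode", "confidence"}
    if not required.issubset(df.columns):
        raise FormatError(f"regulon table requires columns {sorted(required)}")
    if df.duplicated(["tf", "target"]).any():
        raise FormatError("duplicate (tf, target) pair in regulon table")
    return df


def regulon_activity(nm: NormalizedMatrix, regulons: pd.DataFrame,
                     confidence_max: str = "C", min_targets: int = 5,
                     ) -> pd.DataFrame:
    """Spot x TF activity as the signed mean of target gene z-scores.

    activity(s, tf) = mean over targets of mode * z(gene expression
    across spots). Regulons with fewer than ``min_targets`` present
    targets are skipped; only interactions at confidence
    A..``confidence_max`` are used.
    """
    allowed = set(CONFIDENCE_LEVELS[: CONFIDENCE_LEVELS.index(confidence_max) + 1])
    reg = regulons[regulons["confidence"].isin(allowed)]
    gene_pos = {g: i for i, g in enumerate(nm.gene_ids)}
    sd = nm.values.std(axis=0)
    mean = nm.values.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(sd > 0, (nm.values - mean) / sd, 0.0)
    activities = {}
    for tf, sub in reg.groupby("tf", sort=True):
        present = sub[sub["target"].isin(gene_pos)]
        if len(present) < min_targets:
            logger.warning("regulon %s has %d present targets; skipped", tf, len(present))
            continue
        idx = [gene_pos[t] for t in present["target"]]
        modes = present["mode"].to_numpy(dtype=float)
        activities[tf] = (Z[:, idx] * modes).mean(axis=1)
    if not activities:
        raise SttmeError("no usable regulon (>= min_targets present targets)")
    return pd.DataFrame(activities, index=nm.barcodes)


@dataclass
class SurvivalCohort:
    """Per-patient expression with follow-up time (days) and event flag."""

    expression: pd.DataFrame  # genes x patients
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        self.event = np.asarray(self.event, int)
        if (self.time <= 0).any():
            raise InvalidArgumentError("survival times must be positive")
        if not set(np.unique(self.event)) <= {0, 1}:
            raise InvalidArgumentError("event flags must be 0/1")

    @classmethod
    def from_bulk(cls, cohort: BulkCohort) -> "SurvivalCohort":
        return cls(expression=cohort.expression, time=cohort.time,
                   event=cohort.event)

    @classmethod
    def read_csv(cls, path) -> "SurvivalCohort":
        df = pd.read_csv(path)
        for colname in ("patient_id", "time", "event"):
            if colname not in df.columns:
                raise FormatError(f"survival CSV missing column {colname!r}")
        genes = [c for c in df.columns if c not in ("patient_id", "time", "event")]
        expr = df[genes].T
        expr.columns = df["patient_id"]
        return cls(expression=expr, time=df["time"].to_numpy(),
                   event=df["event"].to_numpy())


def score_bulk_signature(cohort: SurvivalCohort, signature: Signature) -> np.ndarray:
    """Per-patient mean of per-gene z-scored expression over signature genes."""
    present = [g for g in signature.genes if g in cohort.expression.index]
    if not present:
        raise SttmeError("no signature gene present in cohort")
    X = cohort.expression.loc[present].to_numpy(dtype=float)
    sd = X.std(axis=1, keepdims=True)
    mean = X.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(sd > 0, (X - mean) / sd, 0.0)
    return Z.mean(axis=0)


@dataclass
class KMResult:
    groups: np.ndarray            # "high" / "low" per patient
    km_high: KaplanMeierFitter
    km_low: KaplanMeierFitter
    statistic: float
    p_value: float


def km_logrank(cohort: SurvivalCohort, score: np.ndarray) -> KMResult:
    """Median-split Kaplan-Meier comparison with a two-group log-rank test.

    Patients at or below the median score go to the low group. Requires
    >= 10 patients, a non-degenerate split, and at least one event.
    """
    score = np.asarray(score, float)
    if len(score) < 10:
        raise InvalidArgumentError("need >= 10 patients")
    if np.ptp(score) == 0:
        raise SttmeError("all scores identical; split is degenerate")
    if cohort.event.sum() == 0:
        raise SttmeError("no events observed; log-rank undefined")
    median = np.median(score)
    high = score > median
    if not high.any() or high.all():
        raise SttmeError("median split produced an empty group")
    groups = np.where(high, "high", "low")
    km_high = KaplanMeierFitter().fit(cohort.time[high], cohort.event[high],
                                      label="high")
    km_low = KaplanMeierFitter().fit(cohort.time[~high], cohort.event[~high],
                                     label="low")
    res = logrank_test(cohort.time[high], cohort.time[~high],
                       cohort.event[high], cohort.event[~high])
    return KMResult(groups=groups, km_high=km_high, km_low=km_low,
                    statistic=float(res.test_statistic), p_value=float(res.p_value))
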