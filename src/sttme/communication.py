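"""Ligand-receptor cell-cell communication between spot clusters.

Communication probability between a sender and receiver cluster for one
interaction is a Hill function of the product of the sender's ligand
expression and the receiver's receptor expression, with multi-subunit
complexes pooled by geometric mean (any missing subunit zeroes the
complex). Significance comes from permuting cluster labels over spots;
pathway and cluster strengths aggregate the significant probabilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from sttme.cluster import ClusterAssignment, NormalizedMatrix
from sttme.errors import FormatError, InvalidArgumentError

logger = logging.getLogger(__name__)

# built-in mini database covering the MIF, SEMA3 and MK pathways;
# real analyses should supply a full database file
BUILTIN_LR = [
    ("MIF_CD74_CXCR4", "MIF", ["MIF"], ["CD74", "CXCR4"]),
    ("MIF_CD74_CD44", "MIF", ["MIF"], ["CD74", "CD44"]),
    ("SEMA3A_NRP1_PLXNA4", "SEMA3", ["SEMA3A"], ["NRP1", "PLXNA4"]),
    ("SEMA3B_NRP1_PLXNA4", "SEMA3", ["SEMA3B"], ["NRP1", "PLXNA4"]),
    ("SEMA3C_NRP2_PLXNA4", "SEMA3", ["SEMA3C"], ["NRP2", "PLXNA4"]),
    ("MDK_SDC1", "MK", ["MDK"], ["SDC1"]),
    ("MDK_SDC4", "MK", ["MDK"], ["SDC4"]),
    ("MDK_NCL", "MK", ["MDK"], ["NCL"]),
    ("MDK_ITGA4_ITGB1", "MK", ["MDK"], ["ITGA4", "ITGB1"]),
    ("MDK_ITGA6_ITGB1", "MK", ["MDK"], ["ITGA6", "ITGB1"]),
]


@dataclass
class LRDatabase:
    """Interaction table: id, pathway, ligand subunits, receptor subunits."""

    interactions: pd.DataFrame  # interaction_id, pathway, ligand, receptor (lists)

    def __post_init__(self) -> None:
        req = {"interaction_id", "pathway", "ligand", "receptor"}
        if not req.issubset(self.interactions.columns):
            raise FormatError(f"LR database requires columns {sorted(req)}")
        if self.interactions["interaction_id"].duplicated().any():
            raise FormatError("duplicate interaction_id")
        for _, row in self.interactions.iterrows():
            if not row["ligand"] or not row["receptor"]:
                raise FormatError(f"empty gene list in {row['interaction_id']}")

    @classmethod
    def builtin(cls) -> "LRDatabase":
        df = pd.DataFrame(BUILTIN_LR,
                          columns=["interaction_id", "pathway", "ligand", "receptor"])
        return cls(interactions=df)

    @classmethod
    def read_csv(cls, path) -> "LRDatabase":
        """CSV with '|'-separated subunits in the ligand/receptor columns."""
        df = pd.read_csv(path)
        df["ligand"] = df["ligand"].astype(str).str.split("|")
        df["receptor"] = df["receptor"].astype(str).str.split("|")
        df = df.rename(columns={"pathway_name": "pathway"}) \
            if "pathway_name" in df.columns else df
        return cls(interactions=df)

    def to_csv(self, path) -> None:
        out = self.interactions.copy()
        out["ligand"] = out["ligand"].map("|".join)
        out["receptor"] = out["receptor"].map("|".join)
        out.to_csv(path, index=False)


@dataclass
class CommunicationTensor:
    """Sender x receiver x interaction probabilities and p-values."""

    prob: np.ndarray
    interaction_ids: list
    pathways: list                       # pathway per interaction
    pval: np.ndarray | None = None
    parameters: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return self.prob.shape[0]

    def outgoing_strength(self, significant_only: bool = False,
                          alpha: float = 0.05) -> np.ndarray:
        P = self._masked(significant_only, alpha)
        return P.sum(axis=(1, 2))

    def incoming_strength(self, significant_only: bool = False,
                          alpha: float = 0.05) -> np.ndarray:
        P = self._masked(significant_only, alpha)
        return P.sum(axis=(0, 2))

    def _masked(self, significant_only: bool, alpha: float) -> np.ndarray:
        if significant_only and self.pval is not None:
            return np.where(self.pval < alpha, self.prob, 0.0)
        return self.prob


def cluster_mean_expression(nm: NormalizedMatrix, ca: ClusterAssignment,
                            trim: float = 0.1) -> pd.DataFrame:
    """Per-cluster trimmed mean of normalized expression (cluster x gene)."""
    rows = []
    for c in range(ca.n_clusters):
        sub = nm.values[ca.labels == c]
        if trim > 0:
            rows.append(scipy.stats.trim_mean(sub, trim, axis=0))
        else:
            rows.append(sub.mean(axis=0))
    return pd.DataFrame(np.vstack(rows), columns=nm.gene_ids,
                        index=range(ca.n_clusters))


def _complex_expression(expr: pd.DataFrame, genes: list) -> np.ndarray | None:
    """Geometric mean over subunits; any missing subunit -> None (skip)."""
    if any(g not in expr.columns for g in genes):
        return None
    vals = expr[genes].to_numpy(float)
    vals = np.clip(vals, 0.0, None)
    # geometric mean: zero if any subunit is zero
    return np.exp(np.where((vals > 0).all(axis=1),
                           np.log(np.where(vals > 0, vals, 1.0)).mean(axis=1),
                           -np.inf))


def communication_probability(expr: pd.DataFrame, db: LRDatabase,
                              K: float = 0.5, n_hill: float = 1.0,
                              ) -> CommunicationTensor:
    """Hill-function communication probabilities for every cluster pair.

    prob(i -> j, interaction) = (l*r)^n / (K^n + (l*r)^n) with l the
    geometric-mean ligand expression in sender i and r the
    geometric-mean receptor expression in receiver j. Interactions with
    genes absent from the matrix are skipped with a warning.
    """
    if K <= 0:
        raise InvalidArgumentError("K must be > 0")
    n_clusters = len(expr)
    probs, ids, pathways = [], [], []
    for _, row in db.interactions.iterrows():
        lig = _complex_expression(expr, row["ligand"])
        rec = _complex_expression(expr, row["receptor"])
        if lig is None or rec is None:
            logger.warning("interaction %s has absent genes; skipped",
                           row["interaction_id"])
            continue
        lr = np.outer(lig, rec)
        with np.errstate(over="ignore"):
            x = lr ** n_hill
            probs.append(x / (K ** n_hill + x))
        ids.append(row["interaction_id"])
        pathways.append(row["pathway"])
    if not ids:
        raise InvalidArgumentError("no interaction usable with this matrix")
    prob = np.stack(probs, axis=-1)  # sender x receiver x interaction
    assert prob.shape[:2] == (n_clusters, n_clusters)
    return CommunicationTensor(prob=prob, interaction_ids=ids, pathways=pathways,
                               parameters=dict(K=K, n_hill=n_hill))


def permutation_significance(nm: NormalizedMatrix, ca: ClusterAssignment,
                             db: LRDatabase, n_perm: int = 100, seed: int = 0,
                             trim: float = 0.1, K: float = 0.5,
                             n_hill: float = 1.0) -> CommunicationTensor:
    """Permutation p-values for the communication probabilities.

    Cluster labels are permuted over spots ``n_perm`` times; for each
    tensor cell, p = (1 + #{permuted prob >= observed}) / (n_perm + 1).
    """
    if n_perm < 20:
        raise InvalidArgumentError("need n_perm >= 20")
    expr = cluster_mean_expression(nm, ca, trim=trim)
    ct = communication_probability(expr, db, K=K, n_hill=n_hill)
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(ct.prob)
    for _ in range(n_perm):
        perm = rng.permutation(ca.labels)
        ca_p = ClusterAssignment(labels=perm, method=ca.method,
                                 parameters=ca.parameters, provenance=ca.provenance)
        expr_p = cluster_mean_expression(nm, ca_p, trim=trim)
        ct_p = communication_probability(expr_p, db, K=K, n_hill=n_hill)
        exceed += ct_p.prob >= ct.prob
    ct.pval = (1.0 + exceed) / (n_perm + 1.0)
    return ct


def aggregate(ct: CommunicationTensor, alpha: float = 0.05) -> dict:
    """Pathway-level probabilities and cluster communication strengths.

    Pathway probability sums the member interactions' probabilities
    (restricted to p < alpha when p-values are available); outgoing and
    incoming strengths are the sender-row and receiver-column sums.
    """
    P = ct._masked(ct.pval is not None, alpha)
    pathways = sorted(set(ct.pathways))
    pathway_prob = {
        pw: P[:, :, [i for i, x in enumerate(ct.pathways) if x == pw]].sum(axis=2)
        for pw in pathways
    }
    outgoing = P.sum(axis=(1, 2))
    incoming = P.sum(axis=(0, 2))
    pathway_totals = {pw: float(m.sum()) for pw, m in pathway_prob.items()}
    ranked = sorted(pathway_totals, key=lambda pw: -pathway_totals[pw])
    return {
        "pathway_prob": pathway_prob,
        "outgoing_strength": outgoing,
        "incoming_strength": incoming,
        "pathway_totals": pathway_totals,
        "ranked_pathways": ranked,
    }
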