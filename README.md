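# sttme — spatial-transcriptomics tumour-microenvironment analysis

`sttme` implements an end-to-end analysis of Visium-style spatial
transcriptomics of solid tumours (developed around non-small cell lung
cancer sections), for computational biologists who want the full chain
from raw spot counts to malignant-spot calls, immune-pattern signatures
and cell–cell communication — together with a synthetic-data generator
that makes every step testable against planted ground truth.

## What it computes

**Two-phase malignant-spot identification.** Spots are clustered on
expression (log-CPM or Pearson residuals → 3000 HVGs → 30 PCs →
shared-nearest-neighbour graph + modularity communities). Each spot
gets an *immune score*, the mean normalized expression of a 10-gene
panel (PTPRC; CD2/CD3D/CD3E/CD3G; CD79A/MS4A1/CD79B; CD68/CD14); the
cluster with the highest immune score becomes the copy-number-neutral
reference. Copy-number profiles are then inferred per spot against that
reference:

```
E = log2(count / nUMI · 10⁴ + 1)
E ← E − mean_ref(E)            (per gene)
E ← clip(E, ±3)
S = moving_average_w(E)        (per chromosome, window w = 101 genes)
S ← S − median_spot(S)         (per spot)
S ← S − mean_ref(S)            (per gene)
```

The per-spot CNV score is `mean_g S²`. Non-reference spots are
hierarchically clustered on `S` (Ward, k clusters); a cluster is called
**malignant** when its scores are significantly elevated over the
reference (one-sided Mann–Whitney, Bonferroni over k) *and* its median
score is at least `min_effect` times the reference median. An
epithelial score (EPCAM/KRT8/KRT19) confirms the calls.

**Signatures and survival.** One-vs-rest Wilcoxon rank-sum DEGs
(min.pct = 0.1, |avg_log2FC| ≥ 0.25, Bonferroni), top-50 signatures,
tumour-specific gene intersection, hypergeometric gene-set
over-representation (BH-adjusted), regulon activity as signed mean
target z-scores, and Kaplan–Meier median-split stratification with the
log-rank test on bulk cohorts.

**Spatial co-localization.** Spearman marker correlations (exact
permutation p for n ≤ 9), plus an edge-count statistic on the hex
spot lattice: the number of edges joining high-MMP7 to high-APOE spots
against a permutation null. The multiplex-IF side classifies cells by
per-channel positivity (Otsu thresholds by default, DAPI required),
counts CD14⁺ and CD14⁺APOE⁺ cells per ROI, and compares high- vs
low-MMP7 ROI classes with a one-sided exact Mann–Whitney test. A 0–12
product IHC score (intensity 0–3 × area bin 0–4) is included.

**Cell–cell communication.** For each ligand–receptor interaction,
`prob(i→j) = (l·r)ⁿ / (Kⁿ + (l·r)ⁿ)` where `l`, `r` are geometric-mean
subunit expressions of sender/receiver trimmed-mean cluster profiles
(any missing subunit zeroes the complex). Significance by permuting
cluster labels; pathway (MIF, SEMA3, MK built in) and
outgoing/incoming cluster strengths aggregate the significant
probabilities.

**Synthetic data.** Spots are Dirichlet mixtures of six cell-type
profiles on a hex lattice with concentric tumour-core / immune-ring /
normal / stroma regions; counts are negative binomial; tumour
components carry a planted arm-level fold gain; bulk cohorts have
signature-dependent exponential hazards; IF cell tables plant a
double-positive density effect. Every planted feature is returned as
ground truth.

## Worked example

```bash
sttme synth spots  --seed 3 --out-dir demo --n-spots 300 --n-genes 800 --n-chroms 4
sttme synth cohort --seed 3 --out-dir demo
cat > demo/config.yaml <<'YAML'
seed: 3
out_dir: demo/out
inputs:
  matrix: demo/matrix.mtx
  features: demo/features.tsv
  barcodes: demo/barcodes.tsv
  positions: demo/tissue_positions.csv
  genome_bed: demo/genome.bed
  truth: demo/truth.csv
  survival: demo/cohort.csv
malignancy: {window: 51, min_effect: 3.0, k_phase2: 4}
YAML
sttme run -c demo/config.yaml
```

The run report (`demo/out/report.json`) contains, for this seed:

- `malignancy`: 4 expression clusters; cluster 1 (the immune
  infiltrate) chosen as reference; 90 spots called malignant with
  precision 0.978 and recall 1.0 against the packaged truth; the
  epithelial-score median is highest in the malignant group (3.70 vs
  3.06 "other" and 2.56 reference), confirming the calls.
- `coloc`: the planted MMP7/APOE pair shows 162 high–high lattice
  edges, z = 3.37, permutation p = 0.003, and spot-level Spearman
  rho = 0.26 — the myeloid/tumour co-location pattern.
- `survival`: the largest cluster signature splits the synthetic
  cohort into groups with log-rank p < 0.001, the high-signature group
  faring worse.
- `communication`: the tumour cluster is the top sender and the
  MK/SEMA3/MIF pathways rank highest, with outgoing/incoming strengths
  per cluster.

`sttme run` prints the report hash; rerunning the same config and seed
reproduces it exactly.

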