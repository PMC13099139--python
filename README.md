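# centroscreen

Analysis pipeline for the spatial organization of centromeres in the human
cell nucleus, from multi-channel fluorescence images (or pre-extracted
per-cell feature tables) to a per-gene hit list for an arrayed,
imaging-based CRISPR knockout screen.

Centromeres — visualized as one CENP-C focus per chromosome — occupy
non-random positions in the interphase nucleus and serve as convenient
proxies for higher-order genome architecture. `centroscreen` quantifies
their distribution per cell, assigns cell-cycle phases, and turns a
384-well screen's worth of such measurements into ranked, direction-labeled
gene calls. A synthetic-data generator with full ground truth makes every
stage testable without any imaging data.

## What it computes

**Clustering score.** For the N spots of one nucleus observed inside its
segmented mask (area A), the empirical Ripley's K function

```
K̂(r) = A / (N(N−1)) · Σ_{i≠j} 1[d_ij ≤ r]
```

is compared against a Monte-Carlo baseline of uniform (CSR) patterns with
the same N drawn inside the same mask — no analytic edge correction, so
arbitrarily irregular nuclei are handled exactly. The per-cell score is the
CSR-standardized K deviation averaged over radii r = {0.05, …, 0.50} ·
R_eq, with R_eq = √(A/π):

```
score = mean_r [ (K̂(r) − μ_CSR(r)) / σ_CSR(r) ]
```

Positive = clustered, negative = dispersed; scaling radii by R_eq makes
the score independent of nuclear size, and the per-N baseline makes it
robust to spot count.

**Spot detection.** Multi-scale Laplacian-of-Gaussian filtering inside the
nuclear mask; maxima above k·MAD of the response (default k = 8) are
watershed-segmented and localized by response-weighted centroids to
sub-pixel precision.

**Cell-cycle gating.** log2 integrated DAPI intensity is bimodal (2N/4N
modes one unit apart); a two-component Gaussian mixture on EdU-negative
cells locates the modes. Cells with detectable EdU are S phase; DNA content
below G1 − 3σ (subG1) or above G2 + 3σ (>4N) is excluded.

**Hit calling.** Per-cell features are averaged per well over QC-passing
nuclei (solidity ≥ 0.85, area ≥ 30 µm², not border-touching), normalized
per plate against the library-well median with a robust Z-score
(Z = (x − median)/(1.4826·MAD)), re-standardized per replicate, and
averaged across the two biological replicates. After excluding dysmorphic
(> 50 % QC failure), cytotoxic (cell-number Z < −2.5) and
replicate-inconsistent (|mean Z| < replicate SD) genes, hits are genes with
|mean Z| > 2.5 on the clustering score or the spot count.

## Worked example

Simulate a small feature-level screen (96 genes + 28 control wells, two
replicates), gate, normalize and call hits:

```bash
centroscreen run --out demo --seed 1
```

which prints `0 hits; manifest at demo/manifest.json` (an all-null library
produces no hits) and writes `demo/report.txt`:

```
centroscreen run report
=======================
cells analysed: 13856 (13175 passing QC)
library genes: 96
hits: 0

exclusions:
  none: 96

control separation (mean clustering Z by role):
  NCAPH2: +3.58
  OR10A5: -0.06
  PLK1: n/a (no usable wells)
  library: -0.13
  scrambled: -0.31

per-phase clustering score (QC-passing cells):
  G1: mean +0.089 (n=6362)
  G2M: mean +0.098 (n=2507)
  S: mean +0.083 (n=3905)
```

Reading this: the NCAPH2-like positive control (simulated with a +4
well-SD clustering effect) separates cleanly at mean Z ≈ +3.6; the
PLK1-like cytotoxic control kills nearly all cells, so its wells fall
below the 20-cell minimum and receive no Z-score; negative controls and
the null library sit at Z ≈ 0, and no library gene crosses the ±2.5 hit
threshold. Per-phase clustering means are flat, as expected for a null
population.

The same stages are available as `simulate`, `detect`, `score`, `gate`,
`screen` and `report` subcommands for running on individual TIFF fields
and CSV tables, and as plain Python functions (`centroscreen.clustering_score`,
`centroscreen.run_screen_analysis`, …).

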