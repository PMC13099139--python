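# Methods

This note documents the models, estimators and design choices behind
`centroscreen`, what the synthetic-data generator does and does not
emulate, and the numerical conventions used throughout.

## Coordinates, units, conventions

Images are 2D arrays indexed (row, col), 0-based, with pixel centers at
integer positions. Masks are boolean pixel grids; a sub-pixel point belongs
to the pixel it rounds to. All physical quantities are metric: lengths in
µm (default pixel size 0.108 µm/pixel, matching a 60× water objective on a
16-bit sCMOS detector; configurable everywhere), areas in µm². Every
stochastic routine takes an explicit integer seed; identical seeds give
bit-identical results at every level, including written CSVs.

## Clustering score

The per-cell statistic is a CSR-standardized, radius-averaged deviation of
the empirical Ripley's K function computed inside the nuclear mask:

* K̂(r) = A/(N(N−1)) · Σ_{i≠j} 1[d_ij ≤ r], with A the mask area and N the
  spot count. Defined for N ≥ 2; cells with fewer spots propagate as
  missing for clustering-score aggregation but still count toward
  spot-count statistics.
* The null is complete spatial randomness **within the mask**: uniform
  over mask pixels with ±0.5 px sub-pixel jitter. For each (mask, N) a
  Monte-Carlo baseline of n_mc = 100 replicates supplies the per-radius
  mean μ(r) and SD σ(r); baselines are cached keyed by mask content hash,
  N, radii, n_mc and seed, so screens scoring many cells that share a
  segmentation mask pay for each baseline once.
* score = mean over r ∈ {0.05, 0.10, …, 0.50}·R_eq of (K̂(r) − μ(r))/σ(r),
  R_eq = √(A/π). Ten radii cover sub-nuclear scales without saturating K
  near the mask diameter. Positive = clustered, negative =
  dispersed/over-regular.

Design notes:

* **No analytic edge correction.** Translation/isotropic corrections
  assume simple windows; the mask-constrained Monte-Carlo baseline absorbs
  boundary effects exactly for arbitrary (including non-convex) nuclei.
  A consequence worth knowing: the *raw* K̂ under CSR carries a negative
  O(r/R) boundary bias relative to πr², which cancels in the standardized
  score because the baseline carries the same bias.
* **Size and count robustness.** Scaling radii by R_eq removes nuclear
  size from the score; standardizing per (mask, N) removes the spot-count
  dependence. Both properties are verified empirically in the acceptance
  suite (stratum means within ±0.15 over R_eq ∈ {3, 6, 10} µm × N ∈
  {23, 46, 92}; pairwise differences of per-N means < 0.1).
* **Null scale.** Because the ten per-radius deviations are positively
  correlated, the null score SD is ≈ 0.75-0.8, not 1; it is stable across
  sizes and counts, which is what the downstream robust-Z normalization
  needs.
* **Scale invariance is exact only in the continuum.** The ±0.5 px jitter
  has different relative size on rasters of different resolution, which
  shifts the baseline SD at the smallest radii; patterns and masks scaled
  ×2 reproduce scores to ~2-3 %, not exactly.

## Spot detection

Scale-normalized Laplacian-of-Gaussian responses (−σ²∇²G) are maximized
over 5 scales spanning σ = 1.0-2.0 px. The scale range deliberately
brackets the point-spread function of diffraction-limited centromere foci
(σ ≈ 1.5 px at 0.108 µm/px): scales much coarser than the PSF let the
fused response of a just-resolved spot pair outweigh the pair's individual
fine-scale peaks and collapse it into one detection, measurably costing
recall on spot pairs 4-5 px apart.

Candidate maxima must lie inside the nucleus mask and exceed k·(1.4826·MAD)
of the response image, default k = 8; the robust noise unit makes the
threshold transfer across exposure levels. Maxima closer than one σ are
merged (stronger wins). Each surviving peak's focus is segmented by a
watershed on the inverted response, and the reported coordinate is the
response-weighted centroid of the focus — sub-pixel accurate (< 0.01 px
RMS noiseless, ≈ 0.3 px at peak SNR 10).

Spots are assigned to nuclei strictly by mask membership; spots outside
every mask are dropped.

## Nuclear segmentation and QC

Segmentation is deliberately simple — Otsu threshold on DAPI, hole
filling, removal of sub-nuclear debris, distance-transform watershed
splitting of touching objects, border flagging — because the synthetic
fields it must serve have controlled density and contrast. It is not
intended for real tissue-culture images.

The QC predicate excludes micronuclei and dysmorphic nuclei: a nucleus is
analysable iff solidity ≥ 0.85 **and** area ≥ 30 µm² **and** it does not
touch the field border. Cuts are strict as stated (boundary values pass).

Normalized radial position of a spot is its distance from the nucleus
centroid divided by the centroid-to-boundary distance along the same ray
(range [0, 1]; uniform points in a disk average 2/3).

## Cell-cycle gating

Integrated DAPI intensity doubles from G1 to G2/M, so log2 DAPI is bimodal
with modes one unit apart. The gate is fitted per pooled population
(default per plate × replicate, ≥ 200 cells):

1. The EdU threshold comes first: the valley between the two dominant
   modes of the log2 EdU histogram (64 bins, Gaussian-smoothed). If EdU is
   unimodal — no S-phase population — the fallback cut is the 99th
   percentile of the background mode plus a 0.5 log2 margin, so background
   cells are never called S.
2. A two-component Gaussian mixture with deterministic percentile
   initialization (25th/75th) is fitted to log2 DAPI of **EdU-negative**
   cells, trimmed to the inner 96 %. Restricting to EdU-negative cells
   removes the S-phase bridge between the modes, which would otherwise
   bias both component means inward; when EdU is unimodal the mixture is
   fitted on all cells. Mode separation < 0.5 raises an error ("cannot
   resolve 2N/4N").
3. Cuts: G1/G2M at the mode midpoint; subG1 at G1 − 3σ₁; >4N at G2 + 3σ₂
   (the exclusion width is a choice; the exclusions themselves are part of
   the gating contract).

Assignment order: DNA content outside [subG1, >4N] ⇒ excluded; else
detectable EdU ⇒ S regardless of DNA content; else G1 vs G2M at the
midpoint. Per-phase feature summaries are computed over QC-passing,
non-excluded cells only.

## Screen analysis

The hit-calling chain follows the standard arrayed-screen convention:

1. **Well aggregation.** Arithmetic means of per-cell features over
   QC-passing cells; wells with < 20 passing cells are unusable and take
   no further part (the threshold is a choice; per-well populations in the
   emulated assay run hundreds of cells).
2. **Per-plate robust Z.** Center = median, scale = 1.4826·MAD, both over
   *usable library wells only* — control wells never influence the
   normalization and receive Z values against the library center. MAD = 0
   falls back to the SD; SD = 0 sets Z = 0 with a warning.
3. **Per-replicate standardization.** The per-plate Z values of one
   replicate are pooled across plates and robust-standardized again
   against the pooled library wells.
4. **Replicate combination.** Mean and SD across replicates per
   (plate, well) — one well per gene per plate, so per gene.
5. **Exclusions**, in order (each gene gets exactly one reason or none):
   dysmorphic (> 50 % of the gene's nuclei fail QC — the fraction is a
   choice), cytotoxic (mean cell-number Z < −2.5, strict), inconsistent
   (every feature whose |mean Z| exceeds the hit threshold has
   |mean Z| < across-replicate SD; applied only to the qualifying
   features). With a single replicate the consistency filter is skipped
   with a warning.
6. **Hits.** |mean Z| > 2.5 (strict) on the clustering score or the spot
   count. Directions from the sign of the qualifying mean Z; phenotype
   categories combine the two directions (clustering↑ + count↓ = tighter
   clustering; clustering↓ + count↑ = dispersion; both↓ = fewer, larger
   clusters).

A plain-SD (non-robust) variant of both normalization stages is available
behind a flag for sensitivity analysis. Cross-screen concordance reports
the Pearson correlation of mean clustering Z over genes not excluded in
either screen, the hit-set intersection, and per-common-hit direction
agreement. Group comparisons use one-way ANOVA + Tukey HSD or pairwise
Welch t-tests with Bonferroni correction, starred at
0.05/0.01/0.001/0.0001.

## Synthetic-data generator

The generator emulates the *statistical structure* of the screen, not its
optics or biology in detail. What it models:

* **Nuclei**: ellipses (default semi-axes 6.5 × 5.0 µm, area ≈ 102 µm²,
  typical of adherent near-diploid human cells) with optional low-order
  Fourier boundary roughness; amplitude 0.25-0.3 produces lobed,
  solidity-failing shapes for QC fixtures.
* **Spot patterns**: CSR (uniform over mask pixels + jitter), Thomas
  clusters (uniform parents, Gaussian offspring redrawn until inside the
  mask, keeping N exact), and radially biased placement (radius
  transformed by a power of a uniform variate). Default N = 46 — one
  CENP-C focus per chromosome of a diploid human karyotype; real per-cell
  counts vary with ploidy and S/G2 duplication, which the screen model
  leaves out. An optional hard-core `min_separation` yields resolvable
  spots for detection fixtures, since sub-Rayleigh pairs are an optics
  limit rather than an algorithm defect.
* **Rendering**: filled nuclei (DAPI), isotropic Gaussian PSF (σ = 1.5 px)
  at the true spot positions, per-phase EdU fill, Poisson shot noise plus
  Gaussian read noise, 16-bit clipping. No aberrations, no illumination
  gradients, no 3D stacks, no mitotic figures.
* **Cell-cycle intensities**: log2 DAPI Gaussian modes at 10.0 and 11.0
  (σ = 0.12), S cells uniform between the modes, EdU background
  log-normal with S cells shifted +2.5 log2 units, subG1/>4N contaminants
  placed outside the ±3σ band (1 %/2 % by default).
* **Screens**: 384-well plates with 7 control wells per plate each of
  scrambled, PLK1, OR10A5 and NCAPH2 roles; one gene per library well
  (1064-gene default spans 3 plates); two biological replicates sharing
  one layout. Per-well cell counts are negative-binomial (mean 200,
  dispersion 10) — overdispersion exercises the robust statistics; the
  PLK1-like control carries a 0.05× viability multiplier, the NCAPH2-like
  control a +4 SD clustering shift with a spot-count decrease.

Null per-cell clustering scores are drawn from an **empirical pool of 256
scored CSR simulations** — produced by the same scorer used downstream —
keeping generator and scorer self-consistent by construction. Per-gene
effects on the clustering score and spot count are expressed in units of
the **null well-to-well SD** (√(well-effect² + cell-level²/n̄)), the scale
on which Z-scores operate, so "shifted by 4 SD" produces mean Z ≈ 4 up to
the attenuation inherent in estimating robust scales from finite plates. A
small per-well random effect (SD 0.15 cell-SD units for clustering, 0.8
spots for counts) models plate-to-plate biology that the null genes share.

What passing tests therefore show: the estimators are calibrated, the
normalization chain is correct, and effects of the modeled kind are
recovered with the claimed sensitivity. What they do not show: performance
on real images (segmentation is synthetic-grade; CellPose-class models
would be needed), robustness to optical artifacts, or hit rates under
biological effect-size distributions.

## Numerical choices and degenerate inputs

* Robust scale constant 1.4826 makes MAD consistent for the normal.
* Baseline radii with σ = 0 (possible only in degenerate masks) are
  dropped from the score average.
* Blank images segment to an empty list, not an error; empty masks and
  N > 0 with empty masks raise.
* Strict inequalities everywhere the thresholds are stated as strict
  (2.5, −2.5, 0.85, 30 µm²); boundary values do not trigger.
* Ties in the watershed and peak merging resolve by response magnitude,
  then scan order — deterministic.
* Problem sizes in tests and the acceptance script (400 nuclei per
  calibration stratum, 200 per Thomas level, 50 rendered fields, 1000-gene
  screens at 200 cells/well, 5000 gated cells) were chosen to keep
  Monte-Carlo noise several-fold below every acceptance band while running
  in minutes on one CPU.

## Known limitations

* The clustering score's absolute values depend on the radii grid and the
  jitter convention; comparisons are meaningful within one configuration.
* The CSR baseline cache keys on the exact mask; screens where every cell
  has a unique mask pay one baseline per cell (≈ 6 ms at N ≤ 100).
* The Thomas sampler conditions on exactly N offspring (no Poisson number
  of parents/offspring), which is the right conditioning for per-cell
  scoring but differs from the textbook stationary process.
* Gate fitting assumes a dominant cycling population; strongly arrested or
  polyploid populations will fail the mode-separation check by design.
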