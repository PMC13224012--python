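# Methods

## The synthetic screen generator

### Latent model

Each cell carries a latent triple (M, R, S) — membrane potential, whole-
cell ROS, mitochondrial superoxide — modelled as a trivariate log-normal:
log-latents are Gaussian with mean `mu`, SDs `sigma` and correlation
matrix `rho` over (M, R, S), built by Cholesky factorization and
exponentiated. The log-normal was chosen for the two properties real
fluorescence intensities show: strict positivity and right skew. Defaults:
`mu = (7.3, 6.6, 7.0)` log-counts, `sigma = (0.3, 0.3, 0.3)`.

The baseline correlation structure encodes the redox-coupling hierarchy
under study:

| line | ρ(M, mtROS) | ρ(M, ROS) | ρ(ROS, mtROS) |
|------|------------|-----------|---------------|
| HPFC (normal) | 0.75 | 0.35 | 0.45 |
| HeLa (tumor)  | 0.60 | 0.30 | 0.45 |

MMP couples more tightly to mitochondrial superoxide than to whole-cell
ROS, and normal cells couple more tightly than tumor cells. ρ(ROS, mtROS)
is not constrained by the coupling analysis; 0.45 was fixed once as a
plausible overlap between the two ROS pools (both matrices are verified
positive semi-definite).

Treatment effects are median multipliers on (M, R, S) plus an off-diagonal
shrinkage of `rho`:

* **cisplatin** (both lines): M×0.4, R×2, S×2, correlations ×0.5 —
  membrane-potential collapse with an oxidative burst and broad loss of
  coupling, non-selective.
* **G4 ligands** (Pt-ttpy, 360A, Phen-DC3) in the tumor line: M×0.5,
  R×0.85, S×0.85 — depolarization *without* a ROS burst (mild ROS
  suppression).
* **G4 ligands in the normal line**: M×0.95, R and S unchanged — the
  tumor-selective action: normal cells respond only marginally.
* **EDL21** (inactive analogue) and **control**: identity in both lines.

These defaults are the package's own calibration of the qualitative
treatment structure; they are tunable per `GroupSpec` and are recorded in
every plate manifest so recovery checks always compare against the
parameters actually used.

### Rendering

Per field (default 512×512 px, 16-bit): nucleus centers are rejection-
sampled with a minimum separation so nuclei never overlap; cell bodies
are discs (radius 14–20 px) trimmed to the nearest-center region, so cell
masks are disjoint but may touch — deliberately exercising watershed
splitting downstream. Mitochondria are short 8-connected random-walk
filaments confined to the cytoplasm. Signals: Hoechst = constant
amplitude on nuclei; ROS = R×0.5 per cell pixel; mtROS/MMP = S/M per
mitochondrial pixel plus a 5% cytoplasmic haze. Noise is applied last:
Poisson shot noise at `poisson_gain` counts/photon (default 2), then
Gaussian read noise (SD 3 counts), on top of a flat background of 100
counts, clipped to the 16-bit range. Ground-truth masks are the exact
pre-noise object supports.

What the generator does **not** emulate: optics (PSF blur, vignetting,
chromatic shift), cell-shape diversity beyond discs, spatial density
gradients, batch/well position effects, debris and imaging artifacts.
Passing tests therefore demonstrate correctness of the measurement and
statistics chain under a controlled generative model — not robustness to
every pathology of real microscopy data.

### Seeding

A single master seed is expanded into per-field child seeds through
`numpy.random.SeedSequence(entropy=master, spawn_key=(field_counter,))`;
each child yields one latent-sampling seed and one rendering seed. All
outputs are byte-identical under a fixed (config, seed) pair.

## Segmentation

Nuclei: Gaussian smoothing (σ = 2 px) → Otsu threshold (configurable to a
fixed value) → connected components → watershed split on the distance
transform, markers from `peak_local_max` with a minimum peak separation of
7 px (≈ the expected nucleus radius; smaller values re-split necks of
touching pairs) → area filter (min 40 px) → contiguous relabelling.
Plateau ties resolve to the lexicographically first pixel (row-major,
0-based), making label maps exactly reproducible. Border-touching objects
are kept by default.

Cells: every background pixel within `max_distance` (default 12 px) of a
nucleus is assigned to its nearest nucleus by exact Euclidean distance
transform, restricted to the guide channel's Otsu foreground (a flat guide
imposes no restriction, so an isolated nucleus grows to its morphological
dilation by a disc). Cells inherit their seed's label; containment
(nucleus ⊆ cell) holds by construction.

Mitochondria: white top-hat with a 3-px disc isolates thin bright
structures on the MMP channel; each cell is thresholded independently
(Otsu within the cell) and the mask labelled by the parent cell, so
mito ⊆ cell always.

## Quantification

Background is a per-field, per-channel scalar: the 5th percentile of
non-cell pixels (median optional). A scalar was preferred over
rolling-ball estimation for determinism and testability. Per cell:
mean/median/integrated intensity over the channel's compartment (Hoechst
over the nucleus, others over the cell), corrected mean
`max(mean − background, 0)`, and mitochondria-restricted means for the
mmp and mtros channels. The mito-restricted corrected mean is the primary
MMP/mtROS readout (the dye signal is mitochondrial); whole-cell means are
also emitted. Means equal brute-force pixel sums ÷ area to machine
precision (tested).

## The 541-feature catalogue

The manifest (`mitohicp/data/feature_manifest_v1.csv`, version 1) is the
single source of truth; its family ledger:

| family | definition | count |
|---|---|---|
| shape | 15 descriptors × {cell, nucleus, mito} | 45 |
| intensity | 13 statistics × 3 compartments × 4 channels | 156 |
| texture | 13 Haralick statistics × 3 × 4 | 156 |
| correlation | {PCC, overlap, Manders} × 6 channel pairs × {cell, nucleus} | 36 |
| granularity | 16 opening radii × 4 channels (cell) | 64 |
| radial | 3 statistics × 4 equal-area bins × 4 channels (cell) | 48 |
| neighbors | 6 metrics × {cell, nucleus} | 12 |
| location | centroids + intensity-weighted centroids (see below) | 24 |

Location: cell and nucleus each carry centroid (2) plus the
intensity-weighted centroid per channel (8); mitochondria carry centroid
(2) plus the mmp-weighted centroid (2).

Numerical conventions:

* **GLCM texture** — intensities are min–max rescaled *within the mask* to
  64 gray levels (per-object quantization, making the statistics invariant
  to affine intensity rescale); symmetric normalized co-occurrence
  matrices are accumulated at the four axial/diagonal offsets of exact
  length `distance` (default 3) and averaged. Haralick correlation on a
  zero-variance region is defined as 0 (not missing) to avoid
  missing-value cascades in profiles.
* **Shape** — perimeter uses the Crofton 4-direction approximation, which
  is close to unbiased on smooth digital shapes, so the form factor
  4πA/P² of a digitized disc stays near 1.
* **Granularity** — fraction of initial masked intensity removed between
  openings with discs of radius r−1 and r; since the mask's complement is
  zero, the spectrum sums to 1 once the opening radius exceeds the object
  radius.
* **Missing values** — features undefined on degenerate geometry (empty
  mito mask, single-pixel objects, zero-variance channels) are NaN, never
  silently 0; per-image aggregation means over the cells where a feature
  is defined.

## Profiling

PCA operates on image-level profiles (mean feature value over the cells
of one image), not per-cell values: per-cell tables are dominated by
within-image heterogeneity, and the image is the replicate unit of a
screen. Profiles are z-scored column-wise (population SD; zero-variance
columns dropped and reported) and decomposed by covariance PCA —
equivalent to correlation PCA after z-scoring. Sign convention: each
component's largest-magnitude loading is positive. Family contributions
are sums of squared loadings over PC1–PC2, normalized across families.
Clustering uses correlation distance (1 − r) with average linkage on
per-group median profiles; Ward + Euclidean is selectable, and constant
rows are rejected under correlation distance with advice to switch.

## Coupling statistics

Pearson r per (group, readout pair), pooled over cells and per image; the
Fisher transform z_r = atanh(r) with CI z_r ± 1.96/√(n−3) back-
transformed. The comparison statistic is the independent-sample Fisher
z-test. It is applied to all three contrast families, including the
within-group MMP–ROS vs MMP–mtROS contrast where the two correlations
share the MMP variable; a dependent-correlation (Steiger) test would be
more exact there and the output metadata flags every comparison as
`independent-sample Fisher z` so downstream users can tell. One-sided p
(normal tail beyond |Z|) is the default display, with the two-sided value
stored alongside.

Scope caveat: pooled-over-cells r and the mean of per-image r values
answer different questions (per-image r removes between-image intensity
drift); both are computed and reported, and neither is privileged.

## Analysis problem sizes

The default screen is 2 cell lines × 6 treatments × 2 wells × 4 fields ×
~30 cells ≈ 2 900 cells, giving ≈ 240 quantified cells per group — above
the 200-cell floor the screen design targets. The coupling-recovery
analysis uses 10 replicates of ~1 080 cells each (45 compact 256-px
fields of 24 cells), with a ±0.10 tolerance on recovered r that budgets
both the log-to-linear attenuation of the log-normal model (at σ = 0.3,
a log-scale ρ of 0.75/0.35 corresponds to linear-scale r of 0.741/0.340)
and measurement attenuation through segmentation and noise. Type-I
calibration of the Fisher comparison runs 1 000 null replicates of
n = 500 per side on the generator's Gaussian (log) scale, where the
test's bivariate-normal assumptions hold exactly; on the linear
(log-normal) scale mild skew inflates the empirical rate slightly above
nominal, which is a property of the test, not of the implementation.

## Known limitations

* Cells are discs; shape features discriminate size and boundary effects,
  not true morphology changes, in synthetic data.
* The per-cell threshold for mitochondria under-segments dim mitochondria
  in high-haze cells; recall is tested at ≥ 0.8, not 1.
* The Fisher test on linear-scale log-normal readouts is slightly
  anti-conservative (see above); log-transforming readouts before
  correlation is recommended when distributions are strongly skewed.
* No batch-effect correction, no multiple-testing correction by default
  (a Bonferroni flag exists on the summaries); stars are per-comparison.
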