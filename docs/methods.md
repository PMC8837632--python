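# Methods

`tlomap` re-implements, as a tested library, the analysis pipeline used
for 3D spatial-transcriptomics (ST) profiling of inflamed rheumatoid-
arthritis synovium: serial cryosections of a biopsy are profiled on
barcoded arrays, spots are clustered into spatial domains, cell-type
composition is estimated from marker signatures, tertiary lymphoid
organs (TLOs) are detected from nucleus density, consecutive sections
are registered into a volume, receptor–ligand signaling is scored
within spot subsets, and a Monte-Carlo power analysis guides study
design. Every stage runs end-to-end on a synthetic volume generator
with known ground truth.

## Synthetic volume generator

The generator emulates the tissue architecture the pipeline is built
to detect, not the sequencing chemistry.

* **Geometry.** Spots lie on a jittered square grid with a 200 px
  pitch (one spot ≈ one 100 µm capture area plus its 200 × 200 px H&E
  crop window); each of `n_sections` sections re-jitters the grid. The
  axial coordinate is `section_index × spacing` (7 µm for consecutive
  sections, 21 µm for spaced series).
* **Zones.** Distance bands around one or more TLO centers define four
  radial zones — `TLO_core`, `ring1`, `ring2`, `lining` — mirroring the
  radial organization of lymphocytic aggregates in synovium. Each zone
  has a base cell-type mixture (core: T/B-lymphocyte rich in the
  "seropositive" group, fibroblast/dendritic-cell rich in the
  "seronegative" group; ring1 macrophage-heavy; ring2 fibroblast-heavy;
  lining a distinct synoviocyte-like mixture). Per-spot mixtures are
  Dirichlet draws around the zone base (concentration 30), so
  composition varies within zones as well as between them.
* **Expression.** A marker-block signature matrix gives each of
  `n_cell_types` types a disjoint block of `markers_per_type` genes
  elevated `2**marker_logfc`-fold (default 4-fold) over a flat
  background. A spot's expected profile is `depth × (π · B)` with the
  profile row-normalized; `depth` is lognormal around `depth_mean`
  (default 5000 UMIs, σ = 0.3 on the log scale) to exercise size-factor
  normalization. Counts are negative binomial with shared size
  parameter (default 10); the NB is the standard overdispersed count
  model for ST spots, and the size → ∞ limit recovers Poisson noise.
* **Cells.** Expected nucleus counts per spot window are zone constants
  (core 60, ring1 30, ring2 20, lining 12); realized counts are
  Poisson, centroids uniform in the window, and nucleus areas smaller
  in the core (mean 30 px² vs 80 px² outside) — dense small lymphocytes
  against sparse large stromal cells. Core spots carry an
  `"infiltrate"` annotation emulating manual histology labels.

What the generator does **not** model: segmentation errors, spot–image
misalignment, zero-inflation beyond NB sampling, per-gene dispersion
heterogeneity, batch effects between sections, and partial tissue
detachment. Passing tests therefore demonstrate correctness of the
algorithms under a faithful but idealized tissue model, not robustness
to every artifact of real arrays.

## Preprocessing

Spots with fewer than 200 detected genes are removed (inclusive at
exactly 200 — "minimal size" is read as a lower bound). Two
normalizations are provided:

* `size_factor_log`: `log1p(count / (total_i / median total))`.
* `regression_residual` (default for clustering): per-gene Pearson
  residuals of the depth-offset count model `mu_ij = total_i ×
  gene_share_j`, clipped at ±√n_spots. This is the analytic form of a
  per-gene regression on log total counts and removes depth without a
  log transform.

Variable genes are ranked by the squared coefficient of variation of
size-factor-scaled counts minus the across-gene median CV² (computed on
the linear scale, per the stated order of operations); ties break
toward higher mean, then gene symbol, for determinism. The statistic is
informative only when per-gene counts are not vanishingly sparse
(Poisson noise contributes `1/mean` to CV²), which the tests respect.

## Spatial clustering

PCA is run on the normalized matrix restricted to the selected variable
genes. The number of informative components is chosen by a
column-permutation test: each permutation shuffles every gene column
independently, the rank-r observed eigenvalue is compared with the
rank-r permuted eigenvalues, and BH adjustment at 5% FDR across ranks
selects the component count (floored at 2 so an embedding always
exists). `n_perm` defaults to 199: the minimum attainable p-value
(1/200) must survive the BH correction over `max_pcs` ranks, which a
few dozen permutations cannot.

The retained scores feed a 3-component tSNE (3 components because the
clustering operates on three embedding coordinates; a flag restores 2),
and spots are clustered by Ward linkage on the tSNE coordinates
(ward.D2: Euclidean ward via `scipy.cluster.hierarchy.linkage`), with
the tree cut at a preset k. Cluster 1 is renumbered to the densest
cluster when a density vector is supplied, matching the convention that
the infiltrate cluster comes first.

Cluster markers use a per-gene negative binomial GLM with log-depth
offset: cluster-vs-rest indicator versus intercept-only, likelihood
ratio against χ²(1). Dispersion is a per-gene method-of-moments
estimate (`var = mu + α mu²`, floored at 1e-8) shared by both fits;
under a permuted-label null the test's type-I error at p < 0.05 sits
inside [0.03, 0.07] on 500-gene simulations. A gene is called DE at
p < 0.001 with log-ratio > 0.5 (difference of mean log1p normalized
expression). Group comparisons of per-spot scores use Welch t tests
with BH adjustment at 0.05.

## Cell-type signature scoring

Markers per cell type are filtered to average log fold change > 1
(strict) at FDR < 5% and truncated to the top 200. Scoring proceeds in
three layers:

1. **Validity filter.** When at least four markers of a type are
   present ("more than 3"), pairwise Pearson correlations across spots
   are computed and a marker is retained iff its mean correlation with
   the other markers is positive. This is the per-gene reading of the
   pairwise rule (it reduces to it for two markers); a strict all-pairs
   mode is provided for comparison. Types with 1–3 present markers are
   scored on those markers directly by default (`strict_presence=True`
   reports them as not-scoreable instead).
2. **Scores.** The raw score is the sum of the validated markers'
   normalized expression per spot; each type is then scaled by its
   maximum over spots (max-scaled ∈ [0, 1]).
3. **Proportions.** Max-scaled scores are renormalized across cell
   types within each spot. The alternative normalization over regions
   for a fixed type is exposed as a comparison mode
   (`proportion_mode="per_type_over_regions"`); the per-spot reading is
   the default because the result is described as the contribution of
   each type *in each region*, which only the within-spot sum
   delivers as a partition of unity.

Scoring operates by default on the **linear** size-factor scale
(count / median-scaled total): signature sums must be non-negative and
proportional to abundance, which signed Pearson residuals and
compressive log counts are not. An explicit `layer=` argument scores
any stored layer. Co-localization of two score maps is the Pearson
correlation across spots with a two-sided p.

## Density, registration, interpolation

Nuclei are assigned to the 200 × 200 px window centered on each spot
(boundary inclusive); spots without nuclei are flagged for removal.
The cell-density score is the within-section percentile of the window
count, `100 × (rank − 1)/(n − 1)` with average ranks for ties (a
single-spot section scores 50), and TLO candidacy is strictly
score > 70. The percentile is invariant under monotone transforms of
the counts, so it needs no kernel bandwidth.

Sections are registered by point-set least squares: a similarity
transform (rotation, isotropic scale, translation — "scaled rotation")
or a rigid transform (scale fixed at 1) mapping each section's spot
cloud onto the reference section. The inner fit is the closed-form 2D
Procrustes/Umeyama solution; correspondences come from
iterative-closest-point with 12 rotation multi-starts (30° apart),
because principal-axis pre-alignment is degenerate for near-square spot
grids. For exact transformed copies the recovered transform matches the
closed-form global optimum to machine precision.

Per-spot scalars are interpolated per section on the Delaunay
triangulation (piecewise linear, convex-hull masked, exact at spot
locations and for linear fields). Linear interpolation was chosen over
bicubic because the output is visualization-only and linear
reproduction is a testable contract. No interpolation is performed
along z; a volume is the z-ordered stack of per-section grids.

## Receptor–ligand interactions and enrichment

For a pair (A, B) and a spot subset, the statistic is the mean of the
two partners' average normalized expression in the subset. The null
permutes subset labels across all spots (n_perm = 999 by default);
`p = (1 + #{null ≥ obs}) / (n_perm + 1)` (never zero). The log
mean-expression ratio is the natural log of the subset statistic over
the all-spot statistic, and a pair is reported at ratio > 0.1 with
p < 0.01. Heteromeric complexes are out of scope (single-gene partners
only); the pair list is an input, not a bundled database.

Gene-set enrichment is the one-sided hypergeometric upper tail against
a user universe, BH controlled at 5% FDR; it matches exhaustive
enumeration exactly for universes up to 25 genes.

## Power analysis

The design has two patient groups, `S` replicate sections per patient
and `K` replicate annotated niches (spots) per section, with outcome

    y = β·group + u_patient + v_section + ε,
    u ~ N(0, σ²_p), v ~ N(0, σ²_s), ε ~ N(0, σ²_r),

and β expressed in residual-SD units so designs are comparable.
Defaults: σ²_p = 0.5, σ²_s = 0.25, σ²_r = 1, effect 1.0, α = 0.05,
n_sim = 2000. Patient means are sufficient for the group contrast, so
the simulation draws them directly (variance
`σ²_p + σ²_s/S + σ²_r/(SK)`) — making each power estimate effectively
instantaneous. The default test is the pooled two-sample t on patient
means: group variances are equal by construction, the test is exact
(size = α and agreement with the closed-form noncentral-t power,
both verified), whereas a Welch correction is visibly conservative at
3–5 patients per group. An `lmm_wald` mode fits a random-intercept
mixed model per replicate (patient intercept only; the section effect
is absorbed into the residual for fitting) for comparison at small
n_sim.

`design_search` evaluates a (patients × sections × spots) grid with a
shared base seed (common random numbers) and returns the frontier of
minimal designs reaching the 80% power target. CRN makes grid
comparisons low-variance but cannot strictly guarantee monotone
rejection fractions for a two-sided test; the monotonicity checks use
effect sizes where the power gap dominates Monte-Carlo error.

## Numerical conventions and degenerate inputs

* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); fixed seeds give byte-identical
  simulator output and deterministic tSNE embeddings.
* Zero-variance markers are dropped from correlation filters with a
  warning; all-zero genes get p = 1 in DE; zero-variance score maps
  return NaN correlations with a warning.
* Percentile scores with a single spot default to 50; ties use average
  ranks.
* Collinear spot sets are rejected by both registration and
  interpolation; subsets below 5 spots are rejected by interaction
  scoring; clusters below 3 spots are rejected by DE.
* Readers reject NaN coordinates, negative counts, and duplicate
  (barcode, section) keys with typed errors.

## Problem sizes used in tests

The test suite and the reproduction script use deliberately compact
problem sizes chosen to keep the statistical checks well-powered:
4-zone clustering runs on ~750 spots × 1000 genes over 5 seeds,
proportion recovery on ~2000 spots × 2000 genes with 5 cell types,
null calibrations on 500 genes / 200 pairs, and the power module at
n_sim = 2000. These sizes are the package's own defaults for its
validation experiments.

## Known limitations

* The signature score is a sum over markers, not a deconvolution; it
  estimates relative, not absolute, cell-type abundance, and types with
  overlapping real-world marker programs will partially alias.
* The NB LRT uses moment dispersion per gene; at very low counts the
  χ² approximation degrades (the calibration tests pin the regime in
  which it is used).
* Registration assumes overlapping tissue between consecutive sections
  and cannot recover reflections.
* The power model is Gaussian at the niche level; it approximates, but
  does not model, overdispersed counts.
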