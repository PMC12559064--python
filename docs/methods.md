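# Methods

`perfmosaic` quantifies mosaic perfusion on CT pulmonary angiography
(CTPA) in chronic thromboembolic pulmonary hypertension (CTEPH).  The
package consumes a CT volume in Hounsfield units plus binary masks for
the left lung, right lung and pulmonary veins (produced upstream by any
segmentation tool), and emits six headline scalars per patient: three
attenuation-compartment proportions, two spatial-entropy values, and one
centralization slope.  This note records the model, the numerical
choices, and what the synthetic phantoms do and do not establish.

## Attenuation compartments

Lung voxel attenuation is modelled as a three-component 1-D Gaussian
mixture over the pooled in-mask voxels of *both* lungs (within the
analysis window, default [−1024, 100] HU):

    p(x) = Σ_k w_k N(x; μ_k, σ_k²),  k ∈ {oligemic, normal, hyperemic}

After fitting, components are ordered by mean (ties broken toward the
lower index) and mapped low → oligemic, middle → normal, high →
hyperemic.  The headline proportion of each compartment is its mixture
weight w_k; voxel-count fractions from the MAP mask are reported
alongside as a QC companion.

Fitting uses variational Bayesian estimation
(`sklearn.mixture.BayesianGaussianMixture`, full covariance on the 1-D
data) with:

* symmetric Dirichlet weight concentration 1/3 — weakly sparsifying, so
  a compartment that is genuinely absent (near-unimodal healthy lungs)
  collapses gracefully toward zero weight instead of splitting the
  dominant mode;
* mean prior at the sample mean with weak precision (1e−2), covariance
  prior at the sample variance;
* max 500 iterations, tolerance 1e−4 on the evidence lower bound;
* deterministic initialization: responsibilities from equal-weight
  Gaussians centred at the 2nd/50th/98th sample percentiles with SD equal
  to a quarter of the pooled SD.  The wide anchors let minority
  compartments of a few percent attract their own component; the sharp
  init SD breaks symmetry quickly.  For degenerate (near-constant) input
  the anchors are nudged apart deterministically so the winner-take-all
  collapse still occurs.  No random restarts: identical input, config
  and seed give bit-identical parameters; the seed only governs the
  uniform subsample drawn when a lung exceeds 2,000,000 voxels
  (classification always uses the full volume).

MAP classification assigns each in-window lung voxel to the component
maximizing w_k·N(x; μ_k, σ_k²) evaluated with the fitted point
parameters; exact ties go to the lower-mean component.  This is
deliberately *not* sklearn's `predict` (which applies variational
digamma corrections); the library call is kept as an independent
cross-check in the tests.

## Spatial heterogeneity

For the hyperemic and normal compartments, each lung's compartment
voxels are binned into a 32×32×32 histogram of their physical
coordinates and the Shannon entropy H = −Σ p_i log₂ p_i is computed
(0 ≤ H ≤ 15 bits).  Choices:

* the binning box is the lung mask's axis-aligned bounding box in mm
  (full voxel extents), making the entropy invariant to the lung's
  position in the scanner and comparable across patients;
* base-2 logarithm; any base rescales all patients identically and
  leaves rank correlations unchanged;
* per-lung entropies are averaged arithmetically across the two lungs;
* an empty compartment is maximally homogeneous: entropy 0 plus a QC
  flag.  Oligemic entropy is computable on request but is not a headline
  metric.

## Perfusion centralization

The hilar point of each lung is the centroid (physical mm, voxel-center
convention) of the pulmonary-vein voxels lying outside both lungs, each
assigned to the side whose lung surface is nearer (Euclidean distance
transform with the anisotropic voxel spacing; ties to the left).  Two
distance maps are computed on the lung mask — distance to the nearest
non-lung voxel (pleural boundary) and distance to the hilar point — and
combined into the centralization map

    rel = d_hilum / (d_hilum + d_periphery) ∈ [0, 1],

0 at the hilum, 1 at the pleura, with the degenerate 0/0 voxel defined
as 0.5.  Mean attenuation is then computed in 21 equal shells of rel
(half-open bins, the last closed; bin centre (j+0.5)/21) and a line is
fitted by unweighted least squares over the nonempty shells.  The slope,
in HU per unit relative distance, is averaged over the two lungs.
Negative slope = attenuation falls toward the periphery, the
centralized-perfusion pattern.  Empty shells are dropped from the fit
(more than 10 empty raises a QC warning); fewer than 3 nonempty shells
is a hard error.  One hilar point is computed per lung because slopes
are per lung; all distances are anisotropy-aware so thick-slice
reconstructions do not bias the axial direction.

Geometric caveat: with a convex lung and a hilar point at its surface,
rel cannot fall much below 0.5 anywhere, so roughly the inner ten shells
are empty and the fit effectively uses the outer half of the range.
This is a property of the normalization itself, shared by any dataset
whose hilar point lies outside the lung mask, not an artifact of the
phantoms.

## Statistics

Computed metrics are compared against clinical/radiologist variables
with Spearman's ρ (midrank ties, pairwise deletion of missing values,
t-approximation p-values on n−2 df; full-enumeration permutation
p-values are available for n ≤ 8).  The family of all (metric, variable)
pairs in a report is corrected with the Benjamini–Hochberg step-up rule;
the report prints the data-derived critical p-value (largest p_(k) ≤
αk/m) and the heatmap masks non-significant cells.  Grubbs (two-sided,
single outlier, t-based critical value) and the D'Agostino–Pearson
omnibus test are screening aids only: flagged values are reported, never
removed.

## Synthetic phantoms

`perfmosaic.phantom` generates chest phantoms with exact ground truth:
a soft-tissue body ellipsoid (40 HU) in air, two ellipsoidal lungs,
per-voxel compartment labels drawn by thresholding a seeded Gaussian
random field (smoothing width `blob_scale`, in mm, sets patch size) at
quantiles matching the target weights, per-compartment Gaussian HU
draws, an optional linear gradient in true hilum-to-pleura relative
distance, and two contrast-filled pulmonary-vein capsules per lung whose
extrapulmonary centroid (the true hilar point) hugs the medial lung
surface.  Everything is reproducible from the spec seed.

Default study sizes, chosen as desk-scale conditions:

* unit-test grid 64×80×64 at 2 mm isotropic (~46k lung voxels);
* preset and slope-study grid 96×120×96 (~155k lung voxels);
* mixture-recovery draws: 20 seeds × 200,000 samples.

Presets encode the two clinical archetypes:

* `severe` — weights (0.25, 0.45, 0.30), means (−900, −780, −620) HU,
  SDs (35, 40, 50), patch width 3 mm, gradient −150 HU/unit: pronounced
  mosaic contrast, scattered patches, central hyperemia with peripheral
  oligemia;
* `minimal` — weights (0.04, 0.90, 0.06), means (−880, −780, −680),
  SDs (30, 35, 30), patch width 4.5 mm, gradient 0: dominant normal
  parenchyma with small, subtle, coarser patches.

Patch widths and grid size were set together at design time so that
radial-profile shells average over many patches and each preset's
generating contract (severe: strongly negative slope, normal weight
≈ 0.45; minimal: near-zero slope, normal weight ≈ 0.90) survives the
patch sampling noise of a single seeded realization.  The dedicated
slope-recovery study goes further and uses moderate compartment contrast
(means −840/−780/−700, SDs 40) with 2 mm patches, because the quantity
under test is the radial gradient estimate and the study should not be
dominated by mosaic sampling noise; with strong-contrast coarse-patch
phantoms the shell means fluctuate by tens of HU and single-seed slopes
scatter accordingly.

The clinical-table simulator draws a Gaussian copula: target Spearman
matrices are converted to latent Pearson correlations via
r = 2 sin(πρ_s/6), checked for positive semi-definiteness (hard error
otherwise), sampled — conditionally on the rank-transformed metric
values when a metrics table is supplied — and pushed through monotone
marginals (4-level ordinal for the radiologist Likert scores, lognormal
for proBNP, normal with plausible scales for the physiologic variables).

What the phantoms do *not* emulate: airway and vessel trees, partial
volume and reconstruction noise, beam hardening, contrast-timing
variability, respiratory motion, and non-ellipsoidal lung anatomy
(including the concave hilum of real lungs).  Passing tests therefore
establish the correctness and stability of the computations under known
ground truth, not clinical performance; the cohort correlations of any
real population remain outside the package's claims.

## Known limitations

* High-attenuation structures inside the lung mask (vessels, artifacts)
  are classified like any other voxel and can inflate the hyperemic
  compartment.
* The mixture weights of heavily overlapping components are weakly
  identifiable; in near-unimodal lungs the oligemic/hyperemic
  proportions should be read together with the QC voxel-count fractions.
* The centralization slope uses unweighted shell means, so sparsely
  populated central shells carry as much weight as dense peripheral
  ones; profiles with many empty shells are flagged.
* Likert-type ordinal variables attenuate rank correlations through
  ties; simulated targets are recovered exactly only for continuous
  marginals.
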