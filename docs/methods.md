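# Methods

This note documents the models and procedures implemented in
`lesiongrad`, the parameters that matter, the synthetic-data conditions
under which the pipeline is validated, and the numerical and design
choices made where more than one convention was defensible. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. Group connectivity gradients

**Model.** Voxelwise functional connectivity matrices (Pearson r over
standardised time series) are estimated per healthy control and averaged
elementwise in the Fisher-z domain: z = arctanh(r), averaged, then
tanh-transformed back. Correlations of magnitude 1 are clipped to
1 − 10⁻⁷ before arctanh (the transform diverges there; the clip is far
below any meaningful correlation resolution). The diagonal of the group
matrix is set to zero before thresholding so self-correlation never
occupies a row's top decile.

Each row is then sparsified at its own `threshold_pct` percentile
(default 90), computed by linear interpolation over the row's values,
retaining entries **strictly above** the cutoff. The strict inequality
makes tie handling deterministic: for a row of V distinct values with V a
multiple of 10, exactly V/10 entries survive. A constant row retains
nothing and is logged; the downstream cosine step rejects zero rows
explicitly.

Pairwise cosine similarity of the sparse rows yields the affinity L;
negative cosines (possible when retained values include negative
correlations) are clamped to zero — not shifted — so L lies in [0, 1],
and the clamp count is recorded for audit.

**Diffusion embedding.** With degrees d_i = Σ_j L_ij, the
α-normalisation W = L/(d_i^α d_j^α) with α = 0.5 (Fokker–Planck
convention: discounts sampling-density effects) is conjugated to the
symmetric operator S = Q^{−1/2} W Q^{−1/2}, q_i = Σ_j W_ij. The top K+1
eigenpairs of S give ψ_k = Q^{−1/2} v_k; ψ_0 is the trivial constant
mode (asserted constant to 10⁻⁶ relative) and is dropped. Component k is
ψ_k · λ_k/(1−λ_k) for `diffusion_time = 0` (the multi-scale weighting),
or ψ_k · λ_k^t for t > 0. A dense symmetric solver is used up to
V = 2000 and an iterative Lanczos solver above (tolerance 10⁻¹⁰).
Disconnected affinity graphs are rejected with the component sizes
(diffusion embedding is undefined across components); eigenvector sign is
fixed by making the voxel of largest |value| positive, or by correlation
with a reference embedding when one is supplied.

**Variance reported per gradient** is λ_k / Σ_j λ_j over the retained
non-trivial eigenvalues. This is one of several conventions in use
(eigenvalue vs squared-eigenvalue mass, and the choice of denominator);
it is stated as such wherever printed and nothing downstream depends on
it.

## 2. Lesion projection and distance maps

Lesion masks are dilated once with a full 3×3×3 structuring element
(one voxel in every direction, clipped to the grid). The per-patient
analysis mask is the group grey-matter template ∩ all session masks −
the dilated lesion; an optional `common_mask_mode` further restricts all
patients to one cohort-wide mask. The lesion's position on gradient k is
a statistic of the *undilated* lesioned voxels' embedding values —
`mean` by default, `min` selectable; both are legitimate summaries of a
lesion's span on a gradient and all group analyses run under a single
declared choice recorded in the report's config block. Distance-to-lesion
is the absolute difference |embedding value − reference| (non-negative,
translation-equivariant). Anatomical distance is the exact Euclidean
distance transform to the nearest lesioned voxel in millimetres
(`nearest_voxel`, default — "distance to the infarct" reads as distance
to the region), with a `centroid` variant for sensitivity analyses.
Lesion volume is voxel count × voxel volume, in cm³.

## 3. Longitudinal concordance

Per voxel, its connectivity profile (FC row restricted to the analysis
mask, self-entry removed) is compared across the k sessions with the
concordance correlation coefficient using biased (divide-by-n) moment
estimators, as in the coefficient's original definition. For k > 2 the
**overall CCC** (sum of pairwise covariances over sum of pairwise
denominators) is the default; it reduces algebraically to the pairwise
formula at k = 2. The mean-of-pairwise-CCCs convention is available
behind `ccc_convention = "mean_pairwise"` for sensitivity checks.
Profiles are compared in r-space (no Fisher step): the coefficient is
applied to the FC matrices as estimated. Voxels with degenerate profile
variance get NaN and are logged; NaNs are excluded pairwise from all
downstream statistics. The map computation is vectorised over voxels via
row sums and row-wise products of the session matrices.

## 4. Statistics

- **Distance–concordance association:** Spearman rank correlation
  (average ranks on ties), lesioned voxels excluded, minimum 10 usable
  voxels.
- **Group test:** one-tailed (greater) Wilcoxon signed-rank on the
  per-patient r_s. Zeros dropped, midranks on ties. For n ≤ 25 the null
  distribution of the positive rank sum is computed exactly by dynamic
  programming over doubled midranks (so ties stay exact); above, a
  normal approximation with tie-corrected variance and continuity
  correction. The reported W is min(T⁺, T⁻), and both one-sided tails
  appear in the JSON report so either W convention can be audited.
- **Anatomical control:** OLS of concordance on anatomical distance
  (with intercept); the residual map is re-correlated with gradient
  distance. The Pearson r of the two maps is reported alongside.
- **Lesion-size control:** Pearson correlation of lesion volume with
  per-patient r_s, per gradient.
- **Bin analysis:** each gradient's range (over intact and lesioned
  voxels) is split into n_bins equal bins, left-closed with a
  right-closed final bin; bins containing a lesioned voxel are
  "affected". Delta-concordance is the pooled mean concordance of intact
  voxels in unaffected bins minus that in affected bins (pooled voxel
  means, so empty bins drop out automatically; the bin-of-bin-means
  alternative was not adopted because it weights sparse bins equally
  with dense ones). The clinical-change group difference in
  delta-concordance is tested by label permutation: statistic
  mean(change) − mean(no change), add-one Monte-Carlo p
  (1 + #extreme)/(n_perm + 1) with a seeded generator, or exhaustive
  enumeration for small groups. Monte-Carlo draws are taken over the
  sorted values so the p-value is invariant to input ordering at a fixed
  seed.
- **Clinical association:** Kendall tau-b (tie-corrected — ordinal
  scores are tied by construction) between slope/intercept of the
  distance–concordance regression and NIHSS/mRS at admission and
  discharge, two-sided p. No multiple-testing correction is applied
  anywhere: the clinical analyses are exploratory and reported
  descriptively.

## 5. The synthetic cohort

**What it emulates.** A shared grey-matter voxel grid (default 10×10×8,
800 voxels, 3 mm isotropic); ~28 controls with one session and ~28
patients with three sessions of 120 timepoints each; focal,
heterogeneous lesions; and longitudinal connectivity change graded in a
latent gradient space.

Each grey-matter voxel carries G latent coordinates in [0, 1] (default
smooth fields: random low-order polynomials of the grid coordinates plus
small noise, min-max normalised — spatially smooth, so latent and
anatomical distance are correlated but not identical, as in real
cortex). Signal is a weighted sum of `n_sources = 10` unit-variance
white source series, with Gaussian-bump weights
w = exp(−d_latent²/2σ²), σ = `source_width` = 0.2, anchored at
farthest-point-sampled latent positions; white noise is added at
`snr = 3` (signal/noise variance) and every voxel series is standardised.
FC therefore decays smoothly with latent distance, which is the single
property the gradient pipeline needs to be able to invert.

**Perturbation.** Patients' sessions re-draw sources and noise from
identical generative parameters; on top, each voxel's weights receive
session-specific Gaussian jitter with standard deviation
amplitude(v) × (voxel weight rms), so the *relative* profile
perturbation is controlled by the amplitude field alone:

- `gradient`: amplitude = γ·exp(−d_latent/τ), d_latent the latent
  distance to the nearest lesioned voxel (γ = 0.8, τ = 0.15 latent
  units);
- `anatomical`: γ·exp(−d_mm/τ_mm), τ_mm = 9 mm;
- `uniform`: γ everywhere; `none`: zero (sessions are plain re-draws).

Lesioned voxels' series are replaced by pure noise in all sessions. The
amplitude field and d_latent are stored as per-voxel ground truth.
γ and τ have no empirical anchor (the generator does not model patient
physiology); they were fixed once, at fixture scale, to values at which
recovery is testable — strong change near the lesion in latent space,
negligible change at distance τ·ln(γ/noise floor) ≈ half the gradient.
Sample sizes (28 + 28), three sessions, and 3 mm voxels mirror the
acute-stroke study design this pipeline addresses; 120 timepoints and
800 voxels are the package's fixture scale, chosen so the full cohort
analysis runs in seconds while keeping FC estimation noise realistic
(r-noise sd ≈ 0.09).

**Lesion placement** defaults to latent-extreme voxels (radius 1–2
voxel spheres intersected with grey matter), mirroring the observation
that real lesions cluster at gradient edges; a `uniform` placement mode
exists for null constructions.

**Clinical scores** are integer NIHSS (0–42) and mRS (0–5): discharge
scores are a monotone map of each patient's mean perturbation amplitude
plus Gaussian noise (sd 2 NIHSS points, scaled for mRS), clipped and
rounded; admission scores add a non-negative Poisson improvement margin
so roughly 60% of patients change between admission and discharge.

**The decorrelated control layout.** The anatomical-specificity check
needs a layout where latent distance is independent of anatomical
distance. Spatial smoothness makes that impossible locally — any smooth
field correlates with anatomy near the lesion — so the control layout
(`field_type = "scrambled"`) assigns latent coordinates as a random
permutation of an evenly spaced lattice, with a wrap-around (ring)
latent metric and evenly spaced anchors. Two properties follow *by
construction*: latent distance carries no anatomical information, and
every voxel sees the identical multiset of latent distances, so
connectivity-profile variance — and with it the noise attenuation of the
concordance estimate — is constant across gradient positions. On a
*linear* latent segment that is not true: end-of-gradient voxels have
higher profile variance than mid-gradient voxels, which couples
concordance to gradient position through estimation noise alone. That
edge effect is a real property of linear gradients (it also produces the
systematically negative r_s seen under uniform perturbation with
extreme-placed lesions); the ring construction removes it where a
specificity null requires exchangeability. The control experiment places
lesions uniformly (the null placement mode — on a ring, "latent
extremes" degenerates to a single point) and uses 84 patients rather
than 28: per-patient r_s carries sd ≈ 0.18 of purely stochastic session
noise, so the larger cohort keeps the Monte-Carlo error of the median
(≈ 0.025) well inside the ±0.05 specificity band being tested.

**What the generator does not model** — hemodynamic response, scanner
noise spectra, head motion, registration error, preprocessing artifacts,
spatial autocorrelation of noise, and the true dimensionality of
cortical connectivity (10 latent sources vs thousands of parcels).
Passing tests therefore demonstrate that the pipeline correctly inverts
the generative model it is given and is specific against the confounds
explicitly simulated (anatomical proximity, lesion size, uniform
change); they do not certify performance on real fMRI, where
preprocessing quality and noise structure dominate.

## 6. Numerical and I/O choices

- Voxel indices are 0-based; all distances are between voxel centres.
- Degenerate inputs fail loudly: constant time series, zero-norm sparse
  rows, empty lesions, disconnected affinities, all-zero Wilcoxon
  samples, and constant predictors all raise with the offending voxel or
  component named.
- Symmetry is enforced exactly after floating-point operations
  (affinity and conjugated operators are re-symmetrised; cosines clipped
  to [0, 1]; concordance clipped to [−1, 1]).
- Volumes are NIfTI-1 (time axis last, isotropic grids enforced on
  read); V×V matrices and embeddings are HDF5 with object timestamps
  disabled; tables are TSV; reports and manifests are JSON with sorted
  keys. All artifacts are byte-identical across runs at a fixed seed —
  for that reason provenance records carry the tool version, config
  hash, input checksums, and seeds, but no wall-clock timestamps (those
  go to the stderr log).
- All randomness derives from a single integer seed via spawned child
  streams; per-test and per-analysis seeds never exceed 2³¹.

## 7. Known limitations

- The multi-session CCC convention (overall vs mean-of-pairs) is not
  settled usage; both are implemented, the overall form is the default,
  and the choice is recorded in every report.
- The variance-explained convention is likewise a documented choice, not
  a community standard.
- The exact Wilcoxon/normal-approximation switch at n = 25 is
  conventional; near the boundary the two differ in the third decimal of
  p at typical effect sizes.
- `run_group_analysis` assumes complete per-gradient results per
  patient; patients failing per-patient preconditions (e.g. analysis
  mask below the minimum voxel count) must be excluded upstream.
- At fixture scale the bin sweep stops at ~100 bins (800 voxels);
  thousand-bin parcellations only make sense at full brain resolution.
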