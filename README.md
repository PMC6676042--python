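# lesiongrad

Connectivity-gradient analysis of functional reorganisation after focal
brain lesions, with a fully synthetic validation cohort.

After an ischemic stroke, functional connectivity changes not only at the
infarct but also in structurally intact regions that are *functionally*
coupled to it (diaschisis). This package asks where those remote changes
concentrate — not in anatomical space, but along **connectivity
gradients**: continuous, low-dimensional axes obtained by spectral
decomposition of the voxelwise functional connectome of healthy controls.

## The method

1. **Gradients from healthy controls.** Per-subject voxelwise Pearson FC
   matrices are averaged across controls in the Fisher-z domain
   (r̄ = tanh(mean arctanh r)). Each row of the group matrix is
   thresholded at its own 90th percentile, the pairwise cosine
   similarities of the sparse rows form a non-negative symmetric affinity
   L, and diffusion-map embedding of L (α = 0.5 anisotropic
   normalisation, λ/(1−λ) component weighting) yields per-voxel embedding
   values on K gradients. Voxels with similar connectivity profiles get
   similar embedding values.
2. **Lesion projection.** A patient's lesion mask (dilated by one voxel
   with a 3×3×3 kernel for exclusion purposes) is projected onto the
   gradients; the lesion's position on gradient k is the mean (or
   minimum) embedding value of its voxels, and the per-voxel
   **distance-to-lesion map** is |embedding value − lesion reference|.
3. **Longitudinal concordance.** For each patient, voxelwise FC matrices
   from three consecutive sessions are compared per voxel with the
   concordance correlation coefficient,
   CCC = Σ 2s_jl / Σ (s_j² + s_l² + (m_j − m_l)²),
   over the voxel's connectivity profile: low concordance = strong
   reorganisation over time.
4. **Inference.** Per patient and gradient, Spearman's r_s between
   distance-to-lesion and concordance (lesioned voxels excluded): r_s > 0
   means change concentrates in voxels functionally similar to the
   lesion. Group-level one-tailed Wilcoxon signed-rank tests; controls
   for anatomical (Euclidean mm) distance via OLS residualisation and for
   lesion volume via Pearson correlation; gradient-bin delta-concordance
   (μ_unaffected − μ_affected) with label-permutation tests against
   clinical change; Kendall tau-b between regression slope/intercept and
   NIHSS/mRS at admission and discharge.

Because no patient data ship with the package, a first-class
**synthetic-cohort generator** provides ground truth: voxels carry latent
coordinates that play the role of true gradients, BOLD-like signal mixes
latent-anchored sources so FC decays with latent distance, and patients
receive a focal lesion plus a longitudinal perturbation whose amplitude
decays with latent distance to the lesion (γ·e^(−d/τ)), with anatomical
and uniform perturbation modes as controls.

## Worked example

```python
from lesiongrad import AnalysisConfig, CohortSpec, analyze_cohort, simulate_cohort

cohort = simulate_cohort(CohortSpec(n_controls=8, n_patients=8, n_timepoints=80),
                         seed=21, grid_dims=(8, 8, 6), G=1)
report = analyze_cohort(cohort, AnalysisConfig(n_perm=500, n_bins_sweep=(5, 10), seed=21))
g1 = report["group"]["gradients"]["1"]
print(g1["median_r_s"], g1["W"], g1["p_one_tailed_greater"])
```

Running `python examples/05_group_statistics.py` (which wraps exactly
this) prints, among other lines:

```
gradient 1: median r_s = +0.849  W = 0.0  p(one-tailed) = 0.0039  | residualised median = +0.587
gradient 2: median r_s = -0.266  W = 0.0  p(one-tailed) = 1.0000  | residualised median = -0.050
```

The generator perturbed connectivity along latent gradient 1 only, and
the analysis recovers exactly that: a strongly positive median r_s with a
significant one-tailed Wilcoxon test on gradient 1 (surviving
anatomical-distance residualisation), and no positive effect on the
untargeted gradients. The other `examples/` scripts walk through each
stage (simulation, gradient estimation, lesion projection, concordance
mapping) with the same printed-number-plus-interpretation style.

## Command line

The same pipeline is scriptable from a shell:

```bash
lesiongrad simulate --seed 7 --out cohort/
lesiongrad gradients --cohort cohort/ --out embedding.h5
lesiongrad map-lesion --cohort cohort/ --embedding embedding.h5 --out dist/
lesiongrad concordance --cohort cohort/ --out conc/
lesiongrad stats --cohort cohort/ --embedding embedding.h5 --out report.json
lesiongrad run-all --seed 7 --out run/     # all of the above, chained
```

Volumes are NIfTI-1, matrices HDF5, tables TSV, reports JSON; outputs are
byte-identical for a fixed seed.

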