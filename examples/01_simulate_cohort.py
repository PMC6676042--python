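"""Simulate a small stroke-study cohort with known latent gradients.

Builds a voxel grid whose grey-matter voxels carry a smooth latent
coordinate (the ground-truth connectivity gradient), then generates
healthy controls (one session each) and lesioned patients (three sessions
with a gradient-graded longitudinal perturbation), plus clinical scores.
"""

import numpy as np

from lesiongrad import CohortSpec, simulate_cohort

spec = CohortSpec(n_controls=6, n_patients=4, n_timepoints=80)
cohort = simulate_cohort(spec, seed=42, grid_dims=(8, 8, 6), G=1)

lay = cohort.layout
print(f"grid {lay.grid_dims}, {lay.n_voxels} grey-matter voxels, "
      f"{lay.n_gradients} latent gradient(s)")
print(f"{len(cohort.controls)} controls x 1 session, "
      f"{len(cohort.patients)} patients x {spec.n_sessions} sessions")

p = cohort.patients[0]
print(f"\npatient {p.subject_id}: lesion of {int(p.lesion_mask.sum())} voxels, "
      f"session matrix {p.sessions[0].shape} (voxels x timepoints)")
amp = p.truth["amplitude"]
print(f"perturbation amplitude: {amp.max():.3f} at the lesion, "
      f"{amp.min():.3f} at the far end of the gradient")
# the amplitude decays exponentially with latent distance to the lesion, so
# connectivity change is concentrated in voxels functionally near the lesion

print("\nclinical scores (NIHSS 0-42, mRS 0-5):")
print(cohort.clinical.to_string())
# discharge scores track each patient's ground-truth perturbation load,
# which is what the clinical association analyses should later recover
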