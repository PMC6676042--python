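"""Project a lesion into gradient space and build distance maps.

Shows the lesion-side machinery: dilating the lesion mask, building the
patient's analysis mask, summarising the lesion position on each gradient
(mean or min of the lesioned voxels' embedding values), and computing
embedding-space and anatomical (mm) distance maps.
"""

import numpy as np

from lesiongrad import (
    AnalysisConfig,
    CohortSpec,
    anatomical_distance,
    build_patient_mask,
    dilate_mask,
    distance_to_lesion,
    group_embedding,
    lesion_reference,
    lesion_volume,
    simulate_cohort,
)

cohort = simulate_cohort(CohortSpec(n_controls=6, n_patients=1), seed=3,
                         grid_dims=(8, 8, 6), G=1)
emb = group_embedding(cohort, AnalysisConfig())
lay = cohort.layout
patient = cohort.patients[0]

dilated = dilate_mask(patient.lesion_mask)
masks = build_patient_mask(lay.gm_mask, [], dilated)
print(f"lesion: {int(patient.lesion_mask.sum())} voxels "
      f"({lesion_volume(patient.lesion_mask, lay.voxel_size_mm):.3f} cm^3), "
      f"dilated to {int(dilated.sum())}")
print(f"analysis mask: {masks.n_voxels} of {int(lay.gm_mask.sum())} grey-matter voxels")

lesion_rows = np.flatnonzero(patient.lesion_mask[lay.gm_mask])
for stat in ("mean", "min"):
    ref = lesion_reference(emb.values, lesion_rows, stat=stat)
    print(f"lesion reference ({stat} of lesioned embedding values): {ref.round(3)}")

ref = lesion_reference(emb.values, lesion_rows, stat="mean")
dist = distance_to_lesion(emb.values, ref)
rows = masks.analysis_mask[lay.gm_mask]
print(f"\ngradient-1 distance-to-lesion over the analysis mask: "
      f"min {dist[rows, 0].min():.3f}, median {np.median(dist[rows, 0]):.3f}, "
      f"max {dist[rows, 0].max():.3f}")
# low values = voxels whose healthy connectivity profile resembles the
# lesioned tissue's; these are the candidates for remote (diaschisis) effects

anat = anatomical_distance(patient.lesion_mask, lay.voxel_size_mm)
print(f"anatomical distance (mm): up to {anat.max():.1f} on this grid")
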