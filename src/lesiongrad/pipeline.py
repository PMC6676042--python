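"""End-to-end orchestration: cohort in, group report out.

The stages mirror the analysis design: (1) gradients are estimated once,
from healthy controls only; (2) each patient's lesion is projected into
that gradient space and the per-voxel longitudinal concordance of their
connectivity profiles is computed on their own analysis mask; (3) the
per-patient distance–concordance statistics are pooled into group tests,
controls, and clinical associations.
"""

from __future__ import annotations

import numpy as np

from .cohort import Cohort, SimulatedSubject
from .concordance import concordance_map
from .connectivity import cosine_affinity, group_average_fc, pearson_fc, row_threshold
from .gradients import DiffusionEmbedding, EmbeddingConfig, diffusion_embed
from .inference import (
    bin_delta_concordance,
    fit_slope_intercept,
    residualize_anatomy,
    run_group_analysis,
    spearman_distance_concordance,
)
from .io import AnalysisConfig, config_hash
from .lesion import (
    anatomical_distance,
    build_patient_mask,
    dilate_mask,
    distance_to_lesion,
    lesion_reference,
    lesion_volume,
)


def group_embedding(cohort: Cohort, config: AnalysisConfig | None = None) -> DiffusionEmbedding:
    """Connectivity gradients of the healthy-control group.

    Per-control Pearson FC matrices are averaged in the Fisher-z domain,
    row-thresholded at ``config.threshold_pct``, converted to a cosine
    affinity, and decomposed by diffusion embedding.
    """
    config = config or AnalysisConfig()
    if not cohort.controls:
        raise ValueError("cohort has no controls to estimate gradients from")
    fcs = [pearson_fc(c.sessions[0]) for c in cohort.controls]
    group_fc = group_average_fc(fcs)
    sparse = row_threshold(group_fc, config.threshold_pct)
    affinity = cosine_affinity(sparse)
    emb_cfg = EmbeddingConfig(
        alpha=config.alpha,
        n_components=config.n_components,
        diffusion_time=config.diffusion_time,
    )
    return diffusion_embed(affinity, emb_cfg)


def analyze_patient(
    patient: SimulatedSubject,
    cohort: Cohort,
    embedding: DiffusionEmbedding,
    config: AnalysisConfig | None = None,
) -> dict:
    """All per-patient quantities for one lesioned subject.

    Returns a dict with per-gradient Spearman r_s (raw and residualised
    against anatomical distance), regression slope/intercept, the
    anatomical-distance correlation, lesion volume, and the
    delta-concordance sweep over ``config.n_bins_sweep``.
    """
    config = config or AnalysisConfig()
    layout = cohort.layout
    if patient.lesion_mask is None or not patient.lesion_mask.any():
        raise ValueError(f"{patient.subject_id}: patient has no lesion mask")

    dilated = dilate_mask(patient.lesion_mask)
    common = layout.gm_mask if config.common_mask_mode else None
    mask_set = build_patient_mask(
        layout.gm_mask, [], dilated, common_mask=common, min_voxels=config.min_mask_voxels
    )
    analysis_rows = mask_set.analysis_mask[layout.gm_mask]

    lesion_rows = np.flatnonzero(patient.lesion_mask[layout.gm_mask])
    reference = lesion_reference(embedding.values, lesion_rows, stat=config.lesion_reference_stat)
    dist_all = distance_to_lesion(embedding.values, reference)
    dist = dist_all[analysis_rows]

    fcs = [pearson_fc(ts[analysis_rows]) for ts in patient.sessions]
    conc = concordance_map(fcs, convention=config.ccc_convention)

    anat_map = anatomical_distance(
        patient.lesion_mask, layout.voxel_size_mm, metric=config.anatomical_metric
    )
    anat = anat_map[mask_set.analysis_mask]
    anat_r, resid = residualize_anatomy(conc, anat)

    K = embedding.values.shape[1]
    r_s, r_s_res, slopes, intercepts = [], [], [], []
    for k in range(K):
        r_s.append(spearman_distance_concordance(dist[:, k], conc))
        r_s_res.append(spearman_distance_concordance(dist[:, k], resid))
        s, i = fit_slope_intercept(dist[:, k], conc)
        slopes.append(s)
        intercepts.append(i)

    deltas: dict = {}
    for nb in config.n_bins_sweep:
        per_grad = []
        for k in range(K):
            try:
                ba = bin_delta_concordance(
                    embedding.values[analysis_rows, k],
                    embedding.values[lesion_rows, k],
                    conc,
                    nb,
                )
                per_grad.append(ba.delta_concordance)
            except ValueError:
                per_grad.append(float("nan"))
        deltas[str(nb)] = per_grad

    return {
        "patient_id": patient.subject_id,
        "n_voxels": mask_set.n_voxels,
        "r_s": r_s,
        "r_s_residualized": r_s_res,
        "slope": slopes,
        "intercept": intercepts,
        "anat_r": anat_r,
        "lesion_volume_cm3": lesion_volume(patient.lesion_mask, layout.voxel_size_mm),
        "lesion_reference": reference.tolist(),
        "delta_concordance": deltas,
    }


def analyze_cohort(
    cohort: Cohort,
    config: AnalysisConfig | None = None,
    embedding: DiffusionEmbedding | None = None,
) -> dict:
    """Run the full pipeline on a cohort; returns a JSON-serialisable report.

    The report carries the group statistics (one per gradient), the
    anatomical and lesion-size controls, the clinical analyses, all
    per-patient results, and the config hash for provenance. Deterministic
    for a fixed ``config.seed``.
    """
    config = config or AnalysisConfig()
    if embedding is None:
        embedding = group_embedding(cohort, config)
    patient_results = [analyze_patient(p, cohort, embedding, config) for p in cohort.patients]
    clinical = cohort.clinical if len(cohort.clinical) else None
    group = run_group_analysis(
        patient_results, clinical=clinical, n_perm=config.n_perm, seed=config.seed
    )
    return {
        "config": config.to_dict(),
        "config_hash": config_hash(config),
        "embedding": {
            "eigenvalues": embedding.eigenvalues.tolist(),
            "variance_ratio": embedding.variance_ratio.tolist(),
            "n_voxels": int(embedding.values.shape[0]),
        },
        "patients": patient_results,
        "group": group,
    }
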