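"""Lesion masks in anatomical and gradient space.

Covers mask dilation, patient-specific analysis masks (the shared
grey-matter template minus the dilated lesion), the lesion's reference
position on each gradient, per-voxel distance-to-lesion maps in embedding
space, Euclidean distance maps in millimetres, and lesion volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass
class PatientMaskSet:
    """Per-patient analysis mask: grey matter minus the dilated lesion."""

    analysis_mask: np.ndarray
    n_voxels: int


def dilate_mask(mask: np.ndarray, iterations: int = 1) -> np.ndarray:
    """Binary dilation with a full 3x3x3 structuring element.

    Extends the mask by one voxel in every direction (including diagonals)
    per iteration; the result is clipped to the grid. Raises on an empty
    mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot dilate an empty mask")
    if iterations < 1:
        return mask.copy()
    structure = np.ones((3, 3, 3), dtype=bool)
    return ndimage.binary_dilation(mask, structure=structure, iterations=iterations)


def build_patient_mask(
    group_gm: np.ndarray,
    session_masks,
    dilated_lesion: np.ndarray,
    common_mask: np.ndarray | None = None,
    min_voxels: int = 50,
) -> PatientMaskSet:
    """Intersect grey matter with all session masks and remove the lesion.

    ``common_mask``, when given, additionally restricts the result to a
    cohort-wide mask (the more conservative control variant in which every
    patient is analysed on an identical voxel set before lesion removal).
    """
    out = np.asarray(group_gm, dtype=bool).copy()
    for sm in session_masks:
        sm = np.asarray(sm, dtype=bool)
        if sm.shape != out.shape:
            raise ValueError("session mask grid mismatch")
        out &= sm
    if common_mask is not None:
        out &= np.asarray(common_mask, dtype=bool)
    out &= ~np.asarray(dilated_lesion, dtype=bool)
    n = int(out.sum())
    if n < min_voxels:
        raise ValueError(f"analysis mask has {n} voxels, below minimum {min_voxels}")
    return PatientMaskSet(analysis_mask=out, n_voxels=n)


def lesion_reference(embedding_values: np.ndarray, lesion_rows, stat: str = "mean") -> np.ndarray:
    """Lesion position on each gradient: min or mean over lesioned voxels.

    ``embedding_values`` is (V, K) over the template voxel set;
    ``lesion_rows`` indexes the lesioned voxels within it. Returns a (K,)
    reference vector.
    """
    rows = np.asarray(lesion_rows)
    vals = np.atleast_2d(np.asarray(embedding_values, dtype=float))
    if rows.size == 0:
        raise ValueError("lesion does not intersect the embedding voxel set")
    sub = vals[rows]
    if stat == "mean":
        return sub.mean(axis=0)
    if stat == "min":
        return sub.min(axis=0)
    raise ValueError(f"unknown lesion reference stat {stat!r}")


def distance_to_lesion(embedding_values: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Per-gradient |embedding value - lesion reference| for every voxel.

    Small values mark voxels whose connectivity profile (as summarised by
    the gradient) resembles the lesioned tissue's.
    """
    vals = np.asarray(embedding_values, dtype=float)
    return np.abs(vals - np.asarray(reference, dtype=float))


def anatomical_distance(
    lesion_mask: np.ndarray,
    voxel_size_mm: float,
    metric: str = "nearest_voxel",
) -> np.ndarray:
    """Euclidean distance (mm) from every voxel centre to the lesion.

    ``nearest_voxel`` gives the distance to the closest lesioned voxel
    (exact Euclidean distance transform); ``centroid`` the distance to the
    lesion's centre of mass. Zero inside the lesion only (nearest_voxel).
    """
    lesion = np.asarray(lesion_mask, dtype=bool)
    if not lesion.any():
        raise ValueError("lesion mask is empty")
    if metric == "nearest_voxel":
        return ndimage.distance_transform_edt(~lesion, sampling=voxel_size_mm)
    if metric == "centroid":
        centroid = np.array(np.nonzero(lesion), dtype=float).mean(axis=1)
        coords = np.indices(lesion.shape, dtype=float)
        diff = coords - centroid[:, None, None, None]
        return voxel_size_mm * np.sqrt((diff**2).sum(axis=0))
    raise ValueError(f"unknown anatomical distance metric {metric!r}")


def lesion_volume(mask: np.ndarray, voxel_size_mm: float) -> float:
    """Lesion volume in cm^3: voxel count x voxel volume."""
    return float(np.asarray(mask, dtype=bool).sum()) * float(voxel_size_mm) ** 3 / 1000.0
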