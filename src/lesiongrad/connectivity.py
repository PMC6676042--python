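"""Voxelwise functional connectivity and the cosine affinity graph.

The group pipeline goes: per-subject Pearson FC -> Fisher-z averaging
across subjects -> per-row 90th-percentile sparsification -> pairwise
cosine similarity of the sparse rows, yielding a non-negative symmetric
affinity matrix ready for spectral (diffusion-map) decomposition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

#: correlations of magnitude 1 are clipped to 1 - FISHER_EPS before arctanh
FISHER_EPS = 1e-7


@dataclass
class SparseRowMatrix:
    """Row-thresholded connectivity matrix (generally asymmetric).

    Attributes
    ----------
    values : (V, V) ndarray
        Per row, entries strictly above that row's percentile; zeros elsewhere.
    retained_count : (V,) ndarray of int
        Number of retained entries per row.
    pct : float
        Percentile used for thresholding.
    """

    values: np.ndarray
    retained_count: np.ndarray
    pct: float


@dataclass
class AffinityMatrix:
    """Symmetric non-negative similarity matrix L with unit diagonal.

    ``clamped_count`` records how many (ordered) off-diagonal cosine values
    were negative and clamped to zero.
    """

    values: np.ndarray
    clamped_count: int


def pearson_fc(ts: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of voxel time series.

    Parameters
    ----------
    ts : (V, T) ndarray
        One row per voxel, T >= 2 timepoints.

    Returns
    -------
    (V, V) ndarray with unit diagonal, symmetric, entries in [-1, 1].

    Raises
    ------
    ValueError
        If any voxel's series is constant (undefined correlation).
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2 or ts.shape[1] < 2:
        raise ValueError("time series must be a (V, T) matrix with T >= 2")
    sd = ts.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"constant time series at voxel row(s) {bad[:10].tolist()}")
    fc = np.corrcoef(ts)
    np.clip(fc, -1.0, 1.0, out=fc)
    np.fill_diagonal(fc, 1.0)
    return fc


def fisher_z(r):
    """Fisher z-transform arctanh(r); |r| = 1 is clipped to 1 - 1e-7 first."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1):
        raise ValueError("correlation magnitude exceeds 1")
    return np.arctanh(np.clip(r, -1.0 + FISHER_EPS, 1.0 - FISHER_EPS))


def inv_fisher_z(z):
    """Inverse Fisher transform tanh(z)."""
    return np.tanh(np.asarray(z, dtype=float))


def group_average_fc(fc_list) -> np.ndarray:
    """Average FC matrices across subjects in the Fisher-z domain.

    Each matrix is z-transformed, the z-scores averaged elementwise, and the
    mean transformed back to r. The diagonal of the result is set to zero so
    that trivial self-correlation never enters the row-wise thresholding that
    follows.

    Raises
    ------
    ValueError
        If the list is empty or shapes disagree.
    """
    if len(fc_list) == 0:
        raise ValueError("need at least one FC matrix")
    shape = np.asarray(fc_list[0]).shape
    acc = np.zeros(shape)
    for i, fc in enumerate(fc_list):
        fc = np.asarray(fc, dtype=float)
        if fc.shape != shape:
            raise ValueError(f"FC matrix {i} has shape {fc.shape}, expected {shape}")
        acc += fisher_z(fc)
    mean_r = inv_fisher_z(acc / len(fc_list))
    np.fill_diagonal(mean_r, 0.0)
    return mean_r


def row_threshold(fc: np.ndarray, pct: float = 90.0) -> SparseRowMatrix:
    """Keep, per row, only entries strictly above the row's percentile.

    The percentile is computed by linear interpolation over all values of
    the row as given (callers zero the diagonal beforehand). Retention uses
    a strict ``>`` so ties at the threshold are dropped — deterministic
    counts at the cost of occasionally retaining fewer entries.

    A constant row retains nothing (its percentile equals the constant);
    this is logged as a warning rather than raised, since the downstream
    cosine step will reject the resulting zero row explicitly.
    """
    if not 0 <= pct < 100:
        raise ValueError("pct must be in [0, 100)")
    fc = np.asarray(fc, dtype=float)
    cutoffs = np.percentile(fc, pct, axis=1, keepdims=True)
    keep = fc > cutoffs
    values = np.where(keep, fc, 0.0)
    retained = keep.sum(axis=1)
    n_empty = int((retained == 0).sum())
    if n_empty:
        logger.warning("row_threshold: %d row(s) retained no entries", n_empty)
    return SparseRowMatrix(values=values, retained_count=retained, pct=float(pct))


def cosine_affinity(sparse: SparseRowMatrix | np.ndarray) -> AffinityMatrix:
    """Pairwise cosine similarity of sparse connectivity rows.

    Returns the affinity matrix L: symmetric, unit diagonal, entries in
    [0, 1]. Negative cosines (possible when retained values include
    negative correlations) are clamped to zero and counted.

    Raises
    ------
    ValueError
        If any row has zero norm (cosine undefined).
    """
    values = sparse.values if isinstance(sparse, SparseRowMatrix) else np.asarray(sparse, dtype=float)
    norms = np.linalg.norm(values, axis=1)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        raise ValueError(f"zero-norm sparse row(s) at voxel(s) {bad[:10].tolist()}")
    unit = values / norms[:, None]
    aff = unit @ unit.T
    aff = 0.5 * (aff + aff.T)  # enforce exact symmetry
    clamped = int(np.count_nonzero(aff < 0))
    np.clip(aff, 0.0, 1.0, out=aff)
    np.fill_diagonal(aff, 1.0)
    return AffinityMatrix(values=aff, clamped_count=clamped)
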