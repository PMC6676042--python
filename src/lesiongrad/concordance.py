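"""Longitudinal agreement of connectivity profiles via Lin's concordance.

The concordance correlation coefficient (CCC) measures agreement between
measurements, penalising not only decorrelation (like Pearson) but also
location and scale shifts. Applied per voxel to its functional
connectivity profile across sessions, low concordance flags voxels whose
connectivity pattern reorganised over time.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np

logger = logging.getLogger(__name__)


def pairwise_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient between two vectors.

    ccc = 2 s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2), with biased
    (divide-by-n) moment estimators, as in the original definition.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    mx, my = x.mean(), y.mean()
    sxy = np.mean(x * y) - mx * my
    sx2 = np.mean(x * x) - mx * mx
    sy2 = np.mean(y * y) - my * my
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0:
        raise ValueError("degenerate input: both vectors constant with equal means")
    return float(2.0 * sxy / denom)


def overall_ccc(vectors) -> float:
    """Overall CCC across k >= 2 vectors (the multi-rater generalisation).

    Sum of pairwise covariances over sum of pairwise denominators:

        sum_{j<l} 2 s_jl  /  sum_{j<l} (s_j^2 + s_l^2 + (m_j - m_l)^2)

    Reduces algebraically to :func:`pairwise_ccc` at k = 2.
    """
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need k >= 2 vectors of equal length")
    m = X.mean(axis=1)
    S = np.cov(X, bias=True)
    num = 0.0
    den = 0.0
    for j, l in combinations(range(X.shape[0]), 2):
        num += 2.0 * S[j, l]
        den += S[j, j] + S[l, l] + (m[j] - m[l]) ** 2
    if den == 0:
        raise ValueError("degenerate input: all vectors constant with equal means")
    return float(num / den)


def concordance_map(fc_by_session, convention: str = "overall") -> np.ndarray:
    """Per-voxel concordance of connectivity profiles across sessions.

    For each voxel, its profile in session j is row v of that session's FC
    matrix with the self-entry removed; the map value is the CCC of these
    profiles across sessions ("overall" sum-of-pairs form by default, or
    the mean of pairwise CCCs with ``convention='mean_pairwise'``).

    Values lie in [-1, 1]; voxels whose denominator is degenerate are set
    to NaN and logged. Vectorised over voxels: all per-voxel means,
    variances and cross-session covariances come from row sums and
    row-wise products of the (V, V) matrices, with each voxel's
    self-entry subtracted out.
    """
    mats = [np.asarray(fc, dtype=float) for fc in fc_by_session]
    k = len(mats)
    if k < 2:
        raise ValueError("need at least 2 sessions")
    V = mats[0].shape[0]
    for fc in mats:
        if fc.shape != (V, V):
            raise ValueError("session FC matrices must share the voxel set")
    if V < 3:
        raise ValueError("need at least 3 voxels")
    n = V - 1  # profile length after removing the self-entry

    diags = np.array([np.diag(fc) for fc in mats])
    means = np.empty((k, V))
    sq = np.empty((k, V))
    for j, fc in enumerate(mats):
        means[j] = (fc.sum(axis=1) - diags[j]) / n  # self-entry removed
        sq[j] = (np.einsum("ij,ij->i", fc, fc) - diags[j] ** 2) / n
    var = sq - means**2

    num = np.zeros(V)
    den = np.zeros(V)
    pair_sum = np.zeros(V) if convention == "mean_pairwise" else None
    n_pairs = 0
    for j, l in combinations(range(k), 2):
        cross = (np.einsum("ij,ij->i", mats[j], mats[l]) - diags[j] * diags[l]) / n
        s_jl = cross - means[j] * means[l]
        d = var[j] + var[l] + (means[j] - means[l]) ** 2
        if convention == "mean_pairwise":
            with np.errstate(divide="ignore", invalid="ignore"):
                pair_sum += np.where(d > 0, 2.0 * s_jl / d, np.nan)
            n_pairs += 1
        else:
            num += 2.0 * s_jl
            den += d
    if convention == "mean_pairwise":
        out = pair_sum / n_pairs
    elif convention == "overall":
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(den > 0, num / den, np.nan)
    else:
        raise ValueError(f"unknown CCC convention {convention!r}")

    n_bad = int(np.isnan(out).sum())
    if n_bad:
        logger.warning("concordance_map: %d voxel(s) with degenerate profiles set to NaN", n_bad)
    return np.clip(out, -1.0, 1.0)
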