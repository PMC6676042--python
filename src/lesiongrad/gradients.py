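"""Diffusion-map embedding of the affinity matrix into connectivity gradients.

Given the symmetric non-negative affinity L, the anisotropic-diffusion
normalisation with exponent ``alpha`` builds a Markov transition operator
whose leading non-trivial eigenvectors are the connectivity gradients:
voxels with similar (sparsified) connectivity profiles receive similar
embedding values. ``alpha = 0.5`` (Fokker–Planck normalisation) discounts
the influence of sampling density and is the default throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import eigsh

from .connectivity import AffinityMatrix

#: switch from dense eigh to iterative eigsh above this matrix size
_DENSE_LIMIT = 2000


@dataclass
class EmbeddingConfig:
    """Tunables of the diffusion embedding.

    alpha : density-normalisation exponent in [0, 1]; 0.5 by default.
    n_components : number of non-trivial gradients K to retain.
    diffusion_time : t >= 0; 0 selects the automatic lambda/(1-lambda)
        multi-scale weighting, t > 0 the fixed-time weighting lambda**t.
    sign_reference : optional (V, K) array used to orient eigenvector signs.
    """

    alpha: float = 0.5
    n_components: int = 3
    diffusion_time: float = 0.0
    sign_reference: np.ndarray | None = None

    def __post_init__(self):
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.diffusion_time < 0:
            raise ValueError("diffusion_time must be >= 0")


@dataclass
class DiffusionEmbedding:
    """Result of :func:`diffusion_embed`.

    values : (V, K) embedding values (gradient k in column k).
    eigenvalues : K non-trivial eigenvalues, descending, all < 1.
    variance_ratio : eigenvalue mass of each retained gradient.
    """

    values: np.ndarray
    eigenvalues: np.ndarray
    variance_ratio: np.ndarray
    config: EmbeddingConfig = field(repr=False, default=None)


def _check_connected(L: np.ndarray) -> None:
    n_comp, labels = connected_components(sp.csr_matrix(L > 0), directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels).tolist()
        raise ValueError(f"affinity graph is disconnected; component sizes {sizes}")


def diffusion_embed(L: AffinityMatrix | np.ndarray, cfg: EmbeddingConfig | None = None) -> DiffusionEmbedding:
    """Embed the affinity matrix into K connectivity gradients.

    Steps: (1) degrees d_i = sum_j L_ij; (2) alpha-normalise
    W = L / (d_i^a d_j^a); (3) conjugate to the symmetric operator
    S = Q^{-1/2} W Q^{-1/2} with q_i = sum_j W_ij; (4) take the top K+1
    eigenpairs of S; (5) map back, psi_k = Q^{-1/2} v_k, and drop the
    trivial constant psi_0; (6) weight gradient k by lambda_k/(1-lambda_k)
    (diffusion_time = 0) or lambda_k**t.

    Eigenvector sign is fixed so the voxel of largest |value| is positive
    (or follows ``cfg.sign_reference`` when given).
    """
    cfg = cfg or EmbeddingConfig()
    L = L.values if isinstance(L, AffinityMatrix) else np.asarray(L, dtype=float)
    V = L.shape[0]
    if L.shape != (V, V):
        raise ValueError("affinity must be square")
    if not np.allclose(L, L.T, atol=1e-10):
        raise ValueError("affinity must be symmetric")
    if np.any(L < 0):
        raise ValueError("affinity must be non-negative")
    k = cfg.n_components
    if k + 1 > V:
        raise ValueError(f"n_components + 1 = {k + 1} exceeds matrix size {V}")
    _check_connected(L)

    d = L.sum(axis=1)
    if cfg.alpha > 0:
        da = d ** cfg.alpha
        W = L / np.outer(da, da)
    else:
        W = L.copy()
    q = W.sum(axis=1)
    qs = np.sqrt(q)
    S = W / np.outer(qs, qs)
    S = 0.5 * (S + S.T)

    if V <= _DENSE_LIMIT:
        lam, vec = np.linalg.eigh(S)
        lam, vec = lam[::-1][: k + 1], vec[:, ::-1][:, : k + 1]
    else:
        lam, vec = eigsh(S, k=k + 1, which="LA", tol=1e-10)
        order = np.argsort(lam)[::-1]
        lam, vec = lam[order], vec[:, order]

    psi = vec / qs[:, None]
    # the leading eigenpair must be the trivial stationary mode
    psi0 = psi[:, 0]
    if np.ptp(psi0) > 1e-6 * max(np.abs(psi0).max(), 1e-300):
        raise ValueError("leading eigenvector is not constant; operator is ill-conditioned")
    lam_k = lam[1:]
    if np.any(lam_k >= 1 - 1e-12):
        raise ValueError("non-trivial eigenvalue reached 1; affinity graph is effectively disconnected")

    if cfg.diffusion_time == 0:
        scale = lam_k / (1.0 - lam_k)
    else:
        scale = np.sign(lam_k) * np.abs(lam_k) ** cfg.diffusion_time
    values = psi[:, 1:] * scale
    emb = DiffusionEmbedding(
        values=values,
        eigenvalues=lam_k,
        variance_ratio=variance_explained(np.clip(lam_k, 0.0, None)),
        config=cfg,
    )
    return align_sign(emb, cfg.sign_reference)


def variance_explained(eigenvalues) -> np.ndarray:
    """Share of retained (non-trivial) eigenvalue mass per gradient.

    ratio_k = lambda_k / sum_j lambda_j over the eigenvalues passed in.
    This is one of several conventions for "variance explained" by
    diffusion gradients; it is the package default and is stated as such
    wherever the numbers are reported.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if np.any(lam < -1e-12):
        raise ValueError("eigenvalues must be non-negative")
    lam = np.clip(lam, 0.0, None)
    if np.any(np.diff(lam) > 1e-12):
        raise ValueError("eigenvalues must be in descending order")
    total = lam.sum()
    if total == 0:
        raise ValueError("all eigenvalues are zero")
    return lam / total


def align_sign(emb: DiffusionEmbedding, reference: np.ndarray | None = None) -> DiffusionEmbedding:
    """Resolve the arbitrary sign of each gradient.

    With a reference embedding, each column is flipped to correlate
    positively with the corresponding reference column; a zero-correlation
    column falls back to the default rule. Without a reference, the sign is
    chosen so the voxel of maximum |value| is positive (first such voxel on
    ties). Idempotent in both modes.
    """
    values = emb.values.copy()
    K = values.shape[1]
    for j in range(K):
        col = values[:, j]
        flip = False
        decided = False
        if reference is not None:
            ref = np.asarray(reference)[:, j]
            c = float(np.dot(col - col.mean(), ref - ref.mean()))
            if c != 0:
                flip = c < 0
                decided = True
        if not decided:
            imax = int(np.argmax(np.abs(col)))
            flip = col[imax] < 0
        if flip:
            values[:, j] = -col
    return DiffusionEmbedding(
        values=values,
        eigenvalues=emb.eigenvalues.copy(),
        variance_ratio=emb.variance_ratio.copy(),
        config=emb.config,
    )
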