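"""Diffusion-map embedding of connectome affinity matrices.

The template manifold is estimated from the group-average connectome;
individual connectomes are embedded with identical parameters and rotated
onto the template with an orthogonal Procrustes fit, so subject
eigenvectors are comparable parcel-by-parcel and component-by-component.

Defaults follow the common gradient-mapping settings: normalized-angle
affinity on a 10%-density connectome, diffusion operator with alpha = 0.5
(approximate Laplace-Beltrami normalization, removing sampling-density
influence) and t = 0, which here triggers multiscale eigenvalue scaling
lambda / (1 - lambda) — the documented behaviour of the diffusion-mapping
tools this mirrors — rather than the literal lambda^0 = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .connectome import ConnectivityMatrix, threshold_by_density

__all__ = [
    "AffinityMatrix",
    "ManifoldEmbedding",
    "AlignedManifoldSet",
    "normalized_angle_affinity",
    "diffusion_map_embed",
    "procrustes_align",
    "build_aligned_set",
]


@dataclass
class AffinityMatrix:
    """Symmetric parcel x parcel similarity in [0, 1], unit diagonal."""

    values: np.ndarray

    @property
    def n_parcels(self) -> int:
        return self.values.shape[0]


@dataclass
class ManifoldEmbedding:
    """Eigenvectors (E1..Ek) and spectrum of a diffusion-map embedding."""

    eigenvectors: np.ndarray  # (n_parcels, n_components)
    eigenvalues: np.ndarray  # (n_components,), nonincreasing
    variance_explained: np.ndarray  # (n_components,) fractions
    alpha: float = 0.5
    t: float = 0.0

    @property
    def n_components(self) -> int:
        return self.eigenvectors.shape[1]

    def center(self) -> np.ndarray:
        """Column mean of the eigenvectors (the manifold center)."""
        return self.eigenvectors.mean(axis=0)


@dataclass
class AlignedManifoldSet:
    """Template embedding plus Procrustes-aligned subject embeddings."""

    template: ManifoldEmbedding
    subjects: dict[str, np.ndarray] = field(default_factory=dict)
    rotations: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.subjects)


def normalized_angle_affinity(C: ConnectivityMatrix) -> AffinityMatrix:
    """Affinity 1 - theta/pi between connectivity profiles (rows).

    theta is the angle between two rows; parallel rows map to 1,
    orthogonal to 0.5, anti-parallel to 0. Requires a thresholded
    connectome with no all-zero row.
    """
    if not C.is_thresholded:
        raise ValueError("affinity expects a density-thresholded connectome")
    W = C.values
    norms = np.linalg.norm(W, axis=1)
    dead = np.flatnonzero(norms == 0)
    if dead.size:
        raise ValueError(f"all-zero connectivity row(s): {dead.tolist()}")
    cos = (W @ W.T) / np.outer(norms, norms)
    cos = np.clip(cos, -1.0, 1.0)
    A = 1.0 - np.arccos(cos) / np.pi
    np.fill_diagonal(A, 1.0)
    A = (A + A.T) / 2.0
    return AffinityMatrix(values=A)


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Pin each column's sign: largest-magnitude entry made positive."""
    out = vectors.copy()
    for j in range(out.shape[1]):
        i = np.argmax(np.abs(out[:, j]))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def diffusion_map_embed(
    A: AffinityMatrix,
    alpha: float = 0.5,
    t: float = 0.0,
    n_components: int = 10,
    multiscale_at_t0: bool = True,
) -> ManifoldEmbedding:
    """Diffusion-map embedding of a symmetric nonnegative affinity.

    The affinity is alpha-normalized (W = D^-a A D^-a), turned into a
    Markov operator, and eigendecomposed through its symmetric conjugate
    for stability. The trivial stationary eigenvector (eigenvalue 1) is
    discarded; the next ``n_components`` eigenvectors are returned scaled
    by lambda/(1-lambda) when ``t == 0`` and ``multiscale_at_t0`` (the
    conventional multiscale rule), else by lambda**t. Variance explained
    is each eigenvalue over the sum of all nontrivial nonnegative
    eigenvalues. Raises on a disconnected affinity graph (repeated unit
    eigenvalue).
    """
    M = np.asarray(A.values, float)
    n = M.shape[0]
    if n_components >= n:
        raise ValueError("n_components must be < n_parcels")
    if (M < 0).any():
        raise ValueError("affinity must be nonnegative")
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError("affinity must be symmetric")

    d = M.sum(axis=1)
    if alpha != 0.0:
        W = M / np.outer(d**alpha, d**alpha)
    else:
        W = M.copy()
    dw = W.sum(axis=1)
    # symmetric conjugate of the Markov operator D_W^-1 W
    S = W / np.sqrt(np.outer(dw, dw))
    S = (S + S.T) / 2.0
    evals, evecs = scipy.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    if evals[1] > 1.0 - 1e-10:
        raise ValueError("affinity graph is disconnected (repeated unit eigenvalue)")

    # psi_i(x) = v_i(x) / v_0(x): diffusion coordinates with the trivial
    # component constant at 1
    psi = evecs / evecs[:, [0]]
    lams = evals[1 : n_components + 1]
    if t == 0 and multiscale_at_t0:
        scale = lams / (1.0 - lams)
    else:
        scale = lams**t
    vectors = _fix_signs(psi[:, 1 : n_components + 1] * scale)

    nontrivial = evals[1:]
    pos = nontrivial[nontrivial > 0]
    denom = pos.sum()
    var_exp = np.where(lams > 0, lams, 0.0) / denom if denom > 0 else np.zeros_like(lams)
    return ManifoldEmbedding(
        eigenvectors=vectors,
        eigenvalues=lams,
        variance_explained=var_exp,
        alpha=alpha,
        t=t,
    )


def procrustes_align(source: np.ndarray, target: np.ndarray):
    """Orthogonal Procrustes: rotation R minimizing ||source R - target||_F.

    SVD solution; reflections allowed, no centering or scaling. Returns
    ``(source @ R, R)``. Warns (and proceeds) on a rank-deficient
    cross-covariance, where the minimizer is not unique.
    """
    source = np.asarray(source, float)
    target = np.asarray(target, float)
    if source.shape != target.shape:
        raise ValueError("source and target must have equal shapes")
    M = source.T @ target
    if np.linalg.matrix_rank(M) < M.shape[0]:
        warnings.warn(
            "rank-deficient cross-covariance; Procrustes rotation not unique",
            stacklevel=2,
        )
    U, _, Vt = np.linalg.svd(M)
    R = U @ Vt
    return source @ R, R


def build_aligned_set(
    group_C: ConnectivityMatrix,
    subject_Cs,
    density: float = 0.10,
    alpha: float = 0.5,
    t: float = 0.0,
    n_components: int = 3,
    n_components_internal: int = 10,
) -> AlignedManifoldSet:
    """Template embedding plus aligned subject embeddings.

    The template is embedded from the (thresholded) group connectome;
    each subject connectome is embedded with identical parameters, the
    full ``n_components_internal``-dimensional eigenspace is
    Procrustes-rotated onto the template's, and the first
    ``n_components`` aligned columns (default 3, the E1-E3 convention)
    are reported. Aligning in the full internal space matters when
    neighbouring eigenvalues are close: subject-level rotations then mix
    nearby components, and a rotation fitted on the leading columns
    alone could not undo mixing with the discarded ones.
    """
    if n_components > n_components_internal:
        raise ValueError("n_components cannot exceed n_components_internal")

    def _embed(C: ConnectivityMatrix) -> ManifoldEmbedding:
        thr = threshold_by_density(C, density) if not C.is_thresholded else C
        return diffusion_map_embed(
            normalized_angle_affinity(thr),
            alpha=alpha,
            t=t,
            n_components=n_components_internal,
        )

    template_full = _embed(group_C)
    template = ManifoldEmbedding(
        eigenvectors=template_full.eigenvectors[:, :n_components],
        eigenvalues=template_full.eigenvalues[:n_components],
        variance_explained=template_full.variance_explained[:n_components],
        alpha=alpha,
        t=t,
    )
    out = AlignedManifoldSet(template=template)
    for i, C in enumerate(subject_Cs):
        sid = C.subject_id or f"sub{i}"
        emb = _embed(C)
        aligned, R = procrustes_align(
            emb.eigenvectors, template_full.eigenvectors
        )
        out.subjects[sid] = aligned[:, :n_components]
        out.rotations[sid] = R
    return out
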