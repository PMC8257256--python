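"""Landmark-based morphometrics baseline: generalized Procrustes analysis.

Specimens are described by L homologous (x, y) landmarks (12 vein
intersections for the fly wing, hence a 24-dimensional shape space).
Configurations are superimposed by optimal translation, rotation, and
uniform scaling (no reflection); the goodness of a superimposition is the
Procrustes distance, the root-sum-of-squares over all 2L coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DiscmorphError
from .stats import PCAResult, pca_decompose

__all__ = ["GPAResult", "procrustes_superimpose", "procrustes_distance", "landmark_pca"]


@dataclass
class GPAResult:
    """Generalized Procrustes superimposition of an ensemble."""

    aligned: np.ndarray  # (n, L, 2)
    mean_shape: np.ndarray  # (L, 2), unit centroid size
    n_iterations: int
    specimen_ids: list | None = None


def _center_and_size(P: np.ndarray):
    c = P.mean(axis=0)
    Q = P - c
    size = np.sqrt((Q**2).sum())
    return Q, size


def _align_one(P: np.ndarray, ref: np.ndarray, scaling: str = "size") -> np.ndarray:
    """Optimal translation + rotation (+ uniform scale) of P onto ref.

    Reflection is never allowed: the rotation comes from an SVD with the
    determinant sign corrected.
    """
    Q, size = _center_and_size(P)
    if size == 0:
        raise DiscmorphError("degenerate specimen: all landmarks coincide")
    Q = Q / size
    H = Q.T @ ref
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    Dm = np.diag([1.0, d])
    Rm = U @ Dm @ Vt
    A = Q @ Rm
    if scaling == "size":
        return A
    if scaling == "match":
        # least-squares scale onto the reference after rotation
        s = (A * ref).sum() / (A * A).sum()
        return A * s
    raise DiscmorphError(f"unknown scaling mode {scaling!r}")


def procrustes_superimpose(
    ensemble,
    tol: float = 1e-8,
    max_iter: int = 200,
    scaling: str = "size",
    specimen_ids: list | None = None,
) -> GPAResult:
    """Generalized Procrustes analysis of >= 2 equal-L landmark sets.

    Every configuration is centered and scaled to unit centroid size, then
    iteratively rotated onto the running mean shape until the mean changes
    by less than ``tol``.  ``scaling='match'`` instead least-squares
    matches each specimen's scale to the mean (an area-matching variant).
    """
    sets = [np.asarray(P, dtype=float) for P in ensemble]
    if len(sets) < 2:
        raise DiscmorphError("need at least 2 specimens")
    L = sets[0].shape[0]
    if any(P.shape != (L, 2) for P in sets):
        raise DiscmorphError("all specimens must share the same landmark count")
    aligned = []
    for P in sets:
        Q, size = _center_and_size(P)
        if size == 0:
            raise DiscmorphError("degenerate specimen: all landmarks coincide")
        aligned.append(Q / size)
    aligned = np.array(aligned)
    mean = aligned[0].copy()
    mean /= np.sqrt((mean**2).sum())
    n_it = 0
    for n_it in range(1, max_iter + 1):
        aligned = np.array([_align_one(P, mean, scaling) for P in aligned])
        new_mean = aligned.mean(axis=0)
        new_mean -= new_mean.mean(axis=0)
        nrm = np.sqrt((new_mean**2).sum())
        if nrm == 0:
            raise DiscmorphError("mean shape collapsed")
        new_mean /= nrm
        if np.sqrt(((new_mean - mean) ** 2).sum()) < tol:
            mean = new_mean
            break
        mean = new_mean
    return GPAResult(aligned=aligned, mean_shape=mean, n_iterations=n_it, specimen_ids=specimen_ids)


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Root-sum-of-squares distance between two aligned configurations."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise DiscmorphError(f"landmark count mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(((a - b) ** 2).sum()))


def landmark_pca(gpa: GPAResult, n_components: int | None = None) -> PCAResult:
    """Centered PCA over flattened aligned landmark vectors (2L dims)."""
    X = gpa.aligned.reshape(len(gpa.aligned), -1)
    return pca_decompose(X, n_components)
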