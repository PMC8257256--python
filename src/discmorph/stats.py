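"""Ensemble statistics in phenotype space.

Variation *within* a group is quantified by nonparametric k-nearest-
neighbor (Kozachenko-Leonenko) differential entropy and by PCA; variation
*between* groups by a k-NN estimator of the Kullback-Leibler divergence
and by centroid geometry: the centroid difference Delta, its norm R, the
unit direction n = Delta/|Delta| and the cosines of n against the
reference group's principal components.  Inference is nonparametric
throughout: bootstrap subsampling for in-sample variance, label shuffling
for null distributions, and marginal (per-column) resampling for the
eigenvalue null spectrum.

The entropy estimator implements the k-NN formula

    H_k = log c_d + log(N - 1) - psi(k) + (d/N) sum_i log rho_k(i)

with c_d the d-ball volume and rho_k(i) the distance of sample i to its
k-th nearest neighbor; a variant replacing log(N - 1) by psi(N) is
available via ``n_term='psi'``.  The two-sample KL estimator is

    D = (d/N) sum_i log(nu_k(i) / rho_k(i)) + log(M / (N - 1)),

with nu_k(i) the distance from x_i to its k-th nearest neighbor in the
other sample.  8-bit intensities are dequantized with seeded
Uniform(-1/2, 1/2) jitter before either estimator (ties give rho = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma, gammaln

from .conformal import DiscImage
from .errors import DiscmorphError, EstimatorError
from .radon import PhenotypeMatrix, Sinogram, inverse_radon

__all__ = [
    "EntropyMap",
    "PCAResult",
    "GroupComparison",
    "ManifoldFit",
    "dequantize",
    "knn_entropy",
    "entropy_map",
    "knn_kl_divergence",
    "symmetrized_kl_map",
    "pca_decompose",
    "count_significant_eigenvalues",
    "centroid_difference_map",
    "alignment_cosine",
    "bootstrap_alignment_curve",
    "shuffle_null_pvalue",
    "fit_manifold_decay",
]


# --------------------------------------------------------------------------
# k-NN estimators
# --------------------------------------------------------------------------


def _unit_ball_log_volume(d: int) -> float:
    return 0.5 * d * np.log(np.pi) - gammaln(0.5 * d + 1.0)


def dequantize(X: np.ndarray, seed: int | None = 0) -> np.ndarray:
    """Add seeded Uniform(-1/2, 1/2) jitter to break intensity ties.

    ``seed=None`` disables the jitter (for data that is already
    continuous); any integer gives a reproducible draw.
    """
    if seed is None:
        return np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    return np.asarray(X, dtype=float) + rng.uniform(-0.5, 0.5, size=np.shape(X))


def _knn_dists(X: np.ndarray, k: int) -> np.ndarray:
    """Distance of each row to its k-th nearest neighbor, excluding itself."""
    tree = cKDTree(X)
    d, _ = tree.query(X, k=k + 1, workers=-1)
    return d[:, k]


def knn_entropy(samples: np.ndarray, k: int = 3, n_term: str = "log_nm1") -> float:
    """k-NN differential entropy estimate in nats.

    ``n_term`` selects the additive sample-size term: 'log_nm1' uses
    log(N - 1) (the default); 'psi' uses the digamma psi(N) found in parts
    of the estimator literature.  The two differ by O(1/N).
    """
    X = np.atleast_2d(np.asarray(samples, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and np.ndim(samples) == 1:
        X = X.T
    n, d = X.shape
    if k < 1 or n <= k:
        raise EstimatorError(f"need n > k >= 1, got n={n}, k={k}")
    rho = _knn_dists(X, k)
    if np.any(rho == 0):
        raise EstimatorError(
            "duplicate points give zero k-NN distance; dequantize the samples first"
        )
    if n_term == "log_nm1":
        nt = np.log(n - 1.0)
    elif n_term == "psi":
        nt = float(digamma(n))
    else:
        raise EstimatorError(f"unknown n_term {n_term!r}")
    return float(_unit_ball_log_volume(d) + nt - digamma(k) + d / n * np.log(rho).sum())


def knn_kl_divergence(X: np.ndarray, Y: np.ndarray, k: int = 2) -> float:
    """k-NN Kullback-Leibler divergence estimate D(P||Q) in nats.

    X ~ P (N samples), Y ~ Q (M samples); rho_k from within X, nu_k from X
    into Y.  The estimator is asymmetric in (X, Y), like the divergence.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] == 1 and np.ndim(np.asarray(X).squeeze()) == 1 and X.shape[1] > 1:
        X = X.T
    if Y.shape[0] == 1 and Y.shape[1] > 1:
        Y = Y.T
    n, d = X.shape
    m, d2 = Y.shape
    if d != d2:
        raise EstimatorError("X and Y must have the same dimension")
    if n <= k or m <= k:
        raise EstimatorError(f"need n, m > k, got n={n}, m={m}, k={k}")
    rho = _knn_dists(X, k)
    nu, _ = cKDTree(Y).query(X, k=k, workers=-1)
    nu = nu[:, k - 1] if k > 1 else nu.ravel()
    if np.any(rho == 0) or np.any(nu == 0):
        raise EstimatorError(
            "zero nearest-neighbor distance; dequantize the samples first"
        )
    return float(d / n * np.log(nu / rho).sum() + np.log(m / (n - 1.0)))


# -- vectorized 1-D paths (per-column maps) ---------------------------------


def _knn_dists_1d_columns(X: np.ndarray, k: int) -> np.ndarray:
    """k-th nearest neighbor distance per entry, independently per column.

    X is (n, m): n samples of m scalar variables.  In 1-D the k nearest
    neighbors of a point lie within k positions in sort order, so the
    distances come from a sliding window over the sorted columns.
    """
    n, m = X.shape
    S = np.sort(X, axis=0)
    cand = np.full((2 * k, n, m), np.inf)
    for j in range(1, k + 1):
        cand[j - 1, j:, :] = S[j:, :] - S[:-j, :]  # j-th predecessor
        cand[k + j - 1, :-j, :] = S[j:, :] - S[:-j, :]  # j-th successor
    kth = np.partition(cand, k - 1, axis=0)[k - 1]
    # undo the sort: kth[i] corresponds to sorted position i
    order = np.argsort(X, axis=0)
    out = np.empty_like(kth)
    np.put_along_axis(out, order, kth, axis=0)
    return out


def _cross_knn_dists_1d_columns(X: np.ndarray, Y: np.ndarray, k: int) -> np.ndarray:
    """Distance from each X entry to its k-th nearest neighbor in Y, per column."""
    n, m = X.shape
    ny = Y.shape[0]
    if ny < k:
        raise EstimatorError("reference sample smaller than k")
    out = np.empty((n, m))
    for c in range(m):
        ys = np.sort(Y[:, c])
        pos = np.searchsorted(ys, X[:, c])
        # candidate neighbors are the k values on each side of the insertion point
        idx = pos[:, None] + np.arange(-k, k)
        idx = np.clip(idx, 0, ny - 1)
        d = np.abs(ys[idx] - X[:, c][:, None])
        out[:, c] = np.partition(d, k - 1, axis=1)[:, k - 1]
    return out


@dataclass
class EntropyMap:
    """Per-variable (pixel or sinogram-bin) entropy estimates in nats."""

    values: np.ndarray
    k: int
    n: int
    minimal: np.ndarray  # True where the pre-jitter column was constant

    def as_image(self, template: DiscImage) -> DiscImage:
        """Reshape a disc-pixel-domain map back onto the disc raster."""
        grid = np.zeros_like(template.grid)
        grid[template.valid] = self.values
        return DiscImage(grid=grid, valid=template.valid.copy(), provenance={"map": "entropy"})


def _columns_of(data) -> np.ndarray:
    """(n, m) column matrix from a PhenotypeMatrix or a DiscImage list."""
    if isinstance(data, PhenotypeMatrix):
        return np.asarray(data.X, dtype=float)
    if isinstance(data, np.ndarray):
        return np.asarray(data, dtype=float)
    # list of DiscImage: valid pixels as columns
    return np.vstack([im.values() for im in data])


def entropy_map(data, k: int = 3, seed: int | None = 0, n_term: str = "log_nm1") -> EntropyMap:
    """Per-column 1-D entropy over an ensemble, after dequantization.

    ``data`` is a PhenotypeMatrix, an (n, m) array, or a list of aligned
    DiscImage (per-pixel map over valid pixels, matching the entropy maps
    of landmark-free analyses).  Columns with zero pre-jitter variance are
    flagged ``minimal``: their estimate reflects only the jitter floor.
    """
    X = _columns_of(data)
    n, m = X.shape
    if n < k + 2:
        raise EstimatorError(f"need at least k+2={k + 2} images, got {n}")
    if n < 20:
        raise EstimatorError(f"entropy maps need n >= 20 images, got {n}")
    minimal = X.std(axis=0) == 0
    Xj = dequantize(X, seed)
    rho = _knn_dists_1d_columns(Xj, k)
    nt = np.log(n - 1.0) if n_term == "log_nm1" else float(digamma(n))
    vals = _unit_ball_log_volume(1) + nt - digamma(k) + np.log(rho).sum(axis=0) / n
    return EntropyMap(values=vals, k=k, n=n, minimal=minimal)


def symmetrized_kl_map(A, B, k: int = 2, seed: int | None = 0) -> np.ndarray:
    """Per-column symmetrized KL divergence between two ensembles.

    Returns (D(A||B) + D(B||A)) / 2 for every column (1-D estimates);
    symmetric in (A, B) by construction.
    """
    XA = _columns_of(A)
    XB = _columns_of(B)
    if XA.shape[1] != XB.shape[1]:
        raise EstimatorError("ensembles do not share a phenotype domain")
    na, nb = XA.shape[0], XB.shape[0]
    if na <= k or nb <= k:
        raise EstimatorError("too few samples for the KL estimator")
    Aj = dequantize(XA, seed)
    Bj = dequantize(XB, None if seed is None else seed + 1)
    if np.array_equal(Aj, Bj):
        raise EstimatorError(
            "the two ensembles are identical after dequantization; the k-NN "
            "divergence estimator requires independent samples"
        )
    rho_a = _knn_dists_1d_columns(Aj, k)
    rho_b = _knn_dists_1d_columns(Bj, k)
    nu_ab = _cross_knn_dists_1d_columns(Aj, Bj, k)
    nu_ba = _cross_knn_dists_1d_columns(Bj, Aj, k)
    d_ab = np.log(nu_ab / rho_a).sum(axis=0) / na + np.log(nb / (na - 1.0))
    d_ba = np.log(nu_ba / rho_b).sum(axis=0) / nb + np.log(na / (nb - 1.0))
    return 0.5 * (d_ab + d_ba)


# --------------------------------------------------------------------------
# PCA and eigenvalue significance
# --------------------------------------------------------------------------


@dataclass
class PCAResult:
    """Centered PCA of a phenotype matrix."""

    eigenvalues: np.ndarray  # variance per component, non-increasing
    components: np.ndarray  # (n_components, n_features), orthonormal rows
    scores: np.ndarray  # (n_samples, n_components)
    mean: np.ndarray  # centroid vector
    explained_fraction: np.ndarray


def _centered_pca(X: np.ndarray, n_components: int):
    mean = X.mean(axis=0)
    Xc = X - mean
    # economy SVD via the Gram matrix: n << n_features in this domain
    n = X.shape[0]
    G = Xc @ Xc.T
    evals, evecs = np.linalg.eigh(G)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    total_var = evals.sum() / (n - 1)
    k = n_components
    sv = np.sqrt(np.maximum(evals[:k], 1e-300))
    comps = (evecs[:, :k] / sv).T @ Xc
    scores = evecs[:, :k] * sv
    eigs = evals[:k] / (n - 1)
    # deterministic sign: largest-magnitude coordinate positive
    for i in range(k):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
            scores[:, i] = -scores[:, i]
    return mean, eigs, comps, scores, total_var


def pca_decompose(matrix, n_components: int | None = None) -> PCAResult:
    """Centered (unscaled) PCA with a deterministic sign convention."""
    X = _columns_of(matrix)
    n, p = X.shape
    if n < 3:
        raise DiscmorphError(f"PCA needs at least 3 rows, got {n}")
    max_comp = min(n - 1, p)
    if n_components is None:
        n_components = max_comp
    if n_components > max_comp:
        raise DiscmorphError(
            f"n_components={n_components} exceeds min(n-1, dims)={max_comp}"
        )
    mean, eigs, comps, scores, total_var = _centered_pca(X, n_components)
    frac = eigs / total_var if total_var > 0 else np.zeros_like(eigs)
    return PCAResult(
        eigenvalues=eigs,
        components=comps,
        scores=scores,
        mean=mean,
        explained_fraction=frac,
    )


def count_significant_eigenvalues(
    matrix,
    n_resamples: int = 100,
    seed: int | None = 0,
    quantile: float = 0.95,
    n_components: int | None = None,
):
    """Eigenvalue significance by marginal resampling.

    Null matrices permute every column independently across rows,
    destroying covariance while preserving marginals.  An observed
    eigenvalue is significant when it exceeds the ``quantile`` of the
    null eigenvalues of the same rank.  Returns (count, observed
    eigenvalues, null spectra array of shape (n_resamples, n_components)).
    """
    X = _columns_of(matrix)
    n, p = X.shape
    if n < 20:
        raise DiscmorphError(f"need n >= 20 images, got {n}")
    if n_resamples < 20:
        import warnings

        warnings.warn("fewer than 20 marginal resamples: the null quantile is coarse")
    k = n_components or min(n - 1, p)
    obs = pca_decompose(matrix, k).eigenvalues
    rng = np.random.default_rng(seed)
    null = np.empty((n_resamples, k))
    for r in range(n_resamples):
        perm = np.argsort(rng.random((n, p)), axis=0)
        Xn = np.take_along_axis(X, perm, axis=0)
        _, eigs, _, _, _ = _centered_pca(Xn, k)
        null[r] = eigs
    thresh = np.quantile(null, quantile, axis=0)
    count = int(np.sum(obs > thresh))
    return count, obs, null


# --------------------------------------------------------------------------
# centroid geometry
# --------------------------------------------------------------------------


@dataclass
class GroupComparison:
    """Centroid difference between two groups in phenotype space."""

    delta: np.ndarray  # Delta = centroid(B) - centroid(A)
    distance: float  # R = |Delta|
    direction: np.ndarray  # n = Delta / R
    cosines: np.ndarray = field(default=None)  # |<n, PC_k>| against a reference PCA

    @classmethod
    def between(cls, A, B) -> "GroupComparison":
        XA, XB = _columns_of(A), _columns_of(B)
        if XA.size == 0 or XB.size == 0:
            raise DiscmorphError("empty ensemble in group comparison")
        delta = XB.mean(axis=0) - XA.mean(axis=0)
        R = float(np.linalg.norm(delta))
        direction = delta / R if R > 0 else np.zeros_like(delta)
        return cls(delta=delta, distance=R, direction=direction)


def centroid_difference_map(A, B, sino_shape: tuple[int, int] | None = None):
    """Centroid difference in Radon space plus its signed disc visualization.

    ``A`` and ``B`` are PhenotypeMatrix objects in the Radon domain (or raw
    row matrices plus an explicit ``sino_shape``).  Returns the
    GroupComparison and the inverse-Radon reconstruction of Delta as a
    signed DiscImage (negative where B is darker than A).
    """
    comp = GroupComparison.between(A, B)
    img = None
    if isinstance(A, PhenotypeMatrix) and A.domain == "radon":
        shape = A.sino_shape()
        sino = Sinogram(
            values=comp.delta.reshape(shape), angles=A.angles, offset_axis=A.offsets
        )
        img = inverse_radon(sino)
    elif sino_shape is not None:
        no, na = sino_shape
        sino = Sinogram(
            values=comp.delta.reshape(sino_shape),
            angles=np.linspace(0.0, 180.0, na, endpoint=False),
            offset_axis=np.arange(no) - no // 2,
        )
        img = inverse_radon(sino)
    return comp, img


def alignment_cosine(comparison: GroupComparison, reference_pca: PCAResult, k: int = 1) -> float:
    """|cos theta| between the centroid-difference direction and PC_k.

    Reported as an absolute value because the sign of a principal
    component is conventional.
    """
    if comparison.distance == 0:
        raise DiscmorphError("zero centroid distance: the direction is undefined")
    pc = reference_pca.components[k - 1]
    if pc.shape != comparison.direction.shape:
        raise DiscmorphError("comparison and PCA dimensions differ")
    return float(abs(np.dot(comparison.direction, pc)))


# --------------------------------------------------------------------------
# bootstrap / shuffle inference and manifold geometry
# --------------------------------------------------------------------------


@dataclass
class ManifoldFit:
    """Decay of the off-axis fraction sqrt(1 - cos^2) with distance R.

    For a 1D-cylinder data manifold sigma/R = sqrt(1 - cos^2 theta) with
    constant sigma, so the log-log slope is -1 (alpha = 1); a cone
    (sigma proportional to R) gives alpha = 0.
    """

    points: np.ndarray  # (n, 2) of (R, cos theta)
    sigma_over_r: np.ndarray
    alpha: float
    intercept: float
    fit_range: tuple[float, float]

    def cylinder_prediction(self, R: np.ndarray) -> np.ndarray:
        """sigma/R for constant sigma (the alpha = 1 reference line),
        anchored at the geometric mean of the observed sigma values."""
        sigma = float(np.exp(np.mean(np.log(self.sigma_over_r * self.points[:, 0]))))
        return sigma / np.asarray(R, dtype=float)


def fit_manifold_decay(points) -> ManifoldFit:
    """Least-squares fit of log sqrt(1 - cos^2) versus log R; alpha = -slope."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise DiscmorphError("points must be (R, cos theta) pairs")
    R = pts[:, 0]
    c = np.clip(np.abs(pts[:, 1]), 0.0, 1.0)
    ok = R > 0
    if ok.sum() < 5:
        raise DiscmorphError("need at least 5 points with R > 0")
    R, c = R[ok], c[ok]
    s = np.sqrt(np.clip(1.0 - c**2, 0.0, None))
    if np.all(s == 0):
        raise DiscmorphError("all cos theta = 1 exactly: the decay fit is degenerate")
    s = np.maximum(s, 1e-12)
    slope, intercept = np.polyfit(np.log(R), np.log(s), 1)
    return ManifoldFit(
        points=np.c_[R, c],
        sigma_over_r=s,
        alpha=float(-slope),
        intercept=float(intercept),
        fit_range=(float(R.min()), float(R.max())),
    )


def orthogonal_residual(comparison: GroupComparison, reference_pca: PCAResult) -> float:
    """Norm of the component of Delta orthogonal to PC1.

    Identically equal to sqrt(1 - cos^2 theta) * R: the exactly assertable
    form of the sigma/R relation.
    """
    pc1 = reference_pca.components[0]
    delta = comparison.delta
    return float(np.linalg.norm(delta - np.dot(delta, pc1) * pc1))


def bootstrap_alignment_curve(
    A,
    B,
    reference=None,
    frac: float = 0.5,
    n_boot: int = 100,
    seed: int | None = 0,
    with_replacement: bool = False,
    pc: int = 1,
) -> np.ndarray:
    """Bootstrap (R, cos theta) pairs for the manifold-decay analysis.

    Each replicate subsamples every group independently (a ``frac``
    fraction without replacement by default, or a full-size resample with
    replacement), recomputes both centroids and the reference PCA, and
    records the centroid distance R and |cos theta| against the reference
    PC.  Groups are never mixed.  ``reference`` defaults to A.
    """
    if not (0.0 < frac <= 1.0):
        raise DiscmorphError(f"frac must be in (0, 1], got {frac}")
    XA, XB = _columns_of(A), _columns_of(B)
    ref_is_a = reference is None or reference is A
    XR = XA if ref_is_a else _columns_of(reference)
    if min(len(XA), len(XB), len(XR)) < 4:
        raise DiscmorphError("groups too small to bootstrap")
    rng = np.random.default_rng(seed)
    out = np.empty((n_boot, 2))
    for b in range(n_boot):
        def draw(X):
            n = len(X)
            if with_replacement:
                idx = rng.integers(n, size=n)
            else:
                m = max(2, int(round(frac * n)))
                idx = rng.permutation(n)[:m]
            return X[idx], idx

        sa, ia = draw(XA)
        sb, _ = draw(XB)
        sr = XA[ia] if ref_is_a else draw(XR)[0]
        delta = sb.mean(axis=0) - sa.mean(axis=0)
        R = np.linalg.norm(delta)
        kmax = min(len(sr) - 1, pc + 1)
        rp = pca_decompose(sr, kmax)
        c = abs(np.dot(delta / R, rp.components[pc - 1])) if R > 0 else 0.0
        out[b] = (R, c)
    return out


def shuffle_null_pvalue(
    X,
    labels,
    reference_label,
    test_label,
    strata=None,
    n_shuffles: int = 200,
    seed: int | None = 0,
    pc: int = 1,
):
    """Shuffle test for the alignment cosine between two labeled groups.

    The observed statistic is |cos theta| between the reference->test
    centroid direction and PC``pc`` of the reference group.  Group labels
    are permuted within strata (e.g., sexes are never mixed), the full
    statistic is recomputed per shuffle, and the p-value uses the +1
    continuity correction: p = (1 + #{null >= observed}) / (n_shuffles+1).

    Returns (p_value, observed, null_values).
    """
    if n_shuffles < 1:
        raise DiscmorphError("n_shuffles must be >= 1")
    M = _columns_of(X)
    labels = np.asarray(labels)
    if strata is None:
        strata = np.zeros(len(labels), dtype=int)
    strata = np.asarray(strata)
    if len(labels) != len(M) or len(strata) != len(M):
        raise DiscmorphError("labels/strata length mismatch")

    def statistic(lab):
        ref = M[lab == reference_label]
        test = M[lab == test_label]
        if len(ref) < 3 or len(test) < 1:
            return np.nan
        delta = test.mean(axis=0) - ref.mean(axis=0)
        R = np.linalg.norm(delta)
        if R == 0:
            return 0.0
        rp = pca_decompose(ref, min(len(ref) - 1, pc))
        return abs(np.dot(delta / R, rp.components[pc - 1]))

    observed = statistic(labels)
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    import warnings

    for s in np.unique(strata):
        if (strata == s).sum() < 2:
            warnings.warn(f"stratum {s!r} has fewer than 2 members; it cannot be shuffled")
    for i in range(n_shuffles):
        lab = labels.copy()
        for s in np.unique(strata):
            idx = np.nonzero(strata == s)[0]
            if len(idx) < 2:
                continue
            lab[idx] = labels[idx][rng.permutation(len(idx))]
        null[i] = statistic(lab)
    p = (1.0 + np.sum(null >= observed)) / (n_shuffles + 1.0)
    return float(p), float(observed), null
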