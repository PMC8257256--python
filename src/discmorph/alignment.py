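"""Global registration of disc images over the group of disc automorphisms.

A Mobius automorphism of the unit disc,

    g(z) = e^{i theta} (z - alpha) / (1 - conj(alpha) z),      |alpha| < 1,

is the residual freedom left after conformal mapping: a rotation theta plus
a shift alpha of the origin.  Images are registered to a common reference
by maximizing normalized (Pearson) cross-correlation over a coarse
theta x alpha grid followed by local halving refinement.  The coarse sweep
is evaluated in polar coordinates, where a disc rotation is a circular
column shift, so all rotation offsets for one alpha are scored in a single
FFT cross-correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .conformal import DiscImage
from .errors import DegenerateImageError, DiscmorphError

__all__ = [
    "MobiusParams",
    "SearchGrid",
    "AlignedEnsemble",
    "apply_mobius",
    "mobius_point",
    "mobius_inverse_point",
    "normalized_cross_correlation",
    "register_to_reference",
    "align_ensemble",
]


@dataclass(frozen=True)
class MobiusParams:
    """Parameters of a disc automorphism: rotation angle and origin shift."""

    rotation: float = 0.0
    center_shift: complex = 0j

    def __post_init__(self) -> None:
        if abs(self.center_shift) >= 1.0:
            raise DiscmorphError(f"|alpha| must be < 1, got {abs(self.center_shift):.3f}")
        object.__setattr__(self, "rotation", float(np.mod(self.rotation, 2.0 * np.pi)))

    def inverse(self) -> "MobiusParams":
        """Parameters of g^{-1}, also a disc automorphism."""
        th = -self.rotation
        al = -self.center_shift * np.exp(1j * self.rotation)
        return MobiusParams(th, al)


def mobius_point(params: MobiusParams, z: np.ndarray) -> np.ndarray:
    """g(z) = e^{i theta}(z - alpha)/(1 - conj(alpha) z)."""
    a = params.center_shift
    return np.exp(1j * params.rotation) * (z - a) / (1.0 - np.conj(a) * z)


def mobius_inverse_point(params: MobiusParams, w: np.ndarray) -> np.ndarray:
    """g^{-1}(w)."""
    a = params.center_shift
    u = np.exp(-1j * params.rotation) * w
    return (u + a) / (1.0 + np.conj(a) * u)


def _rim_padded(img: DiscImage) -> np.ndarray:
    """Image grid with invalid pixels replaced by the nearest valid value
    (cached), so bilinear sampling near the rim does not bleed in zeros."""
    from scipy.ndimage import distance_transform_edt

    cached = img.provenance.get("_rim_padded")
    if cached is not None:
        return cached
    grid = img.grid.copy()
    if (~img.valid).any():
        _, (ir, ic) = distance_transform_edt(~img.valid, return_indices=True)
        grid[~img.valid] = img.grid[ir[~img.valid], ic[~img.valid]]
    img.provenance["_rim_padded"] = grid
    return grid


def _sample_disc(img: DiscImage, w: np.ndarray) -> np.ndarray:
    """Bilinear sample of a disc image at complex disc coordinates."""
    D = img.diameter
    grid = _rim_padded(img)
    cols = (w.real + 1.0) * D / 2.0 - 0.5
    rows = (w.imag + 1.0) * D / 2.0 - 0.5
    return map_coordinates(grid, [rows.ravel(), cols.ravel()], order=1, mode="nearest").reshape(
        w.shape
    )


def apply_mobius(disc_image: DiscImage, params: MobiusParams) -> DiscImage:
    """Resample a disc image under a disc automorphism.

    The output pixel at disc coordinate z takes the bilinearly interpolated
    input intensity at g^{-1}(z); the validity mask is unchanged.
    """
    spec = disc_image.spec
    centers = spec.pixel_centers()
    src = mobius_inverse_point(params, centers)
    out = np.zeros_like(disc_image.grid)
    out[disc_image.valid] = _sample_disc(disc_image, src[disc_image.valid])
    prov = {k: v for k, v in disc_image.provenance.items() if k != "_rim_padded"}
    prov["mobius"] = (params.rotation, params.center_shift)
    return DiscImage(grid=out, valid=disc_image.valid.copy(), provenance=prov)


def normalized_cross_correlation(a: DiscImage, b: DiscImage) -> float:
    """Pearson correlation of intensities over the shared valid support."""
    if a.grid.shape != b.grid.shape:
        raise DiscmorphError("disc images have different rasters")
    sup = a.valid & b.valid
    x = a.grid[sup]
    y = b.grid[sup]
    if x.std() == 0 or y.std() == 0:
        raise DegenerateImageError("zero-variance image in cross-correlation")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass(frozen=True)
class SearchGrid:
    """Coarse-to-fine Mobius search specification.

    Coarse stage: all rotations at ``coarse_theta_step`` spacing crossed
    with alpha on a polar grid of radius step ``alpha_radius_step`` up to
    ``alpha_max`` times ``alpha_angles`` directions; then ``n_refine``
    local step-halvings of all three coordinates, scoring the true
    pixel-domain correlation and keeping the best candidate (monotone).
    """

    coarse_theta_step: float = np.deg2rad(2.0)
    alpha_max: float = 0.30
    alpha_radius_step: float = 0.05
    alpha_angles: int = 24
    n_refine: int = 4
    joint: bool = True  # sweep theta and alpha jointly at the coarse stage

    @property
    def fine_theta_step(self) -> float:
        return self.coarse_theta_step / 2**self.n_refine

    @property
    def fine_alpha_step(self) -> float:
        return self.alpha_radius_step / 2**self.n_refine


def _polar_samples(img: DiscImage, alpha: complex, n_r: int, n_phi: int) -> np.ndarray:
    """Sample ``img`` at g_{theta=0, alpha}^{-1} of a fixed polar grid."""
    r = (np.arange(n_r) + 0.5) / n_r
    phi = 2.0 * np.pi * np.arange(n_phi) / n_phi
    z = r[:, None] * np.exp(1j * phi[None, :])
    src = (z + alpha) / (1.0 + np.conj(alpha) * z)
    return _sample_disc(img, src)


def _coarse_sweep(moving: DiscImage, reference: DiscImage, grid: SearchGrid):
    n_phi = max(8, int(round(2.0 * np.pi / grid.coarse_theta_step)))
    n_r = max(8, moving.diameter // 3)
    ref = _polar_samples(reference, 0j, n_r, n_phi)
    ref = ref - ref.mean()
    ref_f = np.fft.rfft(ref, axis=1)
    denom_ref = np.sqrt((ref**2).sum())
    radii = np.arange(0.0, grid.alpha_max + 1e-9, grid.alpha_radius_step)
    alphas = [0j]
    for rr in radii[1:]:
        for aa in 2.0 * np.pi * np.arange(grid.alpha_angles) / grid.alpha_angles:
            alphas.append(rr * np.exp(1j * aa))
    best = (-np.inf, 0.0, 0j)
    for a in alphas:
        mov = _polar_samples(moving, a, n_r, n_phi)
        mov = mov - mov.mean()
        denom = np.sqrt((mov**2).sum()) * denom_ref
        if denom == 0:
            continue
        mov_f = np.fft.rfft(mov, axis=1)
        # corr[s] = sum_{r,phi} ref(r,phi) * mov(r, phi - s)
        corr = np.fft.irfft((ref_f * np.conj(mov_f)).sum(axis=0), n=n_phi)
        s = int(np.argmax(corr))
        score = corr[s] / denom
        if score > best[0]:
            theta = 2.0 * np.pi * s / n_phi
            best = (score, theta, a)
    return best


def _true_score(moving: DiscImage, reference: DiscImage, params: MobiusParams) -> float:
    centers = moving.spec.pixel_centers()
    sup = moving.valid & reference.valid
    src = mobius_inverse_point(params, centers[sup])
    x = _sample_disc(moving, src)
    y = reference.grid[sup]
    if x.std() == 0 or y.std() == 0:
        return -np.inf
    return float(np.corrcoef(x, y)[0, 1])


def register_to_reference(
    moving: DiscImage,
    reference: DiscImage,
    search: SearchGrid | None = None,
) -> tuple[MobiusParams, DiscImage, float]:
    """Find the disc automorphism maximizing correlation with the reference.

    Returns the best parameters, the resampled aligned image, and the
    attained Pearson correlation.  Deterministic for a fixed search grid.
    """
    search = search or SearchGrid()
    normalized_cross_correlation(moving, reference)  # degenerate-input check

    if search.joint:
        _, theta, alpha = _coarse_sweep(moving, reference, search)
    else:
        _, theta, _ = _coarse_sweep(
            moving,
            reference,
            SearchGrid(
                coarse_theta_step=search.coarse_theta_step,
                alpha_max=0.0,
                alpha_radius_step=search.alpha_radius_step,
                alpha_angles=search.alpha_angles,
                n_refine=search.n_refine,
            ),
        )
        best = (-np.inf, 0j)
        radii = np.arange(0.0, search.alpha_max + 1e-9, search.alpha_radius_step)
        for rr in radii:
            angs = (
                [0.0]
                if rr == 0
                else 2.0 * np.pi * np.arange(search.alpha_angles) / search.alpha_angles
            )
            for aa in angs:
                a = rr * np.exp(1j * aa)
                sc = _true_score(moving, reference, MobiusParams(theta, a))
                if sc > best[0]:
                    best = (sc, a)
        alpha = best[1]

    th_step = search.coarse_theta_step
    al_step = search.alpha_radius_step
    cur = MobiusParams(theta, alpha)
    cur_score = _true_score(moving, reference, cur)
    diag = 1.0 / np.sqrt(2.0)
    for _ in range(search.n_refine):
        th_step /= 2.0
        al_step /= 2.0
        improved = True
        while improved:
            improved = False
            for dt in (-th_step, 0.0, th_step):
                for da in (
                    0j,
                    al_step,
                    -al_step,
                    1j * al_step,
                    -1j * al_step,
                    (1 + 1j) * al_step * diag,
                    (1 - 1j) * al_step * diag,
                    (-1 + 1j) * al_step * diag,
                    (-1 - 1j) * al_step * diag,
                ):
                    if dt == 0.0 and da == 0j:
                        continue
                    a_new = cur.center_shift + da
                    if abs(a_new) >= 0.99:
                        continue
                    cand = MobiusParams(cur.rotation + dt, a_new)
                    sc = _true_score(moving, reference, cand)
                    if sc > cur_score:
                        cur, cur_score = cand, sc
                        improved = True
    aligned = apply_mobius(moving, cur)
    return cur, aligned, float(cur_score)


@dataclass
class AlignedEnsemble:
    """An ensemble of disc images registered to one reference."""

    images: list
    reference_id: str
    params: dict  # image_id -> MobiusParams
    scores: dict  # image_id -> float
    groups: object = None  # pandas.DataFrame of per-image metadata, or None
    failed: dict = field(default_factory=dict)  # image_id -> error message

    @property
    def image_ids(self) -> list:
        return [im.provenance.get("image_id") for im in self.images]


def align_ensemble(
    disc_images: list,
    metadata=None,
    reference_id: str | None = None,
    seed: int | None = None,
    search: SearchGrid | None = None,
) -> AlignedEnsemble:
    """Register every disc image of an ensemble to a single reference.

    The reference is ``reference_id`` when given, otherwise a seeded
    uniform draw over the ensemble (one reference per experiment).
    Degenerate (constant) images are reported in ``failed`` and excluded;
    the rest are aligned.  Left/right chirality must have been handled
    upstream: left images are mirrored before conformal mapping, with the
    flag kept in each image's provenance.
    """
    if not disc_images:
        raise DiscmorphError("empty ensemble")
    shapes = {im.grid.shape for im in disc_images}
    if len(shapes) > 1:
        raise DiscmorphError(f"mixed disc rasters in ensemble: {shapes}")
    ids = [im.provenance.get("image_id", f"img{i:04d}") for i, im in enumerate(disc_images)]
    if reference_id is None:
        rng = np.random.default_rng(seed)
        reference_id = ids[int(rng.integers(len(ids)))]
    if reference_id not in ids:
        raise DiscmorphError(f"reference_id {reference_id!r} not in ensemble")
    ref = disc_images[ids.index(reference_id)]

    aligned, params, scores, failed = [], {}, {}, {}
    for im, iid in zip(disc_images, ids):
        if iid == reference_id:
            out = DiscImage(im.grid.copy(), im.valid.copy(), dict(im.provenance))
            out.provenance["image_id"] = iid
            aligned.append(out)
            params[iid] = MobiusParams()
            scores[iid] = 1.0
            continue
        try:
            p, out, sc = register_to_reference(im, ref, search)
        except DegenerateImageError as exc:
            failed[iid] = str(exc)
            continue
        out.provenance["image_id"] = iid
        aligned.append(out)
        params[iid] = p
        scores[iid] = sc
    return AlignedEnsemble(
        images=aligned,
        reference_id=reference_id,
        params=params,
        scores=scores,
        groups=metadata,
        failed=failed,
    )
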