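"""Procedural generation of wing-like test images with known ground truth.

The generator emulates the anatomy the pipeline is built for: an
elliptical, anterior/posterior-asymmetric blade; five dark longitudinal
veins (L1-L5) fanning from a proximal base to the margin; two cross-veins
(anterior and posterior); low-amplitude stationary texture in the
intervein blade; a light background near intensity 212 (matching
transmitted-light wing imaging, where background reproducibly sits between
210 and 215); and a hinge region delimited by two anchor landmarks (the
humeral break and the alula notch).

Variation is controlled and fully recorded: a single latent score t moves
veins L2-L4 anteriorly and the cross-veins distally (a coherent
"dominant mode"), independent per-vein nuisance jitter provides orthogonal
noise of scale sigma_orth, and per-group offsets displace group means
along the latent mode (and optionally along a second, off-mode
deformation).  Every statistical claim downstream can therefore be checked
against generator truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt, gaussian_filter
from skimage.draw import polygon as draw_polygon

from .boundary import HingeAnchors
from .errors import DiscmorphError

__all__ = [
    "WingTemplate",
    "VariationSpec",
    "WingSample",
    "WingDataset",
    "generate_wing",
    "generate_ensemble",
    "latent_mode_pair",
    "apply_pipeline_perturbations",
]


@dataclass(frozen=True)
class WingTemplate:
    """Geometry and rendering parameters of the synthetic wing.

    Shapes live in a normalized frame: blade centered at the origin,
    proximal end at x = -1, distal tip at x = +1, anterior at negative y.
    """

    aspect: float = 0.52  # blade semi-minor axis relative to the major axis
    taper: float = 0.15  # anterior/posterior asymmetry of the blade
    base_x: float = -0.80  # proximal origin of the vein fan
    vein_phi: tuple = (-1.25, -0.55, -0.10, 0.35, 0.95)  # margin angles of L1..L5
    vein_bend: tuple = (-0.10, -0.05, 0.0, 0.05, 0.12)  # mid-control offsets
    acv_t: float = 0.45  # anterior cross-vein attachment parameter (L3-L4)
    pcv_t: float = 0.70  # posterior cross-vein attachment parameter (L4-L5)
    vein_width_px: float = 1.8
    vein_depth: float = 80.0
    blade_intensity: float = 150.0
    background: float = 212.0
    texture_sigma: float = 2.0
    texture_scale_px: float = 3.0
    anchor_phi: tuple = (3.70, 2.55)  # humeral (anterior), alula (posterior)


@dataclass(frozen=True)
class VariationSpec:
    """The variation structure of an ensemble.

    ``latent_sigma`` is the standard deviation of the per-specimen latent
    score t (standard normal by default); ``latent_gain`` converts t to a
    normalized-frame vein displacement; ``orthogonal_noise_sigma`` is the
    per-vein independent jitter scale (the orthogonal noise sigma);
    ``group_offsets`` maps group name -> (along-mode offset, off-mode
    offset), both expressed in units of ``orthogonal_noise_sigma`` so that
    the displacement-to-noise ratio sigma/R is controlled directly (an
    offset of k sigma shifts the group mean by k * sigma_orth along the
    mode, i.e. by k * sigma_orth / latent_gain latent-score units);
    ``latent_sigma_scale`` maps group name -> a factor on latent_sigma
    (displaced probe groups in controlled-distance experiments use a small
    factor so their centroid distance R is set by the offset, not by the
    sampling noise of the group's own latent scores);
    ``size_scale`` maps group name -> relative blade scale;
    ``chirality_mix`` is the probability of a left wing.
    """

    latent_sigma: float = 1.0
    latent_gain: float = 0.022
    orthogonal_noise_sigma: float = 0.001
    group_offsets: dict = field(default_factory=dict)
    latent_sigma_scale: dict = field(default_factory=dict)
    size_scale: dict = field(default_factory=dict)
    chirality_mix: float = 0.5
    seed: int = 0


@dataclass
class WingSample:
    """One rendered specimen with its complete ground truth."""

    image: np.ndarray  # (H, W) uint8
    mask: np.ndarray  # (H, W) bool
    anchors: HingeAnchors  # pixel (x, y)
    landmarks: np.ndarray  # (12, 2) pixel (x, y)
    image_id: str
    truth: dict


@dataclass
class WingDataset:
    """An ensemble of samples plus manifest and generation truth."""

    samples: list
    manifest: pd.DataFrame
    template: WingTemplate
    spec: VariationSpec
    truth: dict
    perturbations: dict = field(default_factory=dict)

    def by_group(self, name: str) -> list:
        ids = set(self.manifest.loc[self.manifest.group == name, "image_id"])
        return [s for s in self.samples if s.image_id in ids]


# --------------------------------------------------------------------------
# geometry
# --------------------------------------------------------------------------


def _margin(template: WingTemplate, phi: np.ndarray) -> np.ndarray:
    """Blade outline points at parameter phi, in the normalized frame."""
    x = np.cos(phi)
    y = template.aspect * np.sin(phi) * (1.0 - template.taper * np.cos(phi))
    return np.c_[x, y]


def _bezier(p0, p1, p2, t):
    t = np.asarray(t, dtype=float)[:, None]
    return (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2


def _vein_curves(template: WingTemplate, lat: float, off: float, nuisance: np.ndarray):
    """Control geometry of the 5 longitudinal veins and 2 cross-veins.

    ``lat`` and ``off`` are displacements already expressed in the
    normalized frame.  Returns (curves, landmarks): curves is a list of 7
    point arrays (L1..L5, acv, pcv); landmarks are the 12 homologous
    points (5 margin tips, 4 cross-vein junctions, the vein-fan base and
    two mid-vein points).
    """
    g = template
    base = np.array([g.base_x, 0.0])
    phis = np.array(g.vein_phi, dtype=float)
    bends = np.array(g.vein_bend, dtype=float)
    tt = np.linspace(0.0, 1.0, 80)
    curves = []
    tips = []
    for i in range(5):
        tip = _margin(g, np.array([phis[i]]))[0] * 0.985
        p1 = 0.5 * (base + tip) + np.array([0.0, bends[i] * g.aspect])
        dy = 0.0
        if i in (1, 2, 3):
            dy -= lat  # latent mode: anterior shift of L2-L4
        if i == 4:
            dy += off  # off-mode: posterior shift of L5
        dy_n = nuisance[i]
        p1 = p1 + np.array([0.0, dy + dy_n])
        tip = tip + np.array([0.0, (dy + dy_n) * 0.7])
        curves.append(_bezier(base, p1, tip, tt))
        tips.append(tip)
    # cross-veins: chords between neighboring veins; the latent mode also
    # slides them distally along their carrier veins
    acv_t = np.clip(g.acv_t + 1.1 * lat + nuisance[5], 0.1, 0.9)
    pcv_t = np.clip(g.pcv_t + 1.1 * lat + 0.5 * off + nuisance[6], 0.1, 0.9)
    a0 = _point_at(curves[2], acv_t)
    a1 = _point_at(curves[3], acv_t + 0.03)
    p0 = _point_at(curves[3], pcv_t)
    p1_ = _point_at(curves[4], pcv_t + 0.03)
    cvt = np.linspace(0.0, 1.0, 24)
    curves.append(a0[None] * (1 - cvt)[:, None] + a1[None] * cvt[:, None])
    curves.append(p0[None] * (1 - cvt)[:, None] + p1_[None] * cvt[:, None])
    landmarks = np.array(
        tips
        + [a0, a1, p0, p1_]
        + [base, _point_at(curves[0], 0.5), _point_at(curves[4], 0.5)]
    )
    return curves, landmarks


def _point_at(curve: np.ndarray, t: float) -> np.ndarray:
    idx = np.clip(t, 0.0, 1.0) * (len(curve) - 1)
    i0 = int(np.floor(idx))
    i1 = min(i0 + 1, len(curve) - 1)
    fr = idx - i0
    return curve[i0] * (1 - fr) + curve[i1] * fr


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------


def generate_wing(
    template: WingTemplate,
    spec: VariationSpec,
    t: float = 0.0,
    off: float = 0.0,
    nuisance: np.ndarray | None = None,
    chirality: str = "right",
    size_scale: float = 1.0,
    shape: tuple[int, int] = (480, 640),
    seed: int | None = 0,
    image_id: str = "wing0000",
) -> WingSample:
    """Render one specimen.

    ``t`` is the latent score (in units of spec.latent_sigma = 1), ``off``
    an off-mode displacement, ``nuisance`` the 7 per-vein jitters (drawn
    from N(0, sigma_orth^2) when None).  ``seed`` controls the texture and
    any nuisance draw; output is fully deterministic given the arguments.
    """
    rng = np.random.default_rng(seed)
    if nuisance is None:
        nuisance = rng.normal(0.0, spec.orthogonal_noise_sigma, size=7)
    nuisance = np.asarray(nuisance, dtype=float)
    if chirality not in ("left", "right"):
        raise DiscmorphError(f"chirality must be 'left' or 'right', got {chirality!r}")
    H, W = shape
    s = 0.44 * W * size_scale
    cx, cy = W / 2.0, H / 2.0

    lat_norm = t * spec.latent_gain
    off_norm = off * spec.latent_gain
    curves, landmarks_n = _vein_curves(template, lat_norm, off_norm, nuisance)

    phi = np.linspace(0.0, 2.0 * np.pi, 720, endpoint=False)
    outline_n = _margin(template, phi)

    def to_px(P):
        return np.c_[cx + s * P[:, 0], cy + s * P[:, 1]]

    outline = to_px(outline_n)
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw_polygon(outline[:, 1], outline[:, 0], shape=shape)
    mask[rr, cc] = True

    tex = gaussian_filter(rng.standard_normal(shape), template.texture_scale_px)
    tstd = tex.std()
    if tstd > 0:
        tex *= template.texture_sigma / tstd

    dark = np.zeros(shape)
    sigma_w = template.vein_width_px
    for curve in curves:
        cpx = to_px(curve)
        # resample at sub-pixel spacing and rasterize the curve support
        seg = np.linalg.norm(np.diff(cpx, axis=0), axis=1).sum()
        npts = max(int(seg * 2), 8)
        u = np.linspace(0.0, 1.0, npts)
        idx = u * (len(cpx) - 1)
        i0 = np.floor(idx).astype(int)
        i1 = np.minimum(i0 + 1, len(cpx) - 1)
        fr = (idx - i0)[:, None]
        pts = cpx[i0] * (1 - fr) + cpx[i1] * fr
        lo = np.maximum(pts.min(axis=0).astype(int) - 8, 0)
        hi = np.minimum(pts.max(axis=0).astype(int) + 9, [W, H])
        sub = np.ones((hi[1] - lo[1], hi[0] - lo[0]), dtype=bool)
        px = np.clip(np.round(pts[:, 0]).astype(int) - lo[0], 0, sub.shape[1] - 1)
        py = np.clip(np.round(pts[:, 1]).astype(int) - lo[1], 0, sub.shape[0] - 1)
        sub[py, px] = False
        dt = distance_transform_edt(sub)
        stamp = template.vein_depth * np.exp(-(dt**2) / (2.0 * sigma_w**2))
        region = dark[lo[1] : hi[1], lo[0] : hi[0]]
        np.maximum(region, stamp, out=region)

    img = np.full(shape, template.background)
    interior = template.blade_intensity + tex - dark
    img[mask] = interior[mask]
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    anchors_n = _margin(template, np.asarray(template.anchor_phi))
    anchors_px = to_px(anchors_n)
    landmarks_px = to_px(landmarks_n)

    if chirality == "left":
        img = np.fliplr(img).copy()
        mask = np.fliplr(mask).copy()
        anchors_px[:, 0] = W - 1 - anchors_px[:, 0]
        landmarks_px[:, 0] = W - 1 - landmarks_px[:, 0]

    anchors = HingeAnchors(
        humeral=(float(anchors_px[0, 0]), float(anchors_px[0, 1])),
        alula=(float(anchors_px[1, 0]), float(anchors_px[1, 1])),
    )
    truth = {
        "t": float(t),
        "off": float(off),
        "nuisance": nuisance.tolist(),
        "chirality": chirality,
        "size_scale": float(size_scale),
        "area": int(mask.sum()),
        "seed": seed,
    }
    return WingSample(
        image=img, mask=mask, anchors=anchors, landmarks=landmarks_px, image_id=image_id, truth=truth
    )


def latent_mode_pair(
    template: WingTemplate,
    spec: VariationSpec,
    delta: float = 1.0,
    shape: tuple[int, int] = (480, 640),
    seed: int = 0,
) -> tuple[WingSample, WingSample]:
    """Noise-free specimens at t = -delta and t = +delta.

    Pushing both through the pipeline and differencing their phenotype
    vectors yields the ground-truth latent mode direction.
    """
    zeros = np.zeros(7)
    lo = generate_wing(template, spec, t=-delta, nuisance=zeros, shape=shape, seed=seed,
                       image_id="mode_minus")
    hi = generate_wing(template, spec, t=+delta, nuisance=zeros, shape=shape, seed=seed,
                       image_id="mode_plus")
    return lo, hi


def generate_ensemble(
    template: WingTemplate,
    spec: VariationSpec,
    n_per_group: int,
    groups: list | tuple = ("wt",),
    seed: int | None = None,
    shape: tuple[int, int] = (480, 640),
    out_dir: str | Path | None = None,
) -> WingDataset:
    """Generate a multi-group ensemble with manifest and ground truth.

    Each specimen draws t ~ N(group_along, latent_sigma^2), off-mode and
    nuisance noise, a chirality and an alternating sex label.  When
    ``out_dir`` is given, images/masks (PNG), anchors.csv, landmarks.csv,
    meta.csv and truth.json are written there.
    """
    if n_per_group < 2:
        raise DiscmorphError("n_per_group must be >= 2")
    groups = list(groups)
    if len(set(groups)) != len(groups):
        raise DiscmorphError(f"duplicate group names: {groups}")
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    # offsets are specified in units of the orthogonal noise scale;
    # converting through latent_gain places the group mean k*sigma_orth
    # along the deformation mode
    sigma_units = spec.orthogonal_noise_sigma / spec.latent_gain
    samples, rows = [], []
    for g in groups:
        along, off_g = spec.group_offsets.get(g, (0.0, 0.0))
        along_t = along * sigma_units
        off_n = off_g * sigma_units
        scale_g = spec.size_scale.get(g, 1.0)
        lsig = spec.latent_sigma * spec.latent_sigma_scale.get(g, 1.0)
        for i in range(n_per_group):
            iid = f"{g}_{i:04d}"
            t = along_t + lsig * rng.standard_normal()
            nuis = rng.normal(0.0, spec.orthogonal_noise_sigma, size=7)
            chir = "left" if rng.random() < spec.chirality_mix else "right"
            sex = "F" if i % 2 == 0 else "M"
            wseed = int(rng.integers(2**31 - 1))
            sample = generate_wing(
                template,
                spec,
                t=t,
                off=off_n,
                nuisance=nuis,
                chirality=chir,
                size_scale=scale_g,
                shape=shape,
                seed=wseed,
                image_id=iid,
            )
            samples.append(sample)
            rows.append(
                dict(image_id=iid, group=g, sex=sex, chirality=chir, t=t, off=off_g,
                     size_scale=scale_g)
            )
    manifest = pd.DataFrame(rows)
    truth = {
        "groups": {g: list(spec.group_offsets.get(g, (0.0, 0.0))) for g in groups},
        "latent_sigma": spec.latent_sigma,
        "latent_gain": spec.latent_gain,
        "orthogonal_noise_sigma": spec.orthogonal_noise_sigma,
        "seed": seed,
    }
    ds = WingDataset(samples=samples, manifest=manifest, template=template, spec=spec, truth=truth)
    if out_dir is not None:
        _write_dataset(ds, Path(out_dir))
    return ds


def _write_dataset(ds: WingDataset, out: Path) -> None:
    import imageio.v3 as iio

    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    anchor_rows, lm_rows = [], []
    for s in ds.samples:
        iio.imwrite(out / "images" / f"{s.image_id}.png", s.image)
        iio.imwrite(out / "masks" / f"{s.image_id}.png", (s.mask * 255).astype(np.uint8))
        anchor_rows.append(
            dict(
                image_id=s.image_id,
                humeral_x=s.anchors.humeral[0],
                humeral_y=s.anchors.humeral[1],
                alula_x=s.anchors.alula[0],
                alula_y=s.anchors.alula[1],
            )
        )
        row = {"specimen_id": s.image_id}
        for i, (x, y) in enumerate(s.landmarks, start=1):
            row[f"lm{i}_x"] = x
            row[f"lm{i}_y"] = y
        lm_rows.append(row)
    pd.DataFrame(anchor_rows).to_csv(out / "anchors.csv", index=False)
    pd.DataFrame(lm_rows).to_csv(out / "landmarks.csv", index=False)
    ds.manifest.to_csv(out / "meta.csv", index=False)
    per_specimen = {s.image_id: s.truth for s in ds.samples}
    (out / "truth.json").write_text(
        json.dumps({"ensemble": ds.truth, "specimens": per_specimen}, indent=1)
    )


def apply_pipeline_perturbations(
    dataset: WingDataset,
    mode: str,
    magnitude: float | None = None,
    seed: int | None = 0,
) -> WingDataset:
    """Robustness perturbations of pipeline intermediates.

    ``origin_jitter`` shifts each image's conformal base point uniformly
    within +-magnitude px per axis (default 3); ``anchor_jitter`` shifts
    both hinge anchors likewise (default 3); ``boundary_jitter`` displaces
    every extracted contour point uniformly within +-magnitude px (default
    1).  Anchor jitter is applied here; origin/boundary jitter is recorded
    and applied by the pipeline when each wing is processed.  Everything
    downstream is recomputed by re-running the pipeline on the result.
    """
    defaults = {"origin_jitter": 3.0, "anchor_jitter": 3.0, "boundary_jitter": 1.0}
    if mode not in defaults:
        raise DiscmorphError(f"unknown perturbation mode {mode!r}; expected one of {sorted(defaults)}")
    if magnitude is None:
        magnitude = defaults[mode]
    rng = np.random.default_rng(seed)
    samples = dataset.samples
    if mode == "anchor_jitter" and magnitude > 0:
        new_samples = []
        for s in samples:
            d = rng.uniform(-magnitude, magnitude, size=4)
            anchors = HingeAnchors(
                humeral=(s.anchors.humeral[0] + d[0], s.anchors.humeral[1] + d[1]),
                alula=(s.anchors.alula[0] + d[2], s.anchors.alula[1] + d[3]),
            )
            new_samples.append(replace(s, anchors=anchors))
        samples = new_samples
    pert = dict(dataset.perturbations)
    pert[mode] = {"magnitude": float(magnitude), "seed": seed}
    return WingDataset(
        samples=samples,
        manifest=dataset.manifest.copy(),
        template=dataset.template,
        spec=dataset.spec,
        truth=dict(dataset.truth),
        perturbations=pert,
    )
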