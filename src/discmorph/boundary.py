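"""Boundary geometry: mask cleaning, contour extraction, hinge clipping and
curvature-adaptive polygonal approximation.

Coordinates are (x, y) = (col, row), 0-based, with pixel centers at integer
coordinates.  Contours are simple closed polylines oriented counterclockwise
(positive shoelace area in (x, y)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import LinearRing, Point, Polygon
from skimage import measure

from .errors import ContourError, MaskError

__all__ = [
    "Contour",
    "BoundaryPolygon",
    "HingeAnchors",
    "clean_mask",
    "validate_mask",
    "extract_contour",
    "contour_arclengths",
    "smooth_contour",
    "curvature_profile",
    "clip_hinge",
    "place_polygon_vertices",
    "wing_area",
]


@dataclass
class HingeAnchors:
    """Two user-supplied proximal landmarks delimiting the hinge.

    ``humeral`` and ``alula`` are (x, y) pixel coordinates; both must lie on
    or within 3 px of the contour they are used to clip.
    """

    humeral: tuple[float, float]
    alula: tuple[float, float]


@dataclass
class Contour:
    """Ordered closed boundary polyline in subpixel (x, y) coordinates."""

    points: np.ndarray  # (N, 2) float
    closed: bool = True

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ContourError("contour points must be an (N, 2) array")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def signed_area(self) -> float:
        x, y = self.points[:, 0], self.points[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def oriented_ccw(self) -> "Contour":
        if self.signed_area < 0:
            return Contour(self.points[::-1].copy(), self.closed)
        return self

    def is_simple(self) -> bool:
        try:
            return LinearRing(self.points).is_valid
        except Exception:
            return False


@dataclass
class BoundaryPolygon:
    """N-vertex polygonal approximation of a contour.

    Vertices are complex numbers x + iy; ``interior_angles`` are the angles
    alpha_j at each vertex (radians), satisfying sum(pi - alpha_j) = 2*pi.
    """

    vertices: np.ndarray  # (N,) complex
    interior_angles: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=complex)
        if self.interior_angles is None:
            self.interior_angles = interior_angles(self.vertices)
        self.interior_angles = np.asarray(self.interior_angles, dtype=float)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def is_simple(self) -> bool:
        pts = np.c_[self.vertices.real, self.vertices.imag]
        try:
            return LinearRing(pts).is_valid
        except Exception:
            return False


def interior_angles(vertices: np.ndarray) -> np.ndarray:
    """Interior angles of a CCW simple polygon from its vertex triples."""
    v = np.asarray(vertices, dtype=complex)
    prev = np.roll(v, 1)
    nxt = np.roll(v, -1)
    # turn angle at each vertex; interior angle = pi - turn for CCW polygons
    turn = np.angle((nxt - v) / (v - prev))
    return np.pi - turn


def clean_mask(mask: np.ndarray, pad: int = 5) -> tuple[np.ndarray, tuple[int, int]]:
    """Deterministic mask cleanup: largest component, hole filling, border padding.

    Returns the cleaned boolean mask and the (row, col) offset that was added
    to all coordinates (non-zero only when the foreground touched the image
    border and background padding was required).
    """
    m = np.asarray(mask).astype(bool)
    if not m.any():
        raise MaskError("mask is empty")
    labels, n = ndimage.label(m)
    if n > 1:
        sizes = ndimage.sum_labels(m, labels, index=np.arange(1, n + 1))
        m = labels == (1 + int(np.argmax(sizes)))
    m = ndimage.binary_fill_holes(m)
    offset = (0, 0)
    border = m[0, :].any() or m[-1, :].any() or m[:, 0].any() or m[:, -1].any()
    if border:
        m = np.pad(m, pad, mode="constant", constant_values=False)
        offset = (pad, pad)
    return m, offset


def validate_mask(mask: np.ndarray) -> None:
    """Raise :class:`MaskError` unless the mask satisfies its invariants."""
    m = np.asarray(mask).astype(bool)
    if not m.any():
        raise MaskError("mask is empty")
    _, n = ndimage.label(m)
    if n != 1:
        raise MaskError(f"mask has {n} connected components; expected exactly 1")
    if ndimage.binary_fill_holes(m).sum() != m.sum():
        raise MaskError("mask has interior holes")
    if m[0, :].any() or m[-1, :].any() or m[:, 0].any() or m[:, -1].any():
        raise MaskError("mask foreground touches the image border")


def extract_contour(mask: np.ndarray) -> Contour:
    """Trace the foreground/background interface of a valid binary mask.

    The sub-pixel contour is the 0.5-level set of the mask (marching
    squares), oriented counterclockwise.  Consecutive points are at most
    sqrt(2) pixels apart.
    """
    validate_mask(mask)
    m = np.asarray(mask).astype(float)
    contours = measure.find_contours(m, 0.5)
    # the outer boundary is the longest level-set curve
    rc = max(contours, key=len)
    if not np.allclose(rc[0], rc[-1]):
        raise ContourError("contour did not close")
    rc = rc[:-1]
    pts = np.c_[rc[:, 1], rc[:, 0]]  # (row, col) -> (x, y)
    return Contour(pts).oriented_ccw()


def wing_area(mask: np.ndarray) -> int:
    """Foreground pixel count of a mask."""
    return int(np.count_nonzero(np.asarray(mask)))


def contour_arclengths(points: np.ndarray) -> np.ndarray:
    """Cumulative arclength at each point of a closed polyline (s[0] = 0)."""
    seg = np.linalg.norm(np.roll(points, -1, axis=0) - points, axis=1)
    return np.concatenate([[0.0], np.cumsum(seg[:-1])])


def smooth_contour(points: np.ndarray, window: int = 5) -> np.ndarray:
    """Circular moving-average smoothing of a closed polyline."""
    if window < 1:
        return np.asarray(points, dtype=float)
    kernel = np.ones(window) / window
    out = np.empty_like(points, dtype=float)
    for d in range(2):
        padded = np.concatenate([points[-window:, d], points[:, d], points[:window, d]])
        out[:, d] = np.convolve(padded, kernel, mode="same")[window:-window]
    return out


def curvature_profile(contour: Contour, window: int = 7, smoothing: int = 5) -> np.ndarray:
    """Per-point curvature magnitude (1/px) by circumscribed-circle fit.

    The contour is smoothed with a fixed 5-point moving average, then the
    Menger curvature of the triple (i - window, i, i + window) is computed
    for every point.
    """
    if window < 2:
        raise ContourError("curvature window must be >= 2")
    pts = np.asarray(contour.points, dtype=float)
    if len(pts) < 3 * window:
        raise ContourError("contour too short for the requested curvature window")
    p = smooth_contour(pts, smoothing)
    a = np.roll(p, window, axis=0)
    b = p
    c = np.roll(p, -window, axis=0)
    ab = b - a
    bc = c - b
    ca = a - c
    # 2*signed triangle area
    cross = ab[:, 0] * bc[:, 1] - ab[:, 1] * bc[:, 0]
    la = np.linalg.norm(ab, axis=1)
    lb = np.linalg.norm(bc, axis=1)
    lc = np.linalg.norm(ca, axis=1)
    denom = la * lb * lc
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(denom > 0, 2.0 * np.abs(cross) / denom, 0.0)
    return kappa


def _interp_on_contour(points: np.ndarray, s_query: np.ndarray) -> np.ndarray:
    """Linear interpolation of positions along a closed polyline at arclengths."""
    s = contour_arclengths(points)
    total = s[-1] + np.linalg.norm(points[0] - points[-1])
    sq = np.mod(s_query, total)
    idx = np.searchsorted(s, sq, side="right") - 1
    idx = np.clip(idx, 0, len(points) - 1)
    nxt = (idx + 1) % len(points)
    s_next = np.where(nxt == 0, total, s[nxt] if len(s) > 1 else total)
    seg_len = np.maximum(s_next - s[idx], 1e-12)
    t = ((sq - s[idx]) / seg_len)[:, None]
    return points[idx] * (1 - t) + points[nxt] * t


def clip_hinge(contour: Contour, anchors: HingeAnchors, keep: str = "long",
               max_anchor_dist: float = 3.0) -> Contour:
    """Replace the hinge arc between the two anchors by a straight segment.

    The contour points nearest to the humeral and alula anchors are found;
    of the two arcs joining them the kept one is the longer by default
    (``keep='long'``) -- the hinge side is the shorter arc for wing-like
    shapes -- and the other is replaced by the chord, resampled at <= 2 px
    spacing.  The result is re-oriented counterclockwise.
    """
    pts = contour.points
    for name, p in (("humeral", anchors.humeral), ("alula", anchors.alula)):
        d = np.linalg.norm(pts - np.asarray(p, dtype=float), axis=1).min()
        if d > max_anchor_dist:
            raise ContourError(
                f"{name} anchor is {d:.1f} px from the contour (> {max_anchor_dist:g} px)"
            )
    ih = int(np.argmin(np.linalg.norm(pts - np.asarray(anchors.humeral, float), axis=1)))
    ia = int(np.argmin(np.linalg.norm(pts - np.asarray(anchors.alula, float), axis=1)))
    if ih == ia:
        raise ContourError("anchors collapse onto the same contour point")

    def arc(i, j):
        if i <= j:
            return pts[i : j + 1]
        return np.concatenate([pts[i:], pts[: j + 1]])

    arc1 = arc(ih, ia)
    arc2 = arc(ia, ih)
    len1 = contour_arclengths(arc1)[-1]
    len2 = contour_arclengths(arc2)[-1]
    if keep == "long":
        kept = arc1 if len1 >= len2 else arc2
    elif keep == "arc1":
        kept = arc1
    elif keep == "arc2":
        kept = arc2
    else:
        raise ContourError(f"unknown keep mode {keep!r}")
    p_start, p_end = kept[-1], kept[0]
    chord = np.linalg.norm(p_end - p_start)
    n_seg = max(int(np.ceil(chord / 2.0)), 1)
    t = np.linspace(0.0, 1.0, n_seg + 1)[1:-1, None]
    chord_pts = p_start[None, :] * (1 - t) + p_end[None, :] * t
    new_pts = np.concatenate([kept, chord_pts]) if len(chord_pts) else kept
    out = Contour(new_pts).oriented_ccw()
    if not out.is_simple():
        raise ContourError("hinge replacement produced a self-intersecting contour")
    return out


def place_polygon_vertices(
    contour: Contour,
    curvature: np.ndarray,
    n_vertices: int = 100,
) -> BoundaryPolygon:
    """Place polygon vertices equidistantly along the cumulative curvature weight.

    The weight is w(s) = eps + |kappa(s)| with eps = 0.1 * mean|kappa|, so
    high-curvature regions receive proportionally denser vertices while
    straight runs are still sampled.  With constant curvature this reduces
    exactly to equal-arclength placement.
    """
    pts = contour.points
    if n_vertices < 4:
        raise ContourError("a polygon needs at least 4 vertices")
    if n_vertices > len(pts):
        raise ContourError(
            f"n_vertices={n_vertices} exceeds the contour point count {len(pts)}"
        )
    kappa = np.abs(np.asarray(curvature, dtype=float))
    if len(kappa) != len(pts):
        raise ContourError("curvature profile is not aligned with the contour")
    eps = 0.1 * float(kappa.mean()) if kappa.mean() > 0 else 1.0
    w = eps + kappa
    seg = np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)
    # trapezoid weight integral per segment (closed curve)
    w_next = np.roll(w, -1)
    seg_w = 0.5 * (w + w_next) * seg
    cumw = np.concatenate([[0.0], np.cumsum(seg_w)])  # length N+1, cumw[-1] = total
    total = cumw[-1]
    levels = total * np.arange(n_vertices) / n_vertices
    idx = np.searchsorted(cumw, levels, side="right") - 1
    idx = np.clip(idx, 0, len(pts) - 1)
    frac = (levels - cumw[idx]) / np.maximum(seg_w[idx], 1e-12)
    nxt = (idx + 1) % len(pts)
    verts = pts[idx] * (1 - frac[:, None]) + pts[nxt] * frac[:, None]
    # drop accidental duplicates from coincident contour points
    keep = np.linalg.norm(verts - np.roll(verts, 1, axis=0), axis=1) > 1e-9
    verts = verts[keep]
    poly = BoundaryPolygon(verts[:, 0] + 1j * verts[:, 1])
    if not poly.is_simple():
        raise ContourError("polygonal approximation is self-intersecting")
    return poly


def interior_base_point(polygon: BoundaryPolygon) -> complex:
    """Default conformal base point: the vertex centroid, projected inside
    the polygon if the centroid happens to fall outside."""
    c = polygon.vertices.mean()
    shp = Polygon(np.c_[polygon.vertices.real, polygon.vertices.imag])
    if shp.contains(Point(c.real, c.imag)):
        return c
    rp = shp.representative_point()
    return complex(rp.x, rp.y)
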