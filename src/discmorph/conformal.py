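"""Conformal (Riemann) mapping of polygon interiors onto the unit disc.

The map is represented in Schwarz-Christoffel form.  For prevertices
z_1..z_n on the unit circle and interior angles alpha_1..alpha_n, the map
from the disc onto the polygon interior is

    f(w) = A + C * integral_0^w  prod_j (1 - omega/z_j)^(alpha_j/pi - 1) d omega,

with A = f(0) the image of the disc origin (the interior base point) and C
a complex scale constant.  The prevertex *parameter problem* is solved
numerically: prevertex gaps are parameterized by unconstrained logits and
the overdetermined-but-consistent system of all side-length log-ratios
plus the base-point condition is solved by Levenberg-Marquardt (a square
n-3 subsystem admits numerically spurious roots).  Integrals with a prevertex
endpoint use Gauss-Jacobi quadrature with the matching exponent; all paths
obey a half-distance rule relative to the nearest singularity, subdividing
geometrically (compound quadrature).

The "forward" direction of the public API maps the polygon interior onto
the disc (the inverse of f), evaluated by ODE continuation from the base
point followed by Newton polishing.

The pixel raster on the disc is fixed by :class:`DiscMaskSpec`: a D x D
grid whose pixel centers sit at half-integer offsets from the grid center;
a pixel is part of the common domain iff its center lies strictly inside
radius D/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import map_coordinates
from scipy.spatial import cKDTree
from scipy.special import roots_jacobi
from shapely.geometry import Point, Polygon as ShapelyPolygon

from .boundary import BoundaryPolygon, interior_base_point
from .errors import ConformalError, CrowdingError

__all__ = [
    "DiscMaskSpec",
    "DiscImage",
    "RiemannMap",
    "disc_pixel_mask",
    "solve_riemann_map",
    "pushforward_image",
    "area_distortion_field",
]


# --------------------------------------------------------------------------
# common disc raster
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DiscMaskSpec:
    """The shared disc pixel domain: diameter in pixels, half-integer centers."""

    diameter: int = 200

    def __post_init__(self) -> None:
        if self.diameter % 2 != 0 or self.diameter < 2:
            raise ConformalError("disc diameter must be even and >= 2")

    def pixel_centers(self) -> np.ndarray:
        """Complex coordinates of all pixel centers in disc units (|w| <= ~1)."""
        D = self.diameter
        idx = np.arange(D)
        u = (idx + 0.5 - D / 2) * (2.0 / D)  # column -> Re
        U, V = np.meshgrid(u, u)  # V from rows -> Im
        return U + 1j * V


def disc_pixel_mask(spec: DiscMaskSpec | int) -> np.ndarray:
    """Boolean D x D raster of pixels whose centers lie inside the disc.

    Pixel (i, j) is valid iff its center (i + 0.5 - D/2, j + 0.5 - D/2) has
    Euclidean distance < D/2 from the grid center.  For even D no center can
    lie exactly on the circle, so the strict comparison is unambiguous.
    """
    if isinstance(spec, int):
        spec = DiscMaskSpec(spec)
    D = spec.diameter
    idx = np.arange(D)
    x = idx + 0.5 - D / 2
    X, Y = np.meshgrid(x, x)
    return X * X + Y * Y < (D / 2) ** 2


@dataclass
class DiscImage:
    """Intensity raster on the common disc domain."""

    grid: np.ndarray  # (D, D) float
    valid: np.ndarray  # (D, D) bool
    provenance: dict = field(default_factory=dict)

    @property
    def diameter(self) -> int:
        return self.grid.shape[0]

    @property
    def spec(self) -> DiscMaskSpec:
        return DiscMaskSpec(self.diameter)

    def values(self) -> np.ndarray:
        """Intensities at valid pixels, row-major order."""
        return self.grid[self.valid]


# --------------------------------------------------------------------------
# Schwarz-Christoffel machinery
# --------------------------------------------------------------------------


class _SCKernel:
    """Quadrature engine for a fixed set of exponents beta_j.

    Rules are per-exponent Gauss-Jacobi; prevertex positions are passed per
    call so the same kernel serves every iterate of the parameter problem.
    """

    def __init__(self, beta: np.ndarray, nq: int):
        self.beta = np.asarray(beta, dtype=float)
        self.nq = nq
        n = len(self.beta)
        xg, wg = roots_jacobi(nq, 0.0, 0.0)
        self._gl = (xg, wg)
        # per-exponent Gauss-Jacobi nodes as fractions of [0, 1] from the
        # singular endpoint, with their weights
        self._tau = np.empty((n, nq))
        self._wts = np.empty((n, nq))
        for k, b in enumerate(self.beta):
            if abs(b) < 1e-13:
                x, w = xg, wg
            else:
                x, w = roots_jacobi(nq, 0.0, b)
            self._tau[k] = (1.0 + x) / 2.0
            self._wts[k] = w

    # -- integrand -------------------------------------------------------

    def integrand_log(self, w: np.ndarray, z: np.ndarray) -> np.ndarray:
        """log of prod_j (1 - w/z_j)^beta_j, summed over j (principal logs).

        Evaluated in real arithmetic (log of the squared modulus plus
        arctan2 of the argument), which is several times faster than the
        complex log and bit-identical for principal branches.
        """
        with np.errstate(divide="ignore", invalid="ignore"):
            M = 1.0 - w[..., None] / z
            re, im = M.real, M.imag
            s_re = 0.5 * (np.log(re * re + im * im) * self.beta).sum(axis=-1)
            s_im = (np.arctan2(im, re) * self.beta).sum(axis=-1)
            return s_re + 1j * s_im

    def deriv(self, w: np.ndarray, z: np.ndarray, C: complex = 1.0) -> np.ndarray:
        """C * prod_j (1 - w/z_j)^beta_j  (the derivative f'(w) when C is the
        map's scale constant)."""
        w = np.asarray(w, dtype=complex)
        out = np.empty(w.shape, dtype=complex)
        flat = w.reshape(-1)
        # chunk to bound the (points x n) temporary
        step = max(1, 2_000_000 // max(len(z), 1))
        for i in range(0, len(flat), step):
            out.reshape(-1)[i : i + step] = np.exp(self.integrand_log(flat[i : i + step], z))
        return C * out

    # -- compound quadrature --------------------------------------------

    def integrate(self, paths, z: np.ndarray) -> np.ndarray:
        """Integrate the SC integrand along each (a, b, s) straight path.

        ``paths`` is a sequence of (start, end, singular_index) where
        ``singular_index`` is the prevertex index when start == z_s, else -1.
        Each path is split into pieces obeying a half-distance rule relative
        to the nearest other singularity (geometric subdivision toward the
        far end); all pieces of all paths are then evaluated in one batched
        quadrature call.
        """
        paths = list(paths)
        npath = len(paths)
        if npath == 0:
            return np.zeros(0, dtype=complex)
        a0 = np.array([p[0] for p in paths], dtype=complex)
        b0 = np.array([p[1] for p in paths], dtype=complex)
        s0 = np.array([p[2] for p in paths], dtype=np.int64)

        piece_a, piece_b, piece_s, piece_owner = [], [], [], []
        cur = a0
        owner = np.arange(npath)
        sing = s0
        target = b0
        for round_no in range(48):
            L = np.abs(target - cur)
            alive = L > 1e-15
            if not alive.any():
                break
            cur, target, owner, sing = cur[alive], target[alive], owner[alive], sing[alive]
            L = L[alive]
            dmat = np.abs(cur[:, None] - z[None, :])
            excl = sing >= 0
            if excl.any():
                dmat[np.nonzero(excl)[0], sing[excl]] = np.inf
            d = dmat.min(axis=1)
            h = np.where(d > 0, np.minimum(1.0, 0.5 * d / L), 1.0)
            nxt = np.where(h >= 1.0, target, cur + (target - cur) * h)
            piece_a.append(cur)
            piece_b.append(nxt)
            piece_s.append(sing)
            piece_owner.append(owner)
            done = h >= 1.0
            cur, target, owner = nxt[~done], target[~done], owner[~done]
            sing = np.full(len(owner), -1, dtype=np.int64)

        if not piece_a:
            return np.zeros(npath, dtype=complex)
        A = np.concatenate(piece_a)
        B = np.concatenate(piece_b)
        S_idx = np.concatenate(piece_s)
        owners = np.concatenate(piece_owner)
        m = len(A)
        nq = self.nq
        gj = S_idx >= 0
        TAU = np.empty((m, nq))
        WTS = np.empty((m, nq))
        pref = np.empty(m, dtype=complex)
        if gj.any():
            ks = S_idx[gj]
            TAU[gj] = self._tau[ks]
            WTS[gj] = self._wts[ks]
            bt = self.beta[ks]
            with np.errstate(divide="ignore", invalid="ignore"):
                c = -(B[gj] - A[gj]) / z[ks]
                pref[gj] = (B[gj] - A[gj]) * np.exp(bt * np.log(c)) * 0.5 ** (bt + 1.0)
        if (~gj).any():
            x, wts = self._gl
            TAU[~gj] = (1.0 + x) / 2.0
            WTS[~gj] = wts
            pref[~gj] = (B[~gj] - A[~gj]) / 2.0
        W = A[:, None] + (B - A)[:, None] * TAU
        S = self.integrand_log(W.reshape(-1), z).reshape(m, nq)
        if gj.any():
            idx = np.nonzero(gj)[0]
            zs = z[S_idx[idx]]
            with np.errstate(divide="ignore", invalid="ignore"):
                S[idx] -= self.beta[S_idx[idx]][:, None] * np.log(1.0 - W[idx] / zs[:, None])
        vals = (np.exp(S) * WTS).sum(axis=1) * pref
        out = np.zeros(npath, dtype=complex)
        np.add.at(out, owners, vals)
        return out


def _softmax_gaps(y: np.ndarray) -> np.ndarray:
    """Map n-1 unconstrained logits to n positive gaps summing to 2*pi."""
    logits = np.concatenate([y, [0.0]])
    logits = logits - logits.max()
    e = np.exp(logits)
    return 2.0 * np.pi * e / e.sum()


def _unnormalized_vertices(kernel: _SCKernel, z: np.ndarray) -> np.ndarray:
    """f-tilde values at the prevertices (f-tilde(0) = 0)."""
    n = len(z)
    paths = [(z[0], 0.0 + 0.0j, 0)]
    mids = (z + np.roll(z, -1)) / 2.0
    for k in range(n):
        paths.append((z[k], mids[k], k))
        paths.append((z[(k + 1) % n], mids[k], (k + 1) % n))
    vals = kernel.integrate(paths, z)
    v0 = -vals[0]
    sides = vals[1 :: 2][:n] - vals[2 :: 2][:n]
    vt = np.empty(n, dtype=complex)
    vt[0] = v0
    vt[1:] = v0 + np.cumsum(sides[:-1])
    return vt


class RiemannMap:
    """A solved conformal map between a polygon interior and the unit disc.

    ``inverse`` evaluates disc -> polygon (the SC integral); ``forward``
    evaluates polygon -> disc by inverting it.  The rotational gauge is
    fixed so that the derivative of ``forward`` at the base point is real
    and positive, i.e. the scale constant C is a positive real.
    """

    def __init__(
        self,
        prevertices: np.ndarray,
        interior_angles: np.ndarray,
        scale_constant: complex,
        base_point: complex,
        vertices: np.ndarray,
        nq: int = 14,
    ):
        self.prevertices = np.asarray(prevertices, dtype=complex)
        self.interior_angles = np.asarray(interior_angles, dtype=float)
        self.scale_constant = complex(scale_constant)
        self.base_point = complex(base_point)
        self.vertices = np.asarray(vertices, dtype=complex)
        self.beta = self.interior_angles / np.pi - 1.0
        self._kernel = _SCKernel(self.beta, nq)
        self._vtilde = _unnormalized_vertices(self._kernel, self.prevertices)
        self._polar = None

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "prevertices_re": self.prevertices.real.tolist(),
            "prevertices_im": self.prevertices.imag.tolist(),
            "interior_angles": self.interior_angles.tolist(),
            "scale_constant": [self.scale_constant.real, self.scale_constant.imag],
            "base_point": [self.base_point.real, self.base_point.imag],
            "vertices_re": self.vertices.real.tolist(),
            "vertices_im": self.vertices.imag.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RiemannMap":
        return cls(
            np.asarray(d["prevertices_re"]) + 1j * np.asarray(d["prevertices_im"]),
            np.asarray(d["interior_angles"]),
            complex(*d["scale_constant"]),
            complex(*d["base_point"]),
            np.asarray(d["vertices_re"]) + 1j * np.asarray(d["vertices_im"]),
        )

    # -- disc -> polygon -------------------------------------------------

    def inverse(self, w) -> np.ndarray | complex:
        """Evaluate the map disc -> polygon interior at points w (|w| <= 1)."""
        w_arr = np.atleast_1d(np.asarray(w, dtype=complex))
        z = self.prevertices
        paths = []
        anchors = np.empty(len(w_arr), dtype=complex)
        for i, wi in enumerate(w_arr):
            k = int(np.argmin(np.abs(z - wi)))
            if abs(z[k] - wi) < abs(wi):
                paths.append((z[k], wi, k))
                anchors[i] = self._vtilde[k]
            else:
                paths.append((0.0 + 0.0j, wi, -1))
                anchors[i] = 0.0
        vals = self._kernel.integrate(paths, z)
        out = self.base_point + self.scale_constant * (anchors + vals)
        return out if np.ndim(w) else complex(out[0])

    def inverse_deriv(self, w) -> np.ndarray | complex:
        """d(inverse)/dw = C * prod_j (1 - w/z_j)^(beta_j)."""
        w_arr = np.asarray(w, dtype=complex)
        out = self._kernel.deriv(np.atleast_1d(w_arr), self.prevertices, self.scale_constant)
        return out if np.ndim(w) else complex(out[0])

    # -- polygon -> disc -------------------------------------------------

    def forward(self, zpts, tol: float = 1e-12, max_newton: int = 20) -> np.ndarray | complex:
        """Evaluate polygon -> disc by ODE continuation plus Newton polish."""
        z_arr = np.atleast_1d(np.asarray(zpts, dtype=complex))
        scale = max(np.abs(self.vertices - self.base_point).max(), 1e-12)
        w = self._ode_init(z_arr)
        target_tol = tol * scale
        f = self.inverse(w)
        for _ in range(max_newton):
            err = f - z_arr
            if np.abs(err).max() < target_tol:
                break
            fp = self._kernel.deriv(w, self.prevertices, self.scale_constant)
            step = err / fp
            w_new = w - step
            r = np.abs(w_new)
            bad = r >= 1.0
            if bad.any():
                w_new[bad] = w_new[bad] / r[bad] * (1.0 - 1e-14)
            f_new = self.inverse(w_new)
            worse = np.abs(f_new - z_arr) > np.abs(err)
            for _ in range(6):
                if not worse.any():
                    break
                w_new[worse] = (w[worse] + w_new[worse]) / 2.0
                f_new[worse] = self.inverse(w_new[worse])
                worse = worse & (np.abs(f_new - z_arr) > np.abs(err))
            w, f = w_new, f_new
        return w if np.ndim(zpts) else complex(w[0])

    def forward_deriv(self, zpts) -> np.ndarray | complex:
        w = self.forward(zpts)
        return 1.0 / self.inverse_deriv(w)

    def _ode_init(self, z_arr: np.ndarray, n_steps: int = 32) -> np.ndarray:
        """Integrate dw/ds = (z - A) / f'(w) from w=0 along straight rays."""
        delta = z_arr - self.base_point
        w = np.zeros(len(z_arr), dtype=complex)

        def rhs(wc):
            fp = self._kernel.deriv(wc, self.prevertices, self.scale_constant)
            return delta / fp

        h = 1.0 / n_steps
        for _ in range(n_steps):
            k1 = rhs(w)
            k2 = rhs(self._clip(w + 0.5 * h * k1))
            k3 = rhs(self._clip(w + 0.5 * h * k2))
            k4 = rhs(self._clip(w + h * k3))
            w = self._clip(w + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4))
        return w

    @staticmethod
    def _clip(w: np.ndarray, rmax: float = 1.0 - 1e-12) -> np.ndarray:
        r = np.abs(w)
        bad = r > rmax
        if bad.any():
            w = w.copy()
            w[bad] = w[bad] / r[bad] * rmax
        return w

    # -- fast bulk evaluation (polar grid cache) -------------------------

    def _polar_cache(self, n_r: int = 96, n_theta: int = 256):
        if self._polar is not None:
            return self._polar
        u = np.linspace(0.0, 1.0, n_r)
        r = np.sin(0.5 * np.pi * u)
        r[-1] = 1.0 - 1e-9
        theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
        # cumulative radial integration of f' with 2-point Gauss per interval
        xg, wg = roots_jacobi(2, 0.0, 0.0)
        rmid = r[:-1, None] + (r[1:, None] - r[:-1, None]) * (1.0 + xg) / 2.0  # (n_r-1, ng)
        dr = (r[1:] - r[:-1])[:, None] / 2.0
        e = np.exp(1j * theta)
        F = np.empty((n_r, n_theta), dtype=complex)
        F[0] = self.base_point
        W = rmid[:, :, None] * e[None, None, :]  # (n_r-1, ng, n_theta)
        fp = self._kernel.deriv(W.reshape(-1), self.prevertices, self.scale_constant)
        fp = fp.reshape(n_r - 1, len(xg), n_theta)
        seg = (dr[:, :, None] * wg[None, :, None] * fp).sum(axis=1) * e[None, :]
        F[1:] = self.base_point + np.cumsum(seg, axis=0)
        # periodic padding in theta for interpolation
        Fp = np.concatenate([F, F[:, :1]], axis=1)
        th = np.concatenate([theta, [2.0 * np.pi]])
        interp_re = RegularGridInterpolator((u, th), Fp.real, bounds_error=False, fill_value=None)
        interp_im = RegularGridInterpolator((u, th), Fp.imag, bounds_error=False, fill_value=None)
        tree = cKDTree(np.c_[F.real.ravel(), F.imag.ravel()])
        grid_w = (r[:, None] * e[None, :]).ravel()
        grid_f = F.ravel()
        self._polar = (interp_re, interp_im, tree, grid_w, grid_f)
        return self._polar

    def inverse_fast(self, w) -> np.ndarray:
        """Approximate disc -> polygon via the polar-grid cache plus one
        derivative-based correction; adequate for pixel resampling."""
        interp_re, interp_im, _, _, _ = self._polar_cache()
        w_arr = np.atleast_1d(np.asarray(w, dtype=complex))
        r = np.clip(np.abs(w_arr), 0.0, 1.0 - 1e-12)
        u = 2.0 / np.pi * np.arcsin(r)
        th = np.mod(np.angle(w_arr), 2.0 * np.pi)
        pts = np.c_[u, th]
        return interp_re(pts) + 1j * interp_im(pts)

    def forward_fast(self, zpts, n_iter: int = 3) -> np.ndarray:
        """Approximate polygon -> disc for bulk pixels.

        Nearest grid sample initializes w; a few Newton steps with the
        running value of f updated by Simpson integration of f' along each
        Newton segment refine it to sub-disc-pixel accuracy.
        """
        _, _, tree, grid_w, grid_f = self._polar_cache()
        z_arr = np.atleast_1d(np.asarray(zpts, dtype=complex))
        _, idx = tree.query(np.c_[z_arr.real, z_arr.imag], workers=-1)
        w = grid_w[idx].copy()
        F = grid_f[idx].copy()
        # tolerance in source pixels; refine only unconverged points
        tol = 0.05
        active = np.arange(len(z_arr))
        for _ in range(n_iter):
            wa, Fa, za = w[active], F[active], z_arr[active]
            fp = self._kernel.deriv(wa, self.prevertices, self.scale_constant)
            w_new = self._clip(wa - (Fa - za) / fp)
            mid = (wa + w_new) / 2.0
            fpm = self._kernel.deriv(mid, self.prevertices, self.scale_constant)
            fpn = self._kernel.deriv(w_new, self.prevertices, self.scale_constant)
            F_new = Fa + (w_new - wa) * (fp + 4.0 * fpm + fpn) / 6.0
            w[active], F[active] = w_new, F_new
            still = np.abs(F_new - za) > tol
            active = active[still]
            if len(active) == 0:
                break
        return w


# --------------------------------------------------------------------------
# parameter problem
# --------------------------------------------------------------------------


def _polygon_checks(polygon: BoundaryPolygon, base_point: complex) -> None:
    if not polygon.is_simple():
        raise ConformalError("polygon is not simple (self-intersecting)")
    angle_sum = np.sum(np.pi - polygon.interior_angles)
    if abs(angle_sum - 2 * np.pi) > 1e-6:
        raise ConformalError(
            f"interior angles violate the closed-polygon sum: sum(pi - alpha) = {angle_sum:.8f}"
        )
    shp = ShapelyPolygon(np.c_[polygon.vertices.real, polygon.vertices.imag])
    if not shp.contains(Point(base_point.real, base_point.imag)):
        raise ConformalError("base point is not strictly interior to the polygon")


def solve_riemann_map(
    polygon: BoundaryPolygon,
    base_point: complex | None = None,
    nq_solve: int = 10,
    nq_final: int = 14,
    tol: float = 1e-12,
) -> RiemannMap:
    """Solve the SC parameter problem for a simple polygon.

    Unknowns are n-1 prevertex-gap logits; the square residual system
    consists of n-3 side-length log-ratios and the two real components of
    the base-point condition f(0) = base_point.  The rotational gauge is
    fixed afterwards by making the scale constant real positive.
    """
    verts = polygon.vertices
    n = len(verts)
    if n < 3:
        raise ConformalError("polygon must have at least 3 vertices")
    if base_point is None:
        base_point = interior_base_point(polygon)
    base_point = complex(base_point)
    _polygon_checks(polygon, base_point)

    beta = polygon.interior_angles / np.pi - 1.0
    kernel = _SCKernel(beta, nq_solve)
    side_len = np.abs(np.roll(verts, -1) - verts)
    scale = np.abs(verts - base_point).max()
    target_logratio = np.log(side_len[1:] / side_len[0])

    # All n-1 side-length log-ratios plus the two real components of the
    # base-point condition: an overdetermined but consistent system in the
    # n-1 gap logits.  (Constraining only n-3 ratios makes the system
    # square but admits numerically spurious roots in which the two
    # unconstrained sides collapse; the full system does not.)
    def residual(y: np.ndarray) -> np.ndarray:
        gaps = _softmax_gaps(y)
        if gaps.min() < 1e-11:
            # degenerate iterate: steer the solver away without evaluating
            return np.full(n + 1, 1e3)
        theta = np.cumsum(gaps)
        z = np.exp(1j * theta)
        vt = _unnormalized_vertices(kernel, z)
        sides = np.roll(vt, -1) - vt
        C = (verts[1] - verts[0]) / (vt[1] - vt[0])
        A = verts[0] - C * vt[0]
        with np.errstate(divide="ignore", invalid="ignore"):
            logratio = np.log(np.abs(sides[1:]) / abs(sides[0]))
        center = (A - base_point) / scale
        return np.concatenate([logratio - target_logratio, [center.real, center.imag]])

    # gap logits proportional to log side lengths (reduces to equal spacing
    # for regular polygons); equal spacing is the fallback
    inits = [
        np.log(np.maximum(side_len[:-1], 1e-12) / max(side_len[-1], 1e-12)),
        np.zeros(n - 1),
    ]
    sol = None
    res_norm = np.inf
    for y0 in inits:
        cand = optimize.least_squares(
            residual, y0, method="lm", xtol=tol, ftol=tol, gtol=1e-14, max_nfev=80 * n
        )
        cand_norm = np.abs(cand.fun).max()
        if cand_norm < res_norm:
            sol, res_norm = cand, cand_norm
        if res_norm < 1e-7:
            break
    if res_norm > 1e-6:
        raise ConformalError(
            f"SC parameter problem did not converge: max residual {res_norm:.2e}"
        )

    gaps = _softmax_gaps(sol.x)
    if gaps.min() < 1e-8:
        raise CrowdingError(
            f"prevertex crowding: minimum gap {gaps.min():.2e} rad is below 1e-8"
        )
    theta = np.cumsum(gaps)
    z = np.exp(1j * theta)

    kernel_f = _SCKernel(beta, nq_final)
    vt = _unnormalized_vertices(kernel_f, z)
    C = (verts[1] - verts[0]) / (vt[1] - vt[0])
    # rotational gauge: rotate the disc so that C becomes |C| (then the
    # derivative of polygon->disc at the base point is real positive)
    phi = np.angle(C)
    z = z * np.exp(1j * phi)
    C = C * np.exp(-1j * phi)
    # keep arguments ascending in [0, 2*pi); rolling the cyclic order
    # preserves the prevertex/vertex correspondence
    args = np.mod(np.angle(z), 2.0 * np.pi)
    shift = int(np.argmin(args))
    z = np.roll(z, -shift)
    beta_r = np.roll(beta, -shift)
    verts_r = np.roll(verts, -shift)
    angles_r = np.roll(polygon.interior_angles, -shift)

    return RiemannMap(z, angles_r, C, base_point, verts_r, nq=nq_final)


# --------------------------------------------------------------------------
# rasterization onto the disc
# --------------------------------------------------------------------------


def pushforward_image(
    image: np.ndarray,
    mask: np.ndarray,
    rmap: RiemannMap,
    spec: DiscMaskSpec | int = DiscMaskSpec(),
    provenance: dict | None = None,
) -> DiscImage:
    """Rasterize a source image onto the common disc domain.

    Every foreground source pixel is pushed through the forward map and
    binned into the disc raster; each valid disc pixel receiving at least
    one source pixel takes the arithmetic mean of their intensities.  Valid
    pixels left empty (one-to-many regions near the disc center) are filled
    by bilinear sampling of the source at the inverse image of the pixel
    center.
    """
    if isinstance(spec, int):
        spec = DiscMaskSpec(spec)
    D = spec.diameter
    valid = disc_pixel_mask(spec)
    img = np.asarray(image, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if img.shape != m.shape:
        raise ConformalError("image and mask shapes differ")
    rows, cols = np.nonzero(m)
    zsrc = cols.astype(float) + 1j * rows.astype(float)
    w = rmap.forward_fast(zsrc)
    jj = np.clip(((w.real + 1.0) * D / 2).astype(int), 0, D - 1)
    ii = np.clip(((w.imag + 1.0) * D / 2).astype(int), 0, D - 1)
    acc = np.zeros((D, D))
    cnt = np.zeros((D, D))
    np.add.at(acc, (ii, jj), img[rows, cols])
    np.add.at(cnt, (ii, jj), 1.0)
    grid = np.zeros((D, D))
    filled = cnt > 0
    grid[filled] = acc[filled] / cnt[filled]
    # fill valid-but-empty pixels by inverse bilinear sampling
    empty = valid & ~filled
    if empty.any():
        centers = spec.pixel_centers()[empty]
        if empty.sum() <= 4000:
            zc = np.asarray(rmap.inverse(centers))
        else:
            zc = rmap.inverse_fast(centers)
        samp = map_coordinates(img, [zc.imag, zc.real], order=1, mode="nearest")
        grid[empty] = samp
    grid[~valid] = 0.0
    return DiscImage(grid=grid, valid=valid, provenance=dict(provenance or {}))


def area_distortion_field(rmap: RiemannMap, spec: DiscMaskSpec | int = DiscMaskSpec()) -> np.ndarray:
    """|d(inverse)/dw|^2 at valid disc pixel centers: local source area per
    unit disc area.  Returned as a (D, D) array, NaN outside the disc."""
    if isinstance(spec, int):
        spec = DiscMaskSpec(spec)
    valid = disc_pixel_mask(spec)
    centers = spec.pixel_centers()
    field = np.full(valid.shape, np.nan)
    d = rmap.inverse_deriv(centers[valid])
    field[valid] = np.abs(d) ** 2
    return field
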