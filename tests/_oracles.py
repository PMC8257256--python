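"""Independent numerical oracles used only by the test suite.

The centerpiece is a finite-difference Riemann-map solver that shares no
code or method with the package's Schwarz-Christoffel implementation: it
computes the conformal map F of a polygon interior onto the unit disc via
the Green's-function factorization F(z) = (z - z0) * exp(h(z)), where
Re h solves a Laplace problem with smooth boundary data -log|z - z0|
(Shortley-Weller second-order discretization on an irregular boundary)
and Im h is recovered by path integration of the discrete Cauchy-Riemann
derivative h' = phi_x - i*phi_y.
"""

from __future__ import annotations

from collections import deque

import numpy as np
from matplotlib.path import Path as MplPath
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import spsolve


def _segment_crossing(p, q, a, b):
    """Parameter t in (0, 1] such that p + t(q-p) crosses segment [a, b]."""
    r = q - p
    s = b - a
    denom = r[0] * s[1] - r[1] * s[0]
    if abs(denom) < 1e-14:
        return None
    t = ((a[0] - p[0]) * s[1] - (a[1] - p[1]) * s[0]) / denom
    u = ((a[0] - p[0]) * r[1] - (a[1] - p[1]) * r[0]) / denom
    if -1e-12 <= u <= 1 + 1e-12 and 1e-12 < t <= 1 + 1e-12:
        return t
    return None


def fd_riemann_map(vertices: np.ndarray, z0: complex, n_grid: int = 240):
    """Finite-difference Riemann map oracle.

    Returns a callable F(z) evaluating the disc map at interior points
    (bilinear interpolation of the grid solution) with the gauge fixed
    only up to rotation, plus the node spacing h.
    """
    verts = np.asarray(vertices, dtype=complex)
    P = np.c_[verts.real, verts.imag]
    lo = P.min(axis=0) - 1e-6
    hi = P.max(axis=0) + 1e-6
    h = max(hi - lo) / n_grid
    nx = int(np.ceil((hi[0] - lo[0]) / h)) + 3
    ny = int(np.ceil((hi[1] - lo[1]) / h)) + 3
    xs = lo[0] - h + np.arange(nx) * h
    ys = lo[1] - h + np.arange(ny) * h
    X, Y = np.meshgrid(xs, ys)
    pts = np.c_[X.ravel(), Y.ravel()]
    inside = MplPath(P).contains_points(pts).reshape(ny, nx)

    idx = -np.ones((ny, nx), dtype=int)
    ii, jj = np.nonzero(inside)
    idx[ii, jj] = np.arange(len(ii))
    n_unk = len(ii)

    def bdata(x, y):
        return -0.5 * np.log((x - z0.real) ** 2 + (y - z0.imag) ** 2)

    edges = [(P[k], P[(k + 1) % len(P)]) for k in range(len(P))]

    def arm(i, j, di, dj):
        """(arm length, boundary value or None) toward neighbor (i+di, j+dj)."""
        ni, nj = i + di, j + dj
        if 0 <= ni < ny and 0 <= nj < nx and inside[ni, nj]:
            return h, None
        p = np.array([xs[j], ys[i]])
        q = np.array([xs[j] + dj * h, ys[i] + di * h])
        tmin = None
        for a, b in edges:
            t = _segment_crossing(p, q, a, b)
            if t is not None and (tmin is None or t < tmin):
                tmin = t
        if tmin is None:
            tmin = 1.0
        tmin = min(max(tmin, 1e-3), 1.0)
        c = p + tmin * (q - p)
        return tmin * h, bdata(c[0], c[1])

    rows, cols, vals = [], [], []
    rhs = np.zeros(n_unk)
    for m in range(n_unk):
        i, j = ii[m], jj[m]
        hE, gE = arm(i, j, 0, 1)
        hW, gW = arm(i, j, 0, -1)
        hN, gN = arm(i, j, 1, 0)
        hS, gS = arm(i, j, -1, 0)
        cE = 2.0 / (hE * (hE + hW))
        cW = 2.0 / (hW * (hE + hW))
        cN = 2.0 / (hN * (hN + hS))
        cS = 2.0 / (hS * (hN + hS))
        diag = -(cE + cW + cN + cS)
        rows.append(m)
        cols.append(m)
        vals.append(diag)
        for (di, dj, cc, g) in ((0, 1, cE, gE), (0, -1, cW, gW), (1, 0, cN, gN), (-1, 0, cS, gS)):
            if g is None:
                rows.append(m)
                cols.append(idx[i + di, j + dj])
                vals.append(cc)
            else:
                rhs[m] -= cc * g
    A = coo_matrix((vals, (rows, cols)), shape=(n_unk, n_unk)).tocsr()
    phi_vec = spsolve(A, rhs)
    phi = np.full((ny, nx), np.nan)
    phi[ii, jj] = phi_vec

    # discrete h' = phi_x - i*phi_y on nodes with interior neighbors
    core = inside.copy()
    core[1:-1, 1:-1] &= inside[1:-1, :-2] & inside[1:-1, 2:] & inside[:-2, 1:-1] & inside[2:, 1:-1]
    core[0, :] = core[-1, :] = False
    core[:, 0] = core[:, -1] = False
    hp = np.full((ny, nx), np.nan, dtype=complex)
    ic, jc = np.nonzero(core)
    hp[ic, jc] = (phi[ic, jc + 1] - phi[ic, jc - 1]) / (2 * h) - 1j * (
        (phi[ic + 1, jc] - phi[ic - 1, jc]) / (2 * h)
    )

    # integrate h along a BFS spanning tree of core nodes (trapezoid rule)
    him = np.full((ny, nx), np.nan)
    start = (ic[len(ic) // 2], jc[len(jc) // 2])
    him[start] = 0.0
    dq = deque([start])
    while dq:
        i, j = dq.popleft()
        for di, dj, dz in ((0, 1, h), (0, -1, -h), (1, 0, 1j * h), (-1, 0, -1j * h)):
            ni, nj = i + di, j + dj
            if 0 <= ni < ny and 0 <= nj < nx and core[ni, nj] and np.isnan(him[ni, nj]):
                inc = 0.5 * (hp[i, j] + hp[ni, nj]) * dz
                him[ni, nj] = him[i, j] + inc.imag
                dq.append((ni, nj))

    def F(z):
        z = np.atleast_1d(np.asarray(z, dtype=complex))
        out = np.empty(len(z), dtype=complex)
        for m, zz in enumerate(z):
            fx = (zz.real - xs[0]) / h
            fy = (zz.imag - ys[0]) / h
            j0, i0 = int(fx), int(fy)
            tx, ty = fx - j0, fy - i0
            blk_p = phi[i0 : i0 + 2, j0 : j0 + 2]
            blk_q = him[i0 : i0 + 2, j0 : j0 + 2]
            if np.isnan(blk_p).any() or np.isnan(blk_q).any():
                out[m] = np.nan
                continue

            def bil(B):
                return (
                    B[0, 0] * (1 - tx) * (1 - ty)
                    + B[0, 1] * tx * (1 - ty)
                    + B[1, 0] * (1 - tx) * ty
                    + B[1, 1] * tx * ty
                )

            hval = bil(blk_p) + 1j * bil(blk_q)
            out[m] = (zz - z0) * np.exp(hval)
        return out

    return F, h
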