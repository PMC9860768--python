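"""Planar swept-duct centerlines with elliptical cross-sections.

A :class:`Centerline` is a piecewise line/arc curve confined to the X-Z
(sagittal) plane, parameterized by arclength ``s``, carrying an elliptical
cross-section whose semi-axes ``a(s)`` (lateral, along +Y) and ``b(s)``
(in-plane) are piecewise-linear in arclength.  It is the common backbone of
the synthetic airway generator, the analytic flow surrogate and the
Lagrangian wall-collision test: a point is inside the duct iff its
normalized elliptical radius ``rho = sqrt((y'/a)^2 + (z'/b)^2) < 1``.

The local frame at ``s`` is ``(T, e1, e2)`` with ``T`` the unit tangent,
``e1 = +Y`` (constant, out of the sagittal plane) and ``e2 = T x e1``
(in-plane normal).  Gravity is ``-Z`` by convention.
"""
from __future__ import annotations

import numpy as np

__all__ = ["Centerline", "CenterlineBuilder"]

E1 = np.array([0.0, 1.0, 0.0])


class Centerline:
    """Piecewise line/arc curve in the X-Z plane with elliptical sections.

    Parameters
    ----------
    seg_s0, seg_p0x, seg_p0z, seg_alpha0, seg_curv : arrays, one per segment
        Segment start arclength, start point (x, z), start tangent angle
        alpha (radians, measured in the X-Z plane from +X toward +Z) and
        signed curvature d(alpha)/ds (0 for straight segments).
    length : float
        Total arclength.
    sa_s, sa_a, sa_b : arrays
        Cross-section stations: arclengths and semi-axes (meters).
    """

    def __init__(self, seg_s0, seg_p0x, seg_p0z, seg_alpha0, seg_curv,
                 length, sa_s, sa_a, sa_b):
        self.seg_s0 = np.asarray(seg_s0, float)
        self.seg_p0x = np.asarray(seg_p0x, float)
        self.seg_p0z = np.asarray(seg_p0z, float)
        self.seg_alpha0 = np.asarray(seg_alpha0, float)
        self.seg_curv = np.asarray(seg_curv, float)
        self.length = float(length)
        self.sa_s = np.asarray(sa_s, float)
        self.sa_a = np.asarray(sa_a, float)
        self.sa_b = np.asarray(sa_b, float)
        if np.any(np.diff(self.sa_s) < 0):
            raise ValueError("section stations must be sorted by arclength")
        if np.any(self.sa_a <= 0) or np.any(self.sa_b <= 0):
            raise ValueError("semi-axes must be positive")
        self._kdtree = None

    # -- frame ---------------------------------------------------------

    def _segment_index(self, s):
        return np.clip(np.searchsorted(self.seg_s0, s, side="right") - 1,
                       0, len(self.seg_s0) - 1)

    def frame(self, s):
        """Return (P, T, e1, e2) at arclengths ``s`` (vectorized)."""
        s = np.atleast_1d(np.asarray(s, float))
        i = self._segment_index(s)
        u = s - self.seg_s0[i]
        a0 = self.seg_alpha0[i]
        k = self.seg_curv[i]
        alpha = a0 + k * u
        px = self.seg_p0x[i].copy()
        pz = self.seg_p0z[i].copy()
        straight = k == 0.0
        if np.any(straight):
            px[straight] += u[straight] * np.cos(a0[straight])
            pz[straight] += u[straight] * np.sin(a0[straight])
        curved = ~straight
        if np.any(curved):
            kc = k[curved]
            px[curved] += (np.sin(alpha[curved]) - np.sin(a0[curved])) / kc
            pz[curved] -= (np.cos(alpha[curved]) - np.cos(a0[curved])) / kc
        n = len(s)
        P = np.empty((n, 3))
        P[:, 0] = px
        P[:, 1] = 0.0
        P[:, 2] = pz
        T = np.empty((n, 3))
        T[:, 0] = np.cos(alpha)
        T[:, 1] = 0.0
        T[:, 2] = np.sin(alpha)
        e1 = np.broadcast_to(E1, (n, 3))
        e2 = np.empty((n, 3))
        e2[:, 0] = -np.sin(alpha)
        e2[:, 1] = 0.0
        e2[:, 2] = np.cos(alpha)
        return P, T, e1, e2

    def position(self, s):
        return self.frame(s)[0]

    def tangent(self, s):
        return self.frame(s)[1]

    # -- sections ------------------------------------------------------

    def curvature(self, s):
        """Signed curvature d(alpha)/ds at arclengths ``s``."""
        s = np.atleast_1d(np.asarray(s, float))
        return self.seg_curv[self._segment_index(s)]

    def semi_axes(self, s):
        """Semi-axes (a, b) at arclengths ``s``."""
        s = np.atleast_1d(np.asarray(s, float))
        a = np.interp(s, self.sa_s, self.sa_a)
        b = np.interp(s, self.sa_s, self.sa_b)
        return a, b

    def semi_axis_slopes(self, s):
        """Piecewise-constant d a/ds and d b/ds at arclengths ``s``."""
        s = np.atleast_1d(np.asarray(s, float))
        idx = np.clip(np.searchsorted(self.sa_s, s, side="right") - 1,
                      0, len(self.sa_s) - 2)
        ds = np.diff(self.sa_s)
        ds[ds == 0] = np.inf
        da = np.diff(self.sa_a) / ds
        db = np.diff(self.sa_b) / ds
        return da[idx], db[idx]

    def section_area(self, s):
        a, b = self.semi_axes(s)
        return np.pi * a * b

    # -- point queries -------------------------------------------------

    def local_coords(self, x, s):
        """Offsets (y', z') of points ``x`` from the centerline at ``s``."""
        x = np.atleast_2d(np.asarray(x, float))
        P, T, e1, e2 = self.frame(s)
        d = x - P
        yp = np.einsum("ij,ij->i", d, e1)
        zp = np.einsum("ij,ij->i", d, e2)
        return yp, zp

    def normalized_radius(self, x, s):
        """Elliptical radius rho; rho < 1 means inside the duct."""
        yp, zp = self.local_coords(x, s)
        a, b = self.semi_axes(np.atleast_1d(s))
        return np.sqrt((yp / a) ** 2 + (zp / b) ** 2)

    def locate(self, x, n_dense: int = 2000):
        """Arclength of the nearest centerline point (KD-tree + projection)."""
        from scipy.spatial import cKDTree
        x = np.atleast_2d(np.asarray(x, float))
        if self._kdtree is None:
            s_dense = np.linspace(0.0, self.length, n_dense)
            self._kdtree = (s_dense, cKDTree(self.position(s_dense)))
        s_dense, tree = self._kdtree
        _, j = tree.query(x)
        s0 = s_dense[j]
        P, T, _, _ = self.frame(s0)
        s = s0 + np.einsum("ij,ij->i", x - P, T)
        return np.clip(s, 0.0, self.length)

    def advance(self, s, x_old, x_new):
        """Incremental arclength update for a particle step.

        Projects the displacement onto the local tangent with the curved-
        frame metric correction 1/(1 - k * zeta), zeta being the in-plane
        offset from the centerline.
        """
        P, T, _, e2 = self.frame(s)
        zeta = np.einsum("ij,ij->i", x_old - P, e2)
        k = self.curvature(s)
        metric = np.clip(1.0 - k * zeta, 0.5, 1.5)
        return s + np.einsum("ij,ij->i", x_new - x_old, T) / metric


class CenterlineBuilder:
    """Incremental construction of a planar centerline.

    Starts at the origin heading along +X; ``turn`` bends the path in the
    sagittal plane (positive angle turns toward -Z, i.e. downward).
    """

    def __init__(self, start=(0.0, 0.0, 0.0), alpha0: float = 0.0):
        self._segs = []  # (s0, p0x, p0z, alpha0, curvature)
        self._s = 0.0
        self._x = float(start[0])
        self._z = float(start[2])
        self._alpha = float(alpha0)
        self._stations = []  # (s, a, b)

    def station(self, a: float, b: float | None = None):
        """Record a cross-section station at the current arclength."""
        b = a if b is None else b
        self._stations.append((self._s, float(a), float(b)))
        return self

    def straight(self, length: float):
        if length <= 0:
            raise ValueError("segment length must be positive")
        self._segs.append((self._s, self._x, self._z, self._alpha, 0.0))
        self._x += length * np.cos(self._alpha)
        self._z += length * np.sin(self._alpha)
        self._s += length
        return self

    def turn(self, angle_deg: float, radius: float):
        """Circular arc turning downward (toward -Z) by ``angle_deg``."""
        if radius <= 0 or angle_deg <= 0:
            raise ValueError("turn radius and angle must be positive")
        theta = np.radians(angle_deg)
        # downward turn: alpha decreases; signed curvature -1/radius
        k = -1.0 / radius
        arclen = radius * theta
        self._segs.append((self._s, self._x, self._z, self._alpha, k))
        a0, a1 = self._alpha, self._alpha + k * arclen
        self._x += (np.sin(a1) - np.sin(a0)) / k
        self._z -= (np.cos(a1) - np.cos(a0)) / k
        self._alpha = a1
        self._s += arclen
        return self

    @property
    def arclength(self) -> float:
        return self._s

    def build(self) -> Centerline:
        if not self._segs:
            raise ValueError("no segments defined")
        if len(self._stations) < 2:
            raise ValueError("need at least two section stations")
        segs = np.array(self._segs, float)
        st = np.array(self._stations, float)
        return Centerline(segs[:, 0], segs[:, 1], segs[:, 2], segs[:, 3],
                          segs[:, 4], self._s, st[:, 0], st[:, 1], st[:, 2])
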