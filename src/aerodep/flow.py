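"""Analytic continuity-conserving flow surrogates inside swept ducts.

The steady velocity field is built from the duct's centerline: the axial
speed is ``u_ax(s, rho) = (Q / A(s)) * f(rho)`` with ``A`` the local
section area and ``f`` a developed-duct profile (parabolic, plug, or
power-law).  A radial component ``u_r = u_ax * rho * dR/ds`` (per ellipse
axis) keeps streamlines attached to the wall through tapers, so inertia-free
tracers preserve their normalized radius.  This surrogate conserves
volumetric flux through every cross-section but carries no secondary
(swirl) flow and no turbulence; inertial impaction at bends and the glottal
jet acceleration are still represented because the axial direction and
section area vary along the path.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constants as C
from .centerline import Centerline
from .geometry import LabeledSurfaceMesh, GeometryError

__all__ = ["FlowSpec", "FlowField", "continuity_flow", "reverse"]

_PROFILES = ("parabolic", "plug", "power_law")


@dataclass
class FlowSpec:
    """Steady flow condition: rate, direction and velocity profile.

    ``flow_lpm`` is the user-facing volumetric rate in L/min; internal
    computations use m^3/s.  The power-law profile (default exponent n=7)
    is the conventional blunt surrogate for a turbulent mean profile.
    """

    flow_lpm: float = 18.0
    direction: str = "inspiratory"
    profile: str = "power_law"
    power_law_n: float = 7.0
    air_density: float = C.AIR_DENSITY
    air_viscosity: float = C.AIR_VISCOSITY

    def __post_init__(self):
        if self.flow_lpm <= 0:
            raise ValueError("flow rate must be positive")
        if self.direction not in ("inspiratory", "expiratory"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.profile not in _PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")

    @property
    def Q(self) -> float:
        """Volumetric flow rate, m^3/s."""
        return self.flow_lpm * C.LPM_TO_M3S


class FlowField:
    """Queryable steady velocity field along a duct centerline.

    ``signed_q`` is positive when flow runs in the +s (inspiratory)
    direction and negative for expiratory flow.
    """

    def __init__(self, centerline: Centerline, spec: FlowSpec,
                 signed_q: float | None = None):
        self.centerline = centerline
        self.spec = spec
        if signed_q is None:
            signed_q = spec.Q if spec.direction == "inspiratory" else -spec.Q
        self.signed_q = float(signed_q)

    @property
    def direction(self) -> str:
        return "inspiratory" if self.signed_q >= 0 else "expiratory"

    # -- profile -------------------------------------------------------

    def profile_factor(self, rho):
        """u_ax / mean axial speed at normalized radius rho in [0, 1]."""
        rho = np.clip(np.asarray(rho, float), 0.0, 1.0)
        p = self.spec.profile
        if p == "plug":
            return np.ones_like(rho)
        if p == "parabolic":
            return 2.0 * (1.0 - rho ** 2)
        n = self.spec.power_law_n
        peak = (n + 1.0) * (2.0 * n + 1.0) / (2.0 * n * n)
        return peak * np.maximum(1.0 - rho, 0.0) ** (1.0 / n)

    # -- queries -------------------------------------------------------

    def inside(self, x, s=None):
        x = np.atleast_2d(np.asarray(x, float))
        if s is None:
            s = self.centerline.locate(x)
        s = np.atleast_1d(s)
        rho = self.centerline.normalized_radius(x, s)
        return (rho < 1.0) & (s > 0.0) & (s < self.centerline.length)

    def section_info(self, x, s=None):
        """(axial tangent, normalized radius, section area) at points ``x``."""
        x = np.atleast_2d(np.asarray(x, float))
        if s is None:
            s = self.centerline.locate(x)
        s = np.atleast_1d(s)
        T = self.centerline.frame(s)[1]
        rho = self.centerline.normalized_radius(x, s)
        return T, rho, self.centerline.section_area(s)

    def velocity(self, x, s=None):
        """Velocity vectors (m/s) at points ``x`` (must lie inside the duct)."""
        x = np.atleast_2d(np.asarray(x, float))
        if s is None:
            s = self.centerline.locate(x)
        s = np.atleast_1d(np.asarray(s, float))
        cl = self.centerline
        P, T, e1, e2 = cl.frame(s)
        a, b = cl.semi_axes(s)
        da, db = cl.semi_axis_slopes(s)
        d = x - P
        yp = np.einsum("ij,ij->i", d, e1)
        zp = np.einsum("ij,ij->i", d, e2)
        rho = np.sqrt((yp / a) ** 2 + (zp / b) ** 2)
        # section-advance rate; the curved-frame metric (1 - k zeta) keeps
        # streamlines at constant (y/a, z/b) and leaves the section flux
        # exactly Q (the odd zeta term integrates to zero)
        w = self.signed_q / (np.pi * a * b) * self.profile_factor(rho)
        metric = 1.0 - cl.curvature(s) * zp
        u_y = w * yp / a * da
        u_z = w * zp / b * db
        return ((w * metric)[:, None] * T
                + u_y[:, None] * e1 + u_z[:, None] * e2)

    def mean_speed(self, s):
        """Mean axial speed magnitude |Q|/A(s)."""
        return abs(self.signed_q) / self.centerline.section_area(s)

    def flux(self, s, n_r: int = 200, n_phi: int = 64) -> float:
        """Numerically integrated volumetric flux through the section at s."""
        cl = self.centerline
        a, b = cl.semi_axes(np.atleast_1d(float(s)))
        a, b = float(a[0]), float(b[0])
        P, T, e1, e2 = cl.frame(np.atleast_1d(float(s)))
        rho = (np.arange(n_r) + 0.5) / n_r
        phi = 2 * np.pi * np.arange(n_phi) / n_phi
        R, PHI = np.meshgrid(rho, phi, indexing="ij")
        pts = (P[0]
               + (a * R * np.cos(PHI)).ravel()[:, None] * e1[0]
               + (b * R * np.sin(PHI)).ravel()[:, None] * e2[0])
        v = self.velocity(pts, s=np.full(len(pts), float(s)))
        vn = v @ T[0]
        dA = a * b * R.ravel() * (1.0 / n_r) * (2 * np.pi / n_phi)
        return float(np.sum(vn * dA))

    def reverse(self) -> "FlowField":
        """Pointwise-negated field (inspiratory <-> expiratory)."""
        return FlowField(self.centerline, self.spec, signed_q=-self.signed_q)


def _centerline_from_mesh(mesh: LabeledSurfaceMesh) -> Centerline:
    """Reconstruct a straight-duct centerline from an unparameterized mesh.

    Only tube-like meshes swept along a straight axis are supported;
    centroids of cross-section slices must stay on a line.  Curved meshes
    loaded from bare STL need their generating parameters instead.
    """
    from .centerline import CenterlineBuilder
    v = mesh.vertices
    extent = v.max(axis=0) - v.min(axis=0)
    axis = int(np.argmax(extent))
    lo, hi = v[:, axis].min(), v[:, axis].max()
    n_st = 12
    stations = np.linspace(lo, hi, n_st)
    centroids, radii = [], []
    for st in stations:
        sel = np.abs(v[:, axis] - st) < (hi - lo) / (2 * n_st)
        if sel.sum() < 3:
            continue
        ring = v[sel]
        c = ring.mean(axis=0)
        r = np.linalg.norm(np.delete(ring - c, axis, axis=1), axis=1).mean()
        centroids.append(c)
        radii.append(r)
    centroids = np.array(centroids)
    off_axis = np.delete(centroids - centroids.mean(axis=0), axis, axis=1)
    r_mean = float(np.mean(radii))
    if np.abs(off_axis).max() > 0.2 * r_mean:
        raise GeometryError(
            "cannot reconstruct a centerline for a curved mesh; "
            "build the geometry with its parameters instead")
    if axis != 0:
        raise GeometryError("reconstruction expects the duct axis along X")
    cb = CenterlineBuilder(start=(lo, centroids[0][1], centroids[0][2]))
    cb.station(r_mean, r_mean)
    cb.straight(hi - lo)
    cb.station(r_mean, r_mean)
    return cb.build()


def continuity_flow(mesh: LabeledSurfaceMesh, spec: FlowSpec) -> FlowField:
    """Build the analytic flow surrogate for a labeled mesh.

    Uses the mesh's own sweep centerline when present (every generated
    geometry carries one); otherwise attempts straight-duct reconstruction.
    """
    cl = mesh.centerline
    if cl is None:
        cl = _centerline_from_mesh(mesh)
        mesh.centerline = cl
    return FlowField(cl, spec)


def reverse(field: FlowField) -> FlowField:
    """Module-level alias for :meth:`FlowField.reverse`."""
    return field.reverse()
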