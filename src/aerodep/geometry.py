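"""Synthetic mouth-throat airway surface meshes with region labels.

The airway is modeled as a swept-section duct: a straight inlet tube
(mouthpiece extension), an elliptical mouth cavity, a downward sagittal
bend through the oropharynx, a laryngeal segment with a glottal
constriction, and a straight trachea.  Wall faces carry one of five region
labels; region boundaries are planes of constant centerline arclength, and
a face belongs to the region containing its centroid's arclength (a
centroid exactly on a boundary goes to the downstream region).

Meshes are exchanged as STL plus a sidecar CSV (``face_index,label``),
since STL itself carries no attributes.
"""
from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import trimesh

from .centerline import Centerline, CenterlineBuilder

__all__ = [
    "REGIONS", "WALL_REGIONS", "GeometryParams", "LabeledSurfaceMesh",
    "build_synthetic_airway", "straight_tube_mesh", "mesh_metrics",
    "load_stl", "save_stl",
]

#: Region labels in upstream-to-downstream order (inspiratory sense).
REGIONS = ("TUBE", "MOUTH", "OROPHARYNX", "LARYNX", "TRACHEA")

#: Regions whose walls trap particles (the tube/mouthpiece reflects).
WALL_REGIONS = ("MOUTH", "OROPHARYNX", "LARYNX", "TRACHEA")


class GeometryError(ValueError):
    """Invalid geometry parameters or malformed mesh."""


@dataclass
class GeometryParams:
    """Parameters of the synthetic mouth-throat geometry (SI meters/degrees).

    The 245 mm inlet tube reproduces the mouthpiece extension used in the
    deposition experiments this family of geometries emulates; its diameter
    is a free parameter.
    """

    mouth_width: float = 0.026
    mouth_height: float = 0.014
    mouth_length: float = 0.070
    pharynx_diameter: float = 0.012
    pharynx_bend_angle: float = 90.0
    glottis_diameter: float = 0.007
    larynx_length: float = 0.035
    trachea_diameter: float = 0.015
    trachea_length: float = 0.060
    tube_length: float = 0.245
    tube_diameter: float = 0.020
    mesh_resolution: int = 32

    def validate(self) -> None:
        lengths = {
            "mouth_width": self.mouth_width,
            "mouth_height": self.mouth_height,
            "mouth_length": self.mouth_length,
            "pharynx_diameter": self.pharynx_diameter,
            "glottis_diameter": self.glottis_diameter,
            "larynx_length": self.larynx_length,
            "trachea_diameter": self.trachea_diameter,
            "trachea_length": self.trachea_length,
            "tube_length": self.tube_length,
            "tube_diameter": self.tube_diameter,
        }
        for name, v in lengths.items():
            if not v > 0:
                raise GeometryError(f"{name} must be positive, got {v}")
        if not 0 < self.pharynx_bend_angle <= 150:
            raise GeometryError("pharynx_bend_angle must be in (0, 150] deg")
        if self.glottis_diameter >= self.pharynx_diameter:
            raise GeometryError(
                "glottal constriction must be narrower than the pharynx")
        if self.mesh_resolution < 16:
            raise GeometryError("mesh_resolution must be >= 16")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "GeometryParams":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class LabeledSurfaceMesh:
    """Triangle mesh with per-face region labels and two open ends.

    ``region_breaks`` holds the arclength of each region boundary plane in
    ``region_order``; together with ``centerline`` they let the transport
    code classify wall hits without touching individual triangles.
    """

    vertices: np.ndarray
    faces: np.ndarray
    face_labels: np.ndarray
    centerline: Centerline | None = None
    region_breaks: np.ndarray | None = None  # boundaries between consecutive regions
    region_order: tuple = REGIONS
    gravity_axis: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, -1.0]))
    geometry_id: str = "default"

    # -- label lookup --------------------------------------------------

    def label_at_arclength(self, s):
        """Region label(s) at centerline arclength(s); ties go downstream."""
        if self.region_breaks is None:
            raise GeometryError("mesh carries no arclength region map")
        s = np.atleast_1d(np.asarray(s, float))
        idx = np.searchsorted(self.region_breaks, s, side="right")
        idx = np.clip(idx, 0, len(self.region_order) - 1)
        return np.asarray(self.region_order, object)[idx]

    # -- topology ------------------------------------------------------

    def boundary_loops(self):
        """Connected loops of boundary edges (edges used by one face only)."""
        edges = np.sort(
            self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        uniq, counts = np.unique(edges, axis=0, return_counts=True)
        bedges = uniq[counts == 1]
        adj: dict[int, list[int]] = {}
        for u, v in bedges:
            adj.setdefault(int(u), []).append(int(v))
            adj.setdefault(int(v), []).append(int(u))
        seen, loops = set(), []
        for start in adj:
            if start in seen:
                continue
            loop, prev, cur = [start], None, start
            seen.add(start)
            while True:
                nxt = [w for w in adj[cur] if w != prev]
                if not nxt:
                    break
                prev, cur = cur, nxt[0]
                if cur == start:
                    break
                loop.append(cur)
                seen.add(cur)
            loops.append(loop)
        return loops

    def validate(self) -> None:
        if len(self.faces) != len(self.face_labels):
            raise GeometryError("face_labels length mismatch")
        areas = self._face_areas()
        if np.any(areas <= 0):
            raise GeometryError("mesh contains degenerate faces")
        loops = self.boundary_loops()
        if len(loops) != 2:
            raise GeometryError(
                f"expected exactly 2 boundary loops (inlet/outlet), "
                f"found {len(loops)}")
        unknown = set(np.unique(self.face_labels)) - set(self.region_order)
        if unknown:
            raise GeometryError(f"unknown region labels: {unknown}")

    # -- metrics -------------------------------------------------------

    def _face_areas(self):
        v = self.vertices
        t = v[self.faces]
        return 0.5 * np.linalg.norm(
            np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1)

    def area_by_region(self) -> dict:
        areas = self._face_areas()
        return {r: float(areas[self.face_labels == r].sum())
                for r in self.region_order if np.any(self.face_labels == r)}

    def total_area(self) -> float:
        return float(self._face_areas().sum())

    def enclosed_volume(self) -> float:
        """Volume with both openings capped by centroid fans (m^3)."""
        loops = self.boundary_loops()
        if len(loops) != 2:
            raise GeometryError("cannot cap a mesh without 2 boundary loops")
        verts = [self.vertices]
        faces = [self.faces]
        nv = len(self.vertices)
        for loop in loops:
            centroid = self.vertices[loop].mean(axis=0)
            verts.append(centroid[None, :])
            ci = nv
            nv += 1
            ring = np.array(loop)
            fan = np.stack([ring, np.roll(ring, -1),
                            np.full(len(ring), ci)], axis=1)
            faces.append(fan)
        tm = trimesh.Trimesh(np.vstack(verts), np.vstack(faces), process=False)
        trimesh.repair.fix_normals(tm)
        return float(abs(tm.volume))

    # -- I/O -----------------------------------------------------------

    def save(self, path, ascii: bool = False) -> None:
        save_stl(self, path, ascii=ascii)


def _labels_path(path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".labels.csv") if p.suffix != ".stl" \
        else p.with_name(p.stem + ".labels.csv")


def save_stl(mesh: LabeledSurfaceMesh, path, ascii: bool = False) -> None:
    """Write STL plus the ``*.labels.csv`` sidecar (face_index,label)."""
    tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
    tm.export(path, file_type="stl_ascii" if ascii else "stl")
    with open(_labels_path(path), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["face_index", "label"])
        for i, lab in enumerate(mesh.face_labels):
            w.writerow([i, lab])


def load_stl(path, labels_path=None, validate: bool = True) -> LabeledSurfaceMesh:
    """Load an STL and its label sidecar into a :class:`LabeledSurfaceMesh`.

    The mesh has no attached centerline; one is reconstructed on demand by
    the flow module for tube-like geometries.
    """
    tm = trimesh.load(path, file_type="stl", process=False)
    tm.merge_vertices()  # STL is a triangle soup; welding preserves face order
    lp = Path(labels_path) if labels_path else _labels_path(path)
    if not lp.exists():
        raise GeometryError(f"label sidecar not found: {lp}")
    with open(lp) as fh:
        rows = list(csv.DictReader(fh))
    if len(rows) != len(tm.faces):
        raise GeometryError(
            f"label table has {len(rows)} rows for {len(tm.faces)} faces")
    labels = np.array([r["label"] for r in rows], object)
    mesh = LabeledSurfaceMesh(np.asarray(tm.vertices, float),
                              np.asarray(tm.faces), labels)
    if validate:
        mesh.validate()
    return mesh


# -- construction ------------------------------------------------------


def _sweep_mesh(cl: Centerline, ring_spacing: float, n_ring: int):
    """Triangulate the swept surface; returns (vertices, faces, face_s)."""
    n_rings = max(int(np.ceil(cl.length / ring_spacing)) + 1, 8)
    s_ring = np.linspace(0.0, cl.length, n_rings)
    phi = np.linspace(0.0, 2 * np.pi, n_ring, endpoint=False)
    P, T, e1, e2 = cl.frame(s_ring)
    a, b = cl.semi_axes(s_ring)
    verts = (P[:, None, :]
             + a[:, None, None] * np.cos(phi)[None, :, None] * e1[:, None, :]
             + b[:, None, None] * np.sin(phi)[None, :, None] * e2[:, None, :])
    verts = verts.reshape(-1, 3)
    faces = []
    face_s = []
    for i in range(n_rings - 1):
        r0 = i * n_ring
        r1 = (i + 1) * n_ring
        j = np.arange(n_ring)
        jn = (j + 1) % n_ring
        # two triangles per quad, outward winding
        faces.append(np.stack([r0 + j, r1 + j, r0 + jn], axis=1))
        faces.append(np.stack([r0 + jn, r1 + j, r1 + jn], axis=1))
        smid = 0.5 * (s_ring[i] + s_ring[i + 1])
        face_s.extend([np.full(n_ring, smid)] * 2)
    return verts, np.vstack(faces), np.concatenate(face_s)


def build_synthetic_airway(params: GeometryParams | None = None,
                           seed: int = 0, jitter: float = 0.0,
                           geometry_id: str = "default") -> LabeledSurfaceMesh:
    """Construct the labeled swept-section mouth-throat mesh.

    ``jitter`` applies seeded log-normal perturbations (sigma = ``jitter``)
    to the cross-section semi-axes downstream of the tube, emulating
    intersubject anatomical variation; the default 0 is fully deterministic
    in the parameters alone.
    """
    p = params or GeometryParams()
    p.validate()
    rng = np.random.default_rng(seed)

    rt = p.tube_diameter / 2
    aw, bh = p.mouth_width / 2, p.mouth_height / 2
    rp = p.pharynx_diameter / 2
    rg = p.glottis_diameter / 2
    rtr = p.trachea_diameter / 2
    bend_radius = max(1.2 * p.pharynx_diameter, 0.014)

    cb = CenterlineBuilder()
    cb.station(rt, rt)
    cb.straight(p.tube_length)
    cb.station(rt, rt)                      # end of tube
    s_tube = cb.arclength
    cb.straight(p.mouth_length)
    s_mouth = cb.arclength
    cb.turn(p.pharynx_bend_angle, bend_radius)
    s_pharynx = cb.arclength
    cb.straight(p.larynx_length)
    s_larynx = cb.arclength
    cb.straight(p.trachea_length)
    s_total = cb.arclength

    def jit():
        return float(np.exp(rng.normal(0.0, jitter))) if jitter > 0 else 1.0

    # mouth: taper from tube circle to the elliptical cavity, then hold
    cb._stations.append((s_tube + 0.25 * p.mouth_length, aw * jit(), bh * jit()))
    cb._stations.append((s_mouth, aw * jit(), bh * jit()))
    # oropharynx bend: blend ellipse into the circular pharynx
    cb._stations.append((s_pharynx, rp * jit(), rp * jit()))
    # larynx: constriction at mid-length, opening into the trachea
    g = rg * jit()
    if g >= rp:
        raise GeometryError("jittered glottis wider than pharynx")
    cb._stations.append((s_pharynx + 0.5 * p.larynx_length, g, g))
    cb._stations.append((s_larynx, rtr * jit(), rtr * jit()))
    cb._stations.append((s_total, rtr, rtr))

    cb._stations.sort()
    cl = cb.build()

    ring_spacing = min(0.003, p.larynx_length / 8)
    verts, faces, face_s = _sweep_mesh(cl, ring_spacing, p.mesh_resolution)
    breaks = np.array([s_tube, s_mouth, s_pharynx, s_larynx])
    mesh = LabeledSurfaceMesh(
        vertices=verts, faces=faces,
        face_labels=np.empty(len(faces), object),
        centerline=cl, region_breaks=breaks, geometry_id=geometry_id)
    mesh.face_labels[:] = mesh.label_at_arclength(face_s)
    mesh.validate()
    return mesh


def straight_tube_mesh(radius: float, length: float, label: str = "TRACHEA",
                       n_ring: int = 32, ring_spacing: float = 0.005
                       ) -> LabeledSurfaceMesh:
    """A horizontal straight circular duct (axis +X, gravity -Z).

    Useful as an analytic benchmark geometry; the whole wall carries one
    label (a trapping region by default, ``TUBE`` for a reflecting wall).
    """
    if label not in REGIONS:
        raise GeometryError(f"unknown label {label}")
    cb = CenterlineBuilder()
    cb.station(radius, radius)
    cb.straight(length)
    cb.station(radius, radius)
    cl = cb.build()
    verts, faces, face_s = _sweep_mesh(cl, ring_spacing, n_ring)
    order = tuple([label])
    mesh = LabeledSurfaceMesh(
        vertices=verts, faces=faces,
        face_labels=np.array([label] * len(faces), object),
        centerline=cl, region_breaks=np.array([]), region_order=order,
        geometry_id=f"tube_r{radius:g}_L{length:g}")
    mesh.validate()
    return mesh


def mesh_metrics(mesh: LabeledSurfaceMesh) -> dict:
    """Per-region wall areas (m^2), total area and enclosed volume (m^3)."""
    areas = mesh.area_by_region()
    return {
        "area_by_region": areas,
        "total_area": mesh.total_area(),
        "enclosed_volume": mesh.enclosed_volume(),
    }
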