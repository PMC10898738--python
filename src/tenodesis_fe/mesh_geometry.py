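"""Surgical geometry operations on labeled meshes.

Implements the geometric side of the virtual surgery: drilling bone tunnels
into tetrahedral bone meshes, sweeping graft volumes along planned
trajectories, and locating the tibial compartment centers and their femoral
projections used later for kinematic measurements.

All lengths are millimetres (the package-wide mm-N-MPa unit system).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import trimesh

from .errors import DegenerateLandmarkError, GeometryError

__all__ = [
    "LabeledSurfaceMesh",
    "LabeledTetMesh",
    "Cylinder",
    "TrajectoryPolyline",
    "PlateauLandmarks",
    "tibia_width",
    "compartment_centers",
    "project_to_femur",
    "drill_tunnel",
    "sweep_graft",
    "box_tet_mesh",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class LabeledSurfaceMesh:
    """Triangulated surface with named vertex sets.

    Attributes
    ----------
    vertices : (n, 3) float array, mm
    faces : (m, 3) int array of vertex indices
    name : str
    vertex_sets : dict mapping set name to an int index array
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str = "surface"
    vertex_sets: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=int).reshape(-1, 3)
        self.vertex_sets = {k: np.asarray(v, dtype=int) for k, v in self.vertex_sets.items()}
        self.validate()

    def validate(self):
        n = len(self.vertices)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= n):
            raise GeometryError(f"{self.name}: faces index out of range")
        if self.faces.size:
            a = self.vertices[self.faces[:, 1]] - self.vertices[self.faces[:, 0]]
            b = self.vertices[self.faces[:, 2]] - self.vertices[self.faces[:, 0]]
            areas = 0.5 * np.linalg.norm(np.cross(a, b), axis=1)
            if np.any(areas <= 1e-12):
                raise GeometryError(f"{self.name}: degenerate zero-area faces present")
        for sname, idx in self.vertex_sets.items():
            if idx.size and (idx.min() < 0 or idx.max() >= n):
                raise GeometryError(f"{self.name}: vertex set '{sname}' out of range")

    @property
    def is_watertight(self) -> bool:
        return self.as_trimesh().is_watertight

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    def to_stl(self, path):
        self.as_trimesh().export(str(path))

    @classmethod
    def from_stl(cls, path, name=None):
        m = trimesh.load_mesh(str(path))
        return cls(vertices=np.asarray(m.vertices), faces=np.asarray(m.faces),
                   name=name or "surface")


@dataclass
class LabeledTetMesh:
    """Tetrahedral volume mesh with named node and element sets.

    Element orientation is normalized at construction: any tetrahedron with
    negative signed volume has its first two nodes swapped, so the invariant
    "all element volumes strictly positive" holds under a fixed convention.
    """

    nodes: np.ndarray
    elements: np.ndarray
    name: str = "volume"
    node_sets: dict = field(default_factory=dict)
    element_sets: dict = field(default_factory=dict)

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float).reshape(-1, 3)
        self.elements = np.asarray(self.elements, dtype=int).reshape(-1, 4)
        self.node_sets = {k: np.asarray(v, dtype=int) for k, v in self.node_sets.items()}
        self.element_sets = {k: np.asarray(v, dtype=int) for k, v in self.element_sets.items()}
        # fixed orientation convention: positive signed volume
        sv = self._signed_volumes()
        flip = sv < 0
        if np.any(flip):
            self.elements = self.elements.copy()
            self.elements[flip, 0], self.elements[flip, 1] = (
                self.elements[flip, 1].copy(), self.elements[flip, 0].copy())
        self.validate()

    def _signed_volumes(self) -> np.ndarray:
        p = self.nodes[self.elements]
        a, b, c = p[:, 1] - p[:, 0], p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]
        return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0

    def element_volumes(self) -> np.ndarray:
        return self._signed_volumes()

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def volume(self) -> float:
        return float(self.element_volumes().sum())

    def validate(self):
        n = len(self.nodes)
        if len(self.elements) == 0:
            raise GeometryError(f"{self.name}: mesh has no elements")
        if self.elements.min() < 0 or self.elements.max() >= n:
            raise GeometryError(f"{self.name}: element connectivity out of range")
        vols = self.element_volumes()
        if np.any(vols <= 0):
            raise GeometryError(f"{self.name}: non-positive element volumes")
        for sname, idx in self.node_sets.items():
            if idx.size and (idx.min() < 0 or idx.max() >= n):
                raise GeometryError(f"{self.name}: node set '{sname}' out of range")
        for sname, idx in self.element_sets.items():
            if idx.size and (idx.min() < 0 or idx.max() >= len(self.elements)):
                raise GeometryError(f"{self.name}: element set '{sname}' out of range")

    # --- boundary extraction -------------------------------------------------

    _FACE_ORDER = np.array([[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]])

    def boundary_faces(self) -> np.ndarray:
        """Triangles appearing in exactly one tetrahedron."""
        faces = self.elements[:, self._FACE_ORDER].reshape(-1, 3)
        key = np.sort(faces, axis=1)
        _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
        return faces[counts[inv] == 1]

    def surface(self, name=None) -> LabeledSurfaceMesh:
        """Extract the boundary as a compacted surface mesh."""
        faces = self.boundary_faces()
        used = np.unique(faces)
        remap = -np.ones(len(self.nodes), dtype=int)
        remap[used] = np.arange(len(used))
        return LabeledSurfaceMesh(self.nodes[used], remap[faces],
                                  name=name or f"{self.name}_surface")

    # --- legacy VTK I/O ------------------------------------------------------

    def to_vtk(self, path):
        """Write as legacy ASCII VTK unstructured grid.

        Node/element sets are stored as 0/1 integer POINT_DATA / CELL_DATA
        arrays so the file round-trips the full labeling.
        """
        lines = ["# vtk DataFile Version 2.0", self.name, "ASCII",
                 "DATASET UNSTRUCTURED_GRID",
                 f"POINTS {len(self.nodes)} double"]
        lines += [" ".join(f"{v:.17g}" for v in p) for p in self.nodes]
        m = len(self.elements)
        lines.append(f"CELLS {m} {5 * m}")
        lines += ["4 " + " ".join(map(str, e)) for e in self.elements]
        lines.append(f"CELL_TYPES {m}")
        lines += ["10"] * m
        if self.node_sets:
            lines.append(f"POINT_DATA {len(self.nodes)}")
            for sname, idx in sorted(self.node_sets.items()):
                mask = np.zeros(len(self.nodes), dtype=int)
                mask[idx] = 1
                lines.append(f"SCALARS {sname} int 1")
                lines.append("LOOKUP_TABLE default")
                lines += [str(x) for x in mask]
        if self.element_sets:
            lines.append(f"CELL_DATA {m}")
            for sname, idx in sorted(self.element_sets.items()):
                mask = np.zeros(m, dtype=int)
                mask[idx] = 1
                lines.append(f"SCALARS {sname} int 1")
                lines.append("LOOKUP_TABLE default")
                lines += [str(x) for x in mask]
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    @classmethod
    def from_vtk(cls, path):
        with open(path) as fh:
            tokens_lines = fh.read().splitlines()
        name = tokens_lines[1] if len(tokens_lines) > 1 else "volume"
        toks = " ".join(tokens_lines[2:]).split()
        pos = {t.upper(): i for i, t in enumerate(toks) if t.upper() in
               ("POINTS", "CELLS", "CELL_TYPES", "POINT_DATA", "CELL_DATA")}
        i = toks.index("POINTS")
        n = int(toks[i + 1])
        nodes = np.array(toks[i + 3:i + 3 + 3 * n], dtype=float).reshape(n, 3)
        i = toks.index("CELLS")
        m = int(toks[i + 1])
        cells = np.array(toks[i + 3:i + 3 + 5 * m], dtype=int).reshape(m, 5)[:, 1:]

        def read_sets(keyword, count):
            sets = {}
            if keyword not in toks:
                return sets
            j = toks.index(keyword) + 2
            while j < len(toks) and toks[j] == "SCALARS":
                sname = toks[j + 1]
                j += 6  # SCALARS name type ncomp LOOKUP_TABLE default
                mask = np.array(toks[j:j + count], dtype=int)
                sets[sname] = np.flatnonzero(mask)
                j += count
            return sets

        node_sets = read_sets("POINT_DATA", n)
        element_sets = read_sets("CELL_DATA", m)
        return cls(nodes, cells, name=name, node_sets=node_sets,
                   element_sets=element_sets)


@dataclass
class Cylinder:
    """Tunnel cylinder: axis origin, unit direction, radius, length (mm).

    ``length`` may be ``np.inf``, meaning the cylinder pierces the whole bone
    (unbounded along its axis in both directions).
    """

    origin: np.ndarray
    direction: np.ndarray
    radius: float
    length: float = np.inf

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3)
        nrm = np.linalg.norm(self.direction)
        if abs(nrm - 1.0) > 1e-9:
            if nrm == 0:
                raise GeometryError("cylinder direction has zero norm")
            self.direction = self.direction / nrm
        if not self.radius > 0:
            raise GeometryError("cylinder radius must be positive")
        if not self.length > 0:
            raise GeometryError("cylinder length must be positive")

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Strict interior test for an array of points."""
        p = np.atleast_2d(points) - self.origin
        t = p @ self.direction
        radial = np.linalg.norm(p - np.outer(t, self.direction), axis=1)
        inside = radial < self.radius
        if np.isfinite(self.length):
            inside &= (t > 0) & (t < self.length)
        return inside

    def volume(self) -> float:
        if not np.isfinite(self.length):
            raise GeometryError("infinite cylinder has no finite volume")
        return float(np.pi * self.radius**2 * self.length)


@dataclass
class TrajectoryPolyline:
    """Graft path: ordered control points plus a cross-section descriptor.

    Exactly one of ``radius`` (circular graft, e.g. the 4 mm semitendinosus
    bundle) or ``width`` (flat iliotibial-band strap, default thickness 2 mm)
    must be given.
    """

    points: np.ndarray
    radius: float | None = None
    width: float | None = None
    thickness: float = 2.0

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.points) < 2:
            raise GeometryError("trajectory needs at least 2 points")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg <= 1e-6):
            raise GeometryError("consecutive trajectory points coincide")
        if (self.radius is None) == (self.width is None):
            raise GeometryError("specify exactly one of radius or width")
        if self.radius is not None and self.radius <= 0:
            raise GeometryError("cross-section radius must be positive")
        if self.width is not None and (self.width <= 0 or self.thickness <= 0):
            raise GeometryError("strap width and thickness must be positive")

    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    def to_json(self, path):
        d = {"points": self.points.tolist(), "radius": self.radius,
             "width": self.width, "thickness": self.thickness}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.asarray(d["points"]), radius=d.get("radius"),
                   width=d.get("width"), thickness=d.get("thickness", 2.0))


@dataclass
class PlateauLandmarks:
    """Most medial and most lateral aspects of the tibia plateau (mm)."""

    medial: np.ndarray
    lateral: np.ndarray

    def __post_init__(self):
        self.medial = np.asarray(self.medial, dtype=float).reshape(3)
        self.lateral = np.asarray(self.lateral, dtype=float).reshape(3)
        if np.linalg.norm(self.lateral - self.medial) <= 1e-9:
            raise DegenerateLandmarkError("plateau aspects coincide")

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump({"medial": self.medial.tolist(),
                       "lateral": self.lateral.tolist()}, fh)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.asarray(d["medial"]), np.asarray(d["lateral"]))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def tibia_width(landmarks: PlateauLandmarks) -> float:
    """Tibia plateau width: Euclidean distance between the two aspects (mm)."""
    return float(np.linalg.norm(landmarks.lateral - landmarks.medial))


def compartment_centers(landmarks: PlateauLandmarks):
    """Medial and lateral tibial compartment centers (MTC, LTC).

    Placed at 25 % and 75 % of the plateau width along the medial-to-lateral
    aspect line, measured from the medial aspect.
    """
    d = landmarks.lateral - landmarks.medial
    mtc = landmarks.medial + 0.25 * d
    ltc = landmarks.medial + 0.75 * d
    return mtc, ltc


def project_to_femur(point, femur: LabeledSurfaceMesh, axis):
    """Closest femur vertex to the line through ``point`` along ``axis``.

    Returns ``(vertex_index, vertex_coordinates)``. Ties are broken by the
    lowest vertex index (deterministic).
    """
    if len(femur.vertices) == 0:
        raise GeometryError("cannot project onto an empty mesh")
    axis = np.asarray(axis, dtype=float).reshape(3)
    nrm = np.linalg.norm(axis)
    if abs(nrm - 1.0) > 1e-9:
        raise GeometryError("projection axis must be unit-norm")
    rel = femur.vertices - np.asarray(point, dtype=float).reshape(3)
    t = rel @ axis
    d2 = np.einsum("ij,ij->i", rel, rel) - t * t
    idx = int(np.argmin(d2))  # argmin returns the first (lowest-index) minimum
    return idx, femur.vertices[idx].copy()


def drill_tunnel(mesh: LabeledTetMesh, tunnel: Cylinder):
    """Drill a tunnel: delete every tetrahedron whose centroid lies strictly
    inside the cylinder.

    Returns ``(drilled_mesh, removed_volume_mm3)``. The drilled mesh carries a
    new node set ``"tunnel_wall"`` holding the nodes of faces newly exposed by
    the drilling; existing node/element sets are remapped (members referring
    to removed nodes/elements are dropped). Volume is conserved exactly:
    ``mesh.volume() - drilled.volume() == removed_volume``.
    """
    centroids = mesh.element_centroids()
    remove = tunnel.contains(centroids)
    vols = mesh.element_volumes()
    removed_volume = float(vols[remove].sum())
    if not np.any(remove):
        out = replace(mesh, nodes=mesh.nodes.copy(), elements=mesh.elements.copy(),
                      node_sets={**{k: v.copy() for k, v in mesh.node_sets.items()},
                                 "tunnel_wall": np.array([], dtype=int)},
                      element_sets={k: v.copy() for k, v in mesh.element_sets.items()})
        return out, 0.0
    if np.all(remove):
        raise GeometryError("drilling removed every element of the mesh")

    keep = ~remove
    # newly exposed faces: shared between one removed and one kept element
    fo = LabeledTetMesh._FACE_ORDER
    faces = mesh.elements[:, fo].reshape(-1, 3)
    owner_removed = np.repeat(remove, 4)
    key = np.sort(faces, axis=1)
    uniq, inv = np.unique(key, axis=0, return_inverse=True)
    n_owners = np.bincount(inv, minlength=len(uniq))
    n_removed_owner = np.bincount(inv, weights=owner_removed.astype(float),
                                  minlength=len(uniq))
    exposed = (n_owners == 2) & (n_removed_owner == 1)
    wall_nodes_old = np.unique(uniq[exposed])

    kept_elements = mesh.elements[keep]
    used = np.unique(kept_elements)
    remap = -np.ones(len(mesh.nodes), dtype=int)
    remap[used] = np.arange(len(used))

    def remap_nodeset(idx):
        new = remap[idx]
        return new[new >= 0]

    old_to_new_elem = -np.ones(len(mesh.elements), dtype=int)
    old_to_new_elem[keep] = np.arange(keep.sum())

    node_sets = {k: remap_nodeset(v) for k, v in mesh.node_sets.items()}
    node_sets["tunnel_wall"] = remap_nodeset(wall_nodes_old)
    element_sets = {}
    for k, v in mesh.element_sets.items():
        new = old_to_new_elem[v]
        element_sets[k] = new[new >= 0]

    drilled = LabeledTetMesh(mesh.nodes[used], remap[kept_elements],
                             name=mesh.name, node_sets=node_sets,
                             element_sets=element_sets)
    return drilled, removed_volume


def _station_frames(points: np.ndarray):
    """Parallel-transport orthonormal frames along a polyline.

    Returns per-station tangents, and two normals spanning the cross-section
    plane; minimal rotation between consecutive segment tangents avoids frame
    flipping on curved trajectories.
    """
    seg = np.diff(points, axis=0)
    seg_t = seg / np.linalg.norm(seg, axis=1, keepdims=True)
    n_st = len(points)
    tangents = np.empty((n_st, 3))
    tangents[0] = seg_t[0]
    tangents[-1] = seg_t[-1]
    for i in range(1, n_st - 1):
        t = seg_t[i - 1] + seg_t[i]
        nrm = np.linalg.norm(t)
        if nrm < 1e-12:
            raise GeometryError("trajectory reverses direction (180 degree turn)")
        tangents[i] = t / nrm
    # initial normal: any unit vector orthogonal to the first tangent
    ref = np.array([0.0, 0.0, 1.0])
    if abs(tangents[0] @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    u = np.cross(tangents[0], ref)
    u /= np.linalg.norm(u)
    normals = np.empty((n_st, 3))
    binormals = np.empty((n_st, 3))
    normals[0] = u
    binormals[0] = np.cross(tangents[0], u)
    for i in range(1, n_st):
        a, b = tangents[i - 1], tangents[i]
        c = np.cross(a, b)
        s = np.linalg.norm(c)
        d = float(a @ b)
        if s < 1e-12:
            normals[i] = normals[i - 1]
        else:
            # Rodrigues rotation taking a to b
            k = c / s
            ang = np.arctan2(s, d)
            v = normals[i - 1]
            normals[i] = (v * np.cos(ang) + np.cross(k, v) * np.sin(ang)
                          + k * (k @ v) * (1 - np.cos(ang)))
        normals[i] /= np.linalg.norm(normals[i])
        binormals[i] = np.cross(tangents[i], normals[i])
    return tangents, normals, binormals


def _resample_polyline(points: np.ndarray, max_step: float):
    """Insert stations so no segment exceeds ``max_step``; keeps originals."""
    out = [points[0]]
    for a, b in zip(points[:-1], points[1:]):
        n = max(1, int(np.ceil(np.linalg.norm(b - a) / max_step)))
        for j in range(1, n + 1):
            out.append(a + (b - a) * j / n)
    return np.array(out)


def sweep_graft(trajectory: TrajectoryPolyline, name: str = "graft",
                n_theta: int = 16, min_elements: int = 96,
                max_station_spacing: float | None = None) -> LabeledTetMesh:
    """Sweep the graft cross-section along its planned trajectory.

    Circular cross-sections give a tube (regular ``n_theta``-gon disks, one
    hub node plus ring nodes per station, 3 tets per wedge prism); flat
    cross-sections give a strap (width x thickness rectangle, one hexahedral
    cell per station pair split into 6 tets). End node sets
    ``"proximal_end"`` (first station) and ``"distal_end"`` (last station)
    are labeled. Raises :class:`GeometryError` when the trajectory turns
    tighter than the cross-section half-size (swept cells invert).
    """
    circular = trajectory.radius is not None
    half = trajectory.radius if circular else 0.5 * max(trajectory.width,
                                                        trajectory.thickness)
    length = trajectory.length()
    if max_station_spacing is None:
        max_station_spacing = max(half, length / 200.0)
    per_pair = 3 * n_theta if circular else 6
    need = int(np.ceil(min_elements / per_pair)) + 1
    spacing = min(max_station_spacing, length / max(1, need - 1))
    pts = _resample_polyline(trajectory.points, spacing)
    tangents, normals, binormals = _station_frames(pts)
    n_st = len(pts)

    nodes = []
    if circular:
        r = trajectory.radius
        ang = 2 * np.pi * np.arange(n_theta) / n_theta
        for i in range(n_st):
            nodes.append(pts[i])  # hub
            ring = (pts[i][None, :] + r * np.cos(ang)[:, None] * normals[i]
                    + r * np.sin(ang)[:, None] * binormals[i])
            nodes.extend(ring)
        nodes = np.array(nodes)
        per_station = n_theta + 1

        def nid(st, j):  # j = -1 hub, 0..n_theta-1 ring
            return st * per_station + (0 if j == -1 else 1 + (j % n_theta))

        tets = []
        for i in range(n_st - 1):
            for j in range(n_theta):
                # wedge prism between triangle (hub, j, j+1) at stations i, i+1
                a0, b0, c0 = nid(i, -1), nid(i, j), nid(i, j + 1)
                a1, b1, c1 = nid(i + 1, -1), nid(i + 1, j), nid(i + 1, j + 1)
                tets += [[a0, b0, c0, a1], [b0, c0, a1, b1], [c0, a1, b1, c1]]
        tets = np.array(tets)
        prox = np.arange(per_station)
        dist = np.arange(per_station) + (n_st - 1) * per_station
    else:
        w, t = trajectory.width, trajectory.thickness
        corners = np.array([[-w / 2, -t / 2], [w / 2, -t / 2],
                            [w / 2, t / 2], [-w / 2, t / 2]])
        for i in range(n_st):
            for u, v in corners:
                nodes.append(pts[i] + u * normals[i] + v * binormals[i])
        nodes = np.array(nodes)
        per_station = 4

        def nid(st, j):
            return st * per_station + j

        tets = []
        for i in range(n_st - 1):
            a = [nid(i, j) for j in range(4)] + [nid(i + 1, j) for j in range(4)]
            # hexahedron a0..a7 -> 6 tets (standard corner split)
            h = a
            tets += [[h[0], h[1], h[2], h[6]], [h[0], h[2], h[3], h[6]],
                     [h[0], h[3], h[7], h[6]], [h[0], h[7], h[4], h[6]],
                     [h[0], h[4], h[5], h[6]], [h[0], h[5], h[1], h[6]]]
        tets = np.array(tets)
        prox = np.arange(per_station)
        dist = np.arange(per_station) + (n_st - 1) * per_station

    # a turning radius below the cross-section size inverts swept cells:
    # detect via mixed signs of the raw signed volumes before normalization
    p = nodes[tets]
    sv = np.einsum("ij,ij->i", p[:, 1] - p[:, 0],
                   np.cross(p[:, 2] - p[:, 0], p[:, 3] - p[:, 0])) / 6.0
    if np.any(sv == 0) or (np.any(sv > 0) and np.any(sv < 0)):
        raise GeometryError(
            "trajectory turning radius below cross-section size: swept cells invert")

    return LabeledTetMesh(nodes, tets, name=name,
                          node_sets={"proximal_end": prox, "distal_end": dist})


def box_tet_mesh(size, edge_length: float, origin=(0.0, 0.0, 0.0),
                 name: str = "box") -> LabeledTetMesh:
    """Structured tetrahedral mesh of an axis-aligned box.

    The box of dimensions ``size`` (mm) is divided into cubic cells of target
    ``edge_length`` and each cell into 6 tetrahedra; exact total volume.
    """
    size = np.asarray(size, dtype=float)
    origin = np.asarray(origin, dtype=float)
    if np.any(size <= 0) or edge_length <= 0:
        raise GeometryError("box size and edge length must be positive")
    counts = np.maximum(1, np.round(size / edge_length).astype(int))
    nx, ny, nz = counts
    xs = [np.linspace(0, size[i], counts[i] + 1) + origin[i] for i in range(3)]
    X, Y, Z = np.meshgrid(*xs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def gid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    i, j, k = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                          indexing="ij")
    i, j, k = i.ravel(), j.ravel(), k.ravel()
    c = np.stack([gid(i, j, k), gid(i + 1, j, k), gid(i + 1, j + 1, k),
                  gid(i, j + 1, k), gid(i, j, k + 1), gid(i + 1, j, k + 1),
                  gid(i + 1, j + 1, k + 1), gid(i, j + 1, k + 1)], axis=1)
    splits = [[0, 1, 2, 6], [0, 2, 3, 6], [0, 3, 7, 6],
              [0, 7, 4, 6], [0, 4, 5, 6], [0, 5, 1, 6]]
    tets = np.concatenate([c[:, s] for s in splits], axis=0)
    return LabeledTetMesh(nodes, tets, name=name)
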