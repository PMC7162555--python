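"""Surface and tetrahedral mesh data model, I/O and quality metrics.

The central object is :class:`SurfaceMesh`: an indexed triangle soup with
per-face integer markers, oriented counter-clockwise as seen from outside.
Everything downstream (smoothing, decimation, Betti numbers, curvature,
finite elements) consumes this representation.

Coordinates are unitless lengths; by convention the simulation layer
interprets them as micrometres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MeshError",
    "MeshFormatError",
    "MeshValidationError",
    "SurfaceMesh",
    "TetMesh",
    "MeshQualityReport",
    "load_surface",
    "save_surface",
    "classify_manifold",
    "vertex_normal",
    "vertex_normals",
    "face_normals",
    "ring_neighborhood",
    "ordered_one_ring",
    "radius_ratio_triangle",
    "radius_ratio_tet",
    "quality_report",
    "edge_flip",
    "angle_flip_pass",
    "NON_MANIFOLD",
    "MANIFOLD_WITH_BOUNDARY",
    "CLOSED_MANIFOLD",
]

NON_MANIFOLD = "non_manifold"
MANIFOLD_WITH_BOUNDARY = "manifold_with_boundary"
CLOSED_MANIFOLD = "closed_manifold"


class MeshError(Exception):
    """Base class for mesh errors."""


class MeshFormatError(MeshError):
    """A file could not be parsed under the named dialect."""


class MeshValidationError(MeshError):
    """Mesh data violates a structural invariant."""


# ---------------------------------------------------------------------------
# Surface mesh
# ---------------------------------------------------------------------------


class SurfaceMesh:
    """Triangulated surface: vertices, oriented faces, per-face markers.

    Parameters
    ----------
    vertices : (V, 3) float array
        Vertex positions.
    faces : (F, 3) int array
        0-based vertex indices, counter-clockwise seen from outside.
    face_markers : (F,) int array, optional
        Integer boundary markers; 0 means unmarked.
    validate : bool
        Check index ranges, degenerate faces and duplicate faces.
    """

    def __init__(self, vertices, faces, face_markers=None, validate=True):
        self.vertices = np.asarray(vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(faces, dtype=np.int64).reshape(-1, 3)
        if face_markers is None:
            self.face_markers = np.zeros(len(self.faces), dtype=np.int64)
        else:
            self.face_markers = np.asarray(face_markers, dtype=np.int64).reshape(-1)
            if len(self.face_markers) != len(self.faces):
                raise MeshValidationError(
                    "face_markers length %d != face count %d"
                    % (len(self.face_markers), len(self.faces))
                )
        self._cache: dict = {}
        if validate:
            self._validate()

    # -- structural invariants ------------------------------------------------

    def _validate(self):
        V = len(self.vertices)
        if len(self.faces):
            if self.faces.min() < 0 or self.faces.max() >= V:
                raise MeshValidationError(
                    "face index out of range [0, %d)" % V
                )
            f = self.faces
            if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
                bad = np.where(
                    (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
                )[0][0]
                raise MeshValidationError("face %d repeats a vertex" % bad)
            key = np.sort(f, axis=1)
            uniq = np.unique(key, axis=0)
            if len(uniq) != len(f):
                raise MeshValidationError("two faces share the same vertex set")

    # -- derived structure (cached, invalidated on mutation) -------------------

    def invalidate(self):
        """Drop cached adjacency after any in-place mutation."""
        self._cache.clear()

    @property
    def n_vertices(self):
        return len(self.vertices)

    @property
    def n_faces(self):
        return len(self.faces)

    @property
    def edge_faces(self):
        """dict mapping sorted vertex pair -> list of incident face ids."""
        if "edge_faces" not in self._cache:
            ef: dict = {}
            for fi, (a, b, c) in enumerate(self.faces):
                for u, v in ((a, b), (b, c), (c, a)):
                    key = (u, v) if u < v else (v, u)
                    ef.setdefault(key, []).append(fi)
            self._cache["edge_faces"] = ef
        return self._cache["edge_faces"]

    @property
    def vertex_faces(self):
        """list of incident face-id lists, one per vertex."""
        if "vertex_faces" not in self._cache:
            vf = [[] for _ in range(self.n_vertices)]
            for fi, face in enumerate(self.faces):
                for v in face:
                    vf[v].append(fi)
            self._cache["vertex_faces"] = vf
        return self._cache["vertex_faces"]

    @property
    def n_edges(self):
        return len(self.edge_faces)

    def boundary_vertices(self):
        """Set of vertices on edges with exactly one incident face."""
        if "boundary_vertices" not in self._cache:
            bv = set()
            for (u, v), fids in self.edge_faces.items():
                if len(fids) == 1:
                    bv.add(u)
                    bv.add(v)
            self._cache["boundary_vertices"] = bv
        return self._cache["boundary_vertices"]

    def copy(self):
        return SurfaceMesh(
            self.vertices.copy(), self.faces.copy(), self.face_markers.copy(),
            validate=False,
        )

    def __repr__(self):
        return "SurfaceMesh(V=%d, F=%d)" % (self.n_vertices, self.n_faces)


# ---------------------------------------------------------------------------
# Tetrahedral mesh
# ---------------------------------------------------------------------------


def _tet_signed_volume(p):
    return float(np.linalg.det(np.array([p[1] - p[0], p[2] - p[0], p[3] - p[0]]))) / 6.0


class TetMesh:
    """Tetrahedral mesh with positively oriented tets and marker metadata.

    Tets with negative signed volume are repaired by swapping two vertices;
    degenerate tets raise.  ``boundary_faces`` are the triangles incident to
    exactly one tet, oriented outward; ``boundary_face_markers`` is aligned
    with them.
    """

    def __init__(self, vertices, tets, region_markers=None,
                 boundary_face_markers=None):
        self.vertices = np.asarray(vertices, dtype=np.float64).reshape(-1, 3)
        tets = np.asarray(tets, dtype=np.int64).reshape(-1, 4)
        v = self.vertices
        a = v[tets[:, 1]] - v[tets[:, 0]]
        b = v[tets[:, 2]] - v[tets[:, 0]]
        c = v[tets[:, 3]] - v[tets[:, 0]]
        vol6 = np.einsum("ij,ij->i", np.cross(a, b), c)
        scale = np.abs(v).max() if len(v) else 1.0
        if np.any(np.abs(vol6) <= 1e-14 * max(scale, 1.0) ** 3):
            raise MeshValidationError("degenerate (zero-volume) tetrahedron")
        neg = vol6 < 0
        if np.any(neg):
            tets = tets.copy()
            tets[neg] = tets[neg][:, [0, 2, 1, 3]]
        self.tets = tets
        if region_markers is None:
            self.region_markers = np.zeros(len(tets), dtype=np.int64)
        else:
            self.region_markers = np.asarray(region_markers, dtype=np.int64).reshape(-1)
        self.boundary_faces, self._boundary_tets = self._compute_boundary()
        if boundary_face_markers is None:
            self.boundary_face_markers = np.zeros(len(self.boundary_faces),
                                                  dtype=np.int64)
        else:
            self.boundary_face_markers = np.asarray(
                boundary_face_markers, dtype=np.int64).reshape(-1)
            if len(self.boundary_face_markers) != len(self.boundary_faces):
                raise MeshValidationError("boundary marker count mismatch")

    @property
    def n_vertices(self):
        return len(self.vertices)

    @property
    def n_tets(self):
        return len(self.tets)

    def tet_volumes(self):
        v = self.vertices
        t = self.tets
        a = v[t[:, 1]] - v[t[:, 0]]
        b = v[t[:, 2]] - v[t[:, 0]]
        c = v[t[:, 3]] - v[t[:, 0]]
        return np.einsum("ij,ij->i", np.cross(a, b), c) / 6.0

    def _compute_boundary(self):
        # Each tet face listed with outward orientation for a positive tet.
        oriented = [(1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1)]
        count: dict = {}
        rep: dict = {}
        for ti, tet in enumerate(self.tets):
            for loc in oriented:
                tri = (tet[loc[0]], tet[loc[1]], tet[loc[2]])
                key = tuple(sorted(tri))
                count[key] = count.get(key, 0) + 1
                rep[key] = (tri, ti)
        bfaces = []
        btets = []
        for key in sorted(k for k, n in count.items() if n == 1):
            tri, ti = rep[key]
            bfaces.append(tri)
            btets.append(ti)
        return (np.array(bfaces, dtype=np.int64).reshape(-1, 3),
                np.array(btets, dtype=np.int64))

    def __repr__(self):
        return "TetMesh(V=%d, T=%d)" % (self.n_vertices, self.n_tets)


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------


def face_normals(mesh, unit=True):
    """(F, 3) face normals; unit length unless ``unit=False`` (then 2*area)."""
    v = mesh.vertices
    f = mesh.faces
    n = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    if unit:
        norms = np.linalg.norm(n, axis=1)
        norms[norms == 0] = 1.0
        n = n / norms[:, None]
    return n


def _corner_angles(mesh):
    """(F, 3) interior angle at each face corner, radians."""
    v = mesh.vertices
    f = mesh.faces
    p0, p1, p2 = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    angles = np.empty((len(f), 3))
    for k, (a, b, c) in enumerate(((p0, p1, p2), (p1, p2, p0), (p2, p0, p1))):
        u = b - a
        w = c - a
        nu = np.linalg.norm(u, axis=1)
        nw = np.linalg.norm(w, axis=1)
        denom = np.where(nu * nw == 0, 1.0, nu * nw)
        cosang = np.clip(np.einsum("ij,ij->i", u, w) / denom, -1.0, 1.0)
        angles[:, k] = np.arccos(cosang)
    return angles


def vertex_normals(mesh):
    """(V, 3) unit vertex normals: angle-weighted average of face normals.

    The weight of each incident face is the interior angle at the vertex.
    Angle weighting is robust to sliver faces, which area weighting
    over-emphasises.  Vertices with no incident face get a zero normal.
    """
    fn = face_normals(mesh)
    ang = _corner_angles(mesh)
    acc = np.zeros((mesh.n_vertices, 3))
    for k in range(3):
        np.add.at(acc, mesh.faces[:, k], fn * ang[:, k][:, None])
    norms = np.linalg.norm(acc, axis=1)
    nz = norms > 0
    acc[nz] /= norms[nz][:, None]
    return acc


def vertex_normal(mesh, v):
    """Unit normal at vertex ``v`` (angle-weighted incident face normals)."""
    if not mesh.vertex_faces[v]:
        raise MeshValidationError("vertex %d has no incident face" % v)
    fids = mesh.vertex_faces[v]
    acc = np.zeros(3)
    for fi in fids:
        face = mesh.faces[fi]
        i = int(np.where(face == v)[0][0])
        a = mesh.vertices[face[i]]
        b = mesh.vertices[face[(i + 1) % 3]]
        c = mesh.vertices[face[(i + 2) % 3]]
        n = np.cross(b - a, c - a)
        nn = np.linalg.norm(n)
        if nn == 0:
            continue
        u, w = b - a, c - a
        du, dw = np.linalg.norm(u), np.linalg.norm(w)
        ang = math.acos(max(-1.0, min(1.0, float(np.dot(u, w)) / (du * dw))))
        acc += ang * n / nn
    nn = np.linalg.norm(acc)
    if nn == 0:
        raise MeshValidationError("degenerate normal at vertex %d" % v)
    return acc / nn


# ---------------------------------------------------------------------------
# Manifoldness and orientation
# ---------------------------------------------------------------------------


def _vertex_star_ok(mesh, v):
    """True if the faces around ``v`` form a single fan (disk or half-disk)."""
    fids = mesh.vertex_faces[v]
    if not fids:
        return True
    # Link graph: each incident face contributes the edge opposite to v.
    deg: dict = {}
    edges = []
    for fi in fids:
        others = [int(x) for x in mesh.faces[fi] if x != v]
        edges.append(tuple(others))
        for u in others:
            deg[u] = deg.get(u, 0) + 1
    if any(d > 2 for d in deg.values()):
        return False
    # Connectivity of the link.
    adj: dict = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    start = edges[0][0]
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for w in adj[u]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    if len(seen) != len(adj):
        return False
    n_ends = sum(1 for d in deg.values() if d == 1)
    return n_ends in (0, 2)


def _check_orientable(mesh):
    """Propagate orientation across face adjacency; True if no conflict.

    Only meaningful where every edge has at most two incident faces.
    Returns (orientable, flips) where ``flips`` is a boolean array marking
    faces whose orientation disagrees with the propagated assignment.
    """
    F = mesh.n_faces
    flips = np.zeros(F, dtype=bool)
    visited = np.zeros(F, dtype=bool)
    ef = mesh.edge_faces

    def directed_edges(fi):
        a, b, c = mesh.faces[fi]
        return ((a, b), (b, c), (c, a))

    for seed in range(F):
        if visited[seed]:
            continue
        visited[seed] = True
        stack = [seed]
        while stack:
            fi = stack.pop()
            for (u, v) in directed_edges(fi):
                if flips[fi]:
                    u, v = v, u
                key = (u, v) if u < v else (v, u)
                for fj in ef[key]:
                    if fj == fi:
                        continue
                    # fj's stored traversal of this edge
                    p, q = next(
                        (p, q) for (p, q) in directed_edges(fj)
                        if {p, q} == {u, v}
                    )
                    # Consistency requires fj's effective traversal be (v, u).
                    required = (p, q) != (v, u)
                    if visited[fj]:
                        if bool(flips[fj]) != required:
                            return False, flips
                    else:
                        flips[fj] = required
                        visited[fj] = True
                        stack.append(fj)
    return True, flips


def classify_manifold(mesh):
    """Classify a surface mesh.

    Returns
    -------
    (classification, orientable) : (str, bool)
        classification is one of ``non_manifold``,
        ``manifold_with_boundary``, ``closed_manifold``.  A mesh is
        non-manifold if some edge has three or more incident faces or some
        vertex star is not a single fan.  It is closed if additionally every
        edge has exactly two faces.
    """
    ef = mesh.edge_faces
    if any(len(f) > 2 for f in ef.values()):
        return NON_MANIFOLD, False
    used = set(int(x) for x in mesh.faces.ravel())
    for v in used:
        if not _vertex_star_ok(mesh, v):
            return NON_MANIFOLD, False
    orientable, _ = _check_orientable(mesh)
    if all(len(f) == 2 for f in ef.values()) and len(ef) > 0:
        return CLOSED_MANIFOLD, orientable
    return MANIFOLD_WITH_BOUNDARY, orientable


def reorient_consistently(mesh):
    """Repair inconsistent orientation in place (manifold, orientable mesh).

    After propagation, a closed mesh is flipped globally if its signed
    volume is negative, so outward orientation is canonical.
    """
    orientable, flips = _check_orientable(mesh)
    if not orientable:
        raise MeshValidationError("mesh is not orientable")
    if np.any(flips):
        f = mesh.faces
        f[flips] = f[flips][:, [0, 2, 1]]
        mesh.invalidate()
    cls, _ = classify_manifold(mesh)
    if cls == CLOSED_MANIFOLD and enclosed_volume(mesh) < 0:
        mesh.faces = mesh.faces[:, [0, 2, 1]]
        mesh.invalidate()
    return mesh


# ---------------------------------------------------------------------------
# Neighborhoods
# ---------------------------------------------------------------------------


def ordered_one_ring(mesh, v):
    """Cyclically ordered 1-ring of ``v``.

    Returns (ring, closed): ``ring`` lists edge-adjacent vertices following
    the face orientation (counter-clockwise seen from outside); ``closed``
    is False for boundary vertices, where the ring is an open path.
    Raises for non-manifold stars.
    """
    fids = mesh.vertex_faces[v]
    if not fids:
        raise MeshValidationError("vertex %d has no incident face" % v)
    succ: dict = {}
    for fi in fids:
        face = mesh.faces[fi]
        i = int(np.where(face == v)[0][0])
        p = int(face[(i + 1) % 3])
        q = int(face[(i + 2) % 3])
        if p in succ:
            raise MeshValidationError("non-manifold star at vertex %d" % v)
        succ[p] = q
    starts = set(succ) - set(succ.values())
    if starts:
        if len(starts) != 1:
            raise MeshValidationError("non-manifold star at vertex %d" % v)
        start = starts.pop()
        closed = False
    else:
        start = min(succ)
        closed = True
    ring = [start]
    while True:
        nxt = succ.get(ring[-1])
        if nxt is None or nxt == start:
            break
        ring.append(nxt)
        if len(ring) > len(succ) + 1:
            raise MeshValidationError("non-manifold star at vertex %d" % v)
    if not closed and len(ring) != len(succ) + 1:
        raise MeshValidationError("non-manifold star at vertex %d" % v)
    return ring, closed


def ring_neighborhood(mesh, v, r):
    """Vertices within ``r`` edge hops of ``v`` (excluding ``v``).

    Returns (neighbors, ordered).  For ``r == 1`` on a manifold star the
    list is cyclically ordered and ``ordered`` is True; otherwise vertices
    are in breadth-first order and ``ordered`` is False (warning flag).
    """
    if r < 1:
        raise ValueError("ring count must be >= 1")
    try:
        ring, _closed = ordered_one_ring(mesh, v)
        ordered = True
    except MeshValidationError:
        ring = sorted(
            {int(u) for fi in mesh.vertex_faces[v] for u in mesh.faces[fi]} - {v}
        )
        ordered = False
    if r == 1:
        return ring, ordered
    seen = {v} | set(ring)
    out = list(ring)
    frontier = list(ring)
    for _ in range(r - 1):
        nxt = []
        for u in frontier:
            for fi in mesh.vertex_faces[u]:
                for w in mesh.faces[fi]:
                    w = int(w)
                    if w not in seen:
                        seen.add(w)
                        nxt.append(w)
        out.extend(nxt)
        frontier = nxt
    return out, ordered


# ---------------------------------------------------------------------------
# Element quality
# ---------------------------------------------------------------------------


def radius_ratio_triangle(p, q, r):
    """2 * inradius / circumradius of a triangle; 0 for degenerate input."""
    p, q, r = (np.asarray(x, dtype=float) for x in (p, q, r))
    a = np.linalg.norm(q - r)
    b = np.linalg.norm(p - r)
    c = np.linalg.norm(p - q)
    area2 = np.linalg.norm(np.cross(q - p, r - p))  # = 2 * area
    s = max(a, b, c)
    if s == 0 or area2 <= 1e-14 * s * s:
        return 0.0
    r_in = area2 / (a + b + c)
    r_circ = a * b * c / (2.0 * area2)
    return float(min(1.0, 2.0 * r_in / r_circ))


def radius_ratio_tet(a, b, c, d):
    """3 * insphere radius / circumsphere radius of a tet; 0 if degenerate."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    vol = abs(_tet_signed_volume([a, b, c, d]))
    scale = max(np.linalg.norm(x - a) for x in (b, c, d))
    if scale == 0 or vol <= 1e-14 * scale ** 3:
        return 0.0
    area = 0.0
    for (p, q, r) in ((a, b, c), (a, b, d), (a, c, d), (b, c, d)):
        area += 0.5 * np.linalg.norm(np.cross(q - p, r - p))
    r_in = 3.0 * vol / area
    # Circumcenter from |x - v_i|^2 equalities.
    A = 2.0 * np.array([b - a, c - a, d - a])
    rhs = np.array([
        np.dot(b, b) - np.dot(a, a),
        np.dot(c, c) - np.dot(a, a),
        np.dot(d, d) - np.dot(a, a),
    ])
    center = np.linalg.solve(A, rhs)
    r_circ = np.linalg.norm(center - a)
    return float(min(1.0, 3.0 * r_in / r_circ))


def surface_area(mesh):
    return float(np.linalg.norm(face_normals(mesh, unit=False), axis=1).sum() / 2.0)


def enclosed_volume(mesh):
    """Signed enclosed volume by the divergence theorem (closed surfaces)."""
    v = mesh.vertices
    f = mesh.faces
    return float(
        np.einsum(
            "ij,ij->i", np.cross(v[f[:, 0]], v[f[:, 1]]), v[f[:, 2]]
        ).sum() / 6.0
    )


@dataclass
class MeshQualityReport:
    """Angle and radius-ratio statistics of a surface or tet mesh."""

    angle_list: np.ndarray
    angle_mean: float
    angle_std: float
    angle_min: float
    angle_max: float
    triangle_radius_ratios: np.ndarray
    tet_radius_ratios: np.ndarray
    surface_area: float
    enclosed_volume: float | None
    n_vertices: int
    n_edges: int
    n_faces: int
    n_tets: int = 0

    def summary(self):
        lines = [
            "vertices %d  edges %d  faces %d" % (self.n_vertices, self.n_edges,
                                                 self.n_faces),
            "angles (deg): mean %.3f  std %.3f  min %.3f  max %.3f"
            % (self.angle_mean, self.angle_std, self.angle_min, self.angle_max),
            "triangle radius-ratio: min %.4f  mean %.4f"
            % (self.triangle_radius_ratios.min() if len(self.triangle_radius_ratios) else 0.0,
               self.triangle_radius_ratios.mean() if len(self.triangle_radius_ratios) else 0.0),
            "surface area: %.6g" % self.surface_area,
        ]
        if self.enclosed_volume is not None:
            lines.append("enclosed volume: %.6g" % self.enclosed_volume)
        else:
            lines.append("enclosed volume: n/a (open or non-orientable surface)")
        if self.n_tets:
            lines.append("tets %d  tet radius-ratio: min %.4f  mean %.4f"
                         % (self.n_tets, self.tet_radius_ratios.min(),
                            self.tet_radius_ratios.mean()))
        return "\n".join(lines)


def _surface_quality(mesh):
    ang = np.degrees(_corner_angles(mesh)).ravel()
    rr = np.array([
        radius_ratio_triangle(*mesh.vertices[f]) for f in mesh.faces
    ])
    cls, orientable = classify_manifold(mesh)
    vol = None
    if cls == CLOSED_MANIFOLD and orientable:
        vol = enclosed_volume(mesh)
    return ang, rr, surface_area(mesh), vol


def quality_report(mesh):
    """Angle/radius-ratio/area/volume statistics for a mesh.

    For a :class:`TetMesh`, triangle statistics are computed on the
    boundary surface, tet radius-ratios on the tets, and the volume is the
    sum of tet volumes.  Enclosed volume of an open surface is reported as
    ``None`` (absent), never zero.
    """
    if isinstance(mesh, TetMesh):
        surf = SurfaceMesh(mesh.vertices, mesh.boundary_faces, validate=False)
        ang, rr, area, _ = _surface_quality(surf)
        trr = np.array([
            radius_ratio_tet(*mesh.vertices[t]) for t in mesh.tets
        ])
        vol = float(mesh.tet_volumes().sum())
        return MeshQualityReport(
            angle_list=ang,
            angle_mean=float(ang.mean()), angle_std=float(ang.std()),
            angle_min=float(ang.min()), angle_max=float(ang.max()),
            triangle_radius_ratios=rr, tet_radius_ratios=trr,
            surface_area=area, enclosed_volume=vol,
            n_vertices=mesh.n_vertices, n_edges=len(surf.edge_faces),
            n_faces=len(surf.faces), n_tets=mesh.n_tets,
        )
    ang, rr, area, vol = _surface_quality(mesh)
    return MeshQualityReport(
        angle_list=ang,
        angle_mean=float(ang.mean()), angle_std=float(ang.std()),
        angle_min=float(ang.min()), angle_max=float(ang.max()),
        triangle_radius_ratios=rr, tet_radius_ratios=np.array([]),
        surface_area=area, enclosed_volume=vol,
        n_vertices=mesh.n_vertices, n_edges=mesh.n_edges,
        n_faces=mesh.n_faces,
    )


# ---------------------------------------------------------------------------
# Edge flipping
# ---------------------------------------------------------------------------


def _flip_config(mesh, edge):
    """Resolve the two faces and opposite vertices of an interior edge.

    Returns (f1, f2, a, b, c, d) such that face f1 = (a, b, c) and
    f2 = (b, a, d) up to cyclic rotation, or raises with a reason.
    """
    u, v = edge
    key = (u, v) if u < v else (v, u)
    fids = mesh.edge_faces.get(key)
    if fids is None:
        raise MeshValidationError("edge %s does not exist" % (key,))
    if len(fids) == 1:
        raise MeshValidationError("edge %s is a boundary edge" % (key,))
    if len(fids) > 2:
        raise MeshValidationError("edge %s is non-manifold" % (key,))
    f1, f2 = fids
    face1 = [int(x) for x in mesh.faces[f1]]
    # orient so face1 traverses a -> b
    for i in range(3):
        a, b = face1[i], face1[(i + 1) % 3]
        if {a, b} == set(key):
            c = face1[(i + 2) % 3]
            break
    face2 = [int(x) for x in mesh.faces[f2]]
    d = next(x for x in face2 if x not in key)
    return f1, f2, a, b, c, d


def _min_angle(p, q, r):
    ang = []
    for (x, y, z) in ((p, q, r), (q, r, p), (r, p, q)):
        ux, uy, uz = y[0] - x[0], y[1] - x[1], y[2] - x[2]
        wx, wy, wz = z[0] - x[0], z[1] - x[1], z[2] - x[2]
        du = math.sqrt(ux * ux + uy * uy + uz * uz)
        dw = math.sqrt(wx * wx + wy * wy + wz * wz)
        if du == 0 or dw == 0:
            return 0.0
        c = (ux * wx + uy * wy + uz * wz) / (du * dw)
        ang.append(math.acos(max(-1.0, min(1.0, c))))
    return min(ang)


def edge_flip(mesh, edge):
    """Flip an interior edge to the opposite diagonal, in place.

    The faces (a, b, c) and (b, a, d) become (a, d, c) and (d, b, c),
    preserving orientation consistency.  Rejected (raises
    MeshValidationError) for boundary or non-manifold edges, and for flips
    that would duplicate an existing face or create a non-manifold edge.
    """
    f1, f2, a, b, c, d = _flip_config(mesh, edge)
    key_cd = (c, d) if c < d else (d, c)
    if key_cd in mesh.edge_faces:
        raise MeshValidationError(
            "flip of edge %s would create duplicate/non-manifold edge %s"
            % (tuple(edge), key_cd))
    mesh.faces[f1] = (a, d, c)
    mesh.faces[f2] = (d, b, c)
    mesh.invalidate()
    return mesh


def _cross3(u, w):
    return (u[1] * w[2] - u[2] * w[1],
            u[2] * w[0] - u[0] * w[2],
            u[0] * w[1] - u[1] * w[0])


def _dot3(u, w):
    return u[0] * w[0] + u[1] * w[1] + u[2] * w[2]


def _sub3(u, w):
    return (u[0] - w[0], u[1] - w[1], u[2] - w[2])


def angle_flip_pass(mesh, max_rounds=20):
    """Flip every interior edge whose flip raises the local minimum angle.

    A flip is applied iff the minimum of the six post-flip angles exceeds
    the minimum of the six pre-flip angles and neither new face normal
    opposes the mean of the two old face normals.  The sweep repeats to a
    fixpoint (or ``max_rounds``), revisiting only edges whose surrounding
    geometry changed.  Returns the number of flips applied.
    """
    faces = [tuple(int(x) for x in tri) for tri in mesh.faces]
    ef: dict = {}
    for fi, (a, b, c) in enumerate(faces):
        for u, v in ((a, b), (b, c), (c, a)):
            key = (u, v) if u < v else (v, u)
            ef.setdefault(key, []).append(fi)
    pos = [tuple(p) for p in mesh.vertices]
    total = 0
    dirty = sorted(ef.keys())
    for _ in range(max_rounds):
        flips_this_round = 0
        next_dirty: set = set()
        for key in dirty:
            fids = ef.get(key)
            if fids is None or len(fids) != 2:
                continue
            f1, f2 = fids
            face1 = faces[f1]
            a = b = c = None
            for i in range(3):
                if {face1[i], face1[(i + 1) % 3]} == set(key):
                    a, b = face1[i], face1[(i + 1) % 3]
                    c = face1[(i + 2) % 3]
                    break
            d = next(x for x in faces[f2] if x not in key)
            key_cd = (c, d) if c < d else (d, c)
            if key_cd in ef:
                continue
            pa, pb, pc, pd = pos[a], pos[b], pos[c], pos[d]
            pre = min(_min_angle(pa, pb, pc), _min_angle(pb, pa, pd))
            post = min(_min_angle(pa, pd, pc), _min_angle(pd, pb, pc))
            if post <= pre:
                continue
            mean_old = tuple(
                x + y for x, y in zip(_cross3(_sub3(pb, pa), _sub3(pc, pa)),
                                      _cross3(_sub3(pa, pb), _sub3(pd, pb))))
            if (_dot3(_cross3(_sub3(pd, pa), _sub3(pc, pa)), mean_old) <= 0
                    or _dot3(_cross3(_sub3(pb, pd), _sub3(pc, pd)),
                             mean_old) <= 0):
                continue
            # apply: (a,b,c),(b,a,d) -> (a,d,c),(d,b,c)
            faces[f1] = (a, d, c)
            faces[f2] = (d, b, c)
            del ef[key]
            ef[key_cd] = [f1, f2]

            def _replace(u, v, old, new):
                k = (u, v) if u < v else (v, u)
                lst = ef[k]
                lst[lst.index(old)] = new

            _replace(b, c, f1, f2)
            _replace(a, d, f2, f1)
            flips_this_round += 1
            for u, v in ((a, c), (b, c), (a, d), (b, d)):
                k = (u, v) if u < v else (v, u)
                next_dirty.add(k)
                for fx in ef.get(k, ()):
                    fa, fb, fc = faces[fx]
                    for kk in ((fa, fb), (fb, fc), (fc, fa)):
                        next_dirty.add(kk if kk[0] < kk[1] else (kk[1], kk[0]))
            next_dirty.add(key_cd)
        total += flips_this_round
        if flips_this_round == 0:
            break
        dirty = sorted(next_dirty)
    if total:
        mesh.faces = np.array(faces, dtype=np.int64)
        mesh.invalidate()
    return total


# ---------------------------------------------------------------------------
# File I/O: OFF / OBJ / PLY (ASCII)
# ---------------------------------------------------------------------------

_FORMATS = ("off", "obj", "ply")


def _infer_format(path, fmt):
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in _FORMATS:
            raise MeshFormatError("unknown format %r" % fmt)
        return fmt
    ext = str(path).rsplit(".", 1)[-1].lower()
    if ext not in _FORMATS:
        raise MeshFormatError("cannot infer format from extension %r" % ext)
    return ext


def _fan(poly):
    return [(poly[0], poly[i], poly[i + 1]) for i in range(1, len(poly) - 1)]


def _parse_off(lines):
    rows = [(i + 1, ln.split("#")[0].strip()) for i, ln in enumerate(lines)]
    rows = [(no, ln) for no, ln in rows if ln]
    if not rows or rows[0][1].upper() != "OFF":
        raise MeshFormatError("line 1: missing OFF header")
    try:
        counts = rows[1][1].split()
        nv, nf = int(counts[0]), int(counts[1])
    except (IndexError, ValueError):
        raise MeshFormatError("line %d: bad counts line" % rows[1][0])
    verts, faces = [], []
    idx = 2
    for _ in range(nv):
        no, ln = rows[idx]
        parts = ln.split()
        try:
            verts.append([float(x) for x in parts[:3]])
        except (IndexError, ValueError):
            raise MeshFormatError("line %d: bad vertex line" % no)
        idx += 1
    for _ in range(nf):
        no, ln = rows[idx]
        parts = ln.split()
        try:
            n = int(parts[0])
            poly = [int(x) for x in parts[1:1 + n]]
            if len(poly) != n or n < 3:
                raise ValueError
        except (IndexError, ValueError):
            raise MeshFormatError("line %d: bad face line" % no)
        faces.extend(_fan(poly))
        idx += 1
    return np.array(verts), np.array(faces), None


def _parse_obj(lines):
    verts, faces = [], []
    for i, ln in enumerate(lines):
        ln = ln.split("#")[0].strip()
        if not ln:
            continue
        parts = ln.split()
        if parts[0] == "v":
            try:
                verts.append([float(x) for x in parts[1:4]])
            except (IndexError, ValueError):
                raise MeshFormatError("line %d: bad vertex record" % (i + 1))
        elif parts[0] == "f":
            try:
                poly = [int(tok.split("/")[0]) - 1 for tok in parts[1:]]
                if len(poly) < 3:
                    raise ValueError
            except ValueError:
                raise MeshFormatError("line %d: bad face record" % (i + 1))
            faces.extend(_fan(poly))
    return np.array(verts), np.array(faces), None


def _parse_ply(lines):
    it = iter(enumerate(lines, start=1))

    def nextline():
        for no, ln in it:
            ln = ln.strip()
            if ln and not ln.startswith("comment"):
                return no, ln
        raise MeshFormatError("unexpected end of file")

    no, ln = nextline()
    if ln != "ply":
        raise MeshFormatError("line %d: missing ply magic" % no)
    no, ln = nextline()
    if not ln.startswith("format ascii"):
        raise MeshFormatError("line %d: only ASCII PLY is supported" % no)
    elements = []  # (name, count, [props]) where prop = (kind, name)
    while True:
        no, ln = nextline()
        parts = ln.split()
        if parts[0] == "end_header":
            break
        if parts[0] == "element":
            elements.append((parts[1], int(parts[2]), []))
        elif parts[0] == "property":
            if not elements:
                raise MeshFormatError("line %d: property before element" % no)
            if parts[1] == "list":
                elements[-1][2].append(("list", parts[-1]))
            else:
                elements[-1][2].append(("scalar", parts[-1]))
    verts, faces, markers = [], [], []
    for name, count, props in elements:
        for _ in range(count):
            no, ln = nextline()
            toks = ln.split()
            pos = 0
            fields = {}
            for kind, pname in props:
                try:
                    if kind == "list":
                        n = int(toks[pos])
                        fields[pname] = [int(x) for x in toks[pos + 1: pos + 1 + n]]
                        pos += 1 + n
                    else:
                        fields[pname] = float(toks[pos])
                        pos += 1
                except (IndexError, ValueError):
                    raise MeshFormatError("line %d: bad %s record" % (no, name))
            if name == "vertex":
                try:
                    verts.append([fields["x"], fields["y"], fields["z"]])
                except KeyError:
                    raise MeshFormatError("line %d: vertex lacks x/y/z" % no)
            elif name == "face":
                poly = fields.get("vertex_indices", fields.get("vertex_index"))
                if poly is None or len(poly) < 3:
                    raise MeshFormatError("line %d: bad face indices" % no)
                tris = _fan(poly)
                faces.extend(tris)
                mk = int(fields.get("marker", 0))
                markers.extend([mk] * len(tris))
    return np.array(verts), np.array(faces), (np.array(markers, dtype=np.int64)
                                              if markers else None)


def load_surface(path, format=None, repair_orientation=True):
    """Load an ASCII OFF/OBJ/PLY surface mesh.

    OBJ 1-based indices are converted to 0-based; non-triangular polygons
    are fan-triangulated; PLY recovers the integer ``marker`` face property
    (OFF/OBJ default all markers to 0).  If the mesh is manifold and
    orientable but inconsistently oriented, orientation is repaired by
    propagation, and closed meshes are flipped to positive signed volume.
    """
    fmt = _infer_format(path, format)
    try:
        with open(path, "r") as fh:
            lines = fh.readlines()
    except OSError as exc:
        raise MeshFormatError("cannot read %s: %s" % (path, exc))
    parser = {"off": _parse_off, "obj": _parse_obj, "ply": _parse_ply}[fmt]
    verts, faces, markers = parser(lines)
    if len(verts) == 0:
        raise MeshFormatError("%s: no vertices" % path)
    mesh = SurfaceMesh(verts, faces, markers)
    if repair_orientation and len(mesh.faces):
        cls, orientable = classify_manifold(mesh)
        if cls != NON_MANIFOLD and orientable:
            reorient_consistently(mesh)
    return mesh


def save_surface(mesh, path, format=None):
    """Write a surface mesh as ASCII OFF/OBJ/PLY.

    PLY carries face markers as an integer face property ``marker``;
    OFF and OBJ lose markers (documented format limitation).
    """
    fmt = _infer_format(path, format)
    v = mesh.vertices
    f = mesh.faces
    try:
        with open(path, "w") as fh:
            if fmt == "off":
                fh.write("OFF\n%d %d %d\n" % (len(v), len(f), mesh.n_edges))
                for p in v:
                    fh.write("%.17g %.17g %.17g\n" % tuple(p))
                for tri in f:
                    fh.write("3 %d %d %d\n" % tuple(tri))
            elif fmt == "obj":
                for p in v:
                    fh.write("v %.17g %.17g %.17g\n" % tuple(p))
                for tri in f:
                    fh.write("f %d %d %d\n" % (tri[0] + 1, tri[1] + 1, tri[2] + 1))
            else:
                fh.write("ply\nformat ascii 1.0\n")
                fh.write("element vertex %d\n" % len(v))
                fh.write("property float x\nproperty float y\nproperty float z\n")
                fh.write("element face %d\n" % len(f))
                fh.write("property list uchar int vertex_indices\n")
                fh.write("property int marker\n")
                fh.write("end_header\n")
                for p in v:
                    fh.write("%.17g %.17g %.17g\n" % tuple(p))
                for tri, mk in zip(f, mesh.face_markers):
                    fh.write("3 %d %d %d %d\n" % (tri[0], tri[1], tri[2], mk))
    except OSError as exc:
        raise MeshError("cannot write %s: %s" % (path, exc))
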