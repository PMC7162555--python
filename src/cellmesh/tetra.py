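"""Boundary marking and TetGen-dialect interchange.

Closed marked surfaces are grouped into a :class:`MarkedScene` (each with
an interior region seed point and region marker) and exported as a TetGen
ASCII ``.smesh`` piecewise-linear complex; the constrained Delaunay
tetrahedralization itself is delegated to TetGen or any compatible tool,
whose ``.node``/``.ele``/``.face`` output this module reads back into a
:class:`~cellmesh.core.TetMesh`.  Surfaces are screened for pairwise
intersection before export because TetGen fails opaquely on intersecting
input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    CLOSED_MANIFOLD,
    MeshFormatError,
    MeshValidationError,
    SurfaceMesh,
    TetMesh,
    classify_manifold,
)

__all__ = [
    "MarkedScene",
    "mark_faces",
    "point_in_surface",
    "surfaces_intersect",
    "write_tetgen_smesh",
    "read_tetgen_smesh",
    "read_tetgen_output",
    "boundary_surface_of",
]


# ---------------------------------------------------------------------------
# Face marking
# ---------------------------------------------------------------------------


def mark_faces(mesh, selector, marker):
    """Assign ``marker`` to the faces chosen by ``selector``, in place.

    ``selector`` is one of:
      * an iterable of face indices,
      * a centroid predicate ``f(centroid) -> bool``,
      * a pair ``(seed_face, hops)`` marking the edge-adjacency
        neighborhood of a seed face up to ``hops`` hops.

    Marker 0 is reserved for "unmarked" and refused.
    """
    if marker == 0:
        raise MeshValidationError("marker 0 is reserved for unmarked faces")
    if callable(selector):
        centroids = mesh.vertices[mesh.faces].mean(axis=1)
        idx = [i for i in range(mesh.n_faces) if selector(centroids[i])]
    elif (isinstance(selector, tuple) and len(selector) == 2
          and np.isscalar(selector[0]) and np.isscalar(selector[1])):
        seed, hops = int(selector[0]), int(selector[1])
        adj = [[] for _ in range(mesh.n_faces)]
        for fids in mesh.edge_faces.values():
            for a in fids:
                for b in fids:
                    if a != b:
                        adj[a].append(b)
        seen = {seed}
        frontier = [seed]
        for _ in range(hops):
            nxt = []
            for fi in frontier:
                for fj in adj[fi]:
                    if fj not in seen:
                        seen.add(fj)
                        nxt.append(fj)
            frontier = nxt
        idx = sorted(seen)
    else:
        idx = [int(i) for i in selector]
    for i in idx:
        mesh.face_markers[i] = marker
    return mesh


# ---------------------------------------------------------------------------
# Containment and intersection tests
# ---------------------------------------------------------------------------


def point_in_surface(point, mesh, rng_seed=0):
    """Ray-parity containment test against a closed surface.

    Casts a ray in a quasi-random direction and counts triangle
    crossings; retries with a new direction on near-degenerate hits.
    """
    p = np.asarray(point, dtype=float)
    v = mesh.vertices
    f = mesh.faces
    rng = np.random.default_rng(rng_seed)
    for _ in range(16):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        count = 0
        ok = True
        for tri in f:
            hit = _ray_triangle(p, d, v[tri[0]], v[tri[1]], v[tri[2]])
            if hit is None:
                continue
            t, degenerate = hit
            if degenerate:
                ok = False
                break
            if t > 0:
                count += 1
        if ok:
            return count % 2 == 1
    raise MeshValidationError("containment test failed to find a clean ray")


def _ray_triangle(orig, d, a, b, c, eps=1e-12):
    """Moeller-Trumbore; returns (t, degenerate_flag) or None for a miss."""
    e1 = b - a
    e2 = c - a
    pvec = np.cross(d, e2)
    det = float(np.dot(e1, pvec))
    if abs(det) < eps:
        return None
    inv = 1.0 / det
    tvec = orig - a
    u = float(np.dot(tvec, pvec)) * inv
    if u < -eps or u > 1 + eps:
        return None
    qvec = np.cross(tvec, e1)
    w = float(np.dot(d, qvec)) * inv
    if w < -eps or u + w > 1 + eps:
        return None
    t = float(np.dot(e2, qvec)) * inv
    border = min(u, w, 1 - u - w) < 1e-9
    return (t, border or abs(t) < 1e-12)


def _tri_tri_intersect(t1, t2, eps=1e-12):
    """Segment-vs-triangle test in both directions (robust enough for the
    screening use-case; shared-plane coplanar overlap is not detected)."""
    def seg_tri(p, q, a, b, c):
        d = q - p
        L = np.linalg.norm(d)
        if L < eps:
            return False
        hit = _ray_triangle(p, d / L, a, b, c)
        if hit is None:
            return False
        t, _ = hit
        return eps < t < L - eps

    a1, b1, c1 = t1
    a2, b2, c2 = t2
    for (p, q) in ((a1, b1), (b1, c1), (c1, a1)):
        if seg_tri(p, q, a2, b2, c2):
            return True
    for (p, q) in ((a2, b2), (b2, c2), (c2, a2)):
        if seg_tri(p, q, a1, b1, c1):
            return True
    return False


def surfaces_intersect(m1, m2):
    """Pairs of face indices (i, j) where triangles of m1 and m2 cross.

    A bounding-box prefilter keeps the O(n^2) candidate set small at desk
    scale.
    """
    v1, f1 = m1.vertices, m1.faces
    v2, f2 = m2.vertices, m2.faces
    lo1 = v1[f1].min(axis=1)
    hi1 = v1[f1].max(axis=1)
    lo2 = v2[f2].min(axis=1)
    hi2 = v2[f2].max(axis=1)
    pairs = []
    for i in range(len(f1)):
        overlap = np.all(lo1[i] <= hi2, axis=1) & np.all(hi1[i] >= lo2, axis=1)
        for j in np.where(overlap)[0]:
            if _tri_tri_intersect(v1[f1[i]], v2[f2[j]]):
                pairs.append((i, int(j)))
    return pairs


# ---------------------------------------------------------------------------
# Marked scenes
# ---------------------------------------------------------------------------


@dataclass
class MarkedScene:
    """Closed marked surfaces plus region seed points for tetrahedralization.

    ``region_points`` is a list of ((x, y, z), marker) pairs, each strictly
    inside at least one surface.  ``containment`` optionally declares
    nesting as (inner_surface_index, outer_surface_index) pairs.
    """

    surfaces: list
    region_points: list
    containment: list = field(default_factory=list)

    def validate(self):
        for k, s in enumerate(self.surfaces):
            cls, orientable = classify_manifold(s)
            if cls != CLOSED_MANIFOLD or not orientable:
                raise MeshValidationError(
                    "scene surface %d is not a closed orientable manifold" % k)
        for (pt, marker) in self.region_points:
            if not any(point_in_surface(pt, s) for s in self.surfaces):
                raise MeshValidationError(
                    "region point %s (marker %d) is not inside any surface"
                    % (tuple(pt), marker))
        for i in range(len(self.surfaces)):
            for j in range(i + 1, len(self.surfaces)):
                bad = surfaces_intersect(self.surfaces[i], self.surfaces[j])
                if bad:
                    raise MeshValidationError(
                        "surfaces %d and %d intersect at face pairs %s"
                        % (i, j, bad[:5]))
        return self


# ---------------------------------------------------------------------------
# TetGen ASCII dialects
# ---------------------------------------------------------------------------


def write_tetgen_smesh(scene, path):
    """Write a MarkedScene as a TetGen ``.smesh`` piecewise-linear complex.

    Vertices of all surfaces are merged into one node block; each facet
    carries its face marker; the hole block is empty; the region block
    lists the scene's seed points with their region markers.
    """
    scene.validate()
    offsets = []
    total = 0
    for s in scene.surfaces:
        offsets.append(total)
        total += s.n_vertices
    with open(path, "w") as fh:
        fh.write("# Part 1 - node list\n")
        fh.write("%d 3 0 0\n" % total)
        idx = 0
        for s in scene.surfaces:
            for p in s.vertices:
                fh.write("%d %.17g %.17g %.17g\n" % (idx, p[0], p[1], p[2]))
                idx += 1
        fh.write("# Part 2 - facet list\n")
        nfac = sum(s.n_faces for s in scene.surfaces)
        fh.write("%d 1\n" % nfac)
        for s, off in zip(scene.surfaces, offsets):
            for tri, mk in zip(s.faces, s.face_markers):
                fh.write("3 %d %d %d %d\n"
                         % (tri[0] + off, tri[1] + off, tri[2] + off, mk))
        fh.write("# Part 3 - hole list\n0\n")
        fh.write("# Part 4 - region list\n")
        fh.write("%d\n" % len(scene.region_points))
        for k, (pt, marker) in enumerate(scene.region_points):
            fh.write("%d %.17g %.17g %.17g %d\n"
                     % (k, pt[0], pt[1], pt[2], marker))


def _data_lines(path):
    try:
        with open(path) as fh:
            for no, ln in enumerate(fh, start=1):
                ln = ln.split("#")[0].strip()
                if ln:
                    yield no, ln
    except OSError as exc:
        raise MeshFormatError("cannot read %s: %s" % (path, exc))


def read_tetgen_smesh(path):
    """Re-parse a ``.smesh`` file into (vertices, faces, markers,
    region_points).  Used for round-trip verification of the writer."""
    lines = list(_data_lines(path))
    pos = 0

    def take():
        nonlocal pos
        no, ln = lines[pos]
        pos += 1
        return no, ln.split()

    no, head = take()
    nv = int(head[0])
    verts = np.empty((nv, 3))
    base = None
    for k in range(nv):
        no, row = take()
        i = int(row[0])
        if base is None:
            base = i
        verts[i - base] = [float(x) for x in row[1:4]]
    no, head = take()
    nf = int(head[0])
    has_marker = len(head) > 1 and int(head[1]) == 1
    faces = np.empty((nf, 3), dtype=np.int64)
    markers = np.zeros(nf, dtype=np.int64)
    for k in range(nf):
        no, row = take()
        n = int(row[0])
        if n != 3:
            raise MeshFormatError("line %d: only triangular facets supported" % no)
        faces[k] = [int(x) - base for x in row[1:4]]
        if has_marker and len(row) > 4:
            markers[k] = int(row[4])
    no, head = take()
    nholes = int(head[0])
    for _ in range(nholes):
        take()
    no, head = take()
    nregions = int(head[0])
    regions = []
    for _ in range(nregions):
        no, row = take()
        regions.append(((float(row[1]), float(row[2]), float(row[3])),
                        int(float(row[4]))))
    return verts, faces, markers, regions


def read_tetgen_output(node_path, ele_path, face_path=None):
    """Read TetGen ``.node``/``.ele``(/``.face``) files into a TetMesh.

    The first index (0 or 1 based) is auto-detected from the node file;
    per-tet region markers come from the first ``.ele`` attribute column
    and boundary-face markers from the ``.face`` marker column.
    """
    nlines = list(_data_lines(node_path))
    no, head = nlines[0][0], nlines[0][1].split()
    nv = int(head[0])
    if len(nlines) - 1 < nv:
        raise MeshFormatError(
            "%s line %d: %d nodes declared, %d found"
            % (node_path, no, nv, len(nlines) - 1))
    first_index = int(nlines[1][1].split()[0])
    if first_index not in (0, 1):
        raise MeshFormatError("%s line %d: cannot detect index base"
                              % (node_path, nlines[1][0]))
    verts = np.empty((nv, 3))
    for no, ln in nlines[1:nv + 1]:
        row = ln.split()
        try:
            verts[int(row[0]) - first_index] = [float(x) for x in row[1:4]]
        except (IndexError, ValueError):
            raise MeshFormatError("%s line %d: bad node record" % (node_path, no))

    elines = list(_data_lines(ele_path))
    no, head = elines[0][0], elines[0][1].split()
    nt = int(head[0])
    nattr = int(head[2]) if len(head) > 2 else 0
    if len(elines) - 1 < nt:
        raise MeshFormatError(
            "%s line %d: %d tets declared, %d found"
            % (ele_path, no, nt, len(elines) - 1))
    tets = np.empty((nt, 4), dtype=np.int64)
    region = np.zeros(nt, dtype=np.int64)
    for no, ln in elines[1:nt + 1]:
        row = ln.split()
        try:
            k = int(row[0]) - first_index
            tets[k] = [int(x) - first_index for x in row[1:5]]
            if nattr:
                region[k] = int(float(row[5]))
        except (IndexError, ValueError):
            raise MeshFormatError("%s line %d: bad tet record" % (ele_path, no))

    mesh = TetMesh(verts, tets, region_markers=region)

    if face_path is not None:
        flines = list(_data_lines(face_path))
        no, head = flines[0][0], flines[0][1].split()
        nf = int(head[0])
        has_marker = len(head) > 1 and int(head[1]) >= 1
        lookup = {tuple(sorted(tri)): k
                  for k, tri in enumerate(mesh.boundary_faces)}
        for no, ln in flines[1:nf + 1]:
            row = ln.split()
            try:
                tri = tuple(sorted(int(x) - first_index for x in row[1:4]))
                mk = int(row[4]) if has_marker and len(row) > 4 else 0
            except (IndexError, ValueError):
                raise MeshFormatError("%s line %d: bad face record"
                                      % (face_path, no))
            if tri in lookup:
                mesh.boundary_face_markers[lookup[tri]] = mk
    return mesh


def boundary_surface_of(tet_mesh):
    """Extract the outward-oriented boundary surface of a tet mesh.

    Returns (surface, vertex_map) where ``vertex_map[i]`` is the tet-mesh
    vertex index of surface vertex i.  Boundary face markers carry over as
    the surface's face markers.
    """
    bfaces = tet_mesh.boundary_faces
    used = np.unique(bfaces)
    remap = -np.ones(tet_mesh.n_vertices, dtype=np.int64)
    remap[used] = np.arange(len(used))
    surf = SurfaceMesh(tet_mesh.vertices[used], remap[bfaces],
                       face_markers=tet_mesh.boundary_face_markers.copy(),
                       validate=False)
    return surf, used
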