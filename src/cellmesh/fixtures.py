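"""Deterministic synthetic mesh generators.

These stand in for electron-microscopy derived surfaces, which are not
publicly deposited.  The key fixture, :func:`contour_stack_sphere`,
emulates the staircase jaggedness of contour-tiled EM segmentations:
lateral (x, y) resolution in such datasets is far finer than the axial
(z) slice thickness, so reconstructed surfaces carry z-quantized steps
and anisotropic noise.  All generators are deterministic: the same
parameters and seed produce the identical mesh.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core import SurfaceMesh, TetMesh

__all__ = [
    "icosphere",
    "grid",
    "torus",
    "contour_stack_sphere",
    "capped_cylinder",
    "tet_ball",
    "star_tetrahedralize",
    "two_component_scene",
]


# ---------------------------------------------------------------------------
# Subdivision surfaces
# ---------------------------------------------------------------------------

_PHI = (1.0 + 5.0 ** 0.5) / 2.0

_ICOSA_VERTS = np.array([
    (-1, _PHI, 0), (1, _PHI, 0), (-1, -_PHI, 0), (1, -_PHI, 0),
    (0, -1, _PHI), (0, 1, _PHI), (0, -1, -_PHI), (0, 1, -_PHI),
    (_PHI, 0, -1), (_PHI, 0, 1), (-_PHI, 0, -1), (-_PHI, 0, 1),
], dtype=float)

_ICOSA_FACES = np.array([
    (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
    (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
    (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
    (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
], dtype=np.int64)

_OCTA_VERTS = np.array([
    (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
], dtype=float)

_OCTA_FACES = np.array([
    (0, 2, 4), (2, 1, 4), (1, 3, 4), (3, 0, 4),
    (2, 0, 5), (1, 2, 5), (3, 1, 5), (0, 3, 5),
], dtype=np.int64)


def _subdivide(verts, faces):
    """One 4:1 loop-style split (midpoint insertion, no smoothing)."""
    verts = list(map(tuple, verts))
    cache: dict = {}

    def midpoint(a, b):
        key = (a, b) if a < b else (b, a)
        if key not in cache:
            pa, pb = np.array(verts[a]), np.array(verts[b])
            cache[key] = len(verts)
            verts.append(tuple((pa + pb) / 2.0))
        return cache[key]

    new_faces = []
    for a, b, c in faces:
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        new_faces.extend([(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)])
    return np.array(verts), np.array(new_faces, dtype=np.int64)


def _sphere_mesh(base_verts, base_faces, subdivisions, radius):
    v, f = base_verts, base_faces
    for _ in range(subdivisions):
        v, f = _subdivide(v, f)
    v = v / np.linalg.norm(v, axis=1)[:, None] * radius
    return v, f


def icosphere(subdivisions=2, radius=1.0):
    """Subdivided icosahedron projected to a sphere.

    V = 10 * 4**s + 2 and F = 20 * 4**s.
    """
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    v, f = _sphere_mesh(_ICOSA_VERTS, _ICOSA_FACES, subdivisions, radius)
    return SurfaceMesh(v, f)


def grid(m=5, n=5, spacing=1.0):
    """Open planar triangulated grid of m x n vertices in the z=0 plane."""
    if m < 2 or n < 2:
        raise ValueError("grid needs at least 2x2 vertices")
    xs, ys = np.meshgrid(np.arange(m) * spacing, np.arange(n) * spacing,
                         indexing="ij")
    verts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(m * n)])
    faces = []
    for i in range(m - 1):
        for j in range(n - 1):
            a = i * n + j
            b = (i + 1) * n + j
            c = (i + 1) * n + j + 1
            d = i * n + j + 1
            faces.append((a, b, c))
            faces.append((a, c, d))
    return SurfaceMesh(verts, np.array(faces, dtype=np.int64))


def torus(R_major=1.0, r_minor=0.3, m=24, n=12):
    """Closed parametric torus with m x n quads split into triangles."""
    if m < 3 or n < 3:
        raise ValueError("torus resolutions must be >= 3")
    verts = np.empty((m * n, 3))
    for i in range(m):
        u = 2 * np.pi * i / m
        for j in range(n):
            w = 2 * np.pi * j / n
            rr = R_major + r_minor * np.cos(w)
            verts[i * n + j] = (rr * np.cos(u), rr * np.sin(u),
                                r_minor * np.sin(w))
    faces = []
    for i in range(m):
        for j in range(n):
            a = i * n + j
            b = ((i + 1) % m) * n + j
            c = ((i + 1) % m) * n + (j + 1) % n
            d = i * n + (j + 1) % n
            faces.append((a, b, c))
            faces.append((a, c, d))
    return SurfaceMesh(verts, np.array(faces, dtype=np.int64))


def capped_cylinder(r=0.5, h=2.0, res=16, segments=None):
    """Closed cylinder of radius r and height h along z, with fan caps.

    ``segments`` axial rings of quads along the tube (default: enough to
    keep the quads roughly square) provide mid-tube vertices away from
    the sharp cap edges.
    """
    if res < 3:
        raise ValueError("res must be >= 3")
    if segments is None:
        segments = max(1, int(round(h / (2 * np.pi * r / res))))
    ang = 2 * np.pi * np.arange(res) / res
    ring = np.column_stack([r * np.cos(ang), r * np.sin(ang), np.zeros(res)])
    rows = [ring + np.array([0.0, 0.0, h * k / segments])
            for k in range(segments + 1)]
    verts = np.vstack(rows + [[[0.0, 0.0, 0.0]], [[0.0, 0.0, h]]])
    cb = res * (segments + 1)
    ct = cb + 1
    faces = []
    for k in range(segments):
        lo, hi = k * res, (k + 1) * res
        for i in range(res):
            j = (i + 1) % res
            faces.append((lo + i, lo + j, hi + j))
            faces.append((lo + i, hi + j, hi + i))
    for i in range(res):
        j = (i + 1) % res
        faces.append((cb, j, i))
        faces.append((ct, segments * res + i, segments * res + j))
    return SurfaceMesh(verts, np.array(faces, dtype=np.int64))


def contour_stack_sphere(radius=1.0, slice_thickness=0.1, noise_amp=0.02,
                         seed=42, subdivisions=5):
    """Sphere with EM-contour-stack artifacts.

    Vertex z-coordinates are quantized to slice planes of the given
    thickness (the axial staircase of serial-section data); each slice is
    then shifted rigidly in x, y by a seeded uniform offset of amplitude
    ``noise_amp`` (per-slice alignment/registration error), and vertices
    get an additional lateral jitter of a quarter of that amplitude
    (segmentation noise).  Connectivity is that of an icosphere, so the
    result is always a closed genus-0 manifold.  The staircase itself is
    the artifact being emulated and is kept; if the noise additionally
    flips or degenerates faces relative to the quantized staircase (a
    proxy for local self-intersection), the mesh is regenerated with
    halved noise and a warning.
    """
    if slice_thickness <= 0:
        raise ValueError("slice_thickness must be > 0")
    from .core import face_normals

    base = icosphere(subdivisions, radius)
    vq = base.vertices.copy()
    slice_ids = np.round(vq[:, 2] / slice_thickness).astype(int)
    vq[:, 2] = slice_ids * slice_thickness
    quantized = SurfaceMesh(vq, base.faces, validate=False)
    fn_q = face_normals(quantized, unit=False)
    mean_edge = float(np.linalg.norm(
        vq[base.faces[:, 0]] - vq[base.faces[:, 1]], axis=1).mean())
    uniq = np.unique(slice_ids)
    amp = noise_amp
    mesh = quantized
    for _attempt in range(8):
        rng = np.random.default_rng(seed)
        v = vq.copy()
        for s in uniq:
            v[slice_ids == s, :2] += rng.uniform(-amp, amp, size=2)
        v[:, :2] += rng.uniform(-amp / 4, amp / 4, size=(len(v), 2))
        mesh = SurfaceMesh(v, base.faces.copy(), validate=False)
        fn = face_normals(mesh, unit=False)
        areas2 = np.linalg.norm(fn, axis=1)
        # In-plane folds of sliver "tread" triangles are part of the
        # emulated artifact; reject only out-of-plane fold-over of the
        # slice-spanning "riser" faces, and exactly degenerate faces.
        spans = np.ptp(slice_ids[base.faces], axis=1) > 0
        flipped = (np.einsum("ij,ij->i", fn, fn_q) < 0) & spans
        degenerate = areas2 < 1e-9 * mean_edge ** 2
        if not (flipped.any() or degenerate.any()):
            return mesh
        amp *= 0.5
        warnings.warn(
            "contour_stack_sphere: noise flipped faces; retrying with "
            "amplitude %g" % amp)
    return mesh


# ---------------------------------------------------------------------------
# Tetrahedral ball
# ---------------------------------------------------------------------------


def tet_ball(refinement=1):
    """Tetrahedralized unit ball by radial layering of a subdivided octahedron.

    The unit sphere is triangulated by subdividing an octahedron
    ``refinement`` times; ``refinement + 1`` concentric shells of that
    triangulation (radii k / (refinement + 1)) are joined to a center
    vertex.  The innermost shell is coned to the center; each prism
    between consecutive shells is split into eight tets around a Steiner
    centroid, with quad faces split by the minimal-global-index diagonal
    rule so the decomposition conforms across neighboring prisms.
    """
    if refinement < 0:
        raise ValueError("refinement must be >= 0")
    sv, sf = _sphere_mesh(_OCTA_VERTS, _OCTA_FACES, refinement, 1.0)
    S = len(sv)
    L = refinement + 1
    verts = [np.zeros(3)]
    for k in range(1, L + 1):
        verts.extend(sv * (k / L))
    verts = list(np.array(verts))

    def shell(k, i):
        return 1 + (k - 1) * S + i

    tets = []
    # innermost fan
    for (a, b, c) in sf:
        tets.append((0, shell(1, a), shell(1, b), shell(1, c)))

    def split_quad(a, b, B, A):
        """Quad (a, b, B, A) (cyclic) split by min-index diagonal."""
        if min(a, B) < min(b, A):
            return [(a, b, B), (a, B, A)]
        return [(a, b, A), (b, B, A)]

    for k in range(1, L):
        for (ia, ib, ic) in sf:
            a, b, c = shell(k, ia), shell(k, ib), shell(k, ic)
            A, B, C = shell(k + 1, ia), shell(k + 1, ib), shell(k + 1, ic)
            centroid = (verts[a] + verts[b] + verts[c]
                        + verts[A] + verts[B] + verts[C]) / 6.0
            ci = len(verts)
            verts.append(centroid)
            tris = [(a, b, c), (A, B, C)]
            tris += split_quad(a, b, B, A)
            tris += split_quad(b, c, C, B)
            tris += split_quad(c, a, A, C)
            for (p, q, r) in tris:
                tets.append((ci, p, q, r))
    return TetMesh(np.array(verts), np.array(tets, dtype=np.int64))


def star_tetrahedralize(mesh, center=None):
    """Fan tetrahedralization of a closed star-shaped surface.

    Connects every surface triangle to one interior point (default: the
    vertex centroid).  Valid whenever the surface is star-shaped with
    respect to that point; tet quality directly reflects surface triangle
    quality, which makes this useful for studying how surface conditioning
    propagates into volume-mesh and simulation quality.
    """
    if center is None:
        center = mesh.vertices.mean(axis=0)
    center = np.asarray(center, dtype=float)
    verts = np.vstack([mesh.vertices, center[None, :]])
    ci = len(mesh.vertices)
    tets = np.column_stack([
        np.full(len(mesh.faces), ci, dtype=np.int64), mesh.faces
    ])
    return TetMesh(verts, tets)


def two_component_scene():
    """Nested two-surface scene: a unit "plasma membrane" sphere enclosing
    a radius-0.4 "endoplasmic reticulum" sphere, with distinct region
    markers (cytosol between the surfaces, lumen inside the inner one)."""
    from .tetra import MarkedScene  # deferred: tetra imports core only

    pm = icosphere(2, 1.0)
    pm.face_markers[:] = 1
    er = icosphere(2, 0.4)
    er.face_markers[:] = 2
    return MarkedScene(
        surfaces=[pm, er],
        region_points=[((0.7, 0.0, 0.0), 1), ((0.0, 0.0, 0.0), 2)],
        containment=[(1, 0)],  # surface 1 (ER) nests inside surface 0 (PM)
    )
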