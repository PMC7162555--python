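import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cellmesh as cm
from cellmesh import fixtures as fx
from cellmesh.core import (
    CLOSED_MANIFOLD,
    MANIFOLD_WITH_BOUNDARY,
    NON_MANIFOLD,
    MeshFormatError,
    MeshValidationError,
    enclosed_volume,
    reorient_consistently,
)
from conftest import make_cube_surface, make_tripled_edge

EQUILATERAL = ((0, 0, 0), (1, 0, 0), (0.5, math.sqrt(3) / 2, 0))
REGULAR_TET = ((0, 0, 0), (1, 0, 0), (0.5, math.sqrt(3) / 2, 0),
               (0.5, math.sqrt(3) / 6, math.sqrt(6) / 3))


# ---------------------------------------------------------------------------
# Radius ratios
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("pts,expected", [
    (EQUILATERAL, 1.0),
    (((0, 0, 0), (1, 0, 0), (2, 0, 0)), 0.0),          # collinear
    (((0, 0, 0), (1, 0, 0), (0, 1, 0)), 0.82843),       # right isoceles
])
def test_radius_ratio_triangle(pts, expected):
    assert cm.radius_ratio_triangle(*pts) == pytest.approx(expected, abs=1e-5)


@pytest.mark.parametrize("pts,expected", [
    (REGULAR_TET, 1.0),
    (((0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1)), 0.73205),
    (((0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0)), 0.0),  # coplanar
])
def test_radius_ratio_tet(pts, expected):
    assert cm.radius_ratio_tet(*pts) == pytest.approx(expected, abs=1e-5)


def _random_similarity(rng):
    # random rotation via QR, uniform-ish
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    scale = rng.uniform(0.1, 10.0)
    shift = rng.uniform(-5, 5, size=3)
    return lambda p: scale * (q @ np.asarray(p, float)) + shift


@settings(deadline=None, max_examples=25, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_radius_ratios_similarity_invariant(seed):
    rng = np.random.default_rng(seed)
    T = _random_similarity(rng)
    tri = [rng.normal(size=3) for _ in range(3)]
    tet = [rng.normal(size=3) for _ in range(4)]
    assert cm.radius_ratio_triangle(*map(T, tri)) == pytest.approx(
        cm.radius_ratio_triangle(*tri), abs=1e-9)
    assert cm.radius_ratio_tet(*map(T, tet)) == pytest.approx(
        cm.radius_ratio_tet(*tet), abs=1e-9)


# ---------------------------------------------------------------------------
# Quality report
# ---------------------------------------------------------------------------


def test_quality_report_cube():
    rep = cm.quality_report(make_cube_surface())
    assert rep.surface_area == pytest.approx(6.0)
    assert rep.enclosed_volume == pytest.approx(1.0)
    assert rep.angle_mean == pytest.approx(60.0, abs=1e-12)


@pytest.mark.parametrize("mesh_maker", [
    lambda: fx.icosphere(1),
    lambda: fx.grid(4, 6),
    lambda: fx.torus(1, 0.3, 12, 8),
    lambda: fx.contour_stack_sphere(subdivisions=2),
])
def test_angle_mean_is_sixty(mesh_maker):
    # the three angles of every triangle sum to 180 degrees, identically
    rep = cm.quality_report(mesh_maker())
    assert rep.angle_mean == pytest.approx(60.0, abs=1e-10)
    assert np.all(rep.triangle_radius_ratios >= 0)
    assert np.all(rep.triangle_radius_ratios <= 1)


def test_icosphere_area_volume_converge(ico3):
    rep = cm.quality_report(ico3)
    assert rep.surface_area == pytest.approx(4 * math.pi, rel=0.02)
    assert rep.enclosed_volume == pytest.approx(4 * math.pi / 3, rel=0.02)
    # volume approaches the ball monotonically with subdivision
    vols = [cm.quality_report(fx.icosphere(s)).enclosed_volume
            for s in (1, 2, 3)]
    assert vols[0] < vols[1] < vols[2] < 4 * math.pi / 3


def test_open_mesh_volume_absent():
    rep = cm.quality_report(fx.grid(4, 4))
    assert rep.enclosed_volume is None


# ---------------------------------------------------------------------------
# Classification and orientation
# ---------------------------------------------------------------------------


def test_classification(ico2):
    assert cm.classify_manifold(ico2) == (CLOSED_MANIFOLD, True)
    assert cm.classify_manifold(fx.grid(5, 5))[0] == MANIFOLD_WITH_BOUNDARY
    tri = cm.SurfaceMesh([(0, 0, 0), (1, 0, 0), (0, 1, 0)], [(0, 1, 2)])
    assert cm.classify_manifold(tri)[0] == MANIFOLD_WITH_BOUNDARY
    assert cm.classify_manifold(make_tripled_edge())[0] == NON_MANIFOLD


def test_orientation_repair(ico2):
    scrambled = ico2.copy()
    rng = np.random.default_rng(0)
    flip = rng.random(scrambled.n_faces) < 0.5
    scrambled.faces[flip] = scrambled.faces[flip][:, [0, 2, 1]]
    scrambled.invalidate()
    repaired = reorient_consistently(scrambled)
    assert cm.classify_manifold(repaired) == (CLOSED_MANIFOLD, True)
    assert enclosed_volume(repaired) > 0


# ---------------------------------------------------------------------------
# Vertex normals and neighborhoods
# ---------------------------------------------------------------------------


def test_vertex_normal_flat_and_pyramid():
    g = fx.grid(5, 5)
    assert np.allclose(cm.vertex_normal(g, 12), (0, 0, 1))
    # square pyramid, apex on top, base in z < 0
    v = [(0, 0, 0.5), (1, 1, -1), (-1, 1, -1), (-1, -1, -1), (1, -1, -1)]
    f = [(0, 1, 2), (0, 2, 3), (0, 3, 4), (0, 4, 1)]
    pyr = cm.SurfaceMesh(v, f)
    assert np.allclose(cm.vertex_normal(pyr, 0), (0, 0, 1), atol=1e-12)


def test_vertex_normal_sphere(ico2):
    for v in range(0, ico2.n_vertices, 17):
        n = cm.vertex_normal(ico2, v)
        radial = ico2.vertices[v] / np.linalg.norm(ico2.vertices[v])
        angle = math.degrees(math.acos(np.clip(np.dot(n, radial), -1, 1)))
        assert angle < 5.0


def _bfs_rings(mesh, v, r):
    # brute-force breadth-first oracle
    adj = {}
    for (a, b) in mesh.edge_faces:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    seen = {v}
    frontier = {v}
    out = set()
    for _ in range(r):
        frontier = set().union(*(adj[u] for u in frontier)) - seen
        seen |= frontier
        out |= frontier
    return out


def test_ring_neighborhood():
    g = fx.grid(5, 5)
    ring, ordered = cm.ring_neighborhood(g, 12, 1)
    assert ordered and len(ring) == 6
    ico = fx.icosphere(0)
    ring, _ = cm.ring_neighborhood(ico, 0, 1)
    assert len(ring) == 5
    two, _ = cm.ring_neighborhood(ico, 0, 2)
    assert set(two) == _bfs_rings(ico, 0, 2)
    # everything except the antipode, which sits at graph distance 3
    assert len(two) == 10
    antipode = int(np.argmin(ico.vertices @ ico.vertices[0]))
    assert antipode not in two
    three, _ = cm.ring_neighborhood(ico, 0, 3)
    assert len(three) == 11


# ---------------------------------------------------------------------------
# Edge flips
# ---------------------------------------------------------------------------


def _long_rectangle():
    # 1 x 2 rectangle split along the long diagonal
    v = [(0, 0, 0), (2, 0, 0), (2, 1, 0), (0, 1, 0)]
    return cm.SurfaceMesh(v, [(0, 1, 2), (0, 2, 3)])


def test_edge_flip_and_involution():
    m = _long_rectangle()
    cm.edge_flip(m, (0, 2))
    keys = set(m.edge_faces.keys())
    assert (1, 3) in keys and (0, 2) not in keys
    cm.edge_flip(m, (1, 3))
    assert (0, 2) in set(m.edge_faces.keys())
    assert cm.classify_manifold(m)[0] == MANIFOLD_WITH_BOUNDARY


def test_edge_flip_rejections():
    m = _long_rectangle()
    with pytest.raises(MeshValidationError):
        cm.edge_flip(m, (0, 1))  # boundary edge
    # a tetrahedron: flipping any edge would duplicate an existing face
    tet = cm.SurfaceMesh(
        [(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1)],
        [(0, 2, 1), (0, 1, 3), (1, 2, 3), (0, 3, 2)])
    with pytest.raises(MeshValidationError):
        cm.edge_flip(tet, (0, 1))


def test_angle_flip_pass():
    # a Delaunay-quality planar mesh is already locally optimal
    assert cm.angle_flip_pass(fx.grid(5, 5).copy()) == 0
    # skewed parallelogram split along its long diagonal: one flip to the
    # short diagonal raises the minimum angle
    v = [(0, 0, 0), (1, 0, 0), (1.8, 1, 0), (0.8, 1, 0)]
    m = cm.SurfaceMesh(v, [(0, 1, 2), (0, 2, 3)])
    pre_min = cm.quality_report(m).angle_min
    flips = cm.angle_flip_pass(m)
    assert flips == 1
    assert (1, 3) in m.edge_faces
    assert cm.quality_report(m).angle_min >= pre_min
    # monotonicity on a jagged closed surface
    j = fx.contour_stack_sphere(subdivisions=2)
    pre = cm.quality_report(j).angle_min
    cm.angle_flip_pass(j)
    assert cm.quality_report(j).angle_min >= pre


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def test_load_minimal_off(tmp_path):
    p = tmp_path / "tri.off"
    p.write_text("OFF\n3 1 3\n0 0 0\n1 0 0\n0 1 0\n3 0 1 2\n")
    m = cm.load_surface(p)
    assert m.n_vertices == 3 and m.n_faces == 1


def test_load_obj_one_based(tmp_path):
    p = tmp_path / "tri.obj"
    p.write_text("v 0 0 0\nv 1 0 0\nv 0 1 0\nf 1 2 3\n")
    m = cm.load_surface(p)
    assert tuple(m.faces[0]) == (0, 1, 2)


@pytest.mark.parametrize("fmt", ["off", "obj", "ply"])
def test_save_load_roundtrip(tmp_path, ico2, fmt):
    p = tmp_path / ("sphere." + fmt)
    cm.save_surface(ico2, p)
    back = cm.load_surface(p)
    assert back.n_vertices == ico2.n_vertices
    assert back.n_faces == ico2.n_faces
    assert np.allclose(back.vertices, ico2.vertices, atol=1e-12)
    assert np.array_equal(np.sort(back.faces, axis=1),
                          np.sort(ico2.faces, axis=1))


def test_ply_markers_roundtrip_and_off_loss(tmp_path, ico2):
    m = ico2.copy()
    m.face_markers[7] = 5
    ply = tmp_path / "m.ply"
    cm.save_surface(m, ply)
    back = cm.load_surface(ply)
    assert back.face_markers[7] == 5
    assert back.face_markers.sum() == 5
    off = tmp_path / "m.off"
    cm.save_surface(m, off)
    assert cm.load_surface(off).face_markers.sum() == 0  # documented loss


def test_io_and_geometry_against_trimesh(tmp_path, ico2):
    """Independent cross-check: trimesh must parse our OFF/PLY output to
    the same mesh and agree on area and enclosed volume."""
    trimesh = pytest.importorskip("trimesh")
    for fmt in ("off", "ply"):
        p = tmp_path / ("x." + fmt)
        cm.save_surface(ico2, p)
        tm = trimesh.load(str(p), process=False)
        assert np.allclose(tm.vertices, ico2.vertices, atol=1e-6)
        assert np.array_equal(np.asarray(tm.faces), ico2.faces)
    tm = trimesh.Trimesh(ico2.vertices, ico2.faces, process=False)
    rep = cm.quality_report(ico2)
    assert rep.surface_area == pytest.approx(tm.area, rel=1e-9)
    assert rep.enclosed_volume == pytest.approx(tm.volume, rel=1e-9)


def test_parse_errors_name_line(tmp_path):
    p = tmp_path / "bad.off"
    p.write_text("OFF\n3 1 0\n0 0 0\n1 0 x\n0 1 0\n3 0 1 2\n")
    with pytest.raises(MeshFormatError, match="line 4"):
        cm.load_surface(p)
    q = tmp_path / "oob.off"
    q.write_text("OFF\n3 1 0\n0 0 0\n1 0 0\n0 1 0\n3 0 1 9\n")
    with pytest.raises(MeshValidationError):
        cm.load_surface(q)
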