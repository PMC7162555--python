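import math

import numpy as np
import pytest

import cellmesh as cm
from cellmesh import fixtures as fx
from cellmesh.conditioning import (
    SmoothingConfig,
    angle_weighted_position,
    anisotropic_mean_normal,
    decimate,
    lst_corrected_position,
    lst_field,
    local_structure_tensor,
    normal_smooth,
    remove_vertex_retriangulate,
    select_dense_vertices,
    select_flat_vertices,
    smooth,
)
from cellmesh.core import MeshValidationError, face_normals, quality_report
from cellmesh.topology import betti_numbers
from conftest import make_subdivided_cube, make_tripled_edge


# ---------------------------------------------------------------------------
# Local structure tensor
# ---------------------------------------------------------------------------


def test_lst_flat_grid_rank_one():
    g = fx.grid(5, 5)
    T = local_structure_tensor(g, 12, rings=1)
    # 6 neighbors + center, all normals (0,0,1)
    assert np.allclose(T, 7 * np.outer([0, 0, 1], [0, 0, 1]))
    lam = np.sort(np.linalg.eigvalsh(T))[::-1]
    assert lam[0] == pytest.approx(7.0)
    assert lam[1] == 0.0 and lam[2] == 0.0


def test_lst_ridge_spectrum():
    # two orthogonal half-planes meeting along the x-axis
    v, f = [], []
    n = 5
    for i in range(n):           # ridge line y=z=0
        v.append((i, 0.0, 0.0))
    for i in range(n):           # wing in the y direction
        v.append((i, 1.0, 0.0))
    for i in range(n):           # wing in the z direction
        v.append((i, 0.0, 1.0))
    for i in range(n - 1):
        f += [(i, i + 1, n + i + 1), (i, n + i + 1, n + i)]
        f += [(i, 2 * n + i, 2 * n + i + 1), (i, 2 * n + i + 1, i + 1)]
    ridge = cm.SurfaceMesh(v, f)
    T = local_structure_tensor(ridge, 2, rings=1)
    lam = np.sort(np.linalg.eigvalsh(T))[::-1]
    # ridge signature: two comparable eigenvalues, the third vanishes
    # (contrast: plane lambda2 = 0; sphere lambda3 > 0)
    assert lam[1] > 0.3 * lam[0]
    assert lam[2] < 1e-10


def test_lst_sphere_spectrum():
    # coarse sphere: wide-spread normals, all three eigenvalues comparable
    field = lst_field(fx.icosphere(0), rings=1)
    lam = field.eigenvalues[0]
    assert lam[2] > 0.3 * lam[0]
    # PSD + trace equals the number of unit normals summed (ring + center)
    assert np.trace(field.tensors[0]) == pytest.approx(6.0)


# ---------------------------------------------------------------------------
# Angle-weighted smoothing
# ---------------------------------------------------------------------------


def _hexagon_mesh(center=(0.0, 0.0, 0.0)):
    ang = 2 * np.pi * np.arange(6) / 6
    ring = np.column_stack([np.cos(ang), np.sin(ang), np.zeros(6)])
    v = np.vstack([[center], ring])
    f = [(0, 1 + i, 1 + (i + 1) % 6) for i in range(6)]
    return cm.SurfaceMesh(v, f)


def test_hexagon_center_is_fixed_point():
    m = _hexagon_mesh()
    assert np.allclose(angle_weighted_position(m, 0), (0, 0, 0), atol=1e-14)


def test_hexagon_perturbed_center_converges():
    m = _hexagon_mesh(center=(0.2, 0.1, 0.0))
    for _ in range(20):
        m.vertices[0] = angle_weighted_position(m, 0)
    assert np.linalg.norm(m.vertices[0]) < 1e-6


def test_alpha_weight_values():
    # perpendicular edge vectors: alpha = 0 -> weight 1
    # anti-parallel edge vectors: alpha = -1 -> weight 0
    e1, e2 = np.array([1.0, 0, 0]), np.array([0, 1.0, 0])
    assert float(e1 @ e2) + 1.0 == pytest.approx(1.0)
    assert float(e1 @ -e1) + 1.0 == pytest.approx(0.0)


def test_boundary_vertices_unmoved():
    g = fx.grid(5, 5)
    out = smooth(g, SmoothingConfig(iterations=3, use_lst=False,
                                    flip_every=0))
    boundary = sorted(g.boundary_vertices())
    assert np.allclose(out.vertices[boundary], g.vertices[boundary])


def test_lst_corrected_position():
    # all eigenvalues zero: undamped, returns xbar
    lam = np.zeros(3)
    E = np.eye(3)
    x = np.array([1.0, 2.0, 3.0])
    xbar = x + np.array([0.3, -0.2, 0.1])
    assert np.allclose(lst_corrected_position(x, xbar, lam, E), xbar)
    # worked case: motion along E1 damped by 1/(1+6)
    lam = np.array([6.0, 0.0, 0.0])
    E = np.array([[0, 0, 1.0], [1.0, 0, 0], [0, 1.0, 0]])
    xhat = lst_corrected_position(np.zeros(3), np.array([0.1, 0.0, 0.5]),
                                  lam, E)
    assert np.allclose(xhat, [0.1, 0.0, 0.5 / 7], atol=1e-12)
    # enormous eigenvalue kills the motion along its eigenvector
    lam = np.array([1e12, 0.0, 0.0])
    xhat = lst_corrected_position(np.zeros(3), np.array([0.0, 0.0, 0.5]),
                                  lam, E)
    assert abs(xhat[2]) < 1e-9


def test_damping_never_amplifies():
    rng = np.random.default_rng(11)
    for _ in range(50):
        lam = np.sort(rng.uniform(0, 10, 3))[::-1]
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        x = rng.normal(size=3)
        xbar = x + rng.normal(size=3)
        xhat = lst_corrected_position(x, xbar, lam, q.T)
        assert np.linalg.norm(xhat - x) <= np.linalg.norm(xbar - x) + 1e-12


def test_smooth_conditions_jagged_sphere():
    m = fx.contour_stack_sphere(subdivisions=3)
    pre = quality_report(m)
    out = smooth(m, SmoothingConfig(iterations=20))
    post = quality_report(out)
    assert post.angle_std < pre.angle_std
    assert post.enclosed_volume == pytest.approx(pre.enclosed_volume,
                                                 rel=0.05)
    assert betti_numbers(out).as_tuple() == betti_numbers(m).as_tuple()
    # markers untouched (none set -> all zero)
    assert np.array_equal(out.face_markers, np.zeros(out.n_faces, dtype=int))


def test_full_pipeline_reduces_area_and_preserves_volume():
    """The complete pipeline (vertex smoothing + flips + interleaved
    anisotropic normal smoothing) removes jaggedness: angle spread and
    surface area drop while the enclosed volume is nearly unchanged."""
    m = fx.contour_stack_sphere(subdivisions=4)
    pre = quality_report(m)
    out = smooth(m, SmoothingConfig(iterations=20, normal_smooth_iterations=2))
    post = quality_report(out)
    assert post.angle_std < pre.angle_std
    assert post.surface_area <= pre.surface_area
    assert post.enclosed_volume == pytest.approx(pre.enclosed_volume,
                                                 rel=0.05)
    assert betti_numbers(out).as_tuple() == (1, 0, 1)


def test_smooth_is_near_fixed_point_on_smooth_sphere(ico2):
    before = ico2.vertices.copy()
    out = smooth(ico2, SmoothingConfig(iterations=1, flip_every=0))
    edge = np.linalg.norm(
        ico2.vertices[ico2.faces[:, 0]] - ico2.vertices[ico2.faces[:, 1]],
        axis=1).mean()
    disp = np.linalg.norm(out.vertices - before, axis=1).max()
    assert disp < 0.01 * edge


def test_smooth_refuses_non_manifold():
    with pytest.raises(MeshValidationError):
        smooth(make_tripled_edge(), SmoothingConfig(iterations=1))


# ---------------------------------------------------------------------------
# Normal smoothing
# ---------------------------------------------------------------------------


def test_anisotropic_mean_normal_limits(ico2):
    fn = face_normals(ico2)
    # K -> 0 reduces to the (normalized) arithmetic neighbor mean
    n_small = anisotropic_mean_normal(ico2, 5, K=1e-8)
    from cellmesh.conditioning import _face_adjacency
    adj = _face_adjacency(ico2)
    mean = fn[adj[5]].mean(axis=0)
    mean /= np.linalg.norm(mean)
    assert np.allclose(n_small, mean, atol=1e-9)
    # equal neighbor normals are a fixed point for any K
    flat = fx.grid(4, 4)
    nf = anisotropic_mean_normal(flat, 5, K=3.0)
    assert np.allclose(nf, (0, 0, 1))


def test_anisotropic_mean_normal_sharp_weighting():
    # one outlier neighbor normal is exponentially suppressed at K=10
    ni = np.array([0.0, 0.0, 1.0])
    neighbors = np.array([[0, 0, 1.0], [0, 0, 1.0], [1.0, 0, 0]])
    w = np.exp(10.0 * neighbors @ ni)
    nbar = (w[:, None] * neighbors).sum(axis=0) / w.sum()
    nbar /= np.linalg.norm(nbar)
    assert np.linalg.norm(nbar - ni) < 1e-3


def test_normal_smooth_flat_identity():
    g = fx.grid(5, 5)
    out = normal_smooth(g, K=1.0, iterations=2)
    assert np.allclose(out.vertices, g.vertices, atol=1e-12)


def test_normal_smooth_shrinks_bump():
    g = fx.grid(7, 7)
    m = g.copy()
    m.vertices[24, 2] = 0.4  # bump one interior vertex
    heights = [m.vertices[24, 2]]
    for _ in range(3):
        m = normal_smooth(m, K=1.0, iterations=1)
        heights.append(m.vertices[24, 2])
    assert all(h2 < h1 for h1, h2 in zip(heights, heights[1:]))
    assert heights[-1] > 0


def test_normal_smooth_anisotropy_preserves_creases():
    def max_crease_angle(m):
        fn = face_normals(m)
        worst = 0.0
        for fids in m.edge_faces.values():
            if len(fids) == 2:
                c = float(np.clip(fn[fids[0]] @ fn[fids[1]], -1, 1))
                worst = max(worst, math.degrees(math.acos(c)))
        return worst

    cube = make_subdivided_cube(5)
    sharp = normal_smooth(cube, K=10.0, iterations=5)
    soft = normal_smooth(cube, K=0.1, iterations=5)
    # strong anisotropy keeps the 90-degree creases closer to 90
    assert abs(max_crease_angle(sharp) - 90) < abs(max_crease_angle(soft) - 90)


# ---------------------------------------------------------------------------
# Selection and decimation
# ---------------------------------------------------------------------------


def test_select_flat_vertices():
    g = fx.grid(6, 6)
    field = lst_field(g, rings=1)
    interior = set(range(g.n_vertices)) - g.boundary_vertices()
    assert interior <= select_flat_vertices(g, field, 0.1)
    # coarse sphere: normals spread widely, nothing is "flat"
    ico = fx.icosphere(1)
    f2 = lst_field(ico, rings=1)
    assert select_flat_vertices(ico, f2, 0.1) == set()
    # R1 = 1 selects everything (the ratio never exceeds 1)
    assert len(select_flat_vertices(ico, f2, 1.0 + 1e-12)) == ico.n_vertices


def test_select_dense_vertices():
    g = fx.grid(6, 6)
    assert select_dense_vertices(g, 0.0) == set()
    interior = set(range(g.n_vertices)) - g.boundary_vertices()
    # uniform grid: max ring edge (the diagonal) is sqrt(2) x the mean,
    # so nothing is selected at R2 = 1
    assert select_dense_vertices(g, 1.0) & interior == set()


def _dense_cluster_mesh():
    """Planar triangulation with a refined 4x-denser patch in the middle."""
    from scipy.spatial import Delaunay

    xs = np.linspace(0, 5, 6)
    coarse = np.array([(x, y) for x in xs for y in xs])
    fine = np.array([(2.0 + 0.25 * i, 2.0 + 0.25 * j)
                     for i in range(5) for j in range(5)])
    pts = np.unique(np.vstack([coarse, fine]), axis=0)
    tri = Delaunay(pts)
    v = np.column_stack([pts, np.zeros(len(pts))])
    return cm.SurfaceMesh(v, tri.simplices), pts


def test_decimate_dense_cluster_coarsens_patch():
    m, pts = _dense_cluster_mesh()
    patch = [i for i, p in enumerate(pts)
             if 2.0 < p[0] < 3.0 and 2.0 < p[1] < 3.0]

    def patch_mean_edge(mesh):
        inside = {i for i in range(mesh.n_vertices)
                  if 2.0 < mesh.vertices[i, 0] < 3.0
                  and 2.0 < mesh.vertices[i, 1] < 3.0}
        ls = [np.linalg.norm(mesh.vertices[a] - mesh.vertices[b])
              for (a, b) in mesh.edge_faces if a in inside and b in inside]
        return np.mean(ls)

    pre = patch_mean_edge(m)
    out = decimate(m, R2=0.6, use_flat=False, use_dense=True, n_passes=3)
    assert out.n_vertices < m.n_vertices
    assert patch_mean_edge(out) > pre
    assert len(patch) > 0


def test_decimate_flat_grid_criterion_audit():
    g = fx.grid(6, 6)
    field = lst_field(g, rings=1)
    lam = field.eigenvalues
    out = decimate(g, R1=0.1, use_flat=True, n_passes=1)
    assert out.n_vertices < g.n_vertices
    # every interior vertex was a legitimate candidate (ratio < R1)
    interior = set(range(g.n_vertices)) - g.boundary_vertices()
    for v in interior:
        ratio = lam[v, 1] / lam[v, 0] if lam[v, 0] > 0 else 0.0
        assert ratio < 0.1


def test_decimate_no_criteria_is_identity(ico2):
    out = decimate(ico2, use_flat=False, use_dense=False)
    assert out.n_vertices == ico2.n_vertices
    assert np.array_equal(out.faces, ico2.faces)


def test_remove_vertex_euler_bookkeeping():
    g = fx.grid(5, 5)
    out = remove_vertex_retriangulate(g, 12)  # valence-6 interior vertex
    assert (out.n_vertices - g.n_vertices,
            out.n_faces - g.n_faces,
            out.n_edges - g.n_edges) == (-1, -2, -3)
    assert cm.classify_manifold(out)[0] == "manifold_with_boundary"


def test_remove_valence3_vertex():
    # insert a centroid into one icosahedron face (valence-3 vertex),
    # removing it must refill with exactly one face
    ico = fx.icosphere(0)
    c = ico.vertices[ico.faces[0]].mean(axis=0)
    v = np.vstack([ico.vertices, c])
    a, b, cc = ico.faces[0]
    newf = np.vstack([ico.faces[1:], [(a, b, 12), (b, cc, 12), (cc, a, 12)]])
    m = cm.SurfaceMesh(v, newf)
    out = remove_vertex_retriangulate(m, 12)
    assert out.n_faces == 20
    assert betti_numbers(out).as_tuple() == (1, 0, 1)


def test_remove_random_vertices_keeps_sphere_closed(ico2):
    rng = np.random.default_rng(7)
    m = ico2
    for _ in range(10):
        u = int(rng.integers(0, m.n_vertices))
        try:
            m = remove_vertex_retriangulate(m, u)
        except MeshValidationError:
            continue
    assert cm.classify_manifold(m) == ("closed_manifold", True)
    assert betti_numbers(m).as_tuple() == (1, 0, 1)


def test_decimate_refuses_non_manifold():
    with pytest.raises(MeshValidationError):
        decimate(make_tripled_edge(), use_flat=True)
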