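"""Shared fixtures and independent oracles for the test suite.

The expensive conditioned contour-stack meshes are session-scoped so the
full 50-sweep pipeline runs once for all tests that inspect its result.
"""

import numpy as np
import pytest

from cellmesh import SmoothingConfig, SurfaceMesh, smooth
from cellmesh.conditioning import decimate
from cellmesh import fixtures as fx


@pytest.fixture(scope="session")
def ico2():
    return fx.icosphere(2)


@pytest.fixture(scope="session")
def ico3():
    return fx.icosphere(3)


@pytest.fixture(scope="session")
def contour_default():
    """The jagged contour-stack sphere at its default (study) conditions."""
    return fx.contour_stack_sphere()


@pytest.fixture(scope="session")
def conditioned_contour(contour_default):
    """50 sweeps of LST-damped (r=2) angle-weighted smoothing with an
    edge-flip pass every sweep — the full conditioning run."""
    return smooth(contour_default,
                  SmoothingConfig(iterations=50, rings=2, flip_every=1))


@pytest.fixture(scope="session")
def decimated_contour(conditioned_contour):
    """One vertex-removal decimation pass after conditioning."""
    return decimate(conditioned_contour, R1=0.1, use_flat=True, n_passes=1)


# ---------------------------------------------------------------------------
# Constructive fixtures
# ---------------------------------------------------------------------------


def make_cube_surface():
    """Unit cube as 12 triangles, outward oriented."""
    v = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
                  [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]], dtype=float)
    f = [
        (0, 2, 1), (0, 3, 2),  # z=0, normal -z
        (4, 5, 6), (4, 6, 7),  # z=1, normal +z
        (0, 1, 5), (0, 5, 4),  # y=0
        (2, 3, 7), (2, 7, 6),  # y=1
        (1, 2, 6), (1, 6, 5),  # x=1
        (0, 4, 7), (0, 7, 3),  # x=0
    ]
    return SurfaceMesh(v, f)


def make_subdivided_cube(n=5):
    """Closed cube surface with each face an n x n triangulated grid."""
    verts = {}
    faces = []

    def vid(p):
        key = tuple(round(float(x) * n) for x in p)
        if key not in verts:
            verts[key] = (len(verts), np.asarray(p, dtype=float))
        return verts[key][0]

    # (origin, du, dw) with du x dw pointing outward
    panels = [
        ((0, 0, 1), (1, 0, 0), (0, 1, 0)),   # +z
        ((0, 1, 0), (1, 0, 0), (0, -1, 0)),  # -z
        ((0, 0, 0), (0, 1, 0), (0, 0, 1)),   # -x at x=0 -> normal -x? check
        ((1, 0, 0), (0, 0, 1), (0, 1, 0)),   # +x
        ((0, 0, 0), (0, 0, 1), (1, 0, 0)),   # -y
        ((0, 1, 0), (1, 0, 0), (0, 0, 1)),   # +y
    ]
    for origin, du, dw in panels:
        origin = np.array(origin, float)
        du = np.array(du, float)
        dw = np.array(dw, float)
        for i in range(n):
            for j in range(n):
                p00 = origin + du * i / n + dw * j / n
                p10 = origin + du * (i + 1) / n + dw * j / n
                p11 = origin + du * (i + 1) / n + dw * (j + 1) / n
                p01 = origin + du * i / n + dw * (j + 1) / n
                a, b, c, d = vid(p00), vid(p10), vid(p11), vid(p01)
                faces.append((a, b, c))
                faces.append((a, c, d))
    coords = np.zeros((len(verts), 3))
    for _, (idx, p) in verts.items():
        coords[idx] = p
    mesh = SurfaceMesh(coords, faces)
    # panels table may not orient every face outward; repair globally
    from cellmesh.core import reorient_consistently
    return reorient_consistently(mesh)


def make_open_tube(res=16, h=2.0, r=1.0, segments=4):
    """Cylindrical tube without caps: topologically an annulus."""
    ang = 2 * np.pi * np.arange(res) / res
    ring = np.column_stack([r * np.cos(ang), r * np.sin(ang), np.zeros(res)])
    rows = [ring + np.array([0, 0, h * k / segments])
            for k in range(segments + 1)]
    v = np.vstack(rows)
    faces = []
    for k in range(segments):
        lo, hi = k * res, (k + 1) * res
        for i in range(res):
            j = (i + 1) % res
            faces.append((lo + i, lo + j, hi + j))
            faces.append((lo + i, hi + j, hi + i))
    return SurfaceMesh(v, faces)


def make_klein_bottle(m=8, n=8):
    """Combinatorial Klein bottle (positions are an immaterial embedding):
    an m x n quad grid with one wrap reversed."""
    def vid(i, j):
        if i == m:
            i, j = 0, (n - j) % n
        return (i % m) * n + (j % n)

    # torus-like coordinates; self-intersection is irrelevant for topology
    v = np.zeros((m * n, 3))
    for i in range(m):
        for j in range(n):
            u, w = 2 * np.pi * i / m, 2 * np.pi * j / n
            v[i * n + j] = ((2 + np.cos(w)) * np.cos(u),
                            (2 + np.cos(w)) * np.sin(u), np.sin(w))
    faces = []
    for i in range(m):
        for j in range(n):
            a, b = vid(i, j), vid(i + 1, j)
            c, d = vid(i + 1, j + 1), vid(i, j + 1)
            faces.append((a, b, c))
            faces.append((a, c, d))
    return SurfaceMesh(v, faces)


def make_tripled_edge():
    """Three triangles sharing one edge: the canonical non-manifold case."""
    v = [(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1)]
    return SurfaceMesh(v, [(0, 1, 2), (0, 1, 3), (0, 1, 4)])


def well_mixed_oracle(params, volume, area, A0, X0, B0, t_end):
    """Two-ODE well-mixed reduction of the coupled model (independent of
    the FEM path): A couples to B through the surface-to-volume ratio and
    the molecules-per-(um^3 uM) conversion."""
    from scipy.integrate import solve_ivp

    Nc = params.unit_conversion

    def rhs(t, y):
        A, B = y
        X = X0 + B0 - B
        r = params.kon * A * X - params.koff * B
        return [-(area / volume) * r / Nc, r]

    sol = solve_ivp(rhs, (0.0, t_end), [A0, B0], method="Radau",
                    rtol=1e-10, atol=1e-12)
    return sol.y[0, -1], sol.y[1, -1]
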