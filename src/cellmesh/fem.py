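"""P1 finite elements for bulk-surface reaction-diffusion.

The model is a cytosolic species A (uM) binding a membrane-bound species
X to form membrane-bound B (both molecules/um^2):

    dA/dt = D_A lap A                 in the volume
    dX/dt = D_X lapS X - kon A X + koff B     on the boundary
    dB/dt = D_B lapS B + kon A X - koff B     on the boundary
    D_A (n . grad A) = -kon A X + koff B      coupling flux

with lapS the Laplace-Beltrami operator discretized on the flat
triangulated boundary.  Time stepping is backward Euler with first-order
operator splitting: the volume solve uses lagged surface fields, the
surface solve uses the lagged volume trace, and the cycle is Picard
iterated to self-consistency within each step.  The X/B pair is solved as
one block system so their reaction terms cancel exactly and the surface
mass of X + B is conserved to solver precision.

Unit bookkeeping: the coupling flux mixes uM (volume) with
molecules/um^2 (surface); the conversion N_c = 602.2 molecules per
(um^3 uM) makes the flux dimensionally consistent.  Setting N_c = 1
recovers the nondimensional form of the equations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .core import MeshValidationError, SurfaceMesh, TetMesh
from .tetra import boundary_surface_of

__all__ = [
    "RDParameters",
    "RDState",
    "SingleSpeciesConfig",
    "assemble_volume_operators",
    "assemble_surface_operators",
    "step_coupled",
    "simulate_coupled",
    "simulate_single_species",
    "relative_mass_error",
    "l2_error_same_mesh",
    "integrate_field",
]


# ---------------------------------------------------------------------------
# Parameters and state
# ---------------------------------------------------------------------------


@dataclass
class RDParameters:
    """Rates, diffusivities and numerics of the coupled model.

    kon [1/(uM s)], koff [1/s], D_A/D_X/D_B [um^2/s], dt [s].
    ``unit_conversion`` is N_c, molecules per (um^3 uM); 602.2 converts
    micromolar volume concentrations to surface molecule counts.
    """

    kon: float = 1.0
    koff: float = 0.1
    D_A: float = 10.0
    D_X: float = 0.1
    D_B: float = 0.01
    dt: float = 0.01
    picard_tol: float = 1e-6
    picard_max: int = 25
    unit_conversion: float = 602.2

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        for name in ("kon", "koff", "D_A", "D_X", "D_B"):
            if getattr(self, name) < 0:
                raise ValueError("%s must be >= 0" % name)


@dataclass
class RDState:
    """Nodal fields at one time point: A on tet-mesh vertices (uM), X and
    B on boundary-surface vertices (molecules/um^2)."""

    A: np.ndarray
    X: np.ndarray
    B: np.ndarray
    t: float = 0.0
    diagnostics: dict = field(default_factory=dict)


@dataclass
class SingleSpeciesConfig:
    """Decay-diffusion model of a single volume species (e.g. calcium).

    D [um^2/s]; tau [s] linear decay time; ``flux`` is an opaque
    time-function J(t) (concentration um/s) applied on boundary faces
    carrying ``psd_marker``; zero-flux elsewhere; initial value ``u0``.
    """

    D: float = 10.0
    tau: float = 1.0
    flux: object = None
    psd_marker: int = 1
    u0: float = 0.0
    dt: float = 0.01

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be > 0")


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def assemble_volume_operators(tet: TetMesh):
    """Consistent P1 mass and stiffness matrices on a tet mesh.

    Stiffness rows sum to zero (constants are in its kernel); the total
    of the mass matrix equals the mesh volume.
    """
    vol = tet.tet_volumes()
    if np.any(vol <= 0):
        raise MeshValidationError("inverted tetrahedron in mesh")
    v = tet.vertices
    t = tet.tets
    n = tet.n_vertices
    J = np.stack([v[t[:, 1]] - v[t[:, 0]],
                  v[t[:, 2]] - v[t[:, 0]],
                  v[t[:, 3]] - v[t[:, 0]]], axis=1)
    Jinv = np.linalg.inv(J)
    # grads[e, i, :] = gradient of barycentric i on element e
    g = np.empty((len(t), 4, 3))
    g[:, 1:, :] = np.transpose(Jinv, (0, 2, 1))
    g[:, 0, :] = -g[:, 1:, :].sum(axis=1)
    Ke = np.einsum("eik,ejk,e->eij", g, g, vol)
    Me = (np.ones((4, 4)) + np.eye(4))[None, :, :] * (vol / 20.0)[:, None, None]
    rows = np.repeat(t, 4, axis=1).ravel()
    cols = np.tile(t, (1, 4)).ravel()
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    M = sp.coo_matrix((Me.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    return M, K


def _surface_elements(surf: SurfaceMesh):
    v = surf.vertices
    f = surf.faces
    e0 = v[f[:, 2]] - v[f[:, 1]]
    e1 = v[f[:, 0]] - v[f[:, 2]]
    e2 = v[f[:, 1]] - v[f[:, 0]]
    area = 0.5 * np.linalg.norm(np.cross(e2, -e1), axis=1)
    if np.any(area <= 0):
        bad = int(np.argmin(area))
        raise MeshValidationError("degenerate triangle (face %d)" % bad)
    return area, (e0, e1, e2)


def assemble_surface_operators(surf: SurfaceMesh):
    """P1 mass and Laplace-Beltrami stiffness on a triangle surface.

    Each triangle is assembled in its own plane, so on a planar patch
    this reduces to the classical 2D P1 assembly.  Refuses zero-area
    triangles.
    """
    f = surf.faces
    n = surf.n_vertices
    area, edges = _surface_elements(surf)
    # K_e[i, j] = (e_i . e_j) / (4 area), with e_i the edge opposite node i
    Ke = np.empty((len(f), 3, 3))
    for i in range(3):
        for j in range(3):
            Ke[:, i, j] = np.einsum("ij,ij->i", edges[i], edges[j]) / (4.0 * area)
    Me = (np.ones((3, 3)) + np.eye(3))[None, :, :] * (area / 12.0)[:, None, None]
    rows = np.repeat(f, 3, axis=1).ravel()
    cols = np.tile(f, (1, 3)).ravel()
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    M = sp.coo_matrix((Me.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    return M, K


def _weighted_surface_mass(surf, area, coeff):
    """Surface mass matrix with a P0 (per-triangle mean) coefficient."""
    f = surf.faces
    n = surf.n_vertices
    c = coeff[f].mean(axis=1)
    Me = (np.ones((3, 3)) + np.eye(3))[None, :, :] * \
        (c * area / 12.0)[:, None, None]
    rows = np.repeat(f, 3, axis=1).ravel()
    cols = np.tile(f, (1, 3)).ravel()
    return sp.coo_matrix((Me.ravel(), (rows, cols)), shape=(n, n)).tocsr()


def _lift_to_volume(Msurf, corr, n_vol):
    """Scatter a surface-node matrix into volume-node indexing."""
    coo = Msurf.tocoo()
    return sp.coo_matrix(
        (coo.data, (corr[coo.row], corr[coo.col])),
        shape=(n_vol, n_vol)).tocsr()


class _CoupledOperators:
    """Cached assembly for a tet mesh + its boundary surface."""

    def __init__(self, tet, surf=None, corr=None):
        if surf is None or corr is None:
            surf, corr = boundary_surface_of(tet)
        self.surf = surf
        self.corr = np.asarray(corr, dtype=np.int64)
        self.Mv, self.Kv = assemble_volume_operators(tet)
        self.Ms, self.Ks = assemble_surface_operators(surf)
        self.area, _ = _surface_elements(surf)
        self.n_vol = tet.n_vertices
        self.n_surf = surf.n_vertices


def _get_ops(tet, surf, corr, ops):
    return ops if ops is not None else _CoupledOperators(tet, surf, corr)


# ---------------------------------------------------------------------------
# Coupled stepping
# ---------------------------------------------------------------------------


def step_coupled(state, params, tet, surf=None, correspondence=None,
                 ops=None):
    """One backward-Euler step of size params.dt with Picard cycling.

    The volume equation is solved for A with lagged surface fields (the
    boundary reaction enters through the surface mass matrix, converted
    by N_c); the surface X/B pair is then solved as one block system with
    the lagged trace of A.  The cycle repeats until the maximum relative
    nodal change across all three fields drops below ``picard_tol`` or
    ``picard_max`` is reached (non-convergence is flagged in the returned
    state's diagnostics, never raised).
    """
    ops = _get_ops(tet, surf, correspondence, ops)
    dt = params.dt
    Nc = params.unit_conversion
    corr = ops.corr
    A_n, X_n, B_n = state.A, state.X, state.B

    A_new = A_n.copy()
    X_t, B_t = X_n.copy(), B_n.copy()
    base_A = ops.Mv @ (A_n / dt)
    base_XB = np.concatenate([ops.Ms @ (X_n / dt), ops.Ms @ (B_n / dt)])
    converged = False
    its = 0
    for its in range(1, params.picard_max + 1):
        prev = (A_new.copy(), X_t.copy(), B_t.copy())
        # --- volume solve for A with lagged X, B
        M_X = _weighted_surface_mass(ops.surf, ops.area, X_t)
        lhs = (ops.Mv / dt + params.D_A * ops.Kv
               + (params.kon / Nc) * _lift_to_volume(M_X, corr, ops.n_vol))
        rhs = base_A.copy()
        surf_rhs = (params.koff / Nc) * (ops.Ms @ B_t)
        np.add.at(rhs, corr, surf_rhs)
        A_new = spla.spsolve(lhs.tocsc(), rhs)
        A_trace = A_new[corr]
        # --- block surface solve for X, B with lagged A
        M_A = _weighted_surface_mass(ops.surf, ops.area, A_trace)
        S = ops.n_surf
        top = sp.hstack([ops.Ms / dt + params.D_X * ops.Ks + params.kon * M_A,
                         -params.koff * ops.Ms])
        bot = sp.hstack([-params.kon * M_A,
                         ops.Ms / dt + params.D_B * ops.Ks
                         + params.koff * ops.Ms])
        sol = spla.spsolve(sp.vstack([top, bot]).tocsc(), base_XB)
        X_t, B_t = sol[:S], sol[S:]
        # --- convergence: max relative nodal change over all fields
        change = 0.0
        for new, old in zip((A_new, X_t, B_t), prev):
            scale = max(np.abs(new).max(), np.abs(old).max(), 1e-300)
            change = max(change, float(np.abs(new - old).max()) / scale)
        if change < params.picard_tol:
            converged = True
            break
    return RDState(
        A=A_new, X=X_t, B=B_t, t=state.t + dt,
        diagnostics={"picard_iterations": its, "picard_converged": converged,
                     "picard_change": change},
    )


def initial_state(ops_or_tet, A0=1.0, X0=1000.0, B0=0.0):
    """Uniform initial conditions (defaults: A = 1 uM, X = 1000 /um^2)."""
    if isinstance(ops_or_tet, TetMesh):
        ops = _CoupledOperators(ops_or_tet)
    else:
        ops = ops_or_tet
    return RDState(A=np.full(ops.n_vol, float(A0)),
                   X=np.full(ops.n_surf, float(X0)),
                   B=np.full(ops.n_surf, float(B0)))


def simulate_coupled(tet, params=None, T_end=1.0, initial=None,
                     record_states=False):
    """Integrate the coupled model to T_end.

    Returns a dict trajectory with per-step time, min/mean/max of B, the
    surface mass of X + B, the total molecule count
    N_c * int A dV + int B dG, and Picard diagnostics; ``state`` holds the
    final fields.
    """
    params = params or RDParameters()
    ops = _CoupledOperators(tet)
    state = initial if initial is not None else initial_state(ops)
    ones_s = np.ones(ops.n_surf)
    ones_v = np.ones(ops.n_vol)

    def record(st):
        sx = float(ones_s @ (ops.Ms @ st.X))
        sb = float(ones_s @ (ops.Ms @ st.B))
        va = float(ones_v @ (ops.Mv @ st.A))
        return {
            "t": st.t, "B_min": float(st.B.min()),
            "B_mean": sb / float(ones_s @ (ops.Ms @ ones_s)),
            "B_max": float(st.B.max()),
            "surface_mass_XB": sx + sb,
            "total_molecules": params.unit_conversion * va + sb,
        }

    rows = [record(state)]
    states = [state] if record_states else []
    n_steps = int(round(T_end / params.dt))
    for _ in range(n_steps):
        state = step_coupled(state, params, tet, ops=ops)
        rows.append(record(state))
        if record_states:
            states.append(state)
    traj = {k: np.array([r[k] for r in rows]) for k in rows[0]}
    traj["state"] = state
    traj["ops"] = ops
    if record_states:
        traj["states"] = states
    return traj


# ---------------------------------------------------------------------------
# Single-species decay model
# ---------------------------------------------------------------------------


def simulate_single_species(tet, cfg, T_end):
    """Backward-Euler P1 solution of du/dt = D lap u - u/tau with a
    prescribed flux J(t) on the psd-marked boundary patch and zero flux
    elsewhere.

    Uses a lumped mass matrix, which preserves the discrete maximum
    principle of the continuous model on well-shaped meshes.  Returns a
    trajectory dict (t, u_min, u_mean, u_max, total = lumped integral)
    plus the final nodal field ``u``.
    """
    if not np.any(tet.boundary_face_markers == cfg.psd_marker):
        raise MeshValidationError(
            "no boundary face carries psd marker %d" % cfg.psd_marker)
    M, K = assemble_volume_operators(tet)
    mlump = np.asarray(M.sum(axis=1)).ravel()
    surf, corr = boundary_surface_of(tet)
    area, _ = _surface_elements(surf)
    psd = surf.face_markers == cfg.psd_marker
    # unit-flux load vector: one third of each marked face area per node
    load_s = np.zeros(surf.n_vertices)
    for fi in np.where(psd)[0]:
        for vv in surf.faces[fi]:
            load_s[vv] += area[fi] / 3.0
    load = np.zeros(tet.n_vertices)
    np.add.at(load, corr, load_s)

    dt = cfg.dt
    lhs = sp.diags(mlump * (1.0 / dt + 1.0 / cfg.tau)) + cfg.D * K
    solve = spla.factorized(lhs.tocsc())
    u = np.full(tet.n_vertices, float(cfg.u0)) if np.isscalar(cfg.u0) \
        else np.asarray(cfg.u0, dtype=float).copy()
    flux = cfg.flux if cfg.flux is not None else (lambda t: 0.0)

    def record(t, u):
        return {"t": t, "u_min": float(u.min()), "u_mean": float(u.mean()),
                "u_max": float(u.max()), "total": float(mlump @ u)}

    rows = [record(0.0, u)]
    n_steps = int(round(T_end / dt))
    for n in range(1, n_steps + 1):
        t1 = n * dt
        rhs = mlump * u / dt + float(flux(t1)) * load
        u = solve(rhs)
        rows.append(record(t1, u))
    traj = {k: np.array([r[k] for r in rows]) for k in rows[0]}
    traj["u"] = u
    traj["psd_area"] = float(area[psd].sum())
    return traj


# ---------------------------------------------------------------------------
# Error metrics
# ---------------------------------------------------------------------------


def integrate_field(u, mesh):
    """Integral of a nodal P1 field over its mesh (volume or surface)."""
    if isinstance(mesh, TetMesh):
        M, _ = assemble_volume_operators(mesh)
    else:
        M, _ = assemble_surface_operators(mesh)
    return float(np.ones(len(u)) @ (M @ np.asarray(u, dtype=float)))


def relative_mass_error(u1, mesh1, u2, mesh2):
    """Relative difference in total integrated amount between two fields,
    possibly living on different domains:

        eps_rel = | int u1 - int u2 | / int u2
    """
    i1 = integrate_field(u1, mesh1)
    i2 = integrate_field(u2, mesh2)
    return abs(i1 - i2) / abs(i2)


def l2_error_same_mesh(u1, u2, mesh):
    """L2 norm of the difference of two nodal fields on one mesh.

    Restricted to a shared mesh: across differing domains the integrand
    is undefined where the domains do not overlap, so this metric does
    not apply there (use :func:`relative_mass_error`).
    """
    u1 = np.asarray(u1, dtype=float)
    u2 = np.asarray(u2, dtype=float)
    if u1.shape != u2.shape:
        raise ValueError("fields must share the mesh (same length)")
    if isinstance(mesh, TetMesh):
        M, _ = assemble_volume_operators(mesh)
    else:
        M, _ = assemble_surface_operators(mesh)
    d = u1 - u2
    return float(np.sqrt(max(d @ (M @ d), 0.0)))
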