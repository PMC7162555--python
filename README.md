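# cellmesh

Surface meshes reconstructed from volume electron microscopy (serial
block-face or FIB-SEM stacks of cells and organelles) arrive in poor
shape: the axial slice thickness far exceeds the lateral pixel size, so
contour-tiled surfaces carry staircase artifacts, misaligned-slice
jitter, sliver triangles and sometimes non-manifold junctions.  Finite
element simulation on such a mesh is inaccurate or impossible.

`cellmesh` is a library + CLI for turning such meshes into
simulation-ready geometry and then actually simulating on them:

* **Conditioning** — angle-weighted vertex smoothing with local
  structure tensor (LST) damping, angle-based edge flipping, anisotropic
  normal smoothing, and feature-aware vertex-removal decimation.
* **Verification** — manifoldness classification and Betti numbers
  (β₀, β₁, β₂) via an incremental union-find filtration, so conditioning
  can be proven topology-preserving.
* **Geometry** — per-vertex principal curvatures κ₁ ≥ κ₂ by the
  Meyer–Desbrun–Schröder–Barr (MDSB) discrete operators (convex regions
  negative), mesh quality reports (angles, radius-ratios n·rᵢ/rₒ).
* **Interchange** — ASCII OFF/OBJ/PLY I/O with integer face markers,
  boundary/region marking, TetGen `.smesh`/`.node`/`.ele`/`.face`
  dialects for constrained Delaunay tetrahedralization.
* **Simulation** — P1 finite elements for coupled volume–surface
  reaction–diffusion (a cytosolic species A binding membrane-bound X to
  form membrane-bound B), backward Euler with first-order operator
  splitting and Picard cycling, plus a single-species decay model with a
  prescribed receptor flux on a marked membrane patch.

## The core methods, briefly

**Smoothing.** For a vertex x with ordered 1-ring v₁…v_N, each corner
∠(v_{i−1}, v_i, v_{i+1}) defines a perpendicularly bisecting plane Π_i;
x is projected onto each plane and the projections are averaged with
weights α_i + 1, α_i = ê_{i−1}·ê_{i+1}:

    x̄ = Σ (α_i + 1) x_i / Σ (α_i + 1)

The move is damped along high-curvature directions using the LST
T(v) = Σ n_i ⊗ n_i (unit vertex normals of the r-ring), via its
eigenpairs (λ_k, E_k):

    x̂ = x + Σ_k [1/(1 + λ_k)] [(x̄ − x)·E_k] E_k

The eigen-spectrum of T classifies the local geometry — planes
(λ₁ ≫ λ₂ ≈ λ₃ ≈ 0), ridges (λ₁ ≈ λ₂ ≫ λ₃ ≈ 0), spheres/saddles
(λ₁ ≈ λ₂ ≈ λ₃ > 0) — and drives decimation: flat vertices satisfy
λ₂/λ₁ < R₁, dense vertices max_i d(x, v_i)/D̄ < R₂.

**Coupled reaction–diffusion.**  With Ω the cytosol and ∂Ω the membrane,

    ∂A/∂t = D_A ΔA                      in Ω
    ∂X/∂t = D_X Δ_S X − k_on A X + k_off B    on ∂Ω
    ∂B/∂t = D_B Δ_S B + k_on A X − k_off B    on ∂Ω
    D_A (n·∇A) = −k_on A X + k_off B          on ∂Ω

discretized by P1 elements (Laplace–Beltrami on the flat triangulated
boundary), backward Euler in time, Picard-iterated operator splitting
between the volume and surface solves.  X and B are solved as one block
system, so ∫(X+B) dΓ is conserved to machine precision, and the unit
conversion N_c = 602.2 molecules/(μm³·μM) makes the total molecule count
N_c ∫A dΩ + ∫B dΓ conserved to the Picard tolerance.

No EM datasets ship with the package; `cellmesh.fixtures` generates the
study geometries, most importantly `contour_stack_sphere` — a sphere
with z-quantized slices and per-slice lateral misalignment noise that
reproduces the jagged regime of real contour-tiled reconstructions.

## Worked example

```python
import cellmesh as cm
from cellmesh import fixtures as fx

mesh = fx.contour_stack_sphere(subdivisions=3)     # jagged unit sphere
rep = cm.quality_report(mesh)
print(rep.angle_std, rep.surface_area, rep.enclosed_volume)
# 12.80 12.951 4.1789

out = cm.smooth(mesh, cm.SmoothingConfig(iterations=20))
rep2 = cm.quality_report(out)
print(rep2.angle_std, rep2.surface_area, rep2.enclosed_volume)
# 3.02 12.943 4.1780
print(cm.betti_numbers(out).as_tuple())
# (1, 0, 1)
```

Twenty sweeps drop the angle standard deviation from 12.8° to 3.0°
(angles pile up near the equilateral 60°), while the enclosed volume
changes by 0.02% and the topology stays a single watertight genus-0
surface — the conditioning is feature- and topology-preserving.

Simulating the coupled model on a tetrahedralized ball (k_on = 1
μM⁻¹s⁻¹, k_off = 0.1 s⁻¹, D_A = 10, D_X = 0.1, D_B = 0.01 μm²/s,
A(0) = 1 μM, X(0) = 1000 μm⁻², B(0) = 0):

```python
traj = cm.simulate_coupled(fx.tet_ball(1), cm.RDParameters(), T_end=1.0)
print(traj["B_mean"][-1])          # 165.52  molecules/um^2 bound at t = 1 s
print(traj["surface_mass_XB"][-1] / 10.4178)  # 1000.0: X+B conserved
# (10.4178 is the boundary area of the coarse tet ball)
```

The same pipelines are scriptable from the shell:

```sh
cellmesh synth contour_stack_sphere --subdivisions 3 -o jagged.off
cellmesh condition jagged.off conditioned.off --iters 20
cellmesh betti conditioned.off
cellmesh curvature conditioned.off --out curvatures.csv
cellmesh simulate sim.yaml --out trajectory.csv
```

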