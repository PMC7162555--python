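# Methods

This note documents the models, numerical choices and design decisions in
`cellmesh`, and what the synthetic fixtures do and do not establish about
behavior on real microscopy-derived meshes.

## Mesh model

A surface mesh is an indexed triangle set with counter-clockwise
orientation seen from outside and one integer marker per face (0 =
unmarked).  Coordinates are unitless lengths; the simulation layer reads
them as micrometres, which matches the units of the default diffusion
coefficients (μm²/s) and rate constants.  Edges are stored as sorted
vertex pairs.  On load, a manifold orientable mesh with inconsistent face
windings is repaired by propagating orientation across face adjacency,
and a closed mesh is flipped globally if its signed volume is negative,
so outward orientation is canonical.

Classification is total: a mesh is non-manifold if any edge has three or
more incident faces or any vertex star is not a single fan; closed if
additionally every edge has exactly two faces; manifold-with-boundary
otherwise.  Orientability is decided by the same propagation used for
repair.

Vertex normals are the angle-weighted average of incident face normals.
The weighting is a design choice the smoothing literature leaves open;
angle weights are used because area weights over-emphasize exactly the
sliver faces that conditioning is trying to remove.

## Conditioning

### Angle-weighted smoothing with structure-tensor damping

Each sweep visits vertices sequentially in index order (deterministic,
no randomness anywhere in conditioning).  For vertex x with ordered
1-ring v₁…v_N, the corner at v_i defines the perpendicularly bisecting
plane Π_i of ∠(v_{i−1}, v_i, v_{i+1}): the plane through v_i whose
normal is ê_{i−1} − ê_{i+1} (unit edge vectors), i.e. the plane
containing the angle bisector and the direction normal to the corner's
plane — the 3D lift of the 2D torsion-spring construction.  x is
projected onto each Π_i and the projections averaged with weights
α_i + 1 where α_i = ê_{i−1}·ê_{i+1}; corners with nearly parallel edges
(undefined plane) contribute x itself.  Boundary vertices never move.

The move is damped through the local structure tensor
T(v) = Σ nᵢ ⊗ nᵢ over the unit vertex normals of the r-ring
*including the center vertex* (a switchable choice: including the
center stabilizes λ₁ at valence-3 vertices; the eigenvalues simply shift
by the center's rank-one term).  With eigenpairs λ₁ ≥ λ₂ ≥ λ₃ ≥ 0 and
E₁, E₂, E₃:

    x̂ = x + Σ_k [1/(1 + λ_k)] [(x̄ − x)·E_k] E_k

so each eigencomponent of the move shrinks by 1/(1+λ) and |x̂ − x| ≤
|x̄ − x| always.  The tensor field is recomputed once per sweep, not per
vertex update — a cost/fidelity compromise; per-update recomputation
changes results negligibly at fixture scale but costs an extra O(ring)
eigen-decomposition per vertex visit.

### Edge flipping

After every sweep (configurable period) an edge-flip pass visits all
interior edges and flips an edge iff (a) the minimum of the six
post-flip angles exceeds the minimum of the six pre-flip angles, and
(b) neither new face normal opposes the mean of the two old face normals
(guarding against fold-over on curved regions), and (c) the opposite
diagonal does not already exist as an edge (which would create a
duplicate face or non-manifold edge).  The pass iterates to a fixpoint
with a worklist of edges whose surrounding geometry changed, capped at
20 rounds.  By construction the global minimum angle never decreases.

### Anisotropic normal smoothing

For each face i with normal n_i, the anisotropic mean of its edge
neighbors' normals is

    n̄_i = normalize( Σ_j e^{K(n_i·n_ij)} n_ij / Σ_j e^{K(n_i·n_ij)} )

K > 0 sets the anisotropy: as K → 0 this reduces to the arithmetic
neighbor mean (isotropic smoothing); large K suppresses cross-crease
neighbors exponentially and preserves sharp features.  Boundary faces
average over their existing neighbors.  Each vertex is then replaced by
the 1/a_i-weighted average (a_i = incident face area) of its rotations
about each incident face's opposite edge by the signed angle aligning
that face's normal with n̄_i.  The 1/a_i weight follows the printed
update rule of the scheme this implements; its prose description says
"weighted by area", and the two disagree — the printed 1/a_i form is
implemented, which weights small (sliver) faces more strongly and is the
variant that empirically flattens staircase artifacts.

Flat meshes are exact fixed points (every rotation angle is zero).
Normal smoothing is the step that actually removes bump *area*: on the
jagged sphere fixture, vertex smoothing alone equalizes angles but —
because the structure tensor legitimately classifies the staircase as a
feature — barely reduces area, while interleaved normal-smoothing rounds
bring the area down toward the smooth limit.  When
`SmoothingConfig.normal_smooth_iterations = P > 0`, one normal round
runs after every ⌊iterations/(P+1)⌋ sweeps, so angle sweeps always
follow and re-equalize.

### Decimation

Vertices are selected by two composable criteria: flatness
(λ₂/λ₁ < R₁, with λ₁ = 0 counting as perfectly flat) and density
(longest 1-ring edge below R₂ times the global mean edge length).
Selected interior vertices are removed one at a time in ascending index
order; any vertex whose neighborhood was touched earlier in the pass is
deferred to the next pass.  The hole left by a removal is refilled
recursively: the loop vertex with the fewest current incident edges
(ties: lowest index) is connected to the partner that splits the loop
most evenly (ties: lowest index; partners whose chord already exists as
a mesh edge are skipped), and the two sub-loops are filled the same way;
3-loops become faces.  New faces inherit the majority marker of the
removed patch, and the patch is relaxed with two local angle-weighted
smoothing rounds.  Each removal decrements (V, E, F) by (1, 3, 2), so
the Euler characteristic — and, the surface staying manifold, the full
topology — is preserved.

Note that on finely meshed curved surfaces the flatness criterion *does*
fire: λ₂/λ₁ scales with the square of the local angular extent of the
r-ring, so a sphere meshed much finer than its curvature radius is
locally flat by any measurable criterion.  Only coarse meshes of curved
regions (icosahedron-scale) are protected by R₁ = 0.1.

## Topology verification

Betti numbers are computed by an incremental filtration with union-find:
vertices enter first (β₀ = V), then edges (each either merges two
components or raises β₁), then faces (each lowers β₁).  For surface
complexes there are no tetrahedra to detect enclosed voids, so after the
filtration every connected component that is closed (all edges in two
faces) *and orientable* adds one to β₁ and one to β₂.  The credit is per
component, so k disjoint closed surfaces report β₂ = k.  Closed
non-orientable components (e.g. a combinatorial Klein bottle) receive no
credit — the reported numbers then coincide with the rational Betti
numbers — and are counted in a `nonorientable_closed` flag.  If any edge
carries three or more faces the mesh is not a manifold: only β₀ is
reported and the result is flagged incomplete.

## Curvature

Mean curvature uses the cotangent Laplacian of position over the mixed
area (Meyer et al.'s obtuse-safe variant: Voronoi area in non-obtuse
triangles, area/2 at the obtuse corner and area/4 at the others
otherwise); Gaussian curvature uses the angle defect over the same
mixed area.  The mean curvature is signed against the outward
angle-weighted vertex normal, and

    κ₁,₂ = −(H ∓ √max(H² − G, 0)),   κ₁ ≥ κ₂,

which realizes the convention that convex (outward-bulging) regions are
negative: the unit sphere reports κ₁ = κ₂ = −1.  The clamping of
H² − G at zero handles discretization noise near umbilics.  These are
estimates for qualitative use; the angle-defect Gaussian is only exact
in aggregate (the total equals 2πχ to rounding — used as a test oracle),
and pointwise accuracy degrades at irregular valences.

## Marking and tetrahedralization interchange

Faces are marked by explicit index sets, centroid predicates, or
seed-face + edge-adjacency hops; marker 0 is reserved for "unmarked".
A scene of closed marked surfaces with per-region interior seed points
is exported as a TetGen ASCII `.smesh` (merged node block, per-facet
markers, empty hole block, region block).  Before export, region points
are verified by a ray-parity containment test (quasi-random ray
directions, retried on near-degenerate hits) and surface pairs are
screened for intersection (axis-aligned bounding-box prefilter, then
segment-vs-triangle tests both ways; exactly coplanar overlap is not
detected) because the downstream tetrahedralizer fails opaquely on
intersecting input.  Constrained Delaunay tetrahedralization itself is
delegated to TetGen or any compatible tool; its `.node`/`.ele`/`.face`
output is read back with the index base (0 or 1) auto-detected, region
markers from the first `.ele` attribute column and boundary markers from
the `.face` marker column.

So that every downstream computation runs without the external tool, the
fixtures module builds structured tet meshes directly: `tet_ball`
layers a subdivided octahedron sphere radially (prisms split into eight
tets around a Steiner centroid, quads split by the minimal-global-index
diagonal rule so the decomposition conforms across prisms), and
`star_tetrahedralize` cones a closed star-shaped surface to an interior
point — the latter deliberately transfers surface quality defects into
the volume mesh, which is what the conditioning-versus-simulation-error
study needs.

## Finite elements

P1 (linear) elements throughout.  Volume: consistent mass
M_e = (V/20)(1 + δ_ij) and stiffness from barycentric gradients.
Surface: each triangle assembled in its own plane (flat-triangle
Laplace–Beltrami), mass (A/12)(1 + δ_ij), stiffness eᵢ·eⱼ/(4A) with
eᵢ the edge opposite node i.  Zero-area triangles and inverted tets are
refused at assembly.

### Coupled volume–surface stepping

Backward Euler with step δt and first-order operator splitting: the
volume equation is solved for A with the surface fields lagged (the
boundary reaction enters through a surface mass matrix weighted by the
per-triangle mean of the lagged coefficient — a P0 projection that keeps
the operator symmetric); then X and B are solved together as one 2S×2S
block system with the lagged trace of A; the cycle repeats (Picard)
until the maximum relative nodal change across A, X, B falls below
`picard_tol` (default 1e-6, cap 25 cycles; non-convergence is flagged in
diagnostics, never raised).  Because X and B are solved monolithically,
their reaction terms cancel exactly in the sum and 1ᵀK = 0, so
∫(X+B) dΓ is conserved to solver precision independent of δt and Picard
state.

The boundary condition couples μM (volume) to molecules/μm² (surface);
the conversion N_c = 602.2 molecules/(μm³·μM) multiplies the volume
concentration in the flux so both sides are dimensionally consistent.
N_c is configurable; N_c = 1 recovers the nondimensional form of the
equations.  At Picard convergence the weighted-mass symmetry
1ᵀM_X A = 1ᵀM_A X makes the total molecule count
N_c ∫A dΩ + ∫B dΓ conserved to the Picard tolerance.

Linear systems are solved by sparse direct factorization (SuperLU),
adequate at desk scale (10³–10⁴ unknowns); the iteration-free
single-species operator is factorized once per run.

Fully converged Picard cycling makes the split scheme equivalent to
monolithic backward Euler, so the observed convergence order in δt is
one (measured 0.91 on a δt-halving triplet; asserted within [0.8, 1.2]).

### Single-species decay model

du/dt = DΔu − u/τ with flux J(t) prescribed on boundary faces carrying
the psd marker (the postsynaptic-density patch; J is an opaque
user-supplied time function, e.g. a receptor-gating model), zero flux
elsewhere, u(·,0) = u₀.  This solver uses a *lumped* mass matrix: with
backward Euler it preserves the discrete maximum principle on
well-shaped meshes (verified on the layered ball: nodal u stays in
[0, max u₀] for J ≡ 0), at the cost of slightly more numerical
diffusion than the consistent-mass coupled solver.  Uniform initial data
decays exactly geometrically, (1 + δt/τ)⁻ⁿ, matching e^{−t/τ} to <1%
for δt ≤ τ/100; total-mass balance d/dt ∫u dΩ = J·(patch area) holds
exactly in the lumped discrete sense.

### Error metrics

Between meshes whose domains differ slightly (as after conditioning
perturbs the boundary), the L2 difference is undefined where the domains
do not overlap, so the cross-mesh metric is the relative difference of
integrated totals, ε_rel = |∫u′ − ∫u| / ∫u.  The L2 metric
√(∫(u₁−u₂)² dΩ) via the mass matrix is provided only for fields on one
shared mesh.

## Synthetic fixtures: what they emulate and what they do not

`contour_stack_sphere` reproduces the two dominant artifacts of
contour-tiled EM reconstructions on a geometry with known ground truth:
z-quantization of vertex positions to slice planes (the axial staircase
of ~25 nm sections against ~3 nm lateral pixels) and rigid per-slice
lateral offsets plus smaller per-vertex jitter (alignment/registration
and segmentation noise).  Defaults — radius 1, slice thickness 0.1,
noise amplitude 0.02, icosphere subdivision 5 (mean edge ≈ 0.03, a
3× lateral-to-axial resolution ratio) — put the triangle-angle standard
deviation at ≈33°, the badly-conditioned regime of real data.  The
staircase is kept deliberately; only noise that flips slice-spanning
faces (local fold-over, a self-intersection proxy) or produces exactly
degenerate faces triggers regeneration at halved noise.  The fixture is
always a closed genus-0 manifold by construction.

What passing tests on these fixtures do *not* show: robustness to
genuinely non-manifold junctions, holes, or disconnected fragments
(conditioning refuses non-manifold input by contract); behavior on
high-genus or multi-organelle geometries beyond the torus and nested
two-sphere scenes; segmentation errors that change topology.  Those
require curation upstream of this package.

Problem sizes were chosen so the full default verification runs on one
CPU in minutes: the headline conditioning runs 50 sweeps on the
10,242-vertex fixture, the coupled simulation integrates 100 backward
Euler steps on a 455-vertex / 2,176-tet ball, and the conditioning-error
series uses the 642-vertex fixture with fan tetrahedralization.

## Degenerate inputs and tie-breaks

* Radius-ratios of degenerate simplices (collinear/coplanar) are 0, not
  NaN, so quality histograms are total.
* Duplicate-face and out-of-range indices are rejected at construction;
  OBJ indices convert from 1-based at I/O only.
* Enclosed volume of an open or non-orientable surface is reported
  absent (`None`), never zero.
* In hole refilling, all ties break toward the lowest vertex index;
  decimation processes candidates in ascending index order.  The whole
  conditioning stack is deterministic.
* A flat-grid interior corner with exactly anti-parallel edges gets
  bisecting-plane weight α + 1 = 0 and so drops out of the smoothing
  average naturally.
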