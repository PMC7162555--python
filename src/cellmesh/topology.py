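"""Betti numbers of triangulated surfaces.

Incremental algorithm over the simplex filtration (vertices, then edges,
then faces) with union-find, in the style of Delfinado-Edelsbrunner,
adapted to surface meshes where no tetrahedra are available to detect
enclosed voids: after the filtration, every connected component that is a
closed orientable 2-manifold contributes one enclosed void (beta2 += 1)
and one extra handle-free cycle closure (beta1 += 1).  If any edge has
three or more incident faces the mesh is not a manifold and only beta0
is reported (``complete=False``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SurfaceMesh, _check_orientable

__all__ = ["BettiResult", "betti_numbers"]


@dataclass
class BettiResult:
    """beta0: connected components; beta1: independent 1-cycles;
    beta2: enclosed voids; complete=False when only beta0 is valid.
    ``nonorientable_closed`` counts closed components that were not
    credited a void because they are non-orientable."""

    beta0: int
    beta1: int
    beta2: int
    complete: bool = True
    nonorientable_closed: int = 0

    def as_tuple(self):
        return (self.beta0, self.beta1, self.beta2)


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def betti_numbers(mesh: SurfaceMesh) -> BettiResult:
    """First three Betti numbers of a triangulated surface.

    Vertices are inserted first (each a new component), then edges (an
    edge either merges two components or closes a 1-cycle), then faces
    (each face kills a 1-cycle).  Finally each closed orientable component
    re-credits one 1-cycle and adds one void.  Isolated vertices count as
    components.
    """
    V = mesh.n_vertices
    ef = mesh.edge_faces
    uf = _UnionFind(V)

    if any(len(f) > 2 for f in ef.values()):
        beta0 = V
        for (a, b) in ef:
            if uf.union(a, b):
                beta0 -= 1
        return BettiResult(beta0=beta0, beta1=0, beta2=0, complete=False)

    beta0 = V
    beta1 = 0
    for (a, b) in ef:
        if uf.union(a, b):
            beta0 -= 1
        else:
            beta1 += 1
    beta1 -= mesh.n_faces

    # Closed-and-orientable credit, per connected component.
    closed_or = 0
    nonor = 0
    if mesh.n_faces:
        roots: dict = {}
        for (a, b), fids in ef.items():
            r = uf.find(a)
            roots.setdefault(r, True)
            if len(fids) != 2:
                roots[r] = False
        for r, is_closed in sorted(roots.items()):
            if not is_closed:
                continue
            comp_faces = np.array([
                fi for fi in range(mesh.n_faces)
                if uf.find(int(mesh.faces[fi][0])) == r
            ])
            sub = SurfaceMesh(mesh.vertices, mesh.faces[comp_faces],
                              validate=False)
            orientable, _ = _check_orientable(sub)
            if orientable:
                closed_or += 1
            else:
                nonor += 1
    beta1 += closed_or
    beta2 = closed_or
    return BettiResult(beta0=beta0, beta1=beta1, beta2=beta2,
                       complete=True, nonorientable_closed=nonor)
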