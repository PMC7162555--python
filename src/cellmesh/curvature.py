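"""Discrete principal curvatures (Meyer-Desbrun-Schroeder-Barr scheme).

Mean curvature comes from the cotangent-weighted Laplacian of position
over the mixed (obtuse-safe Voronoi) area, signed against the outward
vertex normal; Gaussian curvature from the angle defect over the mixed
area.  Principal curvatures follow the convention that convex
(outward-bulging) regions are NEGATIVE:

    kappa_{1,2} = -(H -/+ sqrt(max(H^2 - G, 0))),   kappa1 >= kappa2,

so the exterior of a unit sphere has kappa1 = kappa2 = -1.  Units are
1/length.  These are estimates suitable for qualitative comparison; the
angle-defect Gaussian term is exact only in the Gauss-Bonnet aggregate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    CLOSED_MANIFOLD,
    MeshValidationError,
    _corner_angles,
    classify_manifold,
    vertex_normals,
)

__all__ = ["CurvatureField", "mdsb_curvatures", "gauss_bonnet_total"]


@dataclass
class CurvatureField:
    """Per-vertex principal curvatures (kappa1 >= kappa2, convex negative)
    and the mixed Voronoi areas used to normalize them."""

    kappa1: np.ndarray
    kappa2: np.ndarray
    mixed_area: np.ndarray


def _cotangents(mesh):
    """(F, 3) cotangent of the interior angle at each face corner."""
    ang = _corner_angles(mesh)
    return 1.0 / np.tan(np.clip(ang, 1e-12, np.pi - 1e-12))


def _mixed_areas(mesh):
    """Meyer et al. obtuse-safe mixed areas per vertex.

    Voronoi area for non-obtuse triangles; for an obtuse triangle, half
    the area goes to the obtuse corner and a quarter to each other corner.
    """
    v = mesh.vertices
    f = mesh.faces
    ang = _corner_angles(mesh)
    cot = _cotangents(mesh)
    area = 0.5 * np.linalg.norm(
        np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]]), axis=1)
    mixed = np.zeros(mesh.n_vertices)
    obtuse_face = (ang > np.pi / 2).any(axis=1)
    edge_sq = np.empty((len(f), 3))
    # edge opposite corner k has endpoints k+1, k+2
    for k in range(3):
        e = v[f[:, (k + 2) % 3]] - v[f[:, (k + 1) % 3]]
        edge_sq[:, k] = np.einsum("ij,ij->i", e, e)
    for k in range(3):
        corner = f[:, k]
        # Voronoi area at corner k: (|e_{k+1}|^2 cot_{k+1} + |e_{k+2}|^2 cot_{k+2}) / 8
        voro = (edge_sq[:, (k + 1) % 3] * cot[:, (k + 1) % 3]
                + edge_sq[:, (k + 2) % 3] * cot[:, (k + 2) % 3]) / 8.0
        contrib = np.where(
            obtuse_face,
            np.where(ang[:, k] > np.pi / 2, area / 2.0, area / 4.0),
            voro,
        )
        np.add.at(mixed, corner, contrib)
    return mixed


def _angle_defects(mesh):
    ang = _corner_angles(mesh)
    s = np.zeros(mesh.n_vertices)
    for k in range(3):
        np.add.at(s, mesh.faces[:, k], ang[:, k])
    return 2.0 * np.pi - s


def gauss_bonnet_total(mesh):
    """Total angle defect of a closed mesh: equals 2*pi*chi exactly."""
    cls, _ = classify_manifold(mesh)
    if cls != CLOSED_MANIFOLD:
        raise MeshValidationError("gauss_bonnet_total requires a closed mesh")
    return float(_angle_defects(mesh).sum())


def mdsb_curvatures(mesh):
    """Per-vertex principal curvatures of a closed orientable mesh.

    Refuses open or non-orientable meshes; assumes outward orientation
    (as produced by the loaders and fixtures).
    """
    cls, orientable = classify_manifold(mesh)
    if cls != CLOSED_MANIFOLD or not orientable:
        raise MeshValidationError(
            "mdsb_curvatures requires a closed orientable mesh "
            "(classification: %s, orientable=%s)" % (cls, orientable))
    v = mesh.vertices
    f = mesh.faces
    cot = _cotangents(mesh)
    # Cotangent Laplacian of position: K(x_i) = sum_j (cot a + cot b)(x_i - x_j)
    lap = np.zeros_like(v)
    for k in range(3):
        i = f[:, (k + 1) % 3]
        j = f[:, (k + 2) % 3]
        w = cot[:, k][:, None]
        d = v[i] - v[j]
        np.add.at(lap, i, w * d)
        np.add.at(lap, j, -w * d)
    mixed = np.maximum(_mixed_areas(mesh), 1e-300)
    kvec = lap / (2.0 * mixed[:, None])  # = 2 H n for the smooth limit
    normals = vertex_normals(mesh)
    # H > 0 on an outward-oriented convex surface (sphere: H = 1/R)
    H = 0.5 * np.einsum("ij,ij->i", kvec, normals)
    G = _angle_defects(mesh) / mixed
    disc = np.sqrt(np.maximum(H * H - G, 0.0))
    kappa1 = -(H - disc)
    kappa2 = -(H + disc)
    return CurvatureField(kappa1=kappa1, kappa2=kappa2, mixed_area=mixed)
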