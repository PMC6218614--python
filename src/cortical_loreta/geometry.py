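"""Metric quantities on triangle meshes.

Everything the discrete Laplace-Beltrami operators consume lives here: edge
lengths, the two angles opposite each edge and their cotangents, triangle
areas via a numerically stabilized Heron formula (robust for needle-like
triangles), and the per-vertex mixed Voronoi area

    A_mixed(i) = Σ over incident triangles T of
        Voronoi region of p_i in T   if T is non-obtuse,
        area(T)/2                    if the angle of T at p_i is obtuse,
        area(T)/4                    if T is obtuse elsewhere.

The mixed regions tile the surface, so Σ_i A_mixed(i) equals the total
surface area — an invariant the test suite enforces to 1e-10 relative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import TriMesh

__all__ = ["MeshGeometry", "compute_geometry", "triangle_area_stable", "cotangent_pair", "mixed_area"]


def triangle_area_stable(a: float, b: float, c: float, tol: float = 1e-12) -> float:
    """Triangle area from side lengths via Kahan's stabilized Heron formula.

    Sides are sorted ``a >= b >= c`` and the area computed as

        area = 0.25 * sqrt((a+(b+c)) * (c-(a-b)) * (c+(a-b)) * (a+(b-c)))

    with the parenthesisation kept exactly as written, which avoids the
    catastrophic cancellation of the classical Heron formula on needle
    triangles.
    """
    a, b, c = sorted((float(a), float(b), float(c)), reverse=True)
    if c <= 0:
        raise ValueError("side lengths must be positive")
    # triangle inequality: c - (a - b) >= 0 up to rounding
    slack = c - (a - b)
    if slack < -tol * a:
        raise ValueError(f"triangle inequality violated: sides {a}, {b}, {c}")
    slack = max(slack, 0.0)
    prod = (a + (b + c)) * slack * (c + (a - b)) * (a + (b - c))
    return 0.25 * np.sqrt(prod)


def _triangle_areas(v: np.ndarray, tris: np.ndarray) -> np.ndarray:
    p0, p1, p2 = v[tris[:, 0]], v[tris[:, 1]], v[tris[:, 2]]
    la = np.linalg.norm(p1 - p2, axis=1)  # opposite corner 0
    lb = np.linalg.norm(p2 - p0, axis=1)
    lc = np.linalg.norm(p0 - p1, axis=1)
    sides = np.sort(np.column_stack([la, lb, lc]), axis=1)[:, ::-1]
    a, b, c = sides[:, 0], sides[:, 1], sides[:, 2]
    prod = (a + (b + c)) * np.maximum(c - (a - b), 0.0) * (c + (a - b)) * (a + (b - c))
    return 0.25 * np.sqrt(prod), np.column_stack([la, lb, lc])


@dataclass
class MeshGeometry:
    """Precomputed metric data for one :class:`~cortical_loreta.mesh.TriMesh`."""

    edge_lengths: np.ndarray            # (E,) mm, aligned with mesh.edges
    triangle_areas: np.ndarray          # (K,) mm^2
    corner_cot: np.ndarray              # (K, 3) cotangent of the angle at each corner
    edge_opposite_cots: list[list[float]]  # per edge: 1 (boundary) or 2 cotangents
    mixed_areas: np.ndarray             # (m,) mm^2
    total_area: float                   # mm^2

    def edge_length(self, i: int, j: int, mesh: TriMesh) -> float:
        eid = mesh.edge_index()[(min(i, j), max(i, j))]
        return float(self.edge_lengths[eid])


def compute_geometry(mesh: TriMesh) -> MeshGeometry:
    """Compute all metric quantities of a mesh in one pass."""
    v = mesh.vertices
    tris = mesh.triangles
    edges = mesh.edges
    edge_lengths = np.linalg.norm(v[edges[:, 0]] - v[edges[:, 1]], axis=1)
    if np.any(edge_lengths <= 0):
        raise ValueError("mesh contains a zero-length edge (duplicate vertices)")
    areas, side_lengths = _triangle_areas(v, tris)
    if np.any(areas <= 0):
        bad = int(np.argmin(areas))
        raise ValueError(f"degenerate triangle {bad} has zero area")
    # cotangent at corner k of triangle: cot = (b² + c² − a²) / (4·area),
    # a the side opposite the corner; consistent with the stabilized areas.
    sq = side_lengths**2  # column k is the squared side opposite corner k
    corner_cot = np.empty_like(sq)
    for k in range(3):
        b2 = sq[:, (k + 1) % 3]
        c2 = sq[:, (k + 2) % 3]
        corner_cot[:, k] = (b2 + c2 - sq[:, k]) / (4.0 * areas)

    eidx = mesh.edge_index()
    edge_opposite: list[list[float]] = [[] for _ in range(len(edges))]
    for tid, tri in enumerate(tris):
        for k in range(3):
            i, j = tri[(k + 1) % 3], tri[(k + 2) % 3]
            eid = eidx[(min(i, j), max(i, j))]
            edge_opposite[eid].append(float(corner_cot[tid, k]))

    mixed = _mixed_areas(mesh, areas, sq, corner_cot)
    return MeshGeometry(
        edge_lengths=edge_lengths,
        triangle_areas=areas,
        corner_cot=corner_cot,
        edge_opposite_cots=edge_opposite,
        mixed_areas=mixed,
        total_area=float(areas.sum()),
    )


def _mixed_areas(
    mesh: TriMesh, areas: np.ndarray, sq: np.ndarray, corner_cot: np.ndarray,
    cos_tol: float = 1e-12,
) -> np.ndarray:
    """Per-vertex mixed Voronoi areas (Meyer's finite-volume regions).

    Obtuseness is decided on the law-of-cosines numerator with relative
    tolerance ``cos_tol``; right angles fall into the (equivalent in the
    limit) Voronoi branch.  The Voronoi region of corner A in a non-obtuse
    triangle is the circumcenter decomposition, equal to
    ``(|AB|²·cot C + |AC|²·cot B) / 8``.
    """
    m = mesh.n_vertices
    mixed = np.zeros(m)
    tris = mesh.triangles
    scale = np.max(sq, axis=1)
    # numerator of cos at corner k: b² + c² − a²  (negative ⇔ obtuse at k)
    numer = np.empty_like(sq)
    for k in range(3):
        numer[:, k] = sq[:, (k + 1) % 3] + sq[:, (k + 2) % 3] - sq[:, k]
    obtuse_corner = np.where(
        np.min(numer, axis=1) < -cos_tol * scale, np.argmin(numer, axis=1), -1
    )
    for tid, tri in enumerate(tris):
        oc = obtuse_corner[tid]
        if oc < 0:  # non-obtuse: circumcenter (Voronoi) decomposition
            for k in range(3):
                lb2 = sq[:, (k + 1) % 3][tid]  # side opposite corner k+1 (= edge A-C)
                lc2 = sq[:, (k + 2) % 3][tid]
                cot_b = corner_cot[tid, (k + 1) % 3]
                cot_c = corner_cot[tid, (k + 2) % 3]
                mixed[tri[k]] += (lb2 * cot_b + lc2 * cot_c) / 8.0
        else:
            for k in range(3):
                mixed[tri[k]] += areas[tid] / 2.0 if k == oc else areas[tid] / 4.0
    return mixed


def cotangent_pair(
    mesh: TriMesh, geometry: MeshGeometry, edge: tuple[int, int]
) -> tuple[float, float | None]:
    """Cotangents of the one or two angles opposite an edge.

    Returns ``(cot α_ij, cot β_ij)``; the second entry is ``None`` for a
    boundary edge with a single incident triangle.
    """
    i, j = int(edge[0]), int(edge[1])
    eidx = mesh.edge_index()
    key = (min(i, j), max(i, j))
    if key not in eidx:
        raise KeyError(f"edge {edge} not in mesh")
    cots = geometry.edge_opposite_cots[eidx[key]]
    if len(cots) == 1:
        return cots[0], None
    return cots[0], cots[1]


def mixed_area(mesh: TriMesh, geometry: MeshGeometry, vertex: int) -> float:
    """Mixed Voronoi area of one vertex (see module docstring for the rule)."""
    if not any(vertex in tri for tri in mesh.triangles):
        raise ValueError(f"vertex {vertex} has no incident triangle")
    return float(geometry.mixed_areas[vertex])
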