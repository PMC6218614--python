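"""Discrete Laplace-Beltrami operators on triangulated cortical surfaces.

Four classical discretizations are provided, all instances of the general
stencil

    Δf(p_i) = (1/d_i) Σ_{j ∈ N(i)} w_ij [f(p_i) − f(p_j)]

with per-edge weights ``w_ij`` and per-vertex masses ``d_i``:

================  =============================  ==========================
scheme            w_ij                           d_i
================  =============================  ==========================
UW_GRAPH          1                              1
W_GRAPH           1 / dist(p_i, p_j)             Σ_j dist(p_i, p_j)
UW_GEOM           (cot α_ij + cot β_ij) / 2      1
W_GEOM            (cot α_ij + cot β_ij) / 2      A_mixed(i)
================  =============================  ==========================

α_ij, β_ij are the two angles opposite edge (i, j); A_mixed is the mixed
Voronoi vertex area.  The assembled stiffness matrix B has positive diagonal
(Σ_j w_ij)/d_i and off-diagonal −w_ij/d_i, so constants lie in its kernel and
diag(d)·B is symmetric.  On meshes with obtuse triangles the cotangent
weights may be negative; they are used as-is, never clipped.

The smoothness prior used by cortical LORETA is BᵀB, which is singular
(constants are in the kernel of B); it is regularized as BᵀB + σI with
σ ∈ (0, η²], η the largest singular value of BᵀB.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import MeshGeometry, compute_geometry
from .mesh import TriMesh

__all__ = [
    "LaplacianScheme",
    "StiffnessMatrix",
    "RegularizedPrior",
    "edge_weight",
    "vertex_mass",
    "assemble_stiffness",
    "regularized_prior",
    "spectral_report",
    "largest_singular_value",
    "SpectralReport",
]


class LaplacianScheme(str, Enum):
    """The four weight/mass schemes."""

    UW_GRAPH = "uw-graph"   # unweighted graph Laplacian
    W_GRAPH = "w-graph"     # weighted graph Laplacian (inverse-distance)
    UW_GEOM = "uw-geom"     # unweighted geometric (cotangent) Laplacian
    W_GEOM = "w-geom"       # geometric Laplacian with mixed-area masses

    @classmethod
    def coerce(cls, value: "LaplacianScheme | str") -> "LaplacianScheme":
        if isinstance(value, cls):
            return value
        v = str(value).lower().replace("_", "-")
        for s in cls:
            if s.value == v:
                return s
        raise ValueError(f"unknown Laplacian scheme {value!r}")


def _edge_weights_all(mesh: TriMesh, geometry: MeshGeometry, scheme: LaplacianScheme) -> np.ndarray:
    if scheme is LaplacianScheme.UW_GRAPH:
        return np.ones(len(mesh.edges))
    if scheme is LaplacianScheme.W_GRAPH:
        return 1.0 / geometry.edge_lengths
    # cotangent weights; boundary edges carry a single cotangent
    return np.array([sum(c) / 2.0 for c in geometry.edge_opposite_cots])


def edge_weight(
    mesh: TriMesh,
    geometry: MeshGeometry,
    scheme: LaplacianScheme | str,
    edge: tuple[int, int],
) -> float:
    """Weight w_ij of one edge under the given scheme."""
    scheme = LaplacianScheme.coerce(scheme)
    i, j = int(edge[0]), int(edge[1])
    eid = mesh.edge_index().get((min(i, j), max(i, j)))
    if eid is None:
        raise KeyError(f"edge {edge} not in mesh")
    if scheme is LaplacianScheme.UW_GRAPH:
        return 1.0
    if scheme is LaplacianScheme.W_GRAPH:
        d = geometry.edge_lengths[eid]
        if d <= 0:
            raise ValueError(f"zero-length edge {edge}")
        return 1.0 / float(d)
    return float(sum(geometry.edge_opposite_cots[eid]) / 2.0)


def vertex_mass(
    mesh: TriMesh,
    geometry: MeshGeometry,
    scheme: LaplacianScheme | str,
    vertex: int,
) -> float:
    """Mass d_i of one vertex under the given scheme."""
    scheme = LaplacianScheme.coerce(scheme)
    nbrs = mesh.neighbors(vertex)
    if len(nbrs) == 0:
        raise ValueError(f"vertex {vertex} is isolated")
    if scheme in (LaplacianScheme.UW_GRAPH, LaplacianScheme.UW_GEOM):
        return 1.0
    if scheme is LaplacianScheme.W_GRAPH:
        return float(
            np.sum(np.linalg.norm(mesh.vertices[nbrs] - mesh.vertices[vertex], axis=1))
        )
    return float(geometry.mixed_areas[vertex])


@dataclass
class StiffnessMatrix:
    """Sparse m×m stiffness matrix B of one Laplace-Beltrami scheme."""

    matrix: sp.csr_matrix
    scheme: LaplacianScheme
    mesh: TriMesh
    edge_weights: np.ndarray   # aligned with mesh.edges
    vertex_masses: np.ndarray  # (m,)

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def toarray(self) -> np.ndarray:
        return self.matrix.toarray()


def assemble_stiffness(
    mesh: TriMesh,
    scheme: LaplacianScheme | str,
    geometry: MeshGeometry | None = None,
) -> StiffnessMatrix:
    """Assemble the sparse stiffness matrix B for one scheme.

    ``B[i,i] = (Σ_j w_ij)/d_i`` and ``B[i,j] = −w_ij/d_i`` for j ∈ N(i).
    Raises on meshes with isolated vertices.
    """
    scheme = LaplacianScheme.coerce(scheme)
    if geometry is None:
        geometry = compute_geometry(mesh)
    m = mesh.n_vertices
    edges = mesh.edges
    deg = np.zeros(m, dtype=int)
    np.add.at(deg, edges.ravel(), 1)
    if np.any(deg == 0):
        raise ValueError(f"mesh has {int(np.sum(deg == 0))} isolated vertices")
    w = _edge_weights_all(mesh, geometry, scheme)
    if scheme is LaplacianScheme.UW_GRAPH:
        d = np.ones(m)
    elif scheme is LaplacianScheme.W_GRAPH:
        d = np.zeros(m)
        np.add.at(d, edges[:, 0], geometry.edge_lengths)
        np.add.at(d, edges[:, 1], geometry.edge_lengths)
    elif scheme is LaplacianScheme.UW_GEOM:
        d = np.ones(m)
    else:
        d = geometry.mixed_areas.copy()
    if np.any(d <= 0):
        raise ValueError("non-positive vertex mass")
    wsum = np.zeros(m)
    np.add.at(wsum, edges[:, 0], w)
    np.add.at(wsum, edges[:, 1], w)
    rows = np.concatenate([edges[:, 0], edges[:, 1], np.arange(m)])
    cols = np.concatenate([edges[:, 1], edges[:, 0], np.arange(m)])
    vals = np.concatenate([-w / d[edges[:, 0]], -w / d[edges[:, 1]], wsum / d])
    B = sp.coo_matrix((vals, (rows, cols)), shape=(m, m)).tocsr()
    return StiffnessMatrix(B, scheme, mesh, w, d)


@dataclass
class RegularizedPrior:
    """The smoothness prior core BᵀB + σI (symmetric positive definite)."""

    matrix: sp.csr_matrix
    sigma: float
    eta: float  # largest singular value of BᵀB


def regularized_prior(B: StiffnessMatrix | sp.spmatrix | np.ndarray, sigma: float) -> RegularizedPrior:
    """Form BᵀB + σI with σ > 0; records η = σ_max(BᵀB).

    The stiffness matrix itself is singular (constants in the kernel), so
    σ = 0 is rejected.  σ outside (0, η²] only triggers a warning — the
    interval is the recommended operating range, not a hard constraint.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0: B'B is singular without regularization")
    mat = B.matrix if isinstance(B, StiffnessMatrix) else sp.csr_matrix(B)
    m = mat.shape[0]
    btb = (mat.T @ mat).tocsr()
    eta = largest_singular_value(btb)
    if eta > 0 and sigma > eta**2:
        warnings.warn(
            f"sigma={sigma:g} exceeds eta^2={eta**2:g}; the smoothing prior "
            "degenerates toward a pure scaling",
            stacklevel=2,
        )
    return RegularizedPrior((btb + sigma * sp.identity(m, format="csr")).tocsr(), float(sigma), float(eta))


def largest_singular_value(matrix: sp.spmatrix | np.ndarray, rtol: float = 1e-8) -> float:
    """Largest singular value; dense SVD below 400 rows, Lanczos above."""
    if sp.issparse(matrix):
        n = min(matrix.shape)
        if n == 0:
            raise ValueError("empty matrix")
        if n < 400:
            return float(np.linalg.svd(matrix.toarray(), compute_uv=False)[0])
        return float(
            spla.svds(matrix.astype(float), k=1, return_singular_vectors=False, tol=rtol)[0]
        )
    arr = np.atleast_2d(np.asarray(matrix, dtype=float))
    if arr.size == 0:
        raise ValueError("empty matrix")
    return float(np.linalg.svd(arr, compute_uv=False)[0])


@dataclass
class SpectralReport:
    eigenvalues: np.ndarray
    n_zero_eigenvalues: int
    min_eigenvalue: float
    diagonally_dominant: bool
    mass_symmetric: bool  # diag(d)·B symmetric to 1e-10 relative

    @property
    def nonnegative(self) -> bool:
        tol = 1e-8 * max(self.eigenvalues.max(), 1e-300)
        return bool(self.min_eigenvalue >= -tol)


def spectral_report(B: StiffnessMatrix) -> SpectralReport:
    """Verify the four textbook properties of a discrete Laplacian.

    The spectrum of the (generally non-symmetric) B is computed through the
    similarity transform D^{1/2} B D^{-1/2} with D = diag(d), which is
    symmetric because diag(d)·B is; eigenvalues are therefore real.  A zero
    eigenvalue is one below 1e-8 times the largest; on a connected mesh there
    is exactly one.
    """
    d = B.vertex_masses
    s = np.sqrt(d)
    mat = B.matrix
    L = sp.diags(d) @ mat  # symmetric: d_i B_ij = -w_ij = d_j B_ji
    sym_err = abs(L - L.T).max()
    mass_symmetric = sym_err <= 1e-10 * max(abs(L).max(), 1e-300)
    S = (sp.diags(s) @ mat @ sp.diags(1.0 / s)).toarray()
    S = 0.5 * (S + S.T)  # kill rounding asymmetry
    eig = np.linalg.eigvalsh(S)
    lam_max = max(eig.max(), 1e-300)
    n_zero = int(np.sum(np.abs(eig) <= 1e-8 * lam_max))
    diag = mat.diagonal()
    offsum = np.asarray(abs(mat).sum(axis=1)).ravel() - np.abs(diag)
    dom = bool(np.all(np.abs(diag) >= offsum - 1e-10 * np.abs(diag)))
    return SpectralReport(
        eigenvalues=eig,
        n_zero_eigenvalues=n_zero,
        min_eigenvalue=float(eig.min()),
        diagonally_dominant=dom,
        mass_symmetric=bool(mass_symmetric),
    )
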