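"""Triangulated cortical surfaces: container, file I/O and synthetic generators.

A :class:`TriMesh` is the discrete form of the cortical 2-manifold: an array of
vertex positions ``p_i`` (mm) and an array of vertex-index triples.  Adjacency
(the 1-ring neighbourhood ``N(i)``), the edge list and the edge→triangle
incidence are derived lazily and cached, since every downstream consumer
(geometry, Laplacians, local-maxima counting) needs them.

Supported file formats: OFF, ASCII PLY, and a plain vertex/face text dialect
(first line ``m k``, then ``m`` coordinate lines, then ``k`` 0-based index
triples).  Parsers report the offending line number on malformed input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "TriMesh",
    "MeshParseError",
    "ValidationReport",
    "load_mesh",
    "write_mesh",
    "validate_mesh",
    "make_icosphere",
    "make_cortex_like_surface",
]


class MeshParseError(ValueError):
    """Raised for malformed mesh files; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass
class TriMesh:
    """Triangle mesh with cached combinatorics.

    Parameters
    ----------
    vertices : (m, 3) float array
        Vertex positions in mm.
    triangles : (k, 3) int array
        Vertex-index triples, 0-based.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    _neighbors: list[np.ndarray] | None = field(default=None, repr=False)
    _edges: np.ndarray | None = field(default=None, repr=False)
    _edge_triangles: list[list[int]] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        m = self.n_vertices
        if self.triangles.size:
            if self.triangles.min() < 0 or self.triangles.max() >= m:
                raise ValueError("triangle index out of range")
            t = self.triangles
            if np.any((t[:, 0] == t[:, 1]) | (t[:, 1] == t[:, 2]) | (t[:, 0] == t[:, 2])):
                raise ValueError("triangle repeats a vertex")

    # -- basic sizes ------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_triangles(self) -> int:
        return self.triangles.shape[0]

    # -- combinatorics ----------------------------------------------------
    def _build_edges(self) -> None:
        pairs = np.vstack(
            [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [2, 0]]]
        )
        pairs = np.sort(pairs, axis=1)
        tri_ids = np.tile(np.arange(self.n_triangles), 3)
        edges, inverse = np.unique(pairs, axis=0, return_inverse=True)
        self._edges = edges
        incidence: list[list[int]] = [[] for _ in range(len(edges))]
        for eid, tid in zip(inverse, tri_ids):
            incidence[eid].append(int(tid))
        self._edge_triangles = incidence
        nbrs: list[set[int]] = [set() for _ in range(self.n_vertices)]
        for i, j in edges:
            nbrs[i].add(int(j))
            nbrs[j].add(int(i))
        self._neighbors = [np.array(sorted(s), dtype=np.int64) for s in nbrs]

    @property
    def edges(self) -> np.ndarray:
        """(E, 2) array of sorted vertex-index pairs, one row per undirected edge."""
        if self._edges is None:
            self._build_edges()
        return self._edges

    @property
    def edge_triangles(self) -> list[list[int]]:
        """For each edge, the ids of its 1 or 2 (or more, if non-manifold) triangles."""
        if self._edge_triangles is None:
            self._build_edges()
        return self._edge_triangles

    def neighbors(self, i: int) -> np.ndarray:
        """1-ring neighbour indices N(i)."""
        if self._neighbors is None:
            self._build_edges()
        return self._neighbors[i]

    def vertex_triangles(self) -> list[list[int]]:
        """For each vertex, the ids of its incident triangles."""
        out: list[list[int]] = [[] for _ in range(self.n_vertices)]
        for tid, tri in enumerate(self.triangles):
            for v in tri:
                out[v].append(tid)
        return out

    def edge_index(self) -> dict[tuple[int, int], int]:
        """Map sorted vertex pair -> edge id."""
        return {(int(i), int(j)): k for k, (i, j) in enumerate(self.edges)}


@dataclass
class ValidationReport:
    n_components: int
    n_boundary_edges: int
    n_nonmanifold_edges: int
    n_degenerate_triangles: int
    n_duplicate_vertices: int

    @property
    def clean(self) -> bool:
        return (
            self.n_components == 1
            and self.n_nonmanifold_edges == 0
            and self.n_degenerate_triangles == 0
        )


def validate_mesh(mesh: TriMesh, degenerate_rel_tol: float = 1e-12) -> ValidationReport:
    """Report connectivity and degeneracy diagnostics for a mesh.

    A triangle is degenerate when its area is below ``degenerate_rel_tol``
    times the squared maximum edge length.
    """
    edges = mesh.edges
    counts = np.array([len(t) for t in mesh.edge_triangles])
    n_boundary = int(np.sum(counts == 1))
    n_nonmanifold = int(np.sum(counts > 2))
    if len(edges):
        ones = np.ones(len(edges))
        adj = coo_matrix(
            (np.concatenate([ones, ones]),
             (np.concatenate([edges[:, 0], edges[:, 1]]),
              np.concatenate([edges[:, 1], edges[:, 0]]))),
            shape=(mesh.n_vertices, mesh.n_vertices),
        )
        n_comp, _ = connected_components(adj, directed=False)
    else:
        n_comp = mesh.n_vertices
    v = mesh.vertices
    n_degen = 0
    for tri in mesh.triangles:
        a, b, c = v[tri]
        cross = np.cross(b - a, c - a)
        area2 = np.linalg.norm(cross)
        longest2 = max(np.dot(b - a, b - a), np.dot(c - a, c - a), np.dot(c - b, c - b))
        if area2 <= degenerate_rel_tol * longest2:
            n_degen += 1
    # duplicate coordinates
    if mesh.n_vertices:
        _, uniq_counts = np.unique(np.round(v, 12), axis=0, return_counts=True)
        n_dup = int(np.sum(uniq_counts > 1))
    else:
        n_dup = 0
    return ValidationReport(int(n_comp), n_boundary, n_nonmanifold, n_degen, n_dup)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _tokens(path: Path) -> list[tuple[int, list[str]]]:
    out = []
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if line:
            out.append((ln, line.split()))
    return out


def _parse_face(fields: list[str], m: int, ln: int, counted: bool) -> list[int]:
    if counted:
        if int(fields[0]) != 3:
            raise MeshParseError(f"non-triangle face with {fields[0]} vertices", ln)
        fields = fields[1:4]
    if len(fields) < 3:
        raise MeshParseError("face with fewer than 3 indices", ln)
    idx = []
    for f in fields[:3]:
        try:
            k = int(f)
        except ValueError as exc:
            raise MeshParseError(f"bad face index {f!r}", ln) from exc
        if k < 0 or k >= m:
            raise MeshParseError(f"face index {k} out of range (m={m})", ln)
        idx.append(k)
    return idx


def _load_off(path: Path) -> TriMesh:
    toks = _tokens(path)
    if not toks:
        raise MeshParseError("empty file", 1)
    pos = 0
    ln, t = toks[pos]
    if t[0].upper() == "OFF":
        if len(t) == 1:
            pos += 1
        else:
            t = t[1:]  # counts on the same line as the keyword
            toks[pos] = (ln, t)
    else:
        raise MeshParseError("missing OFF header", ln)
    if pos >= len(toks):
        raise MeshParseError("missing counts line", ln)
    ln, t = toks[pos]
    try:
        m, k = int(t[0]), int(t[1])
    except (ValueError, IndexError) as exc:
        raise MeshParseError("malformed counts line", ln) from exc
    pos += 1
    if len(toks) < pos + m + k:
        raise MeshParseError(f"expected {m} vertices and {k} faces", toks[-1][0])
    verts = np.empty((m, 3))
    for i in range(m):
        ln, t = toks[pos + i]
        try:
            verts[i] = [float(x) for x in t[:3]]
        except ValueError as exc:
            raise MeshParseError("bad vertex coordinate", ln) from exc
    tris = np.empty((k, 3), dtype=np.int64)
    for i in range(k):
        ln, t = toks[pos + m + i]
        tris[i] = _parse_face(t, m, ln, counted=True)
    return TriMesh(verts, tris)


def _load_ply(path: Path) -> TriMesh:
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise MeshParseError("missing 'ply' magic", 1)
    m = k = None
    fmt_ok = False
    body_start = None
    elements: list[tuple[str, int]] = []
    for ln0, raw in enumerate(lines[1:], start=2):
        t = raw.strip().split()
        if not t:
            continue
        if t[0] == "format":
            if t[1] != "ascii":
                raise MeshParseError("only ASCII PLY supported", ln0)
            fmt_ok = True
        elif t[0] == "element":
            elements.append((t[1], int(t[2])))
            if t[1] == "vertex":
                m = int(t[2])
            elif t[1] == "face":
                k = int(t[2])
        elif t[0] == "end_header":
            body_start = ln0 + 1
            break
    if not fmt_ok or body_start is None:
        raise MeshParseError("incomplete PLY header", len(lines))
    if m is None or k is None:
        raise MeshParseError("PLY header lacks vertex/face elements", body_start - 1)
    toks = [
        (ln, raw.strip().split())
        for ln, raw in enumerate(lines[body_start - 1:], start=body_start)
        if raw.strip()
    ]
    if len(toks) < m + k:
        raise MeshParseError(f"expected {m} vertices and {k} faces", len(lines))
    verts = np.empty((m, 3))
    for i in range(m):
        ln, t = toks[i]
        try:
            verts[i] = [float(x) for x in t[:3]]
        except ValueError as exc:
            raise MeshParseError("bad vertex coordinate", ln) from exc
    tris = np.empty((k, 3), dtype=np.int64)
    for i in range(k):
        ln, t = toks[m + i]
        tris[i] = _parse_face(t, m, ln, counted=True)
    return TriMesh(verts, tris)


def _load_txt(path: Path) -> TriMesh:
    toks = _tokens(path)
    if not toks:
        raise MeshParseError("empty file", 1)
    ln, t = toks[0]
    try:
        m, k = int(t[0]), int(t[1])
    except (ValueError, IndexError) as exc:
        raise MeshParseError("first line must be 'm k'", ln) from exc
    if len(toks) < 1 + m + k:
        raise MeshParseError(f"expected {m} vertices and {k} faces", toks[-1][0])
    verts = np.empty((m, 3))
    for i in range(m):
        ln, t = toks[1 + i]
        try:
            verts[i] = [float(x) for x in t[:3]]
        except ValueError as exc:
            raise MeshParseError("bad vertex coordinate", ln) from exc
    tris = np.empty((k, 3), dtype=np.int64)
    for i in range(k):
        ln, t = toks[1 + m + i]
        tris[i] = _parse_face(t, m, ln, counted=False)
    return TriMesh(verts, tris)


_FORMATS = {"off": ".off", "ply": ".ply", "txt": ".txt"}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in _FORMATS:
            raise ValueError(f"unknown mesh format {fmt!r}")
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in _FORMATS:
        return suffix
    raise ValueError(f"cannot infer mesh format from {path.name!r}")


def load_mesh(path: str | Path, format: str | None = None) -> TriMesh:
    """Load a triangle mesh from OFF, ASCII PLY or plain vertex/face text."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "off":
        return _load_off(path)
    if fmt == "ply":
        return _load_ply(path)
    return _load_txt(path)


def write_mesh(mesh: TriMesh, path: str | Path, format: str | None = None) -> None:
    """Write a mesh losslessly (coordinates at full double precision)."""
    if mesh.n_vertices == 0:
        raise ValueError("empty mesh")
    path = Path(path)
    fmt = _infer_format(path, format)
    m, k = mesh.n_vertices, mesh.n_triangles
    vlines = [" ".join(repr(float(x)) for x in p) for p in mesh.vertices]
    if fmt == "off":
        lines = ["OFF", f"{m} {k} 0"] + vlines + [
            f"3 {a} {b} {c}" for a, b, c in mesh.triangles
        ]
    elif fmt == "ply":
        lines = (
            ["ply", "format ascii 1.0",
             f"element vertex {m}",
             "property double x", "property double y", "property double z",
             f"element face {k}",
             "property list uchar int vertex_indices",
             "end_header"]
            + vlines
            + [f"3 {a} {b} {c}" for a, b, c in mesh.triangles]
        )
    else:
        lines = [f"{m} {k}"] + vlines + [f"{a} {b} {c}" for a, b, c in mesh.triangles]
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Synthetic surface generators
# ---------------------------------------------------------------------------

_ICO_VERTS = None
_ICO_FACES = None


def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    global _ICO_VERTS, _ICO_FACES
    if _ICO_VERTS is None:
        phi = (1.0 + np.sqrt(5.0)) / 2.0
        v = np.array(
            [
                (-1, phi, 0), (1, phi, 0), (-1, -phi, 0), (1, -phi, 0),
                (0, -1, phi), (0, 1, phi), (0, -1, -phi), (0, 1, -phi),
                (phi, 0, -1), (phi, 0, 1), (-phi, 0, -1), (-phi, 0, 1),
            ],
            dtype=float,
        )
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        f = np.array(
            [
                (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
                (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
                (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
                (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
            ],
            dtype=np.int64,
        )
        _ICO_VERTS, _ICO_FACES = v, f
    return _ICO_VERTS.copy(), _ICO_FACES.copy()


def make_icosphere(subdivisions: int, radius: float = 1.0) -> TriMesh:
    """Subdivided icosahedron projected onto the sphere of the given radius.

    Vertex count is ``10·4^s + 2`` and face count ``20·4^s`` for ``s``
    subdivision steps.
    """
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    if radius <= 0:
        raise ValueError("radius must be > 0")
    verts, faces = _icosahedron()
    for _ in range(subdivisions):
        vlist = list(verts)
        midpoint: dict[tuple[int, int], int] = {}

        def mid(i: int, j: int) -> int:
            key = (i, j) if i < j else (j, i)
            if key not in midpoint:
                p = vlist[i] + vlist[j]
                p = p / np.linalg.norm(p)
                midpoint[key] = len(vlist)
                vlist.append(p)
            return midpoint[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        verts = np.array(vlist)
        faces = np.array(new_faces, dtype=np.int64)
    verts = verts / np.linalg.norm(verts, axis=1, keepdims=True) * radius
    return TriMesh(verts, faces)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors along the Fibonacci spiral."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    theta = golden * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def make_cortex_like_surface(
    target_nodes: int,
    corrugation_amplitude: float = 0.12,
    corrugation_frequency: float = 6.0,
    axis_scales: tuple[float, float, float] = (1.0, 0.85, 0.9),
    seed: int = 0,
    radius: float = 65.0,
) -> TriMesh:
    """Closed, irregular, corrugated ellipsoidal surface emulating a cortex.

    Quasi-uniform points on the unit sphere (Fibonacci spiral plus a small
    seeded tangential jitter so the triangulation is irregular) are
    triangulated by their convex hull, displaced radially by a smooth
    sinusoidal corrugation (sulci/gyri-like folds) and scaled per axis into
    an ellipsoid.  The node count equals ``target_nodes`` exactly.

    Parameters
    ----------
    corrugation_amplitude : relative radial fold depth (0 disables folding).
    corrugation_frequency : angular frequency of the folds on the unit sphere.
    radius : mean radius in mm before axis scaling.
    """
    if target_nodes < 12:
        raise ValueError("target_nodes must be >= 12")
    if corrugation_amplitude < 0:
        raise ValueError("corrugation_amplitude must be >= 0")
    from scipy.spatial import ConvexHull

    rng = np.random.default_rng(seed)
    u = _fibonacci_sphere(target_nodes)
    # tangential jitter: ~15% of the mean point spacing, projected back to S²
    jitter = rng.normal(scale=0.15 * 2.0 / np.sqrt(target_nodes), size=u.shape)
    u = u + jitter - (np.sum(u * jitter, axis=1, keepdims=True)) * u
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    hull = ConvexHull(u)
    faces = hull.simplices.astype(np.int64)
    # orient faces outward (hull simplices have arbitrary winding)
    a, b, c = u[faces[:, 0]], u[faces[:, 1]], u[faces[:, 2]]
    outward = np.einsum("ij,ij->i", np.cross(b - a, c - a), (a + b + c) / 3.0)
    flip = outward < 0
    faces[flip] = faces[flip][:, [0, 2, 1]]
    f = corrugation_frequency
    fold = (np.sin(f * u[:, 0]) + np.sin(f * u[:, 1]) + np.sin(f * u[:, 2])) / 3.0
    r = radius * (1.0 + corrugation_amplitude * fold)
    verts = u * r[:, None] * np.asarray(axis_scales, dtype=float)
    return TriMesh(verts, faces)
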