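"""The four Laplace-Beltrami schemes: weights, masses, assembly, spectra."""

import numpy as np
import pytest
import scipy.sparse as sp

import cortical_loreta as cl
from cortical_loreta.geometry import compute_geometry
from cortical_loreta.laplacian import LaplacianScheme

SCHEMES = list(LaplacianScheme)


class TestWeightsAndMasses:
    def test_unweighted_graph(self, tetra):
        g = compute_geometry(tetra)
        assert cl.edge_weight(tetra, g, "uw-graph", (0, 1)) == 1.0
        assert cl.vertex_mass(tetra, g, "uw-graph", 0) == 1.0

    def test_inverse_distance_weight(self):
        mesh = cl.TriMesh([[0, 0, 0], [2, 0, 0], [1, 1, 0]], [[0, 1, 2]])
        g = compute_geometry(mesh)
        assert cl.edge_weight(mesh, g, "w-graph", (0, 1)) == pytest.approx(0.5)

    def test_graph_mass_is_distance_sum(self):
        # vertex 0 with neighbour distances 1, 2, 3
        mesh = cl.TriMesh(
            [[0, 0, 0], [1, 0, 0], [0, 2, 0], [0, 0, 3]],
            [[0, 1, 2], [0, 2, 3], [0, 3, 1]],
        )
        g = compute_geometry(mesh)
        assert cl.vertex_mass(mesh, g, "w-graph", 0) == pytest.approx(6.0)

    def test_cotangent_weight_equilateral(self):
        h = np.sqrt(3.0) / 2.0
        mesh = cl.TriMesh(
            [[0, 0, 0], [1, 0, 0], [0.5, h, 0], [0.5, -h, 0]],
            [[0, 1, 2], [0, 3, 1]],
        )
        g = compute_geometry(mesh)
        for scheme in ("uw-geom", "w-geom"):
            assert cl.edge_weight(mesh, g, scheme, (0, 1)) == pytest.approx(
                1.0 / np.sqrt(3.0), rel=1e-12
            )

    def test_geometric_mass_is_mixed_area(self):
        mesh = cl.make_icosphere(0)
        g = compute_geometry(mesh)
        assert cl.vertex_mass(mesh, g, "w-geom", 3) == pytest.approx(
            5.0 * g.triangle_areas[0] / 3.0, rel=1e-10
        )
        assert cl.vertex_mass(mesh, g, "uw-geom", 3) == 1.0


class TestAssembly:
    def test_tetrahedron_unweighted_rows(self, tetra):
        B = cl.assemble_stiffness(tetra, "uw-graph").toarray()
        for i in range(4):
            assert B[i, i] == pytest.approx(3.0)
            off = np.delete(B[i], i)
            np.testing.assert_allclose(off, -1.0)

    def test_unit_tetrahedron_weighted_graph_rows(self, unit_tetra):
        B = cl.assemble_stiffness(unit_tetra, "w-graph").toarray()
        for i in range(4):
            assert B[i, i] == pytest.approx(1.0, rel=1e-12)
            np.testing.assert_allclose(np.delete(B[i], i), -1.0 / 3.0, rtol=1e-12)

    @pytest.mark.parametrize("scheme", SCHEMES)
    @pytest.mark.parametrize("fixture", ["icosphere2", "cortex300"])
    def test_constants_in_kernel(self, scheme, fixture, request):
        mesh = request.getfixturevalue(fixture)
        B = cl.assemble_stiffness(mesh, scheme)
        resid = np.abs(B.matrix @ np.ones(mesh.n_vertices))
        assert resid.max() <= 1e-10 * np.abs(B.matrix.diagonal()).max()

    @pytest.mark.parametrize("scheme", SCHEMES)
    def test_mass_matrix_symmetrizes(self, cortex300, scheme):
        B = cl.assemble_stiffness(cortex300, scheme)
        L = sp.diags(B.vertex_masses) @ B.matrix
        assert abs(L - L.T).max() <= 1e-10 * abs(L).max()

    def test_sparsity_pattern_is_adjacency(self, cortex300):
        B = cl.assemble_stiffness(cortex300, "uw-geom")
        pattern = B.matrix.copy()
        pattern.data = np.ones_like(pattern.data)
        for i in range(0, cortex300.n_vertices, 37):
            row = pattern.getrow(i).indices
            assert set(row) == set(cortex300.neighbors(i)) | {i}

    def test_obtuse_mesh_keeps_negative_weights(self):
        # edge (0,1) sees two very obtuse opposite angles: cot sum < 0
        mesh = cl.TriMesh(
            [[0, 0, 0], [1, 0, 0], [0.5, 0.05, 0], [0.5, -0.05, 0]],
            [[0, 1, 2], [0, 3, 1]],
        )
        g = compute_geometry(mesh)
        w = cl.edge_weight(mesh, g, "uw-geom", (0, 1))
        assert w < 0
        B = cl.assemble_stiffness(mesh, "uw-geom", g).toarray()
        assert B[0, 1] == pytest.approx(-w)  # not clipped: off-diagonal positive


class TestHarmonicity:
    def test_linear_functions_harmonic_on_planar_mesh(self, planar_grid):
        """Cotangent Laplacian annihilates linear functions at interior nodes."""
        B = cl.assemble_stiffness(planar_grid, "uw-geom")
        rep = cl.validate_mesh(planar_grid)
        assert rep.n_boundary_edges > 0  # open mesh: boundary handled, not crashed
        boundary = set()
        for eid, tris in enumerate(planar_grid.edge_triangles):
            if len(tris) == 1:
                boundary.update(planar_grid.edges[eid])
        interior = [i for i in range(planar_grid.n_vertices) if i not in boundary]
        assert interior
        for f in (planar_grid.vertices[:, 0], planar_grid.vertices[:, 1]):
            r = B.matrix @ f
            assert np.max(np.abs(r[interior])) < 1e-10


class TestSpectra:
    @pytest.mark.parametrize("scheme", SCHEMES)
    def test_connected_mesh_single_zero_eigenvalue(self, icosphere2, scheme):
        rep = cl.spectral_report(cl.assemble_stiffness(icosphere2, scheme))
        assert rep.n_zero_eigenvalues == 1
        assert rep.nonnegative
        assert rep.mass_symmetric

    def test_components_equal_zero_eigenvalues(self, tetra):
        v = np.vstack([tetra.vertices, tetra.vertices + 10.0])
        f = np.vstack([tetra.triangles, tetra.triangles + 4])
        rep = cl.spectral_report(cl.assemble_stiffness(cl.TriMesh(v, f), "uw-graph"))
        assert rep.n_zero_eigenvalues == 2

    def test_two_tetra_eigenvalues_match_dense_oracle(self, tetra):
        """Brute-force eigendecomposition of the 8x8 disjoint-pair matrix."""
        v = np.vstack([tetra.vertices, tetra.vertices + 10.0])
        f = np.vstack([tetra.triangles, tetra.triangles + 4])
        B = cl.assemble_stiffness(cl.TriMesh(v, f), "uw-graph")
        dense = np.sort(np.real(np.linalg.eigvals(B.toarray())))
        rep = cl.spectral_report(B)
        np.testing.assert_allclose(np.sort(rep.eigenvalues), dense, atol=1e-8)

    @pytest.mark.parametrize("scheme", SCHEMES)
    def test_eigenvalues_nonnegative_on_irregular_mesh(self, cortex300, scheme):
        rep = cl.spectral_report(cl.assemble_stiffness(cortex300, scheme))
        assert rep.min_eigenvalue >= -1e-8 * rep.eigenvalues.max()


class TestRegularizedPrior:
    def test_sigma_zero_rejected(self, tetra):
        B = cl.assemble_stiffness(tetra, "uw-graph")
        with pytest.raises(ValueError, match="singular"):
            cl.regularized_prior(B, 0.0)

    def test_zero_stiffness_gives_identity(self):
        prior = cl.regularized_prior(sp.csr_matrix((5, 5)), 1.0)
        np.testing.assert_allclose(prior.matrix.toarray(), np.eye(5))

    def test_spectral_shift(self, tetra):
        B = cl.assemble_stiffness(tetra, "uw-graph")
        base = np.linalg.eigvalsh((B.matrix.T @ B.matrix).toarray())
        for sigma in (0.5, 2.0):
            shifted = np.linalg.eigvalsh(
                cl.regularized_prior(B, sigma).matrix.toarray()
            )
            np.testing.assert_allclose(shifted, base + sigma, rtol=1e-10, atol=1e-10)

    def test_positive_definite_above_sigma(self, cortex300):
        B = cl.assemble_stiffness(cortex300, "w-geom")
        prior = cl.regularized_prior(B, 1e-8)
        lo = np.linalg.eigvalsh(prior.matrix.toarray()).min()
        assert lo >= 1e-8 - 1e-12

    def test_eta_warning_boundary(self, tetra):
        B = cl.assemble_stiffness(tetra, "uw-graph")
        prior = cl.regularized_prior(B, 1.0)
        with pytest.warns(UserWarning, match="eta"):
            cl.regularized_prior(B, 10 * prior.eta**2)


class TestLargestSingularValue:
    def test_identity(self):
        assert cl.largest_singular_value(np.eye(7)) == pytest.approx(1.0)

    def test_diagonal(self):
        assert cl.largest_singular_value(np.diag([3.0, 2.0])) == pytest.approx(3.0)

    def test_scaling(self, tetra):
        B = cl.assemble_stiffness(tetra, "uw-graph").matrix
        s1 = cl.largest_singular_value(B)
        s2 = cl.largest_singular_value((-2.5) * B)
        assert s2 == pytest.approx(2.5 * s1, rel=1e-8)

    def test_sparse_large_matches_dense(self):
        rng = np.random.default_rng(0)
        A = sp.random(450, 450, density=0.01, random_state=rng, format="csr")
        A = A + A.T
        dense = np.linalg.svd(A.toarray(), compute_uv=False)[0]
        assert cl.largest_singular_value(A) == pytest.approx(dense, rel=1e-6)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cl.largest_singular_value(np.empty((0, 0)))
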