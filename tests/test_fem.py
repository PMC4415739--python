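"""Mesh generation and the quasistatic solver against analytic solutions."""

import numpy as np
import pytest

from cellimp import build_layout, generate_mesh, solve_field
from cellimp.fem import MeshError, SolverError, assemble_stiffness, kappa_per_element
from cellimp.fixtures import annulus_fixture, annulus_potential, plate_fixture
from cellimp.geometry import RegionLabel

UM = 1e-6


class TestMesh:
    def test_structured_node_count_without_snapping(self):
        layout, kappa, _ = plate_fixture()
        mesh = generate_mesh(layout, 1 * UM)
        assert mesh.n_nodes == 101 * 101
        assert mesh.n_elements == 2 * 100 * 100

    def test_refinement_quadruples_elements(self):
        layout, _, _ = plate_fixture()
        coarse = generate_mesh(layout, 2 * UM)
        fine = generate_mesh(layout, 1 * UM)
        assert fine.n_elements == 4 * coarse.n_elements

    def test_too_coarse_resolution_rejected(self):
        layout = build_layout("standard")  # gap 8 um -> need <= 2 um
        with pytest.raises(MeshError, match="gap"):
            generate_mesh(layout, 4 * UM)

    @pytest.mark.parametrize("shape", ["parallel", "circle", "cross", "standard"])
    def test_element_regions_match_centroid_classification(self, shape):
        layout = build_layout(shape)
        mesh = generate_mesh(layout, 1 * UM)
        cent = mesh.centroids()
        assert np.array_equal(
            mesh.element_region, layout.classify(cent[:, 0], cent[:, 1])
        )

    @pytest.mark.parametrize("shape", ["parallel", "circle", "cross", "standard"])
    def test_electrode_node_sets_nonempty_and_disjoint(self, shape):
        mesh = generate_mesh(build_layout(shape), 1 * UM)
        assert mesh.dirichlet_a.any() and mesh.dirichlet_b.any()
        assert not (mesh.dirichlet_a & mesh.dirichlet_b).any()

    def test_snapped_mesh_has_no_degenerate_triangles(self):
        mesh = generate_mesh(build_layout("circle"), 0.5 * UM)
        assert mesh.areas().min() > 0.01 * (0.5 * UM) ** 2


class TestPlateOracle:
    """Uniform slab between plates: the exact solution is linear, hence
    in the P1 space, and the FEM is nodally exact."""

    def test_potential_nodally_exact(self):
        layout, kappa, _ = plate_fixture()
        mesh = generate_mesh(layout, 1 * UM)
        sol = solve_field(mesh, {0: kappa, 1: kappa}, V=1.0)
        exact = (mesh.nodes[:, 1] + layout.half_height) / layout.height
        assert np.abs(sol.phi - exact).max() < 1e-10

    def test_potential_varies_only_along_drive_axis(self):
        layout, kappa, _ = plate_fixture()
        mesh = generate_mesh(layout, 2 * UM)
        sol = solve_field(mesh, {0: kappa, 1: kappa}, V=1.0)
        # group nodes by y row: constant within each row
        for yval in np.unique(mesh.nodes[:, 1]):
            row = np.isclose(mesh.nodes[:, 1], yval)
            assert np.ptp(sol.phi[row].real) < 1e-12

    def test_uniform_field_magnitude(self):
        layout, kappa, _ = plate_fixture()
        mesh = generate_mesh(layout, 2 * UM)
        sol = solve_field(mesh, {0: kappa, 1: kappa}, V=1.0)
        _, _, mag = sol.electric_field()
        act = mesh.active_elements
        assert mag[act] == pytest.approx(1.0 / layout.height, rel=1e-10)

    def test_discrete_maximum_principle(self):
        layout, kappa, _ = plate_fixture()
        mesh = generate_mesh(layout, 2 * UM)
        sol = solve_field(mesh, {0: kappa, 1: kappa}, V=2.5)
        assert np.abs(sol.phi).max() <= 2.5 + 1e-12


class TestAnnulusOracle:
    def test_potential_matches_log_solution_coarse(self):
        layout, kappa, _ = annulus_fixture()
        mesh = generate_mesh(layout, 1 * UM)
        sol = solve_field(mesh, {0: kappa, 1: kappa}, V=1.0)
        r = np.hypot(mesh.nodes[:, 0], mesh.nodes[:, 1])
        sel = (r >= 5 * UM) & (r <= 40 * UM)
        err = np.abs(sol.phi[sel].real - annulus_potential(layout, r[sel], 1.0))
        assert err.max() < 0.05  # tight 1% bound is checked at 0.5 um

    def test_solution_scales_linearly_with_voltage(self):
        layout, kappa, _ = annulus_fixture()
        mesh = generate_mesh(layout, 1 * UM)
        s1 = solve_field(mesh, {0: kappa, 1: kappa}, V=1.0)
        s2 = solve_field(mesh, {0: kappa, 1: kappa}, V=2.0)
        assert np.allclose(s2.phi, 2 * s1.phi, atol=1e-12)


class TestAssembly:
    def test_interior_row_sums_vanish(self, parallel_cell_solution):
        """Inserting a constant potential produces zero residual at free
        nodes (partition of unity of P1 gradients)."""
        mesh = parallel_cell_solution.mesh
        kappa = kappa_per_element(mesh, parallel_cell_solution.kappa_map)
        K = assemble_stiffness(mesh, kappa)
        ones = np.ones(mesh.n_nodes, dtype=complex)
        resid = K @ ones
        used = np.zeros(mesh.n_nodes, dtype=bool)
        used[np.unique(mesh.triangles[mesh.active_elements])] = True
        scale = np.abs(K.diagonal()).max()
        assert np.abs(resid[used]).max() < 1e-12 * scale

    def test_missing_region_admittivity_rejected(self):
        mesh = generate_mesh(build_layout("parallel"), 2 * UM)
        with pytest.raises(SolverError, match="CELL"):
            solve_field(mesh, {0: 1e-3 + 0j}, V=1.0)

    def test_non_dissipative_material_rejected(self):
        mesh = generate_mesh(build_layout("parallel"), 2 * UM)
        with pytest.raises(SolverError, match="non-dissipative"):
            solve_field(mesh, {0: 0j, 1: 0j}, V=1.0)

    def test_dirichlet_values_exact_on_electrodes(self, parallel_cell_solution):
        sol = parallel_cell_solution
        assert np.all(sol.phi[sol.mesh.dirichlet_a] == 0.1)
        assert np.all(sol.phi[sol.mesh.dirichlet_b] == 0.0)


def test_field_is_mirror_antisymmetric_across_the_gap():
    """Mirroring the standard device in x swaps the electrodes, so
    phi(-x, y) = V - phi(x, y) at every node (the structured mesh is
    itself mirror-symmetric)."""
    layout = build_layout("standard")
    mesh = generate_mesh(layout, 1 * UM)
    kappa = 1e-3 + 1e-3j
    sol = solve_field(mesh, {0: kappa, 1: kappa}, V=1.0)
    key = np.round(mesh.nodes / (0.01 * UM)).astype(np.int64)
    index = {(-kx, ky): i for i, (kx, ky) in enumerate(map(tuple, key))}
    partner = np.array([index[(kx, ky)] for kx, ky in map(tuple, key)])
    assert np.abs(sol.phi + sol.phi[partner] - 1.0).max() < 1e-9
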