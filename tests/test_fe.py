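"""Finite elements: quality metrics, assembly, loads, solves, stresses."""

import numpy as np
import pytest
from scipy.sparse.linalg import spsolve

from footform import fe, synthetic
from footform.types import ParameterError, TetMesh


def regular_tet() -> TetMesh:
    nodes = np.array(
        [
            [1.0, 1.0, 1.0],
            [1.0, -1.0, -1.0],
            [-1.0, 1.0, -1.0],
            [-1.0, -1.0, 1.0],
        ]
    )
    return TetMesh(nodes=nodes, tets=np.array([[0, 2, 1, 3]]))


def slab_mesh(nx=4, ny=4, nz=2, size=10.0):
    """Flat slab with a 'plantar' node set on its z=0 face."""
    hi = np.array([nx, ny, nz]) * size / nx
    mesh = synthetic.lattice_tet_mesh(
        np.zeros(3), hi, (nx, ny, nz), lambda p: np.ones(len(p), bool)
    )
    faces, _ = mesh.boundary_faces_with_elements()
    bnodes = np.unique(faces)
    z = mesh.nodes[:, 2]
    mesh.node_sets["plantar"] = bnodes[z[bnodes] < 1e-9]
    mesh.node_sets["fixed_proximal"] = np.flatnonzero(z > hi[2] - 1e-9)
    return mesh


# ---------------------------------------------------------------------------
# Quality
# ---------------------------------------------------------------------------

class TestMeshQuality:
    def test_regular_tet_scores_one(self):
        sj = fe.scaled_jacobian(regular_tet())
        assert sj[0] == pytest.approx(1.0, abs=1e-9)

    def test_sliver_flagged(self):
        # near-degenerate sliver: apex height 1e-6 of the base edge
        nodes = np.array(
            [[0, 0, 0], [1, 0, 0], [0.5, 1.0, 0], [0.5, 0.5, 1e-6]], float
        )
        mesh = TetMesh(nodes=nodes, tets=np.array([[0, 1, 2, 3]]))
        report = fe.check_mesh_quality(mesh)
        assert report.scaled_jacobian[0] < 0.3
        assert 0 in report.flagged
        assert not report.passed

    def test_inverted_element_listed_separately(self):
        nodes = regular_tet().nodes
        mesh = TetMesh(nodes=nodes, tets=np.array([[0, 1, 2, 3]]))  # swapped
        report = fe.check_mesh_quality(mesh)
        assert 0 in report.inverted
        assert not report.passed

    def test_lattice_meshes_pass(self, bar_mesh):
        assert fe.check_mesh_quality(bar_mesh).passed


# ---------------------------------------------------------------------------
# Stiffness assembly
# ---------------------------------------------------------------------------

class TestAssembly:
    def test_single_tet_symmetric_with_six_rigid_modes(self):
        mesh = regular_tet()
        K = fe.assemble_stiffness(mesh, 1000.0, 0.3).toarray()
        assert np.allclose(K, K.T, atol=1e-12)
        eig = np.linalg.eigvalsh(K)
        assert np.sum(np.abs(eig) < 1e-8 * np.abs(eig).max()) == 6
        assert np.all(eig > -1e-8 * np.abs(eig).max())

    def test_doubling_modulus_doubles_stiffness(self, bar_mesh):
        K1 = fe.assemble_stiffness(bar_mesh, 1000.0, 0.3)
        K2 = fe.assemble_stiffness(bar_mesh, 2000.0, 0.3)
        assert np.allclose(K2.toarray(), 2.0 * K1.toarray(), rtol=1e-12)

    def test_energy_nonnegative_for_random_displacements(self):
        mesh = regular_tet()
        K = fe.assemble_stiffness(mesh, 500.0, 0.25)
        rng = np.random.default_rng(0)
        for _ in range(100):
            u = rng.standard_normal(K.shape[0])
            assert u @ (K @ u) >= -1e-9

    def test_missing_material_rejected(self, nf_foot_model):
        with pytest.raises(ParameterError):
            fe.material_arrays(nf_foot_model, {"bone": fe.BONE})

    def test_invalid_material_rejected(self):
        with pytest.raises(ParameterError):
            fe.Material(youngs_modulus=-1.0, poisson_ratio=0.3)
        with pytest.raises(ParameterError):
            fe.Material(youngs_modulus=10.0, poisson_ratio=0.5)


# ---------------------------------------------------------------------------
# Loads
# ---------------------------------------------------------------------------

class TestPlantarPressure:
    def test_uniform_pressure_resultant(self):
        # 100 kPa over the 10x10 mm^2 bottom patch -> 10 N upward (+z)
        mesh = slab_mesh()
        faces, _ = fe.plantar_faces(mesh)
        face_regions = {"all": np.arange(len(faces))}
        f = fe.apply_plantar_pressure(mesh, face_regions, {"all": 100.0}, faces)
        total = f.reshape(-1, 3).sum(axis=0)
        assert np.allclose(total, [0.0, 0.0, 10.0], atol=1e-9)

    def test_zero_pressure_zero_vector(self):
        mesh = slab_mesh()
        faces, _ = fe.plantar_faces(mesh)
        f = fe.apply_plantar_pressure(
            mesh, {"all": np.arange(len(faces))}, {"all": 0.0}, faces
        )
        assert np.all(f == 0.0)

    def test_region_split_additivity(self):
        mesh = slab_mesh()
        faces, _ = fe.plantar_faces(mesh)
        n = len(faces)
        whole = fe.apply_plantar_pressure(
            mesh, {"all": np.arange(n)}, {"all": 75.0}, faces
        )
        split = fe.apply_plantar_pressure(
            mesh,
            {"a": np.arange(n // 2), "b": np.arange(n // 2, n)},
            {"a": 75.0, "b": 75.0},
            faces,
        )
        assert np.allclose(whole, split, atol=1e-12)

    def test_unassigned_face_rejected(self):
        mesh = slab_mesh()
        faces, _ = fe.plantar_faces(mesh)
        with pytest.raises(ParameterError):
            fe.apply_plantar_pressure(
                mesh, {"a": np.arange(len(faces) - 1)}, {"a": 10.0}, faces
            )


class TestConnectors:
    def two_node_spring(self, k=200.0):
        mesh = TetMesh(
            nodes=np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]]),
            tets=np.empty((0, 4), int),
        )
        from scipy import sparse

        K = sparse.csr_matrix((6, 6))
        return mesh, fe.add_connectors(K, mesh, [(0, 1)], k)

    def test_stiffness_200_force_200_gives_1mm(self):
        # the fascia connector stiffness: F/k = 200 N / 200 N/mm = 1 mm
        mesh, K = self.two_node_spring(k=200.0)
        fixed = [0, 1, 2, 4, 5]  # clamp node 0, restrain node 1 laterally
        free = [3]
        u = spsolve(K.tocsc()[free][:, free], np.array([200.0]))
        assert u[0] == pytest.approx(1.0, abs=1e-12)

    def test_zero_stiffness_leaves_operator(self):
        mesh, K = self.two_node_spring(k=0.0)
        assert K.nnz == 0

    def test_energy_matches_axial_elongation(self):
        mesh, K = self.two_node_spring(k=137.0)
        rng = np.random.default_rng(2)
        n = np.array([1.0, 0.0, 0.0])
        for _ in range(20):
            u = rng.standard_normal(6)
            elong = (u[3:] - u[:3]) @ n
            assert 0.5 * u @ (K @ u) == pytest.approx(
                0.5 * 137.0 * elong**2, rel=1e-12
            )

    def test_coincident_nodes_rejected(self):
        mesh = TetMesh(
            nodes=np.zeros((2, 3)), tets=np.empty((0, 4), int)
        )
        from scipy import sparse

        with pytest.raises(ParameterError):
            fe.add_connectors(sparse.csr_matrix((6, 6)), mesh, [(0, 1)], 10.0)


class TestAchillesLoad:
    def test_equal_shares_along_axis(self, nf_foot_model):
        f = fe.achilles_load(nf_foot_model, 256.0)
        F = f.reshape(-1, 3)
        nodes = nf_foot_model.node_sets["achilles"]
        assert np.allclose(F.sum(axis=0), [0.0, 0.0, 256.0], atol=1e-9)
        assert np.allclose(F[nodes, 2], 256.0 / len(nodes))


# ---------------------------------------------------------------------------
# Solves
# ---------------------------------------------------------------------------

class TestSolve:
    def test_uniaxial_bar_analytic_strain(self, bar_mesh):
        # E = 7300 MPa under 7.3 MPa traction: strain exactly 1e-3
        mesh = bar_mesh
        E, nu = 7300.0, 0.3
        K = fe.assemble_stiffness(mesh, E, nu)
        faces, _ = mesh.boundary_faces_with_elements()
        top = faces[np.all(mesh.nodes[faces][:, :, 2] > 100 - 1e-9, axis=1)]
        f = np.zeros(3 * mesh.n_nodes)
        v = mesh.nodes
        area_vec = 0.5 * np.cross(
            v[top[:, 1]] - v[top[:, 0]], v[top[:, 2]] - v[top[:, 0]]
        )
        for k in range(3):
            np.add.at(f.reshape(-1, 3), top[:, k], 7.3 * area_vec / 3.0)
        bottom = np.flatnonzero(v[:, 2] < 1e-9)
        # roller supports: fix z on the bottom face, pin lateral rigid modes
        fixed_dofs = [3 * int(n) + 2 for n in bottom]
        corner = int(bottom[np.argmin(np.abs(v[bottom, :2]).sum(axis=1))])
        other = int(bottom[np.argmax(v[bottom, 0])])
        fixed_dofs += [3 * corner, 3 * corner + 1, 3 * other + 1]
        sol = fe.solve(
            K, f, None, mesh, E, nu, fixed_dofs=np.array(fixed_dofs)
        )
        tip = sol.displacements[v[:, 2] > 100 - 1e-9, 2]
        assert np.allclose(tip, 0.1, rtol=1e-8)          # strain 1.0e-3
        assert np.allclose(sol.von_mises, 7.3, rtol=1e-8)
        lateral = sol.displacements[v[:, 2] > 100 - 1e-9, 0]
        assert np.ptp(lateral) == pytest.approx(0.3 * 1e-3 * 10.0, rel=1e-6)

    def test_patch_test_constant_strain(self):
        # linear displacement imposed on the boundary is reproduced exactly
        mesh = slab_mesh(3, 3, 3)
        E, nu = 1000.0, 0.3
        K = fe.assemble_stiffness(mesh, E, nu)
        A = np.array([[1e-3, 2e-4, 0.0], [0.0, -5e-4, 1e-4], [3e-4, 0.0, 8e-4]])
        u_exact = mesh.nodes @ A.T
        faces, _ = mesh.boundary_faces_with_elements()
        bnodes = np.unique(faces)
        fixed_dofs = (3 * bnodes[:, None] + np.arange(3)).ravel()
        sol = fe.solve(
            K,
            np.zeros(3 * mesh.n_nodes),
            None,
            mesh,
            E,
            nu,
            fixed_dofs=fixed_dofs,
            fixed_values=u_exact[bnodes].ravel(),
        )
        assert np.allclose(sol.displacements, u_exact, atol=1e-8)
        # constant strain implies identical stress in every element
        assert np.ptp(sol.stresses, axis=0).max() < 1e-8

    def test_global_equilibrium(self, nf_foot_model):
        mesh = nf_foot_model
        E, nu = fe.material_arrays(mesh, {"bone": fe.BONE, "soft": fe.SOFT_TISSUE})
        K = fe.assemble_stiffness(mesh, E, nu)
        f = fe.achilles_load(mesh, 100.0)
        sol = fe.solve(K, f, mesh.node_sets["fixed_proximal"], mesh, E, nu)
        out_of_balance = sol.reactions.sum(axis=0) + f.reshape(-1, 3).sum(axis=0)
        assert np.linalg.norm(out_of_balance) < 1e-6
        assert sol.residual < 1e-8
        fixed = mesh.node_sets["fixed_proximal"]
        assert np.allclose(sol.displacements[fixed], 0.0)

    def test_unconstrained_system_rejected(self, bar_mesh):
        K = fe.assemble_stiffness(bar_mesh, 1000.0, 0.3)
        with pytest.raises(fe.SingularSystemError):
            fe.solve(K, np.zeros(K.shape[0]), None, bar_mesh, 1000.0, 0.3)

    def test_cantilever_converges_to_beam_theory(self):
        # tip deflection approaches Euler-Bernoulli monotonically and lands
        # within 5% at the third refinement level
        E, nu, P = 1000.0, 0.3, 10.0
        Lb, c = 40.0, 4.0
        eb = P * Lb**3 / (3 * E * c**4 / 12)
        ratios = []
        for h in (1.6, 0.8, 0.4):
            n = (round(c / h), round(c / h), round(Lb / h))
            mesh = synthetic.lattice_tet_mesh(
                np.zeros(3), np.array([c, c, Lb]), n, lambda p: np.ones(len(p), bool)
            )
            K = fe.assemble_stiffness(mesh, E, nu)
            f = np.zeros(3 * mesh.n_nodes)
            tip = np.flatnonzero(mesh.nodes[:, 2] > Lb - 1e-9)
            f.reshape(-1, 3)[tip, 0] = P / len(tip)
            fixed = np.flatnonzero(mesh.nodes[:, 2] < 1e-9)
            sol = fe.solve(K, f, fixed, mesh, E, nu)
            ratios.append(sol.displacements[tip, 0].mean() / eb)
        assert ratios[0] < ratios[1] < ratios[2]  # monotone convergence
        assert abs(ratios[-1] - 1.0) < 0.05


# ---------------------------------------------------------------------------
# von Mises
# ---------------------------------------------------------------------------

class TestVonMises:
    @pytest.mark.parametrize(
        "voigt,expected",
        [
            ([5.0, 0, 0, 0, 0, 0], 5.0),              # uniaxial
            ([-3.0, -3.0, -3.0, 0, 0, 0], 0.0),       # hydrostatic
            ([0, 0, 0, 2.0, 0, 0], 2.0 * np.sqrt(3)),  # pure shear
        ],
    )
    def test_canonical_states(self, voigt, expected):
        assert fe.von_mises(np.array(voigt)) == pytest.approx(expected, abs=1e-12)

    def test_nodal_recovery_preserves_constant_field(self, bar_mesh):
        vm = np.full(bar_mesh.n_elements, 4.2)
        nodal = fe.nodal_von_mises(bar_mesh, vm)
        assert np.allclose(nodal, 4.2)


# ---------------------------------------------------------------------------
# Property tests
# ---------------------------------------------------------------------------

from hypothesis import given, settings
from hypothesis import strategies as st


@st.composite
def voigt_stress(draw):
    comp = st.floats(-100.0, 100.0, allow_nan=False)
    return np.array([draw(comp) for _ in range(6)])


class TestVonMisesProperties:
    @given(voigt_stress(), st.floats(-50.0, 50.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_invariant_under_hydrostatic_shift(self, s, p):
        shifted = s + np.array([p, p, p, 0.0, 0.0, 0.0])
        assert fe.von_mises(shifted) == pytest.approx(
            fe.von_mises(s), rel=1e-9, abs=1e-9
        )

    @given(voigt_stress(), st.floats(0.0, 10.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_positively_homogeneous(self, s, a):
        assert fe.von_mises(a * s) == pytest.approx(
            a * fe.von_mises(s), rel=1e-9, abs=1e-9
        )
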