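"""Bone remodelling: stimulus, adaptation law, fixed points, comparisons."""

import numpy as np
import pytest

from footform import fe, remodel, synthetic
from footform.types import DensityField, ParameterError, TetMesh


@pytest.fixture(scope="module")
def params():
    return remodel.RemodelParams()


def bar_with_traction(traction_mpa, nx=2, nz=8, E=3790.0 * 1.24**3):
    """Uniaxial column under constant end traction: statically determinate,
    so the continuum stress field is independent of the modulus."""
    mesh = synthetic.lattice_tet_mesh(
        np.zeros(3),
        np.array([10.0, 10.0, 40.0]),
        (nx, nx, nz),
        lambda p: np.ones(len(p), bool),
    )
    faces, _ = mesh.boundary_faces_with_elements()
    top = faces[np.all(mesh.nodes[faces][:, :, 2] > 40.0 - 1e-9, axis=1)]
    f = np.zeros(3 * mesh.n_nodes)
    v = mesh.nodes
    area_vec = 0.5 * np.cross(v[top[:, 1]] - v[top[:, 0]], v[top[:, 2]] - v[top[:, 0]])
    for k in range(3):
        np.add.at(f.reshape(-1, 3), top[:, k], traction_mpa * area_vec / 3.0)
    bottom = np.flatnonzero(v[:, 2] < 1e-9)
    fixed_dofs = [3 * int(n) + 2 for n in bottom]
    corner = int(bottom[np.argmin(np.abs(v[bottom, :2]).sum(axis=1))])
    other = int(bottom[np.argmax(v[bottom, 0])])
    fixed_dofs += [3 * corner, 3 * corner + 1, 3 * other + 1]
    return mesh, f, np.array(fixed_dofs)


def _run_remodelling_dofs(mesh, f, fixed_dofs, rho0, rparams, **kw):
    """Remodelling run with roller (per-dof) boundary conditions."""
    return remodel.run_remodelling(
        mesh, f, None, rho0, rparams, fixed_dofs=fixed_dofs, **kw
    )


# ---------------------------------------------------------------------------
# Stimulus
# ---------------------------------------------------------------------------

class TestDailyStimulus:
    def test_zero_stress_zero_stimulus(self, params):
        psi = remodel.daily_stimulus(np.zeros(5), np.full(5, 1.0), params)
        assert np.all(psi == 0.0)

    def test_unit_scale_at_max_density(self, params):
        vm = np.array([3.0])
        psi = remodel.daily_stimulus(vm, np.array([params.rho_max]), params)
        pre = params.n_cycles ** (1 / params.stimulus_exponent)
        assert psi[0] == pytest.approx(pre * 3.0, rel=1e-12)

    def test_cycle_prefactor_closed_form(self, params):
        # 10,000 cycles/day at exponent 4 gives prefactor 10000^0.25 = 10
        psi = remodel.daily_stimulus(
            np.array([1.0]), np.array([params.rho_max]), params
        )
        assert psi[0] == pytest.approx(10.0, rel=1e-12)

    def test_strictly_decreasing_in_density(self, params):
        rho = np.linspace(0.2, 1.8, 50)
        psi = remodel.daily_stimulus(np.full(50, 2.0), rho, params)
        assert np.all(np.diff(psi) < 0)

    def test_nonpositive_density_rejected(self, params):
        with pytest.raises(ParameterError):
            remodel.daily_stimulus(np.ones(2), np.array([1.0, 0.0]), params)


# ---------------------------------------------------------------------------
# Density update
# ---------------------------------------------------------------------------

class TestUpdateDensity:
    def test_setpoint_is_fixed_point(self, params):
        rho = np.full(10, 1.0)
        psi = np.full(10, params.setpoint_stimulus)
        out = remodel.update_density(rho, psi, params)
        assert np.array_equal(out.values, rho)

    def test_lazy_zone_edges_inclusive(self, params):
        rho = np.full(2, 1.0)
        psi = params.setpoint_stimulus * np.array(
            [1.0 + params.lazy_zone_halfwidth, 1.0 - params.lazy_zone_halfwidth]
        )
        out = remodel.update_density(rho, psi, params)
        assert np.array_equal(out.values, rho)

    def test_overload_step_closed_form(self, params):
        # psi = 2 psi*(1+w): growth rate c_r * psi*(1+w)
        hi = params.setpoint_stimulus * (1 + params.lazy_zone_halfwidth)
        rho = np.array([1.0])
        out = remodel.update_density(rho, np.array([2 * hi]), params)
        expected = 1.0 + params.rate_constant * hi * params.dt
        assert out.values[0] == pytest.approx(expected, rel=1e-12)

    def test_clamped_at_bounds(self, params):
        out_hi = remodel.update_density(
            np.array([params.rho_max]), np.array([1e6]), params
        )
        out_lo = remodel.update_density(
            np.array([params.rho_min]), np.array([0.0]), params
        )
        assert out_hi.values[0] == params.rho_max
        assert out_lo.values[0] == params.rho_min

    def test_step_cap(self, params):
        out = remodel.update_density(np.array([1.0]), np.array([1e9]), params)
        assert out.values[0] == pytest.approx(1.0 + params.max_step)


# ---------------------------------------------------------------------------
# Modulus coupling
# ---------------------------------------------------------------------------

class TestModulus:
    def test_linear_case_closed_form(self, params):
        p = params.replace(modulus_coefficient=1000.0, modulus_exponent=1.0)
        assert remodel.modulus_from_density(np.array([0.5]), p)[0] == 500.0

    def test_default_matches_cortical_bone_modulus(self, params):
        # E(1.24 g/cm^3) = 3790 * 1.24^3 ~ 7226 MPa, within 2% of 7300
        E = remodel.modulus_from_density(np.array([1.24]), params)[0]
        assert abs(E - 7300.0) / 7300.0 < 0.02

    def test_strictly_increasing(self, params):
        rho = np.linspace(0.05, 1.8, 100)
        E = remodel.modulus_from_density(rho, params)
        assert np.all(np.diff(E) > 0)


# ---------------------------------------------------------------------------
# Full runs on the uniaxial bar
# ---------------------------------------------------------------------------

class TestRunRemodelling:
    def test_equilibrium_bar_stays_constant(self):
        # choose traction so the initial stimulus sits exactly at the setpoint
        rparams = remodel.RemodelParams(n_days=10)
        rho0 = 1.24
        sigma = (
            rparams.setpoint_stimulus
            / rparams.n_cycles ** (1 / rparams.stimulus_exponent)
            * (rho0 / rparams.rho_max) ** 2
        )
        mesh, f, fixed_dofs = bar_with_traction(sigma)
        history = _run_remodelling_dofs(
            mesh, f, fixed_dofs, DensityField(np.full(mesh.n_elements, rho0)), rparams
        )
        assert history.converged
        assert np.array_equal(history.final.values, history.initial.values)

    def test_overloaded_bar_reaches_analytic_fixed_point(self):
        # without a lazy zone the density must land on the analytic root of
        # n^(1/m) sigma (rho_max/rho)^2 = psi*
        rparams = remodel.RemodelParams(
            n_days=400, lazy_zone_halfwidth=0.0, rate_constant=0.004
        )
        sigma = 1.0  # fixed point rho* = 1.8 sqrt(0.5), inside [rho_min, rho_max]
        rho_star = remodel.analytic_bar_fixed_point(sigma, rparams)
        mesh, f, fixed_dofs = bar_with_traction(sigma)
        rho0 = rho_star / 1.5**0.5  # start with stimulus at 1.5 psi*
        history = _run_remodelling_dofs(
            mesh, f, fixed_dofs, DensityField(np.full(mesh.n_elements, rho0)), rparams
        )
        traj = np.array([s.values.mean() for s in history.snapshots])
        assert np.all(np.diff(traj) >= -1e-12)  # monotone rise
        assert np.all(np.abs(history.final.values - rho_star) / rho_star < 0.01)

    def test_overloaded_bar_ends_inside_lazy_zone(self):
        rparams = remodel.RemodelParams(n_days=400, rate_constant=0.004)
        sigma = 1.0
        mesh, f, fixed_dofs = bar_with_traction(sigma)
        rho_star = remodel.analytic_bar_fixed_point(sigma, rparams)
        history = _run_remodelling_dofs(
            mesh, f, fixed_dofs,
            DensityField(np.full(mesh.n_elements, rho_star / 1.5**0.5)), rparams,
        )
        pre = rparams.n_cycles ** (1 / rparams.stimulus_exponent)
        psi_end = pre * sigma * (rparams.rho_max / history.final.values) ** 2
        lo = rparams.setpoint_stimulus * (1 - rparams.lazy_zone_halfwidth)
        hi = rparams.setpoint_stimulus * (1 + rparams.lazy_zone_halfwidth)
        # the run stops when the daily density change drops below the
        # convergence tolerance, i.e. when |psi - zone edge| <= tol / c_r
        slack = rparams.convergence_tol / rparams.rate_constant + 1e-9
        assert np.all(psi_end >= lo - slack) and np.all(psi_end <= hi + slack)

    def test_zero_load_decays_to_rho_min(self):
        rparams = remodel.RemodelParams(n_days=1000, rate_constant=0.01)
        mesh, f, fixed_dofs = bar_with_traction(0.0)
        history = _run_remodelling_dofs(
            mesh, f, fixed_dofs,
            DensityField(np.full(mesh.n_elements, 0.6)), rparams,
        )
        assert np.all(history.final.values == rparams.rho_min)

    def test_monotone_load_response(self):
        rparams = remodel.RemodelParams(n_days=30, rate_constant=0.004)
        masses = []
        for traction in (2.0, 3.0):
            mesh, f, fixed_dofs = bar_with_traction(traction)
            history = _run_remodelling_dofs(
                mesh, f, fixed_dofs,
                DensityField(np.full(mesh.n_elements, 1.0)), rparams,
            )
            masses.append(history.bone_mass[-1])
        assert masses[1] >= masses[0]

    def test_snapshot_count_and_mass_trace(self):
        rparams = remodel.RemodelParams(n_days=5)
        mesh, f, fixed_dofs = bar_with_traction(1.0)
        history = _run_remodelling_dofs(
            mesh, f, fixed_dofs,
            DensityField(np.full(mesh.n_elements, 1.0)), rparams,
        )
        if not history.converged:
            assert len(history.snapshots) == 6  # n_days/dt + 1
        assert np.all(np.isfinite(history.bone_mass))


# ---------------------------------------------------------------------------
# Density-map comparison
# ---------------------------------------------------------------------------

class TestCompareDensityMaps:
    def _regions(self, mesh):
        z = mesh.element_centroids()[:, 2]
        third = (z.max() - z.min()) / 3
        return {
            "low": np.flatnonzero(z < z.min() + third),
            "mid": np.flatnonzero((z >= z.min() + third) & (z < z.max() - third)),
            "high": np.flatnonzero(z >= z.max() - third),
        }

    def test_identical_fields_perfect_rank_correlation(self, bar_mesh):
        rho = synthetic.make_density_phantom(bar_mesh, "gradient")
        cmp = remodel.compare_density_maps(rho, rho, self._regions(bar_mesh))
        assert cmp.rank_correlation == pytest.approx(1.0)
        assert cmp.same_ranking
        assert not cmp.degenerate

    def test_constant_reference_flagged(self, bar_mesh):
        pred = synthetic.make_density_phantom(bar_mesh, "gradient")
        ref = synthetic.make_density_phantom(bar_mesh, "uniform", value=1.0)
        cmp = remodel.compare_density_maps(pred, ref, self._regions(bar_mesh))
        assert cmp.degenerate
        assert np.isnan(cmp.rank_correlation)

    def test_shell_phantom_ranking(self, bar_mesh):
        """A cortical-shell reference and a shell-weighted prediction rank
        the shell region highest in both fields."""
        ref = synthetic.make_density_phantom(bar_mesh, "cortical_shell")
        pred = DensityField(0.4 + 0.5 * (ref.values == 1.8))
        _, owners = bar_mesh.boundary_faces_with_elements()
        shell = np.unique(owners)
        core = np.setdiff1d(np.arange(bar_mesh.n_elements), shell)
        cmp = remodel.compare_density_maps(
            pred, ref, {"shell": shell, "core": core}
        )
        assert cmp.same_ranking
        assert cmp.region_means["shell"][0] > cmp.region_means["core"][0]
        assert cmp.region_means["shell"][1] > cmp.region_means["core"][1]

    def test_mismatched_meshes_rejected(self, bar_mesh):
        with pytest.raises(ParameterError):
            remodel.compare_density_maps(
                DensityField(np.ones(3)),
                DensityField(np.ones(4)),
                {"all": np.arange(3)},
            )

    def test_calcaneus_regions_partition(self, nf_foot_model):
        regions = remodel.calcaneus_regions(nf_foot_model)
        cal = set(nf_foot_model.element_sets["calcaneus"].tolist())
        for name, ids in regions.items():
            assert set(ids.tolist()) <= cal
        assert len(regions["shell"]) > 0
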