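import numpy as np
import pytest

from poroindent.fem import (
    FESystem,
    SolverSettings,
    classify_facets,
    indentation_bcs,
    protocol_time_grid,
    run_protocol,
)
from poroindent.identification import fit_mesh, fit_settings
from poroindent.mesh import ConfigError, Geometry, build_mesh
from poroindent.protocols import build_protocol


@pytest.fixture(scope="module")
def geom():
    return Geometry()


@pytest.fixture(scope="module")
def mesh0(geom):
    return build_mesh(geom, 0)


@pytest.fixture(scope="module")
def small_system(geom, params):
    mesh = fit_mesh(geom)
    return FESystem(mesh, params, indentation_bcs(mesh, geom),
                    fit_settings())


class TestMesh:
    def test_deterministic_snapshot(self, geom, mesh0):
        again = build_mesh(geom, 0)
        assert mesh0.n_cells == 96  # documented base layout
        np.testing.assert_array_equal(mesh0.r_breaks, again.r_breaks)
        np.testing.assert_array_equal(mesh0.z_breaks, again.z_breaks)

    def test_refinement_quadruples_cells(self, geom, mesh0):
        m1 = build_mesh(geom, 1)
        assert m1.n_cells == 4 * mesh0.n_cells
        assert m1.n_cells >= 2 * mesh0.n_cells  # refinement contract

    def test_positive_map_jacobians(self, mesh0):
        assert mesh0.min_map_jacobian() > 0.0

    def test_edge_zone_resolution(self, mesh0):
        assert mesh0.edge_zone_cell_count() >= 4

    def test_node_exactly_at_punch_edge(self, geom, mesh0):
        assert np.any(np.abs(mesh0.r_breaks - geom.punch_radius) < 1e-12)

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ConfigError):
            Geometry(sample_radius=1.0, punch_radius=2.0)
        with pytest.raises(ConfigError):
            build_mesh(Geometry(), refinement_level=-1)

    def test_vtk_export_is_readable_text(self, mesh0, tmp_path):
        path = tmp_path / "mesh.vtk"
        mesh0.write_vtk(path, point_data={"p": np.zeros(len(mesh0.nodes_p))})
        head = path.read_text().splitlines()
        assert head[0].startswith("# vtk DataFile")
        assert any(line.startswith("CELLS") for line in head)


class TestBoundaryClassification:
    def test_every_boundary_facet_classified_exactly_once(self, geom, mesh0):
        classes = classify_facets(mesh0, geom)
        nr = len(mesh0.r_breaks) - 1
        nz = len(mesh0.z_breaks) - 1
        all_facets = [f for lst in classes.values() for f in lst]
        assert len(all_facets) == len(set(all_facets)) == 2 * nr + 2 * nz

    def test_punch_and_drained_sets_disjoint(self, geom, mesh0):
        classes = classify_facets(mesh0, geom)
        assert not set(classes["punch"]) & set(classes["top_drained"])
        bcs = indentation_bcs(mesh0, geom)
        assert not set(bcs.punch_z_dofs) & set(bcs.drained_p_dofs)

    def test_punch_footprint_covers_radius(self, geom, mesh0):
        bcs = indentation_bcs(mesh0, geom)
        nodes = (bcs.punch_z_dofs - 1) // 2
        r = mesh0.nodes_u[nodes, 0]
        assert r.max() == pytest.approx(geom.punch_radius)
        assert np.all(mesh0.nodes_u[nodes, 1] == geom.sample_height)


class TestAssembly:
    def test_stress_free_reference_has_zero_residual(self, small_system):
        x, internal, J_old = small_system.initial_state()
        R = small_system.residual(x, internal, J_old, 0.1)
        assert np.abs(R).max() == 0.0

    def test_uniform_pressure_is_not_an_equilibrium(self, small_system):
        """A uniform pore pressure with drained outer boundaries drives
        Darcy outflow: the mass-balance residual cannot vanish."""
        x, internal, J_old = small_system.initial_state()
        x[small_system.ndof_u:] = 1000.0
        x[small_system.bcs.drained_p_dofs] = 0.0
        R = small_system.residual(x, internal, J_old, 0.1)
        Rp_free = R[small_system.ndof_u:][
            small_system.free[small_system.ndof_u:]]
        assert np.abs(Rp_free).max() > 1e-8

    def test_tangent_matches_directional_derivative(self, small_system, rng):
        """Central finite difference of the residual along a random
        direction agrees with the assembled tangent to ~1e-5 relative."""
        sys_ = small_system
        x, internal, J_old = sys_.initial_state()
        x = x.copy()
        x[:sys_.ndof_u] += 1e-3 * rng.standard_normal(sys_.ndof_u)
        x[sys_.ndof_u:] += rng.standard_normal(sys_.ndof - sys_.ndof_u)
        R, K = sys_.assemble_system(x, internal, J_old, 0.1)
        v = rng.standard_normal(sys_.ndof)
        h = 1e-6
        Rp = sys_.residual(x + h * v, internal, J_old, 0.1)
        Rm = sys_.residual(x - h * v, internal, J_old, 0.1)
        fd = (Rp - Rm) / (2 * h)
        Kv = K @ v
        assert (np.linalg.norm(Kv - fd)
                / np.linalg.norm(Kv)) < 1e-4


class TestSolveStep:
    def test_zero_increment_from_rest_converges_immediately(self,
                                                            small_system):
        x, internal, J_old = small_system.initial_state()
        x2, aux, iters = small_system.solve_step(x, internal, J_old,
                                                 depth=0.0, dt=0.1)
        assert iters == 0
        dofs = small_system.bcs.punch_z_dofs
        assert np.abs(aux["R"][dofs]).max() == 0.0

    def test_downward_punch_gives_compressive_positive_force(
            self, small_system):
        x, internal, J_old = small_system.initial_state()
        x2, aux, _ = small_system.solve_step(x, internal, J_old,
                                             depth=0.01, dt=0.01)
        ft, fs, ff = small_system.punch_force(x2, internal, J_old, 0.01)
        assert ft > 0.0

    def test_force_split_sums_to_total(self, small_system):
        x, internal, J_old = small_system.initial_state()
        x2, aux, _ = small_system.solve_step(x, internal, J_old,
                                             depth=0.05, dt=0.05)
        ft, fs, ff = small_system.punch_force(x2, internal, J_old, 0.05)
        assert ft == pytest.approx(fs + ff, rel=1e-8)


class TestProtocolDriver:
    def test_time_grid_hits_segment_ends(self):
        p = build_protocol("P2", 1)
        st = SolverSettings(dt_ramp=0.05, dt_growth=1.5)
        t = protocol_time_grid(p, st)
        ramp_end, hold_end = 0.625, p.cycle_window(1)[1]
        for target in (ramp_end, hold_end, p.duration):
            assert np.min(np.abs(t - target)) < 1e-9

    def test_zero_displacement_protocol_gives_zero_force(self, params):
        p = build_protocol("P2", 1)
        res = run_protocol(p, params, settings=fit_settings(),
                           mesh=fit_mesh(), t_end=0.3,
                           displacement=lambda t: 0.0, diagnostics=False)
        np.testing.assert_allclose(res.force, 0.0, atol=1e-9)

    def test_ramp_rises_then_hold_relaxes_monotonically(self, params):
        """Qualitative cycle-1 contract: near-linear force rise during the
        ramp, then monotone relaxation during the hold."""
        p = build_protocol("P2", 1)
        res = run_protocol(p, params, settings=fit_settings(),
                           mesh=fit_mesh(), t_end=20.0, diagnostics=False)
        ramp_end = 0.625
        ramp = res.t <= ramp_end + 1e-9
        hold = res.t > ramp_end + 1e-9
        assert np.all(np.diff(res.force[ramp]) > 0)
        assert np.all(np.diff(res.force[hold]) < 0)
        # near-linear rise: correlation of F vs t over the ramp
        r = np.corrcoef(res.t[ramp][1:], res.force[ramp][1:])[0, 1]
        assert r > 0.99

    def test_undrained_early_response_is_quasi_incompressible(
            self, small_system, geom):
        """Loading much faster than consolidation: volumetric strain in the
        material under the punch stays within ~1e-3 during the early ramp
        (fluid has no time to leave; only the free surface next to the
        punch edge drains instantly)."""
        sys_ = small_system
        x, internal, J_old = sys_.initial_state()
        mesh = sys_.mesh
        nr = len(mesh.r_breaks) - 1
        r_hi = np.tile(mesh.r_breaks[1:], mesh.n_cells // nr)
        # interior of the footprint, away from the edge singularity
        under = r_hi <= 0.8 * geom.punch_radius + 1e-9
        t_prev, d_prev = 0.0, 0.0
        aux = None
        for t in (0.0125, 0.025, 0.0375, 0.05):
            d = 1.6 * t
            x, aux, _ = sys_.advance(x, internal, J_old, d_prev, d,
                                     t - t_prev)
            internal, J_old = aux["internal"], aux["J"]
            t_prev, d_prev = t, d
        J_under = aux["J"][under]
        assert np.max(np.abs(J_under - 1.0)) < 1.0e-3

    def test_spatial_convergence_of_peak_force(self, params):
        """One refinement level changes the cycle-1 peak force by < 3%
        (slowest-converging quantity: the punch-edge pressure
        singularity)."""
        p = build_protocol("P2", 1)
        st = SolverSettings(dt_ramp=0.04, newton_rtol=1e-6,
                            tangent_refresh_steps=4)
        peaks = []
        for lvl in (0, 1):
            res = run_protocol(p, params, settings=st,
                               refinement_level=lvl, t_end=0.63,
                               diagnostics=False)
            peaks.append(res.peak_force())
        assert abs(peaks[1] - peaks[0]) / peaks[1] < 0.03

    def test_temporal_self_convergence_of_peak_force(self, params):
        """Halving every time step changes the cycle-1 peak force by
        well under 1% on the coarse mesh."""
        p = build_protocol("P2", 1)
        peaks = []
        for dt in (0.05, 0.025):
            st = SolverSettings(dt_ramp=dt, dt_growth=1.5,
                                newton_rtol=1e-6, tangent_refresh_steps=4)
            res = run_protocol(p, params, settings=st, mesh=fit_mesh(),
                               t_end=0.7, diagnostics=False)
            peaks.append(res.peak_force())
        assert abs(peaks[1] - peaks[0]) / peaks[1] < 0.01


class TestMassConservation:
    def test_outflow_balances_volume_change_on_column(self):
        """Independently integrated drained-boundary flux matches the
        domain volume change within 1% on a resolved consolidation
        column."""
        from poroindent.benchmark import _column_bcs, linearized_params

        from poroindent.mesh import build_column_mesh

        params = linearized_params()
        mesh = build_column_mesh(0.3, 1.0, 2, 16)
        bcs = _column_bcs(mesh, load=50.0)
        sys_ = FESystem(mesh, params, bcs, SolverSettings())
        x, internal, J_old = sys_.initial_state()
        ramp = 5e-3
        times = np.concatenate([[ramp / 2, ramp],
                                np.geomspace(ramp, 40.0, 80)[1:]])
        t_prev, outflow, rate_prev = 0.0, 0.0, 0.0
        for t in times:
            sys_.f_scale = min(t / ramp, 1.0)
            x, aux, _ = sys_.advance(x, internal, J_old, 0.0, 0.0,
                                     t - t_prev)
            internal, J_old = aux["internal"], aux["J"]
            rate = sys_.boundary_outflow(x, aux)
            outflow += 0.5 * (rate + rate_prev) * (t - t_prev)
            rate_prev = rate
            t_prev = t
        dV = sys_.volume_change(aux)
        assert outflow == pytest.approx(-dV, rel=0.01)
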