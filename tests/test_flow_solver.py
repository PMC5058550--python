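"""Flux boundary profiles, mass split, and IPCS solver invariants."""
import numpy as np
import pytest
from dataclasses import replace

from csfflow.flow_solver import (
    Boundary,
    FlowState,
    FluidProperties,
    Solver,
    SolverConfig,
    build_inflow_profile,
    ipcs_step,
    kinetic_energy,
    mass_balance_split,
    run_cycles,
)
from csfflow.synthetic_data import GEOMETRY_PRESETS, GeometryPreset, make_geometry
from csfflow.waveform_io import SplineWaveform

from conftest import PROPS, run_steady_channel


class TestInflowProfile:
    def test_zero_flux_gives_zero_profile(self):
        mesh = make_geometry(GEOMETRY_PRESETS["CHANNEL_VERIF"])
        b = mesh.boundary("cervical")
        assert np.all(build_inflow_profile(b, 0.0, mesh) == 0.0)

    @pytest.mark.parametrize("q", [1.0, -123.4, 5678.0])
    def test_discrete_flux_identity(self, q):
        mesh = make_geometry(GEOMETRY_PRESETS["ANNULUS_COARSE"])
        b = mesh.boundary("cervical")
        u = build_inflow_profile(b, q, mesh)
        flux = float(np.sum(u * b.face_area))
        assert flux == pytest.approx(q, rel=1e-12)

    def test_tent_profile_peak_speed(self):
        # planar opening of width w, unit-depth: int(tau) = w^2/4, so the
        # midpoint speed is 2Q/w per unit depth
        gp = GeometryPreset("plane_channel", length_mm=10.0, gap_mm=2.0,
                            depth_mm=1.0, axial_cell_mm=1.0,
                            cross_cell_mm=2.0 / 33)
        mesh = make_geometry(gp)
        b = mesh.boundary("cervical")
        q = 10.0
        u = build_inflow_profile(b, q, mesh)
        assert u.max() == pytest.approx(2 * q / gp.gap_mm, rel=1e-3)
        # profile vanishes toward the wall junctions
        assert u[0] < u.max() / 4

    def test_degenerate_boundary_rejected(self):
        mesh = make_geometry(GEOMETRY_PRESETS["CHANNEL_VERIF"])
        b = mesh.boundary("cervical")
        bad = Boundary(b.tag, b.side, b.j, np.zeros_like(b.tau), b.face_area)
        with pytest.raises(ValueError, match="degenerate"):
            build_inflow_profile(bad, 1.0, mesh)


class TestMassBalanceSplit:
    def test_single_inlet_receives_remainder(self):
        assert mass_balance_split(100.0, 10.0, [33.0]) == [90.0]

    def test_equal_areas_split_equally(self):
        out = mass_balance_split(100.0, 10.0, [5.0, 5.0])
        assert out == [45.0, 45.0]

    def test_areas_two_to_one(self):
        out = mass_balance_split(90.0, 0.0, [2.0, 1.0])
        assert out == pytest.approx([60.0, 30.0])

    def test_conservation_holds_for_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            qcs, qaq = rng.normal(size=2) * 100
            areas = rng.uniform(0.5, 5.0, size=3)
            out = mass_balance_split(qcs, qaq, areas)
            assert sum(out) + qaq == pytest.approx(qcs, abs=1e-9)

    def test_unconservable_flux_rejected(self):
        with pytest.raises(ValueError, match="mass not conservable"):
            mass_balance_split(5.0, 1.0, [])


class TestIpcsStep:
    def test_zero_state_zero_forcing_stays_zero(self):
        mesh = make_geometry(GEOMETRY_PRESETS["CHANNEL_VERIF"])
        state = FlowState.zeros(mesh)
        solver = None
        for _ in range(5):
            state, solver = ipcs_step(
                state, {}, PROPS, 1e-3, mesh, solver=solver)
        assert np.all(state.u == 0) and np.all(state.v == 0)
        assert np.allclose(state.p, 0.0, atol=1e-12)

    def test_cfl_violation_raises(self):
        mesh = make_geometry(GEOMETRY_PRESETS["CHANNEL_VERIF"])
        b = mesh.boundary("cervical")
        ubc = np.zeros(mesh.ny)
        ubc[b.j] = build_inflow_profile(b, 5.0e4, mesh)
        state = FlowState.zeros(mesh)
        with pytest.raises(RuntimeError, match="CFL"):
            for _ in range(5):
                state, solver = ipcs_step(
                    state, {"lo": ubc, "hi": ubc}, PROPS, 5e-3, mesh)


class TestPoiseuille:
    def test_profile_matches_parabola_within_one_percent(self, poiseuille):
        mesh, state, q = poiseuille["mesh"], poiseuille["state"], poiseuille["q"]
        gp = poiseuille["preset"]
        i = mesh.nz // 2
        y = mesh.y_centers
        q_depth = q / gp.depth_mm
        w = gp.gap_mm
        exact = 6 * q_depth * y * (w - y) / w**3
        err = np.max(np.abs(state.u[i] - exact)) / exact.max()
        assert err < 0.01

    def test_divergence_below_tolerance(self, poiseuille):
        assert poiseuille["solver"].last_div_max < 1e-6

    def test_no_slip_wall_faces(self, poiseuille):
        state = poiseuille["state"]
        assert np.all(state.v[:, 0] == 0.0)
        assert np.all(state.v[:, -1] == 0.0)


class TestRunInvariants:
    def test_mass_and_divergence_on_pulsatile_run(self, womersley_run):
        res = womersley_run["result"]
        assert res.mass_residual_rel <= 1e-8
        assert res.div_max_per_s <= 1e-6

    def test_zero_amplitude_waveform_gives_zero_traces(self):
        mesh = make_geometry(replace(
            GEOMETRY_PRESETS["CHANNEL_VERIF"], cross_cell_mm=0.25))
        T = 0.8
        wave = SplineWaveform(lambda t: 0.0 * np.asarray(t), T,
                              origin_aligned=True)
        cfg = SolverConfig(dt_s=5e-3, cycles=2, stations_mm={"mid": 20.0})
        res = run_cycles(mesh, {"cervical": wave}, cfg, PROPS)
        tr = res.stations["mid"]
        assert np.allclose(tr.p_pa, 0.0, atol=1e-12)
        assert np.allclose(tr.q_mm3s, 0.0, atol=1e-12)
        assert np.allclose(res.domain_umax, 0.0, atol=1e-12)

    def test_kinetic_energy_decays_without_forcing(self):
        gp = replace(GEOMETRY_PRESETS["CHANNEL_VERIF"], cross_cell_mm=0.125)
        mesh, state, solver = run_steady_channel(gp, 200.0, n_steps=50, dt=2e-3)
        zeros = np.zeros(mesh.ny)
        ke = [kinetic_energy(state, mesh, PROPS)]
        for k in range(40):
            state = solver.step(state, zeros, zeros, state.t + solver.dt)
            ke.append(kinetic_energy(state, mesh, PROPS))
        assert np.all(np.diff(ke) < 0)

    def test_stokes_limit_linearity(self):
        """Doubling the flux doubles u and p everywhere; R is unchanged."""
        gp = replace(GEOMETRY_PRESETS["CHANNEL_VERIF"], cross_cell_mm=0.25,
                     axial_cell_mm=2.0)
        T = 0.8
        cfg = SolverConfig(dt_s=2e-3, cycles=2, convection=False,
                           stations_mm={"a": 10.0, "b": 30.0})
        results = []
        for amp in (100.0, 200.0):
            wave = SplineWaveform(
                lambda t, A=amp: -A * np.sin(2 * np.pi * np.asarray(t) / T),
                T, origin_aligned=True)
            mesh = make_geometry(gp)
            results.append(run_cycles(mesh, {"cervical": wave}, cfg, PROPS))
        r1, r2 = results
        for lab in ("a", "b"):
            assert np.allclose(2 * r1.stations[lab].p_pa,
                               r2.stations[lab].p_pa, rtol=1e-10, atol=1e-10)
            assert np.allclose(2 * r1.stations[lab].umax_mms,
                               r2.stations[lab].umax_mms, rtol=1e-10, atol=1e-12)
        dp1 = (r1.stations["b"].p_pa - r1.stations["a"].p_pa).max()
        dp2 = (r2.stations["b"].p_pa - r2.stations["a"].p_pa).max()
        assert dp1 / 100.0 == pytest.approx(dp2 / 200.0, rel=1e-9)

    def test_periodicity_reached_by_second_cycle(self, womersley_run):
        assert womersley_run["result"].periodicity_residual <= 0.01

    def test_unaligned_waveform_rejected(self):
        mesh = make_geometry(GEOMETRY_PRESETS["CHANNEL_VERIF"])
        wave = SplineWaveform(lambda t: -np.sin(np.asarray(t)), 2 * np.pi)
        cfg = SolverConfig(dt_s=1e-2, cycles=1)
        with pytest.raises(ValueError, match="origin-aligned"):
            run_cycles(mesh, {"cervical": wave}, cfg, PROPS)


class TestFluidProperties:
    def test_viscosity_consistency(self):
        p = FluidProperties()
        assert p.kinematic_viscosity_m2s == pytest.approx(7.0e-7)
        assert p.nu_mm2s == pytest.approx(0.7)

    def test_invalid_properties_rejected(self):
        with pytest.raises(ValueError):
            FluidProperties(density_kg_m3=-1.0)
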