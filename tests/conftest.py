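"""Shared fixtures: analytic benchmark runs and the shipped mesh pair.

The expensive solver runs (oscillatory channel, steady channel, stenosed
annulus at two resolutions, subject presets) are session-scoped so that the
verification, hydrodynamics and acceptance tests all reuse them.
"""
import numpy as np
import pytest

from csfflow.flow_solver import (
    FlowState,
    FluidProperties,
    Solver,
    SolverConfig,
    build_inflow_profile,
    run_cycles,
)
from csfflow.synthetic_data import (
    GEOMETRY_PRESETS,
    GeometryPreset,
    make_geometry,
    preset_series,
)
from csfflow.waveform_io import SplineWaveform, align_cycle_origin, fit_periodic_spline

STATIONS = {"CS": 35.0, "PC": 110.0, "Aq": 128.0}
PROPS = FluidProperties()


def aligned_wave(name: str) -> SplineWaveform:
    return align_cycle_origin(fit_periodic_spline(preset_series(name)))


@pytest.fixture(scope="session")
def props():
    return PROPS


@pytest.fixture(scope="session")
def solver_cfg():
    return SolverConfig(dt_s=5.0e-4, cycles=3, stations_mm=dict(STATIONS))


@pytest.fixture(scope="session")
def con1_wave():
    return aligned_wave("CON1_CS")


@pytest.fixture(scope="session")
def channel_preset():
    return GeometryPreset(
        "plane_channel", length_mm=40.0, gap_mm=2.0, depth_mm=10.0,
        occlusion=0.0, axial_cell_mm=1.0, cross_cell_mm=2.0 / 32)


def run_steady_channel(preset: GeometryPreset, q_mm3s: float, n_steps: int = 600,
                       dt: float = 5.0e-3, convection: bool = True) -> FlowState:
    """Drive the channel with constant flux until steady (diffusive settling)."""
    mesh = make_geometry(preset)
    sol = Solver(mesh, PROPS, dt, convection=convection)
    lo, hi = mesh.boundary("cervical"), mesh.boundary("aqueduct")
    ubc_lo = np.zeros(mesh.ny)
    ubc_lo[lo.j] = build_inflow_profile(lo, q_mm3s, mesh)
    ubc_hi = np.zeros(mesh.ny)
    ubc_hi[hi.j] = build_inflow_profile(hi, q_mm3s, mesh)
    state = FlowState.zeros(mesh)
    for k in range(n_steps):
        state = sol.step(state, ubc_lo, ubc_hi, (k + 1) * dt)
    return mesh, state, sol


@pytest.fixture(scope="session")
def poiseuille(channel_preset):
    """Steady flux-driven plane channel: Q=300 mm^3/s, 32 cells across the gap."""
    q = 300.0
    mesh, state, sol = run_steady_channel(channel_preset, q)
    return {"mesh": mesh, "state": state, "solver": sol, "q": q,
            "preset": channel_preset}


@pytest.fixture(scope="session")
def womersley_run(channel_preset):
    """Three cycles of single-harmonic pulsatile channel flow."""
    T = 60.0 / 71.0
    omega = 2 * np.pi / T
    amp = 300.0
    wave = SplineWaveform(lambda t: -amp * np.sin(omega * np.asarray(t)), T,
                          origin_aligned=True)
    mesh = make_geometry(channel_preset)
    cfg = SolverConfig(dt_s=5.0e-4, cycles=3, stations_mm={"mid": 20.0})
    result = run_cycles(mesh, {"cervical": wave}, cfg, PROPS)
    return {"result": result, "mesh": mesh, "omega": omega, "amp": amp,
            "preset": channel_preset}


@pytest.fixture(scope="session")
def annulus_pair(con1_wave, solver_cfg):
    """The shipped coarse/fine stenosed-annulus runs with the Con1 waveform."""
    runs = {}
    for name in ("ANNULUS_COARSE", "ANNULUS_FINE"):
        mesh = make_geometry(GEOMETRY_PRESETS[name])
        runs[name] = run_cycles(mesh, {"cervical": con1_wave}, solver_cfg, PROPS)
    return runs


@pytest.fixture(scope="session")
def preset_runs(annulus_pair, solver_cfg):
    """Coarse-annulus runs for all three subject presets."""
    runs = {"CON1_CS": annulus_pair["ANNULUS_COARSE"]}
    for name in ("P1_CS", "P2_CS"):
        mesh = make_geometry(GEOMETRY_PRESETS["ANNULUS_COARSE"])
        runs[name] = run_cycles(mesh, {"cervical": aligned_wave(name)},
                                solver_cfg, PROPS)
    return runs
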