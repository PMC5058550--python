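"""Analytic oracles and mesh-independence metrics.

Two families of checks validate the flow solver:

* closed-form solutions — steady plane Poiseuille flow and the oscillatory
  (Womersley-type) planar channel solution — compared against solver runs
  in a space-time relative L2 norm;
* the between-mesh error metrics used in mesh-sensitivity studies: the
  maximum pointwise relative difference of |u| along sampling transects
  (with near-wall and vortex exclusion masks) and the signed percentage
  difference of the peak station-to-station pressure drop.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Dict, Optional, Tuple

import numpy as np

__all__ = [
    "LineSample",
    "ConvergenceReport",
    "sample_line",
    "velocity_line_error",
    "pressure_drop_error",
    "womersley_planar",
    "womersley_planar_flux_profile",
    "compare_run_to_analytic",
]


@dataclass
class LineSample:
    """|u| (and signed axial velocity) along a transverse sampling line."""

    positions_mm: np.ndarray
    speed_mms: np.ndarray
    axial_mms: Optional[np.ndarray] = None
    z_mm: Optional[float] = None

    def __post_init__(self) -> None:
        self.positions_mm = np.asarray(self.positions_mm, dtype=float)
        self.speed_mms = np.asarray(self.speed_mms, dtype=float)
        if self.speed_mms.shape != self.positions_mm.shape:
            raise ValueError("positions and speeds differ in shape")


@dataclass
class ConvergenceReport:
    """Between-mesh error metrics for one coarse/fine run pair."""

    e_u_percent: float
    e_dp_percent: float
    cells_coarse: int
    cells_fine: int
    excluded_points: int = 0
    total_points: int = 0
    lines_z_mm: Tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.e_u_percent < 0:
            raise ValueError("velocity error metric is a magnitude, must be >= 0")

    def to_dict(self) -> Dict:
        return asdict(self)


def sample_line(run, z_mm: float) -> LineSample:
    """Sample |u| (peak-systole snapshot) along the transect nearest z_mm."""
    mesh = run.mesh
    if run.snapshot_speed is None:
        raise ValueError("run has no snapshot to sample")
    i = int(np.clip(int(z_mm / mesh.dz), 0, mesh.nz - 1))
    speed = run.snapshot_speed[i].copy()
    from .flow_solver import cell_axial_velocity  # lazy: avoid import cycle

    axial = cell_axial_velocity(run.snapshot, mesh)[i].copy()
    return LineSample(
        positions_mm=mesh.y_centers.copy(),
        speed_mms=speed,
        axial_mms=axial,
        z_mm=mesh.z_centers[i],
    )


def _interp_to(sample: LineSample, positions: np.ndarray) -> LineSample:
    return LineSample(
        positions_mm=positions,
        speed_mms=np.interp(positions, sample.positions_mm, sample.speed_mms),
        axial_mms=None if sample.axial_mms is None else
        np.interp(positions, sample.positions_mm, sample.axial_mms),
        z_mm=sample.z_mm,
    )


def velocity_line_error(
    coarse: LineSample,
    fine: LineSample,
    noise_floor_frac: float = 0.01,
    exclude_vortex: bool = True,
) -> Tuple[float, np.ndarray]:
    """Maximum percentage |u| discrepancy between two meshes along a line.

    The fine field is interpolated to the coarse positions.  Points where
    the fine speed is below ``noise_floor_frac`` of the line's peak are
    excluded (near-wall caveat), as are points adjacent to a sign change of
    the axial velocity (vortex regions), when axial data is available.

    Returns (error percent, inclusion mask over coarse positions).
    """
    f = _interp_to(fine, coarse.positions_mm)
    floor = noise_floor_frac * float(np.max(f.speed_mms))
    include = f.speed_mms > floor
    include &= coarse.speed_mms > 0  # solid cells carry zero speed
    if exclude_vortex and f.axial_mms is not None and coarse.axial_mms is not None:
        for ax in (f.axial_mms, coarse.axial_mms):
            flips = np.flatnonzero(np.sign(ax[:-1]) * np.sign(ax[1:]) < 0)
            for k in flips:
                include[max(0, k - 1): k + 3] = False
    if not np.any(include):
        raise ValueError("all line points excluded by the masks")
    rel = np.abs(coarse.speed_mms[include] - f.speed_mms[include]) / \
        np.abs(f.speed_mms[include])
    return 100.0 * float(np.max(rel)), include


def pressure_drop_error(coarse_dp_max_pa: float, fine_dp_max_pa: float) -> float:
    """Signed percentage difference of the peak pressure drop between meshes."""
    if fine_dp_max_pa == 0:
        raise ValueError("fine-mesh peak pressure drop is zero")
    return 100.0 * (coarse_dp_max_pa - fine_dp_max_pa) / fine_dp_max_pa


# ---------------------------------------------------------------------------
# Oscillatory channel oracle
# ---------------------------------------------------------------------------

def _womersley_shape(y_mm: np.ndarray, gap_mm: float, nu_mm2s: float,
                     omega_rad_s: float) -> np.ndarray:
    """Complex profile shape 1 - cosh(k y')/cosh(k h/2), y' from mid-gap."""
    c = gap_mm / 2.0
    k = np.sqrt(1j * omega_rad_s / nu_mm2s)
    yp = np.asarray(y_mm, dtype=float) - c
    return 1.0 - np.cosh(k * yp) / np.cosh(k * c)


def womersley_planar(
    gap_mm: float,
    nu_m2s: float,
    omega_rad_s: float,
    grad_amplitude_pa_m: float,
    y_mm,
    t_s,
    rho_kg_m3: float = 1000.0,
) -> np.ndarray:
    """Oscillatory plane-channel velocity for -dp/dz = G cos(omega t).

    Closed form  u(y, t) = Re[ (G / (i rho omega)) (1 - cosh(k y')/cosh(k c))
    e^{i omega t} ]  with  k = sqrt(i omega / nu), walls at y = 0 and
    y = gap.  Reduces to steady Poiseuille flow as omega -> 0.  Returns mm/s.
    """
    if min(gap_mm, nu_m2s, omega_rad_s) <= 0:
        raise ValueError("gap, viscosity and frequency must be positive")
    nu_mm = nu_m2s * 1e6
    # G in Pa/m = 1e-3 Pa/mm = 1e-3 g/(mm^2 s^2); u in mm/s with rho g/mm^3
    G_mm = grad_amplitude_pa_m * 1e-3
    rho_mm = rho_kg_m3 * 1e-6
    shape = _womersley_shape(np.asarray(y_mm), gap_mm, nu_mm, omega_rad_s)
    amp = G_mm / (1j * rho_mm * omega_rad_s)
    t = np.asarray(t_s, dtype=float)
    u = np.real(np.multiply.outer(np.exp(1j * omega_rad_s * t), amp * shape))
    return np.squeeze(u)


def womersley_planar_flux_profile(
    gap_mm: float,
    nu_mm2s: float,
    omega_rad_s: float,
    q_hat_mm2s: complex,
    y_mm,
    t_s,
) -> np.ndarray:
    """Oscillatory channel velocity for prescribed per-depth flux.

    ``q_hat_mm2s`` is the complex flux amplitude per unit depth:
    q(t) = Re[q_hat e^{i omega t}].  The profile is the Womersley shape
    normalized so its integral over the gap equals q(t) at every instant —
    the fully developed solution of a flux-driven channel.
    """
    c = gap_mm / 2.0
    k = np.sqrt(1j * omega_rad_s / nu_mm2s)
    shape = _womersley_shape(np.asarray(y_mm), gap_mm, nu_mm2s, omega_rad_s)
    integral = gap_mm - (2.0 / k) * np.tanh(k * c)
    u_hat = q_hat_mm2s * shape / integral
    t = np.asarray(t_s, dtype=float)
    u = np.real(np.multiply.outer(np.exp(1j * omega_rad_s * t), u_hat))
    return np.squeeze(u)


def compare_run_to_analytic(
    times_s: np.ndarray,
    u_numeric: np.ndarray,
    u_analytic: np.ndarray,
    weights: Optional[np.ndarray] = None,
) -> float:
    """Space-time relative L2 error over the final cycle.

    ``u_numeric`` and ``u_analytic`` are (n_times, n_points) arrays on the
    same grid; ``weights`` optionally weight the spatial points (e.g. by
    cell size).
    """
    un = np.asarray(u_numeric, dtype=float)
    ua = np.asarray(u_analytic, dtype=float)
    if un.shape != ua.shape:
        raise ValueError("numeric and analytic fields differ in shape")
    w = np.ones(un.shape[-1]) if weights is None else np.asarray(weights)
    num = np.sum(w * (un - ua) ** 2)
    den = np.sum(w * ua**2)
    if den == 0:
        return 0.0 if num == 0 else np.inf
    return float(np.sqrt(num / den))
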