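"""Incompressible Navier-Stokes solver for pulsatile CSF flow.

Solves

    du/dt + (u . grad) u = -(1/rho) grad p + nu laplace(u),   div u = 0

with an incremental pressure-correction (IPCS) fractional-step scheme on a
structured staggered (MAC) grid, in 2-D planar or axisymmetric (r, z)
coordinates.  Velocity Dirichlet conditions are prescribed on the entire
boundary: no-slip at walls and, at each inflow/outflow opening, the measured
volumetric flux Q(t) distributed over the opening by a wall-distance weight

    u_Gamma = Q(t) * tau(x) / int_Gamma tau dGamma * n

so that the discrete surface integral of u.n equals Q exactly.  Pressure
gets homogeneous Neumann conditions everywhere; the nullspace is pinned by
zero spatial mean.

Scheme per step (viscous terms implicit, convection explicit 2nd-order
central advanced with Adams-Bashforth 2):

1. tentative velocity:  (u* - u^n)/dt + conv(u^n, u^{n-1}) =
                          -grad p^n / rho + nu laplace(u*)
2. pressure increment:  laplace(phi) = div(u*) / dt,  dphi/dn = 0
3. projection:          u^{n+1} = u* - dt grad(phi),  p^{n+1} = p^n + phi

Internal units are mm-g-s, an SI-consistent system in which pressures are
exactly pascal (1 g/(mm s^2) = 1 Pa), velocities mm/s and fluxes mm^3/s.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .hydrodynamics import ProbeTrace

__all__ = [
    "FluidProperties",
    "Boundary",
    "Mesh",
    "SolverConfig",
    "FlowState",
    "Solver",
    "RunResult",
    "build_inflow_profile",
    "mass_balance_split",
    "ipcs_step",
    "run_cycles",
    "kinetic_energy",
    "write_vtk_snapshot",
]


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid constants.  CSF is water-like at body temperature."""

    density_kg_m3: float = 1000.0
    viscosity_pa_s: float = 7.0e-4

    def __post_init__(self) -> None:
        if self.density_kg_m3 <= 0 or self.viscosity_pa_s <= 0:
            raise ValueError("density and viscosity must be positive")

    @property
    def kinematic_viscosity_m2s(self) -> float:
        return self.viscosity_pa_s / self.density_kg_m3

    @property
    def nu_mm2s(self) -> float:
        """Kinematic viscosity in mm^2/s (solver units)."""
        return self.kinematic_viscosity_m2s * 1e6

    @property
    def rho_g_mm3(self) -> float:
        """Density in g/mm^3 (solver units)."""
        return self.density_kg_m3 * 1e-6


@dataclass
class Boundary:
    """A tagged open boundary segment on one axial end of the domain.

    ``side`` is "lo" (z=0 plane) or "hi" (z=L plane); ``j`` are the open
    transverse face indices; ``tau`` the wall-distance weight at those faces
    (zero at wall junctions by construction of the face-centre sampling);
    ``face_area`` the discrete face areas, which include the 2*pi*r metric
    in axisymmetric meshes.
    """

    tag: str
    side: str
    j: np.ndarray
    tau: np.ndarray
    face_area: np.ndarray

    @property
    def area_mm2(self) -> float:
        return float(np.sum(self.face_area))

    @property
    def tau_norm(self) -> float:
        return float(np.sum(self.tau * self.face_area))


@dataclass
class Mesh:
    """Structured staggered grid with tagged boundaries.

    Axial direction z (index i), transverse direction y (index j); for the
    axisymmetric kind y is the radius r and r=0 never occurs (annulus).
    ``solid`` marks stair-step wall cells of the stenosis bump.
    """

    kind: str  # "planar" | "axisymmetric"
    nz: int
    ny: int
    dz: float
    dy: float
    y0: float  # inner radius (axisymmetric) or 0 (planar)
    depth_mm: float  # out-of-plane depth (planar only; 1 for axisym)
    solid: np.ndarray
    boundaries: List[Boundary] = field(default_factory=list)
    length_mm: float = 0.0
    gap_mm: float = 0.0
    occlusion: float = 0.0
    stenosis_center_mm: Optional[float] = None
    stenosis_extent_mm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("planar", "axisymmetric"):
            raise ValueError(f"unknown mesh kind {self.kind!r}")
        if self.kind == "axisymmetric" and self.y0 <= 0:
            raise ValueError("axisymmetric mesh must have positive inner radius")
        self.solid = np.asarray(self.solid, dtype=bool)
        if self.solid.shape != (self.nz, self.ny):
            raise ValueError("solid mask shape mismatch")

    # -- coordinates -------------------------------------------------------
    @property
    def z_faces(self) -> np.ndarray:
        return np.arange(self.nz + 1) * self.dz

    @property
    def z_centers(self) -> np.ndarray:
        return (np.arange(self.nz) + 0.5) * self.dz

    @property
    def y_faces(self) -> np.ndarray:
        return self.y0 + np.arange(self.ny + 1) * self.dy

    @property
    def y_centers(self) -> np.ndarray:
        return self.y0 + (np.arange(self.ny) + 0.5) * self.dy

    @property
    def fluid(self) -> np.ndarray:
        return ~self.solid

    # -- metric factors ----------------------------------------------------
    def u_face_areas(self) -> np.ndarray:
        """Area of axial (z-normal) faces, per transverse index j."""
        if self.kind == "axisymmetric":
            return 2.0 * np.pi * self.y_centers * self.dy
        return np.full(self.ny, self.dy * self.depth_mm)

    def v_face_areas(self) -> np.ndarray:
        """Area of transverse (y-normal) faces, per face index j=0..ny."""
        if self.kind == "axisymmetric":
            return 2.0 * np.pi * self.y_faces * self.dz
        return np.full(self.ny + 1, self.dz * self.depth_mm)

    def cell_volumes(self) -> np.ndarray:
        if self.kind == "axisymmetric":
            return 2.0 * np.pi * self.y_centers * self.dz * self.dy
        return np.full(self.ny, self.dz * self.dy * self.depth_mm)

    @property
    def min_gap_mm(self) -> float:
        counts = np.sum(self.fluid, axis=1)
        return float(np.min(counts)) * self.dy

    def boundary(self, tag: str) -> Boundary:
        for b in self.boundaries:
            if b.tag == tag:
                return b
        raise KeyError(f"no boundary tagged {tag!r}")

    def boundary_area_mm2(self, tag: str) -> float:
        return self.boundary(tag).area_mm2


@dataclass
class SolverConfig:
    """Time-stepping and probing controls.

    The default time step 1e-4 s over three cardiac cycles follows the study
    conditions ("reference mode"); coarser test-mode steps are set per run.
    """

    dt_s: float = 1.0e-4
    cycles: int = 3
    convection: bool = True
    div_tol_per_s: float = 1.0e-6
    cfl_limit: float = 0.5
    periodicity_tol: float = 0.01
    stations_mm: Dict[str, float] = field(default_factory=dict)
    record_slices: bool = True
    scheme: str = "incremental"  # standard incremental pressure correction

    def __post_init__(self) -> None:
        if self.dt_s <= 0:
            raise ValueError("time step must be positive")
        if self.cycles < 1:
            raise ValueError("need at least one cycle")


@dataclass
class FlowState:
    """Velocity (staggered faces, mm/s) and pressure (cell centres, Pa)."""

    u: np.ndarray  # (nz+1, ny) axial
    v: np.ndarray  # (nz, ny+1) transverse
    p: np.ndarray  # (nz, ny)
    t: float = 0.0

    @classmethod
    def zeros(cls, mesh: Mesh, t: float = 0.0) -> "FlowState":
        return cls(
            u=np.zeros((mesh.nz + 1, mesh.ny)),
            v=np.zeros((mesh.nz, mesh.ny + 1)),
            p=np.zeros((mesh.nz, mesh.ny)),
            t=t,
        )

    def copy(self) -> "FlowState":
        return FlowState(self.u.copy(), self.v.copy(), self.p.copy(), self.t)


# ---------------------------------------------------------------------------
# Boundary profiles and mass balance
# ---------------------------------------------------------------------------

def build_inflow_profile(boundary: Boundary, q_mm3s: float, mesh: Mesh) -> np.ndarray:
    """Distribute a volumetric flux over an opening by the wall-distance weight.

    Returns the axial velocity at the opening's faces,
    ``u = Q tau / sum(tau * area)``, so that the discrete surface integral
    of u.n over the boundary equals Q to round-off.  The profile vanishes at
    wall junctions because tau does.
    """
    norm = boundary.tau_norm
    if norm <= 0:
        raise ValueError(f"degenerate boundary {boundary.tag!r}: integral of tau is zero")
    return q_mm3s * boundary.tau / norm


def mass_balance_split(
    q_cs_mm3s: float, q_aq_mm3s: float, unmeasured_areas_mm2: Sequence[float]
) -> List[float]:
    """Split the unmeasured flux over openings proportionally to their areas.

    The flux through the aqueduct is subtracted from the flux at the foramen
    magnum (cervical) level and the remainder is divided between the
    unmeasured openings scaled by their areas, so that at every instant
    ``sum(returned) + Q_Aq = Q_CS`` (rigid walls, incompressible fluid).
    """
    areas = np.asarray(list(unmeasured_areas_mm2), dtype=float)
    remainder = q_cs_mm3s - q_aq_mm3s
    if areas.size == 0:
        if not math.isclose(remainder, 0.0, abs_tol=1e-12):
            raise ValueError("mass not conservable: no unmeasured inlet to absorb flux")
        return []
    if np.any(areas <= 0):
        raise ValueError("unmeasured inlet areas must be positive")
    return list(remainder * areas / areas.sum())


# ---------------------------------------------------------------------------
# Solver
# ---------------------------------------------------------------------------

class Solver:
    """IPCS stepper with operators assembled and factorized once per run."""

    def __init__(self, mesh: Mesh, props: FluidProperties, dt: float,
                 convection: bool = True):
        self.mesh = mesh
        self.props = props
        self.dt = float(dt)
        self.convection = bool(convection)
        nz, ny = mesh.nz, mesh.ny
        fluid = mesh.fluid
        nu = props.nu_mm2s
        dz, dy = mesh.dz, mesh.dy

        axi = mesh.kind == "axisymmetric"
        Rc = mesh.y_centers if axi else np.ones(ny)
        Rf = mesh.y_faces if axi else np.ones(ny + 1)
        self._Rc, self._Rf = Rc, Rf

        # --- active face/cell maps ---
        act_u = np.zeros((nz + 1, ny), dtype=bool)
        act_u[1:nz, :] = fluid[:-1, :] & fluid[1:, :]
        act_v = np.zeros((nz, ny + 1), dtype=bool)
        act_v[:, 1:ny] = fluid[:, :-1] & fluid[:, 1:]
        self.act_u, self.act_v = act_u, act_v
        uid = np.full((nz + 1, ny), -1, dtype=np.int64)
        uid[act_u] = np.arange(int(act_u.sum()))
        vid = np.full((nz, ny + 1), -1, dtype=np.int64)
        vid[act_v] = np.arange(int(act_v.sum()))
        pid = np.full((nz, ny), -1, dtype=np.int64)
        pid[fluid] = np.arange(int(fluid.sum()))
        self.uid, self.vid, self.pid = uid, vid, pid

        cz = nu / dz**2
        self._cz = cz

        # --- A_u ---
        iu, ju = np.nonzero(act_u)
        self._iu, self._ju = iu, ju
        cyp = nu * Rf[ju + 1] / (Rc[ju] * dy**2)
        cym = nu * Rf[ju] / (Rc[ju] * dy**2)
        rows, cols, vals = [], [], []
        diag = 1.0 / dt + 2.0 * cz + cyp + cym
        row_idx = uid[iu, ju]
        # z-neighbours: active -> couple; Dirichlet (end planes / solid) -> RHS
        for off in (-1, 1):
            nb = uid[iu + off, ju]
            m = nb >= 0
            rows.append(row_idx[m]); cols.append(nb[m]); vals.append(np.full(m.sum(), -cz))
        self._u_dir_lo = uid[iu - 1, ju] < 0  # Dirichlet z-neighbour below
        self._u_dir_hi = uid[iu + 1, ju] < 0
        # y-neighbours: active -> couple; wall/solid -> quadratic ghost.
        # The wall sits on the y-face; a quadratic through (0 at the wall,
        # u0, u1) gives u_ghost = -2 u0 + u1/3, second-order accurate and
        # exact for parabolic profiles.  With both neighbours walled the
        # linear reflection u_ghost = -u0 is used instead.
        def _nb(off):
            jn = ju + off
            inside = (jn >= 0) & (jn < ny)
            return np.where(inside, uid[iu, np.clip(jn, 0, ny - 1)], -1)

        nb_lo, nb_hi = _nb(-1), _nb(1)
        for nb_w, nb_o, cy in ((nb_lo, nb_hi, cym), (nb_hi, nb_lo, cyp)):
            m = nb_w >= 0
            rows.append(row_idx[m]); cols.append(nb_w[m]); vals.append(-cy[m])
            quad = (~m) & (nb_o >= 0)
            refl = (~m) & (nb_o < 0)
            diag = diag + np.where(quad, 2.0 * cy, 0.0) + np.where(refl, cy, 0.0)
            rows.append(row_idx[quad]); cols.append(nb_o[quad])
            vals.append(-cy[quad] / 3.0)
        rows.append(row_idx); cols.append(row_idx); vals.append(diag)
        n_u = row_idx.size
        A_u = sp.csc_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n_u, n_u),
        )
        self._lu_u = splu(A_u)

        # --- A_v ---
        iv, jv = np.nonzero(act_v)
        self._iv, self._jv = iv, jv
        cyp_v = nu * Rc[np.clip(jv, 0, ny - 1)] / (Rf[jv] * dy**2)
        cym_v = nu * Rc[jv - 1] / (Rf[jv] * dy**2)
        diag_v = 1.0 / dt + 2.0 * cz + cyp_v + cym_v
        if axi:
            diag_v = diag_v + nu / Rf[jv] ** 2
        rows, cols, vals = [], [], []
        row_idx_v = vid[iv, jv]
        for off in (-1, 1):
            inz = iv + off
            inside = (inz >= 0) & (inz < nz)
            nb = np.where(inside, vid[np.clip(inz, 0, nz - 1), jv], -1)
            m = nb >= 0
            rows.append(row_idx_v[m]); cols.append(nb[m]); vals.append(np.full(m.sum(), -cz))
            # outside the domain: tangential no-slip at the end plane -> reflection
            refl = ~inside
            diag_v = diag_v + np.where(refl, cz, 0.0)
            # inside but solid: stair wall normal to z, value 0 -> nothing
        for off, cy in ((-1, cym_v), (1, cyp_v)):
            nb = vid[iv, jv + off]  # jv in 1..ny-1 so jv+off in 0..ny: valid
            m = nb >= 0
            rows.append(row_idx_v[m]); cols.append(nb[m]); vals.append(-cy[m])
            # inactive neighbour sits on a wall face with v=0: no contribution
        rows.append(row_idx_v); cols.append(row_idx_v); vals.append(diag_v)
        n_v = row_idx_v.size
        A_v = sp.csc_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n_v, n_v),
        )
        self._lu_v = splu(A_v) if n_v else None

        # --- pressure Poisson ---
        Au = mesh.u_face_areas()
        Av = mesh.v_face_areas()
        vol = mesh.cell_volumes()
        self._Au, self._Av, self._vol = Au, Av, vol
        ic, jc = np.nonzero(fluid)
        row_p = pid[ic, jc]
        rows, cols, vals = [], [], []
        diag_p = np.zeros(row_p.size)
        Tz = Au / dz
        Ty = Av / dy
        for off in (-1, 1):
            inz = ic + off
            # coupled iff the shared u-face is active
            face_i = ic + (1 if off == 1 else 0)
            open_face = act_u[face_i, jc]
            nb = np.where(open_face, pid[np.clip(inz, 0, nz - 1), jc], -1)
            m = nb >= 0
            rows.append(row_p[m]); cols.append(nb[m]); vals.append(-Tz[jc[m]])
            diag_p = diag_p + np.where(m, Tz[jc], 0.0)
        for off in (-1, 1):
            jn = jc + off
            face_j = jc + (1 if off == 1 else 0)
            open_face = act_v[ic, face_j]
            nb = np.where(open_face, pid[ic, np.clip(jn, 0, ny - 1)], -1)
            m = nb >= 0
            rows.append(row_p[m]); cols.append(nb[m]); vals.append(-Ty[face_j[m]])
            diag_p = diag_p + np.where(m, Ty[face_j], 0.0)
        rows.append(row_p); cols.append(row_p); vals.append(diag_p)
        n_p = row_p.size
        A_p = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n_p, n_p),
        ).tocsr()
        # pin the nullspace: first fluid cell held at zero increment
        A_p = A_p.tolil()
        A_p.rows[0] = [0]
        A_p.data[0] = [1.0]
        self._lu_p = splu(A_p.tocsc())
        self._ic, self._jc, self._row_p = ic, jc, row_p

        self._conv_prev: Optional[Tuple[np.ndarray, np.ndarray]] = None
        self.last_div_max = 0.0
        self.last_cfl = 0.0

    # -- pieces -----------------------------------------------------------
    def _convection_terms(self, U: np.ndarray, V: np.ndarray):
        """Central-difference advective-form convection on active faces."""
        mesh = self.mesh
        nz, ny, dz, dy = mesh.nz, mesh.ny, mesh.dz, mesh.dy
        iu, ju = self._iu, self._ju
        iv, jv = self._iv, self._jv

        Upad = np.empty((nz + 1, ny + 2))
        Upad[:, 1:-1] = U
        Upad[:, 0] = -U[:, 0]      # wall ghost (no-slip at y-face)
        Upad[:, -1] = -U[:, -1]
        dudz = (U[iu + 1, ju] - U[iu - 1, ju]) / (2 * dz)
        dudy = (Upad[iu, ju + 2] - Upad[iu, ju]) / (2 * dy)
        vbar = 0.25 * (V[iu - 1, ju] + V[iu - 1, ju + 1] + V[iu, ju] + V[iu, ju + 1])
        conv_u = U[iu, ju] * dudz + vbar * dudy

        Vpad = np.empty((nz + 2, ny + 1))
        Vpad[1:-1, :] = V
        Vpad[0, :] = -V[0, :]      # tangential no-slip ghost at end planes
        Vpad[-1, :] = -V[-1, :]
        dvdz = (Vpad[iv + 2, jv] - Vpad[iv, jv]) / (2 * dz)
        dvdy = (V[iv, jv + 1] - V[iv, jv - 1]) / (2 * dy)
        ubar = 0.25 * (U[iv, jv - 1] + U[iv, jv] + U[iv + 1, jv - 1] + U[iv + 1, jv])
        conv_v = ubar * dvdz + V[iv, jv] * dvdy
        return conv_u, conv_v

    def _divergence_int(self, U: np.ndarray, V: np.ndarray) -> np.ndarray:
        """Net outflux integral per fluid cell, mm^3/s."""
        ic, jc = self._ic, self._jc
        Au, Av = self._Au, self._Av
        return (
            (U[ic + 1, jc] - U[ic, jc]) * Au[jc]
            + V[ic, jc + 1] * Av[jc + 1]
            - V[ic, jc] * Av[jc]
        )

    def step(self, state: FlowState, ubc_lo: np.ndarray, ubc_hi: np.ndarray,
             t_new: float) -> FlowState:
        """Advance one time step; boundary profiles are at the new time level."""
        mesh, dt = self.mesh, self.dt
        nz, ny, dz, dy = mesh.nz, mesh.ny, mesh.dz, mesh.dy
        iu, ju = self._iu, self._ju
        iv, jv = self._iv, self._jv
        U, V, p = state.u, state.v, state.p

        if self.convection:
            conv_u, conv_v = self._convection_terms(U, V)
            if self._conv_prev is None:
                cu_eff, cv_eff = conv_u, conv_v
            else:
                cu_p, cv_p = self._conv_prev
                cu_eff = 1.5 * conv_u - 0.5 * cu_p
                cv_eff = 1.5 * conv_v - 0.5 * cv_p
            self._conv_prev = (conv_u, conv_v)
        else:
            cu_eff = cv_eff = 0.0

        rho = self.props.rho_g_mm3
        # tentative velocity
        rhs_u = U[iu, ju] / dt - cu_eff - (p[iu, ju] - p[iu - 1, ju]) / (rho * dz)
        cz = self._cz
        rhs_u = rhs_u + cz * np.where(self._u_dir_lo & (iu == 1), ubc_lo[ju], 0.0)
        rhs_u = rhs_u + cz * np.where(self._u_dir_hi & (iu == nz - 1), ubc_hi[ju], 0.0)
        U_star = np.zeros_like(U)
        U_star[0, :] = ubc_lo
        U_star[nz, :] = ubc_hi
        U_star[self.act_u] = self._lu_u.solve(rhs_u)

        V_star = np.zeros_like(V)
        if self._lu_v is not None and iv.size:
            rhs_v = V[iv, jv] / dt - cv_eff - (p[iv, jv] - p[iv, jv - 1]) / (rho * dy)
            V_star[self.act_v] = self._lu_v.solve(rhs_v)

        # pressure increment (kinematic phi' = phi/rho folded in: solve for phi)
        b = -self._divergence_int(U_star, V_star) / dt
        b[0] = 0.0  # pinned cell
        phi = self._lu_p.solve(b)
        if not np.all(np.isfinite(phi)):
            raise RuntimeError("pressure Poisson solve failed: non-finite increment")

        phi_f = np.zeros((nz, ny))
        phi_f[mesh.fluid] = phi
        U_new = U_star.copy()
        V_new = V_star.copy()
        U_new[self.act_u] -= dt * (phi_f[iu, ju] - phi_f[iu - 1, ju]) / dz
        if iv.size:
            V_new[self.act_v] -= dt * (phi_f[iv, jv] - phi_f[iv, jv - 1]) / dy

        p_new = p.copy()
        p_new[mesh.fluid] += rho * phi_f[mesh.fluid]
        vol = self._vol[self._jc]
        mean_p = np.sum(p_new[mesh.fluid] * vol) / np.sum(vol)
        p_new[mesh.fluid] -= mean_p

        # invariant checks
        div = self._divergence_int(U_new, V_new) / vol
        self.last_div_max = float(np.max(np.abs(div))) if div.size else 0.0
        cfl = (np.max(np.abs(U_new)) / dz + np.max(np.abs(V_new)) / dy) * dt
        self.last_cfl = float(cfl)

        return FlowState(U_new, V_new, p_new, t_new)


def ipcs_step(
    state: FlowState,
    boundary_values: Dict[str, np.ndarray],
    props: FluidProperties,
    dt: float,
    mesh: Mesh,
    solver: Optional[Solver] = None,
    convection: bool = True,
    cfl_limit: float = 0.5,
) -> Tuple[FlowState, Solver]:
    """One IPCS step from prescribed per-side boundary profiles.

    ``boundary_values`` maps "lo"/"hi" to full-length (ny,) axial-velocity
    rows at the new time level.  Returns the new state and the (reusable)
    solver, whose factorized operators make repeated stepping cheap.
    Raises if the advective CFL limit is exceeded.
    """
    if solver is None:
        solver = Solver(mesh, props, dt, convection=convection)
    ubc_lo = boundary_values.get("lo", np.zeros(mesh.ny))
    ubc_hi = boundary_values.get("hi", np.zeros(mesh.ny))
    new = solver.step(state, ubc_lo, ubc_hi, state.t + dt)
    if solver.last_cfl > cfl_limit:
        raise RuntimeError(
            f"CFL violation: {solver.last_cfl:.3f} > {cfl_limit}; reduce the time step"
        )
    return new, solver


def kinetic_energy(state: FlowState, mesh: Mesh, props: FluidProperties) -> float:
    """Total kinetic energy (g mm^2/s^2) from cell-centred speeds."""
    uc = 0.5 * (state.u[:-1, :] + state.u[1:, :])
    vc = 0.5 * (state.v[:, :-1] + state.v[:, 1:])
    vol = np.broadcast_to(mesh.cell_volumes(), (mesh.nz, mesh.ny))
    ke = 0.5 * props.rho_g_mm3 * (uc**2 + vc**2) * vol
    return float(np.sum(ke[mesh.fluid]))


def cell_speed(state: FlowState, mesh: Mesh) -> np.ndarray:
    """|u| at cell centres (mm/s); zero in solid cells."""
    uc = 0.5 * (state.u[:-1, :] + state.u[1:, :])
    vc = 0.5 * (state.v[:, :-1] + state.v[:, 1:])
    speed = np.hypot(uc, vc)
    speed[mesh.solid] = 0.0
    return speed


def cell_axial_velocity(state: FlowState, mesh: Mesh) -> np.ndarray:
    uc = 0.5 * (state.u[:-1, :] + state.u[1:, :])
    uc[mesh.solid] = 0.0
    return uc


# ---------------------------------------------------------------------------
# Cycle driver
# ---------------------------------------------------------------------------

@dataclass
class RunResult:
    """Probe traces and diagnostics of a multi-cycle pulsatile run."""

    times_s: np.ndarray
    dt_s: float
    period_s: float
    cycles: int
    stations: Dict[str, ProbeTrace]
    region_umax: Dict[str, np.ndarray]
    domain_umax: np.ndarray
    mass_residual_rel: float
    periodicity_residual: float
    mesh: Mesh
    div_max_per_s: float = 0.0
    cfl_max: float = 0.0
    snapshot: Optional[FlowState] = None
    snapshot_speed: Optional[np.ndarray] = None
    snapshot_time_s: Optional[float] = None
    boundary_fluxes: Optional[Dict[str, np.ndarray]] = None
    log: List[str] = field(default_factory=list)

    @property
    def steps_per_cycle(self) -> int:
        return int(round(self.period_s / self.dt_s))

    @property
    def final_cycle(self) -> slice:
        n = self.steps_per_cycle
        return slice(self.times_s.size - n, self.times_s.size)

    def final_traces(self) -> Dict[str, ProbeTrace]:
        """Station traces trimmed to the final cycle, times reset to [0, T)."""
        sl = self.final_cycle
        out = {}
        for label, tr in self.stations.items():
            out[label] = ProbeTrace(
                label=label,
                z_mm=tr.z_mm,
                times_s=self.times_s[sl] - self.times_s[sl][0] + self.dt_s,
                p_pa=tr.p_pa[sl],
                q_mm3s=tr.q_mm3s[sl],
                umax_mms=tr.umax_mms[sl],
                u_profile=None if tr.u_profile is None else tr.u_profile[sl],
                y_mm=tr.y_mm,
            )
        return out


def _relative_l2(a: np.ndarray, b: np.ndarray) -> float:
    denom = np.linalg.norm(b)
    if denom == 0:
        return 0.0 if np.linalg.norm(a - b) == 0 else np.inf
    return float(np.linalg.norm(a - b) / denom)


def run_cycles(
    mesh: Mesh,
    waveforms: Dict[str, "SplineWaveform"],
    config: SolverConfig,
    props: FluidProperties = FluidProperties(),
    snapshot_time_s: Optional[float] = None,
    initial_state: Optional[FlowState] = None,
) -> RunResult:
    """Run ``config.cycles`` cardiac cycles from zero initial velocity.

    ``waveforms`` maps boundary tags to origin-aligned periodic flux
    waveforms; the cervical boundary must be assigned.  Boundaries with no
    waveform receive the mass-conservation remainder split by area.  Records
    slice-averaged pressure, slice flux and peak speeds at every step, and a
    periodicity residual comparing the final two cycles.
    """
    from .waveform_io import SplineWaveform, systolic_peak_time  # local: avoid cycle

    tags = {b.tag for b in mesh.boundaries}
    unknown = set(waveforms) - tags
    if unknown:
        raise ValueError(f"waveforms assigned to unknown boundaries: {sorted(unknown)}")
    if "cervical" not in waveforms:
        raise ValueError("the cervical boundary must be assigned a waveform")
    periods = {t: w.period_s for t, w in waveforms.items()}
    T = periods["cervical"]
    for tag, Tw in periods.items():
        if abs(Tw - T) > 1e-9 * T:
            raise ValueError("boundary waveforms have unequal periods")
    for tag, w in waveforms.items():
        if not w.origin_aligned:
            raise ValueError(f"waveform for {tag!r} is not origin-aligned")

    n_per = max(1, int(round(T / config.dt_s)))
    dt = T / n_per
    total = n_per * config.cycles
    times = dt * np.arange(1, total + 1)

    measured = {tag: np.asarray(waveforms[tag](times)) for tag in waveforms}
    free = [b for b in mesh.boundaries if b.tag not in waveforms]
    q_by_tag: Dict[str, np.ndarray] = dict(measured)
    if free:
        q_cs = measured["cervical"]
        q_aq = np.zeros_like(q_cs)
        for tag, q in measured.items():
            if tag != "cervical":
                q_aq = q_aq + q
        areas = [b.area_mm2 for b in free]
        remainder = q_cs - q_aq
        total_area = sum(areas)
        for b, a in zip(free, areas):
            q_by_tag[b.tag] = remainder * (a / total_area)
    else:
        # two-port domain: outflow carries the inflow flux
        lo_tags = [b.tag for b in mesh.boundaries if b.side == "lo"]
        hi_tags = [b.tag for b in mesh.boundaries if b.side == "hi"]
        for tag in hi_tags:
            if tag not in q_by_tag:
                q_by_tag[tag] = measured["cervical"]

    # mass closure check (rigid walls): flux in at lo == flux out at hi
    q_lo = sum(q_by_tag[b.tag] for b in mesh.boundaries if b.side == "lo")
    q_hi = sum(q_by_tag[b.tag] for b in mesh.boundaries if b.side == "hi")
    peak_q = max(float(np.max(np.abs(q_by_tag["cervical"]))), 1e-300)
    mass_residual = float(np.max(np.abs(np.asarray(q_lo) - np.asarray(q_hi)))) / peak_q
    if mass_residual > 1e-10:
        raise ValueError("boundary fluxes do not balance: domain is rigid and "
                         "incompressible")

    solver = Solver(mesh, props, dt, convection=config.convection)
    state = initial_state.copy() if initial_state is not None else FlowState.zeros(mesh)

    stations = config.stations_mm or {}
    st_face = {lab: int(np.clip(round(z / mesh.dz), 1, mesh.nz - 1))
               for lab, z in stations.items()}
    st_col = {lab: int(np.clip(int(z / mesh.dz), 0, mesh.nz - 1))
              for lab, z in stations.items()}
    vol = mesh.cell_volumes()
    Au = mesh.u_face_areas()
    fluid = mesh.fluid

    rec_p = {lab: np.zeros(total) for lab in stations}
    rec_q = {lab: np.zeros(total) for lab in stations}
    rec_um = {lab: np.zeros(total) for lab in stations}
    rec_prof = {lab: np.zeros((total, mesh.ny)) for lab in stations} \
        if config.record_slices else {}
    domain_umax = np.zeros(total)

    regions: Dict[str, np.ndarray] = {}
    zc = mesh.z_centers
    if "CS" in stations:
        regions["CS"] = np.abs(zc - stations["CS"]) <= 10.0
    if "Aq" in stations:
        regions["Aq"] = zc >= (mesh.length_mm - 10.0)
    if mesh.occlusion > 0 and mesh.stenosis_center_mm is not None:
        regions["FM"] = np.abs(zc - mesh.stenosis_center_mm) <= mesh.gap_mm
    region_masks = {lab: np.broadcast_to(m[:, None], (mesh.nz, mesh.ny)) & fluid
                    for lab, m in regions.items()}
    rec_region = {lab: np.zeros(total) for lab in region_masks}

    if snapshot_time_s is None:
        tp = systolic_peak_time(waveforms["cervical"])
        snapshot_time_s = (config.cycles - 1) * T + tp
    snap_k = int(np.clip(round(snapshot_time_s / dt) - 1, 0, total - 1))
    snapshot = None
    snapshot_speed = None
    snap_t = None
    cfl_max = 0.0
    div_max = 0.0
    log: List[str] = [f"steps/cycle={n_per} dt={dt:.6g}s cycles={config.cycles}"]

    profiles_lo = {}
    profiles_hi = {}
    for b in mesh.boundaries:
        tau_w = build_inflow_profile(b, 1.0, mesh)  # per unit flux
        (profiles_lo if b.side == "lo" else profiles_hi)[b.tag] = (b.j, tau_w)

    for k in range(total):
        t_new = times[k]
        ubc_lo = np.zeros(mesh.ny)
        ubc_hi = np.zeros(mesh.ny)
        for tag, (j, tau_w) in profiles_lo.items():
            ubc_lo[j] = q_by_tag[tag][k] * tau_w
        for tag, (j, tau_w) in profiles_hi.items():
            ubc_hi[j] = q_by_tag[tag][k] * tau_w
        state = solver.step(state, ubc_lo, ubc_hi, t_new)
        if solver.last_cfl > config.cfl_limit:
            raise RuntimeError(
                f"CFL violation at t={t_new:.4f}s: {solver.last_cfl:.3f} > "
                f"{config.cfl_limit}; reduce the time step")
        cfl_max = max(cfl_max, solver.last_cfl)
        div_max = max(div_max, solver.last_div_max)

        speed = cell_speed(state, mesh)
        domain_umax[k] = speed.max()
        for lab in stations:
            col = st_col[lab]
            w = vol * fluid[col]
            rec_p[lab][k] = np.sum(state.p[col] * w) / np.sum(w)
            iface = st_face[lab]
            rec_q[lab][k] = np.sum(state.u[iface] * Au * fluid[min(iface, mesh.nz - 1)])
            rec_um[lab][k] = speed[col].max()
            if config.record_slices:
                rec_prof[lab][k] = state.u[iface]
        for lab, m in region_masks.items():
            rec_region[lab][k] = speed[m].max() if m.any() else 0.0
        if k == snap_k:
            snapshot = state.copy()
            snapshot_speed = speed.copy()
            snap_t = t_new

    # periodicity: relative L2 difference of the last two cycles' traces
    resid = 0.0
    if config.cycles >= 2 and stations:
        s_last = slice(total - n_per, total)
        s_prev = slice(total - 2 * n_per, total - n_per)
        for lab in stations:
            for rec in (rec_p, rec_um):
                resid = max(resid, _relative_l2(rec[lab][s_prev], rec[lab][s_last]))
    log.append(f"max CFL={cfl_max:.4f} max divergence={div_max:.3e}/s "
               f"periodicity residual={resid:.3e}")
    if resid > config.periodicity_tol:
        log.append(f"WARNING: periodicity residual {resid:.3%} exceeds "
                   f"{config.periodicity_tol:.0%}")

    traces = {
        lab: ProbeTrace(
            label=lab,
            z_mm=stations[lab],
            times_s=times,
            p_pa=rec_p[lab],
            q_mm3s=rec_q[lab],
            umax_mms=rec_um[lab],
            u_profile=rec_prof.get(lab),
            y_mm=mesh.y_centers.copy(),
        )
        for lab in stations
    }
    return RunResult(
        times_s=times,
        dt_s=dt,
        period_s=T,
        cycles=config.cycles,
        stations=traces,
        region_umax=rec_region,
        domain_umax=domain_umax,
        mass_residual_rel=mass_residual,
        periodicity_residual=resid,
        mesh=mesh,
        div_max_per_s=div_max,
        cfl_max=cfl_max,
        snapshot=snapshot,
        snapshot_speed=snapshot_speed,
        snapshot_time_s=snap_t,
        boundary_fluxes=q_by_tag,
        log=log,
    )


# ---------------------------------------------------------------------------
# Visualization output (legacy ASCII VTK, cell data on the structured grid)
# ---------------------------------------------------------------------------

def write_vtk_snapshot(path, mesh: Mesh, fields: Dict[str, np.ndarray],
                       comment: str = "csfflow snapshot") -> None:
    """Write cell-centred scalar fields as a legacy-ASCII VTK structured grid."""
    nz, ny = mesh.nz, mesh.ny
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(comment[:255] + "\n")
        fh.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nz + 1} {ny + 1} 1\n")
        fh.write(f"ORIGIN 0 {mesh.y0} 0\n")
        fh.write(f"SPACING {mesh.dz} {mesh.dy} 1\n")
        fh.write(f"CELL_DATA {nz * ny}\n")
        for name, arr in fields.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (nz, ny):
                raise ValueError(f"field {name!r} must be cell-centred (nz, ny)")
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            # VTK structured order: x (axial) fastest
            np.savetxt(fh, arr.T.reshape(ny, nz), fmt="%.6g")
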