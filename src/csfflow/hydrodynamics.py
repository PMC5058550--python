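"""Craniospinal hydrodynamic measures from probe traces.

Given slice-averaged pressure and flux time series at the cervical
subarachnoid space (CS), pontine cistern (PC) and aqueduct (Aq) stations,
this module computes the measures used to compare subjects:

* pressure drops  dp_PC-CS = p_PC - p_CS  and  dp_Aq-PC = p_Aq - p_PC,
  their extrema, and the axial pressure gradient in Pa/cm;
* hydrodynamic resistances  R = dp_max / Q_max  in g/(mm^4 s)
  (numerically identical to Pa/(mm^3/s): 1 Pa = 1 g/(mm s^2));
* the phase difference  theta = (t_umax - t_dpmax) / T_caudal  between peak
  systolic velocity and peak differential pressure, normalized by the
  duration of caudal flow;
* peak systolic velocities per anatomical region, the fraction of the cycle
  with synchronous bidirectional flow in a slice, and across-subject
  max/min ratio tables.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "ProbeTrace",
    "HydroSummary",
    "pressure_drop_series",
    "pressure_gradient",
    "resistance",
    "phase_difference",
    "peak_velocity",
    "bidirectional_fraction",
    "subject_ratio_stats",
    "summarize_run",
]

#: unit identity Pa / (mm^3/s) -> g/(mm^4 s); fixed by dimensional analysis
PA_PER_MM3S_TO_G_MM4S = 1.0


@dataclass
class ProbeTrace:
    """Time series at one probe station over one aligned cycle (or a run).

    All series share the same time grid.  ``u_profile`` optionally carries
    the axial-velocity profile across the slice at every time step (used
    for bidirectional-flow detection).
    """

    label: str
    z_mm: float
    times_s: np.ndarray
    p_pa: np.ndarray
    q_mm3s: np.ndarray
    umax_mms: np.ndarray
    u_profile: Optional[np.ndarray] = None
    y_mm: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        n = np.asarray(self.times_s).size
        for name in ("p_pa", "q_mm3s", "umax_mms"):
            if np.asarray(getattr(self, name)).size != n:
                raise ValueError(f"{name} does not share the station time grid")


@dataclass
class HydroSummary:
    """Per-subject summary of peak velocities, pressure drops, resistances
    and phase difference (the per-run analogue of a results table row)."""

    subject: str
    umax_cs_mms: float
    umax_aq_mms: float
    umax_fm_mms: float
    dp_pc_cs_max_pa: float
    dp_pc_cs_min_pa: float
    dp_aq_pc_max_pa: float
    dp_aq_pc_min_pa: float
    dp_pc_cs_at_qmax_pa: float
    gradient_pa_cm: float
    r_pc_cs_sys: float
    r_pc_cs_dia: float
    r_aq_pc_sys: float
    r_aq_pc_dia: float
    theta: float

    def __post_init__(self) -> None:
        if self.dp_pc_cs_max_pa < self.dp_pc_cs_min_pa:
            raise ValueError("dp_PC-CS max < min")
        if self.dp_aq_pc_max_pa < self.dp_aq_pc_min_pa:
            raise ValueError("dp_Aq-PC max < min")

    #: report columns named after the results-table conventions
    _REPORT_COLUMNS = {
        "umax_cs_mms": ("|u|max_CS [mm/s]", 0),
        "umax_aq_mms": ("|u|max_Aq [mm/s]", 0),
        "umax_fm_mms": ("|u|max_FM [mm/s]", 0),
        "dp_pc_cs_max_pa": ("dp(PC-CS)max [Pa]", 1),
        "dp_pc_cs_min_pa": ("dp(PC-CS)min [Pa]", 1),
        "dp_aq_pc_max_pa": ("dp(Aq-PC)max [Pa]", 1),
        "dp_aq_pc_min_pa": ("dp(Aq-PC)min [Pa]", 1),
        "dp_pc_cs_at_qmax_pa": ("dp(PC-CS)tQmax [Pa]", 1),
        "gradient_pa_cm": ("grad(PC-CS) [Pa/cm]", 1),
        "r_pc_cs_sys": ("R(PC-CS)sys [g/(mm4 s)]", 3),
        "r_pc_cs_dia": ("R(PC-CS)dia [g/(mm4 s)]", 3),
        "r_aq_pc_sys": ("R(Aq-PC)sys [g/(mm4 s)]", 3),
        "r_aq_pc_dia": ("R(Aq-PC)dia [g/(mm4 s)]", 3),
        "theta": ("theta [-]", 2),
    }

    def to_report_row(self) -> Dict[str, float]:
        """Rounded report row: velocities to integers, pressures to 0.1 Pa,
        resistances to 3 decimals."""
        row: Dict[str, float] = {"subject": self.subject}
        for attr, (col, nd) in self._REPORT_COLUMNS.items():
            val = getattr(self, attr)
            row[col] = int(round(val)) if nd == 0 else round(val, nd)
        return row

    def to_dict(self) -> Dict[str, float]:
        return asdict(self)


# ---------------------------------------------------------------------------
# Elementary measures
# ---------------------------------------------------------------------------

def pressure_drop_series(trace_a: ProbeTrace, trace_b: ProbeTrace) -> np.ndarray:
    """Pointwise pressure drop p_B - p_A on the shared time grid.

    Call as ``pressure_drop_series(cs, pc)`` for dp_PC-CS = p_PC - p_CS and
    ``pressure_drop_series(pc, aq)`` for dp_Aq-PC = p_Aq - p_PC.
    """
    ta, tb = np.asarray(trace_a.times_s), np.asarray(trace_b.times_s)
    if ta.shape != tb.shape or not np.allclose(ta, tb, rtol=0, atol=1e-12):
        raise ValueError("probe traces are on mismatched time grids")
    return np.asarray(trace_b.p_pa) - np.asarray(trace_a.p_pa)


def pressure_gradient(dp_pa: float, z_upstream_mm: float, z_downstream_mm: float) -> float:
    """Pressure drop per axial distance, Pa/cm."""
    sep_cm = abs(z_upstream_mm - z_downstream_mm) / 10.0
    if sep_cm == 0:
        raise ValueError("stations coincide: zero separation")
    return dp_pa / sep_cm


def resistance(dp_max_pa: float, q_max_mm3s: float) -> float:
    """Hydrodynamic resistance dp_max / Q_max in g/(mm^4 s).

    1 Pa = 1 kg/(m s^2) = 1 g/(mm s^2), so Pa per (mm^3/s) is identically
    g/(mm^4 s) and the conversion factor is exactly one.  Magnitudes are
    used so that systolic (negative-flux) peaks give positive resistance.
    """
    if q_max_mm3s == 0:
        raise ValueError("zero peak flux: resistance undefined")
    return abs(dp_max_pa) / abs(q_max_mm3s) * PA_PER_MM3S_TO_G_MM4S


def phase_difference(
    times_s: np.ndarray,
    u_trace_mms: np.ndarray,
    dp_series_pa: np.ndarray,
    t_caudal_s: float,
    caudal_mask: Optional[np.ndarray] = None,
) -> float:
    """theta = (t of peak systolic velocity - t of peak dp) / T_caudal.

    ``u_trace_mms`` is the peak-speed series at the cervical station; the
    systolic peak is searched within the caudal phase when a mask is given
    (the trace starts at flow reversal, so the caudal phase leads the
    cycle).  The normalization T is the duration of caudal flow.
    """
    if t_caudal_s <= 0:
        raise ValueError("caudal duration must be positive")
    t = np.asarray(times_s)
    u = np.asarray(u_trace_mms)
    dp = np.asarray(dp_series_pa)
    if caudal_mask is None:
        caudal_mask = t - t[0] <= t_caudal_s
    if not np.any(caudal_mask):
        raise ValueError("empty caudal window")
    idx = np.flatnonzero(caudal_mask)
    t_umax = t[idx[np.argmax(u[idx])]]
    t_dpmax = t[np.argmax(dp)]
    return float((t_umax - t_dpmax) / t_caudal_s)


def peak_velocity(
    times_s: np.ndarray,
    region_umax_mms: np.ndarray,
    systolic_mask: Optional[np.ndarray] = None,
    speed_field: Optional[np.ndarray] = None,
) -> Tuple[float, float, Optional[Tuple[int, int]]]:
    """Peak speed over a region across the systolic phase.

    Returns (value mm/s, time s, location).  The location is the (i, j)
    cell index of the maximum in ``speed_field`` (a snapshot taken at peak
    systole) when provided.
    """
    t = np.asarray(times_s)
    um = np.asarray(region_umax_mms)
    if um.size == 0:
        raise ValueError("empty region")
    mask = np.ones_like(um, dtype=bool) if systolic_mask is None else systolic_mask
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError("no samples during systole")
    k = idx[np.argmax(um[idx])]
    loc = None
    if speed_field is not None:
        loc = tuple(np.unravel_index(int(np.argmax(speed_field)), speed_field.shape))
    return float(um[k]), float(t[k]), loc


def bidirectional_fraction(
    u_slice_mms: np.ndarray, noise_floor_frac: float = 0.01
) -> float:
    """Fraction of the cycle with synchronous bidirectional flow in a slice.

    ``u_slice_mms`` has shape (n_times, n_points): axial velocity samples
    across the slice at each instant.  An instant counts when the slice
    simultaneously contains velocities of both signs exceeding the noise
    floor (default 1 % of the peak speed).
    """
    u = np.asarray(u_slice_mms, dtype=float)
    if u.ndim != 2 or u.shape[1] < 8:
        raise ValueError("need >= 8 sample points across the slice")
    floor = noise_floor_frac * np.max(np.abs(u))
    if floor == 0:
        return 0.0
    both = (u.max(axis=1) > floor) & (u.min(axis=1) < -floor)
    return float(np.mean(both))


def subject_ratio_stats(summaries: Sequence[HydroSummary]) -> pd.DataFrame:
    """Across-subject max/min ratio per metric, to 1 decimal place.

    Metrics with a zero minimum are flagged undefined (NaN ratio).
    """
    if len(summaries) < 2:
        raise ValueError("need at least two subjects")
    metrics = [a for a in HydroSummary._REPORT_COLUMNS if a != "subject"]
    rows = []
    for attr in metrics:
        vals = np.array([abs(getattr(s, attr)) for s in summaries], dtype=float)
        vmax, vmin = float(vals.max()), float(vals.min())
        undefined = vmin == 0.0
        rows.append({
            "metric": attr,
            "max": vmax,
            "min": vmin,
            "ratio": np.nan if undefined else round(vmax / vmin, 1),
            "undefined": undefined,
        })
    return pd.DataFrame(rows).set_index("metric")


# ---------------------------------------------------------------------------
# Run-level summary (results-table analogue)
# ---------------------------------------------------------------------------

def summarize_run(
    run,
    cs_wave,
    aq_wave=None,
    subject: str = "run",
) -> HydroSummary:
    """Summarize a final cycle of a solver run into a HydroSummary.

    ``run`` is a flow_solver.RunResult; ``cs_wave`` (and optionally
    ``aq_wave``) are the origin-aligned flux waveforms that drove it, used
    for the peak-flux normalizations of the resistances.
    """
    from .waveform_io import cycle_metrics  # deferred: module layering

    traces = run.final_traces()
    for lab in ("CS", "PC"):
        if lab not in traces:
            raise ValueError(f"run lacks a {lab!r} probe station")
    cs, pc = traces["CS"], traces["PC"]
    aq = traces.get("Aq")
    T = run.period_s

    dp_pc_cs = pressure_drop_series(cs, pc)
    m_cs = cycle_metrics(cs_wave)
    q_cs_sys = m_cs.q_max_systolic
    q_cs_dia = m_cs.q_max_diastolic
    t_caudal = m_cs.caudal_fraction * T

    t = cs.times_s
    # trace starts just after flow reversal into systole
    k_qmax = int(np.argmin(np.abs(t - m_cs.t_peak_systole * T)))
    dp_at_qmax = float(dp_pc_cs[k_qmax])

    sl = run.final_cycle
    um = {lab: series[sl] for lab, series in run.region_umax.items()}
    caudal_mask = t - t[0] <= t_caudal

    theta = phase_difference(t, um.get("CS", cs.umax_mms), dp_pc_cs, t_caudal,
                             caudal_mask)

    dp_max, dp_min = float(dp_pc_cs.max()), float(dp_pc_cs.min())
    summary_kwargs = dict(
        subject=subject,
        umax_cs_mms=float(np.max(um["CS"])) if "CS" in um else float(np.max(cs.umax_mms)),
        umax_aq_mms=float(np.max(um["Aq"])) if "Aq" in um else
        (float(np.max(aq.umax_mms)) if aq is not None else np.nan),
        umax_fm_mms=float(np.max(um["FM"])) if "FM" in um else np.nan,
        dp_pc_cs_max_pa=dp_max,
        dp_pc_cs_min_pa=dp_min,
        dp_pc_cs_at_qmax_pa=dp_at_qmax,
        gradient_pa_cm=pressure_gradient(dp_max, pc.z_mm, cs.z_mm),
        r_pc_cs_sys=resistance(dp_max, q_cs_sys),
        r_pc_cs_dia=resistance(dp_min, q_cs_dia) if q_cs_dia else np.nan,
        theta=theta,
    )
    if aq is not None:
        dp_aq_pc = pressure_drop_series(pc, aq)
        if aq_wave is not None:
            m_aq = cycle_metrics(aq_wave)
            q_aq_sys, q_aq_dia = m_aq.q_max_systolic, m_aq.q_max_diastolic
        else:
            q_aq_sys, q_aq_dia = q_cs_sys, q_cs_dia
        summary_kwargs.update(
            dp_aq_pc_max_pa=float(dp_aq_pc.max()),
            dp_aq_pc_min_pa=float(dp_aq_pc.min()),
            r_aq_pc_sys=resistance(float(dp_aq_pc.max()), q_aq_sys),
            r_aq_pc_dia=resistance(float(dp_aq_pc.min()), q_aq_dia) if q_aq_dia else np.nan,
        )
    else:
        summary_kwargs.update(
            dp_aq_pc_max_pa=0.0, dp_aq_pc_min_pa=0.0,
            r_aq_pc_sys=np.nan, r_aq_pc_dia=np.nan,
        )
    return HydroSummary(**summary_kwargs)
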