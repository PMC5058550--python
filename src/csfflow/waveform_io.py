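"""Periodic volumetric-flux waveforms as measured by phase-contrast MRI.

PC-MRI yields the volumetric flux through a slice (cervical subarachnoid
space, aqueduct) at a few tens of cardiac phases.  This module holds the
sampled series, interpolates it with a *periodic* cubic spline so that the
flow solver can evaluate the boundary flux at any time, shifts the cycle
origin to the systolic flow reversal, and extracts the timing statistics
(caudal-flow fraction, peak-systole time, zero crossings) used to compare
subjects.

Sign convention: negative flux is caudal (systolic) flow.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "FluxSampleSeries",
    "SplineWaveform",
    "CycleMetrics",
    "read_flux_csv",
    "write_flux_csv",
    "fit_periodic_spline",
    "align_cycle_origin",
    "cycle_metrics",
    "delay_between",
]

#: dense-grid resolution used for all cycle statistics (points per cycle)
DENSE_GRID = 4096
#: bisection refinement tolerance for peak / crossing locations, as a
#: fraction of the period
LOCATE_TOL = 1e-6


@dataclass(frozen=True)
class FluxSampleSeries:
    """One cardiac cycle of sampled volumetric flux at a measurement site.

    Parameters
    ----------
    times_s
        Sample times in seconds, strictly increasing, spanning one cycle.
    fluxes_mm3s
        Volumetric flux in mm^3/s; negative = caudal (systolic).
    heart_rate_bpm
        Heart rate in beats per minute; the period is 60/heart_rate.
    site_label
        Free-text site tag, e.g. ``"CS"`` or ``"Aq"``.
    """

    times_s: np.ndarray
    fluxes_mm3s: np.ndarray
    heart_rate_bpm: float
    site_label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        q = np.asarray(self.fluxes_mm3s, dtype=float)
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "fluxes_mm3s", q)
        if t.ndim != 1 or q.shape != t.shape:
            raise ValueError("times and fluxes must be 1-d arrays of equal length")
        if t.size < 8:
            raise ValueError(
                f"need at least 8 samples per cycle, got {t.size}"
            )
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("times not strictly increasing")
        if not np.all(np.isfinite(q)):
            raise ValueError("fluxes must be finite")
        if not self.heart_rate_bpm > 0:
            raise ValueError("heart rate must be positive")
        period = 60.0 / self.heart_rate_bpm
        span = t[-1] - t[0]
        if abs(period - span) > np.max(dt) * (1 + 1e-9):
            raise ValueError(
                f"sample span {span:.4g} s inconsistent with period "
                f"{period:.4g} s (60/{self.heart_rate_bpm:g} bpm)"
            )

    @property
    def period_s(self) -> float:
        return 60.0 / self.heart_rate_bpm

    @property
    def n_samples(self) -> int:
        return int(self.times_s.size)


class SplineWaveform:
    """Periodic evaluable flux waveform Q(t) [mm^3/s].

    Wraps any callable defined on one period; ``__call__`` accepts arbitrary
    real times and reduces them modulo the period.  ``origin_aligned`` marks
    that t=0 has been shifted to the systolic flow reversal (Q(0)=0 with Q
    entering the caudal, negative phase).
    """

    def __init__(
        self,
        func: Callable[[np.ndarray], np.ndarray],
        period_s: float,
        origin_aligned: bool = False,
        t_start: float = 0.0,
    ) -> None:
        if not period_s > 0:
            raise ValueError("period must be positive")
        self._func = func
        self.period_s = float(period_s)
        self.origin_aligned = bool(origin_aligned)
        self._t_start = float(t_start)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        tw = self._t_start + np.mod(t - self._t_start, self.period_s)
        out = self._func(tw)
        return out if out.ndim else float(out)

    def shifted(self, t0: float, origin_aligned: bool = False) -> "SplineWaveform":
        """Pure time shift: returned wave evaluates self at (t + t0)."""
        return SplineWaveform(
            lambda t, _s=self, _t0=t0: np.asarray(_s(np.asarray(t) + _t0)),
            self.period_s,
            origin_aligned=origin_aligned,
            t_start=0.0,
        )

    def scaled(self, factor: float) -> "SplineWaveform":
        return SplineWaveform(
            lambda t, _s=self, _f=factor: _f * np.asarray(_s(t)),
            self.period_s,
            origin_aligned=self.origin_aligned,
            t_start=self._t_start,
        )


@dataclass(frozen=True)
class CycleMetrics:
    """Timing statistics of one origin-aligned flux cycle.

    All times are fractions of the period.  Under the caudal-negative sign
    convention ``q_max_systolic <= 0 <= q_max_diastolic``.
    """

    caudal_fraction: float
    t_peak_systole: float
    q_max_systolic: float
    q_max_diastolic: float
    zero_crossings: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not 0.0 <= self.caudal_fraction <= 1.0:
            raise ValueError("caudal fraction outside [0, 1]")
        if self.q_max_systolic > 0 or self.q_max_diastolic < 0:
            raise ValueError("systolic/diastolic extrema violate sign convention")


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_flux_csv(path) -> FluxSampleSeries:
    """Read a two-column (time [s], flux [mm^3/s]) waveform CSV.

    Lines starting with ``#`` are comments; two are given meaning when
    present: ``# heart_rate_bpm: <x>`` and ``# site: <label>``.  Without a
    heart-rate comment the period is inferred from the sampled span,
    e.g. a cycle spanning 0.845 s gives 60/0.845 ~ 71 bpm.
    """
    path = Path(path)
    heart_rate = None
    site = ""
    rows = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    key = key.strip().lower()
                    if key == "heart_rate_bpm":
                        heart_rate = float(val)
                    elif key == "site":
                        site = val.strip()
                continue
            parts = [p for p in line.replace(",", " ").split() if p]
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError:
                continue  # header row
    if not rows:
        raise ValueError(f"no numeric samples found in {path}")
    data = np.asarray(rows, dtype=float)
    t, q = data[:, 0], data[:, 1]
    if t.size >= 2 and np.any(np.diff(t) <= 0):
        raise ValueError("times not strictly increasing")
    if t.size < 8:
        raise ValueError(f"need at least 8 samples per cycle, got {t.size}")
    if heart_rate is None:
        heart_rate = 60.0 / (t[-1] - t[0])
    return FluxSampleSeries(t, q, heart_rate, site)


def write_flux_csv(series: FluxSampleSeries, path) -> None:
    """Write a waveform CSV that :func:`read_flux_csv` round-trips exactly."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# heart_rate_bpm: {float(series.heart_rate_bpm)!r}\n")
        if series.site_label:
            fh.write(f"# site: {series.site_label}\n")
        fh.write("time_s,flux_mm3_per_s\n")
        for t, q in zip(series.times_s, series.fluxes_mm3s):
            fh.write(f"{float(t)!r},{float(q)!r}\n")


# ---------------------------------------------------------------------------
# Spline fit and cycle analysis
# ---------------------------------------------------------------------------

def fit_periodic_spline(series: FluxSampleSeries) -> SplineWaveform:
    """Cubic-spline interpolant with periodic end conditions.

    The cardiac cycle wraps, so periodic (not natural/clamped) end conditions
    are used: the interpolant is C2-continuous across the period seam and
    reproduces every sample exactly.
    """
    T = series.period_s
    t = series.times_s
    q = series.fluxes_mm3s
    if abs((t[-1] - t[0]) - T) < 1e-12 * T:
        # samples already include the wrap point
        x, y = t, q.copy()
        y = y.copy()
        y[-1] = y[0]  # enforce exact periodicity for the spline fit
    else:
        x = np.concatenate([t, [t[0] + T]])
        y = np.concatenate([q, [q[0]]])
    cs = CubicSpline(x, y, bc_type="periodic")
    return SplineWaveform(cs, T, t_start=float(t[0]))


def _dense_cycle(wave: SplineWaveform, n: int = DENSE_GRID):
    T = wave.period_s
    t = np.arange(n) * (T / n)
    return t, np.asarray(wave(t))


def _refine_extremum(wave: SplineWaveform, t_lo: float, t_hi: float, sign: float) -> float:
    """Locate an extremum of sign*Q (minimum) in [t_lo, t_hi] by bounded search."""
    res = minimize_scalar(
        lambda t: sign * float(wave(t)),
        bounds=(t_lo, t_hi),
        method="bounded",
        options={"xatol": LOCATE_TOL * wave.period_s},
    )
    return float(res.x)


def _zero_crossings(wave: SplineWaveform, n: int = DENSE_GRID):
    """Refined zero-crossing times in [0, T), with crossing direction."""
    t, q = _dense_cycle(wave, n)
    T = wave.period_s
    tt = np.append(t, T)
    qq = np.append(q, float(wave(T)))
    crossings = []
    for k in range(n):
        a, b = qq[k], qq[k + 1]
        if a == 0.0:
            crossings.append((tt[k], -1.0 if b < 0 else 1.0))
        elif a * b < 0:
            tc = brentq(lambda s: float(wave(s)), tt[k], tt[k + 1],
                        xtol=LOCATE_TOL * T)
            crossings.append((tc, 1.0 if a < 0 else -1.0))
    return crossings


def align_cycle_origin(wave: SplineWaveform) -> SplineWaveform:
    """Shift time so that Q(0)=0 with Q entering the caudal (negative) phase.

    Matches the convention "t = 0 when Q_CS = 0" at the systolic flow
    reversal.  Pure time shift; idempotent.
    """
    _, q = _dense_cycle(wave)
    qmax = float(np.max(np.abs(q)))
    if qmax == 0.0 or np.all(q >= 0) or np.all(q <= 0):
        raise ValueError("no flow reversal found: waveform is single-signed")
    # already aligned?
    q0 = float(wave(0.0))
    slope0 = (float(wave(1e-7 * wave.period_s)) - q0)
    if abs(q0) <= 1e-9 * qmax and slope0 < 0:
        if wave.origin_aligned:
            return wave
        return wave.shifted(0.0, origin_aligned=True)
    downward = [tc for tc, d in _zero_crossings(wave) if d < 0]
    if not downward:
        raise ValueError("no flow reversal found")
    t0 = min(downward)
    return wave.shifted(t0, origin_aligned=True)


def cycle_metrics(wave: SplineWaveform, n: int = DENSE_GRID) -> CycleMetrics:
    """Timing statistics on a dense grid of the spline (not the raw samples).

    The caudal fraction is the fraction of the cycle with Q < 0, measured on
    the refined zero-crossing intervals; peak locations are refined by
    bounded minimisation to 1e-6 of the period.  With several systolic
    peaks the global minimum of Q is used, ties broken by earliest time.
    """
    T = wave.period_s
    t, q = _dense_cycle(wave, max(n, DENSE_GRID))
    dt = T / t.size

    crossings = _zero_crossings(wave, max(n, DENSE_GRID))
    if crossings:
        # integrate the sign over refined crossing intervals
        times = [tc for tc, _ in crossings] + [crossings[0][0] + T]
        caudal = 0.0
        for a, b in zip(times[:-1], times[1:]):
            mid = 0.5 * (a + b)
            if float(wave(mid)) < 0:
                caudal += b - a
        caudal_fraction = caudal / T
    else:
        caudal_fraction = float(np.mean(q < 0))

    k_min = int(np.argmin(q))  # argmin returns earliest tie
    t_sys = _refine_extremum(wave, t[k_min] - dt, t[k_min] + dt, sign=1.0)
    q_sys = float(wave(t_sys))
    k_max = int(np.argmax(q))
    t_dia = _refine_extremum(wave, t[k_max] - dt, t[k_max] + dt, sign=-1.0)
    q_dia = float(wave(t_dia))

    return CycleMetrics(
        caudal_fraction=caudal_fraction,
        t_peak_systole=(t_sys % T) / T,
        q_max_systolic=min(q_sys, 0.0),
        q_max_diastolic=max(q_dia, 0.0),
        zero_crossings=tuple(((tc % T) / T) for tc, _ in crossings),
    )


def systolic_peak_time(wave: SplineWaveform) -> float:
    """Absolute time in [0, T) of the global systolic (most negative) peak."""
    T = wave.period_s
    t, q = _dense_cycle(wave)
    dt = T / t.size
    k = int(np.argmin(q))
    return _refine_extremum(wave, t[k] - dt, t[k] + dt, sign=1.0) % T


def delay_between(wave_a: SplineWaveform, wave_b: SplineWaveform) -> float:
    """Cycle-fraction delay of B's systolic peak relative to A's, in [0, 1)."""
    if abs(wave_a.period_s - wave_b.period_s) > 1e-9 * wave_a.period_s:
        raise ValueError("waveforms have unequal periods")
    T = wave_a.period_s
    ta = systolic_peak_time(wave_a)
    tb = systolic_peak_time(wave_b)
    return ((tb - ta) / T) % 1.0
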