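"""Pressure drops, resistances, phase difference, and ratio tables."""
import numpy as np
import pandas as pd
import pytest

from csfflow.hydrodynamics import (
    HydroSummary,
    ProbeTrace,
    bidirectional_fraction,
    peak_velocity,
    phase_difference,
    pressure_drop_series,
    pressure_gradient,
    resistance,
    subject_ratio_stats,
    summarize_run,
)


def make_trace(label, p, t=None, z=0.0):
    p = np.asarray(p, dtype=float)
    t = np.arange(p.size) * 0.01 if t is None else t
    return ProbeTrace(label, z, t, p, np.zeros_like(p), np.zeros_like(p))


def table1_summaries():
    """The three printed subject rows as HydroSummary fixtures."""
    rows = [
        ("Con1", 59, 134, 27, 33.6, -17.4, 13.1, -14.4, 2.8, 0.008, 0.006,
         0.072, 0.072, 0.27),
        ("P1", 43, 38, 123, 44.4, -14.6, 1.4, -1.5, 4.4, 0.018, 0.006,
         0.022, 0.022, 0.36),
        ("P2", 98, 116, 439, 83.9, -39.6, 8.2, -6.4, 53.6, 0.023, 0.017,
         0.020, 0.020, 0.31),
    ]
    out = []
    for (name, cs, aq, fm, dpx, dpn, dax, dan, dq, rs, rd, ras, rad, th) in rows:
        out.append(HydroSummary(
            subject=name, umax_cs_mms=cs, umax_aq_mms=aq, umax_fm_mms=fm,
            dp_pc_cs_max_pa=dpx, dp_pc_cs_min_pa=dpn,
            dp_aq_pc_max_pa=dax, dp_aq_pc_min_pa=dan,
            dp_pc_cs_at_qmax_pa=dq, gradient_pa_cm=dpx / 7.5,
            r_pc_cs_sys=rs, r_pc_cs_dia=rd, r_aq_pc_sys=ras, r_aq_pc_dia=rad,
            theta=th))
    return out


class TestPressureDrop:
    def test_identical_traces_give_zero(self):
        a = make_trace("CS", [1.0, 2.0, 3.0])
        assert np.all(pressure_drop_series(a, a) == 0.0)

    def test_constant_offset(self):
        cs = make_trace("CS", [2.0] * 5)
        pc = make_trace("PC", [5.0] * 5)
        assert np.allclose(pressure_drop_series(cs, pc), 3.0)

    def test_mismatched_grids_rejected(self):
        a = make_trace("CS", [1.0] * 5)
        b = make_trace("PC", [1.0] * 5, t=np.arange(5) * 0.02)
        with pytest.raises(ValueError, match="time grid"):
            pressure_drop_series(a, b)

    def test_steady_channel_drop_matches_poiseuille(self, poiseuille):
        mesh, state = poiseuille["mesh"], poiseuille["state"]
        gp, q = poiseuille["preset"], poiseuille["q"]
        col = lambda z: int(z / mesh.dz)
        dp = state.p[col(10.0)].mean() - state.p[col(30.0)].mean()
        mu = 7.0e-4  # g/(mm s)
        exact = 12 * mu * 20.0 * (q / gp.depth_mm) / gp.gap_mm**3
        assert dp == pytest.approx(exact, rel=0.01)

    def test_telescoping_identity(self, annulus_pair):
        tr = annulus_pair["ANNULUS_COARSE"].final_traces()
        lhs = pressure_drop_series(tr["CS"], tr["PC"]) + \
            pressure_drop_series(tr["PC"], tr["Aq"])
        rhs = tr["Aq"].p_pa - tr["CS"].p_pa
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_invariance_to_constant_pressure_offset(self, annulus_pair):
        tr = annulus_pair["ANNULUS_COARSE"].final_traces()
        shifted = {lab: ProbeTrace(t.label, t.z_mm, t.times_s, t.p_pa + 37.0,
                                   t.q_mm3s, t.umax_mms)
                   for lab, t in tr.items()}
        a = pressure_drop_series(tr["CS"], tr["PC"])
        b = pressure_drop_series(shifted["CS"], shifted["PC"])
        assert np.allclose(a, b, atol=1e-12)


class TestPressureGradient:
    # printed worked examples: stations at 35 and 110 mm are 7.5 cm apart
    @pytest.mark.parametrize("dp,expect", [
        (33.6, 4.5), (44.4, 5.9), (83.9, 11.2)])
    def test_printed_gradient_examples(self, dp, expect):
        assert round(pressure_gradient(dp, 110.0, 35.0), 1) == expect

    def test_zero_drop(self):
        assert pressure_gradient(0.0, 110.0, 35.0) == 0.0

    def test_zero_separation_rejected(self):
        with pytest.raises(ValueError, match="separation"):
            pressure_gradient(1.0, 50.0, 50.0)


class TestResistance:
    def test_unit_conversion_is_identity(self):
        # 1 Pa = 1 g/(mm s^2): hand case 33.6 Pa / 4200 mm^3/s = 0.008
        assert resistance(33.6, 4200.0) == pytest.approx(0.008)

    def test_numerically_equal_inputs_give_unity(self):
        assert resistance(123.0, 123.0) == pytest.approx(1.0)

    def test_systolic_sign_convention(self):
        assert resistance(10.0, -2000.0) > 0

    def test_zero_flux_rejected(self):
        with pytest.raises(ValueError, match="zero peak flux"):
            resistance(1.0, 0.0)

    def test_steady_channel_resistance_matches_closed_form(self, poiseuille):
        mesh, state = poiseuille["mesh"], poiseuille["state"]
        gp, q = poiseuille["preset"], poiseuille["q"]
        col = lambda z: int(z / mesh.dz)
        dp = state.p[col(10.0)].mean() - state.p[col(30.0)].mean()
        r = resistance(dp, q)
        mu = 7.0e-4
        exact = 12 * mu * 20.0 / (gp.gap_mm**3 * gp.depth_mm)
        assert r == pytest.approx(exact, rel=0.01)


class TestPhaseDifference:
    def test_coincident_peaks_give_zero(self):
        t = np.linspace(0.01, 1.0, 100)
        u = np.sin(np.pi * t)
        assert phase_difference(t, u, u, 0.5) == pytest.approx(0.0)

    def test_constructed_half_period_lag(self):
        t = np.linspace(0.01, 1.0, 1000)
        T_caudal = 0.5
        u = np.exp(-((t - 0.2) ** 2) / 1e-3)
        dp = np.exp(-((t - 0.45) ** 2) / 1e-3)
        theta = phase_difference(t, u, dp, T_caudal)
        assert theta == pytest.approx(-0.5, abs=0.01)

    def test_inertial_sinusoid_gives_minus_half(self):
        # Q = -sin(w t): peak systolic speed at T/4; dp ~ dQ/dt = -cos(w t)
        # peaks at T/2.  With T_caudal = T/2 the quarter-period lead gives
        # theta = -0.5 exactly.
        T = 1.0
        t = np.linspace(T / 1000, T, 1000)
        u = np.abs(-np.sin(2 * np.pi * t / T))
        dp = -np.cos(2 * np.pi * t / T)
        theta = phase_difference(t, u, dp, T / 2,
                                 caudal_mask=t <= T / 2)
        assert theta == pytest.approx(-0.5, abs=0.01)


class TestPeakVelocity:
    def test_uniform_field(self):
        t = np.arange(10) * 0.1
        val, when, _ = peak_velocity(t, np.full(10, 10.0))
        assert val == 10.0

    def test_poiseuille_peak_is_1_5x_mean(self, poiseuille):
        mesh, state = poiseuille["mesh"], poiseuille["state"]
        gp, q = poiseuille["preset"], poiseuille["q"]
        mean_u = q / (gp.gap_mm * gp.depth_mm)
        i = mesh.nz // 2
        assert state.u[i].max() == pytest.approx(1.5 * mean_u, rel=0.01)

    def test_stenosed_peak_occurs_near_throat(self, annulus_pair):
        res = annulus_pair["ANNULUS_COARSE"]
        mesh = res.mesh
        i, j = np.unravel_index(np.argmax(res.snapshot_speed),
                                res.snapshot_speed.shape)
        z_peak = mesh.z_centers[i]
        zc = mesh.stenosis_center_mm
        # at or downstream (caudal side, systolic jet) of the throat
        assert zc - mesh.stenosis_extent_mm <= z_peak <= zc + mesh.stenosis_extent_mm

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError, match="empty region"):
            peak_velocity(np.array([]), np.array([]))


class TestBidirectional:
    def test_unidirectional_cycle_is_nearly_zero(self):
        t = np.linspace(0, 1, 200, endpoint=False)
        y = np.linspace(0, 1, 16)
        profile = y * (1 - y)
        u = np.sin(2 * np.pi * t)[:, None] * profile[None, :]
        assert bidirectional_fraction(u) <= 0.05

    def test_counterflow_field_is_one(self):
        u = np.tile(np.concatenate([np.full(8, 1.0), np.full(8, -1.0)]), (50, 1))
        assert bidirectional_fraction(u) == 1.0

    def test_stenosed_run_exceeds_clean_run(self, annulus_pair, womersley_run):
        sten = annulus_pair["ANNULUS_COARSE"]
        tr = sten.final_traces()
        # the probe just above the stenosis sees the recirculating jet
        frac_sten = bidirectional_fraction(tr["PC"].u_profile)
        clean = womersley_run["result"].final_traces()["mid"]
        frac_clean = bidirectional_fraction(clean.u_profile)
        assert frac_sten > frac_clean

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="8 sample points"):
            bidirectional_fraction(np.zeros((10, 4)))


class TestRatioStats:
    def test_printed_velocity_ratios(self):
        table = subject_ratio_stats(table1_summaries())
        assert table.loc["umax_cs_mms", "ratio"] == 2.3
        assert table.loc["umax_aq_mms", "ratio"] == 3.5
        assert table.loc["dp_aq_pc_max_pa", "ratio"] == 9.4

    def test_identical_summaries_give_unit_ratios(self):
        s = table1_summaries()[0]
        table = subject_ratio_stats([s, s])
        assert (table["ratio"].dropna() == 1.0).all()

    def test_zero_minimum_flagged_undefined(self):
        a, b = table1_summaries()[:2]
        b.dp_aq_pc_max_pa = 0.0
        b.dp_aq_pc_min_pa = -1.0
        table = subject_ratio_stats([a, b])
        assert table.loc["dp_aq_pc_max_pa", "undefined"]
        assert np.isnan(table.loc["dp_aq_pc_max_pa", "ratio"])

    def test_needs_two_subjects(self):
        with pytest.raises(ValueError):
            subject_ratio_stats(table1_summaries()[:1])


class TestSummarizeRun:
    def test_summary_is_consistent_with_traces(self, annulus_pair, con1_wave):
        res = annulus_pair["ANNULUS_COARSE"]
        s = summarize_run(res, con1_wave, subject="Con1")
        tr = res.final_traces()
        dp = tr["PC"].p_pa - tr["CS"].p_pa
        assert s.dp_pc_cs_max_pa == pytest.approx(dp.max())
        assert s.dp_pc_cs_min_pa == pytest.approx(dp.min())
        assert s.gradient_pa_cm == pytest.approx(dp.max() / 7.5)
        assert s.r_pc_cs_sys == pytest.approx(dp.max() / 4200.0, rel=0.02)
        assert s.umax_fm_mms >= s.umax_cs_mms  # jet in the stenosis

    def test_report_row_rounding(self):
        s = table1_summaries()[0]
        row = s.to_report_row()
        assert row["|u|max_CS [mm/s]"] == 59
        assert row["R(PC-CS)sys [g/(mm4 s)]"] == 0.008
        assert row["dp(PC-CS)max [Pa]"] == 33.6
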