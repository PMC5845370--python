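"""Wave solver: eigenmodes, time marching, conservation and oracles."""

import numpy as np
import pytest
import scipy.integrate as si

from spinalwave.errors import StabilityError, UsageError
from spinalwave.materials import assemble_compliance_matrix, moens_korteweg_speed
from spinalwave.pipeline import Numerics, build_profile, run_pulse_experiment
from spinalwave.solver import (
    Excitation,
    Scenario,
    ScenarioConfig,
    assemble_system,
    compute_mode_speeds,
    mode_speeds_from_matrices,
    pressure_summary,
    simulate,
)


class TestExcitation:
    def test_cardiac_flow_is_sinusoid(self):
        exc = Excitation.cardiac(Q0=1e-6, period=0.5)
        assert exc.flow(0.125) == pytest.approx(1e-6)
        assert exc.flow(0.0) == pytest.approx(0.0)

    def test_pulse_flow_vanishes_outside_window(self):
        exc = Excitation.pulse(duration=0.01)
        assert exc.flow(0.005) == pytest.approx(exc.Q0)
        assert exc.flow(0.02) == 0.0

    def test_invalid_kind_rejected(self):
        with pytest.raises(UsageError):
            Excitation("sawtooth")


class TestScenarioConfig:
    @pytest.mark.parametrize("scenario,cord,csf,syx", [
        (Scenario.NORMAL, "fixed", "open_inflow", False),
        (Scenario.CHIARI_NO_SYRINX, "free", "blocked", False),
        (Scenario.CHIARI_WITH_SYRINX, "free", "blocked", True),
    ])
    def test_boundary_condition_table(self, scenario, cord, csf, syx):
        cfg = ScenarioConfig.from_scenario(scenario)
        assert (cfg.cranial_cord_bc, cfg.cranial_csf_bc,
                cfg.syrinx_included) == (cord, csf, syx)


class TestModes:
    def test_moens_korteweg_limit(self):
        """Rigid cord, incompressible fluid, shell-only dura: the single mode
        is the classical thin-tube speed."""
        E_d, h, R, rho = 1.25e6, 1e-3, 5e-3, 1000.0
        c_shell = 2 * np.pi * R**3 / (E_d * h)  # hoop ring, nu = 0
        speeds, _ = mode_speeds_from_matrices(
            np.array([[1.0 / c_shell]]), np.array([np.pi * R**2]), np.array([rho]))
        assert speeds[0] == pytest.approx(
            moens_korteweg_speed(E_d, h, R, rho), rel=1e-9)

    def test_decoupled_cord_is_bar_wave(self):
        A = np.pi * (4e-3) ** 2
        speeds, _ = mode_speeds_from_matrices(
            np.array([[62.5e3 / A]]), np.array([A]), np.array([1000.0]))
        assert speeds[0] == pytest.approx(np.sqrt(62.5e3 / 1000.0), rel=1e-12)

    def test_three_ascending_modes_at_syrinx_station(self, profile, compliance, ms):
        j = profile.station_nearest(profile.extension_length + 0.104)  # x ~ 95 mm
        res = compute_mode_speeds(profile, compliance, j, ms)
        assert res.speeds.size == 3
        assert np.all(np.diff(res.speeds) > 0)
        assert 8.0 < res.speeds[-1] < 15.0

    def test_mode_shape_sign_patterns(self, profile, compliance, ms):
        """Slow: syrinx+cord against SAS; middle: cord against both fluids;
        fast: all layers together."""
        j = profile.station_nearest(profile.extension_length + 0.104)
        res = compute_mode_speeds(profile, compliance, j, ms)
        slow, mid, fast = [np.sign(sh) for sh in res.shapes]  # (syrinx, cord, sas)
        assert slow[0] == slow[1] != slow[2]
        assert mid[0] == mid[2] != mid[1]
        assert fast[0] == fast[1] == fast[2]

    def test_no_syrinx_gives_two_modes(self, profile, compliance, ms):
        j = int(np.flatnonzero(~compliance.has_syrinx)[-1])
        res = compute_mode_speeds(profile, compliance, j, ms)
        assert res.speeds.size == 2


class TestSimulate:
    def test_zero_inflow_keeps_fields_zero(self, profile, compliance, ms):
        sys_ = assemble_system(profile, compliance, Scenario.PULSE_PRELIMINARY, ms)
        f = simulate(sys_, Excitation("transient_pulse", Q0=0.0),
                     duration=0.004, dt=2e-4)
        assert np.abs(f.states).max() == 0.0

    def test_linearity_in_flow_amplitude(self, profile, compliance, ms):
        sys_ = assemble_system(profile, compliance, Scenario.PULSE_PRELIMINARY, ms)
        f1 = simulate(sys_, Excitation.pulse(Q0=0.35e-6), duration=0.01, dt=1e-4)
        f2 = simulate(sys_, Excitation.pulse(Q0=0.70e-6), duration=0.01, dt=1e-4)
        scale = np.abs(f2.states - 2.0 * f1.states).max()
        assert scale <= 1e-10 * np.abs(f2.states).max()

    def test_explicit_integrator_enforces_cfl(self, profile, compliance, ms):
        sys_ = assemble_system(profile, compliance, Scenario.PULSE_PRELIMINARY, ms)
        with pytest.raises(StabilityError) as err:
            simulate(sys_, Excitation.pulse(), duration=0.01, dt=5e-4,
                     integrator="leapfrog")
        assert err.value.suggested_dt is not None
        assert err.value.suggested_dt < 5e-4

    def test_leapfrog_matches_midpoint_when_stable(self, uniform_samples, ms):
        prof = build_profile(uniform_samples, Numerics(ds=2e-3))
        comp = assemble_compliance_matrix(prof, ms)
        sys_ = assemble_system(prof, comp, Scenario.PULSE_PRELIMINARY, ms)
        kw = dict(duration=0.01, save_stride=20)
        fm = simulate(sys_, Excitation.pulse(), dt=5e-5, **kw)
        fl = simulate(sys_, Excitation.pulse(), dt=5e-5, integrator="leapfrog", **kw)
        ref = np.abs(fm.p_sas).max()
        assert np.abs(fm.p_sas - fl.p_sas).max() < 0.05 * ref

    def test_energy_conserved_after_pulse(self, pulse_result):
        """With the excitation off, implicit midpoint holds the total energy."""
        f = pulse_result.field
        E = f.system.energy(f.states)
        after = f.t > f.excitation.pulse_duration + 1e-4
        drift = (E[after].max() - E[after].min()) / E[after].max()
        assert drift < 0.02
        assert E[after].max() > 0

    def test_fields_start_from_rest(self, pulse_result):
        assert np.abs(pulse_result.field.states[0]).max() == 0.0


class TestMassConservation:
    def test_pulse_run(self, pulse_result):
        f = pulse_result.field
        stored = f.system.stored_volume(f.states)
        inflow = si.cumulative_trapezoid(f.Q, f.t, initial=0.0)
        err = np.abs(stored - inflow).max() / np.abs(inflow).max()
        assert err < 0.02

    @pytest.mark.parametrize("run", ["normal_run", "chiari_run",
                                     "chiari_syrinx_run"])
    def test_cardiac_runs(self, run, request):
        _, f = request.getfixturevalue(run)
        stored = f.system.stored_volume(f.states)
        inflow = si.cumulative_trapezoid(f.Q, f.t, initial=0.0)
        err = np.abs(stored - inflow).max() / np.abs(inflow).max()
        assert err < 0.01


class TestWavefrontOracle:
    def test_uniform_waveguide_eigen_vs_time_of_flight(self, uniform_samples, ms):
        """On a uniform section the time-of-flight speeds are an independent
        oracle for the eigen analysis (agreement within 10% per branch)."""
        res = run_pulse_experiment(uniform_samples, ms)
        rel = np.abs(res.wavefront_speeds - res.modes.speeds) / res.modes.speeds
        assert res.wavefront_speeds.size == 3
        assert rel.max() < 0.10

    def test_speeds_insensitive_to_pulse_duration(self, uniform_samples, ms):
        r1 = run_pulse_experiment(uniform_samples, ms)
        r2 = run_pulse_experiment(uniform_samples, ms,
                                  excitation=Excitation.pulse(duration=0.005))
        rel = np.abs(r2.wavefront_speeds - r1.wavefront_speeds) / r1.wavefront_speeds
        assert rel.max() < 0.03

    def test_fixture_pulse_splits_into_three_branches(self, pulse_result):
        f = pulse_result.field
        # single disturbance near the cranial end early in the event
        i5 = int(np.argmin(np.abs(f.t - 0.005)))
        v = np.abs(f.v_sas[i5])
        cum = np.cumsum(v) / v.sum()
        assert f.s_half[np.searchsorted(cum, 0.9)] < 0.12
        # by 25 ms the disturbance spans most of the canal as separate branches
        i25 = int(np.argmin(np.abs(f.t - 0.025)))
        v = np.abs(f.v_sas[i25])
        cum = np.cumsum(v) / v.sum()
        assert f.s_half[np.searchsorted(cum, 0.9)] > 0.2
        assert pulse_result.wavefront_speeds.size == 3


class TestPressureSummary:
    def test_rejects_transient_runs(self, pulse_result):
        with pytest.raises(UsageError):
            pressure_summary(pulse_result.field)

    def test_normal_amplitude_in_physiological_band(self, normal_run):
        rep, f = normal_run
        summ = pressure_summary(f)
        assert 100.0 < summ.p_amp_zero_to_peak < 800.0
        assert summ.p_amp_harmonic <= summ.p_amp_zero_to_peak

    def test_sas_velocity_decreases_caudally(self, normal_run):
        _, f = normal_run
        mask = f.final_cycle_mask()
        amp = np.abs(f.v_sas[mask]).max(axis=0)
        ext = f.profile.extension_length
        sel = f.s_half >= ext
        x = f.s_half[sel]
        a = amp[sel]
        slope = np.polyfit(x, a, 1)[0]
        assert slope < 0
        assert a[:20].mean() > 3.0 * a[-20:].mean()

    def test_mmhg_conversion(self, normal_run):
        rep, f = normal_run
        summ = pressure_summary(f)
        assert summ.dp_craniocaudal_mmhg == pytest.approx(
            summ.dp_craniocaudal_max / 133.322)


class TestGridConvergence:
    def test_mode_speeds_stable_under_refinement(self, fixture_samples, ms):
        res = {}
        for ds in (1e-3, 0.5e-3):
            prof = build_profile(fixture_samples, Numerics(ds=ds))
            comp = assemble_compliance_matrix(prof, ms)
            j = prof.station_nearest(prof.extension_length + 0.104)
            res[ds] = compute_mode_speeds(prof, comp, j, ms).speeds
        rel = np.abs(res[0.5e-3] - res[1e-3]) / res[1e-3]
        assert rel.max() < 0.02

    def test_pressure_amplitude_stable_under_refinement(self, fixture_samples, ms):
        from spinalwave.pipeline import run_scenario
        amps = {}
        for ds, dt in ((1e-3, 1e-4), (0.5e-3, 0.5e-4)):
            num = Numerics(ds=ds, dt_cardiac=dt, n_cycles=2)
            rep, _ = run_scenario(fixture_samples, ms, "normal", numerics=num)
            amps[ds] = rep.p_amp_pa
        assert abs(amps[0.5e-3] - amps[1e-3]) / amps[1e-3] < 0.02
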