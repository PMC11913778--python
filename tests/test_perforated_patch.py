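"""IV analysis: series-resistance correction, membrane properties, ramp/step
E_GABAAR estimation, Vm statistics and response-polarity classification."""

import numpy as np
import pytest

from gabashunt import perforated_patch as pp
from gabashunt import synthetic
from gabashunt.sweeps import CorrectionConfig, ModeError, ProtocolDescriptor, Sweep


def _vc_sweep(command, recorded, dt=5e-5, **kw):
    return Sweep(dt=dt, command=np.asarray(command, float),
                 recorded=np.asarray(recorded, float), mode="VC", **kw)


class TestSeriesResistanceCorrection:
    def test_zero_current_is_identity(self):
        cmd = np.linspace(-130, -30, 100)
        sweep = _vc_sweep(cmd, np.zeros(100))
        out = pp.correct_series_resistance(sweep, CorrectionConfig(rs_MOhm=50.0))
        np.testing.assert_array_equal(out, cmd)

    def test_zero_rs_is_identity(self):
        cmd = np.full(100, -70.0)
        sweep = _vc_sweep(cmd, np.full(100, -500.0))
        out = pp.correct_series_resistance(sweep, CorrectionConfig(rs_MOhm=0.0))
        np.testing.assert_array_equal(out, cmd)

    def test_worked_example(self):
        # -70 mV command, -1000 pA, 50 MOhm, 90% fraction -> -25 mV
        sweep = _vc_sweep([-70.0], [-1000.0])
        out = pp.correct_series_resistance(
            sweep, CorrectionConfig(rs_MOhm=50.0, rs_fraction=0.9)
        )
        assert out[0] == pytest.approx(-25.0)

    def test_rejects_current_clamp(self):
        sweep = Sweep(dt=5e-5, command=np.zeros(10), recorded=np.zeros(10), mode="IC")
        with pytest.raises(ModeError):
            pp.correct_series_resistance(sweep, CorrectionConfig(rs_MOhm=10.0))


class TestMembraneProperties:
    def test_recovers_rc_cell(self):
        # noiseless RC model cell: Rs 20, Rm 80, Cm 100 pF
        truth = synthetic.SweepGroundTruth(rs_MOhm=20.0, rm_MOhm=80.0, cm_pF=100.0)
        sess = synthetic.gen_iv_session(truth)
        mp = pp.estimate_membrane_properties(sess.seal)
        assert mp.rs_MOhm == pytest.approx(20.0, abs=0.5)
        assert mp.r_input_MOhm == pytest.approx(100.0, rel=0.01)
        assert mp.rm_MOhm == pytest.approx(80.0, abs=1.0)
        assert mp.perforation_ok and mp.steady_state_ok

    def test_zero_rs_cell(self):
        truth = synthetic.SweepGroundTruth(rs_MOhm=0.0, rm_MOhm=80.0, cm_pF=100.0)
        sess = synthetic.gen_iv_session(truth)
        mp = pp.estimate_membrane_properties(sess.seal)
        assert mp.rs_peak_MOhm < 2.0
        assert mp.rm_MOhm == pytest.approx(mp.r_input_MOhm, rel=0.05)

    def test_perforation_acceptance_flag(self):
        # quality criterion: recordings require Rs < 100 MOhm
        truth = synthetic.SweepGroundTruth(rs_MOhm=120.0, rm_MOhm=200.0)
        sess = synthetic.gen_iv_session(truth)
        mp = pp.estimate_membrane_properties(sess.seal)
        assert not mp.perforation_ok

    def test_no_transient_raises(self):
        cmd = np.concatenate([np.full(200, -70.0), np.full(800, -80.0)])
        rec = (cmd + 70.0) * 10.0  # purely ohmic, no capacitive peak
        with pytest.raises(pp.FitError):
            pp.estimate_membrane_properties(_vc_sweep(cmd, rec))


class TestRampFit:
    def test_exact_linear_currents(self):
        # baseline I = 10 nS * (V + 70); light adds 5 nS * (V + 60)
        cmd, i0, i1 = synthetic._ramp_command()
        base = 10.0 * (cmd + 70.0)
        light = base + 5.0 * (cmd + 60.0)
        res = pp.fit_iv_ramp(
            _vc_sweep(cmd, base), _vc_sweep(cmd, light), CorrectionConfig(rs_MOhm=0.0)
        )
        assert res.rmp_mV == pytest.approx(-70.0, abs=1e-9)
        assert res.egaba_mV == pytest.approx(-60.0, abs=1e-9)
        assert res.df_mV == pytest.approx(-10.0, abs=1e-9)
        assert res.g_gaba_nS == pytest.approx(5.0, abs=1e-12)

    def test_machine_precision_on_noiseless_generator(self):
        truth = synthetic.SweepGroundTruth(rs_MOhm=0.0, noise_pA=0.0, seed=1)
        sess = synthetic.gen_iv_session(truth)
        res = pp.fit_iv_ramp(
            sess.ramp_baseline, sess.ramp_light, CorrectionConfig(rs_MOhm=0.0)
        )
        assert res.rmp_mV == pytest.approx(truth.rmp_mV, abs=1e-8)
        assert res.egaba_mV == pytest.approx(truth.egaba_mV, abs=1e-8)
        assert res.g_gaba_nS == pytest.approx(truth.g_gaba_nS, abs=1e-10)
        assert res.df_mV == res.rmp_mV - res.egaba_mV  # identity by construction

    def test_zero_conductance_raises_no_intersection(self):
        cmd, _, _ = synthetic._ramp_command()
        base = 10.0 * (cmd + 70.0)
        with pytest.raises(pp.NoIntersectionError):
            pp.fit_iv_ramp(
                _vc_sweep(cmd, base), _vc_sweep(cmd, base.copy()),
                CorrectionConfig(rs_MOhm=0.0),
            )

    def test_crop_windows_remove_contaminated_samples(self):
        truth = synthetic.SweepGroundTruth(rs_MOhm=0.0, noise_pA=0.0, seed=1)
        sess = synthetic.gen_iv_session(truth)
        light = sess.ramp_light
        spoiled = light.recorded.copy()
        k = int(0.120 / light.dt)  # mid-ramp artifact
        spoiled[k : k + 40] += 5000.0
        sweep = Sweep(dt=light.dt, command=light.command, recorded=spoiled,
                      mode="VC", light_onset=light.light_onset,
                      light_duration=light.light_duration)
        res = pp.fit_iv_ramp(
            sess.ramp_baseline, sweep, CorrectionConfig(rs_MOhm=0.0),
            crop_windows=[(0.118, 0.125)],
        )
        assert res.egaba_mV == pytest.approx(truth.egaba_mV, abs=1e-6)

    def test_recovery_with_rs_and_partial_correction(self):
        truth = synthetic.SweepGroundTruth(rs_MOhm=50.0, noise_pA=0.0, seed=2)
        sess = synthetic.gen_iv_session(truth)
        res = pp.fit_iv_ramp(
            sess.ramp_baseline, sess.ramp_light,
            CorrectionConfig(rs_MOhm=50.0, rs_fraction=0.9),
        )
        assert res.egaba_mV == pytest.approx(truth.egaba_mV, abs=1.0)

    def test_bias_decreases_toward_full_correction(self):
        truth = synthetic.SweepGroundTruth(rs_MOhm=60.0, noise_pA=0.0, seed=3)
        sess = synthetic.gen_iv_session(truth)
        biases = []
        for frac in (0.0, 0.5, 0.9, 1.0):
            res = pp.fit_iv_ramp(
                sess.ramp_baseline, sess.ramp_light,
                CorrectionConfig(rs_MOhm=60.0, rs_fraction=frac),
            )
            biases.append(abs(res.egaba_mV - truth.egaba_mV))
        assert all(np.diff(biases) < 0)
        assert biases[-1] < 1e-6  # full correction inverts the distortion


class TestStepFit:
    def test_noiseless_step_estimate(self):
        truth = synthetic.SweepGroundTruth(
            egaba_mV=-80.0, rs_MOhm=0.0, noise_pA=0.0, seed=4
        )
        sess = synthetic.gen_iv_session(truth)
        res, info = pp.fit_iv_step(sess.steps, CorrectionConfig(rs_MOhm=0.0))
        assert res.egaba_mV == pytest.approx(-80.0, abs=0.1)
        assert res.protocol == "step20ms"

    def test_step_and_ramp_agree(self):
        truth = synthetic.SweepGroundTruth(rs_MOhm=40.0, noise_pA=0.0, seed=5)
        sess = synthetic.gen_iv_session(truth)
        cfg = CorrectionConfig(rs_MOhm=40.0, rs_fraction=0.9)
        ramp = pp.fit_iv_ramp(sess.ramp_baseline, sess.ramp_light, cfg)
        step, _ = pp.fit_iv_step(sess.steps, cfg)
        assert abs(step.egaba_mV - ramp.egaba_mV) < 1.0

    def test_stability_diagnostic(self):
        truth = synthetic.SweepGroundTruth(rs_MOhm=0.0, noise_pA=0.0, seed=6)
        sess = synthetic.gen_iv_session(truth)
        _, info = pp.fit_iv_step(
            sess.steps, CorrectionConfig(rs_MOhm=0.0), t_ramp_ms=40.0
        )
        # stationary synaptic reversal: the two step estimates coincide
        assert abs(info["step_time_diff_mV"]) < 0.5

    def test_zero_light_conductance_errors(self):
        truth = synthetic.SweepGroundTruth(g_gaba_nS=0.0, rs_MOhm=0.0, seed=7)
        sess = synthetic.gen_iv_session(truth)
        with pytest.raises(pp.NoIntersectionError):
            pp.fit_iv_step(sess.steps, CorrectionConfig(rs_MOhm=0.0))


class TestVmStatistics:
    def test_constant_trace(self):
        n = int(20.0 / 5e-5)
        sweep = Sweep(dt=5e-5, command=np.zeros(n),
                      recorded=np.full(n, -65.0), mode="IC")
        stats = pp.vm_statistics(sweep, bw_method=0.1)
        assert stats.mean_vm_mV == pytest.approx(-65.0)
        assert stats.mean_abs_dvdt_mV_per_ms == pytest.approx(0.0, abs=1e-12)

    def test_sine_closed_form(self):
        # mean |dV/dt| of A*sin(w t) is (2/pi)*A*w
        dt, A, f = 5e-5, 5.0, 10.0
        t = np.arange(int(20.0 / dt)) * dt
        v = -65.0 + A * np.sin(2 * np.pi * f * t)
        sweep = Sweep(dt=dt, command=np.zeros_like(v), recorded=v, mode="IC")
        stats = pp.vm_statistics(sweep)
        expected = (2.0 / np.pi) * A * (2 * np.pi * f / 1000.0)
        assert stats.mean_abs_dvdt_mV_per_ms == pytest.approx(expected, rel=0.01)

    def test_density_integrates_to_one(self):
        trace = synthetic.gen_vm_trace(duration_s=20.0, seed=8)
        stats = pp.vm_statistics(trace)
        area = np.trapezoid(stats.density, stats.density_grid_mV)
        assert area == pytest.approx(1.0, abs=0.01)

    def test_awake_like_generator_recovery(self):
        # generator tuned to the awake-state fluctuation scale (6.6 mV/ms)
        trace = synthetic.gen_vm_trace(
            duration_s=30.0, target_dvdt_mV_per_ms=6.6, seed=9
        )
        stats = pp.vm_statistics(trace)
        assert stats.mean_abs_dvdt_mV_per_ms == pytest.approx(6.6, rel=0.05)

    def test_short_trace_rejected(self):
        n = int(5.0 / 5e-5)
        sweep = Sweep(dt=5e-5, command=np.zeros(n),
                      recorded=np.full(n, -65.0), mode="IC")
        with pytest.raises(pp.InsufficientDataError):
            pp.vm_statistics(sweep)


class TestPolarity:
    def test_flat_trace_is_hyperpolarizing_tie_break(self):
        n = int(1.0 / 5e-5)
        sweep = Sweep(dt=5e-5, command=np.zeros(n), recorded=np.full(n, -65.0),
                      mode="IC", light_onset=0.4, light_duration=0.01)
        res = pp.classify_polarity([sweep])
        assert res.mean_post_light_mV == 0.0
        assert res.label == "hyperpolarizing"

    def test_depolarizing_deflection(self):
        sweeps = synthetic.gen_polarity_session(
            amplitude_mV=0.8, noise_sd_mV=0.0, seed=10
        )
        assert pp.classify_polarity(sweeps).label == "depolarizing"

    def test_noisy_ipsp_monte_carlo(self):
        # -2 mV IPSP, 0.5 mV noise, 15 sweeps: reliably hyperpolarizing
        for seed in range(5):
            sweeps = synthetic.gen_polarity_session(
                amplitude_mV=-2.0, noise_sd_mV=0.5, n_sweeps=15, seed=seed
            )
            assert pp.classify_polarity(sweeps).label == "hyperpolarizing"

    def test_missing_light_metadata(self):
        n = 1000
        sweep = Sweep(dt=1e-3, command=np.zeros(n), recorded=np.zeros(n), mode="IC")
        with pytest.raises(ValueError):
            pp.classify_polarity([sweep])
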