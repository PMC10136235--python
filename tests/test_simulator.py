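"""Coupled simulation: convergence, summaries, calibration, determinism."""

import copy
import numpy as np
import pytest

from stenoflow.cardiac import CardiacParams
from stenoflow.experiments import BASELINE, _case_config
from stenoflow.simulator import (CycleWaveforms, SimulationConfig, calibrate_case,
                                 estimate_afterload_from_waveforms, run_to_periodic,
                                 summarize, tune_ees_for_sv)
from stenoflow.valve import ValveParams


def synthetic_waveforms(n=800, t_hp=0.8, et_frac=0.4, at_frac=1 / 3,
                        tpg_level=10.0, q_peak=300.0):
    """Hand-built cycle: rectangular TPG, triangular flow peaking at at_frac."""
    dt = t_hp / n
    time = np.arange(1, n + 1) * dt
    n_ej = int(et_frac * n)
    zeta = np.zeros(n)
    zeta[:n_ej] = 1.0
    q = np.zeros(n)
    i_pk = int(at_frac * n_ej)
    q[:i_pk] = np.linspace(0, q_peak, i_pk, endpoint=False)
    q[i_pk:n_ej] = np.linspace(q_peak, 0, n_ej - i_pk)
    q[:n_ej] = np.maximum(q[:n_ej], 1e-9)
    p_ao = 100.0 + 10.0 * np.sin(2 * np.pi * time / t_hp)
    p_lv = p_ao + np.where(np.arange(n) < n_ej, tpg_level, -60.0)
    v = 150.0 - np.concatenate([np.cumsum(q)]) * dt
    return CycleWaveforms(time=time, p_lv=p_lv, p_ao=p_ao, q_av=q, zeta=zeta,
                          v_lv=v, dt=dt, t_hp=t_hp, zeta_min=1e-4)


class TestSummarize:
    def test_constant_gradient_averages_to_itself(self):
        s = summarize(synthetic_waveforms(tpg_level=10.0))
        assert s.mean_tpg == pytest.approx(10.0)
        assert s.max_tpg == pytest.approx(10.0)

    def test_triangular_flow_acceleration_time(self):
        s = summarize(synthetic_waveforms(at_frac=1 / 3))
        assert s.acceleration_time == pytest.approx(s.ejection_time / 3, rel=0.02)

    def test_sv_equals_co_times_period(self):
        s = summarize(synthetic_waveforms())
        assert s.sv == pytest.approx(s.co * 0.8, rel=1e-12)

    def test_degenerate_run_flagged(self):
        wf = synthetic_waveforms()
        wf.q_av[:] = 0.0
        with pytest.raises(ValueError, match="no ejection"):
            summarize(wf)

    def test_estimators_are_the_defining_ratios(self):
        wf = synthetic_waveforms()
        s = summarize(wf)
        tvr_est, tac_est = estimate_afterload_from_waveforms(wf)
        assert tvr_est == pytest.approx(s.map / s.co)
        assert tac_est == pytest.approx(s.sv / s.pp)


class TestCoupledRun:
    def test_converges_and_closes_pv_loop(self, dekker_case):
        cfg, wf = dekker_case
        assert wf.converged
        s = summarize(wf)
        # loop closure: net volume change over the converged cycle < 0.5% SV
        net = wf.qin_vol - s.sv_net
        assert abs(net) < 0.005 * s.sv
        # LV pressure exceeds aortic pressure while flow is accelerating
        # (during deceleration the gradient reverses - that is the physics)
        i_pk = int(np.argmax(wf.q_av))
        accel = (np.arange(len(wf.q_av)) < i_pk) & (wf.q_av > 1.0)
        assert accel.sum() > 50
        assert np.all(wf.p_lv[accel] > wf.p_ao[accel])

    def test_pv_loop_width_matches_flow_integral(self, dekker_case):
        _, wf = dekker_case
        s = summarize(wf)
        assert s.sv_pv_loop == pytest.approx(s.sv, rel=0.01)

    def test_lvedp_honoured_by_atrial_tuning(self, dekker_case):
        cfg, wf = dekker_case
        assert wf.p_lv[-1] == pytest.approx(cfg.cardiac.lvedp, abs=0.25)

    def test_cycle_volume_conservation(self, dekker_case):
        # root inflow volume vs summed terminal outflow volume, < 1% of SV
        _, wf = dekker_case
        s = summarize(wf)
        assert abs(s.sv_net - wf.qout_vol) < 0.01 * s.sv

    def test_deterministic_bitwise(self, baseline_tree):
        from stenoflow.fixtures import patient_fixture
        runs = []
        for _ in range(2):
            cfg = patient_fixture("dekker_av_stenosis")
            cfg.geometry = baseline_tree
            runs.append(run_to_periodic(cfg))
        assert np.array_equal(runs[0].p_lv, runs[1].p_lv)
        assert np.array_equal(runs[0].q_av, runs[1].q_av)
        assert np.array_equal(runs[0].zeta, runs[1].zeta)

    def test_ideal_valve_limit_has_negligible_gradient(self, baseline_tree):
        ao = float(baseline_tree.root.area_prox)
        cfg = SimulationConfig(
            cardiac=CardiacParams(ees=2.0, eed=0.1),
            valve=ValveParams(ames=ao, ao=ao, kt=1e-6, leff=0.1, kvo=50.0),
            geometry=baseline_tree)
        s = summarize(run_to_periodic(cfg))
        assert s.mean_tpg < 1.0


class TestCalibration:
    def test_achieves_targets_within_one_percent(self, calibrated_baseline_case):
        _, wf = calibrated_baseline_case
        assert abs(wf.achieved_tvr - BASELINE["tvr"]) / BASELINE["tvr"] < 0.01
        assert abs(wf.achieved_tac - BASELINE["tac"]) / BASELINE["tac"] < 0.01

    def test_map_equals_co_times_tvr(self, calibrated_baseline_case):
        _, wf = calibrated_baseline_case
        s = summarize(wf)
        assert s.map == pytest.approx(s.co * BASELINE["tvr"], rel=0.02)

    def test_idempotent_on_calibrated_case(self, calibrated_baseline_case):
        cfg2, _ = calibrated_baseline_case
        before = {sid: (t.r1, t.r2, t.ct)
                  for sid, t in cfg2.geometry.terminals.items()}
        cfg3, _ = calibrate_case(cfg2, BASELINE["tvr"], BASELINE["tac"])
        for sid, t in cfg3.geometry.terminals.items():
            assert t.r1 == pytest.approx(before[sid][0], rel=1e-3)
            assert t.ct == pytest.approx(before[sid][2], rel=1e-3)

    def test_waveform_tvr_recovery_after_structural_scaling(self, tree):
        # set TVR structurally, simulate, re-estimate from waveforms: the
        # estimate differs only by the large-artery viscous series resistance
        scaled = tree.scale_afterload(1.0, 1.2)
        cfg, _, _ = _case_config(BASELINE, 0.6, kvo=0.45, tree=scaled)
        wf = run_to_periodic(cfg, tree=scaled)
        tvr_est, _ = estimate_afterload_from_waveforms(wf)
        assert tvr_est == pytest.approx(1.0, rel=0.05)

    def test_sweep_extreme_corner_converges(self, tree, kvo_060):
        cfg, _, _ = _case_config(
            dict(BASELINE, tvr=1.8, tac=0.5), 0.6, kvo_060, tree)
        _, wf = calibrate_case(cfg, 1.8, 0.5)
        assert abs(wf.achieved_tvr - 1.8) / 1.8 < 0.01
        assert abs(wf.achieved_tac - 0.5) / 0.5 < 0.01


class TestSvTuning:
    def test_bisection_hits_stroke_volume_target(self, calibrated_baseline_case):
        cfg, _ = calibrated_baseline_case
        cfg = copy.copy(cfg)
        trial, wf = tune_ees_for_sv(cfg, 60.0, tol=1.0)
        assert summarize(wf).sv == pytest.approx(60.0, abs=1.0)


class TestConfigSerialization:
    def test_yaml_roundtrip(self, tmp_path):
        cfg = SimulationConfig(cardiac=CardiacParams(ees=3.3, eed=0.1, vd=39.3),
                               valve=ValveParams(ames=0.6, kvo=0.5),
                               geometry="tree24", sv_target=87.0)
        path = tmp_path / "run.yaml"
        cfg.to_yaml(path)
        back = SimulationConfig.from_yaml(path)
        assert back.cardiac.ees == cfg.cardiac.ees
        assert back.valve.ames == cfg.valve.ames
        assert back.sv_target == 87.0
        assert back.geometry == "tree24"
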