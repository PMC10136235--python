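"""1D pulse-wave solver physics: propagation, friction, junctions, limits."""

import numpy as np
import pytest

from stenoflow.network import (ArterialSegment, ArterialTree, WindkesselTerminal,
                               amax_from_reference, langewouters_pressure,
                               wave_speed, windkessel_step)
from stenoflow.solver import Engine, junction_couple
from stenoflow.units import MMHG, RHO_BLOOD


def uniform_tube(length=200.0, area=3.0, p1=50.0, r1=0.5, r2=10.0, ct=0.05,
                 visc=0.0):
    seg = ArterialSegment(id=0, parent_id=None, length=length, area_prox=area,
                          area_dist=area, p0=70.0, p1=p1, visc_coeff=visc,
                          terminal=WindkesselTerminal(r1=r1, r2=r2, ct=ct))
    return ArterialTree([seg])


def drive(engine, q_of_t, t_total, sample_nodes=(), sample_every=1e-3):
    """Advance with a prescribed inflow, sampling state at given nodes."""
    samples = {i: [] for i in sample_nodes}
    times = []
    t = 0.0
    while t < t_total - 1e-12:
        n, dt = engine.steps_for(sample_every)
        q = q_of_t(t + np.arange(n) * dt)
        engine.run_cycle(mode=0, period=sample_every, qin_series=q)
        t += n * dt
        times.append(t)
        for i in sample_nodes:
            samples[i].append(engine.A[i])
    return np.asarray(times), {i: np.asarray(v) for i, v in samples.items()}


class TestEquilibrium:
    def test_uniform_state_is_invariant(self):
        tree = uniform_tube()
        eng = Engine(tree, dx_target=2.0, p_init=0.0)
        a0 = eng.A.copy()
        n, dt = eng.steps_for(0.2)
        eng.run_cycle(mode=0, period=0.2, qin_series=np.zeros(n))
        assert np.allclose(eng.A, a0, rtol=1e-12)
        assert np.allclose(eng.Q, 0.0, atol=1e-10)


class TestWaveSpeed:
    def test_pulse_foot_speed_matches_analytic(self):
        # narrow pulse in a long, effectively frictionless tube; compare the
        # foot transit time between two stations with c = sqrt(A/(rho dA/dP)).
        # the far end is effectively closed (huge R2) so the resting state
        # does not drain during the measurement
        tree = uniform_tube(length=200.0, area=3.0, p1=50.0, r2=1e5, ct=0.01)
        eng = Engine(tree, dx_target=1.0, p_init=80.0, mu=0.0)
        x1, x2 = 50, 150  # node indices at dx = 1 cm

        def pulse(t):
            return 3.0 * np.exp(-0.5 * ((t - 0.01) / 0.004) ** 2)

        times, s = drive(eng, pulse, t_total=0.56, sample_nodes=(x1, x2),
                         sample_every=2e-3)
        a1 = s[x1] - s[x1][0]
        a2 = s[x2] - s[x2][0]
        thresh = 0.25 * a1.max()
        t1 = times[np.argmax(a1 > thresh)]
        t2 = times[np.argmax(a2 > thresh)]
        seg = tree.root
        amax = amax_from_reference(3.0, seg.p0, seg.p1)
        c_analytic = wave_speed(80.0, amax, seg.p0, seg.p1, RHO_BLOOD)
        measured = (x2 - x1) / (t2 - t1)
        assert measured == pytest.approx(c_analytic, rel=0.05)


class TestFriction:
    def test_steady_pressure_drop_matches_friction_law(self):
        # constant flow: dP/dx = -2(gamma+2) pi mu Q / A^2
        tree = uniform_tube(length=100.0, area=1.0, p1=200.0, r1=0.5, r2=5.0,
                            ct=0.02)
        gamma, mu = 9.0, 0.04
        eng = Engine(tree, dx_target=1.0, p_init=80.0, gamma_v=gamma, mu=mu)
        q0 = 20.0
        for _ in range(40):
            n, dt = eng.steps_for(0.2)
            eng.run_cycle(mode=0, period=0.2, qin_series=np.full(n, q0))
        m = eng.mesh
        i1, i2 = 10, 90
        p = langewouters_pressure(eng.A, m.amax, m.p0d, m.p1d) / MMHG
        a_mean = eng.A[i1:i2].mean()
        dp_expected = 2 * (gamma + 2) * np.pi * mu * q0 * (i2 - i1) * 1.0 \
            / (a_mean ** 2) / MMHG
        dp_measured = p[i1] - p[i2]
        assert dp_measured == pytest.approx(dp_expected, rel=0.02)


class TestJunctionCoupling:
    def _side(self, a_ref, q, p1=50.0):
        amax = amax_from_reference(a_ref, 70.0, p1)
        a = amax * (0.5 + np.arctan((85.0 - 70.0) / p1) / np.pi)
        return {"a": a, "q": q, "amax": amax, "p0": 70.0, "p1": p1}

    def test_flow_conservation_exact(self):
        out = junction_couple(self._side(4.0, 100.0),
                              [self._side(2.0, 40.0), self._side(1.5, 35.0)])
        q_children = sum(c["q"] for c in out["children"])
        assert out["parent"]["q"] == pytest.approx(q_children, rel=1e-12)

    def test_total_pressure_continuity(self):
        out = junction_couple(self._side(4.0, 100.0),
                              [self._side(2.0, 40.0), self._side(1.5, 35.0)])
        rho = RHO_BLOOD

        def total_p(side, a):
            u = side["q"] / a
            return side["p"] * MMHG + 0.5 * rho * u * u

        tp_par = total_p(out["parent"], out["parent"]["a"])
        for ch in out["children"]:
            assert total_p(ch, ch["a"]) == pytest.approx(tp_par, rel=1e-9)

    def test_identical_single_child_is_transparent(self):
        parent = self._side(3.0, 80.0)
        out = junction_couple(parent, [self._side(3.0, 80.0)])
        assert out["parent"]["q"] == pytest.approx(80.0, rel=1e-9)
        assert out["children"][0]["p"] == pytest.approx(out["parent"]["p"], rel=1e-9)

    def test_reflection_coefficient_matches_impedance_theory(self):
        # area step halves the cross-section at equal wave speed, so the
        # characteristic impedance Z = rho c/A doubles; linear theory gives
        # a pressure reflection coefficient (Z2 - Z1)/(Z2 + Z1) = 1/3
        segs = [
            ArterialSegment(id=0, parent_id=None, length=80.0, area_prox=3.0,
                            area_dist=3.0, p0=70.0, p1=50.0),
            ArterialSegment(id=1, parent_id=0, length=150.0, area_prox=1.5,
                            area_dist=1.5, p0=70.0, p1=50.0,
                            terminal=WindkesselTerminal(r1=1.0, r2=1e5, ct=0.01)),
        ]
        tree = ArterialTree(segs)
        eng = Engine(tree, dx_target=1.0, p_init=80.0, mu=0.0)
        mid = 60

        def pulse(t):
            return 2.0 * np.exp(-0.5 * ((t - 0.02) / 0.008) ** 2)

        times, s = drive(eng, pulse, t_total=0.42, sample_nodes=(mid,),
                         sample_every=2e-3)
        a = s[mid] - s[mid][0]
        incident = a[times < 0.27].max()
        # reflection travels the extra 2*(80-60) cm; gate out the incident tail
        refl = a[times > 0.28].max()
        assert refl / incident == pytest.approx(1.0 / 3.0, rel=0.10)


class TestWindkesselLimit:
    def test_short_rigid_tube_reproduces_0d_windkessel(self):
        r1, r2, ct = 0.3, 1.2, 1.0
        tree = uniform_tube(length=2.0, area=4.0, p1=4000.0, r1=r1, r2=r2, ct=ct)
        eng = Engine(tree, dx_target=1.0, p_init=40.0)
        term = WindkesselTerminal(r1=r1, r2=r2, ct=ct, pc=40.0)

        period = 0.8
        n, dt = eng.steps_for(period)
        t = np.arange(n) * dt
        q = np.where(t < 0.3, 70 * np.pi / (2 * 0.3) * np.sin(np.pi * t / 0.3), 0.0)
        for _ in range(12):
            rec = eng.run_cycle(mode=0, period=period, qin_series=q)
            p0d = np.array([windkessel_step(term, qi, dt) for qi in q])
        # compare pressure waveforms over the last cycle
        err = np.abs(rec["p_root"] - p0d) / p0d.max()
        assert err.max() < 0.03


class TestConvergence:
    def test_halving_dt_changes_summaries_below_half_percent(self, baseline_tree):
        from stenoflow.experiments import BASELINE, _case_config
        from stenoflow.simulator import run_to_periodic, summarize

        cfg, _, _ = _case_config(BASELINE, 0.6, kvo=0.45, tree=baseline_tree)
        out = {}
        for cfl in (0.5, 0.25):
            cfg.cfl = cfl
            wf = run_to_periodic(cfg, tree=baseline_tree)
            out[cfl] = summarize(wf)
        assert out[0.25].mean_tpg == pytest.approx(out[0.5].mean_tpg, rel=5e-3)
        assert out[0.25].sv == pytest.approx(out[0.5].sv, rel=5e-3)
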