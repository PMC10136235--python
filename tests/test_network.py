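"""Wall law, Windkessel elements, tree validation and afterload algebra."""

import numpy as np
import pandas as pd
import pytest

from stenoflow.network import (ArterialSegment, ArterialTree, WindkesselTerminal,
                               amax_from_reference, langewouters_area,
                               langewouters_compliance, langewouters_pressure,
                               windkessel_step)


def simple_tree(r1=0.2, r2=1.8, ct=0.5, n_terminals=2):
    segs = [ArterialSegment(id=0, parent_id=None, length=10.0, area_prox=5.0,
                            area_dist=4.5, p0=70.0, p1=50.0)]
    for k in range(n_terminals):
        segs.append(ArterialSegment(
            id=k + 1, parent_id=0, length=10.0, area_prox=2.0, area_dist=1.8,
            p0=70.0, p1=60.0,
            terminal=WindkesselTerminal(r1=r1, r2=r2, ct=ct)))
    return ArterialTree(segs)


class TestLangewouters:
    def test_inflection_is_half_max(self):
        assert langewouters_area(70.0, 4.0, 70.0, 50.0) == pytest.approx(2.0)

    def test_asymptote(self):
        assert langewouters_area(1e9, 4.0, 70.0, 50.0) == pytest.approx(4.0, rel=1e-6)

    def test_strictly_increasing(self):
        p = np.linspace(-50, 300, 500)
        a = langewouters_area(p, 4.0, 70.0, 50.0)
        assert np.all(np.diff(a) > 0)

    def test_compliance_matches_finite_difference(self):
        # dA/dP at P0 = Amax/(pi*P1); centered difference oracle
        amax, p0, p1 = 4.0, 70.0, 50.0
        h = 1e-4
        fd = (langewouters_area(p0 + h, amax, p0, p1)
              - langewouters_area(p0 - h, amax, p0, p1)) / (2 * h)
        analytic = langewouters_compliance(p0, amax, p0, p1)
        assert analytic == pytest.approx(amax / (np.pi * p1), rel=1e-12)
        assert analytic == pytest.approx(fd, rel=1e-6)

    def test_pressure_inverts_area(self):
        amax, p0, p1 = 4.0, 70.0, 50.0
        a = langewouters_area(113.0, amax, p0, p1)
        assert langewouters_pressure(a, amax, p0, p1) == pytest.approx(113.0, rel=1e-10)

    def test_reference_area_recovery(self):
        amax = amax_from_reference(5.3, 70.0, 50.0)
        assert langewouters_area(95.0, amax, 70.0, 50.0) == pytest.approx(5.3)


class TestWindkessel:
    def test_steady_asymptote(self):
        term = WindkesselTerminal(r1=0.1, r2=0.9, ct=1.5, pc=0.0)
        p = 0.0
        for _ in range(200000):
            p = windkessel_step(term, 100.0, 1e-3)
        assert p == pytest.approx(100.0 * (0.1 + 0.9), rel=1e-3)

    def test_exponential_decay_time_constant(self):
        # Q = 0 from P0: Pc(t) = P0*exp(-t/(R2*Ct)); implicit update oracle
        r2, ct, p0 = 0.9, 1.5, 80.0
        term = WindkesselTerminal(r1=0.1, r2=r2, ct=ct, pc=p0)
        dt, t_end = 1e-5, 1.0
        for _ in range(int(t_end / dt)):
            windkessel_step(term, 0.0, dt)
        assert term.pc == pytest.approx(p0 * np.exp(-t_end / (r2 * ct)), rel=1e-3)

    def test_proximal_resistor_acts_instantly(self):
        term = WindkesselTerminal(r1=0.25, r2=0.9, ct=1.5, pc=50.0)
        p = windkessel_step(term, 100.0, 1e-9)
        assert p == pytest.approx(50.0 + 100.0 * 0.25, rel=1e-6)

    def test_rejects_nonpositive_elements(self):
        with pytest.raises(ValueError):
            WindkesselTerminal(r1=0.0, r2=1.0, ct=1.0)


class TestTreeValidation:
    def test_valid_tree_loads(self):
        t = simple_tree()
        assert t.n_segments() == 3
        assert len(t.terminals) == 2

    def test_rejects_two_roots(self):
        segs = [ArterialSegment(id=0, parent_id=None, length=5, area_prox=5,
                                area_dist=5, p0=70, p1=50,
                                terminal=WindkesselTerminal(0.1, 1.0, 1.0)),
                ArterialSegment(id=1, parent_id=None, length=5, area_prox=5,
                                area_dist=5, p0=70, p1=50,
                                terminal=WindkesselTerminal(0.1, 1.0, 1.0))]
        with pytest.raises(ValueError, match="exactly one root"):
            ArterialTree(segs)

    def test_rejects_unknown_parent(self):
        segs = [ArterialSegment(id=0, parent_id=7, length=5, area_prox=5,
                                area_dist=5, p0=70, p1=50,
                                terminal=WindkesselTerminal(0.1, 1.0, 1.0))]
        with pytest.raises(ValueError):
            ArterialTree(segs)

    def test_rejects_leaf_without_terminal(self):
        segs = [ArterialSegment(id=0, parent_id=None, length=5, area_prox=5,
                                area_dist=5, p0=70, p1=50)]
        with pytest.raises(ValueError, match="Windkessel"):
            ArterialTree(segs)

    def test_rejects_negative_length(self):
        with pytest.raises(ValueError, match="length"):
            ArterialSegment(id=0, parent_id=None, length=-1, area_prox=5,
                            area_dist=5, p0=70, p1=50)

    def test_csv_roundtrip(self, tmp_path):
        t = simple_tree()
        path = tmp_path / "tree.csv"
        t.save(path, header_comment="synthetic test tree")
        t2 = ArterialTree.load(path)
        pd.testing.assert_frame_equal(t.to_frame(), t2.to_frame())

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            ArterialTree.from_frame(pd.DataFrame({"id": [0]}))


class TestAfterloadAlgebra:
    def test_parallel_resistance(self):
        # two identical terminals of (R1+R2) = 2 -> TVR = 1
        t = simple_tree(r1=0.2, r2=1.8, ct=0.5)
        tvr, _ = t.aggregate_afterload()
        assert tvr == pytest.approx(1.0, rel=1e-12)

    def test_rigid_vessels_leave_terminal_compliance(self):
        t = simple_tree(ct=0.5)
        for s in t.segments.values():
            s.p1 = 1e9  # essentially rigid walls
        _, tac = t.aggregate_afterload()
        assert tac == pytest.approx(1.0, rel=1e-4)

    def test_compliance_linearity(self):
        t = simple_tree()
        _, tac0 = t.aggregate_afterload()
        t2 = t.copy()
        for s in t2.segments.values():
            s.area_prox *= 2
            s.area_dist *= 2
            if s.terminal:
                s.terminal.ct *= 2
        _, tac2 = t2.aggregate_afterload()
        assert tac2 == pytest.approx(2 * tac0, rel=1e-9)

    def test_scale_identity(self):
        t = simple_tree()
        tvr0, tac0 = t.aggregate_afterload()
        t2 = t.scale_afterload(tvr0, tac0)
        tvr, tac = t2.aggregate_afterload()
        assert tvr == pytest.approx(tvr0, rel=1e-9)
        assert tac == pytest.approx(tac0, rel=1e-9)

    def test_scale_doubles_every_resistance(self):
        t = simple_tree()
        tvr0, tac0 = t.aggregate_afterload()
        t2 = t.scale_afterload(2 * tvr0, tac0)
        for sid, term in t2.terminals.items():
            assert term.r1 == pytest.approx(2 * t.terminals[sid].r1, rel=1e-12)
            assert term.r2 == pytest.approx(2 * t.terminals[sid].r2, rel=1e-12)

    def test_tac_target_recovery(self):
        t = simple_tree()
        t2 = t.scale_afterload(1.0, 1.7)
        _, tac = t2.aggregate_afterload()
        assert abs(tac - 1.7) / 1.7 < 0.005

    def test_rejects_out_of_range_targets(self):
        t = simple_tree()
        with pytest.raises(ValueError, match="outside bounds"):
            t.scale_afterload(10.0, 1.0)
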