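"""Shared fixtures: generated geometries and cached expensive runs."""

import pytest

from stenoflow.experiments import BASELINE, _calibrated_kvo
from stenoflow.fixtures import patient_fixture, tree24
from stenoflow.simulator import calibrate_case, run_to_periodic


@pytest.fixture(scope="session")
def tree():
    """Default synthetic 24-segment tree (deterministic, seed 0)."""
    return tree24()


@pytest.fixture(scope="session")
def baseline_tree(tree):
    """Tree scaled to the baseline afterload (TVR 1.0, TAC 1.2)."""
    return tree.scale_afterload(BASELINE["tvr"], BASELINE["tac"])


@pytest.fixture(scope="session")
def kvo_by_ava(tree):
    """Valve rate coefficients calibrated at the sweep baseline per AVA level."""
    return {ava: _calibrated_kvo(BASELINE, ava, tree) for ava in (0.6, 1.0, 1.5, 2.0)}


@pytest.fixture(scope="session")
def kvo_060(kvo_by_ava):
    return kvo_by_ava[0.6]


@pytest.fixture(scope="session")
def dekker_case(baseline_tree):
    """Converged severe-stenosis patient run (Ees 3.3, AVA 0.6)."""
    cfg = patient_fixture("dekker_av_stenosis")
    cfg.geometry = baseline_tree
    wf = run_to_periodic(cfg)
    return cfg, wf


@pytest.fixture(scope="session")
def calibrated_baseline_case(tree, kvo_060):
    """Baseline sweep case at AVA 0.6, afterload-calibrated."""
    from stenoflow.experiments import _case_config

    cfg, tvr_t, tac_t = _case_config(BASELINE, 0.6, kvo_060, tree)
    return calibrate_case(cfg, tvr_t, tac_t)
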