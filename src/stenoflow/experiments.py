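"""In-silico sensitivity study of the mean transvalvular gradient.

Reproduces the study design around the coupled simulator: each
determinant of the mean TPG (contractility Ees, diastolic stiffness
Eed, total vascular resistance TVR, total arterial compliance TAC) is
swept over its physiological range with 10 evenly spaced values while
everything else is held at baseline, independently at each aortic-valve
area level; an additional sweep co-varies TAC with TVR along their
hyperbolic coupling.  Ordinary least squares then quantifies the effect
of each determinant on the mean TPG, reported both per natural unit and
per 10% increase from the lowest (baseline) sweep value, where "per
10%" counts compounding 10% increments, i.e. the regressor is
k = ln(x/x_min)/ln(1.1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cardiac import CardiacParams
from .simulator import (SimulationConfig, calibrate_case, calibrate_valve_rates,
                        summarize)
from .valve import ValveParams

log = logging.getLogger(__name__)

#: held-fixed baseline values for the sweeps (mid-physiological; the
#: cardiac-side baselines follow the validated patient)
BASELINE = {
    "ees": 2.0,    # mmHg/mL
    "eed": 0.1,    # mmHg/mL
    "tvr": 1.0,    # mmHg*s/mL
    "tac": 1.2,    # mL/mmHg
    "t_hp": 0.8,   # s
    "lvedp": 11.0,  # mmHg
    "vd": 39.3,    # mL
}

#: sweep ranges: (lo, hi), 10 evenly spaced values
SWEEP_RANGES = {
    "ees": (0.5, 6.0),
    "eed": (0.03, 0.31),
    "tvr": (0.6, 1.8),
    "tac": (0.5, 2.0),
}

AVA_LEVELS = (0.6, 1.0, 1.5, 2.0)


@dataclass
class SweepSpec:
    """One univariate sweep across AVA levels."""

    param: str
    lo: float
    hi: float
    n: int = 10
    ava_levels: tuple = AVA_LEVELS
    baseline: dict = field(default_factory=lambda: dict(BASELINE))
    coupling: str = "none"  # 'none' | 'hyperbolic'

    def __post_init__(self) -> None:
        if self.param not in SWEEP_RANGES:
            raise ValueError(f"unknown sweep parameter {self.param!r}")
        if not self.lo < self.hi:
            raise ValueError("need lo < hi")
        if self.n < 3:
            raise ValueError("need at least 3 sweep points")
        if self.coupling not in ("none", "hyperbolic"):
            raise ValueError(f"unknown coupling {self.coupling!r}")

    @property
    def values(self) -> np.ndarray:
        return np.linspace(self.lo, self.hi, self.n)

    @property
    def label(self) -> str:
        return self.param + ("_coupled" if self.coupling == "hyperbolic" else "")


def default_sweeps() -> list[SweepSpec]:
    """The study's sweep plan: four univariate sweeps x four AVA levels
    (160 cases) plus the hyperbolically coupled afterload sweep (40 cases)."""
    specs = [SweepSpec(p, *SWEEP_RANGES[p]) for p in ("ees", "eed", "tvr", "tac")]
    specs.append(SweepSpec("tvr", *SWEEP_RANGES["tvr"], coupling="hyperbolic"))
    return specs


def hyperbolic_couple(tvr: float, constant: float | None = None) -> float:
    """TAC implied by TVR along the hyperbolic coupling TAC*TVR = constant.

    The constant defaults to the baseline product, so the coupled sweep
    passes through the baseline state.
    """
    if tvr <= 0:
        raise ValueError("TVR must be positive")
    if constant is None:
        constant = BASELINE["tvr"] * BASELINE["tac"]
    return constant / tvr


@dataclass
class RegressionResult:
    """OLS effect of a determinant on mean TPG."""

    beta: float  # per natural unit
    se: float
    p: float
    beta_per_10pct: float  # mmHg per 10% (compounding) increase from the lowest value
    per10_se: float
    per10_p: float
    n: int
    r2: float
    baseline: float  # lowest sweep value, the 10%-scaling reference


def _ols(x: np.ndarray, y: np.ndarray):
    X = sm.add_constant(np.asarray(x, dtype=float))
    fit = sm.OLS(np.asarray(y, dtype=float), X).fit()
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    p = float(fit.pvalues[1])
    if not np.isfinite(se) or se == 0.0:  # perfect fit: floor SE, cap p
        se = 1e-12
        p = 1e-300
    return beta, se, max(p, 1e-300), float(fit.rsquared)


def ols_fit(x, y) -> RegressionResult:
    """OLS of mean TPG on a determinant, per-unit and per-10%-increment.

    The per-10% effect regresses y on the number of compounding 10%
    increases from the lowest x, k = ln(x/x_min)/ln(1.1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need n >= 3 paired observations")
    if np.ptp(x) == 0.0:
        raise ValueError("regressor is constant (rank deficient)")
    beta, se, p, r2 = _ols(x, y)
    x0 = float(np.min(x))
    if x0 > 0:
        k = np.log(x / x0) / np.log(1.1)
        b10, se10, p10, _ = _ols(k, y)
    else:  # a percentage scale needs a positive baseline
        b10 = se10 = p10 = np.nan
    return RegressionResult(beta=beta, se=se, p=p, beta_per_10pct=b10,
                            per10_se=se10, per10_p=p10, n=int(x.size),
                            r2=r2, baseline=x0)


def per10_beta(x, y) -> float:
    """Shorthand: the per-10%-increment OLS effect alone."""
    return ols_fit(x, y).beta_per_10pct


# ----------------------------------------------------------------------
# sweep execution
# ----------------------------------------------------------------------
def _case_config(baseline: dict, ava: float, kvo: float,
                 tree) -> tuple[SimulationConfig, float, float]:
    cardiac = CardiacParams(ees=baseline["ees"], eed=baseline["eed"],
                            t_hp=baseline["t_hp"], t_max=0.44 * baseline["t_hp"],
                            lvedp=baseline["lvedp"], vd=baseline["vd"])
    valve = ValveParams(ames=ava, ao=None, kvo=kvo)
    cfg = SimulationConfig(cardiac=cardiac, valve=valve, geometry=tree)
    return cfg, baseline["tvr"], baseline["tac"]


def _calibrated_kvo(baseline: dict, ava: float, tree) -> float:
    cfg, tvr_t, tac_t = _case_config(baseline, ava, kvo=1.0, tree=tree)
    cfg.geometry = tree.scale_afterload(tvr_t, tac_t)
    cfg.valve = replace(cfg.valve, kvo=None, kvc=None)
    return calibrate_valve_rates(cfg)


RESULT_COLUMNS = ["param", "value", "ava_cm2", "mean_tpg_mmhg", "max_tpg_mmhg",
                  "sv_ml", "co_ml_s", "map_mmhg", "sbp_mmhg", "dbp_mmhg",
                  "pp_mmhg", "ejection_time_s", "acceleration_time_s",
                  "achieved_tvr", "achieved_tac"]


def run_sweep(spec: SweepSpec, tree, kvo: float | dict | None = None,
              max_failure_fraction: float = 0.2) -> pd.DataFrame:
    """Run one sweep: a calibrated, converged simulation per grid point.

    Every case re-converges the arterial tree so that the held-fixed
    afterload matches its set value within 1%.  The valve opening rate
    is calibrated once per AVA level at the sweep baseline (same
    ejection-time argument as a per-patient calibration) unless given.
    Individual case failures are logged and excluded; more than
    ``max_failure_fraction`` failing aborts the sweep.
    """
    rows = []
    failures = 0
    total = 0
    for ava in spec.ava_levels:
        if kvo is None:
            kvo_ava = _calibrated_kvo(spec.baseline, ava, tree)
        elif isinstance(kvo, dict):
            kvo_ava = kvo.get(ava) or _calibrated_kvo(spec.baseline, ava, tree)
        else:
            kvo_ava = kvo
        for v in spec.values:
            total += 1
            base = dict(spec.baseline)
            if spec.param in ("ees", "eed"):
                base[spec.param] = float(v)
            elif spec.param == "tvr":
                base["tvr"] = float(v)
                if spec.coupling == "hyperbolic":
                    base["tac"] = hyperbolic_couple(float(v))
            elif spec.param == "tac":
                base["tac"] = float(v)
            try:
                cfg, tvr_t, tac_t = _case_config(base, ava, kvo_ava, tree)
                _, wf = calibrate_case(cfg, tvr_t, tac_t)
                s = summarize(wf)
            except Exception as exc:  # pragma: no cover - defensive
                failures += 1
                log.warning("sweep case %s=%.4g AVA=%.2f failed: %s",
                            spec.param, v, ava, exc)
                continue
            rows.append({
                "param": spec.label, "value": float(v), "ava_cm2": float(ava),
                "mean_tpg_mmhg": s.mean_tpg, "max_tpg_mmhg": s.max_tpg,
                "sv_ml": s.sv, "co_ml_s": s.co, "map_mmhg": s.map,
                "sbp_mmhg": s.sbp, "dbp_mmhg": s.dbp, "pp_mmhg": s.pp,
                "ejection_time_s": s.ejection_time,
                "acceleration_time_s": s.acceleration_time,
                "achieved_tvr": s.achieved_tvr, "achieved_tac": s.achieved_tac,
            })
    if failures > max_failure_fraction * total:
        raise RuntimeError(f"sweep aborted: {failures}/{total} cases failed")
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def sv_tpg_curve(ava: float, ees_grid, tree, baseline: dict | None = None,
                 kvo: float | None = None) -> pd.DataFrame:
    """(SV, mean TPG) pairs generated by varying contractility at fixed AVA."""
    base = dict(BASELINE if baseline is None else baseline)
    spec = SweepSpec("ees", float(np.min(ees_grid)), float(np.max(ees_grid)),
                     n=len(ees_grid), ava_levels=(ava,), baseline=base)
    df = run_sweep(spec, tree, kvo=kvo)
    out = df[["sv_ml", "mean_tpg_mmhg", "value", "ava_cm2"]].sort_values("sv_ml")
    return out.reset_index(drop=True)


def bp_tpg_map(tac_grid, tvr_grid, tree, baseline: dict | None = None,
               kvo: float | None = None) -> pd.DataFrame:
    """Full-factorial afterload map: (TAC, TVR) -> (SBP, MBP, mean TPG).

    Demonstrates that distinct mean gradients can hide behind comparable
    peripheral pressures when compliance and resistance trade off.
    """
    base = dict(BASELINE if baseline is None else baseline)
    ava = 0.6
    kvo_ava = kvo if kvo is not None else _calibrated_kvo(base, ava, tree)
    rows = []
    for tac in tac_grid:
        for tvr in tvr_grid:
            b = dict(base)
            b["tac"], b["tvr"] = float(tac), float(tvr)
            cfg, tvr_t, tac_t = _case_config(b, ava, kvo_ava, tree)
            _, wf = calibrate_case(cfg, tvr_t, tac_t)
            s = summarize(wf)
            rows.append({"tac": float(tac), "tvr": float(tvr), "sbp_mmhg": s.sbp,
                         "mbp_mmhg": s.mbp, "mean_tpg_mmhg": s.mean_tpg,
                         "sv_ml": s.sv})
    return pd.DataFrame(rows)


def table1_report(results: pd.DataFrame) -> pd.DataFrame:
    """Per-determinant, per-AVA sensitivity table.

    ``results`` is the concatenated output of the default sweeps.  Rows:
    Ees, Eed, TAC, TVR and the coupled (adjusted) TVR; one column block
    per AVA with the per-10% beta, its SE and p-value.
    """
    order = ["ees", "eed", "tac", "tvr", "tvr_coupled"]
    rows = []
    for param in order:
        sub = results[results["param"] == param]
        if sub.empty:
            continue
        for ava in sorted(sub["ava_cm2"].unique()):
            cell = sub[sub["ava_cm2"] == ava]
            r = ols_fit(cell["value"].to_numpy(), cell["mean_tpg_mmhg"].to_numpy())
            rows.append({"param": param, "ava_cm2": float(ava),
                         "beta_per_10pct": r.beta_per_10pct,
                         "se": r.per10_se, "p": r.per10_p,
                         "beta_per_unit": r.beta, "se_per_unit": r.se,
                         "n": r.n, "baseline_value": r.baseline})
    return pd.DataFrame(rows)


def format_table1(table: pd.DataFrame) -> str:
    """Human-readable rendering of :func:`table1_report`."""
    lines = ["Effect of each determinant on mean TPG (mmHg per 10% increase "
             "from the lowest value)"]
    for param, sub in table.groupby("param", sort=False):
        cells = [f"AVA {r.ava_cm2:.1f}: {r.beta_per_10pct:+.2f} +/- {r.se:.2f} "
                 f"(p={r.p:.3g})" for r in sub.itertuples()]
        lines.append(f"  {param:12s} " + " | ".join(cells))
    return "\n".join(lines)
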