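"""Time-varying elastance model of the left ventricle.

The ventricle is represented by a prescribed periodic elastance E(t)
acting on the volume above an unstressed ("dead") volume Vd:

    P_LV(t) = E(t) * (V_LV(t) - Vd)
    E(t)    = (Ees - Eed) * E_N(t / t_max) + Eed

with Ees the end-systolic elastance (contractility), Eed the
end-diastolic elastance (diastolic stiffness), and E_N a normalized
elastance curve rising from 0 at end-diastole to 1 at the time of
maximum elastance t_max.

The normalized curve is a double-Hill ("activation x relaxation")
waveform, a standard smooth surrogate for tabulated human normalized
elastance data:

    E_N(tau) = k * [tau^n1 / (1 + tau^n1)] * [1 / (1 + (tau/tau2)^n2)]

where tau = t/t_max.  tau2 is chosen in closed form so the maximum sits
exactly at tau = 1 and k normalizes that maximum to 1.  E_N(0) = 0 by
construction.

Diastolic filling, which the elastance model itself does not supply, is
closed by a constant-pressure atrium behind a linear diode resistance;
the atrial pressure can be auto-tuned so that the simulated end-diastolic
pressure honours the prescribed LVEDP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class NormalizedElastanceCurve:
    """Normalized elastance E_N(tau), tau = t/t_max, max 1 at tau = 1.

    Parameters
    ----------
    n1, n2:
        Hill exponents of the activation (rising) and relaxation
        (falling) factors.
    period:
        Curve period in tau units (t_HP / t_max); evaluation wraps
        into one period.
    """

    n1: float = 1.32
    n2: float = 21.9
    period: float = 0.8 / 0.35
    tau2: float = field(init=False)
    k: float = field(init=False)

    def __post_init__(self) -> None:
        if self.n1 <= 0 or self.n2 <= 0 or self.period <= 1.0:
            raise ValueError("need n1, n2 > 0 and period > 1 (in t_max units)")
        # Stationarity of log E_N at tau = 1:
        #   n1/(1 + 1) = n2 * r/(1 + r),  r = (1/tau2)^n2
        r = 1.0 / (2.0 * self.n2 / self.n1 - 1.0)
        self.tau2 = r ** (-1.0 / self.n2)
        self.k = (1.0 + 1.0) / 1.0 * (1.0 + r)

    def __call__(self, t_norm):
        return normalized_elastance(t_norm, self.n1, self.n2, self.tau2, self.k, self.period)


def normalized_elastance(t_norm, n1=1.32, n2=21.9, tau2=None, k=None, period=0.8 / 0.24):
    """Evaluate the normalized double-Hill elastance curve.

    ``t_norm`` is time over time-of-maximum-elastance; values are wrapped
    into one period.  Returns values in [0, 1], exactly 1 at ``t_norm = 1``
    and exactly 0 at ``t_norm = 0``.
    """
    if tau2 is None or k is None:
        r = 1.0 / (2.0 * n2 / n1 - 1.0)
        tau2 = r ** (-1.0 / n2)
        k = 2.0 * (1.0 + r)
    tau = np.mod(np.asarray(t_norm, dtype=float), period)
    h1 = tau**n1 / (1.0 + tau**n1)
    h2 = 1.0 / (1.0 + (tau / tau2) ** n2)
    out = k * h1 * h2
    # guard against round-off pushing the peak a hair above 1
    out = np.clip(out, 0.0, 1.0)
    if np.ndim(t_norm) == 0:
        return float(out)
    return out


@dataclass
class CardiacParams:
    """Left-ventricle parameter set.

    Units: elastances mmHg/mL, times s, pressures mmHg, volumes mL,
    resistances mmHg*s/mL.  ``atrial_pressure=None`` requests automatic
    tuning so end-diastolic LV pressure matches ``lvedp``.
    """

    ees: float = 2.0
    eed: float = 0.1
    t_hp: float = 0.8
    # peak-elastance time: ~44% of the cycle.  With the sharp double-Hill
    # relaxation, ejection ends just after the elastance peak, so this places
    # the ejection time at ~0.34 s at 75 bpm - the prolonged LVET typical of
    # the severe-aortic-stenosis population this model targets.
    t_max: float = 0.35
    lvedp: float = 11.0
    vd: float = 39.3
    atrial_pressure: float | None = None
    mitral_resistance: float = 0.01
    curve: NormalizedElastanceCurve | None = None

    def __post_init__(self) -> None:
        if not (self.ees > self.eed > 0.0):
            raise ValueError(f"require Ees > Eed > 0, got Ees={self.ees}, Eed={self.eed}")
        if not (0.0 < self.t_max < self.t_hp):
            raise ValueError("require 0 < t_max < t_hp")
        if self.vd < 0.0:
            raise ValueError("dead volume must be non-negative")
        if self.lvedp <= 0.0:
            raise ValueError("LVEDP must be positive")
        if self.mitral_resistance <= 0.0:
            raise ValueError("mitral resistance must be positive")
        if self.curve is None:
            self.curve = NormalizedElastanceCurve(period=self.t_hp / self.t_max)

    @property
    def edv(self) -> float:
        """End-diastolic volume implied by inverting P = Eed*(V - Vd)."""
        return self.lvedp / self.eed + self.vd

    def to_dict(self) -> dict:
        return {
            "ees": self.ees,
            "eed": self.eed,
            "t_hp": self.t_hp,
            "t_max": self.t_max,
            "lvedp": self.lvedp,
            "vd": self.vd,
            "atrial_pressure": self.atrial_pressure,
            "mitral_resistance": self.mitral_resistance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CardiacParams":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


def elastance_at(t: float, p: CardiacParams):
    """Instantaneous elastance E(t) in mmHg/mL; periodic in t_hp."""
    t_wrapped = np.mod(t, p.t_hp)
    en = p.curve(t_wrapped / p.t_max)
    return (p.ees - p.eed) * en + p.eed


def lv_pressure(t: float, v: float, p: CardiacParams):
    """Instantaneous LV pressure P = E(t)*(V - Vd), mmHg.

    Raises for V < Vd (non-physical state: the elastance model has no
    meaning below the dead volume).
    """
    if np.any(np.asarray(v) < p.vd):
        raise ValueError(f"LV volume {v} below dead volume {p.vd} mL")
    return elastance_at(t, p) * (v - p.vd)


def mitral_inflow(p_lv: float, p: CardiacParams) -> float:
    """Diode-like mitral inflow from the constant-pressure atrium, mL/s."""
    pa = p.atrial_pressure if p.atrial_pressure is not None else p.lvedp
    return max(0.0, (pa - p_lv) / p.mitral_resistance)


def lv_volume_step(v: float, q_in: float, q_av: float, dt: float) -> float:
    """Advance LV volume one step by mass balance: V' = V + (Qin - Qav)*dt."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    return v + (q_in - q_av) * dt
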