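"""Dynamic stenotic aortic valve model.

The instantaneous transvalvular pressure gradient is the sum of an
inertial term and a turbulent (divergent-loss) Bernoulli term:

    dP = L * dQ/dt + beta * Q * |Q|
    L    = rho * l_eff / A_eff
    beta = Kt * (rho/2) * (1/A_eff - 1/Ao)^2

where A_eff = Ames * zeta(t) is the instantaneous orifice area, Ames the
maximal (measured) valve area, Ao the unobstructed area of the channel
(approximated by the ascending-aorta cross-section) and Kt = 1.5 an
empirical turbulence coefficient.  The valve state zeta in [0, 1] obeys
pressure-driven opening/closing rate laws

    dzeta/dt = (1 - zeta) * Kvo * dP     (dP >= 0, opening)
    dzeta/dt = zeta       * Kvc * dP     (dP <  0, closing)

Public functions accept clinical units (mmHg, mL, s, cm^2); the
returned inertance and Bernoulli coefficient are in mmHg*s^2/mL and
mmHg*s^2/mL^2 respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .units import MMHG, RHO_BLOOD

#: floor on the valve state used to keep L and beta finite when closed
ZETA_MIN = 1e-4


@dataclass
class ValveParams:
    """Stenotic-valve parameter set (clinical units).

    ``ames`` is the maximal valve area (the AVA), cm^2; ``ao`` the
    unobstructed downstream area, cm^2 (``None``: take the root-segment
    area of the attached arterial tree); ``kvo``/``kvc`` the
    opening/closing rate coefficients, 1/(mmHg*s) (``None``: calibrate,
    closing set equal to opening); ``rho`` blood density in g/cm^3.
    """

    ames: float = 0.6
    leff: float = 1.5
    ao: float | None = 5.3
    kt: float = 1.5
    kvo: float | None = 0.3
    kvc: float | None = None
    rho: float = RHO_BLOOD
    zeta_min: float = ZETA_MIN
    #: pure stenosis by default: the valve does not conduct backward
    #: (regurgitation is outside the model's scope)
    allow_backflow: bool = False

    def __post_init__(self) -> None:
        if self.ames <= 0:
            raise ValueError("Ames must be positive")
        if self.ao is not None and self.ames > self.ao:
            raise ValueError(f"Ames={self.ames} exceeds unobstructed area Ao={self.ao}")
        if self.kt <= 0 or self.rho <= 0 or self.leff < 0:
            raise ValueError("require Kt > 0, rho > 0, leff >= 0")
        if self.kvo is not None and self.kvo <= 0:
            raise ValueError("Kvo must be positive")
        if self.kvc is None and self.kvo is not None:
            self.kvc = self.kvo

    def with_ava(self, ava: float) -> "ValveParams":
        return replace(self, ames=ava)

    def to_dict(self) -> dict:
        return {
            "ava_cm2": self.ames,
            "leff_cm": self.leff,
            "ao_cm2": self.ao,
            "kt": self.kt,
            "kvo": self.kvo,
            "kvc": self.kvc,
            "rho": self.rho,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ValveParams":
        keymap = {"ava_cm2": "ames", "leff_cm": "leff", "ao_cm2": "ao"}
        kw = {keymap.get(k, k): v for k, v in d.items()}
        return cls(**{k: v for k, v in kw.items() if k in cls.__dataclass_fields__})


@dataclass
class ValveState:
    """Instantaneous valve state: opening fraction, flow, gradient."""

    zeta: float = 0.0
    q: float = 0.0  # mL/s
    dp: float = 0.0  # mmHg

    def __post_init__(self) -> None:
        if not (0.0 <= self.zeta <= 1.0):
            raise ValueError("zeta must lie in [0, 1]")


def effective_area(zeta: float, ames: float, zeta_min: float = ZETA_MIN) -> float:
    """Instantaneous orifice area A_eff = Ames * max(zeta, zeta_min), cm^2.

    The floor keeps the inertance and Bernoulli coefficient finite when
    the valve is closed; the closed-valve diode rule handles shut-off.
    """
    if not (0.0 <= zeta <= 1.0):
        raise ValueError("zeta must lie in [0, 1]")
    return ames * max(zeta, zeta_min)


def inertance(aeff: float, leff: float, rho: float = RHO_BLOOD) -> float:
    """Blood inertance L = rho*leff/Aeff, returned in mmHg*s^2/mL."""
    if aeff <= 0:
        raise ValueError("Aeff must be positive")
    return rho * leff / aeff / MMHG


def bernoulli_coeff(aeff: float, ao: float, kt: float = 1.5, rho: float = RHO_BLOOD) -> float:
    """Turbulent divergent-loss coefficient, mmHg*s^2/mL^2.

    beta = Kt*(rho/2)*(1/Aeff - 1/Ao)^2; zero when Aeff = Ao.
    """
    if aeff <= 0 or ao <= 0:
        raise ValueError("areas must be positive")
    return kt * (rho / 2.0) * (1.0 / aeff - 1.0 / ao) ** 2 / MMHG


def valve_dp(q: float, dqdt: float, L: float, beta: float) -> float:
    """Instantaneous gradient dP = L*dQ/dt + beta*Q*|Q|, mmHg."""
    return L * dqdt + beta * q * abs(q)


def valve_state_step(zeta: float, dp: float, dt: float, kvo: float, kvc: float) -> float:
    """Advance the valve state one step (explicit Euler), clipped to [0, 1].

    Opening law applies for dp >= 0, closing law for dp < 0 (dp in mmHg,
    rate coefficients in 1/(mmHg*s)).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not (0.0 <= zeta <= 1.0):
        raise ValueError("zeta must lie in [0, 1]")
    if dp >= 0.0:
        rate = (1.0 - zeta) * kvo * dp
    else:
        rate = zeta * kvc * dp
    return float(np.clip(zeta + rate * dt, 0.0, 1.0))


def flow_ode_step(state: ValveState, p_lv: float, p_ao: float, params: ValveParams, dt: float) -> ValveState:
    """Advance transvalvular flow and valve state by one time step.

    The gradient equation is rearranged into an ODE for Q,
    dQ/dt = (dP - beta*Q*|Q|)/L with dP = P_LV - P_ao, integrated
    semi-implicitly (the quadratic drag is linearized about the current
    flow), which is unconditionally stable.  With ``leff = 0`` the
    algebraic form Q = sign(dP)*sqrt(|dP|/beta) is used.  A closed valve
    (zeta <= zeta_min) with adverse gradient acts as a diode: Q = 0.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    dp = p_lv - p_ao
    aeff = effective_area(state.zeta, params.ames, params.zeta_min)
    beta = bernoulli_coeff(aeff, params.ao, params.kt, params.rho)
    if params.leff > 0:
        L = inertance(aeff, params.leff, params.rho)
        q_new = (state.q + dt * dp / L) / (1.0 + dt * beta * abs(state.q) / L)
    else:
        q_new = np.sign(dp) * np.sqrt(abs(dp) / beta) if beta > 0 else state.q
    if state.zeta <= params.zeta_min and dp < 0.0:
        q_new = 0.0
    if not params.allow_backflow and q_new < 0.0:
        q_new = 0.0
    zeta_new = valve_state_step(state.zeta, dp, dt, params.kvo, params.kvc)
    return ValveState(zeta=zeta_new, q=float(q_new), dp=float(dp))


def calibrate_valve_rates(config, growth: float = 1.25, kvo_seed: float = 0.01,
                          kvo_cap: float = 1e3, target: float = 0.999):
    """Find the smallest opening-rate coefficient that fully opens the valve.

    Runs the coupled simulation on a geometric grid of Kvo values
    (``kvo_seed * growth**k``) and returns the first one for which the
    valve state reaches ``target`` during the cycle; the closing
    coefficient is set equal to the opening one.  Delegates to the
    coupled simulator (imported lazily to avoid a circular import).
    """
    from .simulator import calibrate_valve_rates as _impl

    return _impl(config, growth=growth, kvo_seed=kvo_seed, kvo_cap=kvo_cap, target=target)
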