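"""Drug concentration profiles from intravenous dosing regimens.

A linear two-compartment disposition model with first-order elimination and
zero-order infusion generates dazukibart serum concentration over time; the
unbound-IFN-beta fraction fed to the response model is obtained by composing
with :func:`dmer.model_core.punbound`.  Profiles are exact biexponential
superpositions, linear in dose.

The binding constant ``K_SS`` is the only PK-layer scalar the response layer
depends on; disposition parameters are configurable typical-monoclonal values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import punbound

HOURS_PER_WEEK = 168.0

__all__ = ["PKParams", "Regimen", "concentration", "punbound_profile"]


@dataclass
class PKParams:
    """Two-compartment IV parameters (time unit: weeks).

    CL : clearance (L/week); V1, V2 : central/peripheral volumes (L);
    Q : intercompartmental clearance (L/week); K_SS : IFN-beta quasi-steady
    state binding constant (ug/mL).
    """

    CL: float = 1.6
    V1: float = 3.5
    V2: float = 2.6
    Q: float = 4.9
    K_SS: float = 1.0

    def __post_init__(self):
        for name in ("CL", "V1", "V2", "Q", "K_SS"):
            if not getattr(self, name) > 0:
                raise ValueError(f"PK parameter {name} must be positive")

    def hybrid_constants(self):
        """Macro rate constants (alpha, beta) and k21."""
        k10 = self.CL / self.V1
        k12 = self.Q / self.V1
        k21 = self.Q / self.V2
        s = k10 + k12 + k21
        disc = np.sqrt(s * s - 4.0 * k10 * k21)
        alpha = 0.5 * (s + disc)
        beta = 0.5 * (s - disc)
        return alpha, beta, k21


@dataclass
class Regimen:
    """Intravenous dosing schedule.  Amounts in mg, times in weeks."""

    dose_amounts: list = field(default_factory=list)
    dose_times: list = field(default_factory=list)
    infusion_duration_hr: float = 1.0

    def __post_init__(self):
        amts = np.asarray(self.dose_amounts, dtype=float)
        times = np.asarray(self.dose_times, dtype=float)
        if amts.shape != times.shape:
            raise ValueError("dose_amounts and dose_times must match")
        if len(times) and (np.any(times < 0) or np.any(np.diff(times) <= 0)):
            raise ValueError("dose times must be non-negative, increasing")
        if np.any(amts < 0) or self.infusion_duration_hr < 0:
            raise ValueError("negative dose or infusion duration")

    @property
    def n_doses(self) -> int:
        return len(self.dose_times)

    @classmethod
    def q4w(cls, dose_mg: float, n_doses: int, start_week: float = 0.0,
            infusion_duration_hr: float = 1.0) -> "Regimen":
        """Every-4-weeks IV regimen, e.g. 600 mg Q4W x 3."""
        times = [start_week + 4.0 * k for k in range(n_doses)]
        return cls([dose_mg] * n_doses, times, infusion_duration_hr)

    @classmethod
    def placebo(cls, n_doses: int = 0, start_week: float = 0.0) -> "Regimen":
        return cls.q4w(0.0, n_doses, start_week) if n_doses else cls()


def _infusion_step(t, alpha, beta, k21, V1):
    """Central concentration per unit infusion rate started at t=0 (0 for t<0)."""
    t = np.maximum(t, 0.0)
    ca = (alpha - k21) / (alpha * (alpha - beta))
    cb = (k21 - beta) / (beta * (alpha - beta))
    return (ca * (1.0 - np.exp(-alpha * t)) + cb * (1.0 - np.exp(-beta * t))) / V1


def _bolus(t, alpha, beta, k21, V1):
    """Central concentration per unit dose given as bolus at t=0 (0 for t<0)."""
    live = t >= 0
    t = np.maximum(t, 0.0)
    ca = (alpha - k21) / (alpha - beta)
    cb = (k21 - beta) / (alpha - beta)
    return np.where(live, (ca * np.exp(-alpha * t) + cb * np.exp(-beta * t)) / V1,
                    0.0)


def concentration(params: PKParams, regimen: Regimen, t):
    """Serum concentration (ug/mL) at time(s) ``t`` weeks.

    Doses in mg distribute into volumes in L, giving mg/L == ug/mL.
    Infusions are zero-order over the configured duration; a zero duration
    selects the bolus limit.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    alpha, beta, k21 = params.hybrid_constants()
    C = np.zeros(t.shape if t.ndim else ())
    T = regimen.infusion_duration_hr / HOURS_PER_WEEK
    for amt, td in zip(regimen.dose_amounts, regimen.dose_times):
        if amt == 0:
            continue
        if T == 0:
            C = C + amt * _bolus(t - td, alpha, beta, k21, params.V1)
        else:
            rate = amt / T
            C = C + rate * (_infusion_step(t - td, alpha, beta, k21, params.V1)
                            - _infusion_step(t - td - T, alpha, beta, k21,
                                             params.V1))
    return C if C.ndim else float(C)


def punbound_profile(params: PKParams, regimen: Regimen, times):
    """Unbound IFN-beta fraction along the concentration-time profile.

    Identically 1 under placebo (zero concentration).
    """
    return punbound(concentration(params, regimen, times), params.K_SS)
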