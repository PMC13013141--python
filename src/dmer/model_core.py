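"""Structural exposure-response mathematics.

Every clinical endpoint is modeled as an indirect response variable whose
loss rate is modulated by a shared drive, itself proportional to the
fraction of interferon-beta left unbound by drug:

    P_unbound = 1 - C / (C + K_SS)
    E_shared  = Emax_norm * P_unbound
    dEnd/dt   = k_in - k_out * End * (1 + Emax_m * E_shared)

The observed dermatomyositis baseline is interpreted as an *altered* steady
state: the patient sits at the equilibrium reached under fully unbound IFN-beta
(P_unbound = 1) and a placebo perturbation.  The input rate is therefore
computed from a corrected ("healthy-equilibrium") baseline

    End_base = End_obs * (1 + Emax_m * Emax_norm) * E_plac ** sign(Emax_m)
    k_in     = k_out * End_base

and the trajectory is initialized at the observed baseline.  For a fixed
P_unbound the ODE is linear in End, so a piecewise-constant exposure profile
admits an exact segment-wise solution; that analytic path is the default and
also serves as the oracle for the numerical integrator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "BindingState",
    "EndpointSpec",
    "SharedParams",
    "EndpointState",
    "punbound",
    "eshared",
    "sign0",
    "corrected_baseline",
    "endpoint_rhs",
    "simulate_endpoint",
    "simulate_endpoint_ode",
    "enzyme_observation",
]


def punbound(C, K_SS):
    """Unbound IFN-beta fraction at drug concentration ``C``.

    Parameters
    ----------
    C : float or ndarray
        Drug serum concentration (ug/mL), >= 0.
    K_SS : float
        Quasi-steady-state binding constant (ug/mL), > 0.  The drug
        concentration at half-maximal binding.
    """
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("concentration must be non-negative")
    if not K_SS > 0:
        raise ValueError("K_SS must be strictly positive")
    out = 1.0 - C / (C + K_SS)
    return out if out.ndim else float(out)


def eshared(emax_norm, p_unbound):
    """Shared effect driving every endpoint: Emax_norm * P_unbound."""
    emax_norm = np.asarray(emax_norm, dtype=float)
    p = np.asarray(p_unbound, dtype=float)
    if np.any((emax_norm < 0) | (emax_norm > 1)) or np.any((p < 0) | (p > 1)):
        raise ValueError("eshared inputs must lie in [0, 1]")
    out = emax_norm * p
    return out if out.ndim else float(out)


def sign0(x: float) -> int:
    """Integer sign with sign(0) = 0, used as the E_plac exponent."""
    return (x > 0) - (x < 0)


@dataclass
class BindingState:
    """Drug / IFN-beta binding snapshot (units of IFN arbitrary but shared)."""

    C: float
    K_SS: float
    IFN_total: float = 1.0

    def __post_init__(self):
        if self.C < 0 or self.K_SS <= 0 or self.IFN_total < 0:
            raise ValueError("invalid binding state")

    @property
    def P_unbound(self) -> float:
        return punbound(self.C, self.K_SS)

    @property
    def IFN_unbound(self) -> float:
        return self.IFN_total * self.P_unbound

    @property
    def IFN_bound(self) -> float:
        return self.IFN_total - self.IFN_unbound


@dataclass
class SharedParams:
    """Parameters shared across all endpoints.

    k_out : endpoint turnover rate (week^-1).
    emax_norm : normalizing maximum effect, fraction in (0, 1).
    e_plac : placebo non-steady-state factor (1 = no placebo effect).
    """

    k_out: float
    emax_norm: float
    e_plac: float = 1.0

    def __post_init__(self):
        if not self.k_out > 0:
            raise ValueError("k_out must be positive")
        if not 0 < self.emax_norm < 1:
            raise ValueError("emax_norm must lie in (0, 1)")
        if not self.e_plac > 0:
            raise ValueError("e_plac must be positive")


@dataclass
class EndpointSpec:
    """Static definition of one clinical endpoint.

    ``baseline`` is the typical observed dermatomyositis baseline (score
    units; x ULN for the enzyme endpoint).  ``emax`` in [-1, 1] sets both the
    size and direction of the drug effect; values fixed by design (0, +/-1)
    carry ``emax_fixed=True``.  ``ruv_sd`` is the additive residual SD on the
    modeled scale.
    """

    name: str
    range_lo: float
    range_hi: float
    improvement_direction: str  # "lower" or "higher"
    emax: float
    baseline: float
    ruv_sd: float
    emax_fixed: bool = False
    is_enzyme: bool = False
    iiv_baseline: float = 0.0
    eta_source: str | None = None  # endpoint whose eta is (partly) reused
    eta_scalar: float = 1.0
    eta_own_var: float | None = None  # lone variance when partially shared
    label: str = ""

    def __post_init__(self):
        if not -1.0 <= self.emax <= 1.0:
            raise ValueError(f"{self.name}: emax must lie in [-1, 1]")
        if self.improvement_direction not in ("lower", "higher"):
            raise ValueError(f"{self.name}: bad improvement direction")
        if not self.ruv_sd > 0:
            raise ValueError(f"{self.name}: ruv_sd must be positive")
        if self.is_enzyme:
            if not self.baseline > 0:
                raise ValueError(f"{self.name}: enzyme baseline must be > 0")
        elif not self.range_lo <= self.baseline <= self.range_hi:
            raise ValueError(f"{self.name}: baseline outside score range")


@dataclass
class EndpointState:
    """Dynamic state of one endpoint for one subject."""

    End_m: float
    End_base_m: float
    k_in_m: float
    t: float = 0.0

    @classmethod
    def at_baseline(cls, observed_baseline: float, emax: float,
                    shared: SharedParams) -> "EndpointState":
        base = corrected_baseline(observed_baseline, emax, shared)
        return cls(End_m=observed_baseline, End_base_m=base,
                   k_in_m=shared.k_out * base, t=0.0)


def corrected_baseline(observed_baseline, emax, shared: SharedParams):
    """Healthy-equilibrium baseline backing out maximal IFN-beta and placebo.

    End_base = End_obs * (1 + Emax * Emax_norm) * E_plac ** sign(Emax).
    With Emax = 0 the placebo exponent is 0, so the observed baseline is
    returned unchanged.
    """
    expo = sign0(emax) if np.isscalar(emax) else np.sign(emax)
    return (np.asarray(observed_baseline, dtype=float)
            * (1.0 + np.asarray(emax) * shared.emax_norm)
            * shared.e_plac ** expo)


def endpoint_rhs(state: EndpointState, emax: float, shared: SharedParams,
                 p_unbound: float) -> float:
    """dEnd/dt at the given state for instantaneous unbound fraction."""
    es = shared.emax_norm * p_unbound
    return state.k_in_m - shared.k_out * state.End_m * (1.0 + emax * es)


def _segment_step(E0, k_in, lam, dt):
    """Exact step of dE/dt = k_in - lam*E over dt (lam may be 0)."""
    lam = np.asarray(lam, dtype=float)
    E0 = np.asarray(E0, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        Ess = np.where(lam != 0, k_in / np.where(lam != 0, lam, 1.0), 0.0)
    decay = np.exp(-lam * dt)
    out = np.where(lam != 0, Ess + (E0 - Ess) * decay, E0 + k_in * dt)
    return out


def simulate_endpoint(spec_or_params, shared: SharedParams, times,
                      p_unbound=1.0, observed_baseline=None, emax=None,
                      clip_to_range=False):
    """Endpoint trajectory under a piecewise-constant unbound-fraction profile.

    Parameters
    ----------
    spec_or_params : EndpointSpec or None
        Endpoint definition; alternatively pass ``observed_baseline`` and
        ``emax`` explicitly (individual parameters after eta composition).
    shared : SharedParams
    times : array of weeks, strictly increasing, times[0] is the baseline.
    p_unbound : scalar, or array of len(times) giving the unbound fraction
        held constant on each [times[k], times[k+1]) segment, or a
        ``(breakpoints, values)`` pair with values constant between
        breakpoints.
    clip_to_range : clip the returned trajectory to the score range
        (off by default; the latent state is fitted unbounded).

    Returns the trajectory at ``times``, exact for the piecewise-constant
    profile (the ODE is linear in End for fixed P_unbound).
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing 1-D")
    spec = spec_or_params
    if spec is not None:
        if observed_baseline is None:
            observed_baseline = spec.baseline
        if emax is None:
            emax = spec.emax
    base_corr = corrected_baseline(observed_baseline, emax, shared)
    k_in = shared.k_out * base_corr

    if isinstance(p_unbound, tuple):
        bk, vals = p_unbound
        bk = np.asarray(bk, dtype=float)
        vals = np.asarray(vals, dtype=float)
        grid = np.union1d(times, bk[(bk > times[0]) & (bk < times[-1])])
        idx = np.searchsorted(bk, grid[:-1], side="right") - 1
        seg_p = vals[np.clip(idx, 0, len(vals) - 1)]
    else:
        p_arr = np.broadcast_to(np.asarray(p_unbound, dtype=float),
                                times.shape).copy()
        grid = times
        seg_p = p_arr[:-1]
    if np.any((seg_p < 0) | (seg_p > 1)):
        raise ValueError("p_unbound must lie in [0, 1]")

    lam = shared.k_out * (1.0 + emax * shared.emax_norm * seg_p)
    E = np.empty(len(grid))
    E[0] = observed_baseline
    for k in range(len(grid) - 1):
        E[k + 1] = _segment_step(E[k], k_in, lam[k], grid[k + 1] - grid[k])
    if len(grid) != len(times):
        E = np.interp(times, grid, E)  # exact: times is a subset of grid
    if clip_to_range and spec is not None:
        E = np.clip(E, spec.range_lo, spec.range_hi)
    return E


def simulate_endpoint_ode(spec_or_params, shared: SharedParams, times,
                          p_unbound_fn, observed_baseline=None, emax=None,
                          rtol=1e-8, atol=1e-10):
    """Numerically integrated trajectory for an arbitrary P_unbound(t).

    Adaptive stiff-capable integration (LSODA); raises with the failing time
    point on solver failure.  Used as the general path and cross-checked
    against the analytic solution for piecewise-constant profiles.
    """
    times = np.asarray(times, dtype=float)
    spec = spec_or_params
    if spec is not None:
        if observed_baseline is None:
            observed_baseline = spec.baseline
        if emax is None:
            emax = spec.emax
    base_corr = corrected_baseline(observed_baseline, emax, shared)
    k_in = shared.k_out * base_corr

    def rhs(t, y):
        p = p_unbound_fn(t)
        return [k_in - shared.k_out * y[0] * (1.0 + emax * shared.emax_norm * p)]

    sol = solve_ivp(rhs, (times[0], times[-1]), [observed_baseline],
                    t_eval=times, method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(
            f"endpoint integration failed near t={sol.t[-1]:.3f}: {sol.message}")
    return sol.y[0]


def enzyme_observation(R_pred, epsilon, ruv_sd, ULN):
    """Denormalize the enzyme ULN-ratio state into an observed concentration.

    The model tracks the ratio of the most abnormal enzyme to its upper limit
    of normal; observations are Y = (R + sd*eps) * ULN.
    """
    ULN = np.asarray(ULN, dtype=float)
    if np.any(ULN <= 0):
        raise ValueError("ULN must be strictly positive")
    out = (np.asarray(R_pred, dtype=float)
           + ruv_sd * np.asarray(epsilon, dtype=float)) * ULN
    return out if out.ndim else float(out)
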