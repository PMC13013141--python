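"""Approximate marginal-likelihood estimation for the joint model.

The marginal likelihood over subject-level random effects is approximated by
a Laplace expansion at the per-subject eta mode, with Gauss-Newton curvature
(J' W J + Omega^-1).  The inner mode search is a damped, vectorized
Gauss-Newton over all subjects simultaneously; the outer problem optimizes
the fixed effects on transformed scales (log for positive parameters, logit
for fractions, [-1, 1] effects mapped through logit((x+1)/2), log(theta+1)
for shifted-lognormal baselines).  Residual error follows the fixed-effect
standard-deviation parameterization with unit-variance noise, so the
interaction term of the exact conditional method vanishes and the Laplace
objective is the natural analogue.

Also provides empirical Bayes estimates with eta/epsilon shrinkage, stepwise
covariate testing by likelihood ratio, and multivariate-normal parameter
uncertainty sampling on the transformed scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from . import engine
from .exposure import Regimen
from .params import ENDPOINT_ORDER, ParameterSet
from .population import OmegaSpec

LOG2PI = math.log(2.0 * math.pi)

__all__ = ["EstimationData", "FitResult", "objective", "fit",
           "ebes_and_shrinkage", "covariate_step", "uncertainty_draws",
           "default_free_parameters", "pack", "unpack"]


# ---------------------------------------------------------------------------
# transformed parameter vector

def _tf(kind, x):
    if kind == "log":
        return math.log(x)
    if kind == "logit":
        return logit(x)
    if kind == "emax":
        return logit((x + 1.0) / 2.0)
    if kind == "log1p":
        return math.log(x + 1.0)
    if kind == "logfac":          # percent effects, factor > 0
        return math.log(1.0 + x / 100.0)
    raise KeyError(kind)


def _itf(kind, z):
    if kind == "log":
        return math.exp(z)
    if kind == "logit":
        return float(expit(z))
    if kind == "emax":
        return 2.0 * float(expit(z)) - 1.0
    if kind == "log1p":
        return math.exp(z) - 1.0
    if kind == "logfac":
        return 100.0 * (math.exp(z) - 1.0)
    raise KeyError(kind)


def _param_kind(name: str) -> str:
    if name.startswith(("kout", "ruv_", "omega_", "e_plac")):
        return "log"
    if name == "emax_norm":
        return "logit"
    if name.startswith("emax_"):
        return "emax"
    if name.startswith("base_"):
        return "log1p"
    if name.startswith("cov_"):
        return "logfac"
    raise ValueError(f"unknown parameter {name!r}")


def _get_param(params: ParameterSet, name: str) -> float:
    if name == "kout":
        return params.shared.k_out
    if name == "emax_norm":
        return params.shared.emax_norm
    if name == "e_plac":
        return params.shared.e_plac
    if name == "omega_emax_norm":
        return params.iiv_emax_norm
    if name == "omega_e_plac":
        return params.iiv_e_plac
    kind, _, ep = name.partition("_")
    if kind == "base":
        return params.endpoints[ep].baseline
    if kind == "emax":
        return params.endpoints[ep].emax
    if kind == "ruv":
        return params.endpoints[ep].ruv_sd
    if kind == "omega":
        return params.endpoints[ep].iiv_baseline
    if name.startswith("cov_"):
        parts = name.split("_", 2)
        for c in params.covariates:
            if (parts[1] == "baseline" and c.target == "baseline"
                    and c.endpoint == parts[2]):
                return c.percent
            if parts[1] == "eplac" and c.target == "e_plac":
                return c.percent
        raise KeyError(name)
    raise ValueError(f"unknown parameter {name!r}")


def _set_param(params: ParameterSet, name: str, value: float):
    if name == "kout":
        params.shared.k_out = value
    elif name == "emax_norm":
        params.shared.emax_norm = value
    elif name == "e_plac":
        params.shared.e_plac = value
    elif name == "omega_emax_norm":
        params.iiv_emax_norm = value
    elif name == "omega_e_plac":
        params.iiv_e_plac = value
    elif name.startswith("cov_"):
        parts = name.split("_", 2)
        for c in params.covariates:
            if (parts[1] == "baseline" and c.target == "baseline"
                    and c.endpoint == parts[2]) or \
                    (parts[1] == "eplac" and c.target == "e_plac"):
                c.percent = value
                return
        raise KeyError(name)
    else:
        kind, _, ep = name.partition("_")
        spec = params.endpoints[ep]
        if kind == "base":
            spec.baseline = value
        elif kind == "emax":
            spec.emax = value
        elif kind == "ruv":
            spec.ruv_sd = value
        elif kind == "omega":
            spec.iiv_baseline = value
        else:
            raise ValueError(f"unknown parameter {name!r}")


def pack(params: ParameterSet, names) -> np.ndarray:
    """Fixed effects -> transformed vector."""
    return np.array([_tf(_param_kind(n), _get_param(params, n))
                     for n in names])


def unpack(params: ParameterSet, names, z) -> ParameterSet:
    """Transformed vector -> new ParameterSet (input is not modified)."""
    import copy
    out = copy.deepcopy(params)
    for n, zi in zip(names, z):
        _set_param(out, n, _itf(_param_kind(n), float(zi)))
    return out


def default_free_parameters(params: ParameterSet, panel,
                            include_e_plac: bool = True,
                            include_omega: bool = False) -> list:
    """Conventional free-parameter list for a fit over ``panel``."""
    names = ["kout", "emax_norm"]
    if include_e_plac:
        names.append("e_plac")
    for e in panel:
        spec = params.endpoints[e]
        names.append(f"base_{e}")
        if not spec.emax_fixed:
            names.append(f"emax_{e}")
        names.append(f"ruv_{e}")
        if include_omega and spec.eta_source is None:
            names.append(f"omega_{e}")
    return names


# ---------------------------------------------------------------------------
# data container

@dataclass
class EstimationData:
    """Rectangular observation arrays plus exposure grids for fitting.

    Built from a tidy dataset; enzyme observations are normalized back to
    the ULN-ratio scale (the modeled state).  Missing endpoint/visit cells
    are masked out of the likelihood.
    """

    panel: list
    visits: np.ndarray
    y: np.ndarray                 # (n_sub, n_vis, n_end), NaN = missing
    mask: np.ndarray              # bool, same shape
    dm_type: np.ndarray           # (n_sub,) strings
    p_seg: np.ndarray             # (n_sub, n_seg)
    grid: np.ndarray
    vidx: np.ndarray
    subject_ids: np.ndarray

    @property
    def n_sub(self) -> int:
        return self.y.shape[0]

    @property
    def n_obs(self) -> int:
        return int(self.mask.sum())

    @classmethod
    def from_tidy(cls, data: pd.DataFrame, params: ParameterSet,
                  panel=None, dt: float = 1.0) -> "EstimationData":
        obs = data[data["record"] == "obs"]
        if panel is None:
            panel = [e for e in ENDPOINT_ORDER
                     if e in set(obs["endpoint"])]
        visits = np.array(sorted(obs["time"].unique()))
        sids = np.array(sorted(data["subject"].unique()))
        n, v, m = len(sids), len(visits), len(panel)
        y = np.full((n, v, m), np.nan)
        srow = {s: i for i, s in enumerate(sids)}
        vcol = {t: j for j, t in enumerate(visits)}
        ecol = {e: k for k, e in enumerate(panel)}
        enz = {e for e in panel if params.endpoints[e].is_enzyme}
        for r in obs.itertuples():
            if r.endpoint not in ecol:
                continue
            val = r.value / r.uln if r.endpoint in enz else r.value
            y[srow[r.subject], vcol[r.time], ecol[r.endpoint]] = val
        dm = obs.drop_duplicates("subject").set_index("subject")["dm_type"]
        dm = dm.reindex(sids).to_numpy()

        doses = data[data["record"] == "dose"]
        breaks = sorted(doses["time"].unique()) if len(doses) else []
        grid, vidx = engine.time_grid(visits, dt=dt, extra_breaks=breaks)
        p_seg = np.ones((n, len(grid) - 1))
        for s, g in doses.groupby("subject"):
            g = g.sort_values("time")
            reg = Regimen(g["amount"].tolist(), g["time"].tolist(),
                          params.infusion_duration_hr)
            p_seg[srow[s]] = engine.segment_punbound(params.pk, reg, grid)
        return cls(panel=list(panel), visits=visits, y=y,
                   mask=np.isfinite(y), dm_type=dm, p_seg=p_seg, grid=grid,
                   vidx=vidx, subject_ids=sids)


# ---------------------------------------------------------------------------
# model evaluation

def _eta_layout(params: ParameterSet, panel):
    """Eta dimensions for a panel: block baseline etas (incl. donors of
    shared endpoints), lone own-parts, emax_norm, e_plac.  Dimensions with
    zero variance in the template are dropped (fixed at zero)."""
    sub = params.subset(panel)
    names = [e for e in sub.block_endpoints
             if params.endpoints[e].iiv_baseline > 0]
    lone = []
    for e in panel:
        s = params.endpoints[e]
        if s.eta_source is not None and s.eta_own_var:
            lone.append(f"{e}_own")
    shared_etas = []
    if params.iiv_emax_norm > 0:
        shared_etas.append("emax_norm")
    if params.iiv_e_plac > 0:
        shared_etas.append("e_plac")
    return sub, names, lone, shared_etas


def _omega_matrix(params: ParameterSet, block_names, lone, shared_etas):
    var = np.array([params.endpoints[e].iiv_baseline for e in block_names])
    sd = np.sqrt(var)
    corr = np.full((len(block_names),) * 2, params.block_correlation)
    np.fill_diagonal(corr, 1.0)
    block = corr * np.outer(sd, sd)
    lone_vars = [params.endpoints[n[:-4]].eta_own_var for n in lone]
    if "emax_norm" in shared_etas:
        lone_vars.append(params.iiv_emax_norm)
    if "e_plac" in shared_etas:
        lone_vars.append(params.iiv_e_plac)
    d = len(block_names) + len(lone_vars)
    omega = np.zeros((d, d))
    omega[:len(block_names), :len(block_names)] = block
    if lone_vars:
        omega[len(block_names):, len(block_names):] = np.diag(lone_vars)
    return omega


class _JointModel:
    """Prediction machinery bound to one dataset and one free-parameter set."""

    def __init__(self, data: EstimationData, params: ParameterSet):
        self.data = data
        self.template = params
        self.panel = data.panel
        _, self.block_names, self.lone, self.shared_etas = \
            _eta_layout(params, self.panel)
        self.eta_names = (list(self.block_names) + list(self.lone)
                          + list(self.shared_etas))
        self.d = len(self.eta_names)
        self.is_mpdm = (data.dm_type == "MPDM")

    def omega(self, params: ParameterSet) -> np.ndarray:
        return _omega_matrix(params, self.block_names, self.lone,
                             self.shared_etas)

    def _eta_col(self, name, etas):
        if name in self.eta_names:
            return etas[:, self.eta_names.index(name)]
        return np.zeros(etas.shape[0])

    def _eta_for_endpoint(self, e, params, etas):
        spec = params.endpoints[e]
        if spec.eta_source is None:
            return self._eta_col(e, etas)
        eta = spec.eta_scalar * self._eta_col(spec.eta_source, etas)
        if spec.eta_own_var is not None:
            eta = eta + self._eta_col(f"{e}_own", etas)
        return eta

    def predict(self, params: ParameterSet, etas: np.ndarray) -> np.ndarray:
        """Latent predictions (n_sub, n_vis, n_end) on the modeled scale."""
        d = self.data
        baselines, _, en, ep, _, _ = self._individual(params, etas)
        emax = np.array([params.endpoints[e].emax for e in self.panel])
        return engine.latent_trajectories(
            d.p_seg, d.grid, baselines, emax, en, ep, params.shared.k_out,
            visit_index=d.vidx)

    def sigma(self, params: ParameterSet) -> np.ndarray:
        return np.array([params.endpoints[e].ruv_sd for e in self.panel])

    def _individual(self, params: ParameterSet, etas: np.ndarray):
        """Individual baselines/shared params and the eta->baseline
        coefficient matrix used for analytic Jacobians."""
        d = self.data
        n = d.n_sub
        cov_base = {c.endpoint: c.factor for c in params.covariates
                    if c.covariate == "MPDM" and c.target == "baseline"}
        cov_ep = np.prod([c.factor for c in params.covariates
                          if c.covariate == "MPDM" and c.target == "e_plac"])
        n_end = len(self.panel)
        baselines = np.empty((n, n_end))
        coeff = np.zeros((n_end, self.d))       # eta j -> log-scale weight
        for k, e in enumerate(self.panel):
            spec = params.endpoints[e]
            theta = spec.baseline
            theta_vec = np.where(self.is_mpdm, theta * cov_base.get(e, 1.0),
                                 theta)
            eta = self._eta_for_endpoint(e, params, etas)
            baselines[:, k] = (theta_vec + 1.0) * np.exp(eta) - 1.0
            if spec.eta_source is None:
                if e in self.eta_names:
                    coeff[k, self.eta_names.index(e)] = 1.0
            else:
                if spec.eta_source in self.eta_names:
                    coeff[k, self.eta_names.index(spec.eta_source)] = \
                        spec.eta_scalar
                if spec.eta_own_var is not None and \
                        f"{e}_own" in self.eta_names:
                    coeff[k, self.eta_names.index(f"{e}_own")] = 1.0
        i_en = self.eta_names.index("emax_norm") \
            if "emax_norm" in self.eta_names else None
        i_ep = self.eta_names.index("e_plac") \
            if "e_plac" in self.eta_names else None
        en = expit(logit(params.shared.emax_norm)
                   + self._eta_col("emax_norm", etas))
        ep_typ = np.where(self.is_mpdm, params.shared.e_plac * cov_ep,
                          params.shared.e_plac)
        ep = ep_typ * np.exp(self._eta_col("e_plac", etas))
        return baselines, coeff, en, ep, i_en, i_ep

    def predict_with_jacobian(self, params: ParameterSet, etas: np.ndarray):
        """Predictions and exact Jacobian w.r.t. etas, (n, v, e) and
        (n, v, e, d)."""
        d = self.data
        baselines, coeff, en, ep, i_en, i_ep = self._individual(params, etas)
        emax = np.array([params.endpoints[e].emax for e in self.panel])
        E, dB, den_, dep_ = engine.latent_trajectories_sens(
            d.p_seg, d.grid, baselines, emax, en, ep, params.shared.k_out,
            visit_index=d.vidx)
        # dB is w.r.t. the endpoint's own baseline; baselines respond to
        # etas as dB/deta_j = (B + 1) * coeff[e, j]
        bfac = (baselines + 1.0)                           # (n, e)
        J = (dB[..., None] * (bfac[:, None, :, None]
                              * coeff[None, None, :, :]))
        if i_en is not None:
            J[..., i_en] += den_ * (en * (1.0 - en))[:, None, None]
        if i_ep is not None:
            J[..., i_ep] += dep_ * ep[:, None, None]
        return E, J


def _laplace_terms(model: _JointModel, params: ParameterSet,
                   etas: np.ndarray, max_iter: int = 30,
                   tol: float = 1e-6, newton_from: int = 2,
                   hess_step: float = 1e-4):
    """Optimize etas per subject and return (ofv, etas_hat, per-subject
    curvatures, flagged subjects).

    A few damped Gauss-Newton passes globalize the search, after which
    full Newton steps (Hessian from finite differences of the analytic
    gradient) give quadratic convergence; Gauss-Newton curvature is the
    fallback wherever the exact Hessian is not positive definite.  The
    Laplace determinant uses the exact Hessian at the mode.
    """
    d = model.data
    mask = d.mask
    sigma = model.sigma(params)
    w = 1.0 / sigma**2                        # per-endpoint weights
    if model.d == 0:      # no random effects: plain weighted least squares
        f = model.predict(params, etas)
        res = np.where(mask, d.y - f, 0.0)
        quad = np.einsum("ive,e->i", res**2, w)
        const = (mask * np.log(2.0 * np.pi * sigma[None, None, :]**2)
                 ).reshape(d.n_sub, -1).sum(axis=1)
        return float((quad + const).sum()), etas, \
            np.zeros((d.n_sub, 0, 0)), np.zeros(d.n_sub, dtype=bool)
    omega = model.omega(params)
    omega_inv = np.linalg.inv(omega)
    sign, logdet_omega = np.linalg.slogdet(omega)
    if sign <= 0:
        raise np.linalg.LinAlgError("omega not positive definite")
    n, dims = d.n_sub, model.d

    def half_objectives(et):
        f = model.predict(params, et)
        res = np.where(mask, d.y - f, 0.0)
        quad = np.einsum("ive,e->i", res**2, w)
        prior = np.einsum("ij,jk,ik->i", et, omega_inv, et)
        return 0.5 * (quad + prior), res

    def grad_and_gn(et):
        f0, J = model.predict_with_jacobian(params, et)
        Jm = np.where(mask[..., None], J, 0.0)
        res = np.where(mask, d.y - f0, 0.0)
        JW = Jm * w[None, None, :, None]
        grad = -np.einsum("ivej,ive->ij", JW, res) + et @ omega_inv
        Hgn = np.einsum("ivej,ivek->ijk", JW, Jm) + omega_inv[None]
        return grad, Hgn

    def exact_hessian(et, grad, Hgn):
        """FD of the analytic gradient; non-PD subjects fall back to GN."""
        Hx = np.empty((n, dims, dims))
        for j in range(dims):
            pert = et.copy()
            pert[:, j] += hess_step
            gj, _ = grad_and_gn(pert)
            Hx[:, :, j] = (gj - grad) / hess_step
        Hx = 0.5 * (Hx + np.swapaxes(Hx, 1, 2))
        pd = np.linalg.eigvalsh(Hx)[:, 0] > 0
        return np.where(pd[:, None, None], Hx, Hgn), pd

    h, _ = half_objectives(etas)
    flagged = np.zeros(n, dtype=bool)
    H = omega_inv[None].repeat(n, axis=0)
    have_exact_H = False
    H_is_final = False
    for it in range(max_iter):
        grad, Hgn = grad_and_gn(etas)
        if it >= newton_from:
            H, _ = exact_hessian(etas, grad, Hgn)
            have_exact_H = True
        else:
            H, have_exact_H = Hgn, False
        try:
            step = -np.linalg.solve(H, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = -grad @ omega
        if have_exact_H and np.max(np.abs(step)) < tol:
            H_is_final = True
            break  # converged; H is the exact curvature at these etas
        # damped update per subject with Armijo sufficient decrease
        gdot = np.einsum("ij,ij->i", grad, step)
        new = etas + step
        h_new, _ = half_objectives(new)
        worse = h_new > h + 1e-4 * gdot + 1e-12
        damp = 0
        while np.any(worse) and damp < 12:
            step[worse] *= 0.5
            gdot[worse] *= 0.5
            new[worse] = etas[worse] + step[worse]
            h_try, _ = half_objectives(new)
            h_new = np.where(worse, h_try, h_new)
            worse = h_new > h + 1e-4 * gdot + 1e-12
            damp += 1
        flagged |= worse
        etas, h = np.where(worse[:, None], etas, new), np.where(worse, h,
                                                                h_new)
        H_is_final = False
    if not H_is_final:   # loop exhausted or etas moved since H was formed
        grad, Hgn = grad_and_gn(etas)
        H, _ = exact_hessian(etas, grad, Hgn)
    sgn, logdet_H = np.linalg.slogdet(H)
    if np.any(sgn <= 0):
        flagged |= (sgn <= 0)
        logdet_H = np.where(sgn > 0, logdet_H, logdet_omega)

    const = (mask * np.log(2.0 * np.pi * sigma[None, None, :]**2)).reshape(
        n, -1).sum(axis=1)
    # the (2pi)^{d/2} of the Laplace integral cancels the eta-prior constant
    ofv_i = 2.0 * h + const + logdet_omega + logdet_H
    return float(ofv_i.sum()), etas, H, flagged


def objective(params: ParameterSet, data, panel=None) -> float:
    """Laplace-type -2 log marginal likelihood of a (tidy or prepared)
    dataset under ``params``.  Deterministic given data and parameters."""
    if isinstance(data, pd.DataFrame):
        data = EstimationData.from_tidy(data, params, panel=panel)
    model = _JointModel(data, params)
    etas = np.zeros((data.n_sub, model.d))
    ofv, _, _, _ = _laplace_terms(model, params, etas)
    return ofv


@dataclass
class FitResult:
    """Outcome of a maximum (approximate) likelihood fit."""

    params: ParameterSet
    free_names: list
    ofv: float
    converged: bool
    n_obj_evals: int
    estimates: dict = field(default_factory=dict)
    fixed: dict = field(default_factory=dict)
    message: str = ""
    data: EstimationData | None = None
    etas_hat: np.ndarray | None = None
    cov_transformed: np.ndarray | None = None
    condition_number: float | None = None

    def to_report(self) -> dict:
        return {
            "ofv": self.ofv, "converged": self.converged,
            "n_objective_evaluations": self.n_obj_evals,
            "estimates": self.estimates, "fixed": self.fixed,
            "condition_number": self.condition_number,
            "message": self.message,
        }


def fit(data, start: ParameterSet, free=None, panel=None,
        maxiter: int = 200, gtol: float = 1e-6, restarts: int = 1,
        compute_uncertainty: bool = False) -> FitResult:
    """Fit the joint model by transformed-scale quasi-Newton optimization.

    ``free`` lists the parameter names to estimate (see
    :func:`default_free_parameters`); everything else is honored as fixed.
    Non-convergence returns the best point found, flagged.
    """
    if isinstance(data, pd.DataFrame):
        data = EstimationData.from_tidy(data, start, panel=panel)
    if free is None:
        free = default_free_parameters(start, data.panel)
    model = _JointModel(data, start)
    state = {"etas": np.zeros((data.n_sub, model.d)), "n": 0,
             "best": (np.inf, None)}

    if not free:
        ofv, etas, _, _ = _laplace_terms(model, start, state["etas"])
        return FitResult(params=start, free_names=[], ofv=ofv, converged=True,
                         n_obj_evals=1, estimates={},
                         fixed=_all_values(start), data=data, etas_hat=etas)

    z0 = pack(start, free)

    def obj(z):
        p = unpack(start, free, z)
        try:
            ofv, etas, _, _ = _laplace_terms(model, p, state["etas"].copy())
        except (np.linalg.LinAlgError, FloatingPointError):
            return 1e12
        state["etas"] = etas
        state["n"] += 1
        if ofv < state["best"][0]:
            state["best"] = (ofv, z.copy())
        return ofv

    opts = {"maxiter": maxiter, "gtol": gtol, "eps": 1e-4}
    res = optimize.minimize(obj, z0, method="L-BFGS-B", options=opts)
    # restarts from the incumbent recover from premature line-search
    # termination on ridged likelihood surfaces
    for _ in range(restarts):
        res2 = optimize.minimize(obj, state["best"][1], method="L-BFGS-B",
                                 options=opts)
        if res2.fun <= res.fun:
            res = res2
    ofv_best, z_best = state["best"]
    if z_best is None:
        z_best, ofv_best = z0, obj(z0)
    final = unpack(start, free, z_best)
    _, etas_hat, _, _ = _laplace_terms(model, final, state["etas"].copy())
    est = {n: _get_param(final, n) for n in free}
    fixed = {k: v for k, v in _all_values(final).items() if k not in est}
    out = FitResult(params=final, free_names=list(free), ofv=float(ofv_best),
                    converged=bool(res.success), n_obj_evals=state["n"],
                    estimates=est, fixed=fixed, message=str(res.message),
                    data=data, etas_hat=etas_hat)
    if compute_uncertainty:
        H = _fd_hessian(obj, z_best)
        out.cov_transformed = _safe_inverse(0.5 * H)
        out.condition_number = _condition_number(0.5 * H)
    return out


def _all_values(params: ParameterSet) -> dict:
    vals = {"kout": params.shared.k_out, "emax_norm": params.shared.emax_norm,
            "e_plac": params.shared.e_plac,
            "omega_emax_norm": params.iiv_emax_norm,
            "omega_e_plac": params.iiv_e_plac}
    for e, s in params.endpoints.items():
        vals[f"base_{e}"] = s.baseline
        vals[f"emax_{e}"] = s.emax
        vals[f"ruv_{e}"] = s.ruv_sd
        if s.eta_source is None:
            vals[f"omega_{e}"] = s.iiv_baseline
    return vals


def _fd_hessian(f, z, step: float = 1e-3) -> np.ndarray:
    """Central-difference Hessian (small dimension, symmetric)."""
    k = len(z)
    H = np.empty((k, k))
    f0 = f(z)
    fp = np.empty(k)
    fm = np.empty(k)
    for i in range(k):
        zp, zm = z.copy(), z.copy()
        zp[i] += step
        zm[i] -= step
        fp[i], fm[i] = f(zp), f(zm)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / step**2
    for i in range(k):
        for j in range(i + 1, k):
            zpp = z.copy()
            zpp[[i, j]] += step
            fpp = f(zpp)
            H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + f0) / step**2
    return H


def _safe_inverse(H: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(0.5 * (H + H.T))
    w = np.maximum(w, 1e-10 * np.max(np.abs(w)))
    return (V / w) @ V.T


def _condition_number(H: np.ndarray) -> float:
    d = np.sqrt(np.abs(np.diag(H)))
    d[d == 0] = 1.0
    R = H / np.outer(d, d)
    w = np.abs(np.linalg.eigvalsh(0.5 * (R + R.T)))
    return float(w.max() / max(w.min(), 1e-300))


def ebes_and_shrinkage(fitres: FitResult):
    """Empirical Bayes etas with eta and epsilon shrinkage tables.

    eta shrinkage = 100 * (1 - SD(EBE)/omega); epsilon shrinkage from the
    SD of individual weighted residuals at the eta modes.
    """
    model = _JointModel(fitres.data, fitres.params)
    etas = fitres.etas_hat
    if etas is None:
        _, etas, _, _ = _laplace_terms(model, fitres.params,
                                       np.zeros((fitres.data.n_sub, model.d)))
    omega = model.omega(fitres.params)
    om_sd = np.sqrt(np.diag(omega))
    ebe_sd = etas.std(axis=0, ddof=1)
    eta_shr = 100.0 * (1.0 - np.divide(ebe_sd, om_sd,
                                       out=np.ones_like(om_sd),
                                       where=om_sd > 0))
    eta_table = pd.DataFrame({"eta": model.eta_names, "omega_sd": om_sd,
                              "ebe_sd": ebe_sd,
                              "shrinkage_pct": np.clip(eta_shr, None, 100.0)})
    f = model.predict(fitres.params, etas)
    sig = model.sigma(fitres.params)
    rows = []
    for k, e in enumerate(model.panel):
        m = fitres.data.mask[:, :, k]
        iwres = (fitres.data.y[:, :, k][m] - f[:, :, k][m]) / sig[k]
        shr = 100.0 * (1.0 - iwres.std(ddof=1)) if m.sum() > 1 else np.nan
        rows.append({"endpoint": e, "eps_shrinkage_pct": shr})
    ebes = pd.DataFrame(etas, columns=model.eta_names)
    ebes.insert(0, "subject", fitres.data.subject_ids)
    return ebes, eta_table, pd.DataFrame(rows)


def covariate_step(data, base_params: ParameterSet, base_free,
                   candidates, forward_alpha: float = 0.01,
                   backward_alpha: float = 0.001, panel=None,
                   maxiter: int = 200, restarts: int = 0):
    """Stepwise covariate selection by likelihood-ratio testing.

    ``candidates`` maps parameter names (``cov_baseline_<endpoint>`` or
    ``cov_eplac``) to initial percent values.  Forward inclusion requires the
    LRT p-value < forward_alpha (chi-square, 1 df per effect); backward
    elimination then removes effects whose deletion is not significant at
    backward_alpha.  Deterministic given the data.
    """
    if isinstance(data, pd.DataFrame):
        data = EstimationData.from_tidy(data, base_params, panel=panel)

    def fit_with(included):
        import copy
        p = copy.deepcopy(base_params)
        # candidate effects not yet in the model start at 0 percent
        from .params import CovariateEffect
        for name in included:
            if name == "cov_eplac":
                if not any(c.target == "e_plac" for c in p.covariates):
                    p.covariates.append(CovariateEffect("MPDM", "e_plac",
                                                        0.0))
            else:
                ep = name.split("_", 2)[2]
                if not any(c.target == "baseline" and c.endpoint == ep
                           for c in p.covariates):
                    p.covariates.append(CovariateEffect("MPDM", "baseline",
                                                        0.0, endpoint=ep))
        return fit(data, p, free=list(base_free) + list(included),
                   maxiter=maxiter, restarts=restarts)

    included = []
    current = fit_with(included)
    improved = True
    while improved:
        improved = False
        best = None
        for name in candidates:
            if name in included:
                continue
            trial = fit_with(included + [name])
            dofv = current.ofv - trial.ofv
            pval = stats.chi2.sf(max(dofv, 0.0), df=1)
            if pval < forward_alpha and (best is None or trial.ofv < best[1].ofv):
                best = (name, trial)
        if best is not None:
            included.append(best[0])
            current = best[1]
            improved = True
    # backward elimination
    pruned = True
    while pruned and included:
        pruned = False
        for name in list(included):
            reduced = fit_with([n for n in included if n != name])
            dofv = reduced.ofv - current.ofv
            pval = stats.chi2.sf(max(dofv, 0.0), df=1)
            if pval >= backward_alpha:
                included.remove(name)
                current = reduced
                pruned = True
                break
    return included, current


def uncertainty_draws(fitres: FitResult, n_draws: int, seed) -> list:
    """Multivariate-normal parameter samples on the transformed scale.

    Uses the fit's transformed-scale covariance (asymptotic approximation);
    draws respect every parameter constraint by construction of the
    transforms.  Returns a list of ParameterSet.
    """
    if n_draws == 0:
        return []
    if fitres.cov_transformed is None:
        raise ValueError("fit was run without compute_uncertainty=True")
    rng = np.random.default_rng(seed)
    z0 = pack(fitres.params, fitres.free_names)
    zs = rng.multivariate_normal(z0, fitres.cov_transformed, size=n_draws,
                                 method="svd")
    return [unpack(fitres.params, fitres.free_names, z) for z in zs]
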