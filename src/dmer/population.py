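"""Interindividual variability: eta draws, transforms, sharing, covariates.

Baseline etas of most endpoints are drawn from a correlated multivariate
normal "block"; some endpoints reuse (part of) another endpoint's eta through
fixed sharing scalars (eta* = theta_X1 * eta_1 + theta_X2 * eta_2 + ...).
Transform conventions:

* endpoint baselines: shifted log-normal, (theta + 1) * exp(eta) - 1,
  preserving the typical value at eta = 0 while admitting individual zeros;
* normalizing maximum effect: logit-normal;
* placebo factor: log-normal.

Muscle-predominant disease (MPDM) acts as percent changes on selected typical
values.  An empirical shift of SPDM baseline MMT-8 toward healthy normal
(capped at the 150 scale maximum) is available for trial simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .params import ParameterSet

__all__ = [
    "OmegaSpec", "draw_etas", "individual_baseline", "individual_emax_norm",
    "individual_eplac", "apply_covariates", "spdm_mmt8_adjustment",
    "SubjectRealization", "draw_subjects",
]


@dataclass
class OmegaSpec:
    """Variance structure of the subject-level random effects.

    block_names/block_matrix: correlated baseline etas and their covariance;
    lone_variances: independent etas (logit-Emax_norm, log-E_plac, lone parts);
    sharing: endpoint -> (donor endpoint, scalar, own lone variance or None).
    """

    block_names: list
    block_matrix: np.ndarray
    lone_variances: dict
    sharing: dict = field(default_factory=dict)

    def __post_init__(self):
        m = np.asarray(self.block_matrix, dtype=float)
        if m.shape != (len(self.block_names),) * 2:
            raise ValueError("block matrix shape mismatch")
        if not np.allclose(m, m.T):
            raise ValueError("block matrix must be symmetric")
        w = np.linalg.eigvalsh(m)
        if np.any(w < -1e-10 * max(1.0, w.max(initial=1.0))):
            raise ValueError(
                f"block matrix not positive semidefinite: eigenvalue {w.min():.3g}")
        if any(v < 0 for v in self.lone_variances.values()):
            raise ValueError("lone variances must be non-negative")
        self.block_matrix = m

    @classmethod
    def from_parameters(cls, params: ParameterSet) -> "OmegaSpec":
        """Build the omega structure from a parameter set.

        Block = all endpoints with their own baseline variance, exchangeable
        correlation ``params.block_correlation`` (the published full
        covariance block is configuration-replaceable).
        """
        names = params.block_endpoints
        var = np.array([params.endpoints[n].iiv_baseline for n in names])
        sd = np.sqrt(var)
        corr = np.full((len(names), len(names)), params.block_correlation)
        np.fill_diagonal(corr, 1.0)
        mat = corr * np.outer(sd, sd)
        lone = {"emax_norm": params.iiv_emax_norm, "e_plac": params.iiv_e_plac}
        sharing = {}
        for n, s in params.endpoints.items():
            if s.eta_source is not None:
                sharing[n] = (s.eta_source, s.eta_scalar, s.eta_own_var)
                if s.eta_own_var is not None:
                    lone[f"{n}_own"] = s.eta_own_var
        return cls(names, mat, lone, sharing)


def draw_etas(omega: OmegaSpec, n: int, seed) -> pd.DataFrame:
    """Draw per-subject eta vectors.

    Block etas are zero-mean multivariate normal with the block covariance;
    lone etas are independent normals; derived etas are composed from their
    donors afterwards via the sharing scalars.
    """
    rng = np.random.default_rng(seed)
    block = rng.multivariate_normal(
        np.zeros(len(omega.block_names)), omega.block_matrix, size=n,
        method="cholesky" if _is_pd(omega.block_matrix) else "svd")
    cols = {name: block[:, j] for j, name in enumerate(omega.block_names)}
    for name, var in omega.lone_variances.items():
        cols[name] = rng.standard_normal(n) * np.sqrt(var)
    for name, (src, scalar, own_var) in omega.sharing.items():
        eta = scalar * cols[src]
        if own_var is not None:
            eta = eta + cols[f"{name}_own"]
        cols[name] = eta
    return pd.DataFrame(cols)


def _is_pd(m) -> bool:
    try:
        np.linalg.cholesky(m)
        return True
    except np.linalg.LinAlgError:
        return False


def individual_baseline(theta, eta):
    """Shifted log-normal baseline: (theta + 1) * exp(eta) - 1.

    Equals theta at eta = 0; reaches 0 at eta = -ln(theta + 1); > -1 always.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0):
        raise ValueError("typical baseline must be non-negative")
    out = (theta + 1.0) * np.exp(np.asarray(eta, dtype=float)) - 1.0
    return out if out.ndim else float(out)


def individual_emax_norm(theta, eta):
    """Logit-normal normalizing maximum effect, kept inside (0, 1)."""
    if not 0 < theta < 1:
        raise ValueError("typical emax_norm must lie in (0, 1)")
    out = expit(logit(theta) + np.asarray(eta, dtype=float))
    return out if out.ndim else float(out)


def individual_eplac(theta, eta):
    """Log-normal placebo factor: theta * exp(eta) > 0."""
    if not theta > 0:
        raise ValueError("typical e_plac must be positive")
    out = theta * np.exp(np.asarray(eta, dtype=float))
    return out if out.ndim else float(out)


def apply_covariates(params: ParameterSet, dm_type: str) -> dict:
    """Typical values adjusted for DM subtype.

    Returns {"baseline": {endpoint: theta}, "e_plac": theta}.  MPDM applies
    each configured percent change multiplicatively; SPDM is the reference.
    """
    if dm_type not in ("SPDM", "MPDM"):
        raise ValueError(f"unknown DM type: {dm_type!r}")
    base = {n: s.baseline for n, s in params.endpoints.items()}
    e_plac = params.shared.e_plac
    if dm_type == "MPDM":
        for c in params.covariates:
            if c.covariate != "MPDM":
                continue
            if c.target == "baseline":
                if c.endpoint in base:
                    base[c.endpoint] *= c.factor
            elif c.target == "e_plac":
                e_plac *= c.factor
    return {"baseline": base, "e_plac": e_plac}


def spdm_mmt8_adjustment(baseline, dm_type, shift: float = 0.946,
                         cap: float = 150.0):
    """Empirical SPDM shift of baseline MMT-8 toward healthy normal.

    SPDM baselines move a fraction ``shift`` of the remaining gap to the
    scale maximum and are capped there; MPDM values are untouched.
    """
    b = np.asarray(baseline, dtype=float)
    is_spdm = np.asarray(dm_type) == "SPDM" if not np.isscalar(dm_type) \
        else dm_type == "SPDM"
    shifted = np.minimum(b + shift * (cap - b), cap)
    out = np.where(is_spdm, shifted, b)
    return out if out.ndim else float(out)


@dataclass
class SubjectRealization:
    """One virtual patient after eta composition and covariates."""

    subject_id: int
    dm_type: str
    baselines: dict          # endpoint -> individual observed baseline
    emax_norm: float
    e_plac: float
    etas: dict
    uln: float = 200.0


def draw_subjects(params: ParameterSet, dm_types, seed,
                  mmt8_spdm_adjust: bool = False) -> list:
    """Realize a cohort of virtual patients.

    ``dm_types`` is a sequence of "SPDM"/"MPDM" labels, one per subject.
    When ``mmt8_spdm_adjust`` (trial-simulation mode) is on, SPDM MMT-8
    baselines are shifted toward 150 with shrunken variability and capped.
    """
    dm_types = list(dm_types)
    n = len(dm_types)
    omega = OmegaSpec.from_parameters(params)
    etas = draw_etas(omega, n, seed)
    rng = np.random.default_rng(None if seed is None else seed + 1)
    ulns = rng.choice(params.uln_catalogue, size=n)
    typ = {dm: apply_covariates(params, dm) for dm in ("SPDM", "MPDM")}
    subjects = []
    for i in range(n):
        dm = dm_types[i]
        baselines = {}
        for name, spec in params.endpoints.items():
            eta = etas[name].iloc[i]
            theta = typ[dm]["baseline"][name]
            if (name == "mmt8" and mmt8_spdm_adjust and dm == "SPDM"):
                eta = eta * np.sqrt(params.mmt8_spdm_var_shrink)
                b = individual_baseline(theta, eta)
                b = spdm_mmt8_adjustment(b, dm, params.mmt8_spdm_shift,
                                         params.endpoints[name].range_hi)
            else:
                b = individual_baseline(theta, eta)
            baselines[name] = b
        subjects.append(SubjectRealization(
            subject_id=i + 1, dm_type=dm, baselines=baselines,
            emax_norm=individual_emax_norm(params.shared.emax_norm,
                                           etas["emax_norm"].iloc[i]),
            e_plac=individual_eplac(typ[dm]["e_plac"], etas["e_plac"].iloc[i]),
            etas={c: float(etas[c].iloc[i]) for c in etas.columns},
            uln=float(ulns[i]),
        ))
    return subjects
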