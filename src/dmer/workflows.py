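"""Standard simulation-estimation experiments built from the package parts.

These are the canonical study-scale workflows: the reduced-panel parameter
recovery experiment (simulate at the shipped typical values, refit from a
deliberately displaced start), the placebo TIS trajectory simulation, and
the null/power calibration of stepwise covariate selection.  Analysis
drivers, tests and the acceptance script all call these entry points so the
same experiment definitions are exercised everywhere.
"""

from __future__ import annotations

import copy

import numpy as np
import pandas as pd

from . import estimation as est
from . import trial_sim
from .params import ParameterSet, default_parameters
from .synthetic_trial import Arm, TrialDesign, generate_trial

RECOVERY_PANEL = ("cdasi_a", "ptga", "enzyme", "mmt8")

__all__ = ["RECOVERY_PANEL", "reduced_panel_design", "displaced_start",
           "recovery_replicate", "recovery_experiment",
           "placebo_tis_experiment", "covariate_null_fixture",
           "covariate_step_replicate"]


def reduced_panel_design(n_per_arm: int = 100) -> TrialDesign:
    """Two-arm (placebo / 600 mg Q4W), 24-week, skin-predominant design over
    the four-endpoint recovery panel with continued dosing."""
    return TrialDesign(
        "recovery", "SPDM",
        [Arm("placebo", 0.0, n_per_arm), Arm("600mg", 600.0, n_per_arm)],
        visits=(0.0, 4.0, 8.0, 12.0, 16.0, 20.0, 24.0),
        panel=RECOVERY_PANEL, doses_per_period=7)


def displaced_start(truth: ParameterSet) -> ParameterSet:
    """Generic displaced starting values for refitting.

    Shared parameters move to neutral round numbers, baselines up 20%,
    estimable maximum effects shrink to +/-0.3, residual SDs up 50% --
    far enough that recovery is informative, standard enough to be a
    routine choice.
    """
    start = copy.deepcopy(truth)
    start.shared.k_out = 0.15
    start.shared.emax_norm = 0.40
    start.shared.e_plac = 1.0
    for spec in start.endpoints.values():
        spec.baseline *= 1.2
        if not spec.emax_fixed and spec.emax != 0:
            spec.emax = -0.3 if spec.emax < 0 else 0.3
        spec.ruv_sd *= 1.5
    return start


def recovery_replicate(seed: int, params: ParameterSet | None = None,
                       n_per_arm: int = 100, maxiter: int = 150,
                       restarts: int = 1) -> dict:
    """Simulate one reduced-panel trial at the typical values and refit.

    Returns the recovered estimates for the shared parameters and the
    estimable per-endpoint maximum effects.
    """
    truth = (params or default_parameters()).subset(RECOVERY_PANEL)
    design = reduced_panel_design(n_per_arm)
    data = generate_trial(design, truth, seed=seed)
    prepared = est.EstimationData.from_tidy(data, truth,
                                            panel=list(RECOVERY_PANEL))
    res = est.fit(prepared, displaced_start(truth), maxiter=maxiter,
                  restarts=restarts)
    out = {k: res.estimates[k] for k in
           ("kout", "emax_norm", "e_plac", "emax_ptga", "emax_enzyme",
            "emax_mmt8")}
    out["ofv"] = res.ofv
    out["converged"] = res.converged
    out["seed"] = seed
    return out


def recovery_experiment(n_replicates: int, base_seed: int = 0,
                        **kwargs) -> pd.DataFrame:
    """Replicate recovery fits; one row per replicate (seed base_seed + r)."""
    rows = [recovery_replicate((base_seed + r) % 2**31, **kwargs)
            for r in range(n_replicates)]
    return pd.DataFrame(rows)


def placebo_tis_experiment(n_trials: int = 200, n_per_arm: int = 120,
                           seed: int = 0,
                           params: ParameterSet | None = None):
    """Replicate mixed-population trials at the default values and return
    (grand median placebo TIS across weeks 4-24, full CTS result)."""
    cfg = trial_sim.CTSConfig(n_trials=n_trials, n_per_arm=n_per_arm,
                              seed=seed)
    res = trial_sim.run_cts(cfg, params or default_parameters())
    return res.placebo_tis_grand_median, res


def covariate_null_fixture(effect_percent: float = 0.0) -> tuple:
    """Reduced single-endpoint fixture for covariate-selection calibration.

    One endpoint (CDASI-A), baseline IIV only, mixed 50/50 SPDM-MPDM placebo
    cohort.  ``effect_percent`` is the generating MPDM effect on the
    baseline (0 = null).  Returns (generating params, fitting template,
    design, base free names, candidate names).
    """
    base = default_parameters().subset(["cdasi_a"])
    base.iiv_emax_norm = 0.0
    base.iiv_e_plac = 0.0
    base.covariates = []
    gen = copy.deepcopy(base)
    if effect_percent != 0.0:
        from .params import CovariateEffect
        gen.covariates = [CovariateEffect("MPDM", "baseline", effect_percent,
                                          endpoint="cdasi_a")]
    design = TrialDesign(
        "covcal", "MIX80",
        [Arm("placebo", 0.0, 40)],
        visits=(0.0, 4.0, 8.0, 12.0), panel=("cdasi_a",),
        mpdm_fraction=0.5)
    free = ["base_cdasi_a", "ruv_cdasi_a"]
    return gen, base, design, free, ["cov_baseline_cdasi_a"]


def covariate_step_replicate(seed: int, effect_percent: float = 0.0,
                             maxiter: int = 60) -> bool:
    """One stepwise-selection replicate; True if the MPDM effect on the
    CDASI-A baseline is selected."""
    gen, base, design, free, candidates = covariate_null_fixture(
        effect_percent)
    data = generate_trial(design, gen, seed=seed)
    included, _ = est.covariate_step(data, base, free, candidates,
                                     panel=["cdasi_a"], maxiter=maxiter)
    return "cov_baseline_cdasi_a" in included
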