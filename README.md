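# dmer — joint exposure–response modeling of dermatomyositis endpoints

Dermatomyositis (DM) trials measure many correlated clinical scores — skin
activity (CDASI-A/D), global assessments (PhGA, PtGA), muscle strength
(MMT-8), function (HAQ, SF-36), muscle enzymes, extramuscular activity
(ExGA) — yet each score alone is sparsely observed in a rare disease.
`dmer` implements a joint exposure–response model in which all eleven
endpoints are driven by one pharmacological quantity: the fraction of
interferon-beta (IFNβ) left unbound by a neutralizing monoclonal antibody
(dazukibart).  The package is aimed at pharmacometricians who need to
simulate, fit and interrogate this class of shared-latent indirect-response
models, and to translate endpoint trajectories into Total Improvement Score
(TIS) responder rates for trial design.

## The model

With drug concentration *C* and quasi-steady-state binding constant
*K*<sub>SS</sub>,

```
P_unbound = 1 − C / (C + K_SS)
E_shared  = Emax_norm · P_unbound
```

Each endpoint *m* is a turnover (indirect response) variable whose loss is
modulated by the shared drive:

```
End_base,m = End_obs,m · (1 + Emax_m · Emax_norm) · E_plac^sign(Emax_m)
k_in,m     = k_out · End_base,m
dEnd_m/dt  = k_in,m − k_out · End_m · (1 + Emax_m · E_shared)
```

The observed DM baseline is an *altered steady state*: the equilibrium the
patient holds under fully unbound IFNβ plus a placebo perturbation
(*E*<sub>plac</sub>).  Drug binding (P_unbound → 0) moves each endpoint
toward its healthy equilibrium at shared rate *k*<sub>out</sub>, in the
direction and magnitude of its *E*<sub>max,m</sub> ∈ [−1, 1].  Subject-level
variability uses a shifted log-normal for baselines ((θ+1)e^η − 1), a
logit-normal for Emax_norm and a log-normal for E_plac, with a correlated
baseline eta block and fixed-scalar eta sharing (e.g. the MMT-8 eta is a
scaled HAQ eta).  Residual error is additive with fixed-effect standard
deviations; enzymes are modeled as ratios to their upper limit of normal.
TIS converts the absolute percent improvement of six core-set measures into
points (maximum 100) with nested minimal/moderate/major categories at
20/40/60.

The shipped configuration (`src/dmer/data/parameters.yaml`) carries the
model's typical values — k_out 0.246 wk⁻¹, Emax_norm 56.4%, E_plac 1.03,
per-endpoint baselines, effects and residual SDs — and
`src/dmer/data/tis_table.yaml` carries the TIS conversion table.

## Worked example

```python
import numpy as np
from dmer import default_parameters
from dmer.model_core import SharedParams, simulate_endpoint
from dmer.trial_sim import CTSConfig, run_cts

p = default_parameters()

# CDASI-A under sustained full IFNβ suppression vs placebo
shared = SharedParams(k_out=0.246, emax_norm=0.564, e_plac=1.03)
weeks = np.arange(0.0, 25.0, 4.0)
on_drug = simulate_endpoint(p.endpoints["cdasi_a"], shared, weeks, p_unbound=0.0)
print(np.round(on_drug, 1))

# 20 replicate six-month trials, placebo vs 600 mg Q4W, 80% MPDM
res = run_cts(CTSConfig(n_trials=20, n_per_arm=120, seed=5), p)
print(round(res.placebo_tis_grand_median, 1))
wk24 = res.responders.query("week == 24 and stratum == 'pooled'")
print(wk24[["arm", "category", "median"]].to_string(index=False))
```

prints

```
[28.3 18.1 14.3 12.8 12.3 12.1 12. ]
25.0
    arm category   median
placebo  minimal 0.691667
placebo moderate 0.258333
placebo    major 0.033333
  600mg  minimal 0.966667
  600mg moderate 0.816667
  600mg    major 0.454167
```

The first line is the CDASI-A time course relaxing from its observed
baseline 28.3 toward the corrected ("healthy-equilibrium") baseline ≈ 12 at
rate k_out.  The second is the median placebo-arm TIS across weeks 4–24
(≈ 25 points: placebo drift plus measurement noise rectified by the
improvement thresholds).  The table shows week-24 responder proportions:
active treatment roughly doubles the moderate-response rate and an order of
magnitude more patients reach major response than under placebo.

A command-line front end mirrors the library:
`dmer simulate|fit|cts|vpc|score-tis --help`.  The numbered scripts under
`analysis/` run the full narrative — staged dataset generation, reduced-panel
refitting, predictive checks, trial simulation — writing tables to
`results/`.

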