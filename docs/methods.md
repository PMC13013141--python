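# Methods

## Model

Eleven clinical endpoints are modeled jointly as indirect-response (turnover)
variables sharing one pharmacological drive.  Unbound interferon-beta
fraction follows a quasi-steady-state binding law, `P_unbound = 1 − C/(C +
K_SS)`, so the drug concentration at half-maximal binding equals the binding
constant.  The shared effect `E_shared = Emax_norm · P_unbound` scales a
per-endpoint maximum effect `Emax_m ∈ [−1, 1]` acting on the loss term:

    dEnd_m/dt = k_in,m − k_out · End_m · (1 + Emax_m · E_shared)

The pivotal structural assumption is the *altered steady state*: a patient's
observed baseline is the equilibrium reached under fully unbound IFNβ plus a
placebo perturbation.  The input rate is therefore computed from a corrected
baseline, `End_base,m = End_obs,m · (1 + Emax_m·Emax_norm) ·
E_plac^sign(Emax_m)` and `k_in,m = k_out · End_base,m`, while integration
starts at the observed baseline.  Two consequences are load-bearing and are
asserted as tests: with `E_plac = 1` and placebo exposure every trajectory
is exactly flat, and under constant `P_unbound = p` the long-run value is
`End_base,m / (1 + Emax_m·Emax_norm·p)`.  `sign(0) = 0`, so endpoints with
`Emax_m = 0` have no placebo effect by construction.

For fixed `P_unbound` the ODE is linear in `End_m`, so trajectories under a
piecewise-constant exposure profile have an exact segment-wise solution.
That analytic path is the default integrator and the oracle against which
the adaptive numerical path (LSODA, rtol 1e-8 / atol 1e-10) is verified to
1e-6 relative.  Latent trajectories are *not* clipped to score ranges; the
model fits unbounded continuous values, and clipping exists only as an
optional observation-layer switch (off by default).

## Exposure

A linear two-compartment IV model with zero-order infusion (default 1 h;
bolus limit available) produces concentration by biexponential
superposition.  Disposition typicals in the shipped configuration (CL 1.6
L/wk, V1 3.5 L, V2 2.6 L, Q 4.9 L/wk) are placeholder typical-monoclonal
values, not study estimates; the response layer depends on the PK only
through `K_SS` (default 1 µg/mL), and at the 600 mg Q4W regimen the drive is
near-saturated, so response-layer conclusions are insensitive to these
defaults.  Tests of the response layer use placebo or prescribed
`P_unbound` profiles throughout.

## Population model

Transform conventions: baselines are shifted log-normal, `(θ+1)·e^η − 1`,
which preserves the typical value at η = 0 and admits individual values of
0 — the package's concrete reading of a one-unit-shifted log-normal, chosen
because it keeps both properties at once; `Emax_norm` is
logit-normal; `E_plac` is log-normal.  Baseline etas of eight endpoints form
a correlated block; the published covariance block is not part of the main
parameter table, so the default builds it from the published diagonal
variances with an exchangeable correlation of 0.3 — a documented,
configuration-replaceable assumption.  Eta sharing uses fixed scalars:
MMT-8's eta is −0.378 times the HAQ eta (a deliberate reading of the
sharing row as "no independent MMT-8 variability"; the printed %CV for
MMT-8 appears to be computed without the scalar), TIS-PhGA reuses the PhGA
eta with scalar 1, and ExGA adds an independent part (variance 0.0592) to
the PhGA eta.

MPDM (muscle-predominant) status acts as percent changes applied
multiplicatively to the CDASI-A baseline (−51.8%), the SF-36 PFD baseline
(−24.3%) and the placebo factor (+6.55%).  The placebo-factor effect
multiplies the factor itself (1.03 → 1.097) rather than its excess over 1;
a percent effect on a parameter value is taken to mean exactly that.

For trial simulation only, SPDM baseline MMT-8 is shifted toward healthy
normal: the typical 113 moves a fraction 0.946 of the gap to the scale
maximum (≈ 148), the eta variance is shrunk ×0.25, and values are capped at
150.  Only the direction of this adjustment — bring skin-predominant
muscle strength near healthy normal — is externally motivated; its
magnitude is the package's own choice and is configurable.

## Residual error and enzymes

All endpoints carry additive residual error with the standard deviation as a
fixed effect and unit-variance noise (one SD per endpoint).  Enzymes are
modeled as the ratio of the most abnormal enzyme to its upper limit of
normal; observations are denormalized as `Y = (R + ε)·ULN` with a small
configurable ULN catalogue (40/200/250 U/L) standing in for the
enzyme-specific limits.  In practice the identity of the most abnormal
enzyme can differ between visits; the model tracks only the ULN ratio, so
this is simplified to a single modeled ratio per subject.

## TIS scoring

TIS sums points from the absolute percent improvement (change from baseline
relative to the measure's total range) of six core-set measures; the
bin→points table and the 20/40/60 minimal/moderate/major cutoffs ship as a
mandatory configuration transcribed from the 2016 adult myositis response
criteria, and every scored result records the table checksum.  Enzyme
improvement is measured on the ULN-ratio scale against a configurable
natural-history span (default 10 × ULN).  Categories are nested by
construction and this invariant is enforced and property-tested.  Scoring
uses observed (noisy) values, as in practice; a noiseless diagnostic mode
exists.

## Synthetic trials

The generator emulates the staged study structure: skin-predominant stages
carry CDASI, SF-36, global-assessment and HAQ panels; the muscle-predominant
stage carries the full eleven-endpoint panel including the TIS core set;
crossover designs switch placebo↔active at week 12 with Q4W dosing (three
doses per period in the staged designs); default stage sizes 32/25/18 mirror
the reported cohorts.  Baselines are correlated across endpoints through
the eta block, noise is additive per the residual model, and a latent truth
record (etas, baselines, noiseless trajectories) is exportable for
parameter-recovery work.  What the generator does *not* emulate: dropout or
missing visits (none by default), visit-window jitter, discreteness and
bounds of real scores, enzyme-identity switching, or assessor effects —
so green tests show internal consistency of the method, not robustness to
those real-data features.

## Estimation

The marginal likelihood over subject random effects is approximated by a
Laplace expansion at the per-subject eta mode.  Because residual SDs do not
depend on etas, the interaction term of conditional-estimation methods
vanishes and the Laplace objective is the natural analogue of the exact
conditional approach.  The inner mode search runs vectorized over subjects:
analytic prediction sensitivities propagate through the same exact segment
recursion as the values (no finite-difference noise), a few damped
Gauss-Newton passes globalize, then Newton steps with the Hessian from
finite differences of the analytic gradient (step 1e-4) converge
quadratically to step tolerance 1e-6; Armijo sufficient decrease guards
against slow two-cycles on curved valleys.  The Laplace determinant uses the
exact Hessian at the mode, falling back to Gauss-Newton curvature for any
subject where it is not positive definite.  The machinery is verified
against the closed-form normal marginal in a linear-Gaussian case, where
Laplace is exact.

The outer problem optimizes transformed fixed effects (log for positive
parameters, logit for fractions, `logit((x+1)/2)` for [−1, 1] effects,
`log(θ+1)` for baselines, `log(1+pct/100)` for covariate percent effects,
log for variances) with L-BFGS-B, forward-difference step 1e-4, gradient
tolerance 1e-6, and one restart from the incumbent to escape premature
line-search termination on ridged surfaces.  Fixed values (the ±1/0 maximum
effects) are honored through an explicit free-parameter list.  In the
recovery experiment the omega structure is fixed at the generating values
and fixed effects plus residual SDs are estimated; diagonal-omega
estimation is supported and unit-tested.  Empirical Bayes etas, eta
shrinkage (100·(1 − SD(EBE)/ω)), epsilon shrinkage (from individual
weighted residual SDs) and a correlation-scaled-information condition
number are reported.  Covariate selection is stepwise by likelihood ratio:
forward at α 0.01, backward at α 0.001, one degree of freedom per effect.
Parameter uncertainty for simulation is multivariate-normal sampling on the
transformed estimation scale from the inverse observed information — an
asymptotic stand-in chosen because downstream trial simulation needs
plausible parameter dispersion, not a particular resampling algorithm; the
transforms make every draw respect the parameter constraints.

Exposure enters estimation and simulation through the same discretization:
`P_unbound` held piecewise-constant on a weekly grid (midpoint sampling of
the continuous profile).  Generator and estimator share this machinery, so
recovery experiments are internally consistent; the discretization error
against the continuous profile is irrelevant at the near-saturating doses
studied.

## Trial simulation and predictive checks

Clinical trial simulation runs replicate trials (replicate r uses seed
base+r), draws a mixed 80% MPDM / 20% SPDM population per arm (counts fixed
within arm), applies the SPDM MMT-8 adjustment, simulates trajectories with
residual noise at scoring visits, scores TIS against the observed week-0
baseline, and aggregates medians with 90% prediction intervals per arm ×
stratum × category × week, pooled and stratified ("six months" is
implemented as Q4W dosing through week 24 with scoring every 4 weeks).  The
pooled proportion equals the realized-count mixture of the strata exactly.
The VPC routine simulates replicate datasets under the design of the input
data and reports, per endpoint × visit × stratum bin, observed quantiles
(2.5/50/97.5 by default; median-only below 5 observations per bin) with
confidence bands of those quantiles across replicates; empty bins are
skipped with a warning.

## Problem sizes

The shipped experiments are sized for single-CPU runs: the acceptance
script uses 5 replicate recovery fits (200 subjects, 4 endpoints, 7 visits)
and 200 replicate TIS trials; the test suite uses 3 recovery replicates,
300 null replicates for stepwise calibration (binomial check at α 0.01) and
200 simulation replicates for VPC calibration.  These sizes were chosen as
the smallest that leave the medians stable against the published interval
widths; all are arguments, not constants.

## Known limitations

* Endpoint latent states are continuous and unbounded; bounded/discrete
  score properties are ignored in fitting, exactly as in the source model
  class.
* The exchangeable baseline correlation (0.3) is an assumption standing in
  for an unpublished covariance block; simulated joint baselines are less
  structured than real ones.
* The Laplace objective is not numerically identical to any particular
  NONMEM estimation method; estimates, not objective values, are the
  comparison surface.
* Shared k_out/Emax_norm/E_plac mean per-endpoint deviations in dynamics are
  absorbed by Emax_m and the residual error.
* PK disposition defaults are placeholders; users with concentration data
  must supply their own PK parameters.
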