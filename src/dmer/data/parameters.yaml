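# Default joint exposure-response parameter set: final-model typical values,
# interindividual variances, eta-sharing scalars, covariate effects and
# additive residual SDs for the 11 dermatomyositis endpoints.
#
# Units: rates week^-1; baselines in score units (enzyme baseline in
# multiples of ULN); emax/emax_norm unitless fractions; covariate effects in
# percent change applied multiplicatively.
shared:
  kout: 0.246          # endpoint turnover rate (week^-1)
  emax_norm: 0.564     # normalizing maximum effect (fraction)
  e_plac: 1.03         # placebo non-steady-state factor

iiv:
  emax_norm: 1.68      # variance, logit scale
  e_plac: 0.00843      # variance, log scale
  block_correlation: 0.3   # exchangeable correlation of baseline etas
                           # (full covariance block not published; configurable)

endpoints:
  cdasi_d:
    label: CDASI-D
    range: [0, 32]
    direction: lower
    baseline: 3.62
    emax: -0.121
    ruv_sd: 1.43
    iiv_baseline: 0.564
  cdasi_a:
    label: CDASI-A
    range: [0, 100]
    direction: lower
    baseline: 28.3
    emax: -1.0
    emax_fixed: true
    ruv_sd: 4.67
    iiv_baseline: 0.147
  sf36_pfd:
    label: SF-36 PFD
    range: [0, 100]
    direction: higher
    baseline: 43.8
    emax: 0.0735
    ruv_sd: 4.68
    iiv_baseline: 0.0589
  sf36_mcs:
    label: SF-36 MCS
    range: [0, 100]
    direction: higher
    baseline: 48.2
    emax: 0.0
    emax_fixed: true
    ruv_sd: 5.78
    iiv_baseline: 0.0311
  phga:
    label: PhGA
    range: [0, 100]
    direction: lower
    baseline: 54.7
    emax: -1.0
    emax_fixed: true
    ruv_sd: 12.0
    iiv_baseline: 0.0904
  ptga:
    label: PtGA
    range: [0, 100]
    direction: lower
    baseline: 59.4
    emax: -0.797
    ruv_sd: 15.4
    iiv_baseline: 0.111
  enzyme:
    label: Muscle enzymes (xULN)
    range: [0, .inf]
    direction: lower
    baseline: 1.19
    emax: -0.511
    ruv_sd: 0.352
    iiv_baseline: 0.0591
    is_enzyme: true
  exga:
    label: ExGA
    range: [0, 10]
    direction: lower
    baseline: 2.97
    emax: -1.0
    emax_fixed: true
    ruv_sd: 1.2
    eta_source: phga       # part of ExGA IIV comes from PhGA
    eta_scalar: 1.0        # fixed
    eta_own_var: 0.0592    # lone (non-block) independent part
  haq:
    label: HAQ (%)
    range: [0, 100]
    direction: lower
    baseline: 37.2
    emax: -0.736
    ruv_sd: 19.0
    iiv_baseline: 0.24     # single variance describing HAQ and MMT-8
  mmt8:
    label: MMT-8
    range: [0, 150]
    direction: higher
    baseline: 113.0
    emax: 0.176
    ruv_sd: 7.32
    eta_source: haq        # MMT-8 eta derived from the HAQ eta
    eta_scalar: -0.378
  tis_phga:
    label: TIS PhGA
    range: [0, 10]
    direction: lower
    baseline: 4.83
    emax: -1.0
    emax_fixed: true
    ruv_sd: 1.06
    eta_source: phga       # PhGA and TIS-PhGA share one eta
    eta_scalar: 1.0

covariates:
  - covariate: MPDM
    endpoint: cdasi_a
    target: baseline
    percent: -51.8
  - covariate: MPDM
    endpoint: sf36_pfd
    target: baseline
    percent: -24.3
  - covariate: MPDM
    endpoint: null
    target: e_plac
    percent: 6.55

pk:
  # Disposition typicals are placeholders on a typical-monoclonal scale
  # (not study estimates); only K_SS enters the response layer.
  CL: 1.6      # L/week
  V1: 3.5      # L
  V2: 2.6      # L
  Q: 4.9       # L/week
  K_SS: 1.0    # ug/mL
  infusion_duration_hr: 1.0

simulation:
  # Empirical shift of SPDM baseline MMT-8 toward healthy normal used only
  # in clinical trial simulation; values capped at the scale maximum 150.
  mmt8_spdm_shift: 0.946      # fraction of the gap to 150 removed
  mmt8_spdm_var_shrink: 0.25  # multiplier on the SPDM MMT-8 eta variance
  uln_catalogue: [40.0, 200.0, 250.0]  # representative enzyme ULNs (U/L)
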