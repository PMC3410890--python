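# Default parameter set for the soil greenhouse-gas flux model.
#
# Every parameter carries value, units and an uncertainty descriptor:
#   {kind: posterior_sd, sd: <x>}  -- summarised Bayesian-calibration posterior
#   {kind: default_cv, cv: 0.10}   -- normal with 10 % coefficient of variation
#   {kind: fixed}                  -- not redrawn in Monte Carlo ensembles
# "calibrated: true" marks parameters that the site calibration targets.
schema_version: 1

gases:
  co2:
    # flux units: ug C m-2 s-1
    f_slope:
      value: 0.25
      units: "ug C m-2 s-1 per CNR unit"
      calibrated: true
      uncertainty: {kind: posterior_sd, sd: 0.02}
    f_intercept:
      value: -0.5
      units: "ug C m-2 s-1"
      calibrated: true
      uncertainty: {kind: posterior_sd, sd: 0.05}
    wfps_a:
      value: 0.05
      units: "fraction"
      calibrated: true
      uncertainty: {kind: posterior_sd, sd: 0.01}
    wfps_b:
      value: 0.55
      units: "fraction"
      calibrated: true
      uncertainty: {kind: posterior_sd, sd: 0.03}
    wfps_c:
      value: 1.0
      units: "fraction"
      calibrated: true
      uncertainty: {kind: posterior_sd, sd: 0.0}
    wfps_d:
      value: 1.5
      units: "dimensionless"
      calibrated: true
      uncertainty: {kind: posterior_sd, sd: 0.1}
    temp_p:
      value: 0.07
      units: "degC-1"
      calibrated: true
      uncertainty: {kind: posterior_sd, sd: 0.004}
  ch4:
    # flux units: ug C m-2 h-1 (uptake magnitude)
    f_slope:
      value: -30.0
      units: "ug C m-2 h-1 per Mg m-3"
      calibrated: true
      uncertainty: {kind: posterior_sd, sd: 2.0}
    f_intercept:
      value: 63.0
      units: "ug C m-2 h-1"
      calibrated: true
      uncertainty: {kind: posterior_sd, sd: 4.0}
    wfps_a:
      value: 0.02
      units: "fraction"
      calibrated: true
      uncertainty: {kind: posterior_sd, sd: 0.005}
    wfps_b:
      value: 0.35
      units: "fraction"
      calibrated: true
      uncertainty: {kind: posterior_sd, sd: 0.02}
    wfps_c:
      value: 0.95
      units: "fraction"
      calibrated: true
      uncertainty: {kind: posterior_sd, sd: 0.02}
    wfps_d:
      value: 1.2
      units: "dimensionless"
      calibrated: true
      uncertainty: {kind: posterior_sd, sd: 0.1}
    temp_p:
      value: 0.02
      units: "degC-1"
      calibrated: true
      uncertainty: {kind: posterior_sd, sd: 0.002}
  n2o:
    # flux units: ug N m-2 h-1
    f_slope:
      value: 0.10
      units: "ug N m-2 h-1 per CNR unit"
      calibrated: true
      uncertainty: {kind: posterior_sd, sd: 0.01}
    f_intercept:
      value: 0.2
      units: "ug N m-2 h-1"
      calibrated: true
      uncertainty: {kind: posterior_sd, sd: 0.03}
    wfps_a:
      value: 0.10
      units: "fraction"
      calibrated: true
      uncertainty: {kind: posterior_sd, sd: 0.01}
    wfps_b:
      value: 0.80
      units: "fraction"
      calibrated: true
      uncertainty: {kind: posterior_sd, sd: 0.03}
    wfps_c:
      value: 1.0
      units: "fraction"
      calibrated: true
      uncertainty: {kind: posterior_sd, sd: 0.0}
    wfps_d:
      value: 2.0
      units: "dimensionless"
      calibrated: true
      uncertainty: {kind: posterior_sd, sd: 0.15}
    temp_p:
      value: 0.08
      units: "degC-1"
      calibrated: true
      uncertainty: {kind: posterior_sd, sd: 0.006}

land_surface:
  t_snow:
    value: 0.0
    units: "degC"
    uncertainty: {kind: default_cv, cv: 0.10}
  t_melt:
    value: 1.0
    units: "degC"
    uncertainty: {kind: default_cv, cv: 0.10}
  s_melt:
    value: 40.0
    units: "mm degC-1"
    uncertainty: {kind: default_cv, cv: 0.10}
  s_st:
    value: 0.92
    units: "dimensionless"
    calibrated: true
    uncertainty: {kind: posterior_sd, sd: 0.03}
  i_st:
    value: 1.2
    units: "degC"
    calibrated: true
    uncertainty: {kind: posterior_sd, sd: 0.2}
  t_snowsoil:
    value: 0.5
    units: "degC"
    calibrated: true
    uncertainty: {kind: posterior_sd, sd: 0.2}
  r_pre:
    value: 0.7
    units: "ratio"
    calibrated: true
    uncertainty: {kind: posterior_sd, sd: 0.05}
  r_pet:
    value: 0.7
    units: "ratio"
    calibrated: true
    uncertainty: {kind: posterior_sd, sd: 0.05}
  t_w:
    value: 2.0
    units: "degC"
    calibrated: true
    uncertainty: {kind: posterior_sd, sd: 0.2}
  wfps_memory:
    value: 0.5
    units: "ratio"
    calibrated: true
    uncertainty: {kind: posterior_sd, sd: 0.05}
  wfps_lnr_slope:
    value: 0.15
    units: "fraction per ln(r) unit"
    calibrated: true
    uncertainty: {kind: posterior_sd, sd: 0.02}

atmosphere:
  ch4_reference_ppb:
    value: 1790.0
    units: "ppb"
    uncertainty: {kind: fixed}
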