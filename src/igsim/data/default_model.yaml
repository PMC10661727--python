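model:
  cl_ref: 0.1
  vc_ref: 3.0
  q_ref: 0.3
  vp_ref: 3.0
  ka_scig: 0.25
  ka_fscig: 0.2
  f_scig: 0.7
  f_fscig: 0.73
  ksyn_ref: 0.2
  lbm_ref: 56.0
  theta_cl: 0.88
  theta_v: 1.0
  omega_cl: 0.25
  omega_vc: 0.25
  omega_ka: 0.3
  omega_ksyn: 0.3
regimens:
  scig:
    formulation: scig
    dose_per_kg: 0.15
    interval: 7.0
    horizon: 140.0
    first_dose_time: 0.0
  fscig:
    formulation: fscig
    dose_per_kg: 0.6
    interval: 28.0
    horizon: 140.0
    first_dose_time: 0.0
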