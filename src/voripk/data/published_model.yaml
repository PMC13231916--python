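# Published final population pharmacokinetic parameter estimates of voriconazole in adults on
# ECMO (the packaged default parameter set).  IIV is stored as %CV of the
# log-normal random effect; omegas are recovered via omega = sqrt(ln(1+(cv/100)^2)).
theta:
  V: 144.79        # L
  CL1: 6.22        # L/h
  CL2: 22.26       # L/h
  Tswitch: 87.96   # h
  k: 0.1           # 1/h, fixed
  CLseq0: 17.68    # L/h
  Thalf_seq: 4.17  # h
iiv_cv_percent:
  V: 27.6
  CL1: 77.0
  CL2: 86.7
  Tswitch: 81.9
beta_geno: -0.44   # natural-log shift of CL2 for IM/PM carriers
sigma_add: 0.091   # mg/L
sigma_prop: 0.12   # fraction
rse_percent:
  V: 8.04
  CL1: 24.8
  CL2: 24.4
  Tswitch: 29.4
  CLseq0: 117.3
  Thalf_seq: 83.7
  beta_geno: 60.0
  sigma_add: 61.3
  sigma_prop: 21.5
shrinkage_percent:
  V: 22.0
  CL1: 14.1
  CL2: 15.9
  Tswitch: 39.6
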