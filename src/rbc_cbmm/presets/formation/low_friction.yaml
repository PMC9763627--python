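name: formation iFgB VTS, low-friction variant
membrane:
  es0: 6.54 uN/m
  eb: 2.4e-19 J
  ka: 0.288 N/m
  kd: 0.144 N/m
  k0: 0.432 N/m
  k_omega: 220 J/m^3
  eta_m: 0.7 uN.s/m
  mass_total: 1.0 mg
adhesion:
  gamma_ifg: 1.0 uJ/m^2
  scheme: vts
  beta: 0.05 nm^-1
  r0: 20 nm
  r_cutoff: 100 nm
  r_glyco: 0 nm
  mu_gap: 1.8 cP
protocol:
  protocol: formation
  duration: 24 s
  n_vertices: 642
  snapshot_interval: 0.25 s
  nave0: 0.0
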