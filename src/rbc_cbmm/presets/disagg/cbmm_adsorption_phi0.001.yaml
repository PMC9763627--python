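name: disaggregation CBMM with bulk exchange, phi0=0.001
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
  gamma_mfg: 0.25 uJ/m^2
  scheme: vts
  beta: 0.05 nm^-1
  r0: 20 nm
  r_cutoff: 100 nm
  r_glyco: 5 nm
  mu_gap: 3.6 cP
transport:
  d_mfg: 1e-15 m^2/s
  adsorption_on: true
  phi0: 0.001
  n0: 1.0
protocol:
  protocol: disaggregation
  duration: 40 s
  pulling_rate: 0.15 um/s
  equilibration: 1.5 s
  initial_offset_fraction: 0.3
  n_vertices: 642
  snapshot_interval: 0.1 s
  nave0: 2.0
  escape_threshold: 32 pN
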