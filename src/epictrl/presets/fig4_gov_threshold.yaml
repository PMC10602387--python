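# Costly government intervention (gamma_g = 0.5) with a healthcare threshold
# in the government's infection cost (i_hc = 0.01); individuals face a
# constant cost alpha = 100. Scan mode traces the two policy branches over
# the government's maximum infection cost alpha_g1.
name: fig4_gov_threshold
mode: scan
epidemic:
  kappa_star: 4.0
  i0: 3.0e-8
utility:
  f: 1.0
  beta: 1.0
  cost:
    alpha0: 100.0
    constant: true
government:
  f_g: 1.0
  beta_g: 1.0
  gamma_g: 0.5
  cost:
    alpha0: 100.0
    alpha1: 1000.0
    i_hc: 0.01
    sigma: 300.0
grid:
  tf: 150.0
  n: 1501
scan:
  parameter: alpha_g1
  values: [800.0, 1600.0, 2400.0, 3200.0]
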