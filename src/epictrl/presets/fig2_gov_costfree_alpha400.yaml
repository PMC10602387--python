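# Cost-free government intervention (gamma_g = 0) with matched preferences
# (alpha_g = alpha = 400 constant): the optimal incentive field steers the
# population equilibrium onto the utilitarian optimum.
name: fig2_gov_costfree_alpha400
mode: government
epidemic:
  kappa_star: 4.0
  i0: 3.0e-8
utility:
  f: 1.0
  beta: 1.0
  cost:
    alpha0: 400.0
    constant: true
government:
  f_g: 1.0
  beta_g: 1.0
  gamma_g: 0.0
  cost:
    alpha0: 400.0
    constant: true
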