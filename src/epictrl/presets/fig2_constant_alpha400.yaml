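# Nash equilibrium with constant infection cost alpha = 400
# (kappa* = 4, i0 = 3e-8, f = 1, beta = 1, no intervention).
name: fig2_constant_alpha400
mode: nash
epidemic:
  kappa_star: 4.0
  i0: 3.0e-8
utility:
  f: 1.0
  beta: 1.0
  cost:
    alpha0: 400.0
    constant: true
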