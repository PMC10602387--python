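# Nash equilibrium with a healthcare-threshold infection cost:
# alpha rises from 100 to 400 around i_hc = 0.1 with steepness 300.
name: fig3_threshold
mode: nash
epidemic:
  kappa_star: 4.0
  i0: 3.0e-8
utility:
  f: 1.0
  beta: 1.0
  cost:
    alpha0: 100.0
    alpha1: 400.0
    i_hc: 0.1
    sigma: 300.0
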