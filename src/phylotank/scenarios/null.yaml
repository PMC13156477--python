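# Null configuration: every effect size zero. Downstream statistics must
# hit their calibrated null distributions on this scenario.
seed: 0
n_species: 30
n_bromeliads: 20
mean_colonists: 20.0
beta_size: 0.0
gamma_avoid: 0.0
gamma_size: 0.0
gamma_pred: 0.0
alpha_survival: 0.0
traits:
  size_pref: {model: white, sigma: 1.0, root: 0.0}
  predator_avoid: {model: white, sigma: 1.0, root: 0.0}
  size_tol: {model: white, sigma: 1.0, root: 0.0}
  predator_vuln: {model: white, sigma: 1.0, root: 0.0}
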