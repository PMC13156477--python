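# Conserved defense: strong predator effects carried by Brownian-motion
# (phylogenetically conserved) traits — avoidance indices recovered from
# the colonization experiment should show detectable phylogenetic signal.
seed: 0
n_species: 30
n_bromeliads: 20
mean_colonists: 20.0
beta_size: 0.0
gamma_avoid: 2.0
gamma_size: 0.0
gamma_pred: 2.5
alpha_survival: 0.0
traits:
  size_pref: {model: white, sigma: 1.0, root: 0.0}
  predator_avoid: {model: brownian, sigma: 1.0, root: 0.0}
  size_tol: {model: white, sigma: 1.0, root: 0.0}
  predator_vuln: {model: brownian, sigma: 1.0, root: 1.0}
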