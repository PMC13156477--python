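# Conserved habitat filtering: strong, phylogenetically conserved
# preference for large habitats (Brownian size_pref around a positive
# root), no predator effects. Richness should rise with habitat size at
# every taxonomic scale.
seed: 0
n_species: 30
n_bromeliads: 20
mean_colonists: 20.0
beta_size: 2.0
gamma_avoid: 0.0
gamma_size: 0.0
gamma_pred: 0.0
alpha_survival: 0.0
traits:
  size_pref: {model: brownian, sigma: 0.3, root: 1.0}
  predator_avoid: {model: white, sigma: 1.0, root: 0.0}
  size_tol: {model: brownian, sigma: 0.3, root: 0.0}
  predator_vuln: {model: white, sigma: 1.0, root: 0.0}
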