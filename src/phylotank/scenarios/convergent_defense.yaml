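# Convergent defense: strong predator effects (oviposition deterrence and
# consumptive mortality) carried by labile, white-noise traits — predator
# responses scattered across the tree, so no phylogenetic signal expected.
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
  predator_avoid: {model: white, sigma: 1.0, root: 0.5}
  size_tol: {model: white, sigma: 1.0, root: 0.0}
  predator_vuln: {model: white, sigma: 1.0, root: 1.0}
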