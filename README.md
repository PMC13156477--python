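# phylotank

Community phylogenetics of bromeliad invertebrate assembly: standardized
relatedness metrics under permutation nulls, species-level response indices
from colonization/extinction experiments, phylogenetic-signal tests, and
AICc model selection across taxonomic scales — plus a synthetic-study
simulator that emulates the survey + two-experiment design this kind of
analysis is built on.

## The problem

Tank bromeliads hold small aquatic invertebrate communities (annelids,
beetle and fly larvae, mosquitoes) that assemble through colonization by
ovipositing adults and local extinction, the latter driven largely by
predatory damselfly larvae. Two environmental drivers — habitat size
(water-holding capacity, mL) and predator presence — shape how many and
*which* species co-occur. If the traits mediating those responses are
phylogenetically conserved, habitat filtering and predation leave
signatures in the *relatedness* of co-occurring species, not just in
species richness. `phylotank` implements the full analytical chain for
testing this with a survey of natural communities plus experiments that
isolate the colonization and extinction stages.

## The statistics

For each local community (one bromeliad) with patristic distances d(i, j)
from a rooted, branch-length phylogeny:

* **MPD / MNTD** — mean pairwise distance among members, and mean distance
  from each member to its nearest co-occurring relative; optionally
  abundance-weighted with weights a_i = count_i^q.
* **NRI / NTI** — negated standardized effect sizes against the
  *taxa-labels* null (uniform permutation of species labels over the pool,
  preserving each community's richness):

      NRI = −(MPD_obs − mean_null) / sd_null,   NTI analogous with MNTD.

  Positive values mean phylogenetic clustering. Pools of ≤ 8 species can be
  evaluated by exhaustive enumeration of all label permutations.
* **Faith's PD** and species richness, with their Pearson correlation used
  to justify dropping PD from the model stage when collinear.
* **Response indices** — per-species z-scores comparing where a species'
  individuals ended up against random-assembly nulls: mean log₁₀ habitat
  size of colonists vs. uniform placement; fraction of colonists in
  predator-free plants vs. a binomial null; and for the extinction
  experiment, survivor-weighted versions under a fixed-survivor-count
  (multivariate hypergeometric) null. |z| ≥ 1.96 flags two-sided
  significance.
* **Blomberg's K** with a tip-shuffle permutation test (and Pagel's λ as an
  option) asks whether those response indices are phylogenetically
  conserved, at three nested taxonomic scales: all invertebrates, insects
  only (no annelids), dipterans only.
* **AICc model selection** — each standardized diversity metric is
  regressed on habitat size (linear + quadratic, centered log₁₀ capacity),
  predation (binary treatment or continuous damselfly biomass), their
  interaction, and survey covariates; all marginality-respecting submodels
  are ranked by AICc = −2 ln L + 2k + 2k(k+1)/(n−k−1), with ties within
  2 ΔAICc broken toward the fewest terms, and per-term partial R²
  reported.

## Worked example

Simulate a study under conserved habitat filtering and run the pieces:

```python
import numpy as np
import phylotank as pt

study = pt.simulate_study(pt.load_scenario("conserved_filter"))
table, meta = study.colonization
pool = pt.build_pool(table)
dist = study.tree.patristic_matrix().submatrix(pool)
ses = pt.ses_metrics(table, dist, pool,
                     weighting=pt.ROLE_WEIGHTING["colonization"],
                     n_runs=999, rng=np.random.default_rng(0))
print(ses[ses.metric == "mpd"].head(4)[
    ["bromeliad", "observed", "null_mean", "null_sd", "nri_or_nti"]])
```

```
bromeliad  observed  null_mean  null_sd  nri_or_nti
    col01     0.315      8.248    5.189       1.529
    col02     3.336      8.124    2.733       1.752
    col03     6.878      8.209    3.203       0.415
    col04     3.566      8.276    3.243       1.452
```

Each row is one bromeliad: its observed abundance-weighted MPD, the mean
and SD of that metric over 999 taxa-labels relabelings, and the resulting
NRI — all positive here, i.e. colonizing communities are phylogenetically
clustered, as expected when a conserved trait controls who colonizes.

```python
idx = pt.size_preference(table, meta)
print(idx.sort_values("z", ascending=False).head(3)[
    ["species", "observed", "null_mean", "z", "significant"]])
```

```
species  observed  null_mean      z  significant
  sp010     2.957      2.337  7.238         True
  sp013     2.902      2.337  6.843         True
  sp027     2.926      2.337  6.609         True
```

These species' colonists sat in far larger plants (mean log₁₀ capacity
2.96 vs. the 2.34 expected under arbitrary choice). Mapping the indices
onto the tree:

```python
sig = pt.blomberg_k(study.tree,
                    idx.dropna(subset=["z"]).set_index("species")["z"],
                    n_perm=999, rng=np.random.default_rng(1))
# Blomberg K = 0.074, permutation p = 0.025 (n = 30 species)
```

The permutation test detects the (Brownian-simulated) conservatism in size
preference.

The same chain runs from the shell:

```bash
phylotank simulate --scenario conserved_filter --seed 1 --outdir sim/
phylotank analyze --tree sim/tree.nwk --survey sim/survey.csv \
    --colonization sim/colonization.csv --extinction sim/extinction.csv \
    --extinction-introduced sim/extinction_introduced.csv \
    --species-meta sim/species_meta.csv --seed 1 --outdir out/
```

which writes `metrics.csv`, `models.csv`, `indices.csv`, `signal.csv`, a
long-format `heatmap.csv` of per-term partial R² / sign / significance per
(dataset × scale × metric), and a `manifest.json` with config hash and
output checksums (reruns are bit-identical).

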