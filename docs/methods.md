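# Methods

This note documents the models, null constructions, numerical choices, and
the synthetic-data generator behind `phylotank`, in the order the pipeline
runs.

## Data model

A study consists of a rooted phylogeny with branch lengths over the species
pool, three bromeliad × species count matrices (survey, colonization
experiment, extinction experiment), per-bromeliad covariates, and species
metadata. Counts are integers: colonization and extinction are events that
happen to individuals, and the experiment readers reject fractional
abundances. Extinction tables carry the designed introduction counts and
enforce introduced(b, s) ≥ surviving(b, s) cell-wise. Habitat size is
log₁₀ of water capacity in mL (any fixed base only rescales regression
coefficients; one base is fixed for reproducibility). Clade membership
(Annelida / Diptera / Coleoptera / other insects) comes from the
species-metadata table, never from parsing tip names, so taxonomic-scale
subsetting is explicit and testable.

Patristic distances are tip-to-tip path lengths; pruning collapses the
degree-2 nodes it creates with summed branch lengths, so distances among
retained tips are invariant (tested against a graph shortest-path oracle
and by a prune/subset commutativity property). Trees read from Newick may
carry a root stem edge; all root-to-node depths used in the package exclude
it. Blomberg's K is provably invariant to that stem (GLS residuals are
orthogonal to the intercept), Pagel's λ is not, and ape/phytools drop it —
excluding it keeps the two routes identical (our VCV matches `ape::vcv` to
1e-15 on shared trees).

## Null models

**Taxa-labels shuffle.** One draw permutes the species labels of the pool
uniformly at random — equivalently the rows/columns of the patristic
distance matrix — leaving community membership, abundances, and hence
per-community richness untouched. The ensemble default is 999 runs (the
field convention for rank p-values; run count is configurable). For pools
of ≤ 8 species the full permutation set can be enumerated instead; the
exhaustive null uses population moments, the Monte-Carlo null the sample
(n−1) SD. A community equal to the entire pool has a constant null and is
flagged degenerate; the degeneracy test uses a relative floor
(sd ≤ 1e−12·max(1, |mean|)) because a constant ensemble can acquire
~1e−16 spread from floating-point summation order.

**Morphospecies randomization.** Individuals identified only to
morphospecies (unsequenced) appear under morphospecies-level columns; each
is independently assigned a molecular identity uniformly among the
morphospecies' members (a frequency-weighted option exists). Metrics can be
averaged over R = 100 identity randomizations (configurable); both the mean
of per-randomization effect sizes and the effect size of run-averaged
moments are reported, since either aggregation is defensible.

## Relatedness metrics

Weighted MPD is Σ_{i<j} a_i a_j d(i,j) / Σ_{i<j} a_i a_j and weighted MNTD
is Σ a_i·nn_i / Σ a_i, with weights a = count^q. The abundance exponent
defaults to q = 0.5 for survey and colonizing communities and is fixed at
q = 1 for the extinction experiment (extinctions happen to individuals).
The square-root default follows the stated purpose of abundance
transformation in this design — keeping species with large clutches from
overshadowing the rest while still reflecting the number of colonization
events; a squared-abundance option (q = 2) is provided because that
transform is also in circulation for colonization-event weighting, but
squaring amplifies rather than dampens dominance, so it is not the
default. Faith's PD includes the path to the root by default (the dominant
convention; configurable). NRI/NTI are the negated SES of MPD/MNTD, so
positive values mean clustering. Degenerate cells (richness < 2, null SD
at the floor) propagate as missing values and are dropped from model fits
with a logged count.

## Response indices

All four indices have exact nulls, used by default; Monte-Carlo versions
of the same nulls exist for cross-checking and agree within Monte-Carlo
error on the worked cases.

* *Size preference* (colonization): observed mean log₁₀ size over a
  species' n colonists; null places each colonist independently and
  uniformly over the B plants, so z = (obs − mean(logsize)) /
  √(var_pop(logsize)/n). Per-individual uniform placement (not weighted by
  plant abundance or capacity) is the reading of "arbitrary choice"; a
  capacity-weighted null is available for sensitivity analysis.
* *Predator avoidance* (colonization): fraction of colonists in
  predator-free plants against Binomial(n, p) with p = (#predator-free)/B.
* *Size / predator sensitivity* (extinction): the species' survivor total
  k is held fixed and which of its N introduced individuals survive is
  drawn uniformly without replacement, giving finite-population moments
  mean = μ_pop and var = (σ²_pop/k)·(N−k)/(N−1) for the survivor mean of
  any per-plant value (log size, or the predator-free indicator). Fixing
  survivors per species (not per bromeliad) is the construction consistent
  with "individuals persisted at random". Size means use log, consistent
  with every other analysis.

Species with fewer than two contributing individuals are skipped; all-
or-none survival, single-site introductions, and all-predator-free layouts
give degenerate nulls and are flagged. Significance is two-sided at
|z| ≥ 1.96 with no multiple-testing correction (a Benjamini–Hochberg
option exists, off by default). Clutches are not collapsed: counts are
individuals.

## Phylogenetic signal

Blomberg's K with the BM-expected ratio (tr V − n/(1ᵀV⁻¹1))/(n−1) and a
tip-shuffle permutation test on the GLS MSE (smaller MSE ⇒ stronger
signal), p = (1 + #{MSE_null ≤ MSE_obs})/(n_perm + 1). K matches
`picante::Kcalc` to printed precision on shared inputs (tested via
Rscript). Pagel's λ (ML on the λ-scaled covariance, bounded to [0, 1]) is
the alternative statistic; results carry the method used. Traits are the
response-index z-scores directly. Tests need ≥ 4 species and a
non-constant trait; scales with fewer than 12 species are reported
descriptively with a low-power flag instead of a formal test — with the 10
designed extinction species a permutation test has no meaningful
resolution. The scale set mirrors the community-analysis scales
(invertebrates / Insecta / Diptera).

## Model selection

Candidates are every subset of the role's terms that respects marginality
(quadratic size only with linear size; interaction only with both mains):
experiments use {size, size², predator(0/1), size × predator}, the survey
adds detritus and uses standardized damselfly biomass as the continuous
predator variable. Size is centered log₁₀ capacity (centering tames
size/size² collinearity; coefficients are reported on the centered scale).
Responses are optionally Box–Cox (strictly positive) or Yeo–Johnson
transformed when full-model diagnostics fail (Shapiro–Wilk and
Breusch–Pagan at α = 0.05), with λ from profile ML on a −2…2 grid in steps
of 0.01, then standardized to mean 0 / SD 1 so coefficients are comparable
across metrics. Gaussian log-likelihood uses the ML variance (SSE/n);
k counts intercept, slopes, and the residual variance, and
AICc = −2 ln L + 2k + 2k(k+1)/(n−k−1). Selection takes the minimum AICc,
except that all models within 2 ΔAICc compete on fewest terms (then lower
AICc). Per-term partial R² is (SSE_−t − SSE_full)/SSE_−t, where dropping a
term also drops its dependents (a main takes its quadratic and
interactions with it). Term significance inside the chosen model is
reported from t-tests at α = 0.05 — a reporting convention, independent of
selection.

## Synthetic-data generator

The generator is the package's testbed and defines its study conditions:

* **Tree** — pure-birth (Yule, rate 1.0) ingroup of n − m species,
  ultrametric; dendropy's birth–death sampler stops exactly at the n-th
  speciation, so every tip is extended by the Yule waiting time to the
  next event (keeping ultrametricity and a non-singular BM covariance).
  An optional m-species outgroup ("annelids", default m = 3) attaches on a
  stem of 3× the ingroup depth with a shallow crown, reproducing the
  long-branch, unbalanced shape that makes whole-tree metrics sensitive to
  deep lineages. A subclade of ~20% of the ingroup is labeled Coleoptera
  and the rest Diptera, so the three taxonomic scales have distinct pools.
* **Traits** — per response trait, Brownian motion with rate σ² along
  branches (conserved) or iid Normal draws (convergent/labile), selectable
  per scenario so conserved-filtering and convergent-defense hypotheses
  are both generatable.
* **Experiments** — 20 bromeliads as 10 capacity levels (geometric over
  the role's range: colonization 45–1050 mL, extinction 40–490 mL) × 2
  predator arms. Colonization: each species receives Poisson(λ = 20)
  colonists, each landing on plant b with probability ∝ exp(β·pref_s·z_b −
  γ_avoid·avoid_s·pred_b) with z the standardized log size. Extinction: 10
  designed species (one outgroup member plus ingroup species spread across
  the tip order) are introduced with counts scaling as a power of capacity
  (base 6 per plant at the geometric-mean capacity, slope 1.0); each
  individual survives with probability logistic(α + γ_size·tol_s·z_b −
  γ_pred·vuln_s·pred_b).
* **Survey** — 20 plants with continuous log-uniform capacities
  (22–1446 mL); colonization followed by extinction on the same plants.
  Damselfly biomass grows as a power of capacity with log-normal scatter
  (log-SD 1.0) and is absent below 60 mL, emulating the natural
  size–predator covariance while remaining a *noisy* proxy of size;
  detritus follows a log-log rule with log-SD 0.7. The power-law slopes
  are placeholders (set to 1.0; the fitted field coefficients are not
  published) and the scatter is set to the R² ≈ 0.4–0.7 typical of field
  size-scaling regressions — with near-deterministic scatter the survey
  covariates become clones of habitat size and no selection procedure
  could attribute richness to size rather than its proxies.

All randomness flows from a single seed through spawned generators, so a
(config, seed) pair reproduces every dataset bit-identically.

Bundled scenarios: `null` (all effect sizes zero — the exact null of every
downstream statistic), `conserved_filter` (β = 2.0 on a Brownian size
preference around a positive root), `convergent_defense` (strong predator
effects, γ_avoid = 2.0 / γ_pred = 2.5, carried by white-noise traits), and
`conserved_defense` (the same strengths on Brownian traits).

## What the simulator does and does not show

The generator reproduces the statistical structure the analysis assumes —
design geometry, count nature, effect pathways, phylogenetic conservatism
— but not everything about real bromeliad data: no spatial autocorrelation
among plants, no within-season population dynamics or emergence, no
multigenerational annelid reproduction (a per-species rate multiplier
would stand in for it), no cryptic-diversity structure unless
morphospecies columns are constructed explicitly, and independent survival
across individuals (no density dependence or predator satiation).
Calibration results on simulated data therefore validate the statistical
machinery, not field-level realism.

With all effects zero, NRI/NTI pool to mean ≈ 0, SD ≈ 1 across replicated
studies; the four response indices and the K permutation test reject at
the nominal 5%. These calibrations use 500 simulated studies (relatedness)
and ≥ 1000 species-datasets / white-noise traits (indices, signal) — sizes
chosen so sampling error on a 5% rate is well under a percentage point
while the whole battery stays a few minutes of CPU. One caveat on PD: with
all effects zero the survey's richness range is narrow and the long-stem
outgroup decouples Faith's PD from richness (r ≈ 0.4–0.6); under
size-structured assembly, where richness actually varies, r > 0.9 — the
regime in which dropping PD as collinear with richness is justified.

## Known limitations

* The exhaustive relatedness null enumerates pool permutations and is
  capped at 8 species; larger pools are Monte-Carlo only.
* Closed-form index nulls assume independent individuals; clutch-mates
  that colonize together violate independence and inflate |z| for
  clutch-laying species (the abundance-exponent option in the relatedness
  metrics is the corresponding guard there).
* Pagel's λ is bounded to [0, 1]; implementations that allow λ slightly
  above 1 can differ at the upper boundary.
* OLS with AICc ignores spatial structure and model-averaging; mixed
  models are out of scope.
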