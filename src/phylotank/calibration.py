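"""Study-level calibration and parameter-recovery experiments.

The simulator's null configuration (every effect size zero) is the exact
null of every downstream statistic, so replicated simulation doubles as the
master calibration suite:

* NRI/NTI over null colonization datasets should be ~N(0, 1);
* each of the four response indices should reject |z| >= 1.96 in ~5% of
  null species-datasets;
* the Blomberg-K permutation test should reject at alpha = 0.05 for ~5% of
  white-noise traits.

Effect-bearing scenarios check that the pipeline recovers what was put in:
under conserved habitat filtering, AICc selects a positive richness ~ size
term at every taxonomic scale; under strong predation, the extinction
experiment's predator term is selected with negative sign on richness; with
Brownian-conserved avoidance traits, the signal test detects conservatism.

Every function takes a seed and returns plain dicts, and is driven entirely
by the package's own simulator — nothing here reads external data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import SCALES, subset_taxonomic_scale
from .metrics import ROLE_WEIGHTING, ses_metrics
from .models import build_design, fit_candidates, standardize, transform_response
from .nulls import build_pool
from .responses import Z_THRESHOLD, compute_response_indices
from .signal import blomberg_k
from .simulate import (
    TRAIT_NAMES, SimulationConfig, TraitModel, load_scenario, simulate_colonization,
    simulate_extinction, simulate_study, simulate_traits, simulate_tree,
)


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _simulate_parts(config: SimulationConfig, rngs):
    tree = simulate_tree(config, rngs[0])
    traits = {n: simulate_traits(tree, config.traits[n], rngs[1])
              for n in TRAIT_NAMES}
    return tree, traits


def nri_nti_null_calibration(
    n_replicates: int = 500, n_runs: int = 999, seed: int = 0
) -> dict:
    """Mean and SD of NRI/NTI over null colonization datasets.

    Simulates ``n_replicates`` colonization experiments with all effect
    sizes zero (20 bromeliads, 30 species), computes abundance-weighted
    NRI/NTI per bromeliad against the taxa-labels null, and pools the
    standardized effect sizes; under the null they should be ~N(0, 1).
    """
    master = _spawn(seed, 1)[0]
    vals: dict[str, list[float]] = {"mpd": [], "mntd": []}
    for rep in range(n_replicates):
        cfg = SimulationConfig(seed=seed + rep)
        rngs = _spawn(seed * 1000003 + rep, 3)
        tree, traits = _simulate_parts(cfg, rngs)
        table, _ = simulate_colonization(tree, traits, cfg, rngs[2])
        pool = build_pool(table)
        dist = tree.patristic_matrix().submatrix(pool)
        ses = ses_metrics(table, dist, pool, n_runs=n_runs, rng=master,
                          weighting=ROLE_WEIGHTING["colonization"])
        for m in vals:
            vals[m] += list(ses.loc[ses["metric"] == m, "ses"].dropna())
    out = {}
    for m, label in (("mpd", "nri"), ("mntd", "nti")):
        a = -np.asarray(vals[m])  # NRI/NTI sign convention
        out[f"{label}_null_mean"] = float(a.mean())
        out[f"{label}_null_sd"] = float(a.std())
        out[f"{label}_n"] = len(a)
    return out


def response_null_rejection_rates(
    n_colonization_reps: int = 34,
    n_extinction_reps: int = 100,
    seed: int = 0,
) -> dict:
    """Fraction of null species-datasets with |z| >= 1.96, per index.

    Colonization replicates contribute ~30 species each to the two
    colonization indices; extinction replicates contribute 10 designed
    species each to the two sensitivity indices.  Nominal rate: 5%.
    """
    frames = []
    for rep in range(max(n_colonization_reps, n_extinction_reps)):
        cfg = SimulationConfig(seed=seed + rep)
        rngs = _spawn(seed * 2000003 + rep, 4)
        tree, traits = _simulate_parts(cfg, rngs)
        args = {}
        if rep < n_colonization_reps:
            args["colonization"] = simulate_colonization(tree, traits, cfg, rngs[2])
        if rep < n_extinction_reps:
            args["extinction"] = simulate_extinction(tree, traits, cfg, rngs[3])
        frames.append(compute_response_indices(**args))
    idx = pd.concat(frames, ignore_index=True)
    out = {}
    for kind, grp in idx.groupby("index_kind"):
        z = grp["z"].dropna()
        out[f"{kind}_rejection_rate"] = float((z.abs() >= Z_THRESHOLD).mean())
        out[f"{kind}_n"] = int(len(z))
    return out


def blomberg_null_rejection_rate(
    n_traits: int = 1000, n_perm: int = 199, seed: int = 0
) -> dict:
    """Rejection rate of the K permutation test on white-noise traits
    (nominal: alpha = 0.05, attainable rate with n_perm permutations is
    floor(0.05 * (n_perm + 1)) / (n_perm + 1))."""
    cfg = SimulationConfig(seed=seed)
    rngs = _spawn(seed * 3000017, 2 + n_traits)
    tree = simulate_tree(cfg, rngs[0])
    rejections = 0
    for i in range(n_traits):
        trait = simulate_traits(tree, TraitModel("white", 1.0), rngs[2 + i])
        res = blomberg_k(tree, trait, n_perm=n_perm, rng=rngs[1])
        rejections += res.p_perm <= 0.05
    return {"blomberg_k_null_rejection_rate": rejections / n_traits,
            "blomberg_k_n": n_traits}


def richness_size_recovery(n_replicates: int = 100, seed: int = 0) -> dict:
    """Under conserved habitat filtering, how often AICc selects a positive
    richness ~ size term at every taxonomic scale (survey datasets)."""
    cfg = load_scenario("conserved_filter")
    hits_all = 0
    hits_scale = {s: 0 for s in SCALES}
    for rep in range(n_replicates):
        cfg.seed = seed + rep
        study = simulate_study(cfg)
        table, meta = study.survey
        design = build_design(meta, "survey")
        ok_all = True
        for scale in SCALES:
            sub, _ = subset_taxonomic_scale(table, study.tree, scale)
            rich = (sub.counts.values > 0).sum(axis=1).astype(float)
            tr = transform_response(rich, design, method="auto")
            res = fit_candidates(design, standardize(tr.y), role="survey")
            ok = "size" in res.chosen_terms and res.coefficients["size"] > 0
            hits_scale[scale] += ok
            ok_all &= ok
        hits_all += ok_all
    out = {"richness_size_all_scales_rate": hits_all / n_replicates,
           "richness_size_n": n_replicates}
    for s in SCALES:
        out[f"richness_size_{s}_rate"] = hits_scale[s] / n_replicates
    return out


def extinction_predator_recovery(n_replicates: int = 100, seed: int = 0) -> dict:
    """Under strong predation, how often the extinction experiment's
    predator term is selected with negative sign on richness."""
    cfg = load_scenario("convergent_defense")
    hits = 0
    for rep in range(n_replicates):
        cfg.seed = seed + rep
        rngs = _spawn(seed * 4000037 + rep, 3)
        tree, traits = _simulate_parts(cfg, rngs)
        table, meta = simulate_extinction(tree, traits, cfg, rngs[2])
        rich = (table.counts.values > 0).sum(axis=1).astype(float)
        design = build_design(meta, "extinction")
        res = fit_candidates(design, standardize(rich), role="extinction")
        hits += ("predator" in res.chosen_terms
                 and res.coefficients["predator"] < 0)
    return {"extinction_predator_rate": hits / n_replicates,
            "extinction_predator_n": n_replicates}


def avoidance_signal_power(
    n_replicates: int = 100, n_perm: int = 999, seed: int = 0
) -> dict:
    """Power of the K permutation test to detect conservatism in predator
    avoidance recovered from colonization data simulated with a
    Brownian-conserved avoidance trait (conserved_defense scenario)."""
    cfg = load_scenario("conserved_defense")
    hits = 0
    for rep in range(n_replicates):
        cfg.seed = seed + rep
        rngs = _spawn(seed * 5000011 + rep, 4)
        tree, traits = _simulate_parts(cfg, rngs)
        table, meta = simulate_colonization(tree, traits, cfg, rngs[2])
        from .responses import predator_avoidance

        av = predator_avoidance(table, meta).dropna(subset=["z"])
        trait = av.set_index("species")["z"]
        res = blomberg_k(tree, trait, n_perm=n_perm, rng=rngs[3])
        hits += res.p_perm < 0.05
    return {"avoidance_signal_power": hits / n_replicates,
            "avoidance_signal_n": n_replicates}
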