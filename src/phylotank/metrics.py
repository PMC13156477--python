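"""Relatedness metrics and their standardized effect sizes (NRI / NTI).

For each local community (one bromeliad) we compute

* MPD  — mean patristic distance over pairs of co-occurring species
  (optionally abundance-weighted), a whole-tree measure of clustering;
* MNTD — mean distance from each member to its nearest co-occurring
  relative, sensitive to structure near the tips;
* Faith's PD — total branch length of the minimal subtree spanning the
  community; and
* species richness.

MPD and MNTD are standardized against the taxa-labels null: under a uniform
relabeling of the pool, a k-species community becomes a uniformly random
k-subset, so the null ensemble is evaluated by permuting the distance
matrix.  The indices reported follow the usual sign convention

    NRI = -(MPD_obs - mean_null) / sd_null,   NTI analogous with MNTD,

so positive values mean phylogenetic clustering.  The Monte-Carlo null uses
the sample (n-1) standard deviation; the exhaustive null (all pool
permutations, feasible for pools of <= 8 species) uses the population
standard deviation over the complete permutation set.

Abundance weighting raises counts to a configurable exponent before
weighting.  Natural and colonizing communities default to a square-root
compression (counts reflect clutch-correlated colonization events and a
compressive transform keeps large clutches from dominating; an exponent of
2.0 is available for squared-abundance weighting); extinction communities
fix the exponent at 1 because extinction happens to individuals.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import CommunityTable, DistanceMatrix, Phylogeny
from .nulls import random_permutations

logger = logging.getLogger("phylotank")

EXHAUSTIVE_POOL_LIMIT = 8


@dataclass
class Weighting:
    """Abundance weighting for MPD/MNTD.

    mode="unweighted" ignores counts entirely; mode="weighted" uses
    ``count ** exponent`` as species weights (exponent must be positive).
    """

    mode: str = "weighted"
    exponent: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in ("weighted", "unweighted"):
            raise ValueError(f"unknown weighting mode {self.mode!r}")
        if self.mode == "weighted" and self.exponent <= 0:
            raise ValueError("weighting exponent must be > 0")

    def weights(self, counts: np.ndarray) -> np.ndarray:
        counts = np.asarray(counts, dtype=float)
        if self.mode == "unweighted":
            return np.ones_like(counts)
        return counts**self.exponent


UNWEIGHTED = Weighting(mode="unweighted")

#: weighting defaults per dataset role (see module docstring)
ROLE_WEIGHTING = {
    "survey": Weighting("weighted", 0.5),
    "colonization": Weighting("weighted", 0.5),
    "extinction": Weighting("weighted", 1.0),
}


@dataclass
class SESResult:
    """Standardized effect size of one metric in one community."""

    bromeliad: str
    metric: str  # "mpd" or "mntd"
    observed: float
    null_mean: float
    null_sd: float
    ses: float
    nri_or_nti: float  # -ses; positive = clustering
    degenerate: bool
    richness: int
    n_runs: int


# ---------------------------------------------------------------------------
# Point metrics
# ---------------------------------------------------------------------------


def _community_arrays(
    counts: pd.Series | dict, dist: DistanceMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """(member indices into dist, member counts) for species with count>0."""
    if isinstance(counts, dict):
        counts = pd.Series(counts)
    counts = counts[counts > 0]
    missing = [s for s in counts.index if s not in dist]
    if missing:
        raise ValueError(f"species not in distance matrix: {missing[:5]}")
    idx = dist.indices(list(counts.index))
    return idx, counts.to_numpy(dtype=float)


def _mpd_from_sub(sub: np.ndarray, w: np.ndarray) -> np.ndarray:
    """MPD for a stack of (…, k, k) sub-distance matrices with weights w."""
    W = np.outer(w, w)
    np.fill_diagonal(W, 0.0)
    return np.einsum("...ij,ij->...", sub, W) / W.sum()

def _mntd_from_sub(sub: np.ndarray, w: np.ndarray) -> np.ndarray:
    sub = sub.copy()
    k = sub.shape[-1]
    ii = np.arange(k)
    sub[..., ii, ii] = np.inf
    nn = sub.min(axis=-1)
    return nn @ w / w.sum()


def mpd(
    counts: pd.Series | dict, dist: DistanceMatrix, weighting: Weighting = UNWEIGHTED
) -> float:
    """Mean pairwise patristic distance among community members.

    Unweighted: mean of d(i, j) over unordered pairs.  Weighted:
    sum_{i<j} a_i a_j d(i,j) / sum_{i<j} a_i a_j with a = count**exponent.
    Requires richness >= 2.
    """
    idx, c = _community_arrays(counts, dist)
    if len(idx) < 2:
        raise ValueError("MPD requires at least 2 species")
    sub = dist.values[np.ix_(idx, idx)]
    return float(_mpd_from_sub(sub, weighting.weights(c)))


def mntd(
    counts: pd.Series | dict, dist: DistanceMatrix, weighting: Weighting = UNWEIGHTED
) -> float:
    """Mean distance from each member to its nearest co-occurring relative."""
    idx, c = _community_arrays(counts, dist)
    if len(idx) < 2:
        raise ValueError("MNTD requires at least 2 species")
    sub = dist.values[np.ix_(idx, idx)]
    return float(_mntd_from_sub(sub, weighting.weights(c)))


def richness(counts: pd.Series | dict) -> int:
    if isinstance(counts, dict):
        counts = pd.Series(counts)
    return int((counts > 0).sum())


def faith_pd(
    species: list[str] | pd.Series, tree: Phylogeny, include_root: bool = True
) -> float:
    """Faith's phylogenetic diversity of a set of tips.

    Sum of branch lengths of the minimal subtree spanning the members; with
    ``include_root`` (the dominant convention, and the default) the path
    from that subtree up to the root is included, so a single-species
    community has PD equal to its root-to-tip depth.
    """
    if isinstance(species, (pd.Series, dict)):
        s = pd.Series(species)
        species = list(s[s > 0].index)
    members = set(species)
    if not members:
        raise ValueError("Faith's PD of an empty community is undefined")
    missing = members - set(tree.tip_labels)
    if missing:
        raise ValueError(f"species not in tree: {sorted(missing)[:5]}")
    # edge is on a root-to-member path iff its subtree contains a member
    total = 0.0
    n_below: dict[int, int] = {}
    mrca_depth = 0.0
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            n_below[id(node)] = 1 if node.taxon.label in members else 0
        else:
            n_below[id(node)] = sum(n_below[id(ch)] for ch in node.child_nodes())
        if node is not tree.tree.seed_node and n_below[id(node)] > 0:
            total += node.edge.length
    if not include_root:
        # subtract the root-to-MRCA path
        node = tree.tree.mrca(taxon_labels=list(members))
        total -= tree.node_depth(node)
    return float(total)


# ---------------------------------------------------------------------------
# Standardized effect sizes
# ---------------------------------------------------------------------------


def ses_metrics(
    table: CommunityTable,
    dist: DistanceMatrix,
    pool: list[str],
    metrics: tuple[str, ...] = ("mpd", "mntd"),
    weighting: Weighting = UNWEIGHTED,
    n_runs: int = 999,
    rng: np.random.Generator | None = None,
    null: str = "montecarlo",
) -> pd.DataFrame:
    """NRI/NTI for every bromeliad in a table against the taxa-labels null.

    ``null="montecarlo"`` draws ``n_runs`` uniform permutations of the pool
    (one ensemble shared by all communities, as a joint relabeling of the
    site matrix would); ``null="exhaustive"`` enumerates all pool
    permutations (pools of <= 8 species only) and uses population moments.

    Returns a long-format frame with one row per (bromeliad, metric):
    observed, null_mean, null_sd, ses, nri_or_nti, degenerate, richness.
    Communities with richness < 2 or null sd = 0 (e.g. community = entire
    pool) are flagged degenerate with missing effect sizes.
    """
    if rng is None:
        rng = np.random.default_rng()
    pool = list(pool)
    P = len(pool)
    occupied = set(table.occupied_species())
    if not occupied <= set(pool):
        raise ValueError("pool must contain every species with nonzero counts")
    pool_dist = dist.submatrix(pool) if list(dist.species) != pool else dist
    D = pool_dist.values

    if null == "exhaustive":
        if P > EXHAUSTIVE_POOL_LIMIT:
            raise ValueError(
                f"exhaustive null limited to pools of <= {EXHAUSTIVE_POOL_LIMIT}"
            )
        perms = np.array(list(itertools.permutations(range(P))), dtype=np.intp)
        ddof = 0
    elif null == "montecarlo":
        if n_runs < 99:
            raise ValueError("n_runs must be >= 99")
        perms = random_permutations(n_runs, P, rng)
        ddof = 1
    else:
        raise ValueError(f"unknown null {null!r}")

    rows: list[SESResult] = []
    counts = table.counts.reindex(columns=pool, fill_value=0)
    for b in table.bromeliads:
        cvec = counts.loc[b]
        k = int((cvec > 0).sum())
        if k < 2:
            for m in metrics:
                rows.append(
                    SESResult(b, m, np.nan, np.nan, np.nan, np.nan, np.nan,
                              True, k, len(perms))
                )
            continue
        idx = pool_dist.indices(list(cvec.index[cvec > 0]))
        w = weighting.weights(cvec[cvec > 0].to_numpy(dtype=float))
        sub_obs = D[np.ix_(idx, idx)]
        M = perms[:, idx]  # (R, k) relabeled member positions
        sub_null = D[M[:, :, None], M[:, None, :]]  # (R, k, k)
        for m in metrics:
            fn = _mpd_from_sub if m == "mpd" else _mntd_from_sub
            obs = float(fn(sub_obs, w))
            null_vals = fn(sub_null, w)
            mu = float(null_vals.mean())
            sd = float(null_vals.std(ddof=ddof))
            # a relative floor catches ensembles that are constant up to
            # floating-point summation order (e.g. community = entire pool)
            degenerate = not np.isfinite(sd) or sd <= 1e-12 * max(1.0, abs(mu))
            ses = (obs - mu) / sd if not degenerate else np.nan
            rows.append(
                SESResult(b, m, obs, mu, sd, ses,
                          -ses if not degenerate else np.nan,
                          degenerate, k, len(perms))
            )
    n_deg = sum(r.degenerate for r in rows)
    if n_deg:
        logger.info("ses_metrics: %d degenerate (bromeliad, metric) cells", n_deg)
    return pd.DataFrame([r.__dict__ for r in rows])


def ses_with_morphospecies(
    table: CommunityTable,
    smeta,
    dist: DistanceMatrix,
    pool: list[str],
    n_randomizations: int = 100,
    rng: np.random.Generator | None = None,
    **ses_kwargs,
) -> pd.DataFrame:
    """SES averaged over morphospecies identity randomizations.

    Unsequenced individuals get a random molecular identity per
    randomization; both aggregations are reported: ``ses`` is the mean of
    the per-randomization effect sizes and ``ses_of_mean_metric`` recomputes
    the effect size from run-averaged observed/null moments.
    """
    from .nulls import randomize_morphospecies

    if rng is None:
        rng = np.random.default_rng()
    stacks = []
    for _ in range(n_randomizations):
        resolved = randomize_morphospecies(table, smeta, rng)
        stacks.append(ses_metrics(resolved, dist, pool, rng=rng, **ses_kwargs))
    allruns = pd.concat(stacks, keys=range(len(stacks)), names=["randomization"])
    grouped = allruns.groupby(["bromeliad", "metric"], sort=False)
    out = grouped[["observed", "null_mean", "null_sd", "ses"]].mean().reset_index()
    out["ses_of_mean_metric"] = (out["observed"] - out["null_mean"]) / out["null_sd"]
    out["nri_or_nti"] = -out["ses"]
    out["degenerate"] = grouped["degenerate"].any().to_numpy()
    out["n_randomizations"] = n_randomizations
    return out


def richness_pd_correlation(
    table: CommunityTable, tree: Phylogeny, include_root: bool = True
) -> float:
    """Pearson r between per-community richness and Faith's PD.

    Used to justify dropping PD from the model-selection stage when it is
    nearly collinear with richness.  Requires >= 3 non-empty communities.
    """
    rich, pd_vals = [], []
    for b in table.bromeliads:
        cvec = table.counts.loc[b]
        if (cvec > 0).sum() == 0:
            continue
        rich.append(richness(cvec))
        pd_vals.append(faith_pd(cvec, tree, include_root=include_root))
    if len(rich) < 3:
        raise ValueError("richness-PD correlation requires >= 3 communities")
    if np.std(rich) == 0 or np.std(pd_vals) == 0:
        raise ValueError("zero variance in richness or PD")
    r, _ = stats.pearsonr(rich, pd_vals)
    return float(r)
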