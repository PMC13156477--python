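"""Phylogenetic signal of continuous response traits.

Blomberg's K compares the observed fit of a trait to the tree's
Brownian-motion covariance structure against the fit expected if the trait
had evolved by Brownian motion:

    K = (MSE0 / MSE)_obs / (MSE0 / MSE)_BM

where, with V the BM variance-covariance matrix among tips and
a = (1'V^-1 x)/(1'V^-1 1) the phylogenetic GLS mean,

    MSE0 = (x - a)'(x - a) / (n - 1)
    MSE  = (x - a)' V^-1 (x - a) / (n - 1)
    (MSE0 / MSE)_BM = (tr V - n / (1'V^-1 1)) / (n - 1).

K = 1 is the Brownian expectation; K > 1 means closer relatives are more
similar than BM predicts, K near 0 means no signal.  Significance comes
from a permutation test: trait values are shuffled across tips and the
observed MSE is ranked among the permuted MSEs (smaller MSE = stronger
signal), giving p = (1 + #{MSE_null <= MSE_obs}) / (n_perm + 1).

Pagel's lambda (maximum likelihood on a GLS likelihood with
lambda-scaled off-diagonal covariances) is available as an alternative
statistic; results carry the method used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .data import Phylogeny, scale_species, SCALES

logger = logging.getLogger("phylotank")

MIN_SPECIES = 4
#: below this many species a formal signal test is considered underpowered
#: and only descriptive output is reported
MIN_SPECIES_FORMAL = 12


@dataclass
class SignalResult:
    trait: str
    scale: str
    method: str
    statistic: float
    p_perm: float
    n_species: int
    n_perm: int
    flag: str  # "ok" | "constant_trait" | "too_few_species" | "low_power_descriptive"


def _gls_mse(V_inv: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """(MSE0, MSE) around the phylogenetic GLS mean."""
    n = len(x)
    one = np.ones(n)
    Vi1 = V_inv @ one
    a = float(x @ Vi1 / (one @ Vi1))
    r = x - a
    return float(r @ r / (n - 1)), float(r @ V_inv @ r / (n - 1))


def blomberg_k(
    tree: Phylogeny,
    trait: dict[str, float] | pd.Series,
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
    scale: str = "invertebrates",
    trait_name: str = "trait",
    formal: bool = True,
) -> SignalResult:
    """Blomberg's K with a tip-shuffle permutation test.

    Tips without trait values are pruned; needs >= 4 species and a
    non-constant trait.  ``formal=False`` reports K descriptively with no
    permutation p-value (used for small species sets).
    """
    if rng is None:
        rng = np.random.default_rng()
    trait = pd.Series(trait).dropna()
    labels = [l for l in tree.tip_labels if l in trait.index]
    n = len(labels)
    if n < MIN_SPECIES:
        logger.info("blomberg_k(%s, %s): skipped, only %d species",
                    trait_name, scale, n)
        return SignalResult(trait_name, scale, "blomberg_k", np.nan, np.nan,
                            n, 0, "too_few_species")
    x = trait[labels].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        return SignalResult(trait_name, scale, "blomberg_k", np.nan, np.nan,
                            n, 0, "constant_trait")
    sub = tree.prune_to(labels) if n < tree.n_tips else tree
    vlabels, V = sub.vcv(labels)
    V_inv = np.linalg.inv(V)
    one = np.ones(n)
    Vi1 = V_inv @ one
    denom_bm = (np.trace(V) - n / (one @ Vi1)) / (n - 1)
    mse0, mse = _gls_mse(V_inv, x)
    K = (mse0 / mse) / denom_bm
    if not formal:
        return SignalResult(trait_name, scale, "blomberg_k", float(K), np.nan,
                            n, 0, "low_power_descriptive")
    # vectorized permutation: MSE for shuffled tip assignments
    X = np.tile(x, (n_perm, 1))
    X = rng.permuted(X, axis=1)
    a_perm = (X @ Vi1) / (one @ Vi1)
    R = X - a_perm[:, None]
    mse_perm = np.einsum("ri,ij,rj->r", R, V_inv, R) / (n - 1)
    p = float((1 + np.sum(mse_perm <= mse)) / (n_perm + 1))
    return SignalResult(trait_name, scale, "blomberg_k", float(K), p, n,
                        n_perm, "ok")


def pagel_lambda(
    tree: Phylogeny,
    trait: dict[str, float] | pd.Series,
    scale: str = "invertebrates",
    trait_name: str = "trait",
) -> SignalResult:
    """ML estimate of Pagel's lambda (off-diagonal covariance scaling)."""
    trait = pd.Series(trait).dropna()
    labels = [l for l in tree.tip_labels if l in trait.index]
    n = len(labels)
    if n < MIN_SPECIES:
        return SignalResult(trait_name, scale, "pagel_lambda", np.nan, np.nan,
                            n, 0, "too_few_species")
    x = trait[labels].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        return SignalResult(trait_name, scale, "pagel_lambda", np.nan, np.nan,
                            n, 0, "constant_trait")
    sub = tree.prune_to(labels) if n < tree.n_tips else tree
    _, V = sub.vcv(labels)
    diag = np.diag(V).copy()

    def negloglik(lam: float) -> float:
        Vl = lam * V
        np.fill_diagonal(Vl, diag)
        sign, logdet = np.linalg.slogdet(Vl)
        if sign <= 0:
            return np.inf
        Vi = np.linalg.inv(Vl)
        one = np.ones(n)
        a = x @ Vi @ one / (one @ Vi @ one)
        r = x - a
        s2 = float(r @ Vi @ r) / n  # ML rate
        return 0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)

    res = optimize.minimize_scalar(negloglik, bounds=(0.0, 1.0), method="bounded")
    return SignalResult(trait_name, scale, "pagel_lambda", float(res.x),
                        np.nan, n, 0, "ok")


def signal_by_scale(
    tree: Phylogeny,
    indices: pd.DataFrame,
    scales: tuple[str, ...] = SCALES,
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
    method: str = "blomberg_k",
    min_species_formal: int = MIN_SPECIES_FORMAL,
) -> pd.DataFrame:
    """Signal test for each response index at each taxonomic scale.

    ``indices`` is the long-format response-index table (columns species,
    index_kind, z).  The z-scores are used directly as trait values.
    Scales with fewer species than ``min_species_formal`` are reported
    descriptively with a low-power flag instead of a formal test (with 10
    designed extinction species there is no meaningful permutation test).
    """
    if rng is None:
        rng = np.random.default_rng()
    if tree.clade_labels is None:
        raise ValueError("tree needs clade labels for scale subsetting")
    results: list[SignalResult] = []
    for kind, grp in indices.groupby("index_kind", sort=False):
        vals = grp.dropna(subset=["z"]).set_index("species")["z"]
        present = [s for s in tree.tip_labels if s in vals.index]
        for sc in scales:
            keep = scale_species(present, tree.clade_labels, sc)
            trait = vals[keep]
            formal = len(keep) >= min_species_formal
            if method == "blomberg_k":
                res = blomberg_k(tree, trait, n_perm=n_perm, rng=rng, scale=sc,
                                 trait_name=kind, formal=formal)
            else:
                res = pagel_lambda(tree, trait, scale=sc, trait_name=kind)
            results.append(res)
    return pd.DataFrame([r.__dict__ for r in results])
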