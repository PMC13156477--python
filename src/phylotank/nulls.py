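"""Randomization engines for community-phylogenetic null models.

Two randomizations drive the whole analysis:

* the *taxa-labels* shuffle — a uniformly random permutation of species
  labels over the pool, equivalently of the rows/columns of the patristic
  distance matrix, leaving community membership (and hence per-bromeliad
  richness) untouched; and
* the *morphospecies identity* randomization — unsequenced individuals,
  recorded only at the morphospecies level, are each assigned a molecular
  species uniformly at random among the morphospecies' molecular members.

Both are seedable and bit-reproducible given the same generator state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import CommunityTable, DistanceMatrix, SpeciesMeta


@dataclass
class NullModelConfig:
    """Ensemble settings for the taxa-labels null (999 runs is the field
    convention for 3-digit rank p-values)."""

    n_runs: int = 999
    seed: int | None = None

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def build_pool(table: CommunityTable) -> list[str]:
    """The species pool defining the shuffle domain for a dataset role.

    survey        -> every species recorded anywhere at the site;
    colonization  -> species with at least one colonist in the experiment;
    extinction    -> the designed introduction list (species introduced
                     anywhere), regardless of survival.
    """
    if table.role == "extinction":
        tot = table.introduced.sum(axis=0)
        pool = list(tot.index[tot > 0])
    else:
        pool = table.occupied_species()
    if not pool:
        raise ValueError(f"empty species pool for role {table.role!r}")
    return pool


def random_permutations(
    n_runs: int, pool_size: int, rng: np.random.Generator
) -> np.ndarray:
    """``(n_runs, pool_size)`` array of independent uniform permutations."""
    base = np.tile(np.arange(pool_size), (n_runs, 1))
    return rng.permuted(base, axis=1)


def taxa_labels_shuffle(
    dist: DistanceMatrix, pool: list[str], rng: np.random.Generator
) -> tuple[DistanceMatrix, np.ndarray]:
    """One draw of the taxa-labels null.

    Returns the distance matrix with rows/columns permuted by a uniformly
    random permutation ``p`` of the pool (label ``i`` takes the phylogenetic
    position of ``pool[p[i]]``), together with ``p`` itself.
    """
    if list(pool) != list(dist.species):
        raise ValueError("pool does not match distance-matrix ordering")
    p = rng.permutation(len(pool))
    shuffled = DistanceMatrix(list(pool), dist.values[np.ix_(p, p)])
    return shuffled, p


def randomize_morphospecies(
    table: CommunityTable,
    smeta: SpeciesMeta,
    rng: np.random.Generator,
    weights: dict[str, dict[str, float]] | None = None,
) -> CommunityTable:
    """Resolve unsequenced (morphospecies-level) counts to molecular species.

    Columns of ``table`` named by a morphospecies id hold the unsequenced
    individuals of that morphospecies; each such individual is independently
    assigned one of the morphospecies' molecular members, uniformly by
    default or with per-member ``weights``.  Sequenced counts (columns named
    by molecular species) are untouched and per-bromeliad totals are
    conserved exactly.
    """
    morpho_ids = set(smeta.morphospecies_ids)
    molecular = set(smeta.molecular_species)
    counts = table.counts.copy()
    for col in list(counts.columns):
        if col in molecular:
            continue
        if col not in morpho_ids:
            raise ValueError(
                f"column {col!r} is neither a molecular species nor a known "
                "morphospecies"
            )
        members = smeta.members(col)
        if not members:
            raise ValueError(f"morphospecies {col!r} has no molecular members")
        if weights and col in weights:
            w = np.array([weights[col].get(m, 0.0) for m in members], float)
            if w.sum() <= 0:
                raise ValueError(f"non-positive weights for morphospecies {col!r}")
            p = w / w.sum()
        else:
            p = np.full(len(members), 1.0 / len(members))
        for m in members:
            if m not in counts.columns:
                counts[m] = 0
        for b in counts.index:
            n = int(counts.at[b, col])
            if n > 0:
                alloc = rng.multinomial(n, p)
                for m, a in zip(members, alloc):
                    counts.at[b, m] = int(counts.at[b, m]) + int(a)
        counts = counts.drop(columns=[col])
    return CommunityTable(counts, table.role, table.introduced)
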