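"""Core data structures and I/O for bromeliad community phylogenetics.

The analysis revolves around three objects: a rooted phylogeny with branch
lengths over the invertebrate species pool, bromeliad x species abundance
matrices for three dataset roles (a natural survey, a colonization
experiment, and an extinction experiment), and per-bromeliad / per-species
metadata.  This module provides those containers, their validation rules,
CSV/Newick readers and writers, patristic distances, taxonomic-scale
subsetting (all invertebrates -> insects only -> dipterans only), and the
survey data-cleaning filters.

Conventions
-----------
* Trees are strict Newick: rooted, every non-root edge carries a
  non-negative branch length, tip labels unique.
* Community matrices are CSV with rows = bromeliads and columns = species;
  counts are non-negative integers (colonization/extinction events happen to
  individuals, so experiment roles reject non-integer counts).
* Habitat size is ``log10`` of the water-holding capacity in mL.
* Clade membership (Annelida / Diptera / Coleoptera / other Insecta) comes
  from the species-metadata table, never from parsing tip names.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger("phylotank")

ROLES = ("survey", "colonization", "extinction")
SCALES = ("invertebrates", "insecta", "diptera")

#: clade labels with a special meaning for taxonomic-scale subsetting
ANNELIDA = "Annelida"
COLEOPTERA = "Coleoptera"
DIPTERA = "Diptera"


class PhylogenyError(ValueError):
    """Invalid tree input (duplicate tips, missing/negative branch lengths)."""


class DegeneratePoolError(ValueError):
    """A species pool too small for the requested analysis."""


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------


@dataclass
class Phylogeny:
    """A rooted, branch-length tree over the species pool.

    Thin wrapper around :class:`dendropy.Tree` that enforces the invariants
    the downstream metrics rely on (unique tips, branch lengths present and
    non-negative) and exposes the handful of operations the pipeline needs.

    Parameters
    ----------
    tree
        Rooted dendropy tree; every edge except the root edge must have a
        non-negative length.
    clade_labels
        Optional map species -> taxonomic group ("Annelida", "Diptera",
        "Coleoptera", other insect orders).  Required for taxonomic-scale
        subsetting.
    """

    tree: dendropy.Tree
    clade_labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        labels = [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise PhylogenyError(f"duplicate tip labels: {dupes}")
        root = self.tree.seed_node
        for node in self.tree.preorder_node_iter():
            if node is root:
                continue
            if node.edge.length is None:
                raise PhylogenyError(
                    f"missing branch length on edge above node "
                    f"{node.taxon.label if node.taxon else node}"
                )
            if node.edge.length < 0:
                raise PhylogenyError(
                    f"negative branch length ({node.edge.length}) above node "
                    f"{node.taxon.label if node.taxon else node}"
                )

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_newick(
        cls, source: str | Path, clade_labels: Mapping[str, str] | None = None
    ) -> "Phylogeny":
        """Read a single rooted Newick tree (string or file path)."""
        text = str(source)
        if "(" not in text:  # looks like a path, not newick data
            text = Path(source).read_text()
        try:
            tree = dendropy.Tree.get(
                data=text, schema="newick", rooting="force-rooted"
            )
        except Exception as exc:  # dendropy's reader errors vary by cause
            raise PhylogenyError(f"could not parse Newick input: {exc}") from exc
        return cls(tree, dict(clade_labels) if clade_labels else None)

    # -- basic accessors ----------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        """Tip labels in sorted order (the canonical species ordering)."""
        return sorted(leaf.taxon.label for leaf in self.tree.leaf_node_iter())

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def total_length(self) -> float:
        return sum(
            node.edge.length
            for node in self.tree.preorder_node_iter()
            if node is not self.tree.seed_node
        )

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.as_newick() + "\n")

    # -- derived structures -------------------------------------------------

    def patristic_matrix(self) -> "DistanceMatrix":
        """Pairwise tip-to-tip path-length (patristic) distances."""
        labels = self.tip_labels
        pdm = self.tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in self.tree.taxon_namespace if t.label in set(labels)}
        n = len(labels)
        values = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
                values[i, j] = values[j, i] = d
        return DistanceMatrix(species=labels, values=values)

    def node_depth(self, node) -> float:
        """Path length from the root to a node, excluding any root (stem)
        edge the Newick may carry."""
        total = 0.0
        while node is not self.tree.seed_node:
            total += node.edge.length
            node = node.parent_node
        return total

    def root_distances(self) -> dict[str, float]:
        """Root-to-tip path length per tip (root stem edge excluded)."""
        return {
            leaf.taxon.label: self.node_depth(leaf)
            for leaf in self.tree.leaf_node_iter()
        }

    def vcv(self, labels: Sequence[str] | None = None) -> tuple[list[str], np.ndarray]:
        """Brownian-motion variance-covariance matrix among tips.

        cov(i, j) is the shared root-to-MRCA path length, computed as
        (depth_i + depth_j - d_ij) / 2; the diagonal is the root-to-tip depth.
        """
        dmat = self.patristic_matrix()
        if labels is None:
            labels = dmat.species
        labels = list(labels)
        sub = dmat.submatrix(labels)
        depths = self.root_distances()
        dep = np.array([depths[l] for l in labels])
        V = (dep[:, None] + dep[None, :] - sub.values) / 2.0
        np.fill_diagonal(V, dep)
        return labels, V

    def prune_to(self, labels: Iterable[str]) -> "Phylogeny":
        """Subtree spanning ``labels``.

        Degree-2 nodes created by pruning are collapsed with summed branch
        lengths, so patristic distances among retained tips are preserved;
        the retained portion of the root edge is kept.
        """
        keep = set(labels)
        missing = keep - set(self.tip_labels)
        if missing:
            raise PhylogenyError(f"labels not in tree: {sorted(missing)}")
        sub = self.tree.extract_tree_with_taxa_labels(keep)
        sub = dendropy.Tree.get(
            data=sub.as_string(schema="newick"), schema="newick",
            rooting="force-rooted",
        )
        clades = (
            {l: self.clade_labels[l] for l in keep if l in self.clade_labels}
            if self.clade_labels
            else None
        )
        return Phylogeny(sub, clades)


def read_phylogeny(
    path: str | Path, clade_labels: Mapping[str, str] | None = None
) -> Phylogeny:
    """Read and validate a rooted Newick tree with branch lengths."""
    return Phylogeny.from_newick(path, clade_labels)


# ---------------------------------------------------------------------------
# Distance matrix
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Symmetric patristic distance matrix with an explicit species order."""

    species: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.species = list(self.species)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.species)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match species list")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        self._index = {s: i for i, s in enumerate(self.species)}

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def indices(self, labels: Sequence[str]) -> np.ndarray:
        return np.array([self._index[l] for l in labels], dtype=np.intp)

    def distance(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = self.indices(labels)
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])


def patristic_distances(tree: Phylogeny) -> DistanceMatrix:
    """Patristic (tree path-length) distances between every pair of tips."""
    return tree.patristic_matrix()


# ---------------------------------------------------------------------------
# Community tables and metadata
# ---------------------------------------------------------------------------


@dataclass
class CommunityTable:
    """Bromeliad x species abundance matrix.

    ``counts`` holds non-negative integer abundances (rows = bromeliads,
    columns = species).  For the extinction role, ``introduced`` records the
    designed introduction counts and must dominate ``counts`` cell-wise
    (individuals can only die, not appear).
    """

    counts: pd.DataFrame
    role: str
    introduced: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        c = self.counts
        if (np.asarray(c.values, dtype=float) < 0).any():
            raise ValueError("negative counts in community table")
        arr = np.asarray(c.values, dtype=float)
        if self.role in ("colonization", "extinction") and not np.allclose(
            arr, np.round(arr)
        ):
            raise ValueError(
                f"{self.role} counts must be integers (events are individuals)"
            )
        self.counts = c.astype(int) if np.allclose(arr, np.round(arr)) else c
        if self.role == "extinction":
            if self.introduced is None:
                raise ValueError("extinction tables require introduced counts")
            intro = self.introduced.reindex(
                index=c.index, columns=c.columns
            )
            if intro.isna().any().any():
                raise ValueError("introduced table does not cover all cells")
            if (intro.values < self.counts.values).any():
                raise ValueError("introduced(b, s) must be >= abundance(b, s)")
            self.introduced = intro.astype(int)

    @property
    def bromeliads(self) -> list[str]:
        return list(self.counts.index.astype(str))

    @property
    def species(self) -> list[str]:
        return list(self.counts.columns.astype(str))

    def occupied_species(self) -> list[str]:
        """Species with at least one individual anywhere."""
        tot = self.counts.sum(axis=0)
        return list(tot.index[tot > 0])

    def subset_species(self, keep: Sequence[str]) -> "CommunityTable":
        keep = [s for s in self.species if s in set(keep)]
        intro = self.introduced[keep] if self.introduced is not None else None
        return CommunityTable(self.counts[keep], self.role, intro)

    def drop_bromeliads(self, drop: Sequence[str]) -> "CommunityTable":
        keep = [b for b in self.bromeliads if b not in set(drop)]
        intro = (
            self.introduced.loc[keep] if self.introduced is not None else None
        )
        return CommunityTable(self.counts.loc[keep], self.role, intro)

    # -- I/O ----------------------------------------------------------------

    def to_csv(self, path: str | Path, introduced_path: str | Path | None = None) -> None:
        self.counts.to_csv(path, index_label="bromeliad")
        if self.introduced is not None and introduced_path is not None:
            self.introduced.to_csv(introduced_path, index_label="bromeliad")

    @classmethod
    def read_csv(
        cls,
        path: str | Path,
        role: str,
        introduced_path: str | Path | None = None,
    ) -> "CommunityTable":
        counts = pd.read_csv(path, index_col=0)
        counts.index = counts.index.astype(str)
        intro = None
        if introduced_path is not None:
            intro = pd.read_csv(introduced_path, index_col=0)
            intro.index = intro.index.astype(str)
        return cls(counts, role, intro)


@dataclass
class BromeliadMeta:
    """Per-bromeliad covariates, indexed by bromeliad id.

    Columns: ``capacity_ml`` (> 0), derived ``log_size`` = log10(capacity),
    ``predator_biomass`` (mg, survey role), ``predator_present`` (bool,
    experiment roles), ``detritus_mass`` (g), ``microhabitat_flag`` (bool).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.copy()
        t.index = t.index.astype(str)
        if "capacity_ml" not in t.columns:
            raise ValueError("metadata requires a capacity_ml column")
        if (t["capacity_ml"] <= 0).any():
            raise ValueError("capacity_ml must be positive")
        t["log_size"] = np.log10(t["capacity_ml"].astype(float))
        if "microhabitat_flag" not in t.columns:
            t["microhabitat_flag"] = False
        t["microhabitat_flag"] = t["microhabitat_flag"].astype(bool)
        if "predator_present" in t.columns:
            t["predator_present"] = t["predator_present"].astype(bool)
        self.table = t

    @property
    def bromeliads(self) -> list[str]:
        return list(self.table.index)

    def log_size(self, bromeliads: Sequence[str] | None = None) -> np.ndarray:
        t = self.table if bromeliads is None else self.table.loc[list(bromeliads)]
        return t["log_size"].to_numpy(dtype=float)

    def predator_present(self, bromeliads: Sequence[str] | None = None) -> np.ndarray:
        t = self.table if bromeliads is None else self.table.loc[list(bromeliads)]
        if "predator_present" in t.columns:
            return t["predator_present"].to_numpy(dtype=bool)
        if "predator_biomass" in t.columns:
            return t["predator_biomass"].to_numpy(dtype=float) > 0
        raise ValueError("metadata has neither predator_present nor predator_biomass")

    def to_csv(self, path: str | Path) -> None:
        self.table.drop(columns=["log_size"]).to_csv(path, index_label="bromeliad")

    @classmethod
    def read_csv(cls, path: str | Path) -> "BromeliadMeta":
        return cls(pd.read_csv(path, index_col=0))


@dataclass
class SpeciesMeta:
    """Species-level metadata: morphospecies membership and clade labels.

    ``table`` is indexed by molecular species id with columns
    ``morphospecies`` and optionally ``clade``.  Each molecular species
    belongs to exactly one morphospecies (guaranteed by the table shape).
    Unsequenced individuals appear in community tables under the
    morphospecies id itself and are resolved by
    :func:`phylotank.nulls.randomize_morphospecies`.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.copy()
        t.index = t.index.astype(str)
        if "morphospecies" not in t.columns:
            raise ValueError("species metadata requires a morphospecies column")
        self.table = t

    @property
    def molecular_species(self) -> list[str]:
        return list(self.table.index)

    def members(self, morphospecies: str) -> list[str]:
        """Molecular species belonging to a morphospecies."""
        sel = self.table.index[self.table["morphospecies"] == morphospecies]
        return list(sel)

    @property
    def morphospecies_ids(self) -> list[str]:
        return list(pd.unique(self.table["morphospecies"]))

    def clade_labels(self) -> dict[str, str]:
        if "clade" not in self.table.columns:
            raise ValueError("species metadata has no clade column")
        return self.table["clade"].to_dict()

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index_label="species")

    @classmethod
    def read_csv(cls, path: str | Path) -> "SpeciesMeta":
        return cls(pd.read_csv(path, index_col=0))


# ---------------------------------------------------------------------------
# Taxonomic scales and survey filters
# ---------------------------------------------------------------------------


def scale_species(
    species: Sequence[str], clade_labels: Mapping[str, str], scale: str
) -> list[str]:
    """Species retained at a taxonomic scale.

    invertebrates: everything; insecta: drop Annelida; diptera: keep only
    Diptera (drops Coleoptera and any other non-dipteran insects).
    """
    if scale not in SCALES:
        raise ValueError(f"scale must be one of {SCALES}, got {scale!r}")
    missing = [s for s in species if s not in clade_labels]
    if missing:
        raise ValueError(f"species without clade label: {missing[:5]}")
    if scale == "invertebrates":
        return list(species)
    if scale == "insecta":
        return [s for s in species if clade_labels[s] != ANNELIDA]
    return [s for s in species if clade_labels[s] == DIPTERA]


def subset_taxonomic_scale(
    table: CommunityTable, tree: Phylogeny, scale: str
) -> tuple[CommunityTable, Phylogeny]:
    """Restrict a dataset to a taxonomic scale, pruning table and tree."""
    if tree.clade_labels is None:
        raise ValueError("tree has no clade labels; supply SpeciesMeta clades")
    keep = scale_species(table.species, tree.clade_labels, scale)
    if len(keep) < 2:
        raise DegeneratePoolError(
            f"scale {scale!r} leaves {len(keep)} species (< 2)"
        )
    if scale == "invertebrates":
        return table, tree
    return table.subset_species(keep), tree.prune_to(keep)


def apply_survey_filters(
    table: CommunityTable,
    meta: BromeliadMeta,
    exclude_species: Sequence[str] = (),
    use_microhabitat_flag: bool = True,
    exclude_bromeliads: Sequence[str] = (),
) -> tuple[CommunityTable, list[str]]:
    """Survey cleaning: drop flagged bromeliads and excluded species.

    Bromeliads carrying the microhabitat flag (communities from a different
    microhabitat) and explicitly listed bromeliads are removed, as are listed
    species (terrestrial accidentals; large predators other than damselflies).
    Returns the filtered table and a removal log; unknown ids raise a warning
    rather than an error.
    """
    log: list[str] = []
    drop_b = list(exclude_bromeliads)
    if use_microhabitat_flag:
        flagged = meta.table.index[meta.table["microhabitat_flag"]]
        drop_b += [b for b in flagged if b not in drop_b]
    present_b = set(table.bromeliads)
    for b in drop_b:
        if b not in present_b:
            warnings.warn(f"excluded bromeliad {b!r} not present in table")
    drop_b = [b for b in drop_b if b in present_b]
    out = table.drop_bromeliads(drop_b)
    log.append(f"removed {len(drop_b)} bromeliads: {sorted(drop_b)}")

    present_s = set(out.species)
    drop_s = []
    for s in exclude_species:
        if s not in present_s:
            warnings.warn(f"excluded species {s!r} not present in table")
            continue
        n = int(out.counts[s].sum())
        log.append(f"removed species {s!r} ({n} individuals)")
        drop_s.append(s)
    out = out.subset_species([s for s in out.species if s not in set(drop_s)])
    for entry in log:
        logger.info("survey filter: %s", entry)
    return out, log
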