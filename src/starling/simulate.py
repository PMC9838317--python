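"""Synthetic datasets: species trees, discordant gene trees, and a
two-stage Beta-distributed taxon-deletion process.

The generator emulates the statistical structure of coalescent-based
benchmark pipelines at the topology level:

* a true species tree S* (uniform random binary topology);
* per-gene true trees, each a copy of S* perturbed by a chosen number of
  random NNI moves (0 = no discordance; more moves = more gene/species
  discordance, a topology-level stand-in for ILS);
* missing data via a *taxon deletion model*: every species a gets a
  deletion probability ds(a) ~ B*(mu_s, nu) and every gene k a probability
  df(k) ~ B*(mu_f, nu), where B*(mu, nu) is the Beta distribution
  reparametrized by its mean mu = alpha/(alpha+beta) and sample size
  nu = alpha+beta.  The gene copy of species a in gene k is deleted iff a
  Bernoulli(ds(a)) draw OR an independent Bernoulli(df(k)) draw fires, so
  the expected deleted fraction is 1 - (1-mu_s)(1-mu_f).

After deletion, genes left with fewer than 4 species are dropped, and
species covered by no surviving gene are pruned from the reference tree —
the same filters applied to real datasets.

All randomness flows from one master seed through named substreams (tree,
discordance, profile, deletion), so datasets are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .families import GeneFamily, make_family
from .search import random_starting_tree
from .tree import TreeError, UnrootedTree, induced_tree

__all__ = [
    "BetaStarParams",
    "DeletionProfile",
    "SimulatedDataset",
    "simulate_species_tree",
    "simulate_gene_trees",
    "sample_deletion_profile",
    "deletion_matrix",
    "apply_deletion",
    "expected_missing_fraction",
    "simulate_dataset",
]

DEFAULT_NU = 5.0  # Beta sample size used throughout the benchmark protocol


@dataclass(frozen=True)
class BetaStarParams:
    """Beta distribution B*(mu, nu) parametrized by mean and sample size.

    mu = alpha/(alpha+beta) in [0, 1]; nu = alpha+beta > 0.  mu = 0 or 1
    short-circuits to the constant 0 or 1.
    """

    mean: float
    size: float = DEFAULT_NU

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean <= 1.0:
            raise ValueError("mean must be in [0, 1]")
        if self.size <= 0:
            raise ValueError("size must be > 0")

    @property
    def alpha(self) -> float:
        return self.mean * self.size

    @property
    def beta(self) -> float:
        return (1.0 - self.mean) * self.size

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.mean in (0.0, 1.0):
            return np.full(n, self.mean)
        return rng.beta(self.alpha, self.beta, size=n)


@dataclass(frozen=True)
class DeletionProfile:
    """Realized per-species and per-gene deletion probabilities."""

    per_species: np.ndarray  # ds(a), length n_species
    per_gene: np.ndarray  # df(k), length K

    def __post_init__(self) -> None:
        for arr in (self.per_species, self.per_gene):
            if arr.size and (arr.min() < 0 or arr.max() > 1):
                raise ValueError("deletion probabilities must lie in [0, 1]")


@dataclass
class SimulatedDataset:
    """A complete synthetic instance: truth, data, and deletion record."""

    species_tree: UnrootedTree  # true tree S* over all simulated species
    pruned_reference: UnrootedTree  # S* restricted to covered species
    families: list[GeneFamily]  # surviving gene families (>= 4 species each)
    deleted: np.ndarray  # bool (n_species, K), True = cell removed
    missing_fraction: float  # deleted cells / (n_species * K)
    species: tuple[str, ...]  # row order of `deleted`


def species_labels(n: int) -> list[str]:
    width = len(str(n))
    return [f"S{i:0{width}d}" for i in range(1, n + 1)]


def simulate_species_tree(n_species: int, seed) -> UnrootedTree:
    """Uniform random binary species tree over n labelled species."""
    if n_species < 4:
        raise TreeError("need at least 4 species")
    return random_starting_tree(species_labels(n_species), seed)


def _random_nni(tree: UnrootedTree, rng: np.random.Generator) -> None:
    """One random NNI, in place (binary trees only)."""
    edges = tree.internal_edges()
    if not edges:
        return
    u, v = edges[rng.integers(len(edges))]
    x = [w for w in tree.adj[u] if w != v][rng.integers(2)]
    c = [w for w in tree.adj[v] if w != u][rng.integers(2)]
    tree.disconnect(u, x)
    tree.disconnect(v, c)
    tree.connect(u, c)
    tree.connect(v, x)


def simulate_gene_trees(
    species_tree: UnrootedTree,
    n_genes: int,
    discordance_nni: int = 0,
    seed=None,
) -> list[UnrootedTree]:
    """Per-gene true trees: copies of S* perturbed by ``discordance_nni``
    random NNI moves each.  Zero moves gives exact copies (no ILS)."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if discordance_nni < 0:
        raise ValueError("discordance_nni must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for _ in range(n_genes):
        t = species_tree.copy()
        for _ in range(discordance_nni):
            _random_nni(t, rng)
        out.append(t)
    return out


def sample_deletion_profile(
    n_species: int,
    n_genes: int,
    mu_species: float,
    mu_gene: float,
    nu: float = DEFAULT_NU,
    rng: np.random.Generator | None = None,
) -> DeletionProfile:
    """Draw ds(a) i.i.d. from B*(mu_species, nu) and df(k) from
    B*(mu_gene, nu)."""
    rng = rng if rng is not None else np.random.default_rng()
    return DeletionProfile(
        per_species=BetaStarParams(mu_species, nu).sample(rng, n_species),
        per_gene=BetaStarParams(mu_gene, nu).sample(rng, n_genes),
    )


def expected_missing_fraction(mu_species: float, mu_gene: float) -> float:
    """Analytic mean deleted fraction of the two-stage union deletion:
    1 - (1 - mu_s)(1 - mu_f)."""
    for mu in (mu_species, mu_gene):
        if not 0.0 <= mu <= 1.0:
            raise ValueError("means must lie in [0, 1]")
    return 1.0 - (1.0 - mu_species) * (1.0 - mu_gene)


def deletion_matrix(
    profile: DeletionProfile, rng: np.random.Generator
) -> np.ndarray:
    """Boolean (n_species, K) grid: cell (a, k) deleted iff the per-species
    Bernoulli(ds(a)) or the independent per-gene Bernoulli(df(k)) fires."""
    n, k = profile.per_species.size, profile.per_gene.size
    hit_species = rng.random((n, k)) < profile.per_species[:, None]
    hit_gene = rng.random((n, k)) < profile.per_gene[None, :]
    return hit_species | hit_gene


def apply_deletion(
    species_tree: UnrootedTree,
    gene_trees: Sequence[UnrootedTree],
    profile: DeletionProfile,
    rng: np.random.Generator | None = None,
) -> SimulatedDataset:
    """Run the two-stage deletion over the species x gene grid.

    Cell (a, k) is deleted iff the per-species Bernoulli(ds(a)) or the
    independent per-gene Bernoulli(df(k)) fires.  Surviving gene trees are
    induced on their remaining species; genes with < 4 species are dropped
    and species covered by no surviving gene are pruned from the reference
    tree.  The recorded missing fraction counts deleted cells over the
    full grid, before the gene filter.
    """
    rng = rng if rng is not None else np.random.default_rng()
    species = tuple(sorted(species_tree.leaf_labels()))
    n, k = len(species), len(gene_trees)
    if profile.per_species.shape != (n,) or profile.per_gene.shape != (k,):
        raise ValueError("profile dimensions do not match species/genes")
    deleted = deletion_matrix(profile, rng)
    missing_fraction = float(deleted.mean()) if deleted.size else 0.0

    families: list[GeneFamily] = []
    for j, gt in enumerate(gene_trees):
        survivors = [species[i] for i in range(n) if not deleted[i, j]]
        if len(survivors) < 4:
            continue
        families.append(make_family(induced_tree(gt, survivors)))
    if not families:
        raise TreeError(
            "deletion removed every informative gene; relax the deletion "
            "probabilities"
        )
    covered = sorted(set().union(*(f.pattern for f in families)))
    pruned = (
        induced_tree(species_tree, covered)
        if len(covered) < n
        else species_tree.copy()
    )
    return SimulatedDataset(
        species_tree=species_tree,
        pruned_reference=pruned,
        families=families,
        deleted=deleted,
        missing_fraction=missing_fraction,
        species=species,
    )


def simulate_dataset(
    n_species: int = 50,
    n_genes: int = 200,
    mu_species: float = 0.6,
    mu_gene: float = 0.6,
    nu: float = DEFAULT_NU,
    discordance_nni: int = 0,
    seed: int = 42,
) -> SimulatedDataset:
    """End-to-end generator with named random substreams.

    Defaults mirror the no-ILS benchmark grid: 50 species, 200 genes, and
    both deletion means at 0.6 (expected missing fraction 0.84).
    """
    if mu_species >= 1.0 and mu_gene >= 1.0:
        raise ValueError("both deletion means at 1 delete everything")
    streams = np.random.SeedSequence(seed).spawn(4)
    tree_rng, disc_rng, prof_rng, del_rng = (np.random.default_rng(s) for s in streams)
    s_star = simulate_species_tree(n_species, tree_rng)
    gene_trees = simulate_gene_trees(s_star, n_genes, discordance_nni, disc_rng)
    profile = sample_deletion_profile(
        n_species, n_genes, mu_species, mu_gene, nu, prof_rng
    )
    return apply_deletion(s_star, gene_trees, profile, del_rng)
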