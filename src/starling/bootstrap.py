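"""Multi-locus bootstrap supports for an inferred species tree.

Gene trees — not alignment sites — are the resampling unit: each replicate
draws K families with replacement from the bootstrap pool (by default the
input families themselves), re-runs the species-tree analysis on the
replicate, and the Felsenstein support of each branch of the best tree is
the fraction of replicate trees that contain the corresponding
bipartition.  Replicate searches start from the replicate's own
distance-based tree, not from the best tree, to avoid biasing supports
toward it.

A replicate may cover fewer species than the best tree (resampling can
drop all genes containing some species).  A branch of the best tree is
counted as supported by such a replicate only if its restriction to the
replicate's taxa is still a nontrivial split of the replicate tree;
replicates uninformative for a branch count against it (conservative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .families import GeneFamily, average_matrix
from .search import SearchConfig, astrid_starting_tree, search
from .tree import (
    Bipartition,
    TreeError,
    UnrootedTree,
    bipartitions,
    write_newick,
)

__all__ = ["SupportTree", "resample_replicate", "bootstrap_supports"]

logger = logging.getLogger(__name__)


@dataclass
class SupportTree:
    """A species tree with one support value in [0, 1] per internal edge."""

    tree: UnrootedTree
    supports: dict[Bipartition, float]
    replicate_trees: list[UnrootedTree]

    def to_newick(self) -> str:
        all_labels = self.tree.leaf_labels()

        def edge_label(child: int, parent: int) -> str | None:
            if child in self.tree.labels:
                return None
            side = self.tree.side_leaves(parent, child)
            bip = Bipartition(frozenset((side, all_labels - side)))
            if not bip.nontrivial:
                return None
            return format(self.supports[bip], ".3f")

        return write_newick(self.tree, edge_label=edge_label)


def resample_replicate(
    families: Sequence[GeneFamily],
    rng: np.random.Generator,
    pool: Sequence[GeneFamily] | None = None,
) -> list[GeneFamily]:
    """Draw ``len(families)`` families with replacement from ``pool``
    (default: the families themselves)."""
    if not families:
        raise TreeError("cannot bootstrap an empty family list")
    pool = list(pool) if pool is not None else list(families)
    idx = rng.integers(len(pool), size=len(families))
    return [pool[i] for i in idx]


def bootstrap_supports(
    best: UnrootedTree,
    families: Sequence[GeneFamily],
    m: int,
    seed: int = 42,
    pool: Sequence[GeneFamily] | None = None,
    config: SearchConfig | None = None,
    fast: bool = False,
) -> SupportTree:
    """Felsenstein supports on ``best`` from m bootstrap replicates.

    Each replicate's RNG stream is derived from (seed, replicate index),
    so individual replicates are reproducible in isolation.  ``fast``
    skips the SPR search and scores replicates with their distance-based
    starting tree only (a documented approximation).
    """
    if m < 1:
        raise ValueError("need at least one bootstrap replicate")
    base = SearchConfig() if config is None else config
    target = {b for b in bipartitions(best) if b.nontrivial}
    counts: dict[Bipartition, int] = {b: 0 for b in target}
    replicate_trees: list[UnrootedTree] = []
    for i in range(m):
        rng = np.random.default_rng([seed, i])
        replicate = resample_replicate(families, rng, pool)
        if fast:
            rep_tree = astrid_starting_tree(average_matrix(replicate))
        else:
            rep_config = SearchConfig(
                random_starts=base.random_starts,
                tolerance=base.tolerance,
                max_iterations=base.max_iterations,
                seed=int(rng.integers(2**31)),
            )
            rep_tree = search(replicate, rep_config).best_tree
        replicate_trees.append(rep_tree)
        rep_splits = bipartitions(rep_tree)
        rep_taxa = rep_tree.leaf_labels()
        for bip in target:
            restricted = bip.restrict(rep_taxa)
            if restricted is not None and restricted.nontrivial:
                if restricted in rep_splits:
                    counts[bip] += 1
    supports = {b: counts[b] / m for b in target}
    logger.info("bootstrap: %d replicates, %d branches", m, len(target))
    return SupportTree(tree=best, supports=supports, replicate_trees=replicate_trees)
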