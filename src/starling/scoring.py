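"""Global length and global induced length of a candidate species tree.

The *global length* of species tree S against an averaged gene distance
matrix D is

    L(S, D) = sum over unordered species pairs {i, j} of
              2^(-M_S(i, j)) * D(i, j)

where M_S is the internode distance matrix of S.  Distance-matrix methods
in the ASTRID family minimize this quantity; with missing data the averaged
D systematically underestimates long distances (a pair is only measured in
the genes that contain both taxa, and removing taxa contracts paths).

The *global induced length* corrects that bias by scoring each gene against
the species tree induced on that gene's coverage pattern:

    L_p(S, G) = sum over genes k, unordered pairs {i, j} in L(G_k) of
                2^(-M_k(i, j)) * D_k(i, j)

with M_k the internode matrix of S restricted to L(G_k).  Genes sharing a
coverage pattern share M_k, so the sum is evaluated per pattern group over
pre-summed distance matrices.

Both sums here run over unordered pairs; the symmetric double-sum
convention would simply double every value and leaves the minimizer
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .families import AveragedMatrix, PatternGroup
from .tree import TreeError, UnrootedTree, induced_tree, internode_matrix

__all__ = [
    "InducedGeometry",
    "induced_geometry",
    "global_length",
    "global_induced_length",
    "pattern_scores",
]


@dataclass(frozen=True)
class InducedGeometry:
    """Species tree induced on a coverage pattern, with its weights."""

    pattern: frozenset[str]
    taxa: tuple[str, ...]
    induced: UnrootedTree
    distances: np.ndarray  # integer internode matrix over taxa
    weights: np.ndarray  # 2^(-distances), zero diagonal


def induced_geometry(
    species_tree: UnrootedTree, pattern: Iterable[str]
) -> InducedGeometry:
    """Induce the species tree on a coverage pattern and precompute the
    2^(-internode distance) weight matrix (exact binary fractions)."""
    pattern = frozenset(pattern)
    sub = induced_tree(species_tree, pattern)
    mat = internode_matrix(sub)
    weights = np.exp2(-mat.values.astype(float))
    np.fill_diagonal(weights, 0.0)
    return InducedGeometry(
        pattern=pattern,
        taxa=mat.taxa,
        induced=sub,
        distances=mat.values,
        weights=weights,
    )


def global_length(species_tree: UnrootedTree, avg: AveragedMatrix) -> float:
    """ASTRID-style criterion on the averaged matrix.

    Pairs never co-observed in any gene have an undefined average and
    contribute 0 (the only finite choice, and the one consistent with the
    induced criterion where such pairs simply never appear).
    """
    missing = set(avg.taxa) - species_tree.leaf_labels()
    if missing:
        raise TreeError(
            f"species absent from the tree: {', '.join(sorted(missing))}"
        )
    geo = induced_geometry(species_tree, avg.taxa)
    order = [avg.index(t) for t in geo.taxa]
    values = avg.values[np.ix_(order, order)]
    valid = avg.valid[np.ix_(order, order)]
    return 0.5 * float(np.sum(geo.weights * np.where(valid, values, 0.0)))


def _group_score(geo: InducedGeometry, group: PatternGroup) -> float:
    # group matrices are built over sorted taxa; geometries likewise
    assert geo.taxa == group.taxa
    return 0.5 * float(np.sum(geo.weights * group.summed))


def pattern_scores(
    species_tree: UnrootedTree, groups: Sequence[PatternGroup]
) -> list[float]:
    """Per-pattern-group contribution to the global induced length."""
    out = []
    for group in groups:
        missing = group.pattern - species_tree.leaf_labels()
        if missing:
            raise TreeError(
                f"species absent from the tree: {', '.join(sorted(missing))}"
            )
        geo = induced_geometry(species_tree, group.pattern)
        out.append(_group_score(geo, group))
    return out


def global_induced_length(
    species_tree: UnrootedTree, groups: Sequence[PatternGroup]
) -> float:
    """The criterion minimized by the tree search; see module docstring."""
    return float(sum(pattern_scores(species_tree, groups)))
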