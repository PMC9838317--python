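"""Gene families: per-gene internode distance matrices, coverage patterns,
the averaged distance matrix, and pattern groups.

A *gene family* is one unrooted gene tree together with a mapping from its
leaves to species.  Single-copy families map each leaf to itself (the leaf
label is the species label).  Multi-copy families may carry several leaves
per species; their species-pair distance is the minimum internode distance
over all leaf pairs mapping to the two species (the MiniNJ rule), which
reduces to the plain internode distance in the single-copy case.

The *coverage pattern* of a family is the set of species it contains.  The
induced-length criterion weights each gene only by the species tree induced
on its pattern, so families sharing a pattern share their weighting and can
be pre-summed into a :class:`PatternGroup` — the workhorse of scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .tree import (
    InternodeMatrix,
    TreeError,
    UnrootedTree,
    _leaf_edge_distances,
    parse_newick,
)

__all__ = [
    "GeneFamily",
    "AveragedMatrix",
    "PatternGroup",
    "read_mapping",
    "load_gene_families",
    "make_family",
    "gene_distance_matrix",
    "average_matrix",
    "group_by_pattern",
    "impute_missing",
    "to_phylip",
]

logger = logging.getLogger(__name__)

MIN_PATTERN_SIZE = 4  # families covering fewer species are uninformative


@dataclass
class GeneFamily:
    """One gene tree plus its leaf-to-species mapping."""

    tree: UnrootedTree
    species_of: dict[int, str]  # leaf node id -> species label
    pattern: frozenset[str] = field(init=False)
    _matrix: InternodeMatrix | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.pattern = frozenset(self.species_of.values())

    @property
    def is_multi_copy(self) -> bool:
        return len(self.species_of) > len(self.pattern)


@dataclass
class AveragedMatrix:
    """Per-species-pair mean of gene internode distances.

    ``values[i, j]`` is the mean distance over the genes covering both
    species i and j; ``counts[i, j]`` is how many genes that is.  Pairs that
    co-occur in no gene are invalid (``counts == 0``) and ``values`` is 0
    there by convention.
    """

    taxa: tuple[str, ...]
    values: np.ndarray  # float, symmetric
    counts: np.ndarray  # int, symmetric, zero diagonal

    @property
    def valid(self) -> np.ndarray:
        return self.counts > 0

    def index(self, label: str) -> int:
        return self.taxa.index(label)


@dataclass
class PatternGroup:
    """All families sharing one coverage pattern, with their distance
    matrices pre-summed (element-wise) over the pattern's sorted taxa."""

    pattern: frozenset[str]
    taxa: tuple[str, ...]
    summed: np.ndarray  # float, symmetric, zero diagonal
    count: int


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------


def read_mapping(path) -> dict[str, str]:
    """Read a gene-leaf -> species mapping file.

    Two dialects are accepted, decided per line:

    * ``species: gene1, gene2, ...``
    * two-column TSV: ``gene<TAB>species``
    """
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ":" in line:
                species, _, genes = line.partition(":")
                species = species.strip()
                for gene in genes.split(","):
                    gene = gene.strip()
                    if gene:
                        mapping[gene] = species
            else:
                parts = line.split("\t")
                if len(parts) != 2:
                    raise TreeError(
                        f"{path}, line {lineno}: expected 'species: genes' "
                        f"or two-column TSV"
                    )
                mapping[parts[0].strip()] = parts[1].strip()
    return mapping


def make_family(
    tree: UnrootedTree, mapping: dict[str, str] | None = None
) -> GeneFamily:
    """Attach a leaf-to-species mapping to a gene tree.

    Without a mapping, each leaf label is its own species label; duplicate
    labels then denote a multi-copy family with the implicit identity
    mapping.  An explicit mapping overrides and must cover every leaf.
    """
    species_of: dict[int, str] = {}
    for nid, label in tree.labels.items():
        if mapping is None:
            species_of[nid] = label
        else:
            try:
                species_of[nid] = mapping[label]
            except KeyError:
                raise TreeError(
                    f"gene leaf {label!r} is absent from the mapping file"
                ) from None
    return GeneFamily(tree=tree, species_of=species_of)


def load_gene_families(path, mapping_path=None) -> list[GeneFamily]:
    """Load gene trees (one Newick per line) into filtered gene families.

    Families whose coverage pattern has fewer than 4 species are dropped
    with a warning.  An empty file or zero surviving families is fatal.
    """
    mapping = read_mapping(mapping_path) if mapping_path is not None else None
    families: list[GeneFamily] = []
    n_read = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                tree = parse_newick(line, allow_duplicate_labels=True)
            except TreeError as exc:
                raise TreeError(f"{path}, line {lineno}: {exc}") from exc
            n_read += 1
            fam = make_family(tree, mapping)
            if len(fam.pattern) < MIN_PATTERN_SIZE:
                logger.warning(
                    "%s, line %d: gene tree covers only %d species (< %d); "
                    "dropped",
                    path,
                    lineno,
                    len(fam.pattern),
                    MIN_PATTERN_SIZE,
                )
                continue
            families.append(fam)
    if n_read == 0:
        raise TreeError(f"{path}: no gene trees found")
    if not families:
        raise TreeError(
            f"{path}: no gene family covers >= {MIN_PATTERN_SIZE} species"
        )
    logger.info(
        "%s: %d gene trees read, %d families kept after the %d-species filter",
        path, n_read, len(families), MIN_PATTERN_SIZE,
    )
    return families


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------


def gene_distance_matrix(family: GeneFamily) -> InternodeMatrix:
    """Species-level internode distance matrix of one family.

    Single-copy: the plain internode matrix of the gene tree.  Multi-copy:
    the MiniNJ minimum over leaf pairs.  Multifurcations need no special
    handling — the internode distance is defined for any unrooted tree.
    """
    if family._matrix is not None:
        return family._matrix
    leaf_ids, edge_dist = _leaf_edge_distances(family.tree)
    inter = np.maximum(edge_dist - 1, 0)
    taxa = tuple(sorted(family.pattern))
    idx = {s: i for i, s in enumerate(taxa)}
    rows = np.array([idx[family.species_of[v]] for v in leaf_ids])
    n = len(taxa)
    values = np.full((n, n), np.iinfo(np.int64).max, dtype=np.int64)
    for a, i in zip(rows, range(len(leaf_ids))):
        np.minimum.at(values[a], rows, inter[i])
    values = np.minimum(values, values.T)
    np.fill_diagonal(values, 0)
    family._matrix = InternodeMatrix(taxa=taxa, values=values)
    return family._matrix


def average_matrix(families: Sequence[GeneFamily]) -> AveragedMatrix:
    """Per-pair mean of the family distance matrices over all species.

    A pair's mean runs over exactly the genes whose coverage pattern
    contains both species; pairs covered by no gene are masked invalid.
    """
    if not families:
        raise TreeError("average_matrix needs at least one family")
    species = tuple(sorted(set().union(*(f.pattern for f in families))))
    idx = {s: i for i, s in enumerate(species)}
    n = len(species)
    total = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=np.int64)
    for fam in families:
        mat = gene_distance_matrix(fam)
        sel = np.array([idx[s] for s in mat.taxa])
        grid = np.ix_(sel, sel)
        total[grid] += mat.values
        counts[grid] += 1
    np.fill_diagonal(counts, 0)
    values = np.divide(total, counts, out=np.zeros_like(total), where=counts > 0)
    return AveragedMatrix(taxa=species, values=values, counts=counts)


def group_by_pattern(families: Sequence[GeneFamily]) -> list[PatternGroup]:
    """Group families by coverage pattern, pre-summing their matrices."""
    groups: dict[frozenset[str], PatternGroup] = {}
    for fam in families:
        mat = gene_distance_matrix(fam)
        grp = groups.get(fam.pattern)
        if grp is None:
            groups[fam.pattern] = PatternGroup(
                pattern=fam.pattern,
                taxa=mat.taxa,
                summed=mat.values.astype(float).copy(),
                count=1,
            )
        else:
            grp.summed += mat.values
            grp.count += 1
    # deterministic order: by sorted taxa tuple
    return sorted(groups.values(), key=lambda g: g.taxa)


# ---------------------------------------------------------------------------
# completion / export
# ---------------------------------------------------------------------------


def impute_missing(avg: AveragedMatrix) -> np.ndarray:
    """Complete the invalid entries of an averaged matrix.

    Invalid pairs get the length of the shortest path through valid entries
    (min over intermediates of summed distances, iterated to stability —
    i.e. graph shortest paths).  Pairs in different components of the
    co-occurrence graph remain infinite; callers decide whether that is an
    error.  Only used to build starting trees, never by the criterion.
    """
    from scipy.sparse.csgraph import shortest_path

    n = len(avg.taxa)
    weights = np.where(avg.valid, avg.values, np.inf)
    np.fill_diagonal(weights, 0)
    if np.all(avg.valid | np.eye(n, dtype=bool)):
        return weights
    return shortest_path(weights, method="D", directed=False)


def to_phylip(avg: AveragedMatrix) -> str:
    """PHYLIP-style square distance matrix (invalid pairs imputed)."""
    full = impute_missing(avg)
    finite = full[np.isfinite(full)]
    fill = (finite.max() + 1.0) if finite.size else 1.0
    full = np.where(np.isfinite(full), full, fill)
    lines = [str(len(avg.taxa))]
    for i, name in enumerate(avg.taxa):
        row = " ".join(f"{x:.6f}" for x in full[i])
        lines.append(f"{name}  {row}")
    return "\n".join(lines) + "\n"
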