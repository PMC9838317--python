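"""Unrooted leaf-labelled trees and the topological primitives built on them.

Everything downstream (distance matrices, the induced-length criterion, the
SPR search) is purely topological: branch lengths and internal node labels
are parsed but discarded.  Trees are stored as an adjacency map over integer
node ids; leaves carry string labels that are unique within a tree.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np
import skbio

__all__ = [
    "TreeError",
    "UnrootedTree",
    "Bipartition",
    "InternodeMatrix",
    "parse_newick",
    "parse_newick_file",
    "write_newick",
    "induced_tree",
    "internode_matrix",
    "bipartitions",
    "rf_distance",
    "enumerate_topologies",
]


class TreeError(ValueError):
    """Raised for malformed trees, labels or Newick input."""


# characters that force quoting of a label on output
_NEEDS_QUOTING = re.compile(r"[\s()\[\]{}:;,'\"=]")


class UnrootedTree:
    """Connected acyclic leaf-labelled graph; internal nodes are anonymous.

    Invariants (checked by :meth:`validate`): every leaf has degree 1 and a
    unique label; every internal node has degree >= 3 (degree-2 nodes are
    suppressed on construction).  Multifurcations (degree > 3) are allowed.
    """

    __slots__ = ("adj", "labels", "_next_id")

    def __init__(self) -> None:
        self.adj: dict[int, list[int]] = {}
        self.labels: dict[int, str] = {}
        self._next_id = 0

    # -- construction ------------------------------------------------------

    def new_node(self, label: str | None = None) -> int:
        nid = self._next_id
        self._next_id += 1
        self.adj[nid] = []
        if label is not None:
            self.labels[nid] = label
        return nid

    def connect(self, u: int, v: int) -> None:
        self.adj[u].append(v)
        self.adj[v].append(u)

    def disconnect(self, u: int, v: int) -> None:
        self.adj[u].remove(v)
        self.adj[v].remove(u)

    def subdivide(self, u: int, v: int) -> int:
        """Replace edge (u, v) by u - w - v and return the new node w."""
        self.disconnect(u, v)
        w = self.new_node()
        self.connect(u, w)
        self.connect(w, v)
        return w

    def remove_node(self, v: int) -> None:
        for u in list(self.adj[v]):
            self.disconnect(v, u)
        del self.adj[v]
        self.labels.pop(v, None)

    def suppress_if_degree_two(self, v: int) -> None:
        if v in self.adj and len(self.adj[v]) == 2 and v not in self.labels:
            a, b = self.adj[v]
            self.remove_node(v)
            self.connect(a, b)

    def suppress_all_degree_two(self) -> None:
        for v in list(self.adj):
            self.suppress_if_degree_two(v)

    # -- inspection --------------------------------------------------------

    def degree(self, v: int) -> int:
        return len(self.adj[v])

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def leaves(self) -> list[int]:
        return list(self.labels)

    def leaf_labels(self) -> frozenset[str]:
        return frozenset(self.labels.values())

    def node_of(self, label: str) -> int:
        for nid, lab in self.labels.items():
            if lab == label:
                return nid
        raise TreeError(f"no leaf labelled {label!r}")

    def internal_nodes(self) -> list[int]:
        return [v for v in self.adj if v not in self.labels]

    def edges(self) -> Iterator[tuple[int, int]]:
        """Each undirected edge once, as (min_id, max_id)."""
        for u, nbrs in self.adj.items():
            for v in nbrs:
                if u < v:
                    yield (u, v)

    def internal_edges(self) -> list[tuple[int, int]]:
        return [
            (u, v)
            for u, v in self.edges()
            if u not in self.labels and v not in self.labels
        ]

    def is_binary(self) -> bool:
        return all(
            len(nbrs) == (1 if v in self.labels else 3)
            for v, nbrs in self.adj.items()
        )

    def copy(self) -> "UnrootedTree":
        t = UnrootedTree()
        t.adj = {v: list(nbrs) for v, nbrs in self.adj.items()}
        t.labels = dict(self.labels)
        t._next_id = self._next_id
        return t

    def side_leaves(self, u: int, v: int) -> frozenset[str]:
        """Labels of all leaves on the v side of edge (u, v)."""
        seen = {u, v}
        stack = [v]
        out = []
        while stack:
            w = stack.pop()
            lab = self.labels.get(w)
            if lab is not None:
                out.append(lab)
            for x in self.adj[w]:
                if x not in seen:
                    seen.add(x)
                    stack.append(x)
        return frozenset(out)

    def validate(self) -> None:
        if not self.adj:
            raise TreeError("empty tree")
        n_nodes = len(self.adj)
        n_edges = sum(len(nbrs) for nbrs in self.adj.values()) // 2
        if n_edges != n_nodes - 1:
            raise TreeError("tree is not acyclic/connected (|E| != |V|-1)")
        # connectivity
        start = next(iter(self.adj))
        seen = {start}
        stack = [start]
        while stack:
            v = stack.pop()
            for u in self.adj[v]:
                if u not in seen:
                    seen.add(u)
                    stack.append(u)
        if len(seen) != n_nodes:
            raise TreeError("tree is disconnected")
        labels = list(self.labels.values())
        if len(set(labels)) != len(labels):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise TreeError(f"duplicate leaf labels: {', '.join(dup)}")
        for v, nbrs in self.adj.items():
            if v in self.labels:
                if len(nbrs) != 1:
                    raise TreeError(f"leaf {self.labels[v]!r} has degree {len(nbrs)}")
            elif len(nbrs) < 3 and n_nodes > 2:
                raise TreeError(f"internal node {v} has degree {len(nbrs)} < 3")

    # -- dunder ------------------------------------------------------------

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<UnrootedTree {self.n_leaves} leaves>"


@dataclass(frozen=True)
class Bipartition:
    """An unordered pair of complementary leaf-label sets (a tree split)."""

    sides: frozenset[frozenset[str]]

    @classmethod
    def of(cls, side_a: Iterable[str], side_b: Iterable[str]) -> "Bipartition":
        a, b = frozenset(side_a), frozenset(side_b)
        if a & b:
            raise TreeError("bipartition sides overlap")
        return cls(frozenset((a, b)))

    @property
    def nontrivial(self) -> bool:
        return all(len(s) >= 2 for s in self.sides)

    def restrict(self, taxa: frozenset[str]) -> "Bipartition | None":
        """Restriction to a taxon subset, or None if it degenerates."""
        a, b = self.sides
        ra, rb = a & taxa, b & taxa
        if not ra or not rb:
            return None
        return Bipartition(frozenset((ra, rb)))

    def __repr__(self) -> str:
        a, b = sorted(("".join(sorted(s)) for s in self.sides))
        return f"{a}|{b}"


@dataclass(frozen=True)
class InternodeMatrix:
    """Symmetric matrix of internode distances over an ordered taxon list.

    The internode distance between two leaves is the number of internal
    nodes on the (unique) path connecting them; a cherry pair has distance 1.
    """

    taxa: tuple[str, ...]
    values: np.ndarray  # (n, n) integer, symmetric, zero diagonal

    def index(self, label: str) -> int:
        return self.taxa.index(label)

    def value(self, a: str, b: str) -> int:
        return int(self.values[self.index(a), self.index(b)])


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------


def _from_skbio(sk, allow_duplicate_labels: bool = False) -> UnrootedTree:
    """Convert a (rooted) skbio TreeNode into an UnrootedTree, suppressing
    the root and any other degree-2 node."""
    tree = UnrootedTree()
    seen_labels: set[str] = set()

    def build(node, parent_id: int | None) -> None:
        if node.is_tip():
            if node.name is None:
                raise TreeError("leaf without a label")
            if node.name in seen_labels and not allow_duplicate_labels:
                raise TreeError(f"duplicate leaf label: {node.name!r}")
            seen_labels.add(node.name)
            # labels dict is keyed by node id, so duplicate values are fine
            # for multi-copy trees; uniqueness is enforced above when required
            nid = tree.new_node()
            tree.labels[nid] = node.name
        else:
            nid = tree.new_node()
            for child in node.children:
                build(child, nid)
        if parent_id is not None:
            tree.connect(parent_id, nid)

    build(sk, None)
    tree.suppress_all_degree_two()
    return tree


def parse_newick(text: str, allow_duplicate_labels: bool = False) -> UnrootedTree:
    """Parse one Newick string into an :class:`UnrootedTree`.

    Branch lengths and internal node labels are discarded.  A rooted input
    (top-level bifurcation) is unrooted by suppressing the root.  Duplicate
    leaf labels are an error unless ``allow_duplicate_labels`` is set (the
    gene-family loader uses that mode for multi-copy families).
    """
    text = text.strip()
    if not text.endswith(";"):
        raise TreeError("Newick string must end with ';'")
    try:
        sk = skbio.TreeNode.read(io.StringIO(text), convert_underscores=False)
    except Exception as exc:  # skbio raises NewickFormatError with position info
        raise TreeError(f"malformed Newick: {exc}") from exc
    tree = _from_skbio(sk, allow_duplicate_labels=allow_duplicate_labels)
    if len(tree.adj) == 1 and tree.labels:
        raise TreeError("a single-leaf tree is not supported")
    if not allow_duplicate_labels:
        tree.validate()
    return tree


def parse_newick_file(path) -> list[UnrootedTree]:
    """Read one tree per line; blank lines and '#' comment lines ignored."""
    trees = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                trees.append(parse_newick(line))
            except TreeError as exc:
                raise TreeError(f"{path}, line {lineno}: {exc}") from exc
    return trees


def _quote_label(label: str) -> str:
    if _NEEDS_QUOTING.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(
    tree: UnrootedTree,
    edge_label: Callable[[int, int], str | None] | None = None,
) -> str:
    """Serialize to Newick.  Output is deterministic: children are ordered
    by the lexicographically smallest leaf label in their subtree.

    ``edge_label(child, parent)`` may supply a label written after the
    closing parenthesis of the child subtree (used for branch supports).
    """
    internals = tree.internal_nodes()
    if not internals:
        # degenerate two-leaf tree
        labs = sorted(tree.labels.values())
        return "(" + ",".join(_quote_label(x) for x in labs) + ");"
    root = internals[0]

    def render(v: int, parent: int | None) -> tuple[str, str]:
        """Return (min leaf label in subtree, newick fragment)."""
        lab = tree.labels.get(v)
        if lab is not None and (parent is not None or tree.degree(v) == 0):
            return lab, _quote_label(lab)
        parts = []
        for u in tree.adj[v]:
            if u != parent:
                parts.append(render(u, v))
        parts.sort(key=lambda p: p[0])
        frag = "(" + ",".join(p[1] for p in parts) + ")"
        if parent is not None and edge_label is not None:
            extra = edge_label(v, parent)
            if extra is not None:
                frag += extra
        return min(p[0] for p in parts), frag

    return render(root, None)[1] + ";"


# ---------------------------------------------------------------------------
# Induced trees and internode distances
# ---------------------------------------------------------------------------


def induced_tree(tree: UnrootedTree, taxa: Iterable[str]) -> UnrootedTree:
    """Restrict ``tree`` to leaf set ``taxa``: drop the other leaves, then
    contract dangling nodes and suppress degree-2 nodes."""
    taxa = frozenset(taxa)
    if len(taxa) < 2:
        raise TreeError("need at least 2 taxa to induce a tree")
    missing = taxa - tree.leaf_labels()
    if missing:
        raise TreeError(f"taxa not in tree: {', '.join(sorted(missing))}")
    t = tree.copy()
    # iteratively strip leaves outside taxa and newly-dangling internals
    stack = [v for v, lab in list(t.labels.items()) if lab not in taxa]
    while stack:
        v = stack.pop()
        if v not in t.adj:
            continue
        nbrs = list(t.adj[v])
        t.remove_node(v)
        for u in nbrs:
            if u not in t.labels and len(t.adj[u]) <= 1:
                stack.append(u)
    t.suppress_all_degree_two()
    return t


def _leaf_edge_distances(tree: UnrootedTree) -> tuple[list[int], np.ndarray]:
    """All-pairs path lengths in edges between leaves, by BFS from each leaf."""
    leaf_ids = tree.leaves()
    pos = {v: i for i, v in enumerate(leaf_ids)}
    n = len(leaf_ids)
    out = np.zeros((n, n), dtype=np.int64)
    for i, src in enumerate(leaf_ids):
        dist = {src: 0}
        frontier = [src]
        while frontier:
            nxt = []
            for v in frontier:
                for u in tree.adj[v]:
                    if u not in dist:
                        dist[u] = dist[v] + 1
                        nxt.append(u)
            frontier = nxt
        for v, d in dist.items():
            j = pos.get(v)
            if j is not None:
                out[i, j] = d
    return leaf_ids, out


def internode_matrix(tree: UnrootedTree) -> InternodeMatrix:
    """Internode distance matrix over sorted leaf labels.

    A path of d edges between two distinct leaves passes through d - 1
    internal nodes, so the matrix is the edge-count distance minus one.
    Well defined for multifurcating trees.
    """
    if tree.n_leaves < 2:
        raise TreeError("internode matrix needs >= 2 leaves")
    leaf_ids, edge_dist = _leaf_edge_distances(tree)
    order = np.argsort([tree.labels[v] for v in leaf_ids])
    taxa = tuple(tree.labels[leaf_ids[i]] for i in order)
    values = np.maximum(edge_dist[np.ix_(order, order)] - 1, 0)
    return InternodeMatrix(taxa=taxa, values=values)


def bipartitions(tree: UnrootedTree) -> frozenset[Bipartition]:
    """Nontrivial bipartitions, one per internal edge."""
    all_labels = tree.leaf_labels()
    out = []
    for u, v in tree.internal_edges():
        side = tree.side_leaves(u, v)
        out.append(Bipartition(frozenset((side, all_labels - side))))
    return frozenset(out)


def rf_distance(t1: UnrootedTree, t2: UnrootedTree) -> tuple[int, float]:
    """Robinson-Foulds distance after restriction to the shared taxon set.

    Returns ``(plain, normalized)`` where plain is the size of the symmetric
    difference of the nontrivial bipartition sets and normalized divides by
    the total number of nontrivial bipartitions in both trees (1.0 for two
    binary trees sharing no split; the convention also covers multifurcating
    references).
    """
    shared = t1.leaf_labels() & t2.leaf_labels()
    if len(shared) < 4:
        raise TreeError(f"trees share only {len(shared)} taxa; need >= 4")
    r1 = induced_tree(t1, shared) if t1.leaf_labels() != shared else t1
    r2 = induced_tree(t2, shared) if t2.leaf_labels() != shared else t2
    b1 = bipartitions(r1)
    b2 = bipartitions(r2)
    plain = len(b1 ^ b2)
    denom = len(b1) + len(b2)
    return plain, (plain / denom if denom else 0.0)


# ---------------------------------------------------------------------------
# Topology enumeration (used as a brute-force oracle at small taxon counts)
# ---------------------------------------------------------------------------


def enumerate_topologies(labels: Sequence[str]) -> Iterator[UnrootedTree]:
    """Yield every unrooted binary topology over ``labels`` exactly once.

    Built by sequential leaf insertion: each of the (2n-5)!! topologies is
    produced once.  Intended for n <= 8.
    """
    labels = list(labels)
    if len(labels) < 3:
        raise TreeError("topology enumeration needs >= 3 labels")

    base = UnrootedTree()
    center = base.new_node()
    for lab in labels[:3]:
        base.connect(center, base.new_node(lab))

    def grow(tree: UnrootedTree, remaining: list[str]) -> Iterator[UnrootedTree]:
        if not remaining:
            yield tree
            return
        lab, rest = remaining[0], remaining[1:]
        for u, v in list(tree.edges()):
            t = tree.copy()
            w = t.subdivide(u, v)
            t.connect(w, t.new_node(lab))
            yield from grow(t, rest)

    yield from grow(base, labels[3:])
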