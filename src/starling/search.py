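"""Species-tree search minimizing the global induced length.

The search is a hill climb over SPR (subtree prune and regraft) moves,
following the FastME/ASTRID family of distance-based searches: every SPR
neighbor of the current tree is scored, and all *non-conflicting* improving
moves (moves whose touched-edge sets are disjoint) are applied in one
batch, which accelerates convergence over best-move-only climbing.  After
a batch the full score is recomputed; if the combination did not improve
(moves can interact), the single best move is applied instead, so the
score trace is strictly decreasing by construction and termination is
guaranteed.

Starting trees are either random (uniform sequential leaf attachment) or
distance-based: neighbor joining on the (imputed) averaged internode
matrix followed by balanced-minimum-evolution NNI refinement, i.e. a
re-implementation of the ASTRID strategy.  Note that Pauplin's BME tree
length over a distance matrix D,  sum 2^(1 - p_ij) D_ij  with p_ij the
topological path length, is exactly the global length criterion, since the
internode distance is p_ij - 1.

Everything is deterministic given the seed: moves are enumerated in a
canonical order and randomness is used only for random starting trees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

from .families import (
    AveragedMatrix,
    GeneFamily,
    PatternGroup,
    average_matrix,
    group_by_pattern,
    impute_missing,
)
from .scoring import global_length, induced_geometry, pattern_scores
from .tree import TreeError, UnrootedTree, _from_skbio

__all__ = [
    "SprMove",
    "SearchConfig",
    "SearchResult",
    "random_starting_tree",
    "astrid_starting_tree",
    "enumerate_spr",
    "apply_spr",
    "evaluate_move",
    "apply_nonconflicting_batch",
    "search",
]

logger = logging.getLogger(__name__)

Edge = frozenset  # an undirected edge, as frozenset({u, v})


@dataclass(frozen=True)
class SprMove:
    """Prune the component containing ``prune[1]`` at node ``prune[0]`` and
    regraft it onto ``regraft``.  ``touched`` is the set of edges whose
    incident geometry the move can alter: the pruned edge, the two other
    edges at the attachment node, the regraft edge, and the path between
    attachment and regraft point."""

    prune: tuple[int, int]
    regraft: tuple[int, int]
    touched: frozenset[frozenset[int]]
    delta: float | None = None


@dataclass
class SearchConfig:
    """Knobs of the tree search.

    ``random_starts = 0`` starts from the distance-based (ASTRID-style)
    tree; ``random_starts = r > 0`` runs r independent random starts and
    keeps the best final score.
    """

    random_starts: int = 0
    tolerance: float = 1e-9
    max_iterations: int = 200
    seed: int = 42

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.random_starts < 0:
            raise ValueError("random_starts must be >= 0")


@dataclass
class SearchResult:
    best_tree: UnrootedTree
    best_score: float
    trace: list[float]
    starting_tree: UnrootedTree
    n_iterations: int


# ---------------------------------------------------------------------------
# starting trees
# ---------------------------------------------------------------------------


def random_starting_tree(labels: Sequence[str], seed) -> UnrootedTree:
    """Uniformly distributed random binary topology over ``labels``.

    Sequential attachment of each next leaf to a uniformly chosen edge
    yields the uniform distribution over the (2n-5)!! unrooted binary
    topologies.  ``seed`` may be an int or a numpy Generator.
    """
    labels = sorted(set(labels))
    if len(labels) < 3:
        raise TreeError("need >= 3 labels for a starting tree")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tree = UnrootedTree()
    center = tree.new_node()
    for lab in labels[:3]:
        tree.connect(center, tree.new_node(lab))
    for lab in labels[3:]:
        edges = list(tree.edges())
        u, v = edges[rng.integers(len(edges))]
        w = tree.subdivide(u, v)
        tree.connect(w, tree.new_node(lab))
    return tree


def _nni_neighbors(tree: UnrootedTree) -> Iterator[UnrootedTree]:
    """The two NNI rearrangements of every internal edge of a binary tree."""
    for u, v in tree.internal_edges():
        (x,) = [w for w in tree.adj[u] if w != v][:1]
        others_v = [w for w in tree.adj[v] if w != u]
        for c in others_v:
            t = tree.copy()
            t.disconnect(u, x)
            t.disconnect(v, c)
            t.connect(u, c)
            t.connect(v, x)
            yield t


def astrid_starting_tree(avg: AveragedMatrix, seed=None) -> UnrootedTree:
    """Distance-based starting tree: NJ on the imputed averaged matrix,
    refined by balanced-minimum-evolution NNIs until no improvement.

    Species pairs never co-observed in any gene are imputed by shortest
    paths through observed pairs; if the co-occurrence graph is
    disconnected no distance-based tree exists and the caller should use
    random starting trees instead.
    """
    import skbio

    if len(avg.taxa) < 4:
        raise TreeError("need >= 4 species for a starting tree")
    full = impute_missing(avg)
    if not np.all(np.isfinite(full)):
        raise TreeError(
            "the species co-occurrence graph is disconnected; no "
            "distance-based starting tree exists - use random starts "
            "(random_starts >= 1)"
        )
    dm = skbio.DistanceMatrix((full + full.T) / 2.0, ids=list(avg.taxa))
    tree = _from_skbio(skbio.tree.nj(dm))
    tree.suppress_all_degree_two()

    complete = AveragedMatrix(
        taxa=avg.taxa,
        values=full,
        counts=np.ones_like(avg.counts) - np.eye(len(avg.taxa), dtype=np.int64),
    )
    best = global_length(tree, complete)
    while True:
        improved = False
        for cand in _nni_neighbors(tree):
            score = global_length(cand, complete)
            if score < best - 1e-12:
                tree, best = cand, score
                improved = True
                break
        if not improved:
            return tree


# ---------------------------------------------------------------------------
# SPR moves
# ---------------------------------------------------------------------------


def _split_signature(tree: UnrootedTree, leaf_bit: dict[str, int]) -> frozenset[int]:
    """Canonical topology fingerprint: the set of leaf bitmasks of every
    edge, each side canonicalized to the one not containing leaf bit 0."""
    full = (1 << len(leaf_bit)) - 1
    internals = tree.internal_nodes()
    root = internals[0] if internals else next(iter(tree.adj))
    mask: dict[int, int] = {}
    order: list[tuple[int, int | None]] = []
    stack = [(root, None)]
    while stack:
        v, parent = stack.pop()
        order.append((v, parent))
        for u in tree.adj[v]:
            if u != parent:
                stack.append((u, v))
    sig = set()
    for v, parent in reversed(order):
        lab = tree.labels.get(v)
        m = (1 << leaf_bit[lab]) if lab is not None else 0
        for u in tree.adj[v]:
            if u != parent:
                m |= mask[u]
        mask[v] = m
        if parent is not None:
            sig.add(m if not (m & 1) else (full ^ m))
    return frozenset(sig)


def _subtree_nodes(tree: UnrootedTree, a: int, b: int) -> set[int]:
    """Nodes of the component containing b when edge (a, b) is cut."""
    seen = {a, b}
    stack = [b]
    while stack:
        v = stack.pop()
        for u in tree.adj[v]:
            if u not in seen:
                seen.add(u)
                stack.append(u)
    seen.discard(a)
    return seen


def _candidate_moves(tree: UnrootedTree) -> Iterator[SprMove]:
    """All (prune, regraft) pairs, canonical order, without topology dedup."""
    for u, v in sorted(tree.edges()):
        for a, b in ((u, v), (v, u)):
            if a in tree.labels:
                continue  # attachment node must be internal
            x, y = (w for w in tree.adj[a] if w != b)
            # BFS over the remaining component from a, recording parents
            parent: dict[int, int] = {a: -1, b: -1}
            queue = [a]
            remaining: list[int] = []
            while queue:
                nxt = []
                for w in queue:
                    for z in tree.adj[w]:
                        if z not in parent:
                            parent[z] = w
                            remaining.append(z)
                            nxt.append(z)
                queue = nxt
            base_touched = [
                frozenset((a, b)),
                frozenset((a, x)),
                frozenset((a, y)),
            ]
            for p in remaining:
                for q in tree.adj[p]:
                    if q == parent[p] or q == a:
                        continue
                    if parent.get(q) != p:
                        continue  # each remaining edge once, as (parent, child)
                    # regrafting onto an edge incident to a recreates the
                    # original topology (it is half of the merged edge)
                    if p == a or q == a:
                        continue
                    touched = list(base_touched)
                    touched.append(frozenset((p, q)))
                    w = p
                    while parent[w] != -1:
                        touched.append(frozenset((w, parent[w])))
                        w = parent[w]
                    yield SprMove(
                        prune=(a, b),
                        regraft=(p, q),
                        touched=frozenset(touched),
                    )


def apply_spr(tree: UnrootedTree, move: SprMove) -> UnrootedTree:
    """Apply an SPR move to a copy of ``tree`` and return it."""
    t = tree.copy()
    a, b = move.prune
    p, q = move.regraft
    t.disconnect(a, b)
    t.suppress_if_degree_two(a)
    c = t.subdivide(p, q)
    t.connect(c, b)
    return t


def enumerate_spr(tree: UnrootedTree) -> list[SprMove]:
    """All SPR moves producing a topology distinct from ``tree``, with at
    most one move per resulting topology."""
    if not tree.is_binary():
        raise TreeError("SPR enumeration requires a binary tree")
    leaf_bit = {lab: i for i, lab in enumerate(sorted(tree.labels.values()))}
    seen = {_split_signature(tree, leaf_bit)}
    out = []
    for move in _candidate_moves(tree):
        sig = _split_signature(apply_spr(tree, move), leaf_bit)
        if sig not in seen:
            seen.add(sig)
            out.append(move)
    return out


# ---------------------------------------------------------------------------
# move evaluation with per-pattern caching
# ---------------------------------------------------------------------------


class _ScoringContext:
    """Per-tree cache: pattern-group scores plus leaf-side bitmasks of every
    edge, so a move only rescores the groups whose induced geometry it can
    change (those with taxa on both sides of some touched edge)."""

    def __init__(self, tree: UnrootedTree, groups: Sequence[PatternGroup]):
        self.tree = tree
        self.groups = groups
        self.leaf_bit = {lab: i for i, lab in enumerate(sorted(tree.labels.values()))}
        self.pattern_masks = [
            sum(1 << self.leaf_bit[s] for s in g.pattern) for g in groups
        ]
        self.group_scores = pattern_scores(tree, groups)
        self.total = float(sum(self.group_scores))
        self.edge_side: dict[frozenset[int], int] = {}
        self._compute_edge_sides()

    def _compute_edge_sides(self) -> None:
        tree = self.tree
        internals = tree.internal_nodes()
        root = internals[0] if internals else next(iter(tree.adj))
        order: list[tuple[int, int | None]] = []
        stack = [(root, None)]
        while stack:
            v, parent = stack.pop()
            order.append((v, parent))
            for u in tree.adj[v]:
                if u != parent:
                    stack.append((u, v))
        mask: dict[int, int] = {}
        for v, parent in reversed(order):
            lab = tree.labels.get(v)
            m = (1 << self.leaf_bit[lab]) if lab is not None else 0
            for u in tree.adj[v]:
                if u != parent:
                    m |= mask[u]
            mask[v] = m
            if parent is not None:
                self.edge_side[frozenset((v, parent))] = m

    def affected_groups(self, move: SprMove) -> list[int]:
        # A pattern's induced (suppressed) topology changes only if the
        # pruned edge lies on the pattern's spanning subtree, i.e. the moved
        # subtree contains some but not all of the pattern's taxa.  A move
        # that only threads a pattern-free subtree through a pattern's paths
        # adds/removes degree-2 points that suppression discards.
        side = self.edge_side[frozenset(move.prune)]
        out = []
        for gi, pat in enumerate(self.pattern_masks):
            inter = side & pat
            if inter and inter != pat:
                out.append(gi)
        return out

    def delta(self, move: SprMove, new_tree: UnrootedTree | None = None) -> float:
        affected = self.affected_groups(move)
        if not affected:
            return 0.0
        if new_tree is None:
            new_tree = apply_spr(self.tree, move)
        d = 0.0
        for gi in affected:
            group = self.groups[gi]
            geo = induced_geometry(new_tree, group.pattern)
            d += 0.5 * float(np.sum(geo.weights * group.summed)) - self.group_scores[gi]
        return d


def evaluate_move(
    tree: UnrootedTree, groups: Sequence[PatternGroup], move: SprMove
) -> float:
    """Score change (new - old) of one SPR move; negative = improvement.

    Only pattern groups separated by a touched edge are rescored; the rest
    contribute exactly 0 because their induced geometry is unchanged.
    """
    return _ScoringContext(tree, groups).delta(move)


def apply_nonconflicting_batch(
    tree: UnrootedTree,
    moves: Sequence[SprMove],
    groups: Sequence[PatternGroup],
    tolerance: float = 1e-9,
) -> tuple[UnrootedTree, list[SprMove]]:
    """Apply a batch of improving moves with pairwise disjoint touched-edge
    sets, best delta first.  The full score is verified afterwards; if the
    batch did not actually improve on the single best move's guarantee (the
    moves interacted), only the best move is applied."""
    ranked = sorted(moves, key=lambda m: (m.delta, sorted(map(sorted, m.touched))))
    accepted: list[SprMove] = []
    used: set[frozenset[int]] = set()
    for move in ranked:
        if move.touched & used:
            continue
        accepted.append(move)
        used |= move.touched
    candidate = tree
    for move in accepted:
        candidate = apply_spr(candidate, move)
    if len(accepted) > 1:
        from .scoring import global_induced_length

        old = global_induced_length(tree, groups)
        new = global_induced_length(candidate, groups)
        if new >= old - tolerance:
            best = ranked[0]
            return apply_spr(tree, best), [best]
    return candidate, accepted


# ---------------------------------------------------------------------------
# the search proper
# ---------------------------------------------------------------------------


def _hill_climb(
    start: UnrootedTree,
    groups: Sequence[PatternGroup],
    config: SearchConfig,
) -> SearchResult:
    tree = start
    ctx = _ScoringContext(tree, groups)
    trace = [ctx.total]
    iterations = 0
    while iterations < config.max_iterations:
        leaf_bit = ctx.leaf_bit
        seen = {_split_signature(tree, leaf_bit)}
        improving: list[SprMove] = []
        for move in _candidate_moves(tree):
            if not ctx.affected_groups(move):
                continue
            new_tree = apply_spr(tree, move)
            sig = _split_signature(new_tree, leaf_bit)
            if sig in seen:
                continue
            seen.add(sig)
            d = ctx.delta(move, new_tree)
            if d < -config.tolerance:
                improving.append(replace(move, delta=d))
        if not improving:
            break
        tree, accepted = apply_nonconflicting_batch(
            tree, improving, groups, config.tolerance
        )
        ctx = _ScoringContext(tree, groups)
        iterations += 1
        logger.debug(
            "iteration %d: %d improving moves, %d applied, score %.9f",
            iterations,
            len(improving),
            len(accepted),
            ctx.total,
        )
        if trace and ctx.total >= trace[-1] - config.tolerance:
            # cannot happen by construction; guard against cycling anyway
            break
        trace.append(ctx.total)
    return SearchResult(
        best_tree=tree,
        best_score=ctx.total,
        trace=trace,
        starting_tree=start,
        n_iterations=iterations,
    )


def search(
    families: Sequence[GeneFamily],
    config: SearchConfig | None = None,
    groups: Sequence[PatternGroup] | None = None,
) -> SearchResult:
    """Infer a species tree minimizing the global induced length.

    With ``random_starts = 0`` the single distance-based starting tree is
    used; otherwise that many independent random starts are run and the
    best final score wins (ties broken by run order).  Deterministic given
    the seed.
    """
    config = config or SearchConfig()
    if not families:
        raise TreeError("no gene families to analyze")
    if groups is None:
        groups = group_by_pattern(families)
    species = sorted(set().union(*(g.pattern for g in groups)))
    if len(species) < 4:
        raise TreeError("fewer than 4 species across all gene families")

    if config.random_starts == 0:
        starts = [astrid_starting_tree(average_matrix(families))]
    else:
        seeds = np.random.SeedSequence(config.seed).spawn(config.random_starts)
        starts = [random_starting_tree(species, np.random.default_rng(s)) for s in seeds]

    best: SearchResult | None = None
    for start in starts:
        result = _hill_climb(start, groups, config)
        if best is None or result.best_score < best.best_score - config.tolerance:
            best = result
    assert best is not None
    return best
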