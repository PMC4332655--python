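"""Reduction of multiply-labeled gene trees to conflict-free species trees.

A gene tree that samples a species more than once (alleles, individuals,
paralogs) is a *multree* and cannot be combined across loci directly.  The
reduction implemented here is deliberately conservative.  A displayed
quartet is *conflict-free* when no other displayed quartet resolves the
same four species differently; the reduction keeps only conflict-free
information, so no edge of the output asserts anything the input did not
already assert, and a species with no conflict-free information
disappears entirely.  When nothing conflict-free survives, the result is
the empty tree.

The output is the tree whose internal edges are ALL the splits of the
conflict-free label set every one of whose induced quartets is
conflict-free.  Two such splits are automatically compatible (were they
to cross, they would induce two different resolutions of one four-species
set, which conflict-freeness forbids), so the construction is always
well-defined; and because every split of any tree that introduces no new
information is itself such a split, the result displays a superset of the
quartets of every conservative tree on those labels -- it is the unique
maximum.  Whenever the conflict-free set is exactly displayable by a tree
(singly-labeled inputs, concordant duplications, the textbook figures)
the result displays exactly that set.
"""

from __future__ import annotations

from collections import defaultdict
from itertools import combinations
from typing import Dict, FrozenSet, Iterable, Iterator, List, Set, Tuple

from .trees import (
    Bipartition,
    LabeledTree,
    Quartet,
    TreeError,
    tree_from_splits,
)

__all__ = [
    "ReductionError",
    "enumerate_binary_split_sets",
    "conflict_free_quartets",
    "reduce_multree",
    "brute_force_reduction",
    "enumerate_topology_split_sets",
    "quartets_of_split_set",
]


class ReductionError(TreeError):
    """Internal consistency failure of the reduction (should not happen)."""


def conflict_free_quartets(multree: LabeledTree) -> Set[Quartet]:
    """Displayed quartets whose four-species set supports a single topology.

    A quartet ``ab|cd`` is conflict-free when no edge of the same tree
    displays ``ac|bd`` or ``ad|bc``.
    """
    displayed = multree.displayed_quartets()
    by_labels: Dict[FrozenSet[str], List[Quartet]] = defaultdict(list)
    for q in displayed:
        by_labels[q.labels].append(q)
    return {qs[0] for qs in by_labels.values() if len(qs) == 1}


def conflict_free_splits(
    labels: FrozenSet[str], cf: Set[Quartet]
) -> List[Bipartition]:
    """All splits of ``labels`` whose every induced quartet lies in ``cf``.

    Searched by assigning labels to the two sides depth-first, pruning a
    branch as soon as one decided cross-quartet falls outside ``cf``;
    the surviving splits are pairwise compatible by construction of
    conflict-freeness (crossing splits would doubly resolve a 4-set).
    """
    labs = sorted(labels)
    n = len(labs)
    if n < 4:
        return []
    cf = set(cf)
    out: List[Bipartition] = []
    # anchor labs[0] on side B to halve the search space
    side_a: List[str] = []
    side_b: List[str] = [labs[0]]

    def ok_with(new: str, own: List[str], other: List[str]) -> bool:
        for a in own:
            for c, d in combinations(other, 2):
                if Quartet.make((new, a), (c, d)) not in cf:
                    return False
        return True

    def assign(i: int) -> None:
        if i == n:
            if len(side_a) >= 2 and len(side_b) >= 2:
                out.append(Bipartition.make(side_a, side_b))
            return
        lab = labs[i]
        remaining = n - i - 1
        if ok_with(lab, side_a, side_b):
            if len(side_a) + 1 + remaining >= 2:
                side_a.append(lab)
                assign(i + 1)
                side_a.pop()
        if ok_with(lab, side_b, side_a):
            side_b.append(lab)
            assign(i + 1)
            side_b.pop()

    assign(1)
    return out


def reduce_multree(multree: LabeledTree) -> LabeledTree:
    """Conservative singly-labeled reduction of a (possibly multi-) tree.

    The label set of the result is the set of species occurring in at
    least one conflict-free quartet; its edges are all splits of that set
    whose induced quartets are all conflict-free.  The result therefore
    displays only conflict-free quartets, and at least as many of them as
    any other tree with that property (the unique maximum); when the
    conflict-free set is exactly displayable, the result displays exactly
    it.  With no informative edge at all the empty tree is returned (no
    edges, no taxa).
    """
    cf = conflict_free_quartets(multree)
    if not cf:
        return LabeledTree.empty()
    labels: FrozenSet[str] = frozenset().union(*(q.labels for q in cf))
    if len(labels) > 24:
        raise ValueError(
    "multree reduction supports up to 24 distinct informative labels"
        )
    splits = conflict_free_splits(labels, cf)
    if not splits:
        return LabeledTree.empty()
    tree = tree_from_splits(labels, splits)
    shown = tree.displayed_quartets()
    if not shown <= cf:  # defensive: contradicts the compatibility theorem
        raise ReductionError(
            "reduction postcondition violated: output displays a quartet "
            "outside the conflict-free set"
        )
    return tree


# ---------------------------------------------------------------------------
# exhaustive oracle (small label sets)
# ---------------------------------------------------------------------------


def _binary_adjacency_trees(n: int) -> List[Dict[int, Set[int]]]:
    """All binary unrooted shapes on n leaves, grown by leaf insertion.

    Leaf node ids increase with insertion order, so sorting the degree-1
    nodes recovers the order in which labels were attached.
    """
    trees: List[Tuple[Dict[int, Set[int]], int]] = [
        ({0: {3}, 1: {3}, 2: {3}, 3: {0, 1, 2}}, 4)
    ]
    for _ in range(3, n):
        grown: List[Tuple[Dict[int, Set[int]], int]] = []
        for adj, nid in trees:
            for u, v in [(a, b) for a in adj for b in adj[a] if a < b]:
                new_adj = {k: set(vs) for k, vs in adj.items()}
                hub, leaf = nid, nid + 1
                new_adj[u].discard(v)
                new_adj[v].discard(u)
                new_adj[hub] = {u, v, leaf}
                new_adj[u].add(hub)
                new_adj[v].add(hub)
                new_adj[leaf] = {hub}
                grown.append((new_adj, nid + 2))
        trees = grown
    return [adj for adj, _ in trees]


def _splits_of_adjacency(
    adj: Dict[int, Set[int]], labs: List[str]
) -> FrozenSet[Bipartition]:
    full = frozenset(labs)
    n = len(labs)
    leaf_ids = sorted(u for u in adj if len(adj[u]) == 1)
    label_of = {u: labs[i] for i, u in enumerate(leaf_ids)}
    splits: Set[Bipartition] = set()
    for u in adj:
        for v in adj[u]:
            if u < v:
                seen = {u}
                stack = [u]
                while stack:
                    x = stack.pop()
                    for y in adj[x]:
                        if y != v and y not in seen:
                            seen.add(y)
                            stack.append(y)
                side = frozenset(label_of[x] for x in seen if x in label_of)
                if 2 <= len(side) <= n - 2:
                    splits.add(Bipartition.make(side, full - side))
    return frozenset(splits)


def enumerate_binary_split_sets(labels: Iterable[str]) -> Iterator[FrozenSet[Bipartition]]:
    """Split sets of all (2n-5)!! binary unrooted topologies on ``labels``."""
    labs = sorted(set(labels))
    n = len(labs)
    if n > 9:
        raise ValueError("binary topology enumeration is limited to 9 labels")
    if n < 4:
        yield frozenset()
        return
    for adj in _binary_adjacency_trees(n):
        yield _splits_of_adjacency(adj, labs)


def enumerate_topology_split_sets(labels: Iterable[str]) -> List[FrozenSet[Bipartition]]:
    """Every unrooted topology (polytomies included) on ``labels``.

    A topology is represented by its set of nontrivial bipartitions.
    Enumeration goes through all binary topologies by sequential leaf
    insertion and then takes every subset of each binary split set
    (contracting internal edges), de-duplicated.  Intended for small label
    sets only.
    """
    labs = sorted(set(labels))
    n = len(labs)
    if n > 8:
        raise ValueError("full topology enumeration is limited to 8 labels")
    if n < 4:
        return [frozenset()]
    cached = _TOPOLOGY_CACHE.get(tuple(labs))
    if cached is not None:
        return cached
    out: Set[FrozenSet[Bipartition]] = set()
    for splits in enumerate_binary_split_sets(labs):
        split_list = sorted(splits, key=repr)
        for k in range(len(split_list) + 1):
            for subset in combinations(split_list, k):
                out.add(frozenset(subset))
    result = sorted(out, key=lambda s: (len(s), sorted(map(repr, s))))
    if len(_TOPOLOGY_CACHE) < 8:  # keep a few label alphabets hot
        _TOPOLOGY_CACHE[tuple(labs)] = result
    return result


_TOPOLOGY_CACHE: Dict[Tuple[str, ...], List[FrozenSet[Bipartition]]] = {}



def quartets_of_split_set(splits: FrozenSet[Bipartition]) -> FrozenSet[Quartet]:
    """Quartets displayed by the tree whose nontrivial splits are given."""
    qs: Set[Quartet] = set()
    for bp in splits:
        for a, b in combinations(sorted(bp.side_a), 2):
            for c, d in combinations(sorted(bp.side_b), 2):
                qs.add(Quartet.make((a, b), (c, d)))
    return frozenset(qs)


def _brute_force_displayed(multree: LabeledTree) -> Set[Quartet]:
    """Edge-by-edge quartet extraction via explicit graph bisection.

    Independent of the production path (which uses one rooted sweep): each
    edge is removed from a networkx copy of the tree and the two
    components are inspected directly.
    """
    import networkx as nx

    g = nx.Graph()
    label_of: Dict[int, str] = {}
    for u, v in multree.edges():
        g.add_edge(u, v)
    for u in multree.leaves():
        label_of[u] = multree._leaf_label[u]
        g.add_node(u)
    out: Set[Quartet] = set()
    for u, v in list(g.edges()):
        g.remove_edge(u, v)
        comp_u = nx.node_connected_component(g, u)
        g.add_edge(u, v)
        side_a = {label_of[x] for x in comp_u if x in label_of}
        side_b = {label_of[x] for x in label_of if x not in comp_u}
        for a, b in combinations(sorted(side_a), 2):
            for c, d in combinations(sorted(side_b), 2):
                if len({a, b, c, d}) == 4:
                    out.add(Quartet.make((a, b), (c, d)))
    return out


def brute_force_reduction(multree: LabeledTree) -> LabeledTree:
    """Exhaustive-search oracle for :func:`reduce_multree` (<= 7 labels).

    Computes the conflict-free quartet set by filtering explicitly
    bisected edges, then scans *all* unrooted topologies on the implied
    label set for those displaying only conflict-free quartets, and
    verifies that one of them dominates every other by quartet-set
    inclusion (the unique maximum).  Test oracle only; refuses larger
    inputs.
    """
    distinct = set(multree.label_set())
    if len(distinct) > 7:
        raise ValueError("brute-force reduction refuses more than 7 distinct labels")
    displayed = _brute_force_displayed(multree)
    by_labels: Dict[FrozenSet[str], List[Quartet]] = defaultdict(list)
    for q in displayed:
        by_labels[q.labels].append(q)
    cf = {qs[0] for qs in by_labels.values() if len(qs) == 1}
    if not cf:
        return LabeledTree.empty()
    labels: FrozenSet[str] = frozenset().union(*(q.labels for q in cf))
    cf_frozen = frozenset(cf)
    candidates = []
    for s in enumerate_topology_split_sets(labels):
        qs = quartets_of_split_set(s)
        if qs <= cf_frozen:
            candidates.append((s, qs))
    best_splits, best_qs = max(candidates, key=lambda c: len(c[1]))
    dominated = all(qs <= best_qs for _s, qs in candidates)
    if not dominated:
        raise ReductionError(
            "oracle: no unique maximum conservative tree exists "
            "(contradicts the split-compatibility theorem)"
        )
    if not best_qs:
        return LabeledTree.empty()
    return tree_from_splits(labels, list(best_splits))
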