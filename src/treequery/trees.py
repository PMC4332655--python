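"""Leaf-labeled phylogenetic trees and their elementary operations.

The central object is :class:`LabeledTree`, an unrooted (optionally rooted
for display) tree whose leaves carry taxon-name labels.  Labels may repeat,
in which case the tree is a *multree* -- the situation that arises when a
gene tree contains several sequences (alleles, individuals, paralogs) for
the same species.  All topological information is expressed through two
canonical units:

* :class:`Bipartition` -- the split of the label set induced by removing
  one edge of an unrooted, singly-labeled tree;
* :class:`Quartet` -- the resolved topology ``ab|cd`` induced on four
  labels, the atomic unit of unrooted phylogenetic information.

Newick I/O is delegated to Biopython's parser; this module adds the
dialect conventions used throughout the package (duplicate leaf labels
allowed, numeric internal labels in [0, 100] read as edge support,
underscores read as spaces, writer emitting underscores).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from io import StringIO
from itertools import combinations
from typing import Dict, FrozenSet, Iterable, Iterator, List, Optional, Set, Tuple

from Bio import Phylo

__all__ = [
    "TreeError",
    "NewickParseError",
    "NoOverlapError",
    "IncompatibleSplitsError",
    "MissingLengthWarning",
    "Bipartition",
    "Quartet",
    "LabeledTree",
    "parse_newick",
    "write_newick",
    "tree_from_splits",
]


class TreeError(ValueError):
    """Structural error on a tree operation."""


class NewickParseError(TreeError):
    """Malformed newick input."""


class NoOverlapError(TreeError):
    """A restriction was requested to a label set disjoint from the tree."""


class IncompatibleSplitsError(TreeError):
    """A split collection is not pairwise compatible (not tree-like)."""


class MissingLengthWarning(UserWarning):
    """A suppressed path mixed present and absent branch lengths."""


# ---------------------------------------------------------------------------
# canonical topological units
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Bipartition:
    """A two-way split of a label set, stored in canonical orientation.

    ``side_a`` is the side containing the lexicographically smallest label,
    which makes the representation unique per split.
    """

    side_a: FrozenSet[str]
    side_b: FrozenSet[str]

    @classmethod
    def make(cls, side_a: Iterable[str], side_b: Iterable[str]) -> "Bipartition":
        a, b = frozenset(side_a), frozenset(side_b)
        if not a or not b:
            raise TreeError("bipartition sides must be nonempty")
        if a & b:
            raise TreeError(f"bipartition sides overlap: {sorted(a & b)}")
        if min(b) < min(a):
            a, b = b, a
        return cls(a, b)

    @property
    def labels(self) -> FrozenSet[str]:
        return self.side_a | self.side_b

    @property
    def is_nontrivial(self) -> bool:
        return len(self.side_a) >= 2 and len(self.side_b) >= 2

    def restricted(self, keep: FrozenSet[str]) -> Optional["Bipartition"]:
        """Induced split on ``keep``; None when it degenerates to trivial."""
        a, b = self.side_a & keep, self.side_b & keep
        if len(a) < 2 or len(b) < 2:
            return None
        return Bipartition.make(a, b)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return "{}|{}".format(",".join(sorted(self.side_a)), ",".join(sorted(self.side_b)))


@dataclass(frozen=True)
class Quartet:
    """Resolved topology ``ab|cd`` on four distinct labels, canonicalized."""

    pair_1: Tuple[str, str]
    pair_2: Tuple[str, str]

    @classmethod
    def make(cls, pair_1: Iterable[str], pair_2: Iterable[str]) -> "Quartet":
        p1 = tuple(sorted(pair_1))
        p2 = tuple(sorted(pair_2))
        if len(p1) != 2 or len(p2) != 2:
            raise TreeError("quartet pairs must each contain two labels")
        if len({*p1, *p2}) != 4:
            raise TreeError("quartet requires four distinct labels")
        if p2 < p1:
            p1, p2 = p2, p1
        return cls(p1, p2)

    @property
    def labels(self) -> FrozenSet[str]:
        return frozenset(self.pair_1) | frozenset(self.pair_2)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return "{}{}|{}{}".format(*self.pair_1, *self.pair_2)


# ---------------------------------------------------------------------------
# the tree object
# ---------------------------------------------------------------------------

Edge = FrozenSet[int]


def _edge(u: int, v: int) -> Edge:
    return frozenset((u, v))


class LabeledTree:
    """Unrooted leaf-labeled tree with optional branch lengths and support.

    Nodes are opaque integers.  Internal (unlabeled) degree-2 nodes are
    suppressed on construction unless the tree is flagged rooted, in which
    case the root alone may have degree 2.  The empty tree (no nodes) is a
    valid value: it is the result of reducing an all-conflict multree.
    """

    def __init__(
        self,
        adj: Dict[int, Dict[int, Optional[float]]],
        leaf_label: Dict[int, str],
        support: Optional[Dict[Edge, float]] = None,
        rooted: bool = False,
        root: Optional[int] = None,
    ):
        self._adj: Dict[int, Dict[int, Optional[float]]] = {
            u: dict(nbrs) for u, nbrs in adj.items()
        }
        self._leaf_label = dict(leaf_label)
        self._support: Dict[Edge, float] = dict(support or {})
        self.rooted = rooted
        self._root = root
        self._normalize()
        self._validate()

    # -- construction helpers ------------------------------------------------

    @classmethod
    def empty(cls) -> "LabeledTree":
        return cls({}, {})

    @classmethod
    def star(cls, labels: Iterable[str]) -> "LabeledTree":
        labels = list(labels)
        if not labels:
            return cls.empty()
        if len(labels) == 1:
            return cls({0: {}}, {0: labels[0]})
        if len(labels) == 2:
            return cls({0: {1: None}, 1: {0: None}}, {0: labels[0], 1: labels[1]})
        center = 0
        adj: Dict[int, Dict[int, Optional[float]]] = {center: {}}
        leaf_label = {}
        for i, lab in enumerate(labels, start=1):
            adj[center][i] = None
            adj[i] = {center: None}
            leaf_label[i] = lab
        return cls(adj, leaf_label)

    def copy(self) -> "LabeledTree":
        return LabeledTree(self._adj, self._leaf_label, self._support, self.rooted, self._root)

    # -- invariants ----------------------------------------------------------

    def _normalize(self) -> None:
        # drop unlabeled isolated or pendant nodes, then suppress unlabeled
        # degree-2 nodes (keeping a rooted tree's root).
        changed = True
        while changed:
            changed = False
            for u in list(self._adj):
                if u in self._leaf_label:
                    continue
                deg = len(self._adj[u])
                if deg <= 1:
                    for v in list(self._adj[u]):
                        del self._adj[v][u]
                        self._support.pop(_edge(u, v), None)
                    del self._adj[u]
                    if self._root == u:
                        self._root = None
                    changed = True
                elif deg == 2 and not (self.rooted and u == self._root):
                    (a, la), (b, lb) = self._adj[u].items()
                    if la is None and lb is None:
                        length: Optional[float] = None
                    else:
                        if la is None or lb is None:
                            warnings.warn(
                                "suppressed path mixes present and missing branch "
                                "lengths; missing treated as 0",
                                MissingLengthWarning,
                                stacklevel=2,
                            )
                        length = (la or 0.0) + (lb or 0.0)
                    sup = self._support.pop(_edge(u, a), None)
                    sup_b = self._support.pop(_edge(u, b), None)
                    if sup is None:
                        sup = sup_b
                    del self._adj[a][u]
                    del self._adj[b][u]
                    del self._adj[u]
                    self._adj[a][b] = length
                    self._adj[b][a] = length
                    if sup is not None:
                        self._support[_edge(a, b)] = sup
                    changed = True
        self._support = {
            e: s
            for e, s in self._support.items()
            if all(u in self._adj for u in e) and len(e) == 2
        }

    def _validate(self) -> None:
        for u, lab in self._leaf_label.items():
            if u not in self._adj:
                raise TreeError(f"labeled node {u} absent from tree")
            if len(self._adj[u]) > 1:
                raise TreeError(f"labeled node {u} ({lab!r}) is not a leaf")
        for e, s in self._support.items():
            if not (0.0 <= s <= 100.0):
                raise TreeError(f"edge support {s} outside [0, 100]")
        # connectivity (trees must be connected)
        if self._adj:
            seen = set()
            stack = [next(iter(self._adj))]
            while stack:
                u = stack.pop()
                if u in seen:
                    continue
                seen.add(u)
                stack.extend(self._adj[u])
            if len(seen) != len(self._adj):
                raise TreeError("tree graph is not connected")
            n_edges = sum(len(v) for v in self._adj.values()) // 2
            if n_edges != len(self._adj) - 1:
                raise TreeError("tree graph contains a cycle")

    # -- basic accessors -----------------------------------------------------

    @property
    def is_empty(self) -> bool:
        return not self._adj

    def leaves(self) -> List[int]:
        return sorted(self._leaf_label)

    def leaf_labels(self) -> List[str]:
        """Label multiset, sorted."""
        return sorted(self._leaf_label.values())

    def label_set(self) -> FrozenSet[str]:
        return frozenset(self._leaf_label.values())

    @property
    def n_leaves(self) -> int:
        return len(self._leaf_label)

    @property
    def is_singly_labeled(self) -> bool:
        return len(set(self._leaf_label.values())) == len(self._leaf_label)

    @property
    def is_multree(self) -> bool:
        return not self.is_empty and not self.is_singly_labeled

    def edges(self) -> Iterator[Tuple[int, int]]:
        for u, nbrs in self._adj.items():
            for v in nbrs:
                if u < v:
                    yield u, v

    def edge_length(self, u: int, v: int) -> Optional[float]:
        return self._adj[u][v]

    def edge_support(self, u: int, v: int) -> Optional[float]:
        return self._support.get(_edge(u, v))

    @property
    def has_lengths(self) -> bool:
        return all(l is not None for u, v in self.edges() for l in (self._adj[u][v],))

    # -- topological information ----------------------------------------------

    def _oriented(self) -> Tuple[int, Dict[int, int], List[int]]:
        """Pick an anchor, return (anchor, parent map, postorder node list)."""
        anchor = next(iter(self._adj))
        parent: Dict[int, int] = {}
        order: List[int] = []
        stack = [anchor]
        seen = {anchor}
        while stack:
            u = stack.pop()
            order.append(u)
            for v in self._adj[u]:
                if v not in seen:
                    seen.add(v)
                    parent[v] = u
                    stack.append(v)
        order.reverse()  # postorder (children before parents)
        return anchor, parent, order

    def _edge_label_sides(self) -> Iterator[Tuple[Tuple[int, int], Set[str], Set[str]]]:
        """For every edge yield (edge, labels-with-a-leaf-on-side-1, side-2).

        On a multree a label may occur on both sides of an edge; the two
        sets are therefore not necessarily disjoint.
        """
        if self.is_empty or self.n_leaves < 2:
            return
        from collections import Counter

        total: Counter = Counter(self._leaf_label.values())
        anchor, parent, order = self._oriented()
        sub: Dict[int, Counter] = {}
        for u in order:
            c: Counter = Counter()
            if u in self._leaf_label:
                c[self._leaf_label[u]] += 1
            for v in self._adj[u]:
                if v != parent.get(u) and v in sub:
                    c.update(sub[v])
            sub[u] = c
        for v, u in parent.items():
            below = sub[v]
            side_below = {lab for lab, k in below.items() if k > 0}
            side_above = {lab for lab, k in total.items() if k > below.get(lab, 0)}
            yield (u, v), side_below, side_above

    def displayed_quartets(self) -> Set[Quartet]:
        """All quartets ``ab|cd`` separated by at least one edge.

        On a multree the same four labels may support two or three
        conflicting topologies, each contributed by a different edge.
        """
        out: Set[Quartet] = set()
        for _e, below, above in self._edge_label_sides():
            if len(below) < 2 or len(above) < 2:
                continue
            for a, b in combinations(sorted(below), 2):
                for c, d in combinations(sorted(above), 2):
                    if a in (c, d) or b in (c, d):
                        continue
                    out.add(Quartet.make((a, b), (c, d)))
        return out

    def bipartitions(self, include_trivial: bool = False) -> Set[Bipartition]:
        """Splits induced by the edges of a singly-labeled tree."""
        if self.is_multree:
            raise TreeError("bipartitions are ill-defined on a multree (duplicate labels)")
        out: Set[Bipartition] = set()
        for _e, below, above in self._edge_label_sides():
            bp = Bipartition.make(below, above)
            if include_trivial or bp.is_nontrivial:
                out.add(bp)
        return out

    def topology_equal(self, other: "LabeledTree") -> bool:
        """Equality of unrooted topologies (singly-labeled trees only)."""
        if self.is_empty or other.is_empty:
            return self.is_empty and other.is_empty
        if self.is_multree or other.is_multree:
            raise TreeError("topology comparison requires singly-labeled trees")
        return (
            self.label_set() == other.label_set()
            and self.bipartitions() == other.bipartitions()
        )

    # -- restriction -----------------------------------------------------------

    def restrict(self, keep: Iterable[str]) -> "LabeledTree":
        """Subtree induced by the labels in ``keep``.

        Leaves outside ``keep`` are deleted; resulting unlabeled degree-1
        nodes are pruned and degree-2 nodes suppressed with path lengths
        summed.  Edge supports are not carried over (the surviving edges
        generally correspond to merged paths).
        """
        keep = frozenset(keep)
        if not isinstance(keep, frozenset) or not all(isinstance(k, str) for k in keep):
            raise TreeError("keep must be a collection of label strings")
        inter = keep & self.label_set()
        if not inter:
            raise NoOverlapError(
                "no overlap: none of the requested labels occur in the tree"
            )
        adj = {u: dict(nbrs) for u, nbrs in self._adj.items()}
        labels = dict(self._leaf_label)
        for u in list(labels):
            if labels[u] not in keep:
                for v in adj[u]:
                    del adj[v][u]
                del adj[u]
                del labels[u]
        return LabeledTree(adj, labels)

    # -- midpoint rooting -------------------------------------------------------

    def midpoint_root(self) -> "LabeledTree":
        """Root at the midpoint of the longest leaf-to-leaf path.

        Requires branch lengths on every edge.  Ties among equally long
        paths are broken by the canonical (lexicographic) order of the
        endpoint label pair.
        """
        if self.is_empty or self.n_leaves < 2:
            raise TreeError("midpoint rooting needs at least two leaves")
        for u, v in self.edges():
            if self._adj[u][v] is None:
                raise TreeError("midpoint rooting requires branch lengths on every edge")
            if self._adj[u][v] < 0:
                raise TreeError("negative branch length")

        # all-pairs leaf distances via DFS from each leaf
        best: Optional[Tuple[float, Tuple[str, str], int, int]] = None
        leaves = self.leaves()
        for a in leaves:
            dist = {a: 0.0}
            prev = {a: None}
            stack = [a]
            while stack:
                u = stack.pop()
                for v, l in self._adj[u].items():
                    if v not in dist:
                        dist[v] = dist[u] + l
                        prev[v] = u
                        stack.append(v)
            for b in leaves:
                if b <= a:
                    continue
                key_labels = tuple(sorted((self._leaf_label[a], self._leaf_label[b])))
                cand = (dist[b], key_labels, a, b)
                if best is None or cand[0] > best[0] + 1e-12 or (
                    abs(cand[0] - best[0]) <= 1e-12 and (cand[1], cand[2], cand[3]) < (best[1], best[2], best[3])
                ):
                    best = cand
        assert best is not None
        total, _labs, a, b = best
        # endpoint from which we walk: the one bearing the smaller label
        if (self._leaf_label[b], b) < (self._leaf_label[a], a):
            a, b = b, a
        # path a -> b
        parent: Dict[int, Optional[int]] = {a: None}
        stack = [a]
        while stack:
            u = stack.pop()
            for v in self._adj[u]:
                if v not in parent:
                    parent[v] = u
                    stack.append(v)
        path = [b]
        while path[-1] != a:
            path.append(parent[path[-1]])  # type: ignore[arg-type]
        path.reverse()

        half = total / 2.0
        adj = {u: dict(nbrs) for u, nbrs in self._adj.items()}
        support = dict(self._support)
        acc = 0.0
        for u, v in zip(path, path[1:]):
            l = adj[u][v]
            if acc + l >= half - 1e-12:
                offset = half - acc
                if abs(offset) <= 1e-12 and u not in self._leaf_label:
                    root = u
                elif abs(l - offset) <= 1e-12 and v not in self._leaf_label:
                    root = v
                else:
                    root = max(adj) + 1
                    sup = support.pop(_edge(u, v), None)
                    del adj[u][v]
                    del adj[v][u]
                    adj[root] = {u: offset, v: l - offset}
                    adj[u][root] = offset
                    adj[v][root] = l - offset
                    if sup is not None:
                        support[_edge(root, v)] = sup
                return LabeledTree(adj, self._leaf_label, support, rooted=True, root=root)
            acc += l
        raise TreeError("midpoint not found on path")  # pragma: no cover

    # -- newick ------------------------------------------------------------------

    def to_newick(self, lengths: Optional[bool] = None, support_fmt: str = ".1f") -> str:
        """Serialize; ``lengths=None`` writes them when every edge has one."""
        if self.is_empty:
            raise TreeError("cannot serialize an empty tree")
        if lengths is None:
            lengths = self.has_lengths

        def fmt_label(lab: str) -> str:
            lab = lab.replace(" ", "_")
            if any(ch in lab for ch in "():;,[]'"):
                return "'{}'".format(lab.replace("'", "''"))
            return lab

        def min_leaf_label(u: int, par: Optional[int]) -> str:
            if u in self._leaf_label:
                return self._leaf_label[u]
            return min(
                min_leaf_label(v, u) for v in self._adj[u] if v != par
            )

        def render(u: int, par: int) -> str:
            parts: List[str] = []
            if u in self._leaf_label:
                body = fmt_label(self._leaf_label[u])
            else:
                children = sorted(
                    (v for v in self._adj[u] if v != par),
                    key=lambda v: min_leaf_label(v, u),
                )
                body = "(" + ",".join(render(v, u) for v in children) + ")"
                sup = self._support.get(_edge(u, par))
                if sup is not None:
                    body += format(sup, support_fmt)
            if lengths and self._adj[u][par] is not None:
                body += ":" + format(self._adj[u][par], ".10g")
            elif lengths:
                body += ":0"
            parts.append(body)
            return "".join(parts)

        if len(self._adj) == 1:
            (u,) = self._adj
            return fmt_label(self._leaf_label[u]) + ";"
        if self.n_leaves == 2 and len(self._adj) == 2:
            (u, v) = sorted(self._leaf_label, key=lambda x: self._leaf_label[x])
            l = self._adj[u][v]
            if lengths and l is not None:
                return "({}:{},{}:{});".format(
                    fmt_label(self._leaf_label[u]),
                    format(l / 2.0, ".10g"),
                    fmt_label(self._leaf_label[v]),
                    format(l / 2.0, ".10g"),
                )
            return "({},{});".format(
                fmt_label(self._leaf_label[u]), fmt_label(self._leaf_label[v])
            )

        if self.rooted and self._root is not None:
            root = self._root
        else:
            # deterministic display root: internal node adjacent to the
            # lexicographically smallest leaf
            leaf = min(self._leaf_label, key=lambda u: (self._leaf_label[u], u))
            root = next(iter(self._adj[leaf]))
        children = sorted(self._adj[root], key=lambda v: min_leaf_label(v, root))
        return "(" + ",".join(render(v, root) for v in children) + ");"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        if self.is_empty:
            return "LabeledTree<empty>"
        return f"LabeledTree<{self.n_leaves} leaves: {self.to_newick(lengths=False)}>"


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


def _scan_balance(text: str) -> None:
    """Cheap pre-scan producing positional errors for unbalanced input."""
    depth = 0
    in_quote = False
    for i, ch in enumerate(text):
        if ch == "'":
            in_quote = not in_quote
            continue
        if in_quote:
            continue
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError(
                    f"unbalanced ')' at position {i} in newick string"
                )
    if in_quote:
        raise NewickParseError("unterminated quoted label in newick string")
    if depth > 0:
        raise NewickParseError(
            f"unbalanced '(': {depth} unclosed at position {len(text)}"
        )


def parse_newick(text: str) -> LabeledTree:
    """Parse one newick tree; duplicate leaf labels (multrees) are allowed.

    Numeric internal-node labels within [0, 100] are read as edge support
    for the edge above that node; underscores in unquoted labels are read
    as spaces (standard newick convention).
    """
    if text is None or not text.strip():
        raise NewickParseError("empty newick string")
    _scan_balance(text)
    try:
        clade_root = Phylo.read(StringIO(text), "newick").root
    except Exception as exc:  # Biopython raises NewickError subclasses
        raise NewickParseError(f"malformed newick (position unknown): {exc}") from exc

    adj: Dict[int, Dict[int, Optional[float]]] = {}
    leaf_label: Dict[int, str] = {}
    support: Dict[Edge, float] = {}
    counter = [0]

    def new_node() -> int:
        counter[0] += 1
        return counter[0]

    def walk(clade, parent: Optional[int]) -> int:
        u = new_node()
        adj[u] = {}
        if parent is not None:
            length = clade.branch_length
            adj[u][parent] = length
            adj[parent][u] = length
        if clade.is_terminal():
            if clade.name is None:
                if clade.confidence is not None:
                    # a bare numeric leaf label parsed as confidence
                    leaf_label[u] = format(clade.confidence, "g")
                else:
                    raise NewickParseError("unlabeled leaf in newick string")
            else:
                leaf_label[u] = str(clade.name).replace("_", " ")
        else:
            conf = clade.confidence
            if conf is not None and parent is not None and 0.0 <= conf <= 100.0:
                support[_edge(u, parent)] = float(conf)
            for child in clade.clades:
                walk(child, u)
        return u

    walk(clade_root, None)
    return LabeledTree(adj, leaf_label, support)


def write_newick(tree: LabeledTree, **kwargs) -> str:
    return tree.to_newick(**kwargs)


# ---------------------------------------------------------------------------
# building a tree from compatible splits
# ---------------------------------------------------------------------------


def tree_from_splits(
    labels: Iterable[str],
    splits: Iterable[Bipartition],
    support: Optional[Dict[Bipartition, float]] = None,
) -> LabeledTree:
    """The unique minimal tree on ``labels`` displaying exactly ``splits``.

    ``splits`` must be nontrivial, pairwise compatible bipartitions of the
    full label set; otherwise :class:`IncompatibleSplitsError` is raised.
    Supports, when given, are attached to the corresponding internal edges.
    """
    label_list = sorted(set(labels))
    full = frozenset(label_list)
    splits = list(dict.fromkeys(splits))
    for bp in splits:
        if bp.labels != full:
            raise TreeError(
                f"split {bp!r} is not on the full label set of the tree"
            )
        if not bp.is_nontrivial:
            raise TreeError(f"trivial split {bp!r} cannot be an internal edge")
    if not label_list:
        return LabeledTree.empty()

    anchor = label_list[0]
    clades: List[FrozenSet[str]] = []
    sup_by_clade: Dict[FrozenSet[str], float] = {}
    for bp in splits:
        side = bp.side_b if anchor in bp.side_a else bp.side_a
        clades.append(side)
        if support and bp in support:
            sup_by_clade[side] = support[bp]
    # laminarity check == pairwise compatibility
    for c, d in combinations(clades, 2):
        if c & d and not (c <= d or d <= c):
            raise IncompatibleSplitsError(
                f"splits are incompatible: {sorted(c)} crosses {sorted(d)}"
            )

    adj: Dict[int, Dict[int, Optional[float]]] = {}
    leaf_label: Dict[int, str] = {}
    supports: Dict[Edge, float] = {}
    counter = [0]

    def new_node() -> int:
        counter[0] += 1
        n = counter[0]
        adj[n] = {}
        return n

    def connect(u: int, v: int) -> None:
        adj[u][v] = None
        adj[v][u] = None

    def build(members: FrozenSet[str], inside: List[FrozenSet[str]]) -> int:
        if len(members) == 1:
            u = new_node()
            leaf_label[u] = next(iter(members))
            return u
        node = new_node()
        maximal = [c for c in inside if not any(c < d for d in inside)]
        covered: Set[str] = set()
        for c in maximal:
            child = build(c, [d for d in inside if d < c])
            connect(node, child)
            if c in sup_by_clade:
                supports[_edge(node, child)] = sup_by_clade[c]
            covered |= c
        for lab in sorted(members - covered):
            u = new_node()
            leaf_label[u] = lab
            connect(node, u)
        return node

    build(full, sorted(set(clades), key=lambda c: (-len(c), sorted(c))))
    return LabeledTree(adj, leaf_label, supports)
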