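"""Synthetic generators for every input the toolkit consumes.

Trees, duplication multrees, perturbed confidence sets, planted
availability matrices and toy taxonomies -- all pure functions of their
parameters and a seed, so any fixture can be regenerated byte-identically
and no external data is ever required.

The perturbed confidence set stands in for bootstrap analysis: what the
consensus and query machinery needs is "B trees with controllable
agreement", which nearest-neighbor-interchange (NNI) perturbation
delivers with a single interpretable knob (the number of moves per
replicate; 0 moves = perfect agreement, support decays as moves grow).
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .consensus import ConfidenceSet
from .decisive import AvailabilityMatrix
from .query import Repository, Taxonomy, DatasetRecord
from .trees import LabeledTree, TreeError

__all__ = [
    "random_binary_tree",
    "make_multree",
    "perturbed_confidence_set",
    "planted_availability",
    "toy_taxonomy",
    "simulate_repository",
]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def random_binary_tree(
    labels: Sequence[str],
    seed,
    branch_rate: Optional[float] = None,
) -> LabeledTree:
    """Uniform unrooted binary topology via sequential random leaf attachment.

    Each leaf after the third is attached to an edge chosen uniformly at
    random, which yields the uniform distribution over the (2n-5)!!
    topologies.  With ``branch_rate`` set, every edge receives an
    independent Exponential(rate) length (mean 1/rate).
    """
    labels = list(labels)
    if len(labels) < 3:
        raise ValueError("random binary tree needs at least 3 labels")
    rng = _rng(seed)
    adj: Dict[int, Dict[int, Optional[float]]] = {
        0: {3: None},
        1: {3: None},
        2: {3: None},
        3: {0: None, 1: None, 2: None},
    }
    leaf_label = {0: labels[0], 1: labels[1], 2: labels[2]}
    nid = 4
    for lab in labels[3:]:
        edges = sorted((u, v) for u in adj for v in adj[u] if u < v)
        u, v = edges[rng.integers(len(edges))]
        hub, leaf = nid, nid + 1
        nid += 2
        del adj[u][v]
        del adj[v][u]
        adj[hub] = {u: None, v: None, leaf: None}
        adj[u][hub] = None
        adj[v][hub] = None
        adj[leaf] = {hub: None}
        leaf_label[leaf] = lab
    if branch_rate is not None:
        edges = sorted((u, v) for u in adj for v in adj[u] if u < v)
        lengths = rng.exponential(1.0 / branch_rate, size=len(edges))
        for (u, v), l in zip(edges, lengths):
            adj[u][v] = float(l)
            adj[v][u] = float(l)
    return LabeledTree(adj, leaf_label)


def make_multree(
    species_tree: LabeledTree,
    dup_labels: Iterable[str],
    mode: str,
    seed,
) -> LabeledTree:
    """Duplicate the given labels onto the species tree.

    ``concordant`` attaches each duplicate next to its original (the two
    copies form a cherry), so the reduction must recover the species tree
    with every taxon intact.  ``discordant`` regrafts each duplicate onto
    the pendant edge of the topologically farthest leaf, engineering
    quartet conflict.
    """
    dup_labels = sorted(set(dup_labels))
    missing = set(dup_labels) - set(species_tree.label_set())
    if missing:
        raise ValueError(f"dup_labels not in tree: {sorted(missing)}")
    if mode not in ("concordant", "discordant"):
        raise ValueError(f"unknown multree mode {mode!r}")
    rng = _rng(seed)
    adj = {u: dict(nbrs) for u, nbrs in species_tree._adj.items()}
    leaf_label = dict(species_tree._leaf_label)

    def next_id() -> int:
        return (max(adj) if adj else 0) + 1

    def topo_dist(a: int) -> Dict[int, int]:
        dist = {a: 0}
        stack = [a]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    stack.append(v)
        return dist

    for lab in dup_labels:
        originals = sorted(u for u, l in leaf_label.items() if l == lab)
        orig = originals[int(rng.integers(len(originals)))]
        if mode == "concordant":
            # replace the leaf by a cherry of two copies
            hub, copy = next_id(), next_id() + 1
            (par,) = adj[orig]
            length = adj[orig][par]
            del adj[par][orig]
            adj[orig] = {hub: None}
            adj[hub] = {par: length, orig: None, copy: None}
            adj[par][hub] = length
            adj[copy] = {hub: None}
            leaf_label[copy] = lab
        else:
            dist = topo_dist(orig)
            far = max(
                (u for u in leaf_label if u != orig),
                key=lambda u: (dist[u], leaf_label[u], u),
            )
            (par,) = adj[far]
            length = adj[far][par]
            hub, copy = next_id(), next_id() + 1
            del adj[far][par]
            del adj[par][far]
            adj[hub] = {par: length, far: None, copy: None}
            adj[par][hub] = length
            adj[far][hub] = None
            adj[copy] = {hub: None}
            leaf_label[copy] = lab
    return LabeledTree(adj, leaf_label)


def _random_nni(tree_adj: Dict[int, Dict[int, Optional[float]]], rng) -> None:
    """One random nearest-neighbor interchange, in place."""
    internal_edges = sorted(
        (u, v)
        for u in tree_adj
        for v in tree_adj[u]
        if u < v and len(tree_adj[u]) >= 3 and len(tree_adj[v]) >= 3
    )
    if not internal_edges:
        return
    u, v = internal_edges[rng.integers(len(internal_edges))]
    u_nbrs = sorted(x for x in tree_adj[u] if x != v)
    v_nbrs = sorted(x for x in tree_adj[v] if x != u)
    a = u_nbrs[rng.integers(len(u_nbrs))]
    b = v_nbrs[rng.integers(len(v_nbrs))]
    # swap subtrees a and b across edge (u, v)
    la, lb = tree_adj[u][a], tree_adj[v][b]
    del tree_adj[u][a]
    del tree_adj[a][u]
    del tree_adj[v][b]
    del tree_adj[b][v]
    tree_adj[u][b] = lb
    tree_adj[b][u] = lb
    tree_adj[v][a] = la
    tree_adj[a][v] = la


def perturbed_confidence_set(
    tree: LabeledTree,
    B: int,
    nni_moves: int,
    seed,
    dataset_id: str = "synthetic",
) -> ConfidenceSet:
    """B replicates of ``tree``, each after ``nni_moves`` random NNI moves.

    ``nni_moves = 0`` gives B identical copies (every consensus support
    100); increasing it degrades agreement, and hence expected support,
    monotonically on average.
    """
    if B < 1:
        raise ValueError("confidence set size B must be at least 1")
    if tree.is_multree:
        raise TreeError("confidence sets are built from singly-labeled trees")
    rng = _rng(seed)
    trees = []
    for _ in range(B):
        adj = {u: dict(nbrs) for u, nbrs in tree._adj.items()}
        for _m in range(nni_moves):
            _random_nni(adj, rng)
        trees.append(LabeledTree(adj, tree._leaf_label))
    return ConfidenceSet(dataset_id=dataset_id, trees=trees)


def planted_availability(
    n_taxa: int,
    n_loci: int,
    planted: Sequence[Tuple[Iterable[str], Iterable[str]]] = (),
    background_density: float = 0.0,
    seed=0,
) -> AvailabilityMatrix:
    """Coverage matrix with fully filled planted blocks over random noise.

    Taxa are named ``t01..``, loci ``L1..``.  Planted (taxon set, locus
    set) blocks are set present; remaining cells are present
    independently with ``background_density``.
    """
    if n_taxa < 1 or n_loci < 1:
        raise ValueError("matrix dimensions must be positive")
    if not (0.0 <= background_density <= 1.0):
        raise ValueError("background_density must lie in [0, 1]")
    width = len(str(n_taxa))
    taxa = [f"t{i:0{width}d}" for i in range(1, n_taxa + 1)]
    loci = [f"L{j}" for j in range(1, n_loci + 1)]
    rng = _rng(seed)
    grid = rng.random((n_taxa, n_loci)) < background_density
    t_index = {t: i for i, t in enumerate(taxa)}
    l_index = {l: j for j, l in enumerate(loci)}
    for block_taxa, block_loci in planted:
        block_taxa, block_loci = list(block_taxa), list(block_loci)
        unknown = [x for x in block_taxa if x not in t_index] + [
            x for x in block_loci if x not in l_index
        ]
        if unknown:
            raise ValueError(f"planted block names unknown: {unknown}")
        for t in block_taxa:
            for l in block_loci:
                grid[t_index[t], l_index[l]] = True
    return AvailabilityMatrix.from_arrays(taxa, loci, grid)


def toy_taxonomy(
    n_genera: int,
    species_per_genus: int,
    seed=0,
    synonyms: bool = False,
) -> Taxonomy:
    """Three-level hierarchy: root -> genera -> species.

    Genus i is named ``G<i>`` and its species ``G<i> s<j>`` (binomials
    with a space, written to newick with an underscore).  With
    ``synonyms``, each genus's first species gains an extra name mapping
    to the same id.
    """
    if n_genera < 1 or species_per_genus < 1:
        raise ValueError("taxonomy counts must be positive")
    records: List[Tuple[int, int, str, str]] = [(1, 1, "root", "no rank")]
    next_id = 2
    for g in range(1, n_genera + 1):
        genus_id = next_id
        next_id += 1
        records.append((genus_id, 1, f"G{g}", "genus"))
        for s in range(1, species_per_genus + 1):
            records.append((next_id, genus_id, f"G{g} s{s}", "species"))
            if synonyms and s == 1:
                records.append((next_id, genus_id, f"G{g} syn{s}", "species"))
            next_id += 1
    return Taxonomy(records)


def simulate_repository(
    n_datasets: int = 50,
    taxa_per_dataset: int = 8,
    B: int = 100,
    nni_moves: int = 2,
    seed: int = 0,
    n_genera: int = 10,
    species_per_genus: int = 8,
    multree_fraction: float = 0.3,
) -> Repository:
    """A complete synthetic repository consumable by the query engine.

    Each data set draws a random taxon subset from a toy taxonomy, a
    random species tree on those taxa, and a confidence set of B
    NNI-perturbed replicates.  A fraction of single-locus data sets store
    a concordant-duplication multree source; multi-locus kinds are tagged
    with synthetic locus lists.  All content is a pure function of the
    seed.
    """
    rng = _rng(seed)
    taxonomy = toy_taxonomy(n_genera, species_per_genus, seed=seed)
    species_ids = sorted(
        t for t in taxonomy.parent if not taxonomy.children(t) and t != taxonomy.root
    )
    records = []
    for i in range(1, n_datasets + 1):
        k = min(taxa_per_dataset, len(species_ids))
        chosen = sorted(rng.choice(species_ids, size=k, replace=False).tolist())
        labels = [taxonomy.name[t] for t in chosen]
        tree = random_binary_tree(labels, rng)
        kind_draw = rng.random()
        dataset_id = f"ds{i:04d}"
        source = None
        if kind_draw < 0.5:
            kind = "single_locus"
            loci = [f"c{i}"]
            reference = None
            source = tree
            if rng.random() < multree_fraction:
                dup = [labels[int(rng.integers(len(labels)))]]
                source = make_multree(tree, dup, "concordant", rng)
        elif kind_draw < 0.8:
            kind = "biclique"
            loci = [f"c{i}a", f"c{i}b"]
            reference = None
        else:
            kind = "dqbc"
            loci = [f"c{i}a", f"c{i}b", f"c{i}c"]
            reference = loci[0]
        cs = perturbed_confidence_set(tree, B, nni_moves, rng, dataset_id=dataset_id)
        records.append(
            DatasetRecord(
                dataset_id=dataset_id,
                kind=kind,
                taxa=labels,
                taxon_ids=chosen,
                loci=loci,
                reference_locus=reference,
                _trees=cs.trees,
                _source=source,
            )
        )
    return Repository(taxonomy, records)
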