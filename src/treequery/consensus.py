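"""Majority-rule consensus over confidence sets, with support and quality.

A *confidence set* is a collection of B trees on one label set -- here
typically bootstrap replicates of a data set.  Queries prune every member
to the taxa of interest and summarize the pruned set as a majority-rule
consensus tree (MRT): the tree containing exactly the nontrivial
bipartitions occurring in strictly more than B/2 members, annotated with
their occurrence frequencies as percent support.  Strict majority makes
the retained splits automatically pairwise compatible; splits at exactly
50% are excluded.

The tree quality statistic q is the mean support of the retained edges
multiplied by the fraction of resolved internal edges (out of the n-3
possible on n taxa); it ranges 0-100 and is 0 for a star.

Two counting engines are provided: a naive dictionary over canonical
bipartitions, and a randomized 128-bit hash representation of splits (a
constant-size object per split) with canonical-form verification guarding
against collisions.  They must agree -- the hash engine is the default
and the naive engine is kept as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .trees import (
    Bipartition,
    LabeledTree,
    NoOverlapError,
    TreeError,
    tree_from_splits,
)

__all__ = [
    "ConfidenceSet",
    "majority_rule_consensus",
    "resolved_fraction",
    "quality_score",
    "prune_set",
]

# seed of the split-hashing generator; fixed so hash codes are stable
# within and across runs (collisions are verified against canonical forms)
_HASH_SEED = 0x5EEDB1A5


@dataclass
class ConfidenceSet:
    """B singly-labeled trees on one common label set."""

    dataset_id: str
    trees: List[LabeledTree]

    def __post_init__(self):
        if len(self.trees) < 1:
            raise ValueError("a confidence set needs at least one tree")
        labels = self.trees[0].label_set()
        for i, t in enumerate(self.trees):
            if t.is_multree:
                raise TreeError(f"tree {i} of {self.dataset_id} is a multree")
            if t.label_set() != labels:
                raise TreeError(
                    f"tree {i} of {self.dataset_id} has a different label set"
                )

    @property
    def size(self) -> int:
        return len(self.trees)

    @property
    def labels(self) -> FrozenSet[str]:
        return self.trees[0].label_set()

    @classmethod
    def read_newick(cls, path, dataset_id: Optional[str] = None, limit: Optional[int] = None) -> "ConfidenceSet":
        """One tree per line; ``limit`` keeps only the first trees."""
        from .trees import parse_newick

        trees = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                trees.append(parse_newick(line))
                if limit is not None and len(trees) >= limit:
                    break
        return cls(dataset_id=dataset_id or str(path), trees=trees)

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            for t in self.trees:
                fh.write(t.to_newick() + "\n")


def _count_naive(trees: Sequence[LabeledTree]) -> Dict[Bipartition, int]:
    counts: Dict[Bipartition, int] = {}
    for t in trees:
        for bp in t.bipartitions():
            counts[bp] = counts.get(bp, 0) + 1
    return counts


def _count_hashed(trees: Sequence[LabeledTree], labels: FrozenSet[str]) -> Dict[Bipartition, int]:
    """Count splits through 128-bit hash codes, verifying canonical forms.

    Each label receives a random 128-bit code; a split's code is the XOR
    of the codes on its canonical side (the side holding the smallest
    label).  A hash collision between distinct splits is detected by
    comparing stored canonical forms and reported as an error; with
    128-bit codes this is a theoretical concern only.
    """
    rng = np.random.default_rng(_HASH_SEED)
    code: Dict[str, int] = {}
    for lab in sorted(labels):
        hi, lo = rng.integers(0, 2 ** 64, size=2, dtype=np.uint64)
        code[lab] = (int(hi) << 64) | int(lo)

    counts_by_hash: Dict[int, int] = {}
    canonical_by_hash: Dict[int, Bipartition] = {}
    for t in trees:
        for bp in t.bipartitions():
            h = 0
            for lab in bp.side_a:  # side_a holds the smallest label
                h ^= code[lab]
            if h in canonical_by_hash:
                if canonical_by_hash[h] != bp:
                    raise RuntimeError(
                        "128-bit split-hash collision detected; rerun with "
                        "the naive counting engine"
                    )
            else:
                canonical_by_hash[h] = bp
            counts_by_hash[h] = counts_by_hash.get(h, 0) + 1
    return {canonical_by_hash[h]: c for h, c in counts_by_hash.items()}


def majority_rule_consensus(
    cs: ConfidenceSet, engine: str = "hash"
) -> LabeledTree:
    """MRT of the confidence set: splits in a strict majority of members,
    each annotated with support = 100 x occurrence frequency."""
    if engine == "hash":
        counts = _count_hashed(cs.trees, cs.labels)
    elif engine == "naive":
        counts = _count_naive(cs.trees)
    else:
        raise ValueError(f"unknown counting engine {engine!r}")
    b = cs.size
    majority = {bp: c for bp, c in counts.items() if 2 * c > b}
    support = {bp: 100.0 * c / b for bp, c in majority.items()}
    return tree_from_splits(cs.labels, list(majority), support)


def resolved_fraction(mrt: LabeledTree) -> float:
    """Fraction of the n-3 possible internal edges present in the tree."""
    if mrt.is_multree:
        raise TreeError("resolved fraction requires a singly-labeled tree")
    n = len(mrt.label_set())
    if n < 4:
        raise TreeError("resolved fraction undefined below four taxa")
    return len(mrt.bipartitions()) / (n - 3)


def quality_score(mrt: LabeledTree) -> float:
    """q = (mean support of retained edges) x (resolved fraction), 0-100.

    The mean runs over the edges retained in the MRT, which by strict
    majority all exceed 50% support; a star scores 0.
    """
    supports = [
        mrt.edge_support(u, v)
        for u, v in mrt.edges()
        if mrt.edge_support(u, v) is not None
    ]
    if not supports:
        return 0.0
    return float(np.mean(supports)) * resolved_fraction(mrt)


def prune_set(cs: ConfidenceSet, keep: Iterable[str]) -> ConfidenceSet:
    """Restrict every member tree to ``keep``; member count is preserved."""
    keep = frozenset(keep)
    overlap = keep & cs.labels
    if not overlap:
        raise NoOverlapError(
            f"no overlap between confidence set {cs.dataset_id} and the keep set"
        )
    if len(overlap) < 4:
        import warnings

        warnings.warn(
            f"pruning {cs.dataset_id} to {len(overlap)} taxa: below the "
            "four-taxon informativeness floor",
            UserWarning,
            stacklevel=2,
        )
    return ConfidenceSet(
        dataset_id=cs.dataset_id,
        trees=[t.restrict(overlap) for t in cs.trees],
    )
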