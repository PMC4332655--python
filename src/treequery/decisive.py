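"""Assembly of decisive multi-locus data sets from taxon x locus coverage.

A supermatrix is *decisive* for a tree when the per-locus restrictions of
that tree pin it down uniquely; some coverage patterns are decisive for
every tree.  Two constructions with that guarantee are provided:

* **maximal bicliques** -- taxon/locus blocks with no missing cell, to
  which no taxon or locus can be added without creating one;
* **decisive quasi-bicliques (dqbc)** -- built around a *reference locus*
  sampled for every included taxon, admitting partially sampled loci that
  cover at least a third of the reference taxa.  The reference column
  makes the pattern decisive for all trees despite the gaps.

Size rules: every data set needs at least four taxa (the smallest count
with an informative unrooted tree); a dqbc with any missing cell needs at
least five taxa, since a complete four-taxon pattern is a biclique
proper.  Brute-force decisiveness checkers (exhaustive enumeration of
binary topologies) back all of this up at small taxon counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .trees import Bipartition, LabeledTree, TreeError
from .multree import enumerate_topology_split_sets

__all__ = [
    "AvailabilityMatrix",
    "SuperDataset",
    "maximal_bicliques",
    "build_dqbc",
    "is_decisive_for_tree",
    "is_decisive_for_all_trees",
    "deduplicate",
    "sample_datasets",
]

MIN_TAXA = 4  # informativeness floor: smallest unrooted tree with an internal edge
DQBC_MIN_FRAC = 1.0 / 3.0  # coverage threshold for non-reference loci


class AvailabilityMatrix:
    """Boolean taxon x locus presence pattern.

    Thin wrapper over a pandas DataFrame (rows = taxa, columns = loci,
    values = bool) enforcing unique row and column names.
    """

    def __init__(self, present: pd.DataFrame):
        if present.index.has_duplicates:
            raise ValueError("duplicate taxon labels in availability matrix")
        if present.columns.has_duplicates:
            raise ValueError("duplicate locus ids in availability matrix")
        self.present = present.astype(bool)

    @classmethod
    def from_arrays(
        cls,
        taxa: Sequence[str],
        loci: Sequence[str],
        grid: np.ndarray,
    ) -> "AvailabilityMatrix":
        return cls(pd.DataFrame(np.asarray(grid, dtype=bool), index=list(taxa), columns=list(loci)))

    @property
    def taxa(self) -> List[str]:
        return list(self.present.index)

    @property
    def loci(self) -> List[str]:
        return list(self.present.columns)

    def taxa_with_locus(self, locus: str) -> FrozenSet[str]:
        if locus not in self.present.columns:
            raise KeyError(f"unknown locus id: {locus!r}")
        col = self.present[locus]
        return frozenset(col.index[col])

    def loci_of_taxon(self, taxon: str) -> FrozenSet[str]:
        row = self.present.loc[taxon]
        return frozenset(row.index[row])

    def submatrix(self, taxa: Iterable[str], loci: Iterable[str]) -> "AvailabilityMatrix":
        return AvailabilityMatrix(self.present.loc[sorted(taxa), sorted(loci)])

    # -- TSV interchange (header row = locus ids, first column = taxa) ------

    @classmethod
    def read_tsv(cls, path) -> "AvailabilityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.astype(int).astype(bool))

    def write_tsv(self, path) -> None:
        self.present.astype(int).to_csv(path, sep="\t")

    def __repr__(self) -> str:  # pragma: no cover
        return f"AvailabilityMatrix<{len(self.taxa)} taxa x {len(self.loci)} loci>"


@dataclass(frozen=True)
class SuperDataset:
    """A (taxa, loci, kind) triple describing one assembled data set."""

    taxa: FrozenSet[str]
    loci: FrozenSet[str]
    kind: str  # single_locus | biclique | dqbc
    reference_locus: Optional[str] = None

    def __post_init__(self):
        if self.kind not in ("single_locus", "biclique", "dqbc"):
            raise ValueError(f"unknown data set kind: {self.kind!r}")
        if len(self.taxa) < MIN_TAXA:
            raise ValueError(f"data sets require at least {MIN_TAXA} taxa")
        if self.kind == "biclique" and len(self.loci) < 2:
            raise ValueError("a biclique data set requires at least 2 loci")
        if self.kind == "dqbc":
            if self.reference_locus is None:
                raise ValueError("a dqbc requires a reference locus")
            if self.reference_locus not in self.loci:
                raise ValueError("reference locus must be among the data set's loci")
        if self.kind != "dqbc" and self.reference_locus is not None:
            raise ValueError("only dqbc data sets carry a reference locus")

    @property
    def size(self) -> int:
        return len(self.taxa) * len(self.loci)

    def key(self) -> Tuple[FrozenSet[str], FrozenSet[str]]:
        return (self.taxa, self.loci)


# ---------------------------------------------------------------------------
# maximal biclique enumeration
# ---------------------------------------------------------------------------


def _sort_datasets(datasets: List[SuperDataset]) -> List[SuperDataset]:
    return sorted(
        datasets,
        key=lambda d: (-d.size, sorted(d.taxa), sorted(d.loci)),
    )


def maximal_bicliques(
    M: AvailabilityMatrix,
    min_taxa: int = MIN_TAXA,
    min_loci: int = 2,
    max_enumeration: int = 2 ** 22,
) -> List[SuperDataset]:
    """All maximal complete taxon/locus blocks meeting the size floors.

    A block is maximal when no taxon and no locus can be added without
    introducing a missing cell; equivalently it is a *closed* pair: its
    taxa are exactly the taxa covering all its loci and vice versa.
    Enumeration walks every subset of the smaller dimension and closes it,
    so it is exact but exponential in ``min(n_taxa, n_loci)``.
    """
    if min_taxa < MIN_TAXA:
        raise ValueError(f"min_taxa below the repository floor of {MIN_TAXA}")
    taxa, loci = M.taxa, M.loci
    transpose = len(taxa) < len(loci)
    if 2 ** min(len(taxa), len(loci)) > max_enumeration:
        raise ValueError(
            "matrix too large for exact maximal-biclique enumeration "
            f"(2^{min(len(taxa), len(loci))} subsets)"
        )

    # bitmask per item of the enumerated dimension over the other dimension
    if transpose:
        enum_items, other_items = taxa, loci
        cover = {
            t: frozenset(M.loci_of_taxon(t)) for t in taxa
        }
        other_cover = {l: M.taxa_with_locus(l) for l in loci}
    else:
        enum_items, other_items = loci, taxa
        cover = {l: M.taxa_with_locus(l) for l in loci}
        other_cover = {t: frozenset(M.loci_of_taxon(t)) for t in taxa}

    seen: Set[Tuple[FrozenSet[str], FrozenSet[str]]] = set()
    out: List[SuperDataset] = []
    all_other = frozenset(other_items)
    for k in range(1, len(enum_items) + 1):
        for subset in combinations(enum_items, k):
            common = all_other
            for item in subset:
                common = common & cover[item]
                if not common:
                    break
            if not common:
                continue
            # closure: every enumerated item covering all of `common`
            closed = frozenset(
                item for item in enum_items if common <= cover[item]
            )
            if transpose:
                block_taxa, block_loci = closed, common
            else:
                block_taxa, block_loci = common, closed
            if len(block_taxa) < min_taxa or len(block_loci) < min_loci:
                continue
            key = (block_taxa, block_loci)
            if key not in seen:
                seen.add(key)
                out.append(
                    SuperDataset(taxa=block_taxa, loci=block_loci, kind="biclique")
                )
    return _sort_datasets(out)


# ---------------------------------------------------------------------------
# decisive quasi-bicliques
# ---------------------------------------------------------------------------


def build_dqbc(
    M: AvailabilityMatrix,
    reference: str,
    min_frac: float = DQBC_MIN_FRAC,
) -> Optional[SuperDataset]:
    """Reference-locus data set: all taxa with the reference, plus every
    locus covering at least ``min_frac`` of those taxa (inclusive).

    Returns None when the result would fall below the size floors: fewer
    than four taxa, or -- when any cell is missing -- fewer than five
    taxa.  A gap-free result is reclassified as a biclique.
    """
    ref_taxa = M.taxa_with_locus(reference)
    if len(ref_taxa) < MIN_TAXA:
        return None
    loci = {reference}
    complete = True
    for locus in M.loci:
        if locus == reference:
            continue
        covered = M.taxa_with_locus(locus) & ref_taxa
        frac = len(covered) / len(ref_taxa)
        if frac + 1e-12 >= min_frac:
            loci.add(locus)
            if len(covered) < len(ref_taxa):
                complete = False
    if len(loci) < 2:
        return None
    if complete:
        return SuperDataset(taxa=ref_taxa, loci=frozenset(loci), kind="biclique")
    if len(ref_taxa) < MIN_TAXA + 1:
        return None  # incomplete pattern needs >= 5 taxa
    return SuperDataset(
        taxa=ref_taxa,
        loci=frozenset(loci),
        kind="dqbc",
        reference_locus=reference,
    )


# ---------------------------------------------------------------------------
# decisiveness checkers (brute force)
# ---------------------------------------------------------------------------


def _locus_taxon_sets(M: AvailabilityMatrix) -> List[FrozenSet[str]]:
    return [M.taxa_with_locus(l) for l in M.loci]


def _fingerprint(
    splits: FrozenSet[Bipartition], locus_taxa: List[FrozenSet[str]]
) -> Tuple[FrozenSet[Bipartition], ...]:
    """Per-locus restricted split sets: the evidence each locus carries."""
    fps = []
    for taxa in locus_taxa:
        restricted = frozenset(
            bp for bp in (s.restricted(taxa) for s in splits) if bp is not None
        )
        fps.append(restricted)
    return tuple(fps)


def is_decisive_for_tree(M: AvailabilityMatrix, tree: LabeledTree) -> bool:
    """True iff ``tree`` is the unique binary tree matching its own
    per-locus restrictions under the coverage pattern ``M``.

    Exhaustive over all (2n-5)!! binary topologies; refuses n > 9.
    """
    labels = frozenset(M.taxa)
    if tree.label_set() != labels:
        raise ValueError("tree labels must equal the matrix's taxa")
    if len(labels) > 9:
        raise ValueError("brute-force decisiveness check refuses more than 9 taxa")
    locus_taxa = _locus_taxon_sets(M)
    target = _fingerprint(frozenset(tree.bipartitions()), locus_taxa)
    n_matching = 0
    for splits in enumerate_topology_split_sets(labels):
        if len(splits) != len(labels) - 3:
            continue  # binary topologies only
        if _fingerprint(splits, locus_taxa) == target:
            n_matching += 1
            if n_matching > 1:
                return False
    return n_matching == 1


def is_decisive_for_all_trees(M: AvailabilityMatrix) -> bool:
    """True iff the pattern is decisive for every binary tree on its taxa.

    Equivalent to: all binary topologies have pairwise distinct per-locus
    restriction fingerprints.  Refuses n > 8.
    """
    labels = frozenset(M.taxa)
    if len(labels) > 8:
        raise ValueError(
            "brute-force all-trees decisiveness check refuses more than 8 taxa"
        )
    if len(labels) < MIN_TAXA:
        raise ValueError("decisiveness needs at least 4 taxa")
    locus_taxa = _locus_taxon_sets(M)
    seen: Set[Tuple[FrozenSet[Bipartition], ...]] = set()
    for splits in enumerate_topology_split_sets(labels):
        if len(splits) != len(labels) - 3:
            continue
        fp = _fingerprint(splits, locus_taxa)
        if fp in seen:
            return False
        seen.add(fp)
    return True


# ---------------------------------------------------------------------------
# collection-level filters
# ---------------------------------------------------------------------------


def deduplicate(datasets: Sequence[SuperDataset]) -> List[SuperDataset]:
    """Drop data sets with identical taxon AND locus sets.

    The first occurrence (in input order) is kept, except that a dqbc
    whose pattern coincides with a biclique yields to the biclique.
    """
    best: Dict[Tuple[FrozenSet[str], FrozenSet[str]], SuperDataset] = {}
    order: List[Tuple[FrozenSet[str], FrozenSet[str]]] = []
    for ds in datasets:
        key = ds.key()
        if key not in best:
            best[key] = ds
            order.append(key)
        elif best[key].kind == "dqbc" and ds.kind == "biclique":
            best[key] = ds
    return [best[k] for k in order]


def sample_datasets(
    datasets: Sequence[SuperDataset], rate: float, seed: int
) -> List[SuperDataset]:
    """Independent thinning: keep each data set with probability ``rate``."""
    if not (0.0 <= rate <= 1.0):
        raise ValueError(f"sampling rate must lie in [0, 1], got {rate}")
    rng = np.random.default_rng(seed)
    draws = rng.random(len(datasets))
    return [ds for ds, u in zip(datasets, draws) if u < rate]
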