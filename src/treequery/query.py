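"""Taxon-list queries over a repository of precomputed confidence sets.

The retrieval model mirrors document search: data sets are documents,
taxa are keywords, and an inverted index maps each taxon id to the data
sets containing it, so candidate finding touches only the posting lists
of the query taxa -- work bounded by their total length, independent of
repository size.

Each candidate with enough overlap becomes a :class:`Hit`: its confidence
set is pruned to the overlapping taxa, summarized as a majority-rule
consensus tree with support, and scored

    S = (w + h * q) / (1 + h),        w = 100 * |overlap| / n_query_in_db

where q is the consensus quality (mean retained support x resolved
fraction), and h weights quality against overlap (slider range
0.01-10.0, default 1.0).  Because w and q are cached per hit, re-ranking
under a new h is pure arithmetic -- no re-pruning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .consensus import ConfidenceSet, majority_rule_consensus, prune_set, quality_score
from .multree import reduce_multree
from .trees import LabeledTree, parse_newick

__all__ = [
    "QueryError",
    "Taxonomy",
    "InvertedIndex",
    "Query",
    "Hit",
    "DatasetRecord",
    "Repository",
    "build_index",
    "expand_query",
    "score_hit",
    "run_query",
    "rerank",
    "compute_lca",
    "reduced_tree_on_demand",
]

H_MIN, H_MAX, H_DEFAULT = 0.01, 10.0, 1.0
DEFAULT_MIN_OVERLAP = 4
DEFAULT_MAX_RECORDS = 1000
DEGRADED_REPLICATES = 100


class QueryError(ValueError):
    pass


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------


class Taxonomy:
    """NCBI-style hierarchy: (taxon_id, parent_id, name, rank) records.

    Multiple synonymous names may map to one taxon id.  The root is the
    record whose parent is itself (or empty).  Parent links must be
    acyclic with a single root.
    """

    def __init__(self, records: Iterable[Tuple[int, int, str, str]]):
        self.parent: Dict[int, int] = {}
        self.name: Dict[int, str] = {}  # primary (first-seen) name per id
        self.rank: Dict[int, str] = {}
        self.name_to_id: Dict[str, int] = {}
        for taxon_id, parent_id, name, rank in records:
            taxon_id, parent_id = int(taxon_id), int(parent_id)
            if taxon_id not in self.parent:
                self.parent[taxon_id] = parent_id
                self.rank[taxon_id] = rank
                self.name[taxon_id] = name
            self.name_to_id.setdefault(name, taxon_id)
        roots = [t for t, p in self.parent.items() if p == t]
        if len(roots) != 1:
            raise ValueError(f"taxonomy must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        self._children: Dict[int, List[int]] = {}
        for t, p in self.parent.items():
            if t != p:
                if p not in self.parent:
                    raise ValueError(f"taxon {t} has unknown parent {p}")
                self._children.setdefault(p, []).append(t)
        # acyclicity: every node must reach the root
        for t in self.parent:
            seen = set()
            while t != self.root:
                if t in seen:
                    raise ValueError("cycle in taxonomy parent links")
                seen.add(t)
                t = self.parent[t]

    @classmethod
    def read_tsv(cls, path) -> "Taxonomy":
        df = pd.read_csv(path, sep="\t", dtype={"taxon_id": int, "parent_id": int})
        return cls(df[["taxon_id", "parent_id", "name", "rank"]].itertuples(index=False))

    def write_tsv(self, path) -> None:
        rows = [
            (t, self.parent[t], self.name[t], self.rank[t])
            for t in sorted(self.parent)
        ]
        extra = [
            (tid, self.parent[tid], name, self.rank[tid])
            for name, tid in sorted(self.name_to_id.items())
            if name != self.name[tid]
        ]
        pd.DataFrame(
            rows + extra, columns=["taxon_id", "parent_id", "name", "rank"]
        ).to_csv(path, sep="\t", index=False)

    def resolve(self, name: str) -> Optional[int]:
        return self.name_to_id.get(name)

    def children(self, taxon_id: int) -> List[int]:
        return sorted(self._children.get(taxon_id, []))

    def descendants(self, taxon_id: int) -> List[int]:
        """All strict descendants, preorder."""
        out: List[int] = []
        stack = self.children(taxon_id)[::-1]
        while stack:
            t = stack.pop()
            out.append(t)
            stack.extend(self.children(t)[::-1])
        return out

    def lineage(self, taxon_id: int) -> List[int]:
        """Path from the node up to and including the root."""
        if taxon_id not in self.parent:
            raise KeyError(f"unknown taxon id {taxon_id}")
        path = [taxon_id]
        while path[-1] != self.root:
            path.append(self.parent[path[-1]])
        return path


def compute_lca(taxonomy: Taxonomy, taxa: Iterable[int]) -> int:
    """Deepest node ancestral to every given id (a node is its own ancestor)."""
    ids = list(taxa)
    if not ids:
        raise QueryError("LCA of an empty taxon set")
    common: Optional[List[int]] = None
    for t in ids:
        lineage = taxonomy.lineage(t)
        if common is None:
            common = lineage
        else:
            anc = set(lineage)
            common = [x for x in common if x in anc]
    assert common
    return common[0]


# ---------------------------------------------------------------------------
# repository
# ---------------------------------------------------------------------------


@dataclass
class DatasetRecord:
    """One data set: metadata plus lazily loadable trees."""

    dataset_id: str
    kind: str  # single_locus | biclique | dqbc
    taxa: List[str]  # leaf labels, aligned with taxon_ids
    taxon_ids: List[int]
    loci: List[str]
    reference_locus: Optional[str] = None
    path: Optional[Path] = None  # directory holding trees.nwk / source.nwk
    _trees: Optional[List[LabeledTree]] = field(default=None, repr=False)
    _source: Optional[LabeledTree] = field(default=None, repr=False)

    @property
    def label_of_id(self) -> Dict[int, str]:
        return dict(zip(self.taxon_ids, self.taxa))

    def confidence_set(self, limit: Optional[int] = None) -> ConfidenceSet:
        if self._trees is not None:
            trees = self._trees if limit is None else self._trees[:limit]
            return ConfidenceSet(self.dataset_id, list(trees))
        assert self.path is not None
        return ConfidenceSet.read_newick(
            Path(self.path) / "trees.nwk", dataset_id=self.dataset_id, limit=limit
        )

    def source_tree(self) -> LabeledTree:
        """The stored source tree (single-locus data sets; may be a multree)."""
        if self._source is not None:
            return self._source
        assert self.path is not None
        src = Path(self.path) / "source.nwk"
        if not src.exists():
            raise QueryError(f"data set {self.dataset_id} stores no source tree")
        return parse_newick(src.read_text().strip())

    def meta_dict(self) -> dict:
        return {
            "dataset_id": self.dataset_id,
            "kind": self.kind,
            "taxa": self.taxa,
            "taxon_ids": self.taxon_ids,
            "loci": self.loci,
            "reference_locus": self.reference_locus,
        }


class Repository:
    """A collection of data sets plus the taxonomy they are named in.

    On disk: ``<root>/taxonomy.tsv`` and one directory per data set under
    ``<root>/datasets/<id>/`` holding ``meta.json``, ``trees.nwk`` (one
    newick per line) and optionally ``source.nwk``.
    """

    def __init__(self, taxonomy: Taxonomy, records: Iterable[DatasetRecord]):
        self.taxonomy = taxonomy
        self.records: Dict[str, DatasetRecord] = {}
        for rec in records:
            if rec.dataset_id in self.records:
                raise ValueError(f"duplicate dataset id {rec.dataset_id}")
            self.records[rec.dataset_id] = rec
        self._reduced_cache: Dict[str, LabeledTree] = {}
        self.reduction_computations = 0  # cache-probe counter

    def __getitem__(self, dataset_id: str) -> DatasetRecord:
        if dataset_id not in self.records:
            raise KeyError(f"unknown dataset id {dataset_id}")
        return self.records[dataset_id]

    def dataset_ids(self) -> List[str]:
        return sorted(self.records)

    @classmethod
    def load(cls, root) -> "Repository":
        root = Path(root)
        taxonomy = Taxonomy.read_tsv(root / "taxonomy.tsv")
        records = []
        for meta_path in sorted((root / "datasets").glob("*/meta.json")):
            meta = json.loads(meta_path.read_text())
            records.append(
                DatasetRecord(
                    dataset_id=meta["dataset_id"],
                    kind=meta["kind"],
                    taxa=meta["taxa"],
                    taxon_ids=[int(t) for t in meta["taxon_ids"]],
                    loci=meta["loci"],
                    reference_locus=meta.get("reference_locus"),
                    path=meta_path.parent,
                )
            )
        return cls(taxonomy, records)

    def save(self, root) -> None:
        root = Path(root)
        root.mkdir(parents=True, exist_ok=True)
        self.taxonomy.write_tsv(root / "taxonomy.tsv")
        for rec in self.records.values():
            d = root / "datasets" / rec.dataset_id
            d.mkdir(parents=True, exist_ok=True)
            (d / "meta.json").write_text(json.dumps(rec.meta_dict(), indent=1))
            rec.confidence_set().write_newick(d / "trees.nwk")
            if rec._source is not None:
                (d / "source.nwk").write_text(rec._source.to_newick() + "\n")


def reduced_tree_on_demand(repository: Repository, dataset_id: str) -> LabeledTree:
    """Singly-labeled reduction of a single-locus source tree, cached.

    Multi-locus data sets refuse: their redundant sequences were handled
    before concatenation, so there is nothing to reduce at query time.
    """
    rec = repository[dataset_id]
    if rec.kind != "single_locus":
        raise QueryError(
            "on-demand reduction applies to single-locus data sets only; "
            f"{dataset_id} is {rec.kind}"
        )
    if dataset_id in repository._reduced_cache:
        return repository._reduced_cache[dataset_id]
    source = rec.source_tree()
    repository.reduction_computations += 1
    reduced = reduce_multree(source) if source.is_multree else source
    repository._reduced_cache[dataset_id] = reduced
    return reduced


# ---------------------------------------------------------------------------
# inverted index
# ---------------------------------------------------------------------------


class InvertedIndex:
    """Posting lists taxon_id -> sorted dataset ids.

    ``postings_consulted`` counts posting-list lookups so the
    size-independence contract (only query-taxon postings are touched)
    can be probed in tests.
    """

    def __init__(self):
        self.postings: Dict[int, List[str]] = {}
        self.postings_consulted = 0

    @property
    def n_taxa(self) -> int:
        return len(self.postings)

    def contains_taxon(self, taxon_id: int) -> bool:
        return taxon_id in self.postings

    def candidates(self, taxon_ids: Iterable[int]) -> Dict[str, int]:
        """dataset id -> number of query taxa it contains.

        Touches exactly one posting list per query taxon present in the
        index; never scans the repository.
        """
        overlap: Dict[str, int] = {}
        for t in taxon_ids:
            posting = self.postings.get(t)
            if posting is None:
                continue
            self.postings_consulted += 1
            for ds in posting:
                overlap[ds] = overlap.get(ds, 0) + 1
        return overlap


def build_index(datasets: Iterable[Tuple[str, Iterable[int]]]) -> InvertedIndex:
    """Index (dataset id, taxon-id set) pairs; duplicate ids are an error."""
    idx = InvertedIndex()
    seen: Set[str] = set()
    acc: Dict[int, List[str]] = {}
    for dataset_id, taxon_ids in datasets:
        if dataset_id in seen:
            raise ValueError(f"duplicate dataset id {dataset_id}")
        seen.add(dataset_id)
        for t in set(taxon_ids):
            acc.setdefault(int(t), []).append(dataset_id)
    idx.postings = {t: sorted(ds) for t, ds in acc.items()}
    return idx


def index_repository(repository: Repository) -> InvertedIndex:
    return build_index(
        (rec.dataset_id, rec.taxon_ids) for rec in repository.records.values()
    )


# ---------------------------------------------------------------------------
# queries, scoring, hits
# ---------------------------------------------------------------------------


@dataclass
class Query:
    raw_names: List[str]
    taxon_ids: List[int]  # resolved, deduplicated, order-preserving
    unresolved: List[str]
    n_query_in_db: int
    h: float = H_DEFAULT
    min_overlap: int = DEFAULT_MIN_OVERLAP

    def __post_init__(self):
        if not (H_MIN <= self.h <= H_MAX):
            raise QueryError(f"h must lie in [{H_MIN}, {H_MAX}], got {self.h}")


def expand_query(
    names: Iterable[str],
    taxonomy: Taxonomy,
    index: InvertedIndex,
    h: float = H_DEFAULT,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> Query:
    """Resolve names against the taxonomy; expand uninomials as genera.

    Multinomials must match exactly (no fuzzy matching); a uninomial is
    taken as a genus name and contributes every species-or-below
    descendant of that node.  Unresolvable names are reported in
    ``unresolved``, never silently dropped.  ``n_query_in_db`` counts
    only resolved taxa that actually occur in the index.
    """
    raw = [n.strip().replace("_", " ") for n in names if n.strip()]
    resolved: List[int] = []
    unresolved: List[str] = []
    seen: Set[int] = set()

    def add(tid: int) -> None:
        if tid not in seen:
            seen.add(tid)
            resolved.append(tid)

    for name in raw:
        tid = taxonomy.resolve(name)
        if tid is None:
            unresolved.append(name)
            continue
        if " " not in name:  # uninomial: expand to the whole genus
            for d in taxonomy.descendants(tid):
                if not taxonomy.children(d):  # species-or-below terminals
                    add(d)
        else:
            add(tid)

    n_in_db = sum(1 for t in resolved if index.contains_taxon(t))
    if n_in_db == 0:
        raise QueryError("no query taxa in database")
    return Query(
        raw_names=raw,
        taxon_ids=resolved,
        unresolved=unresolved,
        n_query_in_db=n_in_db,
        h=h,
        min_overlap=min_overlap,
    )


def score_hit(overlap: int, n_query_in_db: int, q: float, h: float) -> float:
    """Normalized hit score S = (100*overlap/n_query_in_db + h*q) / (1+h)."""
    if n_query_in_db <= 0:
        raise QueryError("n_query_in_db must be positive")
    if not (0 < overlap <= n_query_in_db):
        raise QueryError("overlap must satisfy 0 < overlap <= n_query_in_db")
    if not (0.0 <= q <= 100.0):
        raise QueryError("quality q must lie in [0, 100]")
    if h <= 0:
        raise QueryError("h must be positive")
    w = 100.0 * overlap / n_query_in_db
    return (w + h * q) / (1.0 + h)


@dataclass
class Hit:
    """A scored query result; w and q are cached so that re-ranking under
    a new h never re-prunes or re-consenses."""

    dataset_id: str
    kind: str
    n_loci: int
    overlap_labels: FrozenSet[str]
    w: float
    q: float
    S: float
    mrt: LabeledTree
    lca: int
    lca_name: str

    @property
    def overlap(self) -> int:
        return len(self.overlap_labels)


def run_query(
    index: InvertedIndex,
    repository: Repository,
    query: Query,
    max_records: int = DEFAULT_MAX_RECORDS,
    replicates: Optional[int] = None,
) -> List[Hit]:
    """Score every candidate data set with sufficient overlap.

    ``replicates`` defaults to all stored trees when at most
    ``max_records`` candidates qualify, and degrades to the first 100
    replicates otherwise.  Hits are sorted by S descending, ties broken
    by dataset id; at most ``max_records`` are returned.  An empty result
    is a valid outcome, not an error.
    """
    overlap_by_ds = index.candidates(query.taxon_ids)
    eligible = sorted(
        (ds, ov) for ds, ov in overlap_by_ds.items() if ov >= query.min_overlap
    )
    if replicates is None and len(eligible) > max_records:
        replicates = DEGRADED_REPLICATES
    query_ids = set(query.taxon_ids)
    hits: List[Hit] = []
    for dataset_id, overlap in eligible:
        rec = repository[dataset_id]
        keep = frozenset(
            lab for tid, lab in zip(rec.taxon_ids, rec.taxa) if tid in query_ids
        )
        cs = rec.confidence_set(limit=replicates)
        pruned = prune_set(cs, keep)
        mrt = majority_rule_consensus(pruned)
        q = quality_score(mrt)
        w = 100.0 * overlap / query.n_query_in_db
        s = score_hit(overlap, query.n_query_in_db, q, query.h)
        lca = compute_lca(repository.taxonomy, rec.taxon_ids)
        hits.append(
            Hit(
                dataset_id=dataset_id,
                kind=rec.kind,
                n_loci=len(rec.loci),
                overlap_labels=keep,
                w=w,
                q=q,
                S=s,
                mrt=mrt,
                lca=lca,
                lca_name=repository.taxonomy.name[lca],
            )
        )
    hits.sort(key=lambda hit: (-hit.S, hit.dataset_id))
    return hits[:max_records]


def rerank(hits: Sequence[Hit], h: float) -> List[Hit]:
    """Re-score cached hits under a new h; pure arithmetic on (w, q)."""
    if not (H_MIN <= h <= H_MAX):
        raise QueryError(f"h must lie in [{H_MIN}, {H_MAX}], got {h}")
    rescored = [
        Hit(
            dataset_id=hit.dataset_id,
            kind=hit.kind,
            n_loci=hit.n_loci,
            overlap_labels=hit.overlap_labels,
            w=hit.w,
            q=hit.q,
            S=(hit.w + h * hit.q) / (1.0 + h),
            mrt=hit.mrt,
            lca=hit.lca,
            lca_name=hit.lca_name,
        )
        for hit in hits
    ]
    rescored.sort(key=lambda hit: (-hit.S, hit.dataset_id))
    return rescored
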