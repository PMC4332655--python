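# Methods

## Tree model

Trees are unrooted, leaf-labeled, with optional nonnegative branch
lengths and optional per-edge support in [0, 100].  Labels may repeat
(multrees).  Unlabeled degree-2 nodes are suppressed on construction;
when suppression merges a path, lengths are summed (a path mixing known
and missing lengths treats missing as 0 and emits a
`MissingLengthWarning`).  The empty tree (no nodes) is a first-class
value: it is the correct reduction of a multree with no conflict-free
information.

Newick dialect: Biopython's parser is the backend; duplicate leaf labels
are preserved, numeric internal-node labels in [0, 100] are read as edge
support (values outside that range are dropped), unquoted underscores
are read as spaces, and the writer emits underscores with supports at
one decimal.  A pre-scan reports the position of unbalanced parentheses
or unterminated quotes, which Biopython's own errors do not carry.

All quartet/consensus computation treats trees as unrooted; rooting is
presentation-only.  Midpoint rooting places the root halfway along the
longest leaf-to-leaf path and requires branch lengths; ties between
equally long paths are broken by the lexicographic order of the endpoint
label pair (the convention is ours — display tools rarely document
theirs).

## Multree reduction

A quartet `ab|cd` is *displayed* when some edge has leaves labeled `a`
and `b` on one side and `c` and `d` on the other; on a multree one
4-species set can display two or three conflicting quartets.  A
displayed quartet is *conflict-free* when its species set displays no
alternative.

The reduction returns the tree on the conflict-free label set whose
internal edges are **all** splits every one of whose induced quartets is
conflict-free.  Two observations make this well-defined and canonical:

1. *Compatibility.*  If two such splits crossed, choosing one label from
   each of the four intersection cells would yield two different
   resolutions of one 4-set, both conflict-free — impossible, since
   conflict-freeness allows at most one resolution per 4-set.  Hence the
   splits always fit one tree.
2. *Maximality.*  Any tree displaying only conflict-free quartets has
   all of its splits in the collected set, so the constructed tree
   displays a superset of its quartets.  The output is therefore the
   unique maximum conservative tree, and whenever the conflict-free set
   is exactly displayable (singly-labeled inputs, concordant
   duplications) the output displays exactly it.

The conflict-free set is *not* always exactly displayable: discordant
duplications can leave individually unconflicted quartets that are
jointly incompatible (about 5% of random discordant fixtures).  The
maximum-tree semantics handles these gracefully; a defensive
postcondition check still fails loudly if the output ever displayed a
quartet outside the conflict-free set.  When no qualifying split exists
the result is the empty tree — no edges, no taxa.  Species that occur in
conflict-free quartets but cannot be placed on any qualifying split are
retained on the central polytomy (kept, but unplaced).

Split search is a depth-first bipartition assignment with early pruning
(a branch dies at the first decided cross-quartet outside the
conflict-free set); it is exponential in the worst case and capped at 24
distinct informative labels, comfortably above the single-locus gene
trees this is meant for.  `brute_force_reduction` (≤ 7 labels) is an
independent oracle: it enumerates every unrooted topology — all binary
shapes by sequential leaf insertion, then all edge contractions — keeps
those displaying only conflict-free quartets, and verifies that a unique
inclusion-maximum exists.

## Decisive assembly

The availability matrix is a boolean taxon × locus DataFrame (TSV
interchange: header = locus ids, first column = taxon labels, 0/1
cells).  Maximal bicliques are enumerated by closing every subset of the
smaller dimension (a maximal biclique is exactly a closed pair: its taxa
are all taxa covering its loci and vice versa); enumeration is exact and
exponential in `min(#taxa, #loci)`, guarded at 2^22 subsets.  Floors:
≥ 4 taxa (the smallest informative unrooted tree) and ≥ 2 loci (a
single-locus data set is its own, trivially decisive, kind).

Quasi-biclique construction takes every taxon having the reference locus
and every locus covering at least a third of them — the threshold is
interpreted inclusively as ≥ 1/3 exactly, since the printed 33.3% is a
rounded fraction; the reference locus itself always passes at 100%.  A
gap-free result is reclassified as a biclique (it is then in fact closed
in both directions, i.e. maximal); an incomplete result needs ≥ 5 taxa.
Whether the construction should demand two loci *besides* the reference
is not settled anywhere we know of; we require ≥ 2 loci in total.

Decisiveness checks are deliberately brute-force.  A pattern is decisive
for tree `T` when `T` is the only binary topology whose per-locus
restrictions match `T`'s; restrictions are compared as restricted split
sets ("fingerprints").  Decisive *for all trees* is equivalent to all
binary topologies having pairwise distinct fingerprints, which one pass
over the (2n−5)!! enumeration decides in O(#topologies · #loci) — the
check refuses n > 8 (all-trees) / n > 9 (single-tree), where the
enumeration reaches 10,395 / 135,135 topologies.

De-duplication treats two data sets as equal exactly when both their
taxon sets and locus sets coincide, keeping the first occurrence except
that a quasi-biclique always yields to an identical biclique.  Random
thinning (`sample_datasets`) keeps each data set independently with the
given probability under a seeded generator — the mechanism used to tame
combinatorially exploding collections (dense clades can be thinned to a
few percent).

## Consensus and quality

The majority-rule consensus of B singly-labeled trees on one label set
contains exactly the nontrivial splits occurring in **strictly** more
than B/2 members; the strict rule excludes exactly-50% splits (the
two-tree tie gives a star) and guarantees the retained splits are
mutually compatible without any further checks.  Support = 100 ×
frequency, kept exact internally and printed at one decimal.

Two counting engines must agree on every input: a dictionary over
canonical splits, and a randomized 128-bit hash per split (XOR of
per-label codes on the canonical side, fixed generator seed
`0x5EEDB1A5`) with stored canonical forms verified on every lookup so a
collision is detected rather than silently miscounted.

Quality `q` = mean support of retained edges × resolved fraction, where
the resolved fraction divides by `n−3`, the internal-edge count of a
binary unrooted tree — the denominator convention is fixed here once
(one could also count nodes of a rooted display; we do not).  A star
scores 0; unanimity scores 100.

## Query engine

Taxa are named per an NCBI-style taxonomy table (taxon_id, parent_id,
name, rank; synonyms map extra names to one id; the root is its own
parent).  Name resolution is exact — no fuzzy matching; misspelled names
are reported back, never dropped.  A uninomial is treated as a genus and
expands to every terminal descendant of that node.  `n_query_in_db`
counts only resolved taxa with a posting in the index, so names absent
from the repository do not dilute the overlap score.

The inverted index maps taxon_id → sorted data-set ids.  Candidate
retrieval touches exactly the posting lists of the query taxa, so its
work is bounded by their total length and independent of repository
size; the instrumented `postings_consulted` counter exists so tests can
probe this contract rather than trust it.

Per eligible candidate (overlap ≥ `min_overlap`, default 4 — the paper's
"minimum number of query taxa" is not stated numerically, and 4 is the
repository-wide informativeness floor), the engine prunes the first
`replicates` trees to the overlap, builds the consensus, computes
`w`, `q`, `S = (w + h·q)/(1+h)`, and the taxonomy LCA of the full data
set.  `replicates` defaults to all stored trees unless more than
`max_records` (default 1,000) candidates qualify, in which case it
degrades to 100 — mirroring the stated engine defaults.  Ties in `S`
break by data-set id for reproducibility.  On-demand multree reduction
applies to single-locus data sets only (multi-locus assembly already
consumed reduced taxa) and is cached per repository.

## Synthetic data

All generators are pure functions of parameters + seed.

* `random_binary_tree` — uniform over unrooted binary topologies via
  sequential random leaf attachment; optional i.i.d. Exponential(rate)
  branch lengths.
* `make_multree` — concordant mode doubles a leaf into a cherry (the
  reduction must return the original tree with all taxa, the generator's
  headline round-trip property); discordant mode grafts the duplicate
  onto the farthest leaf's pendant edge, engineering quartet conflict.
* `perturbed_confidence_set` — B copies of a tree, each after a given
  number of random NNI moves.  This stands in for bootstrap resampling:
  what the downstream machinery needs is a set of trees with
  controllable agreement, and NNI count is one interpretable knob
  (0 moves → all supports 100; support decays on average as moves grow).
  It does not emulate data-driven branch-wise signal heterogeneity, so
  passing tests say nothing about how real bootstrap supports distribute
  — only that counting, pruning and scoring are correct.
* `planted_availability` — fully filled (taxon, locus) blocks over
  i.i.d. Bernoulli background, for exact plant-recovery checks.
* `toy_taxonomy` — root → genera → species, names `G<i>` / `G<i> s<j>`.
* `simulate_repository` — a complete repository: 50 data sets of 8 taxa
  by default, a confidence set of B = 100 replicates at 2 NNI moves each
  (desk-scale stand-ins for the production 1,000-replicate sets), ~half
  single-locus (a third of those with concordant-duplication multree
  sources), the rest tagged biclique/dqbc.

## Problem sizes used in the checks

The self-checks run at sizes where exhaustive enumeration is the
arbiter: 200 random multrees with ≤ 7 distinct labels against the
all-topology oracle; decisiveness on patterns of ≤ 8 taxa (10,395
topologies); 50 random matrices up to 12 × 8 against exhaustive
locus-subset search; a 50-data-set repository with overlaps 4..53 of a
54-name query for the ranking semantics (distinct overlaps make the
h → 0 ordering comparison exact); and a 10× decoy-inflated index for the
size-independence probe.

## Known limitations

* Reduction and biclique enumeration are exact-exponential algorithms
  with explicit caps — right for gene-tree and hub-group scale, wrong
  for thousands of taxa or loci.
* Supports are dropped on restriction (a pruned edge generally merges
  several source edges, whose supports do not compose); consensus is
  always recomputed from the pruned replicates instead.
* Decisiveness beyond n = 9 is not decided by this package (no
  characterization shortcut is implemented, only enumeration).
* The repository stores plain newick text per data set; no compression
  or hash-addressed storage is attempted — the index contract, not raw
  throughput, is what this implementation preserves.
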