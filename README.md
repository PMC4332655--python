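# treequery

Species-tree retrieval for comparative biologists: given a repository of
precomputed gene/species trees (each stored as a *confidence set* of
bootstrap replicates) and a list of taxon names, `treequery` finds the
data sets that overlap the list, prunes every replicate to the shared
taxa, summarizes each pruned set as a support-annotated majority-rule
consensus tree, and returns the hits ranked by a tunable blend of
taxonomic overlap and tree quality.

The toolkit also covers the two assembly problems that make such a
repository possible:

* **Multree reduction.** Gene trees often carry the same species on
  several leaves (alleles, multiple individuals, paralogs) — *multrees* —
  and cannot be combined across loci as they stand.  A displayed quartet
  `ab|cd` is *conflict-free* when no part of the same tree resolves those
  four species differently; the reduction returns the singly-labeled
  tree whose edges are exactly the splits all of whose induced quartets
  are conflict-free.  Such splits are provably pairwise compatible, and
  the result retains at least as much conflict-free information as any
  other tree that introduces none — it is the unique maximum
  conservative species-level summary of the gene tree.

* **Decisive multi-locus assembly.**  From a taxon × locus availability
  matrix `M`, the toolkit assembles supermatrix skeletons that are
  *decisive*: the per-locus restrictions `T|taxa(locus i)` of a tree `T`
  pin `T` down uniquely.  Two constructions guarantee decisiveness for
  *all* trees: **maximal bicliques** (taxon/locus blocks with no missing
  cell, extendable by no taxon or locus) and **decisive quasi-bicliques**
  (a *reference locus* covering every included taxon, plus each locus
  covering ≥ 1/3 of those taxa).  Every data set needs ≥ 4 taxa; an
  incomplete quasi-biclique needs ≥ 5 (a complete 4-taxon one is already
  a biclique).  Brute-force checkers verify decisiveness by exhausting
  all (2n−5)!! binary topologies at small n.

## Scoring

For query list `A` and stored tree `T`, let `L(T|A)` be the shared taxa,
`n` the number of query taxa present in the repository, and

    w = 100 · |L(T|A)| / n                     (overlap score, 0–100)
    q = (mean bootstrap support of retained
         consensus edges) · (resolved fraction) (quality score, 0–100)
    S = (w + h·q) / (1 + h)                    (normalized hit score)

where the resolved fraction is the number of consensus splits over the
`n−3` possible, and `h ∈ [0.01, 10]` (default 1.0) weights quality
against overlap.  `S` ranges 0–100; as `h → 0` the ranking converges to
ranking by overlap, while large `h` favors well-supported subtrees.
Worked example: a 200-name query (all in the repository) hitting a tree
that shares 80 names, whose pruned consensus is fully resolved with mean
support 70%, at `h = 0.5`:

    S = ((80/200)·100 + 0.5·70) / (1 + 0.5) = 50

`w` and `q` are cached per hit, so moving the `h` slider re-ranks
without re-pruning anything.

## Worked example

Build a fully synthetic repository (25 data sets, 100 bootstrap
replicates each, mild NNI perturbation), index it, and query 8 species
names:

```sh
treequery simulate repo --datasets 25 --taxa-per 10 --b 100 --nni 2 --seed 42 --out repo
treequery build-index --repo repo --out index.json
treequery query --repo repo --index index.json --names names.txt --h 1.0
```

which prints (first hit):

```
rank dataset_id kind         n_loci overlap      w      q      S  lca_name
   1 ds0003     dqbc              3       8  100.0   77.8   88.9  root
```

Reading the row: data set `ds0003` (a 3-locus decisive quasi-biclique)
contains all 8 query taxa (`w = 100`); its 100 replicate trees pruned to
those taxa give a majority-rule consensus whose support and resolution
combine to `q = 77.8`; at `h = 1` the normalized score is
`S = (100 + 77.8)/2 = 88.9`.  The consensus trees themselves are written
with `--trees-out hits.nwk`.  Other entry points: `treequery reduce`
(multree → conflict-free species tree; an all-conflict input yields an
empty file) and `treequery assemble` (availability TSV → biclique/dqbc
data sets as JSON).

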