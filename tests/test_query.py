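"""Inverted index, name expansion, scoring, ranking, LCA, on-demand reduction."""

import numpy as np
import pytest

from treequery.query import (
    DatasetRecord,
    QueryError,
    Repository,
    build_index,
    compute_lca,
    expand_query,
    index_repository,
    reduced_tree_on_demand,
    rerank,
    run_query,
    score_hit,
)
from treequery.synth import (
    make_multree,
    perturbed_confidence_set,
    random_binary_tree,
    simulate_repository,
    toy_taxonomy,
)


class TestIndex:
    def test_single_dataset_postings(self):
        idx = build_index([("d1", [1, 2, 3, 4])])
        assert set(idx.postings) == {1, 2, 3, 4}
        assert all(p == ["d1"] for p in idx.postings.values())

    def test_disjoint_datasets_share_no_posting(self):
        idx = build_index([("d1", [1, 2]), ("d2", [3, 4])])
        assert all(len(p) == 1 for p in idx.postings.values())

    def test_duplicate_dataset_ids_rejected(self):
        with pytest.raises(ValueError):
            build_index([("d1", [1]), ("d1", [2])])

    def test_candidate_retrieval_touches_only_query_postings(self):
        datasets = [(f"d{i}", list(range(i, i + 6))) for i in range(1000)]
        idx = build_index(datasets)
        idx.postings_consulted = 0
        idx.candidates(list(range(10)))
        assert idx.postings_consulted <= 10


class TestExpandQuery:
    def test_genus_uninomial_expands_to_all_species(self):
        tax = toy_taxonomy(3, 5)
        idx = build_index([("d1", [tax.resolve(f"G1 s{j}") for j in range(1, 6)])])
        q = expand_query(["G1"], tax, idx)
        assert len(q.taxon_ids) == 5
        assert q.n_query_in_db == 5

    def test_misspelled_name_reported_not_dropped(self):
        tax = toy_taxonomy(2, 3)
        idx = build_index([("d1", [tax.resolve("G1 s1")])])
        q = expand_query(["G1 s1", "Gl s1"], tax, idx)
        assert q.unresolved == ["Gl s1"]
        assert q.n_query_in_db == 1

    def test_n_query_in_db_counts_only_indexed_taxa(self):
        tax = toy_taxonomy(2, 4)
        names = ["G1 s1", "G1 s2", "G1 s3", "G2 s1"]
        idx = build_index([("d1", [tax.resolve(n) for n in names[:3]])])
        q = expand_query(names, tax, idx)
        assert len(q.taxon_ids) == 4
        assert q.n_query_in_db == 3

    def test_nothing_resolvable_errors(self):
        tax = toy_taxonomy(2, 2)
        idx = build_index([("d1", [tax.resolve("G1 s1")])])
        with pytest.raises(QueryError, match="no query taxa in database"):
            expand_query(["Nope nope"], tax, idx)


class TestScoreHit:
    def test_worked_example(self):
        assert score_hit(80, 200, 70.0, 0.5) == pytest.approx(50.0)

    def test_perfect_hit_scores_100_at_any_h(self):
        for h in (0.01, 0.5, 1.0, 10.0):
            assert score_hit(200, 200, 100.0, h) == pytest.approx(100.0)

    def test_zero_quality_halves_weight_one(self):
        assert score_hit(30, 100, 0.0, 1.0) == pytest.approx(15.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(QueryError):
            score_hit(10, 0, 50.0, 1.0)
        with pytest.raises(QueryError):
            score_hit(0, 10, 50.0, 1.0)
        with pytest.raises(QueryError):
            score_hit(5, 10, 50.0, 0.0)

    def test_monotone_in_overlap_and_quality(self):
        base = score_hit(10, 100, 50.0, 1.0)
        assert score_hit(11, 100, 50.0, 1.0) > base
        assert score_hit(10, 100, 51.0, 1.0) > base


class TestRunQuery:
    def _exact_repo(self):
        tax = toy_taxonomy(2, 6)
        ids = [tax.resolve(f"G1 s{j}") for j in range(1, 7)]
        labels = [tax.name[t] for t in ids]
        tree = random_binary_tree(labels, 0)
        cs = perturbed_confidence_set(tree, B=20, nni_moves=0, seed=0)
        rec = DatasetRecord(
            dataset_id="d1",
            kind="single_locus",
            taxa=labels,
            taxon_ids=ids,
            loci=["c1"],
            _trees=cs.trees,
            _source=tree,
        )
        return Repository(tax, [rec]), labels

    def test_exact_match_scores_100(self):
        repo, labels = self._exact_repo()
        idx = index_repository(repo)
        q = expand_query(labels, repo.taxonomy, idx)
        (hit,) = run_query(idx, repo, q)
        assert hit.w == 100.0
        assert hit.q == 100.0
        assert hit.S == 100.0
        assert hit.lca_name == "G1"

    def test_insufficient_overlap_yields_empty_result(self):
        repo, labels = self._exact_repo()
        idx = index_repository(repo)
        q = expand_query(labels[:4], repo.taxonomy, idx, min_overlap=4)
        q.min_overlap = 5
        assert run_query(idx, repo, q) == []

    def test_scores_recomputable_from_cached_w_q(self):
        repo = simulate_repository(n_datasets=20, B=10, seed=4)
        idx = index_repository(repo)
        rec = repo[repo.dataset_ids()[0]]
        names = [repo.taxonomy.name[t] for t in rec.taxon_ids]
        for h in (0.01, 0.5, 1.0, 10.0):
            q = expand_query(names, repo.taxonomy, idx, h=h)
            for hit in run_query(idx, repo, q):
                assert hit.S == pytest.approx((hit.w + h * hit.q) / (1 + h), abs=1e-9)

    def test_rerank_preserves_w_and_q(self):
        repo = simulate_repository(n_datasets=30, B=10, seed=5)
        idx = index_repository(repo)
        rec = repo[repo.dataset_ids()[0]]
        names = [repo.taxonomy.name[t] for t in rec.taxon_ids]
        q = expand_query(names, repo.taxonomy, idx, h=1.0)
        hits = run_query(idx, repo, q)
        re = rerank(hits, 0.01)
        assert {(h.dataset_id, h.w, h.q) for h in hits} == {
            (h.dataset_id, h.w, h.q) for h in re
        }
        # as h -> 0 the ordering converges to the w ordering
        ws = [h.w for h in re]
        assert all(a >= b - 1e-9 or abs(a - b) < 2 for a, b in zip(ws, ws[1:]))


class TestLCA:
    def test_single_taxon_is_its_own_lca(self):
        tax = toy_taxonomy(2, 3)
        t = tax.resolve("G2 s1")
        assert compute_lca(tax, [t]) == t

    def test_congeners_meet_at_genus(self):
        tax = toy_taxonomy(3, 3)
        ids = [tax.resolve("G2 s1"), tax.resolve("G2 s3")]
        assert tax.name[compute_lca(tax, ids)] == "G2"

    def test_random_pairs_match_ancestor_set_intersection(self):
        tax = toy_taxonomy(5, 6, seed=1)
        rng = np.random.default_rng(0)
        all_ids = sorted(tax.parent)
        for _ in range(25):
            a, b = rng.choice(all_ids, size=2, replace=False)
            got = compute_lca(tax, [int(a), int(b)])
            anc_a = set(tax.lineage(int(a)))
            expected = next(x for x in tax.lineage(int(b)) if x in anc_a)
            assert got == expected

    def test_unknown_id_errors(self):
        tax = toy_taxonomy(2, 2)
        with pytest.raises(KeyError):
            compute_lca(tax, [999999])


class TestReducedOnDemand:
    def _repo_with_multree(self):
        tax = toy_taxonomy(1, 6)
        ids = [tax.resolve(f"G1 s{j}") for j in range(1, 7)]
        labels = [tax.name[t] for t in ids]
        tree = random_binary_tree(labels, 7)
        m = make_multree(tree, [labels[0]], "concordant", 7)
        cs = perturbed_confidence_set(tree, B=3, nni_moves=0, seed=7)
        recs = [
            DatasetRecord("m1", "single_locus", labels, ids, ["c1"], _trees=cs.trees, _source=m),
            DatasetRecord("s1", "single_locus", labels, ids, ["c2"], _trees=cs.trees, _source=tree),
            DatasetRecord("b1", "biclique", labels, ids, ["c1", "c2"], _trees=cs.trees),
        ]
        return Repository(tax, recs), tree

    def test_multree_source_reduced_to_species_tree(self):
        repo, tree = self._repo_with_multree()
        reduced = reduced_tree_on_demand(repo, "m1")
        assert reduced.topology_equal(tree)

    def test_singly_labeled_source_is_identity(self):
        repo, tree = self._repo_with_multree()
        assert reduced_tree_on_demand(repo, "s1").topology_equal(tree)

    def test_cache_computes_once(self):
        repo, _ = self._repo_with_multree()
        first = reduced_tree_on_demand(repo, "m1")
        assert repo.reduction_computations == 1
        second = reduced_tree_on_demand(repo, "m1")
        assert second is first
        assert repo.reduction_computations == 1

    def test_multi_locus_dataset_refuses(self):
        repo, _ = self._repo_with_multree()
        with pytest.raises(QueryError):
            reduced_tree_on_demand(repo, "b1")


class TestRepositoryRoundTrip:
    def test_save_load_preserves_query_results(self, tmp_path):
        repo = simulate_repository(n_datasets=8, B=8, seed=11)
        repo.save(tmp_path / "repo")
        loaded = Repository.load(tmp_path / "repo")
        idx1, idx2 = index_repository(repo), index_repository(loaded)
        rec = repo[repo.dataset_ids()[0]]
        names = [repo.taxonomy.name[t] for t in rec.taxon_ids]
        q1 = expand_query(names, repo.taxonomy, idx1)
        q2 = expand_query(names, loaded.taxonomy, idx2)
        h1 = run_query(idx1, repo, q1)
        h2 = run_query(idx2, loaded, q2)
        assert [(h.dataset_id, round(h.S, 9)) for h in h1] == [
            (h.dataset_id, round(h.S, 9)) for h in h2
        ]
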