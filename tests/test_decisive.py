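"""Decisive data-set assembly: bicliques, dqbcs, decisiveness checkers."""

import itertools

import numpy as np
import pytest

from treequery.decisive import (
    AvailabilityMatrix,
    SuperDataset,
    build_dqbc,
    deduplicate,
    is_decisive_for_all_trees,
    is_decisive_for_tree,
    maximal_bicliques,
    sample_datasets,
)
from treequery.multree import enumerate_binary_split_sets
from treequery.synth import planted_availability, random_binary_tree
from treequery.trees import tree_from_splits


def matrix(taxa, loci, rows):
    return AvailabilityMatrix.from_arrays(taxa, loci, np.array(rows, dtype=bool))


def exhaustive_maximal_bicliques(M, min_taxa=4, min_loci=2):
    """Independent oracle: iterate every locus subset, keep locus-closed
    blocks, verify maximality by single-element extension."""
    out = set()
    for k in range(1, len(M.loci) + 1):
        for loci in itertools.combinations(M.loci, k):
            taxa = frozenset(M.taxa)
            for l in loci:
                taxa &= M.taxa_with_locus(l)
            if len(taxa) < min_taxa:
                continue
            # locus-maximal? no locus outside the subset covers all taxa
            if any(
                l not in loci and taxa <= M.taxa_with_locus(l) for l in M.loci
            ):
                continue
            # taxon-maximal by construction (taxa = all common taxa)
            if len(loci) >= min_loci:
                out.add((taxa, frozenset(loci)))
    return out


class TestMaximalBicliques:
    def test_full_matrix_yields_itself(self):
        M = matrix([f"t{i}" for i in range(6)], ["a", "b", "c"], np.ones((6, 3)))
        (only,) = maximal_bicliques(M)
        assert only.taxa == frozenset(M.taxa)
        assert only.loci == frozenset(M.loci)

    def test_no_block_above_floor_yields_empty_list(self):
        M = matrix(
            ["t1", "t2", "t3", "t4"],
            ["a", "b"],
            [[1, 0], [1, 0], [0, 1], [0, 1]],
        )
        assert maximal_bicliques(M) == []

    @pytest.mark.parametrize("seed", [7, 11, 23])
    def test_matches_exhaustive_locus_subset_search(self, seed):
        rng = np.random.default_rng(seed)
        M = AvailabilityMatrix.from_arrays(
            [f"t{i:02d}" for i in range(10)],
            [f"L{j}" for j in range(5)],
            rng.random((10, 5)) < 0.6,
        )
        got = {(b.taxa, b.loci) for b in maximal_bicliques(M)}
        assert got == exhaustive_maximal_bicliques(M)

    def test_single_element_extension_breaks_coverage(self):
        rng = np.random.default_rng(5)
        M = AvailabilityMatrix.from_arrays(
            [f"t{i:02d}" for i in range(9)],
            [f"L{j}" for j in range(5)],
            rng.random((9, 5)) < 0.65,
        )
        for b in maximal_bicliques(M):
            for t in set(M.taxa) - b.taxa:
                assert not b.loci <= M.loci_of_taxon(t)
            for l in set(M.loci) - b.loci:
                assert not b.taxa <= M.taxa_with_locus(l)

    def test_deterministic_order_by_size_then_lexicographic(self):
        rng = np.random.default_rng(2)
        M = AvailabilityMatrix.from_arrays(
            [f"t{i:02d}" for i in range(8)],
            [f"L{j}" for j in range(4)],
            rng.random((8, 4)) < 0.7,
        )
        sizes = [b.size for b in maximal_bicliques(M)]
        assert sizes == sorted(sizes, reverse=True)


class TestBuildDqbc:
    def test_one_third_threshold_is_inclusive(self):
        # second locus covers 3 of 8 reference taxa: 3/8 >= 1/3
        taxa = [f"t{i}" for i in range(8)]
        grid = np.zeros((8, 2), bool)
        grid[:, 0] = True
        grid[:3, 1] = True
        ds = build_dqbc(AvailabilityMatrix.from_arrays(taxa, ["ref", "B"], grid), "ref")
        assert ds.kind == "dqbc"
        assert ds.loci == {"ref", "B"}
        assert ds.reference_locus == "ref"

    def test_below_threshold_locus_excluded(self):
        taxa = [f"t{i}" for i in range(10)]
        grid = np.zeros((10, 2), bool)
        grid[:, 0] = True
        grid[:3, 1] = True  # 3/10 < 1/3
        assert build_dqbc(AvailabilityMatrix.from_arrays(taxa, ["ref", "B"], grid), "ref") is None

    def test_complete_pattern_reclassified_as_biclique(self):
        M = matrix(["a", "b", "c", "d"], ["ref", "B"], np.ones((4, 2)))
        ds = build_dqbc(M, "ref")
        assert ds.kind == "biclique"
        assert ds.reference_locus is None

    def test_incomplete_four_taxon_pattern_rejected(self):
        M = matrix(
            ["a", "b", "c", "d"],
            ["ref", "B"],
            [[1, 1], [1, 1], [1, 1], [1, 0]],
        )
        assert build_dqbc(M, "ref") is None

    def test_five_taxa_with_gap_accepted(self):
        M = matrix(
            ["a", "b", "c", "d", "e"],
            ["ref", "B"],
            [[1, 1], [1, 1], [1, 1], [1, 1], [1, 0]],
        )
        ds = build_dqbc(M, "ref")
        assert ds is not None and ds.kind == "dqbc"
        assert len(ds.taxa) == 5

    def test_unknown_reference_errors(self):
        M = matrix(["a", "b", "c", "d"], ["x"], np.ones((4, 1)))
        with pytest.raises(KeyError):
            build_dqbc(M, "nope")

    def test_reference_column_is_complete(self):
        M = planted_availability(
            8, 4, planted=[([f"t{i}" for i in range(1, 9)], ["L1"])], background_density=0.5, seed=3
        )
        ds = build_dqbc(M, "L1")
        assert ds is not None
        assert M.taxa_with_locus("L1") >= ds.taxa


class TestDecisiveness:
    def test_full_coverage_locus_is_decisive_for_any_tree(self):
        taxa = [f"t{i}" for i in range(6)]
        grid = np.zeros((6, 2), bool)
        grid[:, 0] = True
        grid[:4, 1] = True
        M = AvailabilityMatrix.from_arrays(taxa, ["all", "part"], grid)
        for seed in range(3):
            t = random_binary_tree(taxa, seed)
            assert is_decisive_for_tree(M, t)

    def test_three_taxon_loci_carry_no_quartet(self):
        M = matrix(
            ["A", "B", "C", "D"],
            ["L1", "L2"],
            [[1, 0], [1, 1], [1, 1], [0, 1]],  # {A,B,C} and {B,C,D}
        )
        for splits in enumerate_binary_split_sets(["A", "B", "C", "D"]):
            t = tree_from_splits(frozenset("ABCD"), list(splits))
            assert not is_decisive_for_tree(M, t)
        assert not is_decisive_for_all_trees(M)

    def test_six_taxa_two_overlapping_loci_match_restriction_oracle(self):
        # loci covering {t0..t4} and {t1..t5}: verdict must equal an
        # independently computed one (tree-restriction comparison)
        taxa = [f"t{i}" for i in range(6)]
        grid = np.zeros((6, 2), bool)
        grid[:5, 0] = True
        grid[1:, 1] = True
        M = AvailabilityMatrix.from_arrays(taxa, ["L1", "L2"], grid)
        tree = random_binary_tree(taxa, 1)
        locus_taxa = [M.taxa_with_locus(l) for l in M.loci]

        def restriction_profile(t):
            return tuple(frozenset(t.restrict(s).bipartitions()) for s in locus_taxa)

        target = restriction_profile(tree)
        all_trees = [
            tree_from_splits(frozenset(taxa), list(s))
            for s in enumerate_binary_split_sets(taxa)
        ]
        oracle = sum(restriction_profile(t) == target for t in all_trees) == 1
        assert is_decisive_for_tree(M, tree) == oracle

    def test_biclique_and_dqbc_patterns_are_decisive_for_all_trees(self):
        M = planted_availability(
            7,
            3,
            planted=[([f"t{i}" for i in range(1, 8)], ["L1"])],
            background_density=0.5,
            seed=9,
        )
        ds = build_dqbc(M, "L1")
        assert ds is not None
        assert is_decisive_for_all_trees(M.submatrix(ds.taxa, ds.loci))
        full = matrix([f"t{i}" for i in range(5)], ["a", "b"], np.ones((5, 2)))
        assert is_decisive_for_all_trees(full)

    def test_size_guards(self):
        taxa = [f"t{i}" for i in range(10)]
        M = AvailabilityMatrix.from_arrays(taxa, ["a"], np.ones((10, 1)))
        with pytest.raises(ValueError):
            is_decisive_for_tree(M, random_binary_tree(taxa, 0))
        with pytest.raises(ValueError):
            is_decisive_for_all_trees(M)


class TestDedupAndSampling:
    def _ds(self, taxa, loci, kind="biclique", ref=None):
        return SuperDataset(frozenset(taxa), frozenset(loci), kind, ref)

    def test_identical_lists_collapse(self):
        a = self._ds("abcd", ["x", "y"])
        assert deduplicate([a, a]) == [a]

    def test_dqbc_yields_to_equal_biclique(self):
        d = self._ds("abcde", ["x", "y"], kind="dqbc", ref="x")
        b = self._ds("abcde", ["x", "y"])
        assert deduplicate([d, b]) == [b]
        assert deduplicate([b, d]) == [b]

    def test_disjoint_datasets_unchanged(self):
        a = self._ds("abcd", ["x", "y"])
        b = self._ds("efgh", ["z", "w"])
        assert deduplicate([a, b]) == [a, b]

    def test_sampling_extremes(self):
        a = self._ds("abcd", ["x", "y"])
        datasets = [a] * 50
        assert sample_datasets(datasets, 1.0, seed=1) == datasets
        assert sample_datasets(datasets, 0.0, seed=1) == []
        with pytest.raises(ValueError):
            sample_datasets(datasets, 1.5, seed=1)

    def test_sampling_rate_within_binomial_bounds(self):
        a = self._ds("abcd", ["x", "y"])
        n, rate = 10_000, 0.2
        kept = len(sample_datasets([a] * n, rate, seed=42))
        sd = (n * rate * (1 - rate)) ** 0.5
        assert abs(kept - n * rate) < 3 * sd

    def test_sampling_reproducible(self):
        datasets = [self._ds("abcd", [f"x{i}", "y"]) for i in range(100)]
        assert sample_datasets(datasets, 0.5, 7) == sample_datasets(datasets, 0.5, 7)
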