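import itertools

import numpy as np
import pytest

from rnnimean import (
    Move,
    RankedTree,
    TreeError,
    apply_move,
    bfs_distance,
    count_ranked_trees,
    diameter,
    distance,
    enumerate_space,
    findpath,
    neighbours,
    random_ranked_tree,
)
from rnnimean.rnni import MoveError

from conftest import all_pairs_bfs


class TestApplyMove:
    def test_rank_move_swaps_clusters(self, balanced4):
        out = apply_move(balanced4, Move("rank", 1))
        assert out.clusters == (
            frozenset("CD"),
            frozenset("AB"),
            frozenset("ABCD"),
        )

    def test_rank_move_on_adjacent_pair_fails(self, balanced4):
        # {C,D} is the root's child: adjacent pair
        with pytest.raises(MoveError):
            apply_move(balanced4, Move("rank", 2))

    def test_nni_on_non_adjacent_pair_fails(self, balanced4):
        with pytest.raises(MoveError):
            apply_move(balanced4, Move("nni", 1))

    def test_nni_both_variants_on_caterpillar(self, caterpillar4):
        # moving C down next to A or B, depending on variant
        outs = {
            apply_move(caterpillar4, Move("nni", 1, v)).clusters[:2]
            for v in (0, 1)
        }
        assert outs == {
            (frozenset("AC"), frozenset("ABC")),
            (frozenset("BC"), frozenset("ABC")),
        }

    def test_nni_outcomes_are_neighbours(self, caterpillar4):
        nbrs = neighbours(caterpillar4)
        for v in (0, 1):
            out = apply_move(caterpillar4, Move("nni", 1, v))
            assert out in nbrs

    def test_moves_are_invertible(self, graph4):
        trees, _, _ = graph4
        for t in trees:
            for mv in [Move("rank", 1), Move("nni", 1, 0), Move("nni", 2, 1)]:
                try:
                    u = apply_move(t, mv)
                except MoveError:
                    continue
                assert t in neighbours(u)

    def test_out_of_range_rank(self, balanced4):
        with pytest.raises(MoveError):
            apply_move(balanced4, Move("rank", 3))


class TestNeighbours:
    def test_three_leaf_space_is_a_triangle(self):
        trees = enumerate_space(["A", "B", "C"])
        assert len(trees) == 3
        for t in trees:
            assert neighbours(t) == set(trees) - {t}

    def test_balanced4_has_three_neighbours(self, balanced4, graph4):
        nbrs = neighbours(balanced4)
        assert len(nbrs) == 3
        # brute-force adjacency over the full space agrees
        trees, index, adjacency = graph4
        expected = {trees[j] for j in adjacency[index[balanced4]]}
        assert nbrs == expected

    def test_caterpillar4_has_four_neighbours(self, caterpillar4):
        assert len(neighbours(caterpillar4)) == 4  # 2(n-2)

    def test_two_leaves_no_neighbours(self):
        assert neighbours(RankedTree([{"A", "B"}])) == set()

    @pytest.mark.parametrize("n", [4, 6, 8, 10])
    def test_size_bounds_and_symmetry(self, n):
        rng = np.random.default_rng(n)
        taxa = [f"t{i}" for i in range(n)]
        for _ in range(25):
            t = random_ranked_tree(taxa, rng)
            nbrs = neighbours(t)
            assert n - 2 <= len(nbrs) <= 2 * (n - 2)
            assert t not in nbrs
            for u in nbrs:
                assert t in neighbours(u)

    def test_all_neighbours_valid(self):
        rng = np.random.default_rng(0)
        taxa = [f"t{i}" for i in range(7)]
        for _ in range(20):
            t = random_ranked_tree(taxa, rng)
            for u in neighbours(t):
                RankedTree(u.clusters)  # full validation


class TestFindPath:
    def test_identity_path(self, balanced4):
        path = findpath(balanced4, balanced4)
        assert len(path) == 0
        assert path.trees == [balanced4]

    def test_three_leaf_pairs_have_length_one(self):
        trees = enumerate_space(["A", "B", "C"])
        for a, b in itertools.combinations(trees, 2):
            assert len(findpath(a, b)) == 1

    def test_path_endpoints_and_step_validity(self, graph5):
        trees, _, _ = graph5
        rng = np.random.default_rng(3)
        for _ in range(50):
            a, b = (trees[i] for i in rng.integers(len(trees), size=2))
            path = findpath(a, b)
            assert path.src == a and path.dst == b
            path.validate()
            for t, u in zip(path.trees, path.trees[1:]):
                assert u in neighbours(t)

    def test_taxon_mismatch(self, balanced4):
        other = RankedTree([{"A", "B"}, {"A", "B", "X"}])
        with pytest.raises(TreeError):
            findpath(balanced4, other)

    def test_cluster_property_small(self, graph5):
        trees, _, _ = graph5
        rng = np.random.default_rng(11)
        for _ in range(50):
            a, b = (trees[i] for i in rng.integers(len(trees), size=2))
            shared = set(a.clusters) & set(b.clusters)
            for t in findpath(a, b).trees:
                assert shared <= set(t.clusters)

    def test_serialisation(self, caterpillar4, balanced4):
        path = findpath(caterpillar4, balanced4)
        assert "Begin trees" in path.to_nexus()
        listing = path.move_listing()
        assert len(listing.splitlines()) == len(path)


class TestDistance:
    def test_zero_iff_equal(self, balanced4, caterpillar4):
        assert distance(balanced4, balanced4) == 0
        assert distance(balanced4, caterpillar4) > 0

    def test_one_move_distance(self, graph5):
        trees, _, _ = graph5
        rng = np.random.default_rng(5)
        for _ in range(30):
            t = trees[rng.integers(len(trees))]
            for u in neighbours(t):
                assert distance(t, u) == 1

    def test_matches_bfs_on_all_n4_pairs(self, graph4):
        trees, _, adjacency = graph4
        assert len(trees) == 18
        for i, t in enumerate(trees):
            dist = all_pairs_bfs(adjacency, i)
            for j, u in enumerate(trees):
                assert distance(t, u) == dist[j]

    def test_symmetry_random_n8(self):
        rng = np.random.default_rng(17)
        taxa = [f"t{i}" for i in range(8)]
        for _ in range(50):
            a = random_ranked_tree(taxa, rng)
            b = random_ranked_tree(taxa, rng)
            assert distance(a, b) == distance(b, a)

    def test_length_equals_findpath(self, graph5):
        trees, _, _ = graph5
        rng = np.random.default_rng(23)
        for _ in range(50):
            a, b = (trees[i] for i in rng.integers(len(trees), size=2))
            assert distance(a, b) == len(findpath(a, b))


class TestBfsOracle:
    def test_three_leaf(self):
        trees = enumerate_space(["A", "B", "C"])
        assert bfs_distance(trees[0], trees[1]) == 1
        assert bfs_distance(trees[0], trees[0]) == 0

    def test_refuses_large_n(self):
        taxa = [f"t{i}" for i in range(9)]
        rng = np.random.default_rng(0)
        a = random_ranked_tree(taxa, rng)
        b = random_ranked_tree(taxa, rng)
        with pytest.raises(ValueError, match="refuse"):
            bfs_distance(a, b)


class TestEnumerate:
    @pytest.mark.parametrize("n,count", [(3, 3), (4, 18), (5, 180)])
    def test_counts(self, n, count):
        taxa = [f"t{i}" for i in range(n)]
        trees = enumerate_space(taxa)
        assert len(trees) == count == count_ranked_trees(n)
        assert len(set(trees)) == count

    def test_all_enumerated_trees_valid(self):
        for t in enumerate_space(["A", "B", "C", "D"]):
            RankedTree(t.clusters)  # full validation

    def test_refuses_large_n(self):
        with pytest.raises(ValueError):
            enumerate_space([f"t{i}" for i in range(8)])


class TestDiameter:
    def test_n2_unique_tree(self):
        assert diameter(2) == 0

    @pytest.mark.parametrize("n", [3, 4, 5])
    def test_closed_form_matches_bfs(self, n):
        assert diameter(n) == diameter(n, method="bfs") == (n - 1) * (n - 2) // 2

    def test_n6_closed_form_achieved(self):
        # caterpillar vs reversed caterpillar realises the closed form;
        # (full all-pairs BFS at n=6 confirms equality, see acceptance run)
        taxa = [f"t{i}" for i in range(6)]
        cat = RankedTree(
            [frozenset(taxa[: i + 2]) for i in range(5)], validate=False
        )
        rev = RankedTree(
            [frozenset(taxa[::-1][: i + 2]) for i in range(5)], validate=False
        )
        assert distance(cat, rev) == diameter(6) == 10


class TestComplexity:
    def test_distance_scales_quadratically(self):
        """Runtime fit: quadratic term dominates cubic on n = 20..100."""
        import time

        sizes = [20, 40, 60, 80, 100]
        times = []
        for n in sizes:
            rng = np.random.default_rng(n)
            taxa = [f"t{i}" for i in range(n)]
            pairs = [
                (random_ranked_tree(taxa, rng), random_ranked_tree(taxa, rng))
                for _ in range(3)
            ]
            start = time.perf_counter()
            for a, b in pairs:
                distance(a, b)
            times.append((time.perf_counter() - start) / len(pairs))
        # fit t = a*n^2 and t = a*n^3; the quadratic model must explain the
        # growth better (smaller relative residual)
        x = np.array(sizes, dtype=float)
        y = np.array(times)
        res2 = np.linalg.lstsq(np.vstack([x**2]).T, y, rcond=None)[1]
        res3 = np.linalg.lstsq(np.vstack([x**3]).T, y, rcond=None)[1]
        assert res2[0] < res3[0]
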