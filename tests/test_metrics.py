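import itertools
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from banksy import (
    ClusterPartition,
    ari,
    build_knn,
    consensus_match,
    metagene_score,
    ncc,
    smooth_labels,
)
from banksy.metrics import contingency


class TestNCC:
    def test_separated_clusters_zero_off_diagonal(self):
        coords = np.vstack(
            [np.column_stack([np.arange(5.0), np.zeros(5)]),
             np.column_stack([np.arange(5.0) + 100, np.zeros(5)])]
        )
        labels = np.array([0] * 5 + [1] * 5)
        g = build_knn(coords, k=2)
        mat, clusters = ncc(ClusterPartition(labels), g)
        assert clusters == [0, 1]
        np.testing.assert_allclose(np.diag(mat), 1.0)
        assert mat[0, 1] == 0.0 and mat[1, 0] == 0.0

    def test_six_cell_line_hand_enumeration(self):
        # cells at x = 1..6, k = 1, A = {0,1,2}, B = {3,4,5}.
        # Directed nearest-neighbor edges (distance ties -> lower index):
        # 0->1, 1->0, 2->1, 3->2, 4->3, 5->4.
        # From B: one edge into A (3->2), two within B => NCC[B, A] = 1/2.
        coords = np.column_stack([np.arange(1.0, 7.0), np.zeros(6)])
        labels = np.array([0, 0, 0, 1, 1, 1])
        g = build_knn(coords, k=1)
        mat, _ = ncc(ClusterPartition(labels), g)
        assert mat[1, 0] == pytest.approx(0.5)
        assert mat[0, 1] == pytest.approx(0.0)  # no edge from A into B
        np.testing.assert_allclose(np.diag(mat), 1.0)

    def test_matches_direct_edge_count_oracle(self, rng):
        coords = rng.uniform(0, 10, (60, 2))
        labels = rng.integers(0, 4, 60)
        g = build_knn(coords, k=5)
        mat, clusters = ncc(ClusterPartition(labels), g)
        for ri, r in enumerate(clusters):
            denom = sum(
                labels[v] == r for u in np.flatnonzero(labels == r) for v in g.neighbors[u]
            )
            for qi, q in enumerate(clusters):
                num = sum(
                    labels[v] == q for u in np.flatnonzero(labels == r) for v in g.neighbors[u]
                )
                assert mat[ri, qi] == pytest.approx(num / denom)

    def test_invariant_to_relabeling_and_reordering(self, rng):
        coords = rng.uniform(0, 10, (40, 2))
        labels = rng.integers(0, 3, 40)
        g = build_knn(coords, k=4)
        mat1, _ = ncc(ClusterPartition(labels), g)
        # relabel clusters 0,1,2 -> 10,11,12 (order-preserving): same matrix
        mat2, _ = ncc(ClusterPartition(labels + 10), g)
        np.testing.assert_allclose(mat1, mat2)
        perm = rng.permutation(40)
        g_perm = build_knn(coords[perm], k=4)
        mat3, _ = ncc(ClusterPartition(labels[perm]), g_perm)
        np.testing.assert_allclose(mat1, mat3)

    def test_isolated_cluster_yields_nan_row(self):
        # the single B cell's nearest neighbor is in A, so B has no
        # within-cluster edges and its NCC row is undefined
        coords = np.array([[0.0, 0], [1.0, 0], [2.0, 0]])
        labels = np.array([0, 0, 1])
        g = build_knn(coords, k=1)
        with pytest.warns(UserWarning, match="undefined"):
            mat, clusters = ncc(ClusterPartition(labels), g)
        assert np.isnan(mat[1]).all()
        assert not np.isnan(mat[0]).any()


def brute_force_assignment(M):
    """Factorial oracle: best injective row->column assignment by overlap."""
    n_rows, n_cols = M.shape
    best = -1
    k = min(n_rows, n_cols)
    for rows in itertools.permutations(range(n_rows), k):
        for cols in itertools.permutations(range(n_cols), k):
            total = sum(M[r, c] for r, c in zip(rows, cols))
            best = max(best, total)
    return best


class TestConsensus:
    def test_identical_partitions_identity_mapping(self):
        labels = np.array([0, 0, 1, 1, 2])
        a, b = ClusterPartition(labels), ClusterPartition(labels.copy())
        mapping, total, relabeled = consensus_match(a, b)
        assert mapping == {0: 0, 1: 1, 2: 2}
        assert total == 5
        np.testing.assert_array_equal(relabeled.labels, labels)

    def test_two_by_two_contingency(self):
        # contingency [[5,0],[1,4]]: diagonal matching, total overlap 9
        a = ClusterPartition(np.array([0] * 5 + [1] * 5))
        b = ClusterPartition(np.array([0] * 5 + [0] + [1] * 4))
        mapping, total, _ = consensus_match(a, b)
        assert mapping == {0: 0, 1: 1}
        assert total == 9

    def test_matches_factorial_oracle(self, rng):
        la = rng.integers(0, 4, 50)
        lb = rng.integers(0, 3, 50)
        a, b = ClusterPartition(la), ClusterPartition(lb)
        M, _, _ = contingency(a, b)
        assert M.shape == (4, 3)
        _, total, _ = consensus_match(a, b)
        assert total == brute_force_assignment(M)

    def test_unmatched_clusters_get_fresh_labels(self):
        a = ClusterPartition(np.array([0, 0, 1, 1]))
        b = ClusterPartition(np.array([0, 0, 1, 2]))
        mapping, _, relabeled = consensus_match(a, b)
        assert set(mapping.values()) <= {0, 1}
        assert relabeled.n_clusters == 3
        assert max(relabeled.labels) == 2  # fresh label above a's range

    def test_disjoint_cell_sets_raise(self):
        with pytest.raises(ValueError, match="different cell sets"):
            consensus_match(ClusterPartition(np.zeros(3, int)), ClusterPartition(np.zeros(4, int)))


class TestMetagene:
    def test_identical_sets_score_zero(self, rng):
        expr = rng.normal(0, 1, (4, 30))
        expr[2] = expr[0]
        expr[3] = expr[1]
        genes = ["a", "b", "c", "d"]
        score = metagene_score(expr, genes, up_in_1=["a", "b"], up_in_2=["c", "d"])
        np.testing.assert_allclose(score, 0.0, atol=1e-9)

    def test_single_gene_arithmetic(self):
        # z-values (+2, -1) for the two genes in one cell -> score 2 - (-1) = 3
        expr = np.array([[2.0], [-1.0]])
        score = metagene_score(expr, ["up2", "up1"], up_in_1=["up1"], up_in_2=["up2"],
                               zscale=False)
        assert score[0] == pytest.approx(3.0)

    def test_matches_mean_difference_oracle(self, rng):
        expr = rng.normal(0, 1, (6, 25))
        genes = [f"g{i}" for i in range(6)]
        s1, s2 = ["g0", "g1", "g2"], ["g3", "g4"]
        score = metagene_score(expr, genes, up_in_1=s1, up_in_2=s2)
        z = (expr - expr.mean(axis=1, keepdims=True)) / expr.std(axis=1, keepdims=True)
        oracle = z[[3, 4]].mean(axis=0) - z[[0, 1, 2]].mean(axis=0)
        np.testing.assert_allclose(score, oracle, atol=1e-9)

    @pytest.mark.parametrize(
        "s1,s2,msg",
        [([], ["g1"], "nonempty"), (["g0"], ["g0"], "disjoint"), (["g9"], ["g1"], "not in")],
    )
    def test_invalid_gene_sets(self, rng, s1, s2, msg):
        expr = rng.normal(0, 1, (3, 10))
        with pytest.raises(ValueError, match=msg):
            metagene_score(expr, ["g0", "g1", "g2"], up_in_1=s1, up_in_2=s2)


def smoothing_oracle(labels, neighbors, rounds, threshold):
    """Plain round-by-round re-implementation of the smoothing rule."""
    current = list(labels)
    for _ in range(rounds):
        new = list(current)
        for u in range(len(current)):
            counts = Counter(current[v] for v in neighbors[u] if current[v] != current[u])
            if not counts:
                continue
            (top_label, top_count), *rest = counts.most_common()
            tied = sum(1 for _, c in counts.items() if c == top_count) > 1
            if top_count > threshold and not tied:
                new[u] = top_label
        current = new
    return np.asarray(current)


class TestSmoothLabels:
    def test_homogeneous_labels_unchanged(self, rng):
        coords = rng.uniform(0, 10, (40, 2))
        g = build_knn(coords, k=15)
        labels = np.zeros(40, dtype=int)
        out = smooth_labels(ClusterPartition(labels), g)
        np.testing.assert_array_equal(out.labels, labels)

    def test_single_outlier_flipped_first_round(self, rng):
        coords = rng.uniform(0, 1, (16, 2))
        g = build_knn(coords, k=15)
        labels = np.zeros(16, dtype=int)
        labels[7] = 1
        out = smooth_labels(ClusterPartition(labels), g, rounds=1)
        assert out.labels[7] == 0
        assert np.all(out.labels == 0)

    def test_matches_round_by_round_oracle(self, rng):
        coords = rng.uniform(0, 6, (120, 2))
        g = build_knn(coords, k=15)
        labels = rng.integers(0, 2, 120)
        for rounds in (1, 3):
            out = smooth_labels(ClusterPartition(labels), g, rounds=rounds)
            expected = smoothing_oracle(labels, g.neighbors, rounds, 8)
            np.testing.assert_array_equal(out.labels, expected)

    def test_noise_contraction(self, rng):
        # two clean half-planes with sprinkled label noise: each round can
        # only shrink the disagreement with the clean field
        coords = rng.uniform(0, 10, (200, 2))
        clean = (coords[:, 0] > 5).astype(int)
        noisy = clean.copy()
        flip = rng.choice(200, 12, replace=False)
        noisy[flip] = 1 - noisy[flip]
        g = build_knn(coords, k=15)
        prev_err = (noisy != clean).sum()
        labels = noisy
        for _ in range(3):
            labels = smooth_labels(ClusterPartition(labels), g, rounds=1).labels
            err = (labels != clean).sum()
            assert err <= prev_err
            prev_err = err

    def test_tie_keeps_original_label(self):
        # center cell sees 1 and 2 equally often above no threshold; with
        # flip_threshold=0 a tie still keeps the original label
        coords = np.array([[0.0, 0], [1.0, 0], [-1.0, 0], [0.0, 1], [0.0, -1]])
        labels = np.array([0, 1, 1, 2, 2])
        g = build_knn(coords, k=4)
        out = smooth_labels(ClusterPartition(labels), g, rounds=1, flip_threshold=0)
        assert out.labels[0] == 0


def ari_pair_counting_oracle(a, b):
    """ARI from scratch by enumerating all cell pairs."""
    n = len(a)
    both = same_a = same_b = 0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            pairs += 1
            sa, sb = a[i] == a[j], b[i] == b[j]
            same_a += sa
            same_b += sb
            both += sa and sb
    expected = same_a * same_b / pairs
    max_index = (same_a + same_b) / 2
    if max_index == expected:
        return 1.0
    return (both - expected) / (max_index - expected)


class TestARI:
    def test_identical_partitions(self, rng):
        labels = rng.integers(0, 5, 30)
        assert ari(labels, labels.copy()) == pytest.approx(1.0)

    def test_singletons_vs_one_cluster(self):
        a = np.arange(20)
        b = np.zeros(20, dtype=int)
        assert ari(a, b) == pytest.approx(0.0)

    def test_matches_pair_counting_oracle(self, rng):
        a = rng.integers(0, 4, 50)
        b = rng.integers(0, 3, 50)
        assert ari(a, b) == pytest.approx(ari_pair_counting_oracle(a, b), abs=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_symmetry_property(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 4, 40)
        b = rng.integers(0, 4, 40)
        assert ari(a, b) == pytest.approx(ari(b, a), abs=1e-12)
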