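"""Uncentered-Pearson clustering: correlation, merge order, purity extraction."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import cosine as scipy_cosine, squareform

from paxms.clustering import (
    Dendrogram,
    bait_pure_clusters,
    distance_matrix,
    hierarchical_cluster,
    single_bait_interactors,
    uncentered_pearson,
    write_cdt_gtr,
)
from paxms.identifications import CountMatrix


def mean_matrix(values, proteins, baits):
    df = pd.DataFrame(values, index=pd.Index(proteins, name="protein"), columns=baits)
    return CountMatrix(df.astype(float), "replicate_mean")


def oracle_agglomerate(d: np.ndarray, linkage: str = "average"):
    """Brute-force agglomerative oracle recomputing linkage from member sets.

    Cluster distances are recomputed from the original matrix at every step
    (no Lance-Williams updates); ties break on the lowest contained leaf
    indices, as the implementation specifies.
    """
    n = d.shape[0]
    clusters: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    next_id = n
    merges = []
    while len(clusters) > 1:
        best = None
        for a in clusters:
            for b in clusters:
                if a >= b:
                    continue
                pair_d = [d[i, j] for i in clusters[a] for j in clusters[b]]
                if linkage == "average":
                    dd = float(np.mean(pair_d))
                elif linkage == "single":
                    dd = float(np.min(pair_d))
                else:
                    dd = float(np.max(pair_d))
                la, lb = sorted((min(clusters[a]), min(clusters[b])))
                key = (dd, la, lb)
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        if min(clusters[a]) > min(clusters[b]):
            a, b = b, a
        merges.append((a, b, best[0][0]))
        clusters[next_id] = clusters.pop(a) | clusters.pop(b)
        next_id += 1
    return merges


def random_distance_matrix(rng, n):
    profiles = rng.random((n, 4)) + 0.05
    norms = np.linalg.norm(profiles, axis=1, keepdims=True)
    unit = profiles / norms
    d = 1.0 - unit @ unit.T
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2


class TestUncenteredPearson:
    def test_identity(self):
        assert uncentered_pearson([3, 1, 4], [3, 1, 4]) == pytest.approx(1.0)

    def test_orthogonal(self):
        assert uncentered_pearson([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        # rms about zero is sqrt(2.5) for both; r = (2 + 2) / (2 * 2.5)
        assert uncentered_pearson([1, 2], [2, 1]) == pytest.approx(0.8)

    def test_all_zero_profile_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            uncentered_pearson([0, 0], [1, 2])

    def test_scale_invariance_and_bounds(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            x = rng.normal(size=5)
            y = rng.normal(size=5)
            r = uncentered_pearson(x, y)
            assert -1.0 <= r <= 1.0
            a, b = rng.uniform(0.1, 10, size=2)
            assert uncentered_pearson(a * x, b * y) == pytest.approx(r)

    def test_agrees_with_cosine_similarity(self):
        # uncentered Pearson is the cosine of the profile angle
        rng = np.random.default_rng(12)
        for _ in range(50):
            x, y = rng.normal(size=(2, 6))
            assert uncentered_pearson(x, y) == pytest.approx(1.0 - scipy_cosine(x, y))


class TestDistanceMatrix:
    def test_identical_and_orthogonal_rows(self):
        m = mean_matrix([[1, 0], [2, 0], [0, 3]], ["p1", "p2", "p3"], ["A", "B"])
        labels, d = distance_matrix(m)
        assert labels == ["p1", "p2", "p3"]
        assert d[0, 1] == pytest.approx(0.0)
        assert d[0, 2] == pytest.approx(1.0)
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0.0)

    def test_hand_computed_distance(self):
        m = mean_matrix([[1, 2], [2, 1]], ["p1", "p2"], ["A", "B"])
        _, d = distance_matrix(m)
        assert d[0, 1] == pytest.approx(0.2)

    def test_all_zero_row_error_names_protein(self):
        m = mean_matrix([[1, 2], [0, 0]], ["p1", "dead"], ["A", "B"])
        with pytest.raises(ValueError, match="dead"):
            distance_matrix(m)


class TestHierarchicalCluster:
    def test_forced_merge_order(self):
        d = np.array([[0.0, 0.1, 0.9], [0.1, 0.0, 0.9], [0.9, 0.9, 0.0]])
        dend = hierarchical_cluster(d, labels=["A", "B", "C"])
        assert dend.merges[0][:2] == (0, 1)
        assert dend.merges[0][2] == pytest.approx(0.1)
        assert dend.merges[1][2] == pytest.approx(0.9)

    def test_equidistant_tie_break_lowest_leaf_index(self):
        d = np.full((3, 3), 0.5)
        np.fill_diagonal(d, 0.0)
        dend = hierarchical_cluster(d)
        assert dend.merges[0][:2] == (0, 1)

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_cluster(np.zeros((1, 1)))

    @pytest.mark.parametrize("linkage", ["average", "single", "complete"])
    def test_merge_sequence_matches_brute_force_oracle(self, linkage):
        rng = np.random.default_rng(2012)
        for _ in range(200):
            n = int(rng.integers(3, 11))
            d = random_distance_matrix(rng, n)
            dend = hierarchical_cluster(d, linkage=linkage)
            oracle = oracle_agglomerate(d, linkage)
            assert [m[:2] for m in dend.merges] == [m[:2] for m in oracle]
            assert np.allclose([m[2] for m in dend.merges], [m[2] for m in oracle])

    def test_average_merge_heights_non_decreasing(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            d = random_distance_matrix(rng, int(rng.integers(3, 12)))
            heights = [m[2] for m in hierarchical_cluster(d).merges]
            assert all(b >= a - 1e-12 for a, b in zip(heights, heights[1:]))

    def test_merge_heights_match_scipy_average_linkage(self):
        rng = np.random.default_rng(99)
        for _ in range(25):
            d = random_distance_matrix(rng, 8)
            ours = sorted(m[2] for m in hierarchical_cluster(d).merges)
            theirs = sorted(sch.linkage(squareform(d, checks=False), method="average")[:, 2])
            assert np.allclose(ours, theirs)

    def test_leaf_order_is_a_permutation(self):
        rng = np.random.default_rng(5)
        d = random_distance_matrix(rng, 9)
        dend = hierarchical_cluster(d)
        assert sorted(dend.leaf_order()) == list(range(9))


class TestSingleBaitInteractors:
    def test_selection_rules(self):
        m = mean_matrix(
            [[2.5, 0, 0], [2.0, 1.0, 0], [0, 0, 0]],
            ["solo", "double", "silent"],
            ["SOS1", "Epsin1", "Control"],
        )
        assign = single_bait_interactors(m)
        assert assign == {"solo": "SOS1"}

    def test_threshold_is_strict(self):
        m = mean_matrix([[0.5, 0.5]], ["p"], ["A", "B"])
        assert single_bait_interactors(m, tau=0.5) == {}
        m2 = mean_matrix([[0.6, 0.5]], ["p"], ["A", "B"])
        assert single_bait_interactors(m2, tau=0.5) == {"p": "A"}

    def test_control_counts_as_a_bait_column(self):
        m = mean_matrix([[0, 0, 3.0]], ["p"], ["A", "B", "Control"])
        assert single_bait_interactors(m) == {"p": "Control"}


class TestBaitPureClusters:
    @staticmethod
    def _cluster(values, proteins, baits, assign):
        m = mean_matrix(values, proteins, baits)
        labels, d = distance_matrix(m)
        dend = hierarchical_cluster(d, labels=labels)
        return bait_pure_clusters(dend, assign), dend

    def test_separated_groups_recovered_exactly(self):
        values = [[5, 0, 0, 0], [4, 0, 0, 0], [0, 3, 0, 0], [0, 2, 0, 0],
                  [0, 0, 7, 0], [0, 0, 0, 1]]
        proteins = [f"p{i}" for i in range(6)]
        assign = {"p0": "A", "p1": "A", "p2": "B", "p3": "B", "p4": "C", "p5": "D"}
        clusters, _ = self._cluster(values, proteins, ["A", "B", "C", "D"], assign)
        assert sorted((b, tuple(sorted(ps))) for b, ps in clusters) == [
            ("A", ("p0", "p1")), ("B", ("p2", "p3")), ("C", ("p4",)), ("D", ("p5",)),
        ]

    def test_uniform_label_yields_single_root_cluster(self):
        values = [[5, 1], [4, 2], [3, 1]]
        assign = {p: "A" for p in ["p0", "p1", "p2"]}
        clusters, _ = self._cluster(values, ["p0", "p1", "p2"], ["A", "B"], assign)
        assert len(clusters) == 1
        assert sorted(clusters[0][1]) == ["p0", "p1", "p2"]

    def test_alternating_labels_give_singletons(self):
        d = np.array([[0.0, 0.2, 0.4], [0.2, 0.0, 0.4], [0.4, 0.4, 0.0]])
        dend = hierarchical_cluster(d, labels=["x", "y", "z"])
        clusters = bait_pure_clusters(dend, {"x": "A", "y": "B", "z": "A"})
        assert all(len(ps) == 1 for _, ps in clusters)
        assert len(clusters) == 3

    def test_each_leaf_in_exactly_one_cluster(self):
        rng = np.random.default_rng(17)
        d = random_distance_matrix(rng, 10)
        labels = [f"p{i}" for i in range(10)]
        dend = hierarchical_cluster(d, labels=labels)
        assign = {l: ("A" if i % 3 else "B") for i, l in enumerate(labels)}
        clusters = bait_pure_clusters(dend, assign)
        seen = [p for _, ps in clusters for p in ps]
        assert sorted(seen) == sorted(labels)

    def test_unassigned_leaf_rejected(self):
        d = np.array([[0.0, 0.5], [0.5, 0.0]])
        dend = hierarchical_cluster(d, labels=["a", "b"])
        with pytest.raises(ValueError, match="unassigned"):
            bait_pure_clusters(dend, {"a": "A"})


class TestCdtGtr:
    def test_two_leaf_tree_single_node_row(self, tmp_path):
        m = mean_matrix([[1, 0], [0, 1]], ["p1", "p2"], ["A", "B"])
        labels, d = distance_matrix(m)
        dend = hierarchical_cluster(d, labels=labels)
        cdt, gtr = write_cdt_gtr(m, dend, tmp_path / "t")
        gtr_lines = open(gtr).read().splitlines()
        assert len(gtr_lines) == 1
        assert gtr_lines[0].startswith("NODE1X\tGENE0X\tGENE1X\t")

    def test_similarity_is_one_minus_distance(self, tmp_path):
        m = mean_matrix([[5, 0, 0], [4, 0, 0], [0, 0, 3]], ["a", "b", "c"], ["A", "B", "C"])
        labels, d = distance_matrix(m)
        dend = hierarchical_cluster(d, labels=labels)
        _, gtr = write_cdt_gtr(m, dend, tmp_path / "t")
        sims = [float(l.split("\t")[3]) for l in open(gtr).read().splitlines()]
        assert sims[0] == pytest.approx(1.0)  # identical-direction pair merges first
        assert sims[1] == pytest.approx(0.0)

    def test_cdt_rows_follow_dendrogram_leaf_order(self, tmp_path):
        rng = np.random.default_rng(23)
        vals = rng.random((6, 3)) + 0.1
        m = mean_matrix(vals, [f"p{i}" for i in range(6)], ["A", "B", "C"])
        labels, d = distance_matrix(m)
        dend = hierarchical_cluster(d, labels=labels)
        cdt, _ = write_cdt_gtr(m, dend, tmp_path / "t")
        rows = [l.split("\t")[1] for l in open(cdt).read().splitlines()[2:]]
        assert rows == dend.leaf_labels_in_order()
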