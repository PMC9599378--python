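import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acam import (
    ConsensusGraph,
    Partition,
    ari,
    consensus_adjacency,
    representative_clusters,
    restrict_to_markers,
    run_clusterings,
    select_diverse,
)
from acam.io_preprocess import ExpressionMatrix

from conftest import random_partition
from oracles import (
    brute_force_ari,
    brute_force_consensus_edges,
    brute_force_min_variance_row,
    brute_force_row_variances,
)


def make_partition(labels, name="p"):
    return Partition(
        assignment={f"c{i}": l for i, l in enumerate(labels)}, method_name=name
    )


class TestAri:
    def test_self_agreement_is_one(self):
        p = make_partition([0, 0, 1, 2, 1])
        assert ari(p, p) == 1.0

    def test_against_all_in_one_is_zero(self):
        p = make_partition([0, 0, 1, 1])
        q = make_partition([0, 0, 0, 0])
        assert ari(p, q) == pytest.approx(0.0, abs=1e-12)

    def test_crossed_pairs_match_pair_counting(self):
        p = make_partition([0, 0, 1, 1])  # {ab|cd}
        q = make_partition([0, 1, 0, 1])  # {ac|bd}
        expected = brute_force_ari([0, 0, 1, 1], [0, 1, 0, 1])
        assert ari(p, q) == pytest.approx(expected, abs=1e-12)

    def test_mismatched_cells_raise(self):
        p = make_partition([0, 1])
        q = Partition(assignment={"x": 0, "y": 1}, method_name="q")
        with pytest.raises(ValueError, match="different cell sets"):
            ari(p, q)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_brute_force_and_is_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 31))
        cells = [f"c{i}" for i in range(n)]
        p, q = random_partition(rng, cells), random_partition(rng, cells)
        order = sorted(cells)
        expected = brute_force_ari(
            [p.assignment[c] for c in order], [q.assignment[c] for c in order]
        )
        assert ari(p, q) == pytest.approx(expected, abs=1e-12)
        assert ari(q, p) == pytest.approx(ari(p, q), abs=1e-12)

    def test_invariant_to_label_permutation(self):
        rng = np.random.default_rng(5)
        cells = [f"c{i}" for i in range(25)]
        p, q = random_partition(rng, cells), random_partition(rng, cells)
        relabeled = Partition(
            assignment={c: f"x{v}" for c, v in q.assignment.items()},
            method_name="relabeled",
        )
        assert ari(p, relabeled) == pytest.approx(ari(p, q), abs=1e-12)


class TestSelectDiverse:
    def test_four_identical_one_dissident(self):
        rng = np.random.default_rng(11)
        base = [int(x) for x in rng.integers(0, 3, size=40)]
        dissident = [int(x) for x in rng.integers(0, 4, size=40)]
        parts = [make_partition(base, f"m{i}") for i in range(4)]
        parts.append(make_partition(dissident, "m4"))
        kept, _ = select_diverse(parts)
        expected_drop = brute_force_min_variance_row(parts)
        assert [p.method_name for p in kept] == [
            p.method_name for i, p in enumerate(parts) if i != expected_drop
        ]

    def test_all_identical_tie_removes_first(self):
        parts = [make_partition([0, 0, 1, 1, 2], f"m{i}") for i in range(3)]
        kept, _ = select_diverse(parts)
        assert [p.method_name for p in kept] == ["m1", "m2"]

    def test_output_length_and_order(self):
        rng = np.random.default_rng(2)
        cells = [f"c{i}" for i in range(30)]
        parts = [random_partition(rng, cells) for _ in range(5)]
        kept, R = select_diverse(parts)
        assert len(kept) == 4
        names = [p.method_name for p in parts]
        assert [p.method_name for p in kept] == [n for n in names if n in {p.method_name for p in kept}]
        assert np.allclose(R.values, R.values.T)
        assert np.allclose(np.diag(R.values), 1.0)

    def test_needs_three_partitions(self):
        parts = [make_partition([0, 1], f"m{i}") for i in range(2)]
        with pytest.raises(ValueError, match="at least 3"):
            select_diverse(parts)

    def test_matches_brute_force_over_random_sets(self):
        rng = np.random.default_rng(99)
        for _ in range(30):
            n = int(rng.integers(10, 40))
            cells = [f"c{i}" for i in range(n)]
            parts = [random_partition(rng, cells) for _ in range(5)]
            kept, _ = select_diverse(parts)
            removed = (
                {p.method_name for p in parts} - {p.method_name for p in kept}
            ).pop()
            idx = next(i for i, p in enumerate(parts) if p.method_name == removed)
            variances = brute_force_row_variances(parts)
            assert variances[idx] <= min(variances) + 1e-12


class TestConsensusAdjacency:
    def test_identical_partitions_give_cliques(self):
        parts = [make_partition([0, 0, 1, 1, 1], f"m{i}") for i in range(4)]
        g = consensus_adjacency(parts)
        assert g.edges == brute_force_consensus_edges(parts)
        assert sorted(map(len, g.groups)) == [2, 3]

    def test_one_method_breaks_an_edge(self):
        # three agree on {ab|cd}; the fourth splits a from b -> only c-d left
        parts = [make_partition([0, 0, 1, 1], f"m{i}") for i in range(3)]
        parts.append(make_partition([0, 1, 2, 2], "m3"))
        g = consensus_adjacency(parts)
        assert g.edges == {("c2", "c3")}

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_exhaustive_pairwise_and(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        cells = [f"c{i}" for i in range(n)]
        parts = [random_partition(rng, cells) for _ in range(4)]
        g = consensus_adjacency(parts)
        assert g.edges == brute_force_consensus_edges(parts)

    def test_no_edge_between_separated_cells(self):
        rng = np.random.default_rng(1)
        cells = [f"c{i}" for i in range(50)]
        parts = [random_partition(rng, cells) for _ in range(3)]
        g = consensus_adjacency(parts)
        for u, v in g.edges:
            assert all(p.assignment[u] == p.assignment[v] for p in parts)


class TestRepresentativeClusters:
    @staticmethod
    def cliques_graph(sizes):
        parts = []
        labels = [i for i, s in enumerate(sizes) for _ in range(s)]
        parts = [make_partition(labels, f"m{i}") for i in range(4)]
        return consensus_adjacency(parts)

    def test_size_threshold_strictly_greater(self):
        g = self.cliques_graph([30, 4])
        reps = representative_clusters(g, threshold=10, seed=0)
        assert [len(c) for c in reps.clusters] == [30]
        assert len(reps.leftover) == 4

    def test_lower_threshold_keeps_both(self):
        g = self.cliques_graph([30, 4])
        reps = representative_clusters(g, threshold=3, seed=0)
        assert sorted(len(c) for c in reps.clusters) == [4, 30]
        assert reps.leftover == set()

    def test_three_cliques_recovered_exactly(self):
        g = self.cliques_graph([20, 20, 20])
        for seed in (0, 1, 42):
            reps = representative_clusters(g, threshold=10, seed=seed)
            assert sorted(map(len, reps.clusters)) == [20, 20, 20]
            assert {frozenset(c) for c in reps.clusters} == {
                frozenset(grp) for grp in g.groups
            }

    def test_no_cluster_passing_raises(self):
        g = self.cliques_graph([4, 4])
        with pytest.raises(ValueError, match="threshold"):
            representative_clusters(g, threshold=10, seed=0)

    def test_clusters_internally_connected(self):
        rng = np.random.default_rng(8)
        # all methods agree on a 40-cell block; the rest is noise
        parts = [
            make_partition(
                [0] * 40 + [int(x) for x in rng.integers(1, 4, size=80)], f"m{m}"
            )
            for m in range(4)
        ]
        g = consensus_adjacency(parts)
        reps = representative_clusters(g, threshold=5, seed=0)
        edge_set = g.edges
        for cluster in reps.clusters:
            # BFS inside the cluster using only consensus edges
            members = sorted(cluster)
            adj = {c: set() for c in members}
            for u, v in edge_set:
                if u in adj and v in adj:
                    adj[u].add(v)
                    adj[v].add(u)
            seen, stack = {members[0]}, [members[0]]
            while stack:
                for nb in adj[stack.pop()]:
                    if nb not in seen:
                        seen.add(nb)
                        stack.append(nb)
            assert seen == set(members)


class TestRunClusterings:
    def test_blobs_recovered_by_all_backends(self, small_dataset):
        from acam import lognormalize

        raw, truth, db = small_dataset
        expr, _ = restrict_to_markers(lognormalize(raw), db)
        parts = run_clusterings(expr, seed=3)
        assert len(parts) == 5
        truth_part = Partition(
            assignment={c: truth[c] for c in expr.cell_ids}, method_name="truth"
        )
        for p in parts:
            assert ari(p, truth_part) >= 0.9, p.method_name

    def test_determinism(self, small_dataset):
        from acam import lognormalize

        raw, _, db = small_dataset
        expr, _ = restrict_to_markers(lognormalize(raw), db)
        a = run_clusterings(expr, backends=["kmeans", "gmm", "ward"], seed=5)
        b = run_clusterings(expr, backends=["kmeans", "gmm", "ward"], seed=5)
        for p, q in zip(a, b):
            assert p.assignment == q.assignment

    def test_too_few_backends_rejected(self, small_dataset):
        from acam import lognormalize

        raw, _, db = small_dataset
        expr, _ = restrict_to_markers(lognormalize(raw), db)
        with pytest.raises(ValueError, match="at least 3"):
            run_clusterings(expr, backends=["kmeans"], seed=0)


def test_purity_consensus_only_splits_never_merges():
    # partitions that refine a planted truth: every consensus group stays
    # inside one true class
    rng = np.random.default_rng(21)
    truth = [i // 30 for i in range(90)]
    parts = []
    for m in range(4):
        refinement = [t * 10 + int(rng.integers(0, 2)) for t in truth]
        parts.append(make_partition(refinement, f"m{m}"))
    g = consensus_adjacency(parts)
    for group in g.groups:
        classes = {truth[int(c[1:])] for c in group}
        assert len(classes) == 1


def test_partition_tsv_roundtrip(tmp_path):
    p = make_partition([0, 1, 1, 2], "m")
    path = tmp_path / "p.tsv"
    p.to_tsv(path)
    q = Partition.from_tsv(path, method_name="m")
    assert {c: str(v) for c, v in p.assignment.items()} == q.assignment
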