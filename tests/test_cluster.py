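"""Average-linkage clustering and the two tree-cut criteria."""

import itertools

import numpy as np
import pytest

from conftest import random_fragment
from tmmotif.cluster import (
    average_linkage,
    cut_sequence_tree,
    cut_structural_tree,
    sequence_objective,
    structural_objective,
)
from tmmotif.metrics import DistanceMatrix, dist_sequence_matrix, dist_torsion_matrix, rmsd_matrix
from tmmotif.synth import make_fragment_groups


def naive_average_linkage(values):
    """Independent O(n^3) agglomerator used as an oracle for scipy linkage."""
    n = values.shape[0]
    active = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(active) > 1:
        best = None
        for a, b in itertools.combinations(sorted(active), 2):
            d = np.mean([values[i, j] for i in active[a] for j in active[b]])
            if best is None or d < best[0] - 1e-12:
                best = (d, a, b)
        d, a, b = best
        active[next_id] = active.pop(a) + active.pop(b)
        merges.append((a, b, d))
        next_id += 1
    return merges


def partition_at(merges, n, h):
    """Union-find partition from merges with height <= h (independent of fcluster)."""
    parent = list(range(2 * n - 1))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for k, (a, b, height) in enumerate(merges):
        if height <= h + 1e-12:
            parent[find(int(a))] = n + k
            parent[find(int(b))] = n + k
    groups = {}
    for leaf in range(n):
        groups.setdefault(find(leaf), []).append(leaf)
    return sorted(groups.values())


class TestAverageLinkage:
    def test_two_leaves(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0.0, 0.4], [0.4, 0.0]]))
        dend = average_linkage(dm)
        assert dend.merges.shape == (1, 4)
        assert dend.merges[0, 2] == pytest.approx(0.4)

    def test_matches_hand_agglomeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            n = 8
            raw = rng.uniform(0.05, 1.0, size=(n, n))
            values = (raw + raw.T) / 2
            np.fill_diagonal(values, 0.0)
            dm = DistanceMatrix([f"l{i}" for i in range(n)], values)
            dend = average_linkage(dm)
            oracle = naive_average_linkage(values)
            assert np.allclose(sorted(h for _, _, h in oracle), sorted(dend.merges[:, 2]), atol=1e-9)
            # partitions agree at every merge height
            for h in dend.merges[:, 2]:
                ours = {frozenset(c) for c in dend.cut(h)}
                theirs = {frozenset(c) for c in partition_at(oracle, n, h)}
                assert ours == theirs

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        n = 10
        raw = rng.uniform(0.05, 1.0, size=(n, n))
        values = (raw + raw.T) / 2
        np.fill_diagonal(values, 0.0)
        ids = [f"l{i}" for i in range(n)]
        dend = average_linkage(DistanceMatrix(ids, values))
        perm = rng.permutation(n)
        dend_p = average_linkage(DistanceMatrix([ids[i] for i in perm], values[np.ix_(perm, perm)]))
        for h in dend.merges[:, 2]:
            a = {frozenset(ids[i] for i in c) for c in dend.cut(h)}
            b = {frozenset(dend_p.leaf_ids[i] for i in c) for c in dend_p.cut(h)}
            assert a == b

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, np.nan], [np.nan, 0.0]]))


def rand_index(labels_a, labels_b):
    agree = total = 0
    keys = list(labels_a)
    for x, y in itertools.combinations(keys, 2):
        total += 1
        agree += (labels_a[x] == labels_a[y]) == (labels_b[x] == labels_b[y])
    return agree / total


class TestStructuralCut:
    @pytest.mark.parametrize("k", [2, 3])
    def test_planted_conformer_recovery(self, k):
        frags, truth = make_fragment_groups(k, 10, seed=11)
        dend = average_linkage(dist_torsion_matrix(frags))
        cset = cut_structural_tree(dend, frags)
        planted = {f.frag_id: g for f, g in zip(frags, truth)}
        found = {fid: i for i, c in enumerate(cset.clusters) for fid in c}
        assert rand_index(planted, found) == 1.0

    def test_all_identical_single_cluster(self):
        frags, _ = make_fragment_groups(1, 6, noise_sd=0.0, seed=2)
        dend = average_linkage(dist_sequence_matrix(frags))
        cset = cut_structural_tree(dend, frags)
        assert len(cset.clusters) == 1
        assert cset.mean_rmsd[0] == pytest.approx(0.0, abs=1e-6)

    def test_objective_matches_exhaustive_enumeration(self):
        frags, _ = make_fragment_groups(3, 7, seed=5)  # n = 21 <= 30
        dend = average_linkage(dist_torsion_matrix(frags))
        ordered = [next(f for f in frags if f.frag_id == i) for i in dend.leaf_ids]
        rmsd = rmsd_matrix(ordered)
        cset = cut_structural_tree(dend, frags, rmsd=rmsd)
        brute = min(
            structural_objective(dend.cut(h), rmsd, 1.5, 2.0)
            for h in dend.candidate_heights()
        )
        assert cset.objective == pytest.approx(brute, abs=1e-9)


class TestSequenceCut:
    def test_two_tight_families(self):
        rng = np.random.default_rng(3)
        fam1 = [random_fragment(rng, 6) for _ in range(1)]
        # two families of 5: near-identical sequences within a family
        def family(seq, n):
            frags = []
            for i in range(n):
                f = random_fragment(rng, len(seq))
                f.sequence = seq
                frags.append(f)
            return frags

        frags = family("AAAWWW", 5) + family("DDDKKK", 5)
        for i, f in enumerate(frags):  # unique ids
            f.source_id = f"fam{i}"
        dend = average_linkage(dist_sequence_matrix(frags))
        cset = cut_sequence_tree(dend)
        assert sorted(len(c) for c in cset.clusters) == [5, 5]
        assert cset.outliers == []

    def test_star_like_single_cluster(self):
        n = 8
        values = np.full((n, n), 0.7)
        np.fill_diagonal(values, 0.0)
        dend = average_linkage(DistanceMatrix([f"l{i}" for i in range(n)], values))
        cset = cut_sequence_tree(dend)
        assert len(cset.clusters) == 1

    def test_single_leaf_is_outlier(self):
        from tmmotif.cluster import Dendrogram

        d = Dendrogram(["only"], np.empty((0, 4)))
        cset = cut_sequence_tree(d)
        assert len(cset.outliers) == 1

    def test_objective_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(9)
        n = 14
        raw = rng.uniform(0.05, 1.0, size=(n, n))
        values = (raw + raw.T) / 2
        np.fill_diagonal(values, 0.0)
        dend = average_linkage(DistanceMatrix([f"l{i}" for i in range(n)], values))
        cset = cut_sequence_tree(dend, min_size=4)
        brute = min(sequence_objective(dend.cut(h), 4) for h in dend.candidate_heights())
        assert cset.objective == brute

    def test_cluster_bookkeeping(self):
        """clusters / outliers / largest statistics match direct counting."""
        frags, truth = make_fragment_groups(2, 5, seed=4)
        dend = average_linkage(dist_torsion_matrix(frags))
        cset = cut_structural_tree(dend, frags)
        assert sum(len(c) for c in cset.clusters) == len(frags)
        assert len(cset.outliers) == sum(1 for c in cset.clusters if len(c) == 1)
        assert cset.largest == max(len(c) for c in cset.clusters)


def test_newick_export_roundtrips_leaves():
    frags, _ = make_fragment_groups(2, 3, seed=6)
    dend = average_linkage(dist_torsion_matrix(frags))
    nwk = dend.to_newick()
    assert nwk.endswith(";")
    for leaf in dend.leaf_ids:
        assert leaf in nwk
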