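import numpy as np
import pytest
import skbio
from skbio import TreeNode

from ovhet.cluster_phylo import (
    DistanceMatrix,
    af_distance,
    build_af_matrix,
    build_patient_tree,
    cluster_samples,
    neighbor_joining,
    tree_leaf_pairs,
)
from ovhet.variant_io import AFMatrix, Locus

from conftest import make_call, random_additive_tree


class TestBuildAFMatrix:
    def test_absent_call_is_zero(self):
        calls = [make_call("A", pos=1, depth=100, alt_reads=20)]
        mat = build_af_matrix(calls, sample_ids=["A", "B"])
        assert mat.values.tolist() == [[0.2], [0.0]]

    def test_synonymous_exclusion(self):
        calls = [
            make_call("A", pos=1, effect="synonymous"),
            make_call("A", pos=2, ref="C", alt="G", effect="vus"),
        ]
        mat = build_af_matrix(calls, exclude_synonymous=True)
        assert len(mat.loci) == 1 and mat.loci[0].pos == 2

    def test_purely_synonymous_set_errors(self):
        calls = [make_call("A", pos=1, effect="synonymous")]
        with pytest.raises(ValueError, match="no loci"):
            build_af_matrix(calls, exclude_synonymous=True)

    def test_column_count_conservation(self):
        calls = [
            make_call("A", pos=i, effect="synonymous" if i % 3 == 0 else "vus")
            for i in range(1, 20)
        ]
        full = build_af_matrix(calls)
        reduced = build_af_matrix(calls, exclude_synonymous=True)
        n_syn = sum(1 for c in calls if c.effect == "synonymous")
        assert len(reduced.loci) == len(full.loci) - n_syn


class TestClusterSamples:
    def _matrix(self, values, ids=None):
        loci = [Locus("chr1", i + 1, "A", "T") for i in range(values.shape[1])]
        ids = ids or [f"S{i}" for i in range(values.shape[0])]
        return AFMatrix(ids, loci, values)

    def test_identical_rows_merge_at_height_zero(self):
        mat = self._matrix(np.array([[0.2, 0.3], [0.2, 0.3], [0.9, 0.9]]))
        result = cluster_samples(mat)
        assert result.sample_linkage[0, 2] == pytest.approx(0.0)

    def test_k2_recovers_constructed_pairs(self):
        base = np.array([[0.0, 0.0], [0.01, 0.0], [1.0, 1.0], [1.0, 0.99]])
        mat = self._matrix(base, ids=["a1", "a2", "b1", "b2"])
        result = cluster_samples(mat, k=2)
        assert result.flat_clusters["a1"] == result.flat_clusters["a2"]
        assert result.flat_clusters["b1"] == result.flat_clusters["b2"]
        assert result.flat_clusters["a1"] != result.flat_clusters["b1"]

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(5)
        values = rng.uniform(size=(6, 10))
        ids = [f"S{i}" for i in range(6)]
        loci = [Locus("chr1", i + 1, "A", "T") for i in range(10)]
        m1 = AFMatrix(ids, loci, values)
        perm = rng.permutation(6)
        m2 = AFMatrix([ids[i] for i in perm], loci, values[perm])
        r1, r2 = cluster_samples(m1), cluster_samples(m2)
        assert r1.flat_clusters == r2.flat_clusters
        assert np.allclose(r1.sample_linkage, r2.sample_linkage)

    def test_single_sample_errors(self):
        with pytest.raises(ValueError, match=">= 2"):
            cluster_samples(self._matrix(np.array([[0.1, 0.2]])))


class TestAFDistance:
    def test_identical_samples_distance_zero(self):
        mat = AFMatrix(["A", "B"], [Locus("chr1", 1, "A", "T")], np.array([[0.4], [0.4]]))
        d = af_distance(mat)
        assert d.values[0, 1] == pytest.approx(0.0)

    def test_three_four_five(self):
        loci = [Locus("chr1", 1, "A", "T"), Locus("chr1", 2, "A", "T")]
        mat = AFMatrix(["A", "B"], loci, np.array([[0.0, 0.0], [0.3, 0.4]]))
        assert af_distance(mat, "euclidean").values[0, 1] == pytest.approx(0.5)
        assert af_distance(mat, "manhattan").values[0, 1] == pytest.approx(0.7)

    def test_triangle_inequality_random_matrices(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            values = rng.uniform(size=(4, 6))
            loci = [Locus("chr1", i + 1, "A", "T") for i in range(6)]
            d = af_distance(AFMatrix(list("ABCD"), loci, values)).values
            for i in range(4):
                for j in range(4):
                    for k in range(4):
                        assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


class TestNeighborJoining:
    def test_recovers_known_four_taxon_tree_with_outgroup(self):
        """NJ on the additive matrix of ((a:1,b:2):1,(c:3,d:4):1,(out:9));
        recovers topology and branch lengths exactly."""
        tree = TreeNode.read(["((a:1,b:2):1,(c:3,d:4):1,out:9);"])
        names = ["a", "b", "c", "d", "out"]
        tips = {t.name: t for t in tree.tips()}
        dm = np.zeros((5, 5))
        for i, x in enumerate(names):
            for j in range(i + 1, 5):
                dm[i, j] = dm[j, i] = tips[x].distance(tips[names[j]])
        nj = neighbor_joining(DistanceMatrix(names, dm))
        assert nj.compare_rfd(tree, rooted=False) == 0
        # branch lengths recovered exactly on additive input
        for name, expected in zip("abcd", (1.0, 2.0, 3.0, 4.0)):
            assert nj.find(name).length == pytest.approx(expected, abs=1e-9)

    def test_matches_reference_nj_topology(self):
        """Cross-check against scikit-bio's NJ on random additive matrices."""
        rng = np.random.default_rng(17)
        for _ in range(20):
            d, _ = random_additive_tree(rng, int(rng.integers(5, 9)))
            ours = neighbor_joining(d)
            ref = skbio.tree.nj(
                skbio.DistanceMatrix(d.values, ids=d.sample_ids)
            )
            assert ours.compare_rfd(ref, rooted=False) == 0

    def test_three_taxa_star(self):
        d = DistanceMatrix(["a", "b", "c"], np.array(
            [[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]]
        ))
        tree = neighbor_joining(d)
        assert {t.name for t in tree.tips()} == {"a", "b", "c"}
        assert tree.find("a").length == pytest.approx(1.0)
        assert tree.find("b").length == pytest.approx(2.0)
        assert tree.find("c").length == pytest.approx(3.0)

    def test_too_few_taxa_errors(self):
        d = DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError, match=">= 3"):
            neighbor_joining(d)

    def test_no_negative_branch_lengths_on_noisy_input(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            d, _ = random_additive_tree(rng, 6)
            noisy = d.values + rng.uniform(0, 0.2, d.values.shape)
            noisy = (noisy + noisy.T) / 2
            np.fill_diagonal(noisy, 0.0)
            tree = neighbor_joining(DistanceMatrix(d.sample_ids, noisy))
            for node in tree.traverse():
                if node.length is not None:
                    assert node.length >= 0.0


class TestBuildPatientTree:
    def test_outgroup_rooting_preserves_unrooted_topology(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            d, _ = random_additive_tree(rng, 7)
            unrooted = neighbor_joining(d)
            rooted = build_patient_tree(d, d.sample_ids[0])
            assert rooted.compare_rfd(unrooted, rooted=False) == 0

    def test_outgroup_is_child_of_root(self):
        rng = np.random.default_rng(37)
        d, _ = random_additive_tree(rng, 6)
        rooted = build_patient_tree(d, "t3")
        root_children_tips = [c.name for c in rooted.children if c.is_tip()]
        assert "t3" in root_children_tips

    def test_absent_outgroup_errors(self):
        rng = np.random.default_rng(41)
        d, _ = random_additive_tree(rng, 5)
        with pytest.raises(ValueError, match="outgroup"):
            build_patient_tree(d, "missing")


class TestTreeLeafPairs:
    def test_balanced_tree_has_two_cherries(self):
        tree = TreeNode.read(["((A:1,B:1):1,(C:1,D:1):1);"])
        assert tree_leaf_pairs(tree) == [("A", "B"), ("C", "D")]

    def test_caterpillar_has_single_cherry(self):
        tree = TreeNode.read(["(((A:1,B:1):1,C:1):1,D:1);"])
        assert tree_leaf_pairs(tree) == [("A", "B")]

    def test_outgroup_excluded(self):
        tree = TreeNode.read(["((A:1,B:1):1,(C:1,OUT:1):1);"])
        assert tree_leaf_pairs(tree, exclude=["OUT"]) == [("A", "B")]
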