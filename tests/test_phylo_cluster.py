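import numpy as np
import pytest

from vpseq.phylo_cluster import DistanceMatrix, cut_tree, species_tally, upgma


def dm(labels, d):
    return DistanceMatrix(labels=labels, d=np.array(d, dtype=float))


def leaf_depth(root, label, acc=0.0):
    if root.is_leaf:
        return root.height if root.label == label else None
    for ch in root.children:
        r = leaf_depth(ch, label)
        if r is not None:
            return r
    return None


def cophenetic(root):
    """Pairwise merge heights from the tree (distance = 2 * LCA height)."""
    out = {}

    def walk(nd):
        if nd.is_leaf:
            return [nd.label]
        groups = [walk(ch) for ch in nd.children]
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                for a in groups[i]:
                    for b in groups[j]:
                        out[frozenset((a, b))] = 2 * nd.height
        return [x for g in groups for x in g]

    walk(root)
    return out


class TestUpgma:
    def test_two_leaves_root_height(self):
        t = upgma(dm(["A", "B"], [[0, 0.4], [0.4, 0]]))
        assert t.height == 0.2
        assert sorted(t.leaves()) == ["A", "B"]

    def test_three_leaf_hand_example(self):
        t = upgma(dm(["A", "B", "C"], [[0, 0.2, 0.6], [0.2, 0, 0.6], [0.6, 0.6, 0]]))
        assert t.height == pytest.approx(0.3)
        inner = [ch for ch in t.children if not ch.is_leaf][0]
        assert inner.height == pytest.approx(0.1)
        assert sorted(inner.leaves()) == ["A", "B"]

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            upgma(dm(["A", "B"], [[0, 1], [2, 0]]))
        with pytest.raises(ValueError):
            upgma(dm(["A", "B"], [[0, -1], [-1, 0]]))

    def test_ultrametric_leaf_depths(self, rng):
        for _ in range(20):
            n = 6
            m = rng.random((n, n))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            t = upgma(dm([f"L{i}" for i in range(n)], m))
            # all leaves are at height 0 => root-to-leaf path height equals root height
            assert all(leaf_depth(t, f"L{i}") == 0.0 for i in range(n))

    def test_matches_scipy_average_linkage(self, rng):
        from scipy.cluster.hierarchy import cophenet, linkage
        from scipy.spatial.distance import squareform

        for _ in range(100):
            n = 6
            m = rng.random((n, n)) + 0.01
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            labels = [f"L{i}" for i in range(n)]
            t = upgma(dm(labels, m))
            ours = cophenetic(t)
            condensed = squareform(m, checks=False)
            z = linkage(condensed, method="average")
            coph = squareform(cophenet(z))
            for i in range(n):
                for j in range(i + 1, n):
                    assert ours[frozenset((labels[i], labels[j]))] == pytest.approx(coph[i, j])

    def test_newick_roundtrip_topology(self):
        import io

        from Bio import Phylo

        t = upgma(dm(["A", "B", "C"], [[0, 0.2, 0.6], [0.2, 0, 0.6], [0.6, 0.6, 0]]))
        tree = Phylo.read(io.StringIO(t.newick()), "newick")
        assert sorted(x.name for x in tree.get_terminals()) == ["A", "B", "C"]


class TestCutTree:
    @pytest.fixture
    def tree(self):
        return upgma(dm(["A", "B", "C"], [[0, 0.2, 0.6], [0.2, 0, 0.6], [0.6, 0.6, 0]]))

    def test_k_extremes(self, tree):
        assert cut_tree(tree, k=1) == [["A", "B", "C"]]
        assert cut_tree(tree, k=3) == [["A"], ["B"], ["C"]]

    def test_h_cut_hand_example(self, tree):
        assert cut_tree(tree, h=0.2) == [["A", "B"], ["C"]]

    def test_k_yields_exactly_k(self, rng):
        n = 8
        m = rng.random((n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        t = upgma(dm([f"L{i}" for i in range(n)], m))
        for k in range(1, n + 1):
            assert len(cut_tree(t, k=k)) == k

    def test_h_monotone(self, rng):
        n = 7
        m = rng.random((n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        t = upgma(dm([f"L{i}" for i in range(n)], m))
        sizes = [len(cut_tree(t, h=h)) for h in np.linspace(0, 1, 11)]
        assert sizes == sorted(sizes, reverse=True)

    def test_errors(self, tree):
        with pytest.raises(ValueError):
            cut_tree(tree, k=4)
        with pytest.raises(ValueError):
            cut_tree(tree)
        with pytest.raises(ValueError):
            cut_tree(tree, k=2, h=0.1)


class TestSpeciesTally:
    SPECIES = {"a1": "Fk", "a2": "Fk", "b1": "Lf", "c1": "Lu", "d1": "Ph",
               "d2": "Ph", "e1": "Fk", "e2": "Lf", "e3": "Lu", "e4": "Ph"}

    def test_categories(self):
        clusters = [["a1"], ["a2", "e1"], ["b1", "c1"], ["d1", "d2"],
                    ["e1", "e2", "e3", "e4"]]
        summaries, table = species_tally(clusters, self.SPECIES)
        cats = [s.category for s in summaries]
        assert cats == ["singleton", "one_species", "two_species", "one_species",
                        "all_species"]
        assert table["clusters"].sum() == len(clusters)

    def test_marginals_conserve_cluster_count(self, rng):
        ids = list(self.SPECIES)
        for _ in range(10):
            k = int(rng.integers(2, 6))
            perm = list(rng.permutation(ids))
            bounds = sorted(rng.choice(range(1, len(ids)), size=k - 1, replace=False))
            clusters, prev = [], 0
            for b in list(bounds) + [len(ids)]:
                clusters.append(perm[prev:b])
                prev = b
            clusters = [c for c in clusters if c]
            _, table = species_tally(clusters, self.SPECIES)
            assert table["clusters"].sum() == len(clusters)

    def test_unmapped_member_raises(self):
        with pytest.raises(KeyError, match="zzz"):
            species_tally([["zzz"]], self.SPECIES)
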