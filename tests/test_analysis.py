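"""Distance matrices, clustering diagnostics, NJ and UPGMA."""

import numpy as np
import pytest

import deephier as dh
from deephier.analysis import AnalysisError, DistanceMatrix


def unit_rows(a):
    return a / np.linalg.norm(a, axis=1, keepdims=True)


def random_additive_tree(n_leaves: int, rng: np.random.Generator):
    """Random unrooted binary tree with branch lengths in [0.1, 2].

    Returns (leaf names, leaf order, additive distance matrix) where matrix
    entries are leaf-to-leaf path lengths — the exactness domain of NJ.
    """
    nodes = {i: {} for i in range(3)}  # adjacency: node -> {neighbour: length}
    next_id = 3
    internal = next_id
    nodes[internal] = {}
    next_id += 1
    for leaf in range(3):
        w = float(rng.uniform(0.1, 2.0))
        nodes[leaf][internal] = w
        nodes[internal][leaf] = w
    leaves = [0, 1, 2]
    while len(leaves) < n_leaves:
        # split a random edge with a new internal node, hang a new leaf on it
        a = int(rng.choice(list(nodes)))
        b = int(rng.choice(list(nodes[a])))
        old = nodes[a].pop(b)
        nodes[b].pop(a)
        mid = next_id; next_id += 1
        leaf = next_id; next_id += 1
        f = float(rng.uniform(0.2, 0.8))
        nodes[mid] = {a: old * f, b: old * (1 - f)}
        nodes[a][mid] = old * f
        nodes[b][mid] = old * (1 - f)
        w = float(rng.uniform(0.1, 2.0))
        nodes[mid][leaf] = w
        nodes[leaf] = {mid: w}
        leaves.append(leaf)

    names = {leaf: f"t{i}" for i, leaf in enumerate(leaves)}
    n = len(leaves)
    D = np.zeros((n, n))
    for i, src in enumerate(leaves):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in nodes[u].items():
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for j, dst in enumerate(leaves):
            D[i, j] = dist[dst]
    return names, leaves, D


class TestPairwiseDistances:
    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(0)
        emb = rng.standard_normal((10, 6))
        dm = dh.pairwise_distances(emb)
        for i in range(10):
            for j in range(10):
                assert dm.matrix[i, j] == pytest.approx(
                    float(np.sqrt(np.sum((emb[i] - emb[j]) ** 2))), abs=1e-9
                )

    def test_duplicates_and_antipodes(self):
        emb = np.array([[1.0, 0.0], [1.0, 0.0], [-1.0, 0.0]])
        dm = dh.pairwise_distances(emb, ids=["a", "a2", "b"])
        assert dm.matrix[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert dm.matrix[0, 2] == pytest.approx(2.0, abs=1e-12)

    def test_invariants_on_unit_vectors(self):
        rng = np.random.default_rng(1)
        emb = unit_rows(rng.standard_normal((20, 8)))
        dm = dh.pairwise_distances(emb)
        assert np.all(dm.matrix <= 2 + 1e-9)
        np.testing.assert_allclose(dm.matrix, dm.matrix.T)
        np.testing.assert_allclose(np.diag(dm.matrix), 0)
        # triangle inequality on sampled triples
        for _ in range(50):
            i, j, k = rng.integers(0, 20, size=3)
            assert dm.matrix[i, k] <= dm.matrix[i, j] + dm.matrix[j, k] + 1e-9

    def test_single_embedding_rejected(self):
        with pytest.raises(AnalysisError):
            dh.pairwise_distances(np.ones((1, 4)))


class TestSilhouette:
    def test_tight_separated_clusters_score_high(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 0.01, size=(20, 3)) + np.array([5, 0, 0])
        b = rng.normal(0, 0.01, size=(20, 3)) - np.array([5, 0, 0])
        emb = np.vstack([a, b])
        labels = ["a"] * 20 + ["b"] * 20
        score = dh.silhouette_by_level(emb, {"family": labels})["family"]
        assert score > 0.9

    def test_random_labels_score_near_zero(self):
        rng = np.random.default_rng(3)
        emb = rng.standard_normal((300, 5))
        labels = rng.integers(0, 3, size=300)
        score = dh.silhouette_by_level(emb, {"family": labels})["family"]
        assert abs(score) < 0.1

    def test_matches_from_scratch_computation(self):
        rng = np.random.default_rng(4)
        emb = rng.standard_normal((12, 3))
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 2])
        got = dh.silhouette_by_level(emb, {"family": labels})["family"]
        # independent per-point a/b computation
        d = np.sqrt(((emb[:, None] - emb[None]) ** 2).sum(-1))
        svals = []
        for i in range(12):
            own = labels == labels[i]
            a = d[i, own & (np.arange(12) != i)].mean()
            b = min(d[i, labels == c].mean() for c in set(labels) - {labels[i]})
            svals.append((b - a) / max(a, b))
        assert got == pytest.approx(np.mean(svals), abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(AnalysisError):
            dh.silhouette_by_level(np.ones((4, 2)), {"family": ["x"] * 4})


class TestWardClustering:
    def test_k_equals_n_gives_singletons(self):
        rng = np.random.default_rng(5)
        emb = rng.standard_normal((7, 3))
        labels = dh.agglomerative_ward(emb, 7)
        assert len(set(labels)) == 7

    def test_k_one_gives_single_cluster(self):
        rng = np.random.default_rng(5)
        labels = dh.agglomerative_ward(rng.standard_normal((7, 3)), 1)
        assert set(labels) == {0}

    def test_recovers_separated_blobs(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 0.05, size=(25, 4)) + 3
        b = rng.normal(0, 0.05, size=(25, 4)) - 3
        labels = dh.agglomerative_ward(np.vstack([a, b]), 2)
        assert len(set(labels[:25])) == 1 and len(set(labels[25:])) == 1
        assert labels[0] != labels[-1]

    def test_k_out_of_range_rejected(self):
        with pytest.raises(AnalysisError):
            dh.agglomerative_ward(np.ones((4, 2)), 5)


class TestAMICurve:
    def test_k_sequence_matches_sweep_definition(self):
        rng = np.random.default_rng(7)
        emb = rng.standard_normal((120, 4))
        curve = dh.ami_curve(emb, {"family": rng.integers(0, 3, 120)},
                             k_from=2, k_to=100, step=3)
        assert curve.ks == list(range(2, 101, 3))
        assert len(curve.ks) == 33

    def test_perfect_agreement_scores_one(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 0.01, size=(15, 3)) + 5
        b = rng.normal(0, 0.01, size=(15, 3)) - 5
        emb = np.vstack([a, b])
        labels = [0] * 15 + [1] * 15
        curve = dh.ami_curve(emb, {"family": labels}, k_from=2, k_to=2, step=3)
        assert curve.scores["family"][0] == pytest.approx(1.0)

    def test_adjusted_for_chance_near_zero(self):
        from sklearn.metrics import adjusted_mutual_info_score

        rng = np.random.default_rng(9)
        scores = [
            adjusted_mutual_info_score(
                rng.integers(0, 5, 200), rng.integers(0, 5, 200)
            )
            for _ in range(50)
        ]
        assert abs(np.mean(scores)) < 0.05

    def test_truncates_k_above_n_with_warning(self):
        rng = np.random.default_rng(10)
        emb = rng.standard_normal((20, 3))
        with pytest.warns(UserWarning):
            curve = dh.ami_curve(emb, {"family": rng.integers(0, 2, 20)},
                                 k_from=2, k_to=100, step=3)
        assert curve.ks[-1] <= 20


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        # d(a,b)=3, d(a,c)=4, d(b,c)=5 -> pendant lengths 1, 2, 3
        dm = DistanceMatrix(
            ["a", "b", "c"],
            np.array([[0.0, 3, 4], [3, 0, 5], [4, 5, 0]]),
        )
        tree = dh.neighbor_joining(dm)
        lengths = {t.name: t.length for t in tree.tree.tips()}
        assert lengths["a"] == pytest.approx(1.0, abs=1e-9)
        assert lengths["b"] == pytest.approx(2.0, abs=1e-9)
        assert lengths["c"] == pytest.approx(3.0, abs=1e-9)

    def test_recovers_known_five_taxon_tree(self):
        names, leaves, D = random_additive_tree(5, np.random.default_rng(11))
        dm = DistanceMatrix([names[l] for l in leaves], D)
        tree = dh.neighbor_joining(dm)
        back = tree.tip_distances()
        order = [back.ids.index(i) for i in dm.ids]
        np.testing.assert_allclose(back.matrix[np.ix_(order, order)], D, atol=1e-9)

    def test_additive_recovery_on_random_six_leaf_trees(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            names, leaves, D = random_additive_tree(6, rng)
            dm = DistanceMatrix([names[l] for l in leaves], D)
            back = dh.neighbor_joining(dm).tip_distances()
            order = [back.ids.index(i) for i in dm.ids]
            np.testing.assert_allclose(back.matrix[np.ix_(order, order)], D, atol=1e-9)

    def test_identical_rows_become_zero_length_cherry(self):
        D = np.array(
            [[0.0, 0.0, 4, 4], [0.0, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]]
        )
        tree = dh.neighbor_joining(DistanceMatrix(["a", "b", "c", "d"], D))
        tips = {t.name: t for t in tree.tree.tips()}
        assert tips["a"].length == pytest.approx(0.0, abs=1e-12)
        assert tips["b"].length == pytest.approx(0.0, abs=1e-12)
        assert tips["a"].parent is tips["b"].parent

    def test_leaf_set_preserved_and_newick_parses(self):
        rng = np.random.default_rng(13)
        emb = unit_rows(rng.standard_normal((8, 5)))
        dm = dh.pairwise_distances(emb, ids=[f"s{i}" for i in range(8)])
        tree = dh.neighbor_joining(dm)
        assert tree.leaf_ids() == set(dm.ids)
        import io
        from skbio import TreeNode

        reparsed = TreeNode.read(io.StringIO(tree.newick()))
        assert {t.name for t in reparsed.tips()} == set(dm.ids)
        assert all(
            t.length >= 0 for t in tree.tree.traverse() if t.length is not None
        )

    def test_too_few_taxa_rejected(self):
        with pytest.raises(AnalysisError):
            dh.neighbor_joining(DistanceMatrix(["a", "b"], np.zeros((2, 2))))


class TestUPGMA:
    @staticmethod
    def ultrametric_matrix():
        # clock-like tree: ((a:1,b:1):2,(c:2,d:2):1) with heights 1, 2, 3
        D = np.array(
            [
                [0.0, 2, 6, 6],
                [2, 0, 6, 6],
                [6, 6, 0, 4],
                [6, 6, 4, 0],
            ]
        )
        return DistanceMatrix(["a", "b", "c", "d"], D)

    def test_exact_on_ultrametric_input(self):
        from scipy.cluster.hierarchy import cophenet
        from scipy.spatial.distance import squareform

        dm = self.ultrametric_matrix()
        order, Z = dh.upgma_order(dm)
        np.testing.assert_allclose(cophenet(Z), squareform(dm.matrix), atol=1e-12)

    def test_merge_order_matches_manual_steps(self):
        dm = self.ultrametric_matrix()
        _, Z = dh.upgma_order(dm)
        # manual UPGMA: (a,b) at height 2 first, then (c,d) at 4, then root at 6
        assert sorted(Z[0, :2]) == [0, 1] and Z[0, 2] == pytest.approx(2.0)
        assert sorted(Z[1, :2]) == [2, 3] and Z[1, 2] == pytest.approx(4.0)
        assert Z[2, 2] == pytest.approx(6.0)

    def test_leaf_order_groups_clusters(self):
        dm = self.ultrametric_matrix()
        order, _ = dh.upgma_order(dm)
        assert {tuple(order[:2]), tuple(order[2:])} == {("a", "b"), ("c", "d")} or \
               {tuple(order[:2]), tuple(order[2:])} == {("c", "d"), ("a", "b")}

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(14)
        emb = rng.standard_normal((9, 4))
        dm = dh.pairwise_distances(emb, ids=[f"x{i}" for i in range(9)])
        perm = rng.permutation(9)
        dmp = DistanceMatrix(
            [dm.ids[i] for i in perm], dm.matrix[np.ix_(perm, perm)]
        )
        from scipy.cluster.hierarchy import cophenet
        from scipy.spatial.distance import squareform

        _, Z1 = dh.upgma_order(dm)
        _, Z2 = dh.upgma_order(dmp)
        c1 = squareform(cophenet(Z1))
        c2 = squareform(cophenet(Z2))
        np.testing.assert_allclose(
            c2, c1[np.ix_(perm, perm)], atol=1e-9
        )


class TestExportClusters:
    def test_one_fasta_per_cluster(self, toy_dataset, tmp_path):
        ds = toy_dataset.dataset
        labels = [s.label.subsubfamily for s in ds.sequences]
        paths = dh.export_clusters_fasta(ds, labels, tmp_path)
        assert len(paths) == ds.hierarchy.n_classes("subsubfamily")
        for p in paths:
            records = dh.read_fasta(p)
            assert len(records) == 6  # toy dataset has 6 per class

    def test_zero_noise_cluster_contains_planted_motif(self, toy_dataset, tmp_path):
        spec = toy_dataset.spec
        ds = toy_dataset.dataset
        labels = [s.label.subsubfamily for s in ds.sequences]
        paths = dh.export_clusters_fasta(ds, labels, tmp_path)
        for p in paths:
            subsub = p.stem.replace("cluster_", "")
            motif = next(
                m.motif for node, m in spec.motifs.items()
                if len(node) == 3 and node[2] == subsub
            )
            for rec in dh.read_fasta(p):
                assert motif in rec.residues
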