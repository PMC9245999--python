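"""MDS, PCA and neighbor-joining against exact-recovery oracles and
independent library implementations (scikit-bio, scikit-learn, dendropy)."""

import io
import itertools

import dendropy
import numpy as np
import pytest
from sklearn.decomposition import PCA

import ystrpop as y
from ystrpop.errors import DegenerateInputError, ValidationError
from ystrpop.ordination_phylo import newick_string


def euclidean(points):
    p = np.asarray(points, dtype=float)
    return np.sqrt(((p[:, None] - p[None]) ** 2).sum(-1))


class TestClassicalMds:
    def test_collinear_points_recovered_in_one_dimension(self):
        d = euclidean([[0.0], [1.0], [3.0]])
        res = y.classical_mds(d, k=1)
        x = np.sort(res.coordinates[:, 0])
        gaps = np.diff(x)
        assert sorted(gaps) == pytest.approx([1.0, 2.0])

    def test_equilateral_distances_give_equal_leading_eigenvalues(self):
        d = np.ones((3, 3)) - np.eye(3)
        res = y.classical_mds(d, k=2)
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1])

    def test_embeddable_matrix_reproduced_exactly(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(5, 2))
        d = euclidean(pts)
        res = y.classical_mds(d, k=2)
        np.testing.assert_allclose(euclidean(res.coordinates), d, atol=1e-9)

    def test_matches_skbio_pcoa(self):
        from skbio.stats.ordination import pcoa

        rng = np.random.default_rng(1)
        pts = rng.normal(size=(7, 3))
        d = euclidean(pts)
        res = y.classical_mds(d, k=3)
        ref = pcoa(d, number_of_dimensions=3)
        np.testing.assert_allclose(
            np.abs(res.coordinates), np.abs(ref.samples.to_numpy()), atol=1e-8
        )

    def test_k_reduced_with_warning_when_rank_deficient(self):
        d = euclidean([[0.0], [1.0], [2.0], [5.0]])  # rank-1 configuration
        with pytest.warns(UserWarning):
            res = y.classical_mds(d, k=3)
        assert res.coordinates.shape[1] == 1

    def test_negative_distances_floored(self):
        d = np.array([[0, -0.02, 0.3], [-0.02, 0, 0.4], [0.3, 0.4, 0]])
        res = y.classical_mds(d, k=1)
        assert np.isfinite(res.coordinates).all()

    def test_label_permutation_permutes_coordinates(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(6, 2))
        d = euclidean(pts)
        labels = [f"P{i}" for i in range(6)]
        res = y.classical_mds(d, k=2, labels=labels)
        perm = [3, 0, 5, 1, 4, 2]
        res_p = y.classical_mds(
            d[np.ix_(perm, perm)], k=2, labels=[labels[i] for i in perm]
        )
        dist_orig = euclidean(res.coordinates)
        dist_perm = euclidean(res_p.coordinates)
        np.testing.assert_allclose(
            dist_orig[np.ix_(perm, perm)], dist_perm, atol=1e-9
        )


class TestPcaFrequencies:
    def test_identical_rows_zero_variance(self):
        f = np.tile([0.2, 0.3, 0.5], (4, 1))
        res = y.pca_frequencies(f)
        np.testing.assert_allclose(res.eigenvalues, 0.0, atol=1e-12)

    def test_two_profiles_rank_one(self):
        f = np.array([[0.8, 0.2], [0.8, 0.2], [0.1, 0.9]])
        res = y.pca_frequencies(f)
        assert res.explained_fraction[0] == pytest.approx(1.0)
        assert res.eigenvalues[1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_sklearn(self):
        rng = np.random.default_rng(2)
        f = rng.dirichlet(np.ones(6), size=10)
        res = y.pca_frequencies(f)
        ref = PCA().fit(f)
        np.testing.assert_allclose(
            res.explained_fraction,
            ref.explained_variance_ratio_,
            atol=1e-9,
        )
        np.testing.assert_allclose(
            np.abs(res.coordinates), np.abs(ref.transform(f)), atol=1e-8
        )

    def test_explained_fractions_sum_to_one(self):
        rng = np.random.default_rng(4)
        f = rng.dirichlet(np.ones(5), size=8)
        res = y.pca_frequencies(f)
        assert res.explained_fraction.sum() == pytest.approx(1.0, abs=1e-9)

    def test_too_few_rows(self):
        with pytest.raises(DegenerateInputError):
            y.pca_frequencies(np.array([[0.5, 0.5], [0.4, 0.6]]))


def random_additive_tree(rng, n_taxa):
    """Random binary topology with positive lengths; returns (labels, D)
    built by an independent path-length computation on an edge list."""
    # start from a star of 3, repeatedly split a random edge with a new leaf
    next_node = [n_taxa]  # internal node ids from n_taxa upward

    def new_internal():
        next_node[0] += 1
        return next_node[0] - 1

    edges = {}  # (u, v) sorted -> length

    def add_edge(u, v, ln):
        edges[(min(u, v), max(u, v))] = ln

    center = new_internal()
    for leaf in range(3):
        add_edge(leaf, center, float(rng.uniform(0.5, 3.0)))
    for leaf in range(3, n_taxa):
        u, v = list(edges)[rng.integers(len(edges))]
        ln = edges.pop((u, v))
        mid = new_internal()
        split = float(rng.uniform(0.2, 0.8)) * ln
        add_edge(u, mid, split)
        add_edge(mid, v, ln - split)
        add_edge(leaf, mid, float(rng.uniform(0.5, 3.0)))
    # path lengths via dense Floyd-Warshall over the small node graph
    n_nodes = next_node[0]
    big = np.full((n_nodes, n_nodes), np.inf)
    np.fill_diagonal(big, 0.0)
    for (u, v), ln in edges.items():
        big[u, v] = big[v, u] = ln
    for m in range(n_nodes):
        big = np.minimum(big, big[:, [m]] + big[[m], :])
    labels = [f"T{i}" for i in range(n_taxa)]
    return labels, big[:n_taxa, :n_taxa]


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = y.nj_tree(d, labels=["A", "B", "C"])
        lengths = {c.name: ln for c, ln in tree.root.children}
        assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)

    def test_four_taxon_tree_recovered(self):
        # ((A:1,B:2):1,(C:3,D:1)) as an additive matrix
        d = np.array(
            [[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]], float
        )
        tree = y.nj_tree(d, labels=list("ABCD"))
        labels, coph = tree.cophenetic(list("ABCD"))
        np.testing.assert_allclose(coph, d, atol=1e-9)

    @pytest.mark.parametrize("n_taxa", [4, 5, 6])
    def test_random_additive_matrices_recovered_exactly(self, n_taxa):
        rng = np.random.default_rng(100 + n_taxa)
        for _ in range(10):
            labels, d = random_additive_tree(rng, n_taxa)
            tree = y.nj_tree(d, labels=labels)
            _, coph = tree.cophenetic(labels)
            np.testing.assert_allclose(coph, d, atol=1e-9)

    def test_five_taxa_unique_additive_fit(self):
        """Exhaustive check: among all 15 unrooted 5-taxon topologies, only
        the NJ topology admits an exact additive fit of the input."""
        rng = np.random.default_rng(77)
        labels, d = random_additive_tree(rng, 5)
        tree = y.nj_tree(d, labels=labels)
        nj_split = frozenset(_splits(tree))
        exact_fits = set()
        for topo_splits, coph, internal in _all_five_taxon_topologies(labels, d):
            # a genuine tree needs positive internal branches
            if np.allclose(coph, d, atol=1e-8) and min(internal) > 1e-8:
                exact_fits.add(topo_splits)
        assert exact_fits == {nj_split}

    def test_matches_skbio_topology(self):
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(8)
        labels, d = random_additive_tree(rng, 6)
        ours = y.nj_tree(d, labels=labels)
        ref = skbio_nj(DistanceMatrix(d, labels))
        ref_d = np.array(
            [[ref.find(a).distance(ref.find(b)) for b in labels] for a in labels]
        )
        _, coph = ours.cophenetic(labels)
        np.testing.assert_allclose(coph, ref_d, atol=1e-8)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(DegenerateInputError):
            y.nj_tree(np.zeros((2, 2)), labels=["A", "B"])


def _splits(tree):
    """Nontrivial leaf bipartitions of an unrooted tree."""
    all_leaves = frozenset(tree.leaf_labels)
    out = []

    def walk(node):
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset()
        for child, _ in node.children:
            sub = walk(child)
            if 1 < len(sub) < len(all_leaves) - 1:
                out.append(frozenset([sub, all_leaves - sub]))
            below |= sub
        return below

    walk(tree.root)
    return out


def _all_five_taxon_topologies(labels, d):
    """Yield (splits, least-squares cophenetic matrix) for each of the 15
    unrooted 5-taxon topologies, fitting branch lengths by least squares."""
    n = 5
    idx = {lab: i for i, lab in enumerate(labels)}
    # every unrooted binary 5-taxon topology is defined by its two
    # nontrivial splits: a 2-vs-3 split plus a 2-vs-3 split of the other pair
    for pair1 in itertools.combinations(labels, 2):
        rest = [l for l in labels if l not in pair1]
        for pair2 in itertools.combinations(rest, 2):
            # topology: (pair1)(pair2)(singleton) on a central path
            singleton = [l for l in rest if l not in pair2][0]
            splits = frozenset(
                [
                    frozenset([frozenset(pair1), frozenset(labels) - frozenset(pair1)]),
                    frozenset([frozenset(pair2), frozenset(labels) - frozenset(pair2)]),
                ]
            )
            # edges: 5 pendant + 2 internal; build path-indicator system
            # nodes: X joins pair1, Y joins pair2, both attach to Z (singleton's node)
            edge_names = [*labels, "XZ", "YZ"]

            def path_edges(a, b):
                cols = []
                for leaf in (a, b):
                    cols.append(edge_names.index(leaf))
                grp = lambda l: 0 if l in pair1 else (1 if l in pair2 else 2)
                ga, gb = grp(a), grp(b)
                if ga != gb:
                    for g in (ga, gb):
                        if g == 0:
                            cols.append(edge_names.index("XZ"))
                        elif g == 1:
                            cols.append(edge_names.index("YZ"))
                return cols

            rows = []
            targets = []
            pairs = list(itertools.combinations(labels, 2))
            for a, b in pairs:
                row = np.zeros(len(edge_names))
                for c in path_edges(a, b):
                    row[c] += 1
                rows.append(row)
                targets.append(d[idx[a], idx[b]])
            sol, *_ = np.linalg.lstsq(np.array(rows), np.array(targets), rcond=None)
            coph = np.zeros((n, n))
            for (a, b), row in zip(pairs, rows):
                coph[idx[a], idx[b]] = coph[idx[b], idx[a]] = row @ sol
            internal = [sol[edge_names.index("XZ")], sol[edge_names.index("YZ")]]
            yield splits, coph, internal


class TestNewick:
    def test_three_taxon_star_format(self):
        d = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], float)
        tree = y.nj_tree(d, labels=["A", "B", "C"])
        s = newick_string(tree)
        assert s.endswith(";") and s.count(",") == 2
        assert "A:" in s and "B:" in s and "C:" in s

    def test_round_trip_through_dendropy(self):
        rng = np.random.default_rng(12)
        labels, d = random_additive_tree(rng, 6)
        tree = y.nj_tree(d, labels=labels)
        buf = io.StringIO()
        y.write_newick(tree, buf)
        parsed = dendropy.Tree.get(data=buf.getvalue(), schema="newick")
        pdm = parsed.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in parsed.taxon_namespace}
        back = np.array(
            [
                [pdm.patristic_distance(taxa[a], taxa[b]) for b in labels]
                for a in labels
            ]
        )
        np.testing.assert_allclose(back, d, atol=1e-6)

    def test_label_quoting_and_negative_lengths(self):
        root = y.TreeNode(
            children=[
                (y.TreeNode(name="pop one"), -0.5),
                (y.TreeNode(name="B"), 1.0),
                (y.TreeNode(name="C"), 2.0),
            ]
        )
        s = newick_string(y.PhyloTree(root))
        assert "'pop one':-0.5" in s
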