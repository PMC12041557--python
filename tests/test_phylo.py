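"""Tree I/O, Brownian covariance and independent-contrast machinery."""

import math

import dendropy
import numpy as np
import pytest

from famscan.phylo import (NewickError, brownian_covariance,
                           independent_contrasts, pic_correlation, prune_to,
                           read_newick, write_newick)
from famscan.synthetic import simulate_tree, simulate_traits


def dendropy_distances(newick, labels):
    """Independent patristic-distance oracle."""
    dt = dendropy.Tree.get(data=newick, schema="newick",
                           preserve_underscores=True)
    pdm = dt.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in dt.taxon_namespace}
    n = len(labels)
    D = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                D[i, j] = pdm.patristic_distance(taxa[a], taxa[b])
    return D


def mrca_depth_oracle(tree):
    """Covariance by explicit root-path walking, independent of the implementation."""
    depths = tree.depths()
    ancestors = []
    for tip in tree.tip_indices:
        path = []
        u = tip
        while u >= 0:
            path.append(u)
            u = tree.parent[u]
        ancestors.append(path)
    n = tree.n_tips
    V = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                V[i, j] = depths[tree.tip_indices[i]]
            else:
                shared = set(ancestors[i]) & set(ancestors[j])
                V[i, j] = max(depths[u] for u in shared)
    return V


def pic_oracle(tree, x):
    """Second, nested-dict implementation of the pruning recursion."""

    def rec(u):
        if not tree.children[u]:
            return float(x[tree.labels[u]]), tree.brlen[u], []
        (v1, e1, c1), (v2, e2, c2) = (rec(c) for c in tree.children[u])
        contrast = (v1 - v2) / math.sqrt(e1 + e2)
        val = (v1 * e2 + v2 * e1) / (e1 + e2)
        return val, tree.brlen[u] + e1 * e2 / (e1 + e2), \
            c1 + c2 + [(u, contrast)]

    _, _, contrasts = rec(0)
    return dict(contrasts)


class TestNewickIO:
    def test_three_taxon_example(self, three_taxon_tree):
        assert three_taxon_tree.n_tips == 3
        assert np.allclose(three_taxon_tree.tip_depths(), 2.0)

    def test_single_tip(self):
        t = read_newick("(A:1);")
        assert t.tip_labels == ("A",)
        assert t.tip_depths()[0] == 1.0

    @pytest.mark.parametrize("bad", [
        "((A:1,B:1:1,C:2);",      # unbalanced parentheses
        "((A:1,B),C:2);",         # missing branch length
        "((A:1,A:1):1,C:2);",     # duplicate tip label
    ])
    def test_malformed_input_rejected(self, bad):
        with pytest.raises(NewickError):
            read_newick(bad)

    def test_round_trip_preserves_distances(self):
        tree = simulate_tree(46, seed=5)
        back = read_newick(write_newick(tree))
        labs, D1 = tree.pairwise_tip_distances()
        labs2, D2 = back.pairwise_tip_distances()
        assert labs == labs2
        assert np.allclose(D1, D2, atol=1e-12)
        # cross-check against an independent distance computation
        D3 = dendropy_distances(write_newick(tree), list(labs))
        assert np.allclose(D1, D3, atol=1e-9)


class TestPrune:
    def test_drop_one_tip_rehomes_root(self, three_taxon_tree):
        p = prune_to(three_taxon_tree, {"A", "B"})
        assert p.tip_labels == ("A", "B")
        assert np.allclose(p.tip_depths(), 1.0)  # root is now the A-B ancestor
        _, D = p.pairwise_tip_distances()
        assert D[0, 1] == pytest.approx(2.0)

    def test_keep_all_is_identity_on_distances(self, tree46):
        p = prune_to(tree46, tree46.tip_labels)
        _, D1 = tree46.pairwise_tip_distances()
        _, D2 = p.pairwise_tip_distances()
        assert np.allclose(D1, D2, atol=1e-12)

    def test_unknown_label_is_reported(self, three_taxon_tree):
        with pytest.raises(KeyError, match="ZZ"):
            prune_to(three_taxon_tree, {"A", "ZZ"})

    def test_random_pruning_preserves_distances(self):
        tree = simulate_tree(20, seed=7)
        keep = list(tree.tip_labels[:15])
        sub = prune_to(tree, keep)
        labs, D = sub.pairwise_tip_distances()
        full_labs, full_D = tree.pairwise_tip_distances()
        pos = {l: i for i, l in enumerate(full_labs)}
        for i, a in enumerate(labs):
            for j, b in enumerate(labs):
                assert D[i, j] == pytest.approx(full_D[pos[a], pos[b]],
                                                abs=1e-12)


class TestBrownianCovariance:
    def test_printed_example(self, three_taxon_tree):
        V = brownian_covariance(three_taxon_tree)
        assert V.species == ("A", "B", "C")
        assert np.allclose(V.matrix, [[2, 1, 0], [1, 2, 0], [0, 0, 2]])

    def test_star_tree_is_diagonal(self):
        t = read_newick("(A:3,B:3,C:3,D:3);")
        V = brownian_covariance(t).matrix
        assert np.allclose(V, 3 * np.eye(4))

    def test_psd_and_mrca_oracle_on_random_trees(self):
        for seed in range(20):
            tree = simulate_tree(10, seed=seed)
            V = brownian_covariance(tree).matrix
            assert np.allclose(V, V.T)
            assert np.linalg.eigvalsh(V).min() >= -1e-10
            assert np.allclose(V, mrca_depth_oracle(tree), atol=1e-12)
            assert np.all(V.diagonal()[:, None] >= V - 1e-12)


class TestIndependentContrasts:
    def test_two_tip_formula(self):
        t = read_newick("(A:1,B:1);")
        cs = independent_contrasts(t, {"A": 3, "B": 1})
        assert cs.values == pytest.approx([2 / math.sqrt(2)])

    def test_constant_trait_gives_zero_contrasts(self, tree46):
        x = {lab: 7.7 for lab in tree46.tip_labels}
        assert np.allclose(independent_contrasts(tree46, x).values, 0.0)

    def test_matches_recursive_oracle(self, three_taxon_tree):
        x = {"A": 1.0, "B": 3.0, "C": 6.0}
        cs = independent_contrasts(three_taxon_tree, x)
        oracle = pic_oracle(three_taxon_tree, x)
        got = dict(zip(cs.node_ids, cs.values))
        for node, val in oracle.items():
            assert got[node] == pytest.approx(val, abs=1e-12)

    def test_oracle_equivalence_on_random_trees(self, rng):
        for seed in range(5):
            tree = simulate_tree(12, seed=seed)
            x = {lab: rng.normal() for lab in tree.tip_labels}
            cs = independent_contrasts(tree, x)
            oracle = pic_oracle(tree, x)
            assert np.sum(cs.values ** 2) == pytest.approx(
                sum(v * v for v in oracle.values()), abs=1e-10)

    def test_missing_tip_named(self, three_taxon_tree):
        with pytest.raises(KeyError, match="C"):
            independent_contrasts(three_taxon_tree, {"A": 1, "B": 2})

    def test_polytomy_resolution_is_deterministic(self):
        t = read_newick("(B:1,A:1,C:1,D:1);")
        r1 = t.resolve_polytomies()
        assert r1.is_binary()
        assert r1.to_newick() == t.resolve_polytomies().to_newick()
        # distances unchanged by zero-length resolution
        labs, D1 = t.pairwise_tip_distances()
        labs2, D2 = r1.pairwise_tip_distances()
        assert labs == labs2 and np.allclose(D1, D2)


class TestPicCorrelation:
    def test_identical_traits(self, tree46, rng):
        x = {lab: rng.normal() for lab in tree46.tip_labels}
        assert pic_correlation(tree46, x, x).r == pytest.approx(1.0)
        neg = {k: -v for k, v in x.items()}
        assert pic_correlation(tree46, x, neg).r == pytest.approx(-1.0)

    def test_zero_variance_flagged(self, tree46, rng):
        x = {lab: rng.normal() for lab in tree46.tip_labels}
        const = {lab: 5.0 for lab in tree46.tip_labels}
        res = pic_correlation(tree46, x, const)
        assert res.degenerate and math.isnan(res.r)

    def test_recovers_planted_cross_correlation(self, tree46):
        """Bivariate Brownian traits at rho=0.7: the PIC estimate is unbiased."""
        C = np.array([[1.0, 0.7, 0, 0, 0.0],
                      [0.7, 1.0, 0, 0, 0.0],
                      [0, 0, 1, 0, 0],
                      [0, 0, 0, 1, 0],
                      [0, 0, 0, 0, 1.0]])
        rs = []
        for seed in range(300):
            tr = simulate_traits(tree46, trait_correlations=C, seed=seed)
            x = np.log10(tr["mlsp"]).to_dict()
            y = np.log10(tr["body_mass"]).to_dict()
            rs.append(pic_correlation(tree46, x, y).r)
        assert np.mean(rs) == pytest.approx(0.7, abs=0.05)
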