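"""Transition probabilities, pruning, +G, optimizers, and tree distance."""

import itertools

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import gamma as gamma_dist

import rotasub as rs
from rotasub import fixtures as fx
from rotasub.likelihood import LikelihoodError
from rotasub.trees import IndexedTree


@pytest.fixture(scope="module")
def four_taxon_data(toy9):
    fine, _, _ = toy9
    tree = rs.read_newick("((a:0.2,b:0.3)n1:0.15,(c:0.4,d:0.1)n2:0.25)r;")
    aln, _ = rs.simulate_alignment(tree, fine, 6, seed=5)
    return tree, aln, fine


def brute_force_site_loglik(tree, aln, model, site):
    it = IndexedTree(tree) if not isinstance(tree, IndexedTree) else tree
    internal = [v for v in range(it.n_nodes) if not it.is_leaf[v]]
    P = {v: model.transition_matrix(it.edge_length[v])
         for v in range(1, it.n_nodes)}
    total = 0.0
    for assign in itertools.product(range(model.n_states),
                                    repeat=len(internal)):
        st = dict(zip(internal, assign))
        pr = model.pi[st[0]]
        for v in range(1, it.n_nodes):
            parent = st[it.parent[v]]
            if it.is_leaf[v]:
                c = aln.codes[aln.taxa.index(it.labels[v]), site]
                pr *= P[v][parent, c] if c >= 0 else 1.0
            else:
                pr *= P[v][parent, st[v]]
        total += pr
    return np.log(total)


class TestTransitionMatrix:
    def test_p0_is_identity(self, toy9):
        fine, _, _ = toy9
        np.testing.assert_allclose(fine.transition_matrix(0.0),
                                   np.eye(fine.n_states), atol=1e-12)

    def test_two_state_closed_form(self):
        Q = np.array([[-1.0, 1.0], [1.0, -1.0]])
        for t in (0.1, 0.7, 2.0):
            P = rs.transition_matrix(Q, t)
            assert P[0, 0] == pytest.approx((1 + np.exp(-2 * t)) / 2,
                                            abs=1e-12)

    def test_rows_stochastic_and_semigroup(self, model55):
        s, t = 0.23, 0.61
        Ps = model55.transition_matrix(s)
        Pt = model55.transition_matrix(t)
        Pst = model55.transition_matrix(s + t)
        assert np.abs(Ps.sum(axis=1) - 1).max() < 1e-10
        assert Ps.min() >= 0 and Ps.max() <= 1
        np.testing.assert_allclose(Ps @ Pt, Pst, atol=1e-9)

    def test_eigen_path_matches_expm(self, model55):
        from scipy.linalg import expm

        P1 = model55.transition_matrix(0.37)
        P2 = expm(model55.Q * 0.37)
        np.testing.assert_allclose(P1, P2, atol=1e-10)

    def test_negative_time_rejected(self, toy9):
        fine, _, _ = toy9
        with pytest.raises(Exception):
            fine.transition_matrix(-0.1)
        with pytest.raises(LikelihoodError):
            rs.transition_matrix(fine.Q, -1.0)


class TestPruning:
    def test_single_taxon_site_is_log_pi(self, toy9):
        fine, _, _ = toy9
        # 2-taxon star with one zero branch and one totally ambiguous taxon
        tree = rs.read_newick("(a:0.0,b:0.0)r;")
        codes = np.array([[3], [-2]], dtype=np.int16)
        aln = rs.RotasequenceAlignment(["a", "b"], codes, fine.alphabet)
        ll = rs.pruning_loglik(tree, aln, fine)
        assert ll == pytest.approx(np.log(fine.pi[3]), abs=1e-12)

    def test_two_taxon_closed_form(self, toy9):
        fine, _, _ = toy9
        t1, t2 = 0.2, 0.4
        tree = rs.read_newick(f"(a:{t1},b:{t2})r;")
        codes = np.array([[1], [5]], dtype=np.int16)
        aln = rs.RotasequenceAlignment(["a", "b"], codes, fine.alphabet)
        P1 = fine.transition_matrix(t1)
        P2 = fine.transition_matrix(t2)
        expected = np.log(np.sum(fine.pi * P1[:, 1] * P2[:, 5]))
        assert rs.pruning_loglik(tree, aln, fine) == pytest.approx(expected,
                                                                   abs=1e-12)

    def test_matches_brute_force_enumeration(self, four_taxon_data):
        tree, aln, fine = four_taxon_data
        _, per_site = rs.pruning_loglik(tree, aln, fine,
                                        return_per_site=True)
        for site in range(3):
            assert per_site[site] == pytest.approx(
                brute_force_site_loglik(tree, aln, fine, site), abs=1e-8)

    def test_gap_site_matches_brute_force(self, four_taxon_data):
        tree, aln, fine = four_taxon_data
        codes = aln.codes.copy()
        codes[0, 0] = -1
        codes[2, 0] = -2
        aln2 = rs.RotasequenceAlignment(aln.taxa, codes, aln.alphabet)
        _, per_site = rs.pruning_loglik(tree, aln2, fine,
                                        return_per_site=True)
        assert per_site[0] == pytest.approx(
            brute_force_site_loglik(tree, aln2, fine, 0), abs=1e-8)

    def test_root_placement_invariance(self, four_taxon_data):
        import dendropy

        tree, aln, fine = four_taxon_data
        base = rs.pruning_loglik(tree, aln, fine)
        rerooted = dendropy.Tree(tree)
        edge = rerooted.find_node_with_taxon_label("c").edge
        rerooted.reroot_at_edge(edge, length1=edge.length / 2,
                                length2=edge.length / 2)
        assert rs.pruning_loglik(rerooted, aln, fine) == pytest.approx(
            base, abs=1e-9)

    def test_55_state_pruning_matches_brute_force_small_tree(self, model55):
        tree = rs.read_newick("((a:0.3,b:0.2)x:0.1,c:0.4)r;")
        aln, _ = rs.simulate_alignment(tree, model55, 2, seed=6)
        _, per_site = rs.pruning_loglik(tree, aln, model55,
                                        return_per_site=True)
        for site in range(2):
            assert per_site[site] == pytest.approx(
                brute_force_site_loglik(tree, aln, model55, site), abs=1e-8)

    def test_taxon_mismatch_lists_difference(self, four_taxon_data):
        tree, aln, fine = four_taxon_data
        bad = rs.RotasequenceAlignment(["a", "b", "c", "zz"], aln.codes,
                                       aln.alphabet)
        with pytest.raises(LikelihoodError, match="zz"):
            rs.pruning_loglik(tree, bad, fine)


class TestDiscreteGamma:
    def test_large_alpha_limit_is_rate_one(self):
        # outer-category offset scales as 1.27/sqrt(alpha) for the mean method
        rates = rs.discrete_gamma(1e7, 4).rates
        assert np.abs(np.array(rates) - 1.0).max() < 1e-3

    def test_rates_increase_and_mean_one(self):
        for alpha in (0.2, 0.5, 1.0, 5.0):
            r = np.array(rs.discrete_gamma(alpha, 4).rates)
            assert (np.diff(r) > 0).all()
            assert r.mean() == pytest.approx(1.0, abs=1e-12)

    def test_matches_quadrature_oracle(self):
        alpha, k = 0.5, 4
        edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), a=alpha,
                               scale=1 / alpha)
        expected = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            val, _ = quad(lambda x: x * gamma_dist.pdf(x, a=alpha,
                                                       scale=1 / alpha),
                          lo, min(hi, 1e3), limit=200)
            expected.append(val * k)
        np.testing.assert_allclose(rs.discrete_gamma(alpha, k).rates,
                                   expected, atol=1e-6)

    def test_invalid_shape_rejected(self):
        with pytest.raises(LikelihoodError):
            rs.discrete_gamma(0.0)


class TestBranchLengthOptimization:
    def test_two_taxon_recovery_within_three_se(self, toy9):
        fine, _, _ = toy9
        t_true = 0.3
        tree_true = rs.read_newick(f"(x:{t_true / 2},y:{t_true / 2})r;")
        aln, _ = rs.simulate_alignment(tree_true, fine, 10_000, seed=7)
        start = rs.read_newick("(x:0.05,y:0.05)r;")
        fit, ll = rs.optimize_branch_lengths(start, aln, fine)
        total = sum(e.length for e in fit.preorder_edge_iter()
                    if e.length is not None)
        # Fisher information of a single path length at 1e4 sites: SE via
        # numerical curvature of the per-site log-likelihood
        eps = 1e-3
        f = [rs.pruning_loglik(
            rs.read_newick(f"(x:{(total + d) / 2},y:{(total + d) / 2})r;"),
            aln, fine) for d in (-eps, 0, eps)]
        se = 1.0 / np.sqrt(max(-(f[0] - 2 * f[1] + f[2]) / eps ** 2, 1e-9))
        assert abs(total - t_true) < 3 * se
        assert ll >= rs.pruning_loglik(tree_true, aln, fine) - 1e-6

    def test_identical_sequences_drive_lengths_to_lower_bound(self, toy9):
        fine, _, _ = toy9
        codes = np.tile(np.arange(6, dtype=np.int16), (3, 1))
        aln = rs.RotasequenceAlignment(["a", "b", "c"], codes, fine.alphabet)
        tree = rs.read_newick("((a:0.2,b:0.2)n:0.2,c:0.2)r;")
        fit, _ = rs.optimize_branch_lengths(tree, aln, fine)
        for e in fit.preorder_edge_iter():
            if e.length is not None:
                assert e.length <= 1e-5

    def test_optimizing_twice_changes_little(self, toy9):
        fine, _, _ = toy9
        tree = rs.scale_tree(rs.random_tree(5, seed=8), 0.5)
        aln, _ = rs.simulate_alignment(tree, fine, 400, seed=9)
        fit1, ll1 = rs.optimize_branch_lengths(tree, aln, fine, tol=1e-6)
        fit2, ll2 = rs.optimize_branch_lengths(fit1, aln, fine, tol=1e-6)
        assert ll2 - ll1 < 1e-3
        assert ll2 >= ll1 - 1e-9

    def test_local_optimality_of_fitted_branch(self, toy9):
        fine, _, _ = toy9
        tree = rs.read_newick("(x:0.1,y:0.1)r;")
        aln, _ = rs.simulate_alignment(rs.read_newick("(x:0.1,y:0.1)r;"),
                                       fine, 3000, seed=10)
        fit, ll = rs.optimize_branch_lengths(tree, aln, fine)
        total = sum(e.length for e in fit.preorder_edge_iter()
                    if e.length is not None)
        for delta in (-0.03, 0.03):
            t = max(total + delta, 1e-6)
            perturbed = rs.read_newick(f"(x:{t / 2},y:{t / 2})r;")
            assert rs.pruning_loglik(perturbed, aln, fine) <= ll + 1e-9


class TestShapeAndFrequencyOptimization:
    def test_alpha_recovery_within_three_se(self, toy9):
        fine, _, _ = toy9
        alpha_true = 0.5
        tree = rs.read_newick("(x:0.4,y:0.4)r;")
        aln, _ = rs.simulate_alignment(tree, fine, 5000, seed=11,
                                       rates=rs.discrete_gamma(alpha_true, 4))
        alpha_hat, _ = rs.optimize_alpha(tree, aln, fine)
        eps = 0.02
        lls = [rs.pruning_loglik(tree, aln, fine,
                                 rs.discrete_gamma(alpha_hat + d, 4))
               for d in (-eps, 0, eps)]
        se = 1.0 / np.sqrt(max(-(lls[0] - 2 * lls[1] + lls[2]) / eps ** 2,
                               1e-9))
        assert abs(alpha_hat - alpha_true) < 3 * se

    def test_no_rate_variation_pushes_alpha_to_upper_bound(self, toy9):
        fine, _, _ = toy9
        tree = rs.read_newick("((x:0.2,y:0.3)n:0.1,(z:0.25,w:0.15)m:0.2)r;")
        aln, _ = rs.simulate_alignment(tree, fine, 5000, seed=12)
        alpha_hat, ll = rs.optimize_alpha(tree, aln, fine)
        assert alpha_hat > 50.0
        # and the heterogeneity adds essentially nothing to the fit
        assert ll - rs.pruning_loglik(tree, aln, fine) < 1.0

    def test_plus_f_frequency_recovery(self, toy9):
        from rotasub.model_build import exchangeabilities_to_irm

        fine, _, _ = toy9
        pi0 = fine.pi * np.linspace(1.0, 3.0, fine.n_states)
        pi0 /= pi0.sum()
        gen = exchangeabilities_to_irm(fine.exchangeabilities, pi0,
                                       fine.alphabet)
        tree = rs.read_newick("(x:0.4,y:0.4)r;")
        aln, _ = rs.simulate_alignment(tree, gen, 10_000, seed=13)
        pi_hat, _, ll = rs.optimize_frequencies(tree, aln, fine)
        assert np.abs(pi_hat - pi0).max() < 0.02
        assert ll >= rs.pruning_loglik(tree, aln, fine)


class TestTreeDistance:
    def test_identical_trees_distance_zero(self):
        t = rs.random_tree(6, seed=14)
        assert rs.euclidean_tree_distance(t, t) == pytest.approx(0.0)

    def test_single_branch_difference(self):
        t1 = rs.read_newick("((a:1,b:1):1,(c:1,d:1):1);")
        t2 = rs.read_newick("((a:1,b:1.5):1,(c:1,d:1):1);")
        assert rs.euclidean_tree_distance(t1, t2) == pytest.approx(0.5)

    def test_conflicting_bipartition_enumeration(self):
        # ((a,b),(c,d)) vs ((a,c),(b,d)): each tree's internal bipartition is
        # absent from the other; the two root-child edges express the same
        # unrooted bipartition, so their lengths add (2+3 and 4+5); pendant a
        # differs by 0.5
        t1 = rs.read_newick("((a:1,b:1):2,(c:1,d:1):3);")
        t2 = rs.read_newick("((a:1.5,c:1):4,(b:1,d:1):5);")
        expected = np.sqrt(5 ** 2 + 9 ** 2 + 0.5 ** 2)
        assert rs.euclidean_tree_distance(t1, t2) == pytest.approx(expected)

    def test_leaf_set_mismatch_rejected(self):
        from rotasub.trees import TreeError

        t1 = rs.read_newick("(a:1,b:1);")
        t2 = rs.read_newick("(a:1,c:1);")
        with pytest.raises(TreeError):
            rs.euclidean_tree_distance(t1, t2)
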