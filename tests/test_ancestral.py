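"""Marginal/joint ancestral reconstruction, LLO, and accuracy scoring."""

import itertools

import numpy as np
import pytest

import rotasub as rs
from rotasub import ancestral as anc
from rotasub import fixtures as fx
from rotasub.alphabet_io import RotasequenceAlignment, UNKNOWN
from rotasub.trees import IndexedTree


def brute_force_posterior(tree, aln, model, node, site):
    """Enumerate all internal assignments, marginalize onto one node."""
    it = IndexedTree(tree)
    internal = [v for v in range(it.n_nodes) if not it.is_leaf[v]]
    P = {v: model.transition_matrix(it.edge_length[v])
         for v in range(1, it.n_nodes)}
    post = np.zeros(model.n_states)
    target = it.by_label[node]
    best, best_assign = -1.0, None
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
        post[st[target]] += pr
        if pr > best:
            best, best_assign = pr, dict(st)
    return post / post.sum(), best_assign, it


class TestMarginal:
    def test_zero_branches_put_all_mass_on_leaf_state(self, toy9):
        fine, _, _ = toy9
        tree = rs.read_newick("((a:0,b:0)n:0,c:0)r;")
        codes = np.array([[4], [4], [4]], dtype=np.int16)
        aln = RotasequenceAlignment(["a", "b", "c"], codes, fine.alphabet)
        post = anc.marginal_reconstruct(tree, aln, fine, "n")
        assert post[0, 4] == pytest.approx(1.0)

    def test_star_tree_closed_form(self, toy9):
        fine, _, _ = toy9
        t = 0.3
        tree = rs.read_newick(f"(a:{t},b:{t},c:{t})r;")
        codes = np.array([[1], [1], [7]], dtype=np.int16)
        aln = RotasequenceAlignment(["a", "b", "c"], codes, fine.alphabet)
        P = fine.transition_matrix(t)
        direct = fine.pi * P[:, 1] * P[:, 1] * P[:, 7]
        direct /= direct.sum()
        post = anc.marginal_reconstruct(tree, aln, fine, "r")
        np.testing.assert_allclose(post[0], direct, atol=1e-12)

    def test_matches_brute_force_marginalization(self, toy9):
        fine, _, _ = toy9
        tree = rs.read_newick("((a:0.2,b:0.3)n1:0.15,(c:0.4,d:0.1)n2:0.25)r;")
        aln, _ = rs.simulate_alignment(tree, fine, 3, seed=21)
        post = anc.marginal_reconstruct(tree, aln, fine, "n2")
        for site in range(3):
            ref, _, _ = brute_force_posterior(tree, aln, fine, "n2", site)
            np.testing.assert_allclose(post[site], ref, atol=1e-10)

    def test_posteriors_normalize(self, toy9):
        fine, _, _ = toy9
        tree = rs.random_tree(5, seed=22)
        aln, _ = rs.simulate_alignment(tree, fine, 30, seed=23)
        post = anc.marginal_reconstruct(tree, aln, fine, "node1")
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-10)

    def test_root_posterior_invariant_to_rerooting(self, toy9):
        import dendropy

        fine, _, _ = toy9
        tree = rs.read_newick("((a:0.2,b:0.3)n1:0.15,(c:0.4,d:0.1)n2:0.25)r;")
        aln, _ = rs.simulate_alignment(tree, fine, 5, seed=24)
        post_n1 = anc.marginal_reconstruct(tree, aln, fine, "n1")
        rerooted = dendropy.Tree(tree)
        node = rerooted.find_node_with_taxon_label("a").parent_node
        rerooted.reroot_at_node(node)
        post_n1_rerooted = anc.marginal_reconstruct(rerooted, aln, fine, "n1")
        np.testing.assert_allclose(post_n1, post_n1_rerooted, atol=1e-9)

    def test_unknown_node_raises(self, toy9):
        fine, _, _ = toy9
        tree = rs.random_tree(4, seed=25)
        aln, _ = rs.simulate_alignment(tree, fine, 5, seed=26)
        with pytest.raises(anc.AncestralError):
            anc.marginal_reconstruct(tree, aln, fine, "nope")


class TestJoint:
    def test_zero_tree_copies_unanimous_leaves(self, toy9):
        fine, _, _ = toy9
        tree = rs.read_newick("((a:0,b:0)n:0,c:0)r;")
        codes = np.array([[2, 5], [2, 5], [2, 5]], dtype=np.int16)
        aln = RotasequenceAlignment(["a", "b", "c"], codes, fine.alphabet)
        out = anc.joint_reconstruct(tree, aln, fine)
        assert np.array_equal(out["n"], [2, 5])
        assert np.array_equal(out["r"], [2, 5])

    def test_three_leaf_majority_root(self):
        # symmetric 2-state chain, equal branches, leaves (1,1,0) -> root 1
        fine, _, _ = fx.toy_model((1, 1), seed=6)
        tree = rs.read_newick("(a:0.2,b:0.2,c:0.2)r;")
        codes = np.array([[1], [1], [0]], dtype=np.int16)
        aln = RotasequenceAlignment(["a", "b", "c"], codes, fine.alphabet)
        out = anc.joint_reconstruct(tree, aln, fine)
        assert out["r"][0] == 1

    def test_matches_exhaustive_argmax(self, toy9):
        fine, _, _ = toy9
        tree = rs.read_newick(
            "(((a:0.2,b:0.4)n1:0.1,c:0.3)n2:0.2,(d:0.5,e:0.1)n3:0.3)r;")
        aln, _ = rs.simulate_alignment(tree, fine, 3, seed=27)
        out = anc.joint_reconstruct(tree, aln, fine)
        for site in range(3):
            _, best, it = brute_force_posterior(tree, aln, fine, "r", site)
            for v, state in best.items():
                assert out[it.labels[v]][site] == state

    def test_joint_probability_matches_independent_recomputation(self, toy9):
        fine, _, _ = toy9
        tree = rs.read_newick("((a:0.2,b:0.3)n1:0.15,(c:0.4,d:0.1)n2:0.25)r;")
        aln, _ = rs.simulate_alignment(tree, fine, 4, seed=28)
        out = anc.joint_reconstruct(tree, aln, fine)
        it = IndexedTree(tree)
        P = {v: fine.transition_matrix(it.edge_length[v])
             for v in range(1, it.n_nodes)}
        for site in range(4):
            # probability of the returned assignment ...
            st = {it.by_label[k]: int(v[site]) for k, v in out.items()}
            pr = fine.pi[st[0]]
            for v in range(1, it.n_nodes):
                parent = st[it.parent[v]]
                c = aln.codes[aln.taxa.index(it.labels[v]), site] \
                    if it.is_leaf[v] else st[v]
                pr *= P[v][parent, c]
            # ... equals the exhaustive max-product value
            _, best, _ = brute_force_posterior(tree, aln, fine, "r", site)
            pr_best = fine.pi[best[0]]
            for v in range(1, it.n_nodes):
                parent = best[it.parent[v]]
                c = aln.codes[aln.taxa.index(it.labels[v]), site] \
                    if it.is_leaf[v] else best[v]
                pr_best *= P[v][parent, c]
            assert pr == pytest.approx(pr_best, rel=1e-10)


class TestLLO:
    def test_zero_length_cherry_perfect_recovery(self, toy9):
        fine, _, _ = toy9
        tree = rs.read_newick("((A:0,B:0)ab:0.0,(C:0.1,D:0.1)cd:0.1)r;")
        codes = np.tile(np.array([3, 1, 3, 3], dtype=np.int16)[:, None],
                        (1, 6))
        aln = RotasequenceAlignment(["A", "B", "C", "D"], codes,
                                    fine.alphabet)
        rec = anc.leave_leaves_out(tree, aln, fine, ("A", "B"))
        assert np.array_equal(rec, np.full(6, 3, dtype=np.int16))

    def test_non_sibling_pair_rejected(self, toy9):
        fine, _, _ = toy9
        tree = rs.read_newick("((A:0.1,B:0.1)ab:0.1,(C:0.1,D:0.1)cd:0.1)r;")
        aln, _ = rs.simulate_alignment(tree, fine, 10, seed=29)
        with pytest.raises(anc.AncestralError, match="sibling"):
            anc.leave_leaves_out(tree, aln, fine, ("A", "C"))

    def test_all_gap_sites_come_back_unknown(self, toy9):
        fine, _, _ = toy9
        tree = rs.read_newick("((A:0.1,B:0.1)ab:0.1,(C:0.1,D:0.1)cd:0.1)r;")
        aln, _ = rs.simulate_alignment(tree, fine, 6, seed=30)
        codes = aln.codes.copy()
        codes[aln.taxa.index("C"), 0] = -1
        codes[aln.taxa.index("D"), 0] = -2
        aln2 = RotasequenceAlignment(aln.taxa, codes, aln.alphabet)
        rec = anc.leave_leaves_out(tree, aln2, fine, ("A", "B"))
        assert rec[0] == UNKNOWN

    @pytest.mark.parametrize("algorithm", ["joint", "marginal"])
    def test_near_zero_divergence_recovers_target(self, toy9, algorithm):
        fine, _, _ = toy9
        tree = rs.scale_tree(rs.random_tree(8, seed=31), 0.01)
        it = IndexedTree(tree)
        # find a terminal sibling pair
        pair = None
        for v in range(it.n_nodes):
            kids = it.children[v]
            if len(kids) == 2 and all(it.is_leaf[c] for c in kids):
                pair = (it.labels[kids[0]], it.labels[kids[1]])
                break
        aln, _ = rs.simulate_alignment(tree, fine, 200, seed=32)
        rec = anc.leave_leaves_out(tree, aln, fine, pair,
                                   algorithm=algorithm)
        acc = anc.reconstruction_accuracy(rec, aln.row(pair[0]),
                                          fine.alphabet)
        assert acc["state_percent"] >= 95.0


class TestAccuracy:
    def test_extremes_and_masked_dominance(self, alpha55):
        a = np.arange(10, dtype=np.int16)
        assert anc.reconstruction_accuracy(a, a)["state_percent"] == 100.0
        b = a + 20
        assert anc.reconstruction_accuracy(b, a)["state_percent"] == 0.0
        rng = np.random.default_rng(3)
        x = rng.integers(0, 55, 200).astype(np.int16)
        y = rng.integers(0, 55, 200).astype(np.int16)
        acc = anc.reconstruction_accuracy(x, y, alpha55)
        assert acc["masked_percent"] >= acc["state_percent"]

    def test_unknowns_excluded_from_denominator(self):
        inferred = np.array([1, UNKNOWN, 2], dtype=np.int16)
        reference = np.array([1, 2, 2], dtype=np.int16)
        acc = anc.reconstruction_accuracy(inferred, reference)
        assert acc["n_compared"] == 2 and acc["state_percent"] == 100.0

    def test_length_mismatch_raises(self):
        with pytest.raises(anc.AncestralError):
            anc.reconstruction_accuracy(np.array([1]), np.array([1, 2]))
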