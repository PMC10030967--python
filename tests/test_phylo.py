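"""Mk likelihood, NJ, tree search and bootstrap."""

import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from synnetflow.phylo import (
    MkParams,
    Node,
    Tree,
    _transition,
    bootstrap,
    hamming_distances,
    mk_loglik,
    ml_search,
    neighbor_joining,
    rf_distance,
    simulate_characters,
    start_tree,
)


def two_leaf_tree(t1, t2):
    root = Node(None)
    root.add(Node("a", t1))
    root.add(Node("b", t2))
    return Tree(root)


def brute_loglik(tree, matrix, params):
    """Oracle: sum over all interior-state assignments."""
    internals = [n for n in tree.postorder() if n.children]
    pi = np.array([params.pi0, 1 - params.pi0])
    total = 0.0
    for col in matrix.columns:
        states = matrix[col]
        site = 0.0
        for rate, w in zip(params.rates, params.weights):
            cat = 0.0
            for assign in itertools.product((0, 1), repeat=len(internals)):
                amap = {id(n): s for n, s in zip(internals, assign)}
                pr = pi[amap[id(tree.root)]]
                for n in tree.postorder():
                    if n.parent is None:
                        continue
                    s = amap[id(n)] if n.children else states[n.name]
                    pr *= _transition(params.pi0, n.blen, rate)[amap[id(n.parent)], s]
                cat += pr
            site += w * cat
        total += np.log(site)
    return total


class TestMkLoglik:
    def test_zero_branch_lengths_give_stationary_probability(self):
        tree = two_leaf_tree(0.0, 0.0)
        mat = pd.DataFrame({0: [0, 0]}, index=["a", "b"])
        params = MkParams(0.6)
        assert mk_loglik(tree, mat, params) == pytest.approx(np.log(0.6))

    @pytest.mark.parametrize("t", [0.1, 0.7, 3.0])
    def test_symmetric_two_taxon_closed_form(self, t):
        # pi = 1/2: L(0,0) over total path t is (1 + exp(-2t)) / 4
        tree = two_leaf_tree(t / 2, t / 2)
        mat = pd.DataFrame({0: [0, 0]}, index=["a", "b"])
        got = mk_loglik(tree, mat, MkParams(0.5))
        assert got == pytest.approx(np.log((1 + np.exp(-2 * t)) / 4), abs=1e-10)
        # and the t -> infinity limit is 1/4
        far = mk_loglik(two_leaf_tree(500, 500), mat, MkParams(0.5))
        assert far == pytest.approx(np.log(0.25), abs=1e-6)

    def test_pruning_matches_interior_state_enumeration(self, rng):
        taxa = ["t1", "t2", "t3", "t4", "t5"]
        for _ in range(3):
            base = Node(None)
            for nm in taxa[:3]:
                base.add(Node(nm, rng.uniform(0.05, 1.0)))
            tree = Tree(base)
            for nm in taxa[3:]:
                edges = tree.edges()
                edge = edges[rng.integers(len(edges))]
                mid = Node(None, rng.uniform(0.05, 1.0))
                parent = edge.parent
                parent.children[parent.children.index(edge)] = mid
                mid.parent = parent
                mid.add(edge)
                mid.add(Node(nm, rng.uniform(0.05, 1.0)))
            mat = pd.DataFrame(rng.integers(0, 2, (5, 30)), index=taxa)
            params = MkParams(rng.uniform(0.2, 0.8), (0.5, 2.5), (0.6, 0.4))
            assert mk_loglik(tree, mat, params) == pytest.approx(
                brute_loglik(tree, mat, params), abs=1e-9)

    def test_likelihood_invariant_under_rerooting(self, rng):
        newick = "((a:0.2,b:0.3):0.15,(c:0.25,(d:0.1,e:0.4):0.2):0.1,f:0.3);"
        mat = pd.DataFrame(rng.integers(0, 2, (6, 40)),
                           index=["a", "b", "c", "d", "e", "f"])
        params = MkParams(0.65, (0.4, 2.1), (0.5, 0.5))
        ref = mk_loglik(Tree.from_newick(newick), mat, params)
        for leaf in ("a", "d", "f"):
            dt = dendropy.Tree.get(data=newick, schema="newick")
            node = dt.find_node_with_taxon_label(leaf)
            half = node.edge.length / 2
            dt.reroot_at_edge(node.edge, length1=half, length2=half,
                              update_bipartitions=False)
            rerooted = Tree.from_newick(dt.as_string(schema="newick").strip())
            assert mk_loglik(rerooted, mat, params) == pytest.approx(ref, abs=1e-9)

    def test_non_binary_matrix_rejected(self):
        tree = two_leaf_tree(0.1, 0.1)
        mat = pd.DataFrame({0: [0, 2]}, index=["a", "b"])
        with pytest.raises(ValueError, match="binary"):
            mk_loglik(tree, mat, MkParams(0.5))

    def test_variable_character_logl_strictly_negative(self):
        tree = two_leaf_tree(0.3, 0.3)
        mat = pd.DataFrame({0: [0, 1]}, index=["a", "b"])
        assert mk_loglik(tree, mat, MkParams(0.5)) < 0


class TestNeighborJoining:
    def test_recovers_additive_topology(self):
        # hand-built additive matrix on ((a,b),(c,d)): internal edge 2
        names = ["a", "b", "c", "d"]
        D = pd.DataFrame([
            [0, 3, 7, 8],
            [3, 0, 8, 9],
            [7, 8, 0, 5],
            [8, 9, 5, 0],
        ], index=names, columns=names, dtype=float)
        tree = neighbor_joining(D)
        want = Tree.from_newick("((a:1,b:2):1,(c:2,d:3):1);")
        assert rf_distance(tree, want) == 0

    def test_identical_profiles_become_siblings(self):
        mat = pd.DataFrame(
            [[1, 0, 1, 0, 1], [1, 0, 1, 0, 1], [0, 1, 0, 1, 0], [1, 1, 0, 0, 0]],
            index=["a", "a2", "b", "c"])
        tree = start_tree(mat)
        assert _siblings(tree, "a", "a2")

    def test_label_order_invariance(self, rng):
        mat = pd.DataFrame(rng.integers(0, 2, (5, 60)),
                           index=["a", "b", "c", "d", "e"])
        t1 = start_tree(mat)
        t2 = start_tree(mat.iloc[::-1])
        assert rf_distance(t1, t2) == 0


def _siblings(tree, x, y):
    for n in tree.postorder():
        if n.children and {c.name for c in n.children} == {x, y}:
            return True
    return False


class TestMlSearch:
    def test_recovers_simulating_topology(self):
        true = Tree.from_newick(
            "(((a:0.15,b:0.15):0.1,(c:0.15,d:0.15):0.1):0.1,"
            "((e:0.15,f:0.15):0.1,(g:0.15,h:0.15):0.1):0.1);")
        mat = simulate_characters(true, 500, MkParams(0.5), seed=10)
        tree, params, logl = ml_search(mat)
        assert rf_distance(tree, true) == 0

    def test_search_never_worsens_start(self, rng):
        mat = pd.DataFrame(rng.integers(0, 2, (5, 80)),
                           index=["a", "b", "c", "d", "e"])
        st = start_tree(mat)
        p0 = MkParams.default(2)
        start_logl = mk_loglik(st, mat, p0)
        _, _, final_logl = ml_search(mat, params_init=p0)
        assert final_logl >= start_logl - 1e-9

    def test_deterministic(self, rng):
        mat = pd.DataFrame(rng.integers(0, 2, (6, 100)),
                           index=list("abcdef"))
        t1, p1, l1 = ml_search(mat)
        t2, p2, l2 = ml_search(mat)
        assert t1.to_newick() == t2.to_newick()
        assert l1 == l2


class TestBootstrap:
    def test_unanimous_signal_gets_full_support(self):
        # 500 characters all supporting the split {a,b} | {c,d,e}
        rows = {sp: [1] * 250 + [0] * 250 for sp in ("a", "b")}
        rows |= {sp: [0] * 250 + [1] * 250 for sp in ("c", "d", "e")}
        mat = pd.DataFrame(rows).T
        tree, _, _ = bootstrap(mat, n_replicates=10, seed=1)
        supports = [n.support for n in tree.internal_edges() if n.support is not None]
        assert supports and all(s == 100.0 for s in supports)

    def test_single_replicate_supports_binary(self, rng):
        mat = pd.DataFrame(rng.integers(0, 2, (5, 60)), index=list("abcde"))
        tree, _, _ = bootstrap(mat, n_replicates=1, seed=3)
        for n in tree.internal_edges():
            if n.support is not None:
                assert n.support in (0.0, 100.0)

    def test_same_seed_same_supports(self, rng):
        mat = pd.DataFrame(rng.integers(0, 2, (5, 60)), index=list("abcde"))
        t1, _, _ = bootstrap(mat, n_replicates=5, seed=9)
        t2, _, _ = bootstrap(mat, n_replicates=5, seed=9)
        assert t1.to_newick(with_support=True) == t2.to_newick(with_support=True)
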