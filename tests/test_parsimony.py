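"""Sankoff scoring, heuristic MP search, Lundberg rooting, bootstrap, fit
indices and the Model/Results surface."""

import dendropy
import numpy as np
import pytest

from gocensus.encoding import CharacterMatrixView
from gocensus.parsimony import (CostModel, ParsimonyModel, RootedTree,
                                Topology, bootstrap_support, fit_indices,
                                lundberg_root, mp_search, tree_length,
                                write_newick)

from _oracles import all_unrooted_trees, fitch_length, sankoff_score

ORD = CostModel("ordered")
UNORD = CostModel("unordered")


def _view(states, orientation="ToL"):
    states = np.asarray(states)
    return CharacterMatrixView([f"t{i}" for i in range(states.shape[0])],
                               [f"c{j}" for j in range(states.shape[1])],
                               states, orientation)


def _topology(adj, n_tips):
    return Topology(n_tips, {k: list(v) for k, v in adj.items()},
                    max(adj) + 1)


def _quartet(ab_cd=True):
    """((t0,t1),(t2,t3)) if ab_cd else ((t0,t2),(t1,t3))."""
    if ab_cd:
        return _topology({0: [4], 1: [4], 2: [5], 3: [5],
                          4: [0, 1, 5], 5: [2, 3, 4]}, 4)
    return _topology({0: [4], 2: [4], 1: [5], 3: [5],
                      4: [0, 2, 5], 5: [1, 3, 4]}, 4)


class TestTreeLength:
    def test_constant_characters_cost_nothing(self):
        view = _view(np.full((4, 6), 7))
        assert tree_length(_quartet(), view, ORD) == 0
        assert tree_length(_quartet(), view, UNORD) == 0

    def test_two_taxa_single_edge_cost(self):
        view = _view([[0], [5]])
        two = Topology(2, {0: [1], 1: [0]}, 2)
        assert tree_length(two, view, ORD) == 5
        assert tree_length(two, view, UNORD) == 1

    def test_fitch_pass_by_hand_on_quartet(self):
        view = _view([[0], [0], [1], [1]])
        assert tree_length(_quartet(), view, UNORD) == 1
        assert tree_length(_quartet(ab_cd=False), view, UNORD) == 2

    def test_state_outside_range_errors(self):
        with pytest.raises(ValueError):
            CharacterMatrixView(["a", "b"], ["c"], np.array([[0], [32]]),
                                "ToL")

    def test_rerooting_invariance(self):
        rng = np.random.default_rng(4)
        states = rng.integers(0, 8, size=(6, 10))
        view = _view(states)
        res = mp_search(view, ORD, n_starts=2, seed=0)
        base = res.best_length
        # score the same topology after rooting it on every branch
        for anc in (0, 31):
            rooted = lundberg_root(res.best, view, ORD, anc)
            assert tree_length(rooted, view, ORD) == base
        newick = write_newick(lundberg_root(res.best, view, ORD, 0))
        reread = dendropy.Tree.get(data=newick, schema="newick")
        assert tree_length(reread, view, ORD) == base

    def test_sankoff_unordered_equals_fitch_everywhere(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(4, 8))
            m = int(rng.integers(2, 8))
            states = rng.integers(0, 5, size=(n, m))
            edges = all_unrooted_trees(n)[int(rng.integers(0, 3))]
            adj = {}
            for u, v in edges:
                adj.setdefault(u, []).append(v)
                adj.setdefault(v, []).append(u)
            top = _topology(adj, n)
            got = tree_length(top, _view(states), UNORD)
            expected = sum(fitch_length(edges, states[:, j])
                           for j in range(m))
            assert got == expected


class TestMpSearch:
    def test_perfect_quartet_signal_recovers_split(self):
        states = np.array([[0] * 10, [0] * 10, [5] * 10, [5] * 10])
        res = mp_search(_view(states), ORD, n_starts=3, seed=0)
        assert len(res.topologies) == 1
        assert res.best.splits() == {frozenset({2, 3})}
        assert res.best_length == 50

    def test_matches_exhaustive_minimum_on_small_matrices(self):
        rng = np.random.default_rng(12)
        for _ in range(8):
            n = int(rng.integers(5, 8))
            states = rng.integers(0, 6, size=(n, 6))
            trees = all_unrooted_trees(n)
            C = ORD.matrix()
            best = min(sankoff_score(e, states, C) for e in trees)
            res = mp_search(_view(states), ORD, n_starts=4, seed=1)
            assert res.best_length == best

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        states = rng.integers(0, 9, size=(8, 12))
        r1 = mp_search(_view(states), ORD, n_starts=4, seed=42)
        r2 = mp_search(_view(states), ORD, n_starts=4, seed=42)
        assert r1.best_length == r2.best_length
        assert [t.canonical_key() for t in r1.topologies] == \
            [t.canonical_key() for t in r2.topologies]

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            mp_search(_view([[0], [1]]), ORD, seed=0)


class TestLundbergRoot:
    def test_all_zero_taxon_attracts_zero_ancestor(self):
        rng = np.random.default_rng(9)
        states = np.vstack([np.zeros((1, 8), dtype=int),
                            rng.integers(3, 9, size=(4, 8))])
        view = _view(states)
        res = mp_search(view, ORD, n_starts=3, seed=0)
        rooted = lundberg_root(res.best, view, ORD, 0)
        children = rooted.tree.seed_node.child_nodes()
        pendant_tips = [c.taxon.label for c in children if c.is_leaf()]
        assert "t0" in pendant_tips
        assert not rooted.root_tie

    def test_placement_score_matches_bruteforce_ancestor(self):
        rng = np.random.default_rng(5)
        states = rng.integers(0, 7, size=(5, 6))
        view = _view(states)
        res = mp_search(view, ORD, n_starts=3, seed=2)
        top = res.best
        # oracle: attach an explicit all-zero ancestor row on every branch;
        # the ancestor gets an id above all internal nodes, with dummy rows
        # padding the state matrix up to that id
        anc_id = max(top.adj) + 1
        aug = np.zeros((anc_id + 1, 6), dtype=int)
        aug[:5] = states
        best = None
        for edge in top.edges():
            cand = top.copy()
            cand._next_id = anc_id + 1
            cand.attach_tip(anc_id, edge)
            edges = [(u, v) for u in cand.adj for v in cand.adj[u] if u < v]
            s = sankoff_score(edges, aug, ORD.matrix())
            best = s if best is None else min(best, s)
        rooted = lundberg_root(top, view, ORD, 0)
        assert rooted.rooting_score == best

    def test_identical_rows_tie_and_flag(self):
        states = np.tile(np.array([[3, 5, 1]]), (5, 1))
        view = _view(states)
        res = mp_search(view, ORD, n_starts=2, seed=0)
        rooted = lundberg_root(res.best, view, ORD, 0)
        assert rooted.root_tie

    def test_max_polarity_accepts_state_31(self):
        rng = np.random.default_rng(2)
        states = rng.integers(20, 32, size=(5, 6))
        view = _view(states, "ToF")
        res = mp_search(view, ORD, n_starts=2, seed=0)
        rooted = lundberg_root(res.best, view, ORD, 31)
        assert rooted.ancestral_state == 31
        with pytest.raises(ValueError):
            lundberg_root(res.best, view, ORD, 15)


class TestBootstrap:
    def test_exclusive_conflict_free_clade_gets_full_support(self):
        # 8 taxa; tips 5-7 share 40 high-state characters nobody else has
        states = np.zeros((8, 40), dtype=int)
        states[5:, :] = 25
        view = _view(states)
        res = mp_search(view, ORD, n_starts=2, seed=0)
        rooted = lundberg_root(res.best, view, ORD, 0)
        supports = bootstrap_support(view, ORD, rooted, n_reps=30, seed=1)
        clade = frozenset({"t5", "t6", "t7"})
        assert supports[clade] == 100.0

    def test_single_character_supports_are_all_or_nothing(self):
        rng = np.random.default_rng(0)
        states = rng.integers(0, 5, size=(5, 1))
        view = _view(states)
        res = mp_search(view, ORD, n_starts=2, seed=0)
        rooted = lundberg_root(res.best, view, ORD, 0)
        supports = bootstrap_support(view, ORD, rooted, n_reps=20, seed=3)
        assert set(supports.values()) <= {0.0, 100.0}

    def test_same_seed_same_support_map(self):
        rng = np.random.default_rng(1)
        states = rng.integers(0, 6, size=(6, 15))
        view = _view(states)
        res = mp_search(view, ORD, n_starts=2, seed=0)
        rooted = lundberg_root(res.best, view, ORD, 0)
        s1 = bootstrap_support(view, ORD, rooted, n_reps=15, seed=9)
        rooted2 = lundberg_root(res.best, view, ORD, 0)
        s2 = bootstrap_support(view, ORD, rooted2, n_reps=15, seed=9)
        assert s1 == s2


class TestFitIndices:
    def test_perfectly_congruent_matrix(self):
        states = np.array([[0] * 5, [0] * 5, [4] * 5, [4] * 5])
        ci, ri, rc = fit_indices(_quartet(), _view(states), ORD)
        assert (ci, ri, rc) == (1.0, 1.0, 1.0)

    def test_hand_computed_half_consistency(self):
        # character 0,0,1,1 split against the tree ((t0,t2),(t1,t3))
        ci, ri, rc = fit_indices(_quartet(ab_cd=False),
                                 _view([[0], [0], [1], [1]]), UNORD)
        assert ci == pytest.approx(0.5)
        assert rc <= min(ci, ri) + 1e-12

    def test_rc_bounded_by_factors(self):
        rng = np.random.default_rng(8)
        states = rng.integers(0, 6, size=(6, 10))
        view = _view(states)
        res = mp_search(view, ORD, n_starts=2, seed=0)
        ci, ri, rc = fit_indices(res.best, view, ORD)
        assert 0 < ci <= 1 and 0 <= ri <= 1
        assert rc <= min(ci, ri) + 1e-12


class TestNewick:
    def _rooted_3tip(self):
        tns = dendropy.TaxonNamespace(["A", "B", "C"])
        tree = dendropy.Tree(taxon_namespace=tns)
        tree.is_rooted = True
        inner = tree.seed_node.new_child()
        for lab in ("A", "B"):
            inner.new_child(taxon=tns.get_taxon(lab))
        inner.label = "100"
        tree.seed_node.new_child(taxon=tns.get_taxon("C"))
        return RootedTree(tree=tree, taxa=("A", "B", "C"), length=0)

    def test_three_tip_shape(self):
        txt = write_newick(self._rooted_3tip())
        assert txt.strip() == "((A,B)100,C);"

    def test_write_parse_write_idempotent(self):
        txt = write_newick(self._rooted_3tip())
        tree = dendropy.Tree.get(data=txt, schema="newick")
        again = write_newick(RootedTree(tree=tree, taxa=("A", "B", "C"),
                                        length=0))
        assert again == txt

    def test_polytomy_preserved(self):
        tree = dendropy.Tree.get(data="(A,B,C,D);", schema="newick")
        tree.is_rooted = True
        txt = write_newick(RootedTree(tree=tree, taxa=tuple("ABCD"), length=0))
        assert txt.strip() == "(A,B,C,D);"

    def test_unlabeled_tips_error(self):
        tree = dendropy.Tree()
        tree.seed_node.new_child()
        tree.seed_node.new_child()
        with pytest.raises(ValueError, match="unlabeled"):
            write_newick(RootedTree(tree=tree, taxa=(), length=0))


class TestModelResults:
    def test_fit_returns_rooted_results_with_summary(self):
        rng = np.random.default_rng(6)
        states = rng.integers(0, 10, size=(7, 12))
        model = ParsimonyModel(_view(states), cost="ordered", n_starts=3)
        res = model.fit(seed=5, n_bootstrap=10)
        assert res.best_length == tree_length(res.tree, model.view, ORD)
        assert res.tree.ancestral_state == 0  # ToL polarity default
        text = res.summary()
        assert "Tree length" in text and str(res.best_length) in text
        assert "Bootstrap replicates" in text

    def test_tof_orientation_defaults_to_state_31(self):
        rng = np.random.default_rng(6)
        states = rng.integers(0, 10, size=(6, 8))
        res = ParsimonyModel(_view(states, "ToF"), n_starts=2).fit(seed=1)
        assert res.tree.ancestral_state == 31
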