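"""Fitch length, search, consensus, bootstrap and ensemble indices."""

import numpy as np
import pytest

import pantherin as pt
from pantherin.parsimony import (
    _encode_matrix,
    _from_dendropy,
    _per_character_maxima,
    _per_character_minima,
    _per_character_steps,
    combine_indices,
)
from conftest import random_matrix
from _oracles import (
    exhaustive_matrix_length,
    exhaustive_mpt_splits,
    naive_indices,
    random_unrooted_tree_edges,
)


def _matrix(taxa, rows):
    return pt.CharacterMatrix(taxa=taxa, states=np.array([list(r) for r in rows]))


class TestFitchLength:
    def test_invariant_character_contributes_zero(self):
        m = _matrix(list("ABCD"), ["00", "00", "00", "01"])
        tree = pt.read_newick("((A,B),(C,D));")
        assert pt.fitch_length(tree, m) == 1  # only the variable character

    def test_textbook_four_taxon_case(self):
        m = _matrix(list("ABCD"), ["0", "0", "1", "1"])
        assert pt.fitch_length(pt.read_newick("((A,B),(C,D));"), m) == 1
        assert pt.fitch_length(pt.read_newick("((A,C),(B,D));"), m) == 2

    def test_missing_matches_everything(self):
        m = _matrix(list("ABCD"), ["0", "?", "1", "1"])
        assert pt.fitch_length(pt.read_newick("((A,B),(C,D));"), m) == 1

    def test_rerooting_and_taxon_order_invariance(self, rng):
        m = random_matrix(rng, 6, 15)
        t1 = pt.read_newick("((t0,t1),((t2,t3),(t4,t5)));")
        t2 = pt.read_newick("(((t4,t5),(t2,t3)),t1,t0);")  # rerooted/unrooted form
        assert pt.fitch_length(t1, m) == pt.fitch_length(t2, m)
        perm = list(rng.permutation(6))
        m2 = pt.CharacterMatrix(
            taxa=[m.taxa[i] for i in perm], states=m.states[perm]
        )
        assert pt.fitch_length(t1, m2) == pt.fitch_length(t1, m)

    def test_leaf_taxon_mismatch_named(self):
        m = _matrix(list("ABCD"), ["01", "00", "10", "11"])
        with pytest.raises(ValueError, match="E"):
            pt.fitch_length(pt.read_newick("((A,B),(C,E));"), m)

    def test_matches_exhaustive_assignment_oracle(self, rng):
        # random trees x random multistate matrices, brute-forced per character
        for _ in range(25):
            n = 8
            edges = random_unrooted_tree_edges(n, rng)
            m = random_matrix(rng, n, 10)
            tree = _tree_from_edges(edges, m.taxa)
            assert pt.fitch_length(tree, m) == exhaustive_matrix_length(
                edges, m.states
            )


def _tree_from_edges(edges, taxa):
    """Newick text from an oracle edge list (leaves 0..n-1 -> taxa names)."""
    adj = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    root = max(adj)  # an internal node

    def sub(u, parent):
        kids = [v for v in adj[u] if v != parent]
        if not kids:
            return taxa[u]
        return "(" + ",".join(sub(v, u) for v in kids) + ")"

    return pt.read_newick(sub(root, None) + ";")


class TestSearch:
    def test_compatible_characters_unique_mpt(self):
        # characters jointly supporting ((A,B),(C,D),E)
        m = _matrix(list("ABCDE"), ["11", "11", "00", "00", "10"])
        res = pt.search_mpt(m, mode="exact")
        assert res.n_trees == 1
        splits = _from_dendropy(res.mpts[0], m.taxa).bipartitions()
        assert frozenset([2, 3]) in splits or frozenset([0, 1]) in splits

    def test_branch_and_bound_equals_exhaustive_enumeration(self, rng):
        # 9-taxon matrices: MPT sets identical to scoring all 135135 topologies
        for _ in range(3):
            m = random_matrix(rng, 9, 12, n_states=2)
            best_len, oracle_splits = exhaustive_mpt_splits(m.states)
            res = pt.search_mpt(m, mode="exact")
            assert res.score.L == best_len
            found = {
                _from_dendropy(t, m.taxa).bipartitions() for t in res.mpts
            }
            assert found == oracle_splits

    def test_heuristic_attains_exact_optimum(self, rng):
        m = random_matrix(rng, 9, 15, n_states=2)
        exact = pt.search_mpt(m, mode="exact")
        hits = sum(
            pt.search_mpt(m, mode="heuristic", seed=s, n_starts=10).score.L
            == exact.score.L
            for s in range(1, 6)
        )
        assert hits >= 4

    def test_too_few_taxa_rejected(self):
        m = _matrix(list("ABC"), ["0", "1", "0"])
        with pytest.raises(ValueError, match="4 taxa"):
            pt.search_mpt(m)

    def test_zero_homoplasy_recovers_generating_topology(self, six_taxon_tree):
        spec = pt.SimSpec(
            seed=5, tree=six_taxon_tree, n_chars=12, homoplasy_rate=0.0,
            ensure_coverage=True,
        )
        m = pt.simulate_characters(spec)
        res = pt.search_mpt(m, mode="exact")
        assert res.n_trees == 1
        want = _from_dendropy(six_taxon_tree, m.taxa).bipartitions()
        got = _from_dendropy(res.mpts[0], m.taxa).bipartitions()
        assert got == want


class TestEnsembleIndices:
    def test_homoplasy_free_matrix_all_ones(self, six_taxon_tree):
        m = pt.simulate_characters(
            pt.SimSpec(seed=2, tree=six_taxon_tree, n_chars=10, ensure_coverage=True)
        )
        s = pt.ensemble_indices(six_taxon_tree, m)
        assert (s.CI, s.HI, s.RI, s.RC) == (1.0, 0.0, 1.0, 1.0)

    def test_identities_reproduce_reported_values(self):
        # CI = 0.66, RI = 0.65 imply HI = 0.34 and RC = 0.43 at 2 decimals
        HI, RC = combine_indices(0.66, 0.65)
        assert round(HI, 2) == 0.34
        assert round(RC, 2) == 0.43

    def test_matches_per_character_oracle(self, rng):
        for _ in range(10):
            m = random_matrix(rng, 8, 12)
            edges = random_unrooted_tree_edges(8, rng)
            tree = _tree_from_edges(edges, m.taxa)
            score = pt.ensemble_indices(tree, m)
            internal = _from_dendropy(tree, m.taxa)
            steps = _per_character_steps(internal, _encode_matrix(m))
            L, CI, HI, RI, RC = naive_indices(
                list(steps), list(_per_character_minima(m)), list(_per_character_maxima(m))
            )
            assert score.L == L
            assert score.CI == pytest.approx(CI, abs=1e-12)
            assert score.HI == pytest.approx(HI, abs=1e-12)
            assert score.RI == pytest.approx(RI, abs=1e-12)
            assert score.RC == pytest.approx(RC, abs=1e-12)

    def test_hi_complement_and_rc_product_exact(self, rng):
        m = random_matrix(rng, 7, 20)
        tree = _tree_from_edges(random_unrooted_tree_edges(7, rng), m.taxa)
        s = pt.ensemble_indices(tree, m)
        assert s.HI == 1.0 - s.CI
        assert s.RC == s.CI * s.RI

    def test_all_invariant_matrix_signalled(self):
        m = _matrix(list("ABCD"), ["0", "0", "0", "0"])
        with pytest.raises(ValueError, match="CI undefined"):
            pt.ensemble_indices(pt.read_newick("((A,B),(C,D));"), m)


class TestConsensus:
    def test_identical_trees_unchanged(self):
        t = pt.read_newick("((A,B),((C,D),E));")
        cons = pt.strict_consensus([t, pt.read_newick("((A,B),((C,D),E));")])
        taxa = sorted(l.taxon.label for l in t.leaf_node_iter())
        assert _from_dendropy(cons, taxa).bipartitions() == _from_dendropy(
            t, taxa
        ).bipartitions()

    def test_conflicting_pair_collapses_to_star(self):
        a = pt.read_newick("((A,B),C,D);")
        b = pt.read_newick("((A,C),B,D);")
        cons = pt.strict_consensus([a, b])
        assert _from_dendropy(cons, list("ABCD")).bipartitions() == frozenset()

    def test_consensus_splits_occur_in_every_input(self, rng):
        for _ in range(10):
            taxa = [f"t{i}" for i in range(8)]
            trees = [
                _tree_from_edges(random_unrooted_tree_edges(8, rng), taxa)
                for _ in range(2)
            ]
            cons = pt.strict_consensus(trees)
            cs = _from_dendropy(cons, taxa).bipartitions()
            for t in trees:
                assert cs <= _from_dendropy(t, taxa).bipartitions()

    def test_leaf_set_mismatch_rejected(self):
        with pytest.raises(ValueError, match="leaf sets"):
            pt.strict_consensus(
                [pt.read_newick("((A,B),(C,D));"), pt.read_newick("((A,B),(C,E));")]
            )


class TestBootstrap:
    def test_strong_signal_high_support(self, six_taxon_tree):
        m = pt.simulate_characters(
            pt.SimSpec(seed=3, tree=six_taxon_tree, n_chars=18, homoplasy_rate=0.0,
                       ensure_coverage=True)
        )
        support = pt.bootstrap(m, replicates=100, seed=3)
        true_clades = [{"A", "B"}, {"C", "D"}, {"E", "F"}]
        for clade in true_clades:
            key = next(
                (k for k in support if k == frozenset(clade)
                 or k == frozenset(m.taxa) - frozenset(clade)),
                None,
            )
            assert key is not None and support[key] >= 95.0

    def test_reproducible_for_fixed_seed(self, six_taxon_tree):
        m = pt.simulate_characters(
            pt.SimSpec(seed=4, tree=six_taxon_tree, n_chars=12, homoplasy_rate=0.5)
        )
        a = pt.bootstrap(m, replicates=30, seed=9)
        b = pt.bootstrap(m, replicates=30, seed=9)
        assert a == b

    def test_model_facade_summary_and_annotation(self, six_taxon_tree):
        m = pt.simulate_characters(
            pt.SimSpec(seed=6, tree=six_taxon_tree, n_chars=14, ensure_coverage=True)
        )
        res = pt.ParsimonyModel(m).fit()
        res.bootstrap_support(replicates=20, seed=1)
        cons = res.annotated_consensus()
        labels = [
            n.label for n in cons.preorder_internal_node_iter() if n.label
        ]
        assert labels and all(0 <= float(l) <= 100 for l in labels)
        assert "L = " in res.summary()
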