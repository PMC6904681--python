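"""Newick I/O and rooted-tree operations."""

import numpy as np
import pytest

from plclock import (
    NewickParseError,
    TreeError,
    TreeSet,
    read_newick,
    read_tree_list,
    write_tree_list,
)
from plclock.simulate import perturb_tree, simulate_chronogram


def _path_lengths(tree):
    """All-pairs terminal path lengths via root-to-tip traversal (oracle)."""
    depths = tree.depths()
    paths = {}
    leaves = tree.leaves()
    anc = {}
    for leaf in leaves:
        chain = []
        n = leaf
        while n is not None:
            chain.append(n)
            n = n.parent
        anc[leaf] = chain
    for i, a in enumerate(leaves):
        for b in leaves[i + 1 :]:
            common = next(n for n in anc[a] if n in set(anc[b]))
            paths[frozenset([a.label, b.label])] = (
                depths[a] + depths[b] - 2 * depths[common]
            )
    return paths


class TestReadNewick:
    def test_basic_structure(self, basic_tree):
        assert sorted(basic_tree.leaf_labels()) == ["A", "B", "C"]
        assert len(basic_tree.root.children) == 2
        assert basic_tree.find_leaf("C").length == 2.0

    def test_round_trip_identity(self, basic_tree):
        again = read_newick(basic_tree.to_newick())
        assert again.to_newick() == basic_tree.to_newick()

    @pytest.mark.parametrize(
        "bad",
        ["((A:1,B:1):1,C:2", "", "((A:1,A:1):1,C:2);", ";"],
        ids=["unterminated", "empty", "duplicate-labels", "no-content"],
    )
    def test_malformed_input(self, bad):
        with pytest.raises(NewickParseError):
            read_newick(bad)

    def test_missing_lengths_default_zero_with_warning(self):
        with pytest.warns(UserWarning, match="no length"):
            tree = read_newick("((A,B):1,C:2);")
        assert tree.find_leaf("A").length == 0.0

    def test_quoted_labels_and_comments(self):
        tree = read_newick("(('taxon one':1,B:1)90:1,C:2)[a comment];")
        assert "taxon one" in tree.leaf_labels()

    def test_support_labels_parsed(self):
        tree = read_newick("((A:1,B:1)95:1,C:2);")
        internal = [n for n in tree.preorder() if not n.is_leaf and n.parent]
        assert internal[0].support == 95.0


class TestTreeList:
    def test_two_records(self):
        ts = read_tree_list("(A:1,B:1);\n(A:2,B:2);\n")
        assert len(ts) == 2

    def test_empty_errors(self):
        with pytest.raises(NewickParseError, match="empty tree set"):
            read_tree_list("   \n")

    def test_malformed_record_reports_index(self):
        with pytest.raises(NewickParseError, match="record 1"):
            read_tree_list("(A:1,B:1);\n(A:1,A:1);\n")

    def test_simulated_bootstrap_count_and_round_trip(self):
        base = simulate_chronogram(10, 20.0, seed=5)
        ts = perturb_tree(base, n_replicates=100, nni_prob=0.1, seed=5, s=500)
        assert len(ts) == 100
        again = read_tree_list(write_tree_list(ts))
        assert len(again) == 100
        assert again[0].to_newick() == ts[0].to_newick()

    def test_universe_violation(self):
        t1 = read_newick("(A:1,B:1);")
        with pytest.raises(TreeError, match="universe"):
            TreeSet(trees=[t1], universe=frozenset({"A"}))


class TestMRCA:
    def test_all_terminals_is_root(self, basic_tree):
        assert basic_tree.mrca({"A", "B", "C"}) is basic_tree.root

    def test_single_taxon_is_itself(self, basic_tree):
        assert basic_tree.mrca({"A"}) is basic_tree.find_leaf("A")

    def test_unknown_label_errors(self, basic_tree):
        with pytest.raises(TreeError, match="Z"):
            basic_tree.mrca({"A", "Z"})

    def test_against_path_intersection_oracle(self):
        tree = simulate_chronogram(40, 100.0, seed=3)
        rng = np.random.default_rng(3)
        labels = tree.leaf_labels()
        for _ in range(25):
            taxa = set(rng.choice(labels, size=5, replace=False))
            # oracle: intersect root-to-tip ancestor chains, take deepest
            chains = []
            for t in taxa:
                chain = []
                n = tree.find_leaf(t)
                while n is not None:
                    chain.append(n)
                    n = n.parent
                chains.append(chain)
            shared = set(chains[0]).intersection(*map(set, chains[1:]))
            depths = tree.depths()
            expected = max(shared, key=lambda n: depths[n])
            assert tree.mrca(taxa) is expected

    def test_idempotent_under_leafset_closure(self):
        tree = simulate_chronogram(20, 10.0, seed=7)
        rng = np.random.default_rng(7)
        labels = tree.leaf_labels()
        for _ in range(10):
            taxa = set(rng.choice(labels, size=4, replace=False))
            node = tree.mrca(taxa)
            assert tree.mrca(tree.leafset(node)) is node


class TestMonophyly:
    def test_examples(self, basic_tree):
        assert basic_tree.is_monophyletic({"A", "B"})
        assert not basic_tree.is_monophyletic({"A", "C"})

    def test_against_leafset_enumeration(self):
        tree = simulate_chronogram(15, 10.0, seed=9)
        clades = {tree.leafset(n) for n in tree.preorder()}
        rng = np.random.default_rng(9)
        labels = tree.leaf_labels()
        for _ in range(30):
            size = int(rng.integers(1, 8))
            taxa = frozenset(rng.choice(labels, size=size, replace=False))
            assert tree.is_monophyletic(taxa) == (taxa in clades)


class TestPrune:
    def test_prune_root_child(self, basic_tree):
        pruned = basic_tree.prune_terminal("C")
        assert pruned.to_newick() == "(A:1,B:1);"

    def test_prune_sums_suppressed_lengths(self, basic_tree):
        pruned = basic_tree.prune_terminal("A")
        assert sorted(pruned.leaf_labels()) == ["B", "C"]
        assert pruned.find_leaf("B").length == pytest.approx(2.0)
        assert pruned.find_leaf("C").length == pytest.approx(2.0)

    def test_original_untouched(self, basic_tree):
        before = basic_tree.to_newick()
        basic_tree.prune_terminal("A")
        assert basic_tree.to_newick() == before

    def test_too_few_terminals(self):
        with pytest.raises(TreeError, match="fewer than 2"):
            read_newick("(A:1,B:1);").prune_terminal("A")

    def test_preserves_pairwise_path_lengths(self):
        tree = simulate_chronogram(12, 30.0, seed=13)
        before = _path_lengths(tree)
        for label in tree.leaf_labels()[:6]:
            pruned = tree.prune_terminal(label)
            assert pruned.n_leaves == tree.n_leaves - 1
            after = _path_lengths(pruned)
            for pair, dist in after.items():
                assert dist == pytest.approx(before[pair], rel=1e-9)


class TestNodeAges:
    def test_examples(self, basic_tree):
        ages = basic_tree.node_ages()
        assert ages[basic_tree.root] == pytest.approx(2.0)
        ab = basic_tree.mrca({"A", "B"})
        assert ages[ab] == pytest.approx(1.0)
        assert ages[basic_tree.find_leaf("C")] == 0.0

    def test_single_cherry(self):
        tree = read_newick("(A:5,B:5);")
        assert tree.node_ages()[tree.root] == pytest.approx(5.0)

    def test_non_ultrametric_errors_with_spread(self):
        tree = read_newick("((A:1,B:2):1,C:2);")
        with pytest.raises(TreeError, match="spread"):
            tree.node_ages()

    def test_generator_truth(self):
        tree = simulate_chronogram(25, 80.0, seed=21)
        ages = tree.node_ages()
        assert ages[tree.root] == pytest.approx(80.0, rel=1e-9)
        for node in tree.preorder():
            if node.parent is not None:
                assert ages[node.parent] >= ages[node] - 1e-9
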