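"""Tree distances, trimming and composite scores."""
import itertools

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from gtdiscord.trees import (EST1, EST2, TIE, LeafSetMismatchError, PhyloTree,
                             distance_score, normalized_rf, path_distance,
                             rank_discordance, rf_distance, root_on_outgroup,
                             selected_relationships_score,
                             topo_distance_matrix, trim_to_common_taxa)

from conftest import random_topology


def dendropy_rf(t1: PhyloTree, t2: PhyloTree) -> int:
    """Independent RF oracle via dendropy's bipartition encoding."""
    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(data=t1.to_newick(), schema="newick",
                          preserve_underscores=True, taxon_namespace=tns)
    b = dendropy.Tree.get(data=t2.to_newick(), schema="newick",
                          preserve_underscores=True, taxon_namespace=tns)
    for t in (a, b):
        t.is_rooted = False
        t.deroot()
        t.encode_bipartitions()
    return int(treecompare.symmetric_difference(a, b))


def brute_force_path_matrix(t: PhyloTree, labels):
    """Edge-count path lengths by explicit all-pairs traversal on an
    adjacency list built independently of topo_distance_matrix."""
    clone = dendropy.Tree.get(data=t.to_newick(), schema="newick",
                              preserve_underscores=True)
    clone.is_rooted = False
    clone.deroot()
    adj = {}
    for edge in clone.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        a, b = id(edge.tail_node), id(edge.head_node)
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    leaf = {lf.taxon.label: id(lf) for lf in clone.leaf_node_iter()}
    n = len(labels)
    D = np.zeros((n, n))
    for i, la in enumerate(labels):
        # Dijkstra-free BFS
        dist = {leaf[la]: 0}
        frontier = [leaf[la]]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        for j, lb in enumerate(labels):
            D[i, j] = dist[leaf[lb]]
    return D


class TestTrim:
    def test_identity(self):
        t = PhyloTree.from_newick("(((a,b),c),(d,e));")
        out = trim_to_common_taxa(t, t.taxa)
        assert rf_distance(out, t) == 0

    def test_caterpillar_example(self):
        t = PhyloTree.from_newick("((((a,b),c),d),e);")
        out = trim_to_common_taxa(t, {"a", "c", "d", "e"})
        expected = PhyloTree.from_newick("((a,c),d,e);")
        assert rf_distance(out, expected) == 0

    def test_branch_lengths_summed(self):
        t = PhyloTree.from_newick("((((a:1,b:1):2,c:1):3,d:1):1,e:1);")
        out = trim_to_common_taxa(t, {"a", "c", "d", "e"})
        lengths = {lf.taxon.label: lf.edge.length
                   for lf in out.tree.leaf_node_iter()}
        assert lengths["a"] == pytest.approx(3.0)  # 1 + suppressed 2

    def test_not_a_subset_errors(self):
        t = PhyloTree.from_newick("((a,b),(c,d));")
        with pytest.raises(ValueError):
            trim_to_common_taxa(t, {"a", "b", "c", "x"})

    def test_too_few_tips_errors(self):
        t = PhyloTree.from_newick("((a,b),(c,d),e);")
        with pytest.raises(ValueError):
            trim_to_common_taxa(t, {"a", "b", "c"})

    def test_does_not_mutate_source(self):
        t = PhyloTree.from_newick("((a,b),(c,d),e);")
        trim_to_common_taxa(t, {"a", "b", "c", "d"})
        out = trim_to_common_taxa(t, {"a", "b", "c", "e"})
        assert out.taxa == {"a", "b", "c", "e"}


class TestRF:
    def test_identical_is_zero(self, quartet_ab):
        assert rf_distance(quartet_ab, quartet_ab.copy()) == 0

    def test_conflicting_quartets(self, quartet_ab, quartet_ac):
        assert rf_distance(quartet_ab, quartet_ac) == 2
        assert normalized_rf(quartet_ab, quartet_ac) == pytest.approx(1.0)

    def test_leaf_set_mismatch_names_taxa(self, quartet_ab):
        other = PhyloTree.from_newick("((a,b),(c,e));")
        with pytest.raises(LeafSetMismatchError, match="e"):
            rf_distance(quartet_ab, other)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_dendropy_oracle(self, seed):
        t1 = random_topology(20, seed)
        t2 = random_topology(20, seed + 100)
        assert rf_distance(t1, t2) == dendropy_rf(t1, t2)

    @pytest.mark.parametrize("seed", range(4))
    def test_metric_axioms(self, seed):
        a = random_topology(12, seed)
        b = random_topology(12, seed + 10)
        c = random_topology(12, seed + 20)
        assert rf_distance(a, b) == rf_distance(b, a)
        assert rf_distance(a, a.copy()) == 0
        assert rf_distance(a, c) <= rf_distance(a, b) + rf_distance(b, c)
        assert 0.0 <= normalized_rf(a, b) <= 1.0

    def test_rooting_is_ignored(self):
        unrooted = PhyloTree.from_newick("((a,b),(c,d),e);")
        rooted = root_on_outgroup(unrooted, "e")
        assert rf_distance(rooted, unrooted) == 0


class TestPathDistance:
    def test_identical_is_zero(self, quartet_ab):
        assert path_distance(quartet_ab, quartet_ab.copy()) == 0.0

    def test_quartet_example(self, quartet_ab, quartet_ac):
        # pairwise edge-count vectors (2,3,3,3,3,2) vs (3,2,3,3,2,3)
        assert path_distance(quartet_ab, quartet_ac) == pytest.approx(2.0)
        assert path_distance(quartet_ab, quartet_ac,
                             form="sum_abs") == pytest.approx(4.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force(self, seed):
        t1 = random_topology(15, seed)
        t2 = random_topology(15, seed + 50)
        labels = sorted(t1.taxa)
        d1 = brute_force_path_matrix(t1, labels)
        d2 = brute_force_path_matrix(t2, labels)
        iu = np.triu_indices(len(labels), k=1)
        expected = float(np.sqrt(np.sum((d1[iu] - d2[iu]) ** 2)))
        assert path_distance(t1, t2) == pytest.approx(expected)
        np.testing.assert_array_equal(topo_distance_matrix(t1, labels), d1)


class TestRankDiscordance:
    def test_est1_equals_ref(self, quartet_ab, quartet_ac):
        five1 = PhyloTree.from_newick("(((a,b),c),(d,e));")
        five2 = PhyloTree.from_newick("(((a,d),c),(b,e));")
        rec = rank_discordance(five1.copy(), five2, five1)
        assert rec.least_discordant == EST1
        assert rec.most_discordant == EST2
        assert rec.metrics_agree

    def test_tie_disqualifies(self, quartet_ab, quartet_ac):
        rec = rank_discordance(quartet_ac.copy(), quartet_ac, quartet_ab)
        assert rec.least_discordant == TIE
        assert not rec.metrics_agree

    def test_distances_symmetric_fields(self):
        t1 = random_topology(10, 1)
        t2 = random_topology(10, 2)
        ref = random_topology(10, 3)
        rec = rank_discordance(t1, t2, ref)
        assert rec.rf_est1_est2 == rf_distance(t1, t2)
        assert rec.rf_est1_ref == rf_distance(t1, ref)
        assert 0.0 <= rec.normalized_rf_est1_ref <= 1.0


class TestDistanceScore:
    def test_optimal_tree_scores_one(self):
        concat = PhyloTree.from_newick("(((a,b),c),((d,e),f));")
        max_d = PhyloTree.from_newick("(((a,e),d),((c,f),b));")
        test = concat.copy()
        min_d = concat.copy()
        score = distance_score(test, concat, min_d, max_d)
        assert score == pytest.approx(1.0)

    def test_worst_tree_scores_zero(self):
        concat = PhyloTree.from_newick("(((a,b),c),((d,e),f));")
        max_d = PhyloTree.from_newick("(((a,e),d),((c,f),b));")
        score = distance_score(max_d.copy(), concat, concat.copy(), max_d)
        assert score == pytest.approx(0.0)

    def test_matches_hand_computation(self):
        test = random_topology(10, 7)
        concat = random_topology(10, 8)
        min_d = random_topology(10, 9)
        max_d = random_topology(10, 10)
        trees = [test, concat, min_d, max_d]
        rf = np.zeros((4, 4))
        pd_ = np.zeros((4, 4))
        for i in range(4):
            for j in range(i + 1, 4):
                rf[i, j] = rf[j, i] = rf_distance(trees[i], trees[j])
                pd_[i, j] = pd_[j, i] = path_distance(trees[i], trees[j])
        c = [0.5 * (rf[0, i] / rf.max() + pd_[0, i] / pd_.max())
             for i in (1, 2, 3)]
        expected = ((1 - c[0]) + (1 - c[1]) + c[2]) / 3
        assert distance_score(test, concat, min_d, max_d) == pytest.approx(expected)

    def test_degenerate_errors(self):
        t = PhyloTree.from_newick("((a,b),(c,d));")
        with pytest.raises(ValueError):
            distance_score(t, t.copy(), t.copy(), t.copy())


class TestSelectedRelationships:
    concat = PhyloTree.from_newick("((((a,b),c),d),(e,(f,g)));", rooted=True)
    max_d = PhyloTree.from_newick("((((a,e),c),d),(b,(f,g)));", rooted=True)

    def test_empty_list_scores_zero(self):
        assert selected_relationships_score(
            self.concat, [], self.concat, self.concat, self.max_d) == 0

    def test_all_concat_clades_not_in_max(self):
        clades = [frozenset(lf.taxon.label for lf in nd.leaf_iter())
                  for nd in self.concat.tree.postorder_node_iter()
                  if nd.child_nodes() and nd is not self.concat.tree.seed_node]
        rels = [s for s in clades if len(s) >= 2
                and not self.max_d.is_monophyletic(s)]
        score = selected_relationships_score(
            self.concat.copy(), rels, self.concat, self.concat, self.max_d)
        assert score == len(rels)

    def test_manual_tally(self):
        test = PhyloTree.from_newick("((((a,b),d),c),(e,(f,g)));", rooted=True)
        rels = [{"a", "b"}, {"a", "b", "c"}, {"f", "g"}]
        # {a,b}: in test and concat -> +1; {a,b,c}: not in test -> 0;
        # {f,g}: in test, in concat (+1) and in max_d (-1) -> 0
        score = selected_relationships_score(
            test, rels, self.concat, self.concat, self.max_d)
        assert score == 1

    def test_unknown_taxa_error(self):
        with pytest.raises(ValueError, match="unknown"):
            selected_relationships_score(
                self.concat, [{"a", "zz"}], self.concat, self.concat,
                self.max_d)
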