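"""Coalescent species trees from gene-tree sets, and their evaluation.

The species-tree estimator maximizes the induced-quartet agreement score
with the gene-tree set (the optimality criterion of quartet-based
coalescent methods): exhaustive enumeration up to 8 taxa, NNI hill-climbing
from a greedy bipartition consensus (or an NJ start when taxon sets vary)
above that.  Gene trees may sample different taxa; each contributes only
the quartets it resolves.  Per-branch evaluation covers quartet support,
gene concordance factors, split frequencies and multispecies-coalescent
branch lengths inverted from quartet frequencies, plus tree-level scores:
the composite distance score, selected-relationship tallies, predictive
power against an independent gene-tree sample, and control-node presence.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .trees import (PhyloTree, distance_score, rf_distance,
                    selected_relationships_score, topo_distance_matrix,
                    trim_to_common_taxa)


# --------------------------------------------------------------------------
# quartet machinery
# --------------------------------------------------------------------------
def _quartet_topologies(tree: PhyloTree, global_index: Mapping[str, int]
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Resolved quartet topologies of ``tree`` in global taxon ids.

    Returns (quartets, topologies): quartets is (Q, 4) of sorted global
    ids; topologies[q] in {0,1,2} encodes which taxon pairs with the
    smallest id (0: second, 1: third, 2: fourth), or -1 if unresolved.
    """
    labels = sorted(tree.taxa, key=lambda l: global_index[l])
    gids = np.array([global_index[l] for l in labels])
    D = topo_distance_matrix(tree, labels)
    n = len(labels)
    if n < 4:
        return np.empty((0, 4), dtype=int), np.empty(0, dtype=int)
    combos = np.array(list(itertools.combinations(range(n), 4)))
    a, b, c, d = combos.T
    s0 = D[a, b] + D[c, d]  # ab|cd
    s1 = D[a, c] + D[b, d]  # ac|bd
    s2 = D[a, d] + D[b, c]  # ad|bc
    sums = np.stack([s0, s1, s2], axis=1)
    topo = np.argmin(sums, axis=1)
    sorted_sums = np.sort(sums, axis=1)
    topo[sorted_sums[:, 0] == sorted_sums[:, 1]] = -1  # unresolved
    return gids[combos], topo


class QuartetSet:
    """Precomputed resolved quartets of a gene-tree set, in global ids."""

    def __init__(self, gene_trees: Sequence[PhyloTree],
                 taxa: Sequence[str] | None = None):
        if not gene_trees:
            raise ValueError("need at least one gene tree")
        union: set[str] = set()
        for gt in gene_trees:
            union |= gt.taxa
        self.taxa = sorted(taxa if taxa is not None else union)
        if len(self.taxa) < 4:
            raise ValueError("need at least 4 taxa")
        self.index = {l: i for i, l in enumerate(self.taxa)}
        self._qmap: dict[tuple[int, ...], np.ndarray] = {}
        counts: dict[tuple[int, ...], np.ndarray] = {}
        for gt in gene_trees:
            quartets, topo = _quartet_topologies(gt, self.index)
            for q, t in zip(quartets, topo):
                if t < 0:
                    continue
                key = tuple(int(x) for x in q)
                if key not in counts:
                    counts[key] = np.zeros(3, dtype=np.int64)
                counts[key][t] += 1
        self.keys = sorted(counts)
        self.key_index = {k: i for i, k in enumerate(self.keys)}
        self.counts = np.array([counts[k] for k in self.keys], dtype=np.int64) \
            if self.keys else np.zeros((0, 3), dtype=np.int64)
        self.n_gene_trees = len(gene_trees)

    def covers_all_pairs(self) -> bool:
        covered = np.zeros((len(self.taxa), len(self.taxa)), dtype=bool)
        for key in self.keys:
            for i, j in itertools.combinations(key, 2):
                covered[i, j] = True
        iu = np.triu_indices(len(self.taxa), k=1)
        return bool(covered[iu].all())

    def score(self, tree: PhyloTree) -> int:
        """Total number of gene-tree quartets agreeing with ``tree``."""
        quartets, topo = _quartet_topologies(tree, self.index)
        total = 0
        for q, t in zip(quartets, topo):
            if t < 0:
                continue
            row = self.key_index.get(tuple(int(x) for x in q))
            if row is not None:
                total += int(self.counts[row, t])
        return total


# --------------------------------------------------------------------------
# species-tree search
# --------------------------------------------------------------------------
def _all_unrooted_topologies(taxa: Sequence[str]):
    """Yield every unrooted binary topology as a newick string (<= 8 taxa)."""
    taxa = sorted(taxa)
    if len(taxa) > 8:
        raise ValueError("exhaustive enumeration limited to 8 taxa")

    def grow(structure, leaf):
        # structure is a nested tuple representing an unrooted tree rooted
        # arbitrarily at a trifurcation: (a, b, c) at top level
        yield from _insert_all(structure, leaf)

    def _insert_all(node, leaf):
        if isinstance(node, str):
            yield (node, leaf)
            return
        for i, child in enumerate(node):
            for new_child in _insert_all(child, leaf):
                yield tuple(new_child if j == i else c
                            for j, c in enumerate(node))
        # also insert into the edge above this node (only for binary pairs)
        if len(node) == 2:
            yield (node, leaf)

    def to_newick(node) -> str:
        if isinstance(node, str):
            return node
        return "(" + ",".join(to_newick(c) for c in node) + ")"

    trees = [(taxa[0], taxa[1], taxa[2])]
    for leaf in taxa[3:]:
        new_trees = []
        for tr in trees:
            # insert on each of the three top edges or within subtrees
            for i, child in enumerate(tr):
                for new_child in _insert_all(child, leaf):
                    new_trees.append(tuple(
                        new_child if j == i else c for j, c in enumerate(tr)))
        trees = new_trees
    for tr in trees:
        yield to_newick(tr) + ";"


def greedy_consensus_start(gene_trees: Sequence[PhyloTree],
                           taxa: Sequence[str]) -> PhyloTree:
    """Start tree for the NNI search.

    When all gene trees share the full taxon set: greedy bipartition
    consensus (splits added in frequency order when compatible), resolved
    arbitrarily to binary.  Otherwise: neighbor joining on the across-tree
    average topological distance matrix.
    """
    taxa = sorted(taxa)
    same = all(gt.taxa == frozenset(taxa) for gt in gene_trees)
    if same:
        from collections import Counter
        counter: Counter = Counter()
        for gt in gene_trees:
            counter.update(gt.unrooted_splits())
        chosen: list[frozenset] = []
        for split, _ in counter.most_common():
            if all(_compatible(split, other, taxa) for other in chosen):
                chosen.append(split)
        tree = _tree_from_splits(chosen, taxa)
    else:
        n = len(taxa)
        idx = {l: i for i, l in enumerate(taxa)}
        total = np.zeros((n, n))
        count = np.zeros((n, n))
        for gt in gene_trees:
            labels = sorted(gt.taxa)
            D = topo_distance_matrix(gt, labels)
            ids = [idx[l] for l in labels]
            for a in range(len(labels)):
                for b in range(a + 1, len(labels)):
                    i, j = ids[a], ids[b]
                    total[i, j] += D[a, b]
                    total[j, i] += D[a, b]
                    count[i, j] += 1
                    count[j, i] += 1
        if np.any(count[np.triu_indices(n, k=1)] == 0):
            raise ValueError("taxon overlap too sparse: some taxon pair "
                             "never co-occurs in a gene tree")
        with np.errstate(invalid="ignore"):
            D = np.where(count > 0, total / np.maximum(count, 1), 0.0)
        np.fill_diagonal(D, 0.0)
        import io
        from skbio import DistanceMatrix
        from skbio.tree import nj
        buf = io.StringIO()
        nj(DistanceMatrix(D, ids=taxa)).write(buf)
        tree = PhyloTree.from_newick(buf.getvalue().replace(":-", ":"),
                                     rooted=False)
    return _resolve_binary(tree)


def _compatible(s1: frozenset, s2: frozenset, taxa: Sequence[str]) -> bool:
    full = frozenset(taxa)
    for a in (s1, full - s1):
        for b in (s2, full - s2):
            if not (a & b):
                return True
    return False


def _tree_from_splits(splits: Sequence[frozenset], taxa: Sequence[str]) -> PhyloTree:
    """Build a tree containing the given compatible unrooted splits."""
    import dendropy
    anchor = sorted(taxa)[0]
    # root at the anchor: each split is the side not containing the anchor,
    # hence a clade of the rooted tree; insert larger clades first
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = True
    root = tree.seed_node
    node_of: dict[frozenset, object] = {}
    leaves = {}
    for lab in sorted(taxa):
        nd = dendropy.Node()
        nd.taxon = tns.require_taxon(lab)
        root.add_child(nd)
        leaves[lab] = nd
    for split in sorted(splits, key=len, reverse=True):
        side = frozenset(split)
        # find the node whose children cover exactly this set of leaves
        holder = root
        while True:
            advanced = False
            for child in holder.child_nodes():
                below = frozenset(lf.taxon.label for lf in child.leaf_iter())
                if side < below:
                    holder = child
                    advanced = True
                    break
            if not advanced:
                break
        group = [c for c in holder.child_nodes()
                 if frozenset(lf.taxon.label for lf in c.leaf_iter()) <= side]
        covered = frozenset(lab for c in group
                            for lab in (lf.taxon.label for lf in c.leaf_iter()))
        if covered != side or len(group) == len(holder.child_nodes()):
            continue  # incompatible in rooted form; skip defensively
        new = dendropy.Node()
        for c in group:
            holder.remove_child(c)
            new.add_child(c)
        holder.add_child(new)
    out = PhyloTree(tree, "none")
    return out


def _resolve_binary(tree: PhyloTree) -> PhyloTree:
    clone = tree.tree.clone(depth=1)
    clone.resolve_polytomies()
    clone.is_rooted = False
    clone.deroot()
    for edge in clone.preorder_edge_iter():
        if edge.length is None:
            edge.length = None
    return PhyloTree(clone, tree.units)


def estimate_species_tree(gene_trees: Sequence[PhyloTree],
                          mode: str = "auto") -> tuple[PhyloTree, int]:
    """Maximum quartet-agreement species tree for a gene-tree set.

    ``mode``: "exhaustive" (<= 8 taxa; all unrooted topologies scored),
    "nni" (hill-climb from the greedy consensus start), or "auto".
    Returns (tree, quartet score).
    """
    if len(gene_trees) < 2:
        raise ValueError("need at least two gene trees")
    qs = QuartetSet(gene_trees)
    if not qs.covers_all_pairs():
        raise ValueError("taxon overlap too sparse: some taxon pair is "
                         "covered by no quartet")
    n = len(qs.taxa)
    if mode == "auto":
        mode = "exhaustive" if n <= 8 else "nni"
    if mode == "exhaustive":
        best_tree, best_score = None, -1
        for newick in _all_unrooted_topologies(qs.taxa):
            cand = PhyloTree.from_newick(newick, rooted=False)
            s = qs.score(cand)
            if s > best_score:
                best_tree, best_score = cand, s
        return best_tree, best_score
    if mode != "nni":
        raise ValueError(f"unknown mode {mode!r}")
    from .genetree import nni_neighbors
    current = greedy_consensus_start(gene_trees, qs.taxa)
    current_score = qs.score(current)
    for _ in range(200):
        best_nb, best_score = None, current_score
        for nb in nni_neighbors(current):
            s = qs.score(nb)
            if s > best_score:
                best_nb, best_score = nb, s
        if best_nb is None:
            break
        current, current_score = best_nb, best_score
    return current, current_score


def load_annotated_species_tree(source: str,
                                ) -> tuple[PhyloTree, dict[frozenset, float]]:
    """Import an externally estimated species tree with branch supports.

    Accepts a newick string or a path to one.  Supports are read from
    ``[pp=...]`` bracket annotations on internal branches or from numeric
    internal-node labels (the usual support-as-label convention); they are
    returned as a map from canonical split to value, suitable for the
    ``support`` argument of :func:`branch_metrics`.
    """
    import re
    from pathlib import Path

    text = source
    if "(" not in text:
        text = Path(source).read_text()
    text = re.sub(r"\)\s*\[&?pp=([0-9.eE+-]+)\]", r")\1", text)
    text = re.sub(r"\[[^\]]*\]", "", text)  # drop remaining comments
    import dendropy
    tree = dendropy.Tree.get(data=text, schema="newick",
                             preserve_underscores=True,
                             suppress_internal_node_taxa=True)
    out = PhyloTree(tree, "none")
    taxa = out.taxa
    anchor = min(taxa)
    support: dict[frozenset, float] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf() or nd is tree.seed_node or nd.label is None:
            continue
        try:
            value = float(nd.label)
        except ValueError:
            continue
        side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if anchor in side:
            side = frozenset(taxa - side)
        if 2 <= len(side) <= len(taxa) - 2:
            support[side] = value
    return out, support


# --------------------------------------------------------------------------
# per-branch metrics
# --------------------------------------------------------------------------
@dataclass
class BranchMetrics:
    """Quartet frequencies and concordance measures around one branch."""

    split: frozenset[str]  # canonical side (without the anchor taxon)
    q1: float
    q2: float
    q3: float
    support: float  # q1 by default, or imported annotation
    coalescent_length: float
    gcf: float | None  # None when no gene tree is decisive
    split_frequency: float
    n_decisive: int

    @property
    def defined(self) -> bool:
        return self.gcf is not None


def coalescent_branch_length(q1: float) -> float:
    """Invert the MSC concordant-quartet probability to a branch length.

    x = -ln(3/2 (1 - q1)) for q1 > 1/3; 0 at or below the star-tree value
    1/3; +inf at q1 = 1.
    """
    if not (0.0 <= q1 <= 1.0):
        raise ValueError("q1 must be in [0, 1]")
    if q1 >= 1.0:
        return float("inf")
    if q1 <= 1.0 / 3.0:
        return 0.0
    return float(-np.log(1.5 * (1.0 - q1)))


def _edge_partitions(st: PhyloTree):
    """For each internal edge of the unrooted tree, the four neighbor
    leaf-sets (A, B below the child's two sides; C, D on the parent side)."""
    clone = st.tree.clone(depth=1)
    clone.is_rooted = False
    clone.deroot()
    all_taxa = frozenset(lf.taxon.label for lf in clone.leaf_node_iter())
    parts = []
    for nd in clone.postorder_node_iter():
        if nd.is_leaf() or nd is clone.seed_node:
            continue
        kids = nd.child_nodes()
        if len(kids) != 2:
            raise ValueError("branch metrics require a binary species tree")
        A = frozenset(lf.taxon.label for lf in kids[0].leaf_iter())
        B = frozenset(lf.taxon.label for lf in kids[1].leaf_iter())
        parent = nd.parent_node
        sibs = [c for c in parent.child_nodes() if c is not nd]
        C = frozenset(lf.taxon.label for lf in sibs[0].leaf_iter())
        D = all_taxa - A - B - C
        if not D:  # parent is the trifurcation seed with only two others
            if len(sibs) < 2:
                continue
            C = frozenset(lf.taxon.label for lf in sibs[0].leaf_iter())
            D = frozenset(lf.taxon.label for lf in sibs[1].leaf_iter())
        parts.append((A, B, C, D))
    return parts


def _restricted_split_in(gt_splits: set[frozenset], gt_taxa: frozenset,
                         side: frozenset, anchor_taxa: frozenset) -> bool:
    """Is the bipartition side|rest, restricted to gt_taxa, a split of gt?"""
    s = side & gt_taxa
    o = (anchor_taxa - side) & gt_taxa
    if len(s) < 2 or len(o) < 2:
        return False
    anchor = min(gt_taxa)
    canon = o if anchor in s else s
    return canon in gt_splits


def branch_metrics(st: PhyloTree, gene_trees: Sequence[PhyloTree],
                   support: Mapping[frozenset, float] | None = None
                   ) -> list[BranchMetrics]:
    """Quartet frequencies, gCF, split frequency and coalescent length for
    every internal branch of a binary species tree.

    Quartet frequencies q1/q2/q3 count, over all gene trees and all
    one-taxon-per-side quartets around the branch, how often the gene tree
    induces each resolution.  gCF is the fraction of decisive gene trees
    containing the branch's bipartition restricted to their taxa; split
    frequency is that fraction over all gene trees.  ``support`` may carry
    imported per-split support values (e.g. from an external coalescent
    run), otherwise q1 is used.
    """
    all_taxa = st.taxa
    anchor = min(all_taxa)
    gt_info = []
    for gt in gene_trees:
        labels = sorted(gt.taxa)
        gt_info.append((gt.taxa, {l: i for i, l in enumerate(labels)},
                        topo_distance_matrix(gt, labels),
                        gt.unrooted_splits()))
    out = []
    for A, B, C, D in _edge_partitions(st):
        counts = np.zeros(3)
        side = A | B
        canon = (all_taxa - side) if anchor in side else side
        n_concord = 0
        n_decisive = 0
        n_present = 0
        for gt_taxa, gt_idx, Dmat, gt_splits in gt_info:
            a_s = sorted(A & gt_taxa)
            b_s = sorted(B & gt_taxa)
            c_s = sorted(C & gt_taxa)
            d_s = sorted(D & gt_taxa)
            if a_s and b_s and c_s and d_s:
                ai = np.array([gt_idx[x] for x in a_s])
                bi = np.array([gt_idx[x] for x in b_s])
                ci = np.array([gt_idx[x] for x in c_s])
                di = np.array([gt_idx[x] for x in d_s])
                # pairwise path sums for the three pairings
                sab = Dmat[np.ix_(ai, bi)][:, :, None, None] \
                    + Dmat[np.ix_(ci, di)][None, None, :, :]
                sac = Dmat[np.ix_(ai, ci)][:, None, :, None] \
                    + Dmat[np.ix_(bi, di)][None, :, None, :]
                sad = Dmat[np.ix_(ai, di)][:, None, None, :] \
                    + Dmat[np.ix_(bi, ci)][None, :, :, None]
                stack = np.stack([sab, sac, sad])
                mins = stack.min(axis=0)
                resolved = (stack == mins).sum(axis=0) == 1
                winner = stack.argmin(axis=0)
                for topo in range(3):
                    counts[topo] += int(np.sum(resolved & (winner == topo)))
            # decisiveness for gCF: >= 2 taxa on each side after restriction
            s_r = side & gt_taxa
            o_r = (all_taxa - side) & gt_taxa
            if len(s_r) >= 2 and len(o_r) >= 2:
                n_decisive += 1
                if _restricted_split_in(gt_splits, gt_taxa, side, all_taxa):
                    n_concord += 1
                    n_present += 1
            elif _restricted_split_in(gt_splits, gt_taxa, side, all_taxa):
                n_present += 1
        total = counts.sum()
        if total > 0:
            q = counts / total
        else:
            q = np.array([np.nan, np.nan, np.nan])
        q1 = float(q[0]) if total > 0 else float("nan")
        sup = support.get(canon) if support else None
        out.append(BranchMetrics(
            split=canon,
            q1=q1, q2=float(q[1]) if total else float("nan"),
            q3=float(q[2]) if total else float("nan"),
            support=float(sup) if sup is not None else q1,
            coalescent_length=coalescent_branch_length(q1)
            if total > 0 else float("nan"),
            gcf=(n_concord / n_decisive) if n_decisive else None,
            split_frequency=n_present / len(gene_trees),
            n_decisive=n_decisive))
    return out


# --------------------------------------------------------------------------
# predictive power and control nodes
# --------------------------------------------------------------------------
def _st_split_frequency_in_gt(st: PhyloTree, gt: PhyloTree) -> float | None:
    """Fraction of the species tree's internal splits, restricted to the
    gene tree's taxa, that are present (and informative) in the gene tree."""
    gt_splits = gt.unrooted_splits()
    gt_taxa = gt.taxa
    all_taxa = st.taxa
    n_informative = 0
    n_found = 0
    for side in st.unrooted_splits():
        s = side & gt_taxa
        o = (all_taxa - side) & gt_taxa
        if len(s) < 2 or len(o) < 2:
            continue
        n_informative += 1
        if _restricted_split_in(gt_splits, gt_taxa, side, all_taxa):
            n_found += 1
    if n_informative == 0:
        return None
    return n_found / n_informative


def predictive_power(st: PhyloTree, independent_gts: Sequence[PhyloTree],
                     n_trials: int = 100, seed: int = 0
                     ) -> tuple[float, tuple[float, float], np.ndarray]:
    """How often the species tree's relationships appear in an independent
    gene-tree sample.

    Per gene tree: the fraction of the species tree's bipartitions
    (restricted to that tree's taxa) found in it.  The gene trees are
    resampled with replacement for ``n_trials`` trials; returns the mean of
    trial means, a 95% percentile interval, and the trial means themselves.
    """
    if not independent_gts:
        raise ValueError("independent gene-tree set is empty")
    freqs = np.array([f for f in
                      (_st_split_frequency_in_gt(st, gt)
                       for gt in independent_gts) if f is not None])
    if freqs.size == 0:
        raise ValueError("no independent gene tree is informative")
    rng = np.random.default_rng(seed)
    trial_means = np.array([
        float(np.mean(rng.choice(freqs, size=freqs.size, replace=True)))
        for _ in range(n_trials)])
    ci = (float(np.percentile(trial_means, 2.5)),
          float(np.percentile(trial_means, 97.5)))
    return float(trial_means.mean()), ci, trial_means


def compare_predictive_power(trials_a: np.ndarray, trials_b: np.ndarray
                             ) -> tuple[float, float]:
    """Two-sample z-test on two trial-mean distributions."""
    from scipy.stats import norm
    a = np.asarray(trials_a, dtype=float)
    b = np.asarray(trials_b, dtype=float)
    se = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
    if se == 0:
        return 0.0, 1.0
    z = (a.mean() - b.mean()) / se
    return float(z), float(2.0 * norm.sf(abs(z)))


def control_nodes_present(st: PhyloTree,
                          controls: Sequence[Iterable[str]]) -> int:
    """Number of predefined control clades monophyletic in the tree."""
    count = 0
    for clade in controls:
        clade = frozenset(clade)
        unknown = clade - st.taxa
        if unknown:
            raise ValueError(f"control clade names unknown taxa: "
                             f"{sorted(unknown)}")
        if st.is_monophyletic(clade):
            count += 1
    return count


# --------------------------------------------------------------------------
# tree-level report
# --------------------------------------------------------------------------
@dataclass
class SpeciesTreeReport:
    """Evaluation metrics for one species tree."""

    name: str
    tree: PhyloTree
    quartet_score: int | None
    branches: list[BranchMetrics]
    mean_support: float
    mean_split_frequency: float
    mean_rf_among_gts: float
    distance_score: float | None = None
    selected_relationships: int | None = None
    predictive_mean: float | None = None
    predictive_ci: tuple[float, float] | None = None
    control_nodes: int | None = None

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "tree": self.tree.to_newick(),
            "quartet_score": self.quartet_score,
            "mean_support": self.mean_support,
            "mean_split_frequency": self.mean_split_frequency,
            "mean_rf_among_gts": self.mean_rf_among_gts,
            "distance_score": self.distance_score,
            "selected_relationships": self.selected_relationships,
            "predictive_mean": self.predictive_mean,
            "predictive_ci": self.predictive_ci,
            "control_nodes": self.control_nodes,
            "n_branches": len(self.branches),
        }


def mean_rf_among(gene_trees: Sequence[PhyloTree]) -> float:
    """Mean pairwise RF among gene trees, each pair trimmed to shared taxa."""
    vals = []
    for i in range(len(gene_trees)):
        for j in range(i + 1, len(gene_trees)):
            shared = gene_trees[i].taxa & gene_trees[j].taxa
            if len(shared) < 4:
                continue
            a = trim_to_common_taxa(gene_trees[i], shared)
            b = trim_to_common_taxa(gene_trees[j], shared)
            vals.append(rf_distance(a, b))
    return float(np.mean(vals)) if vals else float("nan")


def evaluate_species_tree(name: str, st: PhyloTree,
                          gene_trees: Sequence[PhyloTree],
                          quartet_score: int | None = None,
                          refs: tuple[PhyloTree, PhyloTree, PhyloTree] | None = None,
                          relationships: Sequence[Iterable[str]] | None = None,
                          independent_gts: Sequence[PhyloTree] | None = None,
                          controls: Sequence[Iterable[str]] | None = None,
                          seed: int = 0) -> SpeciesTreeReport:
    """Full per-tree evaluation against its underlying gene trees."""
    branches = branch_metrics(st, gene_trees)
    defined = [b for b in branches if np.isfinite(b.q1)]
    report = SpeciesTreeReport(
        name=name, tree=st, quartet_score=quartet_score, branches=branches,
        mean_support=float(np.mean([b.support for b in defined]))
        if defined else float("nan"),
        mean_split_frequency=float(np.mean([b.split_frequency
                                            for b in branches]))
        if branches else float("nan"),
        mean_rf_among_gts=mean_rf_among(gene_trees))
    if refs is not None:
        concat, min_d, max_d = refs
        report.distance_score = distance_score(st, concat, min_d, max_d)
        if relationships is not None:
            from .trees import root_on_outgroup
            anchor = min(st.taxa)
            report.selected_relationships = selected_relationships_score(
                root_on_outgroup(st, anchor), relationships,
                root_on_outgroup(concat, anchor),
                root_on_outgroup(min_d, anchor),
                root_on_outgroup(max_d, anchor))
    if independent_gts:
        mean, ci, _ = predictive_power(st, independent_gts, seed=seed)
        report.predictive_mean = mean
        report.predictive_ci = ci
    if controls is not None:
        from .trees import root_on_outgroup
        report.control_nodes = control_nodes_present(
            root_on_outgroup(st, min(st.taxa)), controls)
    return report
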