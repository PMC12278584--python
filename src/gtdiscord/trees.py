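"""Tree containers, Newick I/O and topology distances.

Trees are held as :class:`PhyloTree`, a thin wrapper around a
:class:`dendropy.Tree` that additionally records the unit of its branch
lengths (``"coalescent"``, ``"substitution"`` or ``"none"``).  All distance
computations are topology-only and treat trees as unrooted, which is the
convention of the discordance experiment: rooting is bookkeeping (every
locus is rooted on its outgroup for display), the metrics are not.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
import numpy as np

UNIT_COALESCENT = "coalescent"
UNIT_SUBSTITUTION = "substitution"
UNIT_NONE = "none"
_UNITS = {UNIT_COALESCENT, UNIT_SUBSTITUTION, UNIT_NONE}


class LeafSetMismatchError(ValueError):
    """Raised when two trees being compared do not share a leaf set."""


@dataclass
class PhyloTree:
    """A phylogenetic tree with a declared branch-length unit.

    Parameters
    ----------
    tree:
        The underlying dendropy tree.  Each :class:`PhyloTree` owns its own
        ``TaxonNamespace``; comparisons clone both trees into a shared
        namespace internally.
    units:
        One of ``"coalescent"``, ``"substitution"`` or ``"none"``.
    """

    tree: dendropy.Tree
    units: str = UNIT_NONE

    def __post_init__(self) -> None:
        if self.units not in _UNITS:
            raise ValueError(f"unknown branch-length unit {self.units!r}")
        labels = [lf.taxon.label for lf in self.tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise ValueError("taxon labels are not unique")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError(f"negative branch length {edge.length}")

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_newick(cls, newick: str, units: str = UNIT_NONE,
                    rooted: bool | None = None) -> "PhyloTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True)
        if rooted is not None:
            tree.is_rooted = rooted
        elif tree.is_rooted is None:
            tree.is_rooted = len(tree.seed_node.child_nodes()) == 2
        return cls(tree, units)

    def to_newick(self, lengths: bool = True) -> str:
        s = self.tree.as_string(
            schema="newick", suppress_rooting=True,
            unquoted_underscores=True,
            suppress_edge_lengths=not lengths)
        return s.strip()

    # ----------------------------------------------------------- properties
    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(lf.taxon.label for lf in self.tree.leaf_node_iter())

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    @property
    def rooted(self) -> bool:
        return bool(self.tree.is_rooted)

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.tree.clone(depth=1), self.units)

    def with_units(self, units: str) -> "PhyloTree":
        out = self.copy()
        out.units = units
        return out

    def scale_lengths(self, factor: float, units: str | None = None) -> "PhyloTree":
        out = self.copy()
        for edge in out.tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= factor
        if units is not None:
            out.units = units
        return out

    # --------------------------------------------------------------- splits
    def unrooted_splits(self) -> set[frozenset[str]]:
        """Internal bipartitions as canonical leaf-label sets.

        Each split is represented by the side *not* containing the
        lexicographically smallest taxon; trivial (pendant) splits are
        excluded.
        """
        taxa = self.taxa
        anchor = min(taxa)
        n = len(taxa)
        splits: set[frozenset[str]] = set()
        below: dict[int, frozenset[str]] = {}
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                below[id(node)] = frozenset((node.taxon.label,))
                continue
            side = frozenset().union(*(below[id(c)] for c in node.child_nodes()))
            below[id(node)] = side
            if node is self.tree.seed_node:
                continue
            if anchor in side:
                side = taxa - side
            if 2 <= len(side) <= n - 2:
                splits.add(side)
        return splits

    def is_monophyletic(self, taxa: Iterable[str]) -> bool:
        """True iff ``taxa`` form a clade on this (rooted) tree."""
        taxa = frozenset(taxa)
        if not taxa or not taxa <= self.taxa:
            return False
        if len(taxa) == 1:
            return True
        mrca = self.tree.mrca(taxon_labels=list(taxa))
        if mrca is None:
            return False
        clade = frozenset(lf.taxon.label for lf in mrca.leaf_iter())
        return clade == taxa


def root_on_outgroup(tree: PhyloTree, outgroup: str) -> PhyloTree:
    """Root ``tree`` on the pendant edge of ``outgroup`` (midpoint of it)."""
    if outgroup not in tree.taxa:
        raise ValueError(f"outgroup {outgroup!r} not in tree")
    clone = tree.tree.clone(depth=1)
    leaf = None
    for lf in clone.leaf_node_iter():
        if lf.taxon.label == outgroup:
            leaf = lf
            break
    edge = leaf.edge
    if edge.length is not None:
        clone.reroot_at_edge(edge, length1=edge.length / 2.0,
                             length2=edge.length / 2.0,
                             update_bipartitions=False)
    else:
        clone.reroot_at_edge(edge, update_bipartitions=False)
    clone.is_rooted = True
    return PhyloTree(clone, tree.units)


# --------------------------------------------------------------------------
# trimming
# --------------------------------------------------------------------------
def trim_to_common_taxa(tree: PhyloTree, taxa: Iterable[str]) -> PhyloTree:
    """Prune ``tree`` down to ``taxa``.

    Degree-2 nodes created by pruning are suppressed and their branch
    lengths summed, matching how concatenation reference topologies are
    trimmed to each locus's taxon sampling.
    """
    taxa = frozenset(taxa)
    missing = taxa - tree.taxa
    if missing:
        raise ValueError(f"taxa not in tree: {sorted(missing)}")
    if len(taxa) < 4:
        raise ValueError(f"cannot trim below 4 tips (requested {len(taxa)})")
    # NB: clone(depth=1) shares the TaxonNamespace with the source tree, so
    # the namespace must not be purged here (it would corrupt the source)
    clone = tree.tree.clone(depth=1)
    clone.retain_taxa_with_labels(sorted(taxa))
    return PhyloTree(clone, tree.units)


# --------------------------------------------------------------------------
# distances
# --------------------------------------------------------------------------
def _require_same_taxa(t1: PhyloTree, t2: PhyloTree) -> frozenset[str]:
    if t1.taxa != t2.taxa:
        only1 = sorted(t1.taxa - t2.taxa)
        only2 = sorted(t2.taxa - t1.taxa)
        raise LeafSetMismatchError(
            f"leaf sets differ; only in first: {only1}; only in second: {only2}")
    return t1.taxa


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Unrooted Robinson-Foulds distance: the number of internal
    bipartitions present in exactly one of the two trees."""
    _require_same_taxa(t1, t2)
    return len(t1.unrooted_splits() ^ t2.unrooted_splits())


def normalized_rf(t1: PhyloTree, t2: PhyloTree) -> float:
    """RF rescaled by the maximum 2(n-3) for binary unrooted trees."""
    taxa = _require_same_taxa(t1, t2)
    n = len(taxa)
    if n < 4:
        raise ValueError("normalized RF requires >= 4 taxa")
    return rf_distance(t1, t2) / (2.0 * (n - 3))


def topo_distance_matrix(tree: PhyloTree, labels: Sequence[str]) -> np.ndarray:
    """Tip-to-tip path lengths in edge counts, on the unrooted topology."""
    nodes = list(tree.tree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    adj: list[list[int]] = [[] for _ in nodes]
    seed = tree.tree.seed_node
    # a degree-2 root is an artifact of rooting: fuse its two edges
    fuse_root = len(seed.child_nodes()) == 2
    for nd in nodes:
        if fuse_root and nd is seed:
            a, b = (index[id(c)] for c in nd.child_nodes())
            adj[a].append(b)
            adj[b].append(a)
            continue
        for ch in nd.child_nodes():
            i, j = index[id(nd)], index[id(ch)]
            adj[i].append(j)
            adj[j].append(i)
    leaf_idx = {}
    for nd in tree.tree.leaf_node_iter():
        leaf_idx[nd.taxon.label] = index[id(nd)]
    n = len(labels)
    D = np.zeros((n, n), dtype=float)
    for a, lab in enumerate(labels):
        start = leaf_idx[lab]
        dist = np.full(len(nodes), -1, dtype=int)
        dist[start] = 0
        queue = [start]
        while queue:
            nxt = []
            for u in queue:
                for v in adj[u]:
                    if dist[v] < 0:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            queue = nxt
        for b, lab2 in enumerate(labels):
            D[a, b] = dist[leaf_idx[lab2]]
    return D


def path_distance(t1: PhyloTree, t2: PhyloTree, form: str = "euclidean") -> float:
    """Steel-Penny path difference between two trees on the same leaf set.

    With d_T(i,j) the number of edges between tips i and j, the default
    (Euclidean) form is sqrt(sum (d1-d2)^2) over unordered tip pairs,
    the behaviour of phangorn's ``treedist``; ``form="sum_abs"`` gives the
    absolute-sum variant.
    """
    taxa = _require_same_taxa(t1, t2)
    labels = sorted(taxa)
    d1 = topo_distance_matrix(t1, labels)
    d2 = topo_distance_matrix(t2, labels)
    iu = np.triu_indices(len(labels), k=1)
    diff = d1[iu] - d2[iu]
    if form == "euclidean":
        return float(np.sqrt(np.sum(diff ** 2)))
    if form == "sum_abs":
        return float(np.sum(np.abs(diff)))
    raise ValueError(f"unknown path distance form {form!r}")


# --------------------------------------------------------------------------
# discordance ranking
# --------------------------------------------------------------------------
EST1 = "Est.GT.1"
EST2 = "Est.GT.2"
TIE = "tie/ambiguous"


@dataclass
class DistanceRecord:
    """All pairwise distances for one locus and the discordance ranking."""

    locus_id: str
    rf_est1_ref: int
    rf_est2_ref: int
    rf_est1_est2: int
    path_est1_ref: float
    path_est2_ref: float
    path_est1_est2: float
    normalized_rf_est1_ref: float
    normalized_rf_est2_ref: float
    normalized_rf_est1_est2: float
    least_discordant_rf: str
    least_discordant_path: str
    least_discordant: str
    most_discordant: str
    metrics_agree: bool


def _rank(d1: float, d2: float) -> tuple[str, str]:
    if d1 < d2:
        return EST1, EST2
    if d2 < d1:
        return EST2, EST1
    return TIE, TIE


def rank_discordance(est1: PhyloTree, est2: PhyloTree, ref: PhyloTree,
                     locus_id: str = "", path_form: str = "euclidean") -> DistanceRecord:
    """Rank the two estimated gene trees by discordance with ``ref``.

    Both RF and path distances must agree on which tree is most discordant
    (and neither may tie) for ``metrics_agree`` to be set; loci failing this
    are excluded from the preference experiment.
    """
    taxa = _require_same_taxa(est1, est2)
    _require_same_taxa(est1, ref)
    s1, s2, sr = (t.unrooted_splits() for t in (est1, est2, ref))
    rf1, rf2, rf12 = len(s1 ^ sr), len(s2 ^ sr), len(s1 ^ s2)
    labels = sorted(taxa)
    d1, d2, dr = (topo_distance_matrix(t, labels)
                  for t in (est1, est2, ref))
    iu = np.triu_indices(len(labels), k=1)

    def _path(a, b):
        diff = a[iu] - b[iu]
        if path_form == "euclidean":
            return float(np.sqrt(np.sum(diff ** 2)))
        return float(np.sum(np.abs(diff)))

    p1, p2, p12 = _path(d1, dr), _path(d2, dr), _path(d1, d2)
    least_rf, most_rf = _rank(rf1, rf2)
    least_path, most_path = _rank(p1, p2)
    agree = (least_rf != TIE and least_path != TIE and most_rf == most_path)
    least = least_rf if agree else TIE
    most = most_rf if agree else TIE
    denom = 2.0 * (len(taxa) - 3)
    return DistanceRecord(
        locus_id=locus_id,
        rf_est1_ref=rf1, rf_est2_ref=rf2, rf_est1_est2=rf12,
        path_est1_ref=p1, path_est2_ref=p2, path_est1_est2=p12,
        normalized_rf_est1_ref=rf1 / denom,
        normalized_rf_est2_ref=rf2 / denom,
        normalized_rf_est1_est2=rf12 / denom,
        least_discordant_rf=least_rf, least_discordant_path=least_path,
        least_discordant=least, most_discordant=most,
        metrics_agree=agree)


# --------------------------------------------------------------------------
# composite species-tree scores
# --------------------------------------------------------------------------
def distance_score(test: PhyloTree, concat: PhyloTree, min_discord: PhyloTree,
                   max_discord: PhyloTree, path_form: str = "euclidean") -> float:
    """Composite scaled RF+path score of a test species tree.

    For each reference R, c(test, R) = (RF/RFmax + path/pathmax)/2 with the
    maxima taken over all pairwise comparisons within the evaluated set of
    four trees.  The score

        ((1 - c(Concat)) + (1 - c(MinDiscord)) + c(MaxDiscord)) / 3

    is high when the test tree sits near the low-discordance references and
    far from the maximal-discordance one.
    """
    trees = [test, concat, min_discord, max_discord]
    for t in trees[1:]:
        _require_same_taxa(test, t)
    n = len(trees)
    rf = np.zeros((n, n))
    pd_ = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            rf[i, j] = rf[j, i] = rf_distance(trees[i], trees[j])
            pd_[i, j] = pd_[j, i] = path_distance(trees[i], trees[j], path_form)
    rf_max, pd_max = rf.max(), pd_.max()
    if rf_max == 0 and pd_max == 0:
        raise ValueError("all pairwise distances are zero; score undefined")

    def c(i: int) -> float:
        parts = []
        if rf_max > 0:
            parts.append(rf[0, i] / rf_max)
        if pd_max > 0:
            parts.append(pd_[0, i] / pd_max)
        return float(np.mean(parts))

    return ((1.0 - c(1)) + (1.0 - c(2)) + c(3)) / 3.0


def selected_relationships_score(test: PhyloTree,
                                 relationships: Sequence[Iterable[str]],
                                 concat: PhyloTree, min_discord: PhyloTree,
                                 max_discord: PhyloTree) -> int:
    """Tally of selected clade relationships shared with the references.

    +1 for each relationship present in ``test`` and in the concatenation or
    minimum-discordance tree; -1 for each present in ``test`` and in the
    maximum-discordance tree; relationships absent from ``test`` score 0.
    """
    score = 0
    known = test.taxa | concat.taxa | min_discord.taxa | max_discord.taxa
    for rel in relationships:
        rel = frozenset(rel)
        unknown = rel - known
        if unknown:
            raise ValueError(f"relationship references unknown taxa: {sorted(unknown)}")
        if not test.is_monophyletic(rel):
            continue
        if concat.is_monophyletic(rel) or min_discord.is_monophyletic(rel):
            score += 1
        if max_discord.is_monophyletic(rel):
            score -= 1
    return score
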