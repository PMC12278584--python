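"""Per-locus gene-tree estimation and reference-topology refits.

Each locus gets two candidate gene trees, one per model family (a GTR
nucleotide fit and a codon-model fit), found by NNI hill-climbing from a
neighbor-joining start with branch lengths re-optimized per accepted move.
The reference species-tree topology trimmed to the locus's taxa completes
the trio of topologies whose refitted log-likelihoods drive the
discordance-preference experiment.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .alignment import MISSING, CodonAlignment
from .models import FittedModel, optimize_branch_lengths
from .trees import (DistanceRecord, PhyloTree, rank_discordance,
                    root_on_outgroup, trim_to_common_taxa)

LNL_TIE_TOLERANCE = 1e-6

REF_LABEL = "Ref.ST"
EST1_LABEL = "Est.GT.1"
EST2_LABEL = "Est.GT.2"


# --------------------------------------------------------------------------
# NNI neighborhood
# --------------------------------------------------------------------------
def _rooted_at_leaf(tree: PhyloTree):
    """Clone rooted on the pendant edge of the first taxon, so every
    internal edge has a well-defined parent with exactly one sibling."""
    clone = tree.tree.clone(depth=1)
    clone.is_rooted = True
    anchor = sorted(tree.taxa)[0]
    leaf = next(lf for lf in clone.leaf_node_iter()
                if lf.taxon.label == anchor)
    length = leaf.edge.length
    if length is not None:
        clone.reroot_at_edge(leaf.edge, length1=length / 2.0,
                             length2=length / 2.0, update_bipartitions=False)
    else:
        clone.reroot_at_edge(leaf.edge, update_bipartitions=False)
    return clone


def _internal_edges(clone) -> list:
    """Internal edges of the leaf-rooted clone, deterministic order."""
    seed = clone.seed_node
    out = []
    for nd in clone.preorder_node_iter():
        if nd is seed or nd.parent_node is seed:
            continue
        if nd.child_nodes() and nd.parent_node.child_nodes():
            out.append(nd)
    return out


def n_internal_edges(tree: PhyloTree) -> int:
    return len(_internal_edges(_rooted_at_leaf(tree)))


def nni_move(tree: PhyloTree, edge_index: int, which: int) -> PhyloTree:
    """The tree after one nearest-neighbor interchange.

    ``edge_index`` selects an internal edge (deterministic order);
    ``which`` in {0, 1} selects which of the two rearrangements to apply.
    """
    clone = _rooted_at_leaf(tree)
    v = _internal_edges(clone)[edge_index]
    u = v.parent_node
    s = next(c for c in u.child_nodes() if c is not v)
    c = v.child_nodes()[which]
    s_len, c_len = s.edge.length, c.edge.length
    u.remove_child(s)
    v.remove_child(c)
    u.add_child(c)
    v.add_child(s)
    s.edge.length, c.edge.length = s_len, c_len
    return PhyloTree.from_newick(
        clone.as_string(schema="newick", suppress_rooting=True),
        units=tree.units, rooted=False)


def nni_neighbors(tree: PhyloTree) -> list[PhyloTree]:
    """All trees one nearest-neighbor interchange away (unrooted sense)."""
    out = []
    for k in range(n_internal_edges(tree)):
        for which in range(2):
            out.append(nni_move(tree, k, which))
    return out


def random_nni_walk(tree: PhyloTree, moves: int, rng) -> PhyloTree:
    """``moves`` uniform random NNI rearrangements, applied in sequence.

    Operates on a light adjacency representation (no dendropy cloning), so
    it is cheap enough for simulation studies that perturb thousands of
    trees.
    """
    # adjacency with per-edge lengths; fuse a degree-2 root
    adj: dict[int, dict[int, float | None]] = {}
    label: dict[int, str] = {}
    index: dict[int, int] = {}
    for i, nd in enumerate(tree.tree.preorder_node_iter()):
        index[id(nd)] = i
        adj[i] = {}
        if nd.is_leaf():
            label[i] = nd.taxon.label
    seed = tree.tree.seed_node
    fuse = len(seed.child_nodes()) == 2
    for nd in tree.tree.preorder_node_iter():
        i = index[id(nd)]
        if fuse and nd is seed:
            a, b = nd.child_nodes()
            ia, ib = index[id(a)], index[id(b)]
            length = None
            if a.edge.length is not None or b.edge.length is not None:
                length = (a.edge.length or 0.0) + (b.edge.length or 0.0)
            adj[ia][ib] = adj[ib][ia] = length
            continue
        for ch in nd.child_nodes():
            if fuse and nd is seed:
                continue
            j = index[id(ch)]
            adj[i][j] = adj[j][i] = ch.edge.length
    if fuse:
        del adj[index[id(seed)]]

    for _ in range(moves):
        internal = [(u, v) for u in adj for v in adj[u]
                    if u < v and u not in label and v not in label]
        u, v = internal[int(rng.integers(len(internal)))]
        c_opts = [x for x in adj[v] if x != u]
        s_opts = [x for x in adj[u] if x != v]
        c = c_opts[int(rng.integers(len(c_opts)))]
        s = s_opts[int(rng.integers(len(s_opts)))]
        lc, ls = adj[v].pop(c), adj[u].pop(s)
        del adj[c][v], adj[s][u]
        adj[v][s] = adj[s][v] = ls
        adj[u][c] = adj[c][u] = lc

    # serialize rooted at the first leaf
    start = min(label)

    def sub(node: int, parent: int) -> str:
        nbrs = [x for x in adj[node] if x != parent]
        length = adj[node][parent]
        suffix = "" if length is None else f":{length:.10g}"
        if not nbrs:
            return f"{label[node]}{suffix}"
        return "(" + ",".join(sub(x, node) for x in nbrs) + ")" + suffix

    (first_nbr,) = list(adj[start])
    length = adj[start][first_nbr]
    # the pendant edge's length rides on the neighbor side; the leaf side
    # gets zero so that derooting restores the full edge
    leaf_part = label[start] if length is None else f"{label[start]}:0"
    newick = f"({leaf_part},{sub(first_nbr, start)});"
    return PhyloTree.from_newick(newick, units=tree.units, rooted=False)


def _topology_key(tree: PhyloTree) -> frozenset:
    return frozenset(tree.unrooted_splits())


# --------------------------------------------------------------------------
# starting tree
# --------------------------------------------------------------------------
def nj_start_tree(aln: CodonAlignment, level: str = "nucleotide") -> PhyloTree:
    """Neighbor-joining start tree.

    ``level="nucleotide"``: JC-corrected nucleotide distances (the natural
    start for the nucleotide family); ``level="aa"``: Poisson-corrected
    amino-acid distances (the natural start for the codon families, which
    see the data through its protein).
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    if level == "nucleotide":
        mat, n_states = aln.nucleotide_matrix(), 4
    elif level == "aa":
        mat, n_states = aln.amino_acid_matrix(), 20
    else:
        raise ValueError(f"unknown distance level {level!r}")
    cap = (n_states - 1) / n_states - 0.01
    n = aln.n_taxa
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = (mat[i] != MISSING) & (mat[j] != MISSING)
            if not both.any():
                p = 0.5 * cap
            else:
                p = float(np.mean(mat[i][both] != mat[j][both]))
            p = min(p, cap)
            b = (n_states - 1) / n_states
            d = -b * np.log(1.0 - p / b)
            D[i, j] = D[j, i] = max(d, 1e-6)
    import io
    dm = DistanceMatrix(D, ids=aln.taxa)
    buf = io.StringIO()
    nj(dm).write(buf)
    newick = buf.getvalue()
    # NJ can emit tiny negative branch lengths; floor them for downstream use
    tree = PhyloTree.from_newick(newick.replace(":-", ":"), rooted=False)
    return tree


# --------------------------------------------------------------------------
# NNI hill-climb
# --------------------------------------------------------------------------
def infer_gene_tree(aln: CodonAlignment, model, start: PhyloTree | None = None,
                    seed: int = 0, coarse: bool = True,
                    max_rounds: int = 25) -> tuple[PhyloTree, float]:
    """Maximum-likelihood gene tree by exhaustive-NNI hill climbing.

    From a neighbor-joining (or supplied) start, all NNI neighbors are
    scored with branch lengths re-optimized on each candidate topology;
    the search moves while any neighbor improves the log-likelihood.
    Returns the fitted tree (substitution units) and its lnL.
    """
    if aln.n_taxa < 4:
        raise ValueError("gene-tree inference needs >= 4 taxa")
    if start is None:
        level = "aa" if getattr(model, "state_space", "") == "codon" \
            else "nucleotide"
        start = nj_start_tree(aln, level=level)
    current = start

    cache: dict[frozenset, tuple[PhyloTree, float]] = {}

    def score(topo: PhyloTree) -> tuple[PhyloTree, float]:
        key = _topology_key(topo)
        if key not in cache:
            fit = optimize_branch_lengths(topo, aln, model, n_starts=1,
                                          seed=seed, coarse=coarse, tol=1e-3)
            cache[key] = (fit.tree, fit.lnL)
        return cache[key]

    current_tree, current_lnl = score(current)
    for _ in range(max_rounds):
        best_tree, best_lnl = current_tree, current_lnl
        for nb in nni_neighbors(current_tree):
            cand_tree, cand_lnl = score(nb)
            if cand_lnl > best_lnl + LNL_TIE_TOLERANCE:
                best_tree, best_lnl = cand_tree, cand_lnl
        if best_lnl <= current_lnl + LNL_TIE_TOLERANCE:
            break
        current_tree, current_lnl = best_tree, best_lnl
    return current_tree, current_lnl


# --------------------------------------------------------------------------
# per-locus records
# --------------------------------------------------------------------------
@dataclass
class GeneRecord:
    """One locus: alignment, the three candidate topologies, distances,
    refitted models and per-model topology preferences."""

    locus_id: str
    alignment: CodonAlignment
    topologies: dict[str, PhyloTree]  # Ref.ST / Est.GT.1 / Est.GT.2
    distances: DistanceRecord | None = None
    fits: dict[tuple[str, str], FittedModel] = field(default_factory=dict)
    preferred: dict[str, str | None] = field(default_factory=dict)

    def lnls_for(self, model_name: str) -> dict[str, float]:
        return {topo: fit.lnL for (m, topo), fit in self.fits.items()
                if m == model_name}


def build_gene_record(aln: CodonAlignment, ref_st: PhyloTree, family1, family2,
                      outgroup: str, seed: int = 0,
                      coarse: bool = True) -> GeneRecord:
    """Estimate both candidate gene trees for a locus and rank discordance.

    ``family1`` is the nucleotide family (Est.GT.1), ``family2`` the codon
    family (Est.GT.2); the reference topology is trimmed to the locus's
    taxa, and all three trees are rooted on the designated outgroup for
    bookkeeping (distances and likelihoods are unrooted).
    """
    if outgroup not in aln.taxa:
        raise ValueError(f"outgroup {outgroup!r} absent from locus {aln.locus_id}")
    ref = trim_to_common_taxa(ref_st, aln.taxa)
    est1, _ = infer_gene_tree(aln, family1, seed=seed, coarse=coarse)
    est2, _ = infer_gene_tree(aln, family2, seed=seed + 1, coarse=coarse)
    topologies = {
        REF_LABEL: root_on_outgroup(ref, outgroup),
        EST1_LABEL: root_on_outgroup(est1, outgroup),
        EST2_LABEL: root_on_outgroup(est2, outgroup),
    }
    rec = GeneRecord(aln.locus_id, aln, topologies)
    rec.distances = rank_discordance(topologies[EST1_LABEL],
                                     topologies[EST2_LABEL],
                                     topologies[REF_LABEL],
                                     locus_id=aln.locus_id)
    return rec


def refit_three_topologies(record: GeneRecord, models: Mapping[str, object],
                           n_starts: int = 4, seed: int = 0,
                           optimize_params: Mapping[str, Sequence[str]] | None = None,
                           coarse: bool = False) -> GeneRecord:
    """Refit branch lengths for every model on each of the three topologies.

    Stores one FittedModel per model x topology and, per model, the
    preferred topology (argmax lnL, ties within 1e-6 recorded as None).
    Non-convergent fits are kept and flagged, not fatal: relative lnLs
    among topologies are still informative.
    """
    opt = optimize_params or {}
    for m_idx, (model_name, model) in enumerate(sorted(models.items())):
        lnls: dict[str, float] = {}
        for t_idx, topo_label in enumerate(sorted(record.topologies)):
            topo = record.topologies[topo_label]
            fit = optimize_branch_lengths(
                topo, record.alignment, model, n_starts=n_starts,
                seed=seed + 100 * m_idx + t_idx,
                optimize_params=opt.get(model_name, ()), coarse=coarse)
            record.fits[(model_name, topo_label)] = fit
            lnls[topo_label] = fit.lnL
        best = max(lnls, key=lnls.get)
        runner_up = max((v for k, v in lnls.items() if k != best), default=-np.inf)
        record.preferred[model_name] = None \
            if lnls[best] - runner_up < LNL_TIE_TOLERANCE else best
    return record
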