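"""Synthetic data: species trees, coalescent gene trees, codon alignments.

The generator emulates the statistical structure of a multi-locus
protein-coding dataset for a rapid radiation: a species tree in coalescent
units with a tunable fraction of very short internal branches (anomaly-zone
candidates), gene trees drawn from the multispecies coalescent (one sampled
allele per species, discordance arising purely from incomplete lineage
sorting), codon alignments simulated on each gene tree under a nucleotide or
mutation-selection codon model, and per-locus taxon occupancy thinning with
an always-retained outgroup.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

from .alignment import SENSE_CODONS, CodonAlignment
from .models import EigenQ, GTRParams, codon_mutation_layer
from .trees import (PhyloTree, UNIT_COALESCENT, UNIT_SUBSTITUTION,
                    trim_to_common_taxa)

SHORT_BRANCH_THRESHOLD = 0.1  # coalescent units


@dataclass
class SimConfig:
    """Study-scale defaults for the synthetic dataset.

    Defaults emulate a ~56-taxon, 100-locus protein-coding dataset with
    locus lengths of a few hundred to a few thousand nucleotides and
    per-locus occupancy between 34 and 50 species.
    """

    n_taxa: int = 56
    n_loci: int = 100
    n_codons_range: tuple[int, int] = (100, 1600)
    birth_rate: float = 1.0
    coal_scale: float = 2.0
    short_branch_fraction: float = 0.2
    subst_scale: float = 0.1  # substitutions per codon site per coalescent unit
    occupancy_range: tuple[int, int] | None = None  # default: (34, 50) clamped
    seed: int = 0

    def effective_occupancy(self) -> tuple[int, int]:
        """The study-style occupancy window (34, 50), clamped to n_taxa."""
        if self.occupancy_range is not None:
            return self.occupancy_range
        hi = min(50, self.n_taxa)
        lo = min(34, hi)
        return (max(4, lo), hi)

    def validate(self) -> None:
        if self.n_taxa < 4:
            raise ValueError(f"need at least 4 taxa, got {self.n_taxa}")
        if self.n_loci < 1 or self.n_codons_range[0] < 1:
            raise ValueError("counts must be >= 1")
        if self.n_codons_range[0] > self.n_codons_range[1]:
            raise ValueError("invalid n_codons_range")
        if not (0.0 <= self.short_branch_fraction <= 1.0):
            raise ValueError("short_branch_fraction must be in [0, 1]")
        if self.subst_scale <= 0:
            raise ValueError("subst_scale must be positive")
        if self.birth_rate <= 0 or self.coal_scale <= 0:
            raise ValueError("rates must be positive")
        lo, hi = self.effective_occupancy()
        if lo < 4:
            raise ValueError("occupancy minimum must be >= 4")
        if lo > hi or hi > self.n_taxa:
            raise ValueError("invalid occupancy_range")


def taxon_labels(n: int) -> list[str]:
    return [f"T{i + 1:02d}" for i in range(n)]


# --------------------------------------------------------------------------
# species tree
# --------------------------------------------------------------------------
def simulate_species_tree(cfg: SimConfig) -> PhyloTree:
    """Pure-birth species tree rescaled to coalescent units.

    Internal branches are floored at 0.1 coalescent units and then
    ceil(short_branch_fraction * (n_taxa - 2)) of them are forced below 0.1
    to create anomaly-zone candidates.  Deterministic under ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    labels = taxon_labels(cfg.n_taxa)

    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = True
    root = tree.seed_node
    # forward Yule: split a uniformly chosen active tip at each event
    birth_times = {id(root): 0.0}
    active = [root]
    now = 0.0
    while len(active) < cfg.n_taxa:
        k = len(active)
        now += rng.exponential(1.0 / (cfg.birth_rate * k))
        idx = rng.integers(k)
        node = active.pop(idx)
        birth_times[id(node)] = birth_times.get(id(node), 0.0)
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            birth_times[id(child)] = now
            active.append(child)
    now += rng.exponential(1.0 / cfg.birth_rate)  # stem below first tip
    order = rng.permutation(cfg.n_taxa)
    for i, leaf in enumerate(active):
        taxon = tns.require_taxon(labels[order[i]])
        leaf.taxon = taxon
    for node in tree.preorder_node_iter():
        if node is root:
            node.edge.length = None
            continue
        parent_t = birth_times[id(node.parent_node)]
        end_t = birth_times[id(node)] if node.child_nodes() else now
        node.edge.length = (end_t - parent_t) * cfg.coal_scale

    internal = [nd for nd in tree.preorder_node_iter()
                if nd is not root and nd.child_nodes()]
    for nd in internal:  # floor, so "not short" is well defined
        nd.edge.length = max(nd.edge.length, SHORT_BRANCH_THRESHOLD)
    n_short = int(np.ceil(cfg.short_branch_fraction * (cfg.n_taxa - 2)))
    if n_short > 0 and internal:
        n_short = min(n_short, len(internal))
        chosen = rng.choice(len(internal), size=n_short, replace=False)
        for i in chosen:
            internal[i].edge.length = rng.uniform(0.01, 0.09)
    return PhyloTree(tree, UNIT_COALESCENT)


def pick_outgroup(species_tree: PhyloTree) -> str:
    """A deterministic outgroup: the first label in the smaller root subtree."""
    root = species_tree.tree.seed_node
    kids = root.child_nodes()
    sides = [sorted(lf.taxon.label for lf in k.leaf_iter()) for k in kids]
    sides.sort(key=lambda s: (len(s), s))
    return sides[0][0]


# --------------------------------------------------------------------------
# multispecies coalescent
# --------------------------------------------------------------------------
def simulate_gene_trees(species_tree: PhyloTree, n_loci: int,
                        seed: int = 0) -> list[PhyloTree]:
    """Multispecies-coalescent gene trees, one haploid sample per species.

    Within each species-tree branch of length x (coalescent units) the k
    entering gene lineages merge at total rate k(k-1)/2; survivors pass
    rootward, and coalescence is forced above the root (duration
    infinity).  Gene-tree branch lengths are in coalescent units.
    """
    if species_tree.units != UNIT_COALESCENT:
        raise ValueError("species tree must carry coalescent-unit branch lengths")
    for edge in species_tree.tree.preorder_edge_iter():
        if edge.head_node is not species_tree.tree.seed_node and edge.length is None:
            raise ValueError("species tree has missing branch lengths")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_loci):
        out.append(_simulate_one_gene_tree(species_tree, rng))
    return out


def _simulate_one_gene_tree(species_tree: PhyloTree, rng) -> PhyloTree:
    tns = dendropy.TaxonNamespace()
    pending: dict[int, list] = {}
    # each un-coalesced lineage accumulates traversed branch duration into
    # lengths[id(node)] until it is attached to a parent
    lengths: dict[int, float] = {}

    def advance(lineages, duration):
        entries = {id(ln): 0.0 for ln in lineages}
        t_local = 0.0
        while len(lineages) > 1:
            k = len(lineages)
            wait = rng.exponential(2.0 / (k * (k - 1)))
            if t_local + wait > duration:
                break
            t_local += wait
            pair = rng.choice(k, size=2, replace=False)
            a, b = lineages[int(pair[0])], lineages[int(pair[1])]
            parent = dendropy.Node()
            for child in (a, b):
                parent.add_child(child)
                child.edge.length = lengths.pop(id(child)) \
                    + (t_local - entries[id(child)])
            lengths[id(parent)] = 0.0
            entries[id(parent)] = t_local
            lineages = [ln for ln in lineages if ln is not a and ln is not b]
            lineages.append(parent)
        if np.isfinite(duration):
            for ln in lineages:
                lengths[id(ln)] += duration - entries[id(ln)]
        return lineages

    root_lineage = None
    for node in species_tree.tree.postorder_node_iter():
        if node.is_leaf():
            leaf = dendropy.Node()
            leaf.taxon = tns.require_taxon(node.taxon.label)
            lengths[id(leaf)] = 0.0
            lineages = [leaf]
        else:
            lineages = []
            for child in node.child_nodes():
                lineages.extend(pending.pop(id(child)))
        if node is species_tree.tree.seed_node:
            # forced coalescence above the root: rate k(k-1)/2 indefinitely
            root_lineage = advance(lineages, np.inf)[0]
        else:
            pending[id(node)] = advance(lineages, float(node.edge.length)) \
                if not node.is_leaf() else lineages
    gt = dendropy.Tree(taxon_namespace=tns)
    gt.seed_node = root_lineage
    gt.is_rooted = True
    root_lineage.edge.length = None
    return PhyloTree(gt, UNIT_COALESCENT)


def to_substitution_units(tree: PhyloTree, subst_scale: float) -> PhyloTree:
    """Convert coalescent-unit branch lengths to expected substitutions per
    codon site with a single global multiplier."""
    if tree.units != UNIT_COALESCENT:
        raise ValueError("tree is not in coalescent units")
    if subst_scale <= 0:
        raise ValueError("subst_scale must be positive")
    return tree.scale_lengths(subst_scale, UNIT_SUBSTITUTION)


# --------------------------------------------------------------------------
# sequence simulation
# --------------------------------------------------------------------------
def _simulation_matrix(model) -> tuple[np.ndarray, np.ndarray]:
    """The 61-state generator used for simulation.

    Nucleotide GTR parameters are lifted to the sense-codon mutation layer
    (stop codons excluded by construction, so no stop is ever emitted);
    codon models are used as-is.
    """
    if isinstance(model, GTRParams):
        mu, pi_mut = codon_mutation_layer(model)
        Q = mu.copy()
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mean_rate = -float(np.dot(pi_mut, np.diag(Q)))
        return Q / mean_rate, pi_mut
    Q, pi = model.rate_matrix()
    return Q, pi


def implied_nucleotide_freqs(model) -> np.ndarray:
    """Stationary nucleotide frequencies implied by the simulating process
    (codon stationary frequencies marginalized over the three positions)."""
    _, pi = _simulation_matrix(model)
    codon_nucs = np.array([[("ACGT").index(c) for c in codon]
                           for codon in SENSE_CODONS])
    freqs = np.zeros(4)
    for pos in range(3):
        for s in range(61):
            freqs[codon_nucs[s, pos]] += pi[s]
    return freqs / freqs.sum()


def simulate_codon_alignment(gene_tree: PhyloTree, model, n_codons: int,
                             seed: int = 0, locus_id: str = "") -> CodonAlignment:
    """Evolve sense codons along ``gene_tree`` under ``model``.

    Root states are drawn from the model's stationary distribution and
    propagated by the transition matrices of the (possibly gamma-scaled)
    rate matrix; only sense codons are ever produced.
    """
    if n_codons < 1:
        raise ValueError("need at least one codon")
    if gene_tree.units != UNIT_SUBSTITUTION:
        raise ValueError("gene tree must be in substitution units "
                         "(see to_substitution_units)")
    rng = np.random.default_rng(seed)
    Q, pi = _simulation_matrix(model)
    eig = EigenQ(Q, pi)
    rates = model.rate_categories()
    site_rates = rates[rng.integers(rates.size, size=n_codons)] \
        if rates.size > 1 else np.ones(n_codons)

    states: dict[int, np.ndarray] = {}
    tree = gene_tree.tree
    states[id(tree.seed_node)] = rng.choice(61, size=n_codons, p=pi)
    taxa, rows = [], []
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            t = float(node.edge.length or 0.0)
            parent_states = states[id(node.parent_node)]
            child = np.empty(n_codons, dtype=np.int64)
            if t == 0.0:
                child[:] = parent_states
            else:
                for r in np.unique(site_rates):
                    sites = np.nonzero(site_rates == r)[0]
                    P = eig.P(r * t)
                    P = P / P.sum(axis=1, keepdims=True)
                    cdf = np.cumsum(P, axis=1)
                    u = rng.random(sites.size)
                    site_cdfs = cdf[parent_states[sites]]
                    child[sites] = np.minimum(
                        (site_cdfs < u[:, None]).sum(axis=1), 60)
            states[id(node)] = child
        if node.is_leaf():
            taxa.append(node.taxon.label)
            rows.append(states[id(node)])
    order = np.argsort(taxa)
    return CodonAlignment(locus_id, [taxa[i] for i in order],
                          np.vstack([rows[i] for i in order]))


# --------------------------------------------------------------------------
# occupancy thinning
# --------------------------------------------------------------------------
def thin_taxa(aln: CodonAlignment, tree: PhyloTree,
              occupancy_range: tuple[int, int], seed: int = 0,
              outgroup: str | None = None) -> tuple[CodonAlignment, PhyloTree]:
    """Retain a uniform-random subset of taxa within the occupancy range.

    The designated outgroup is always retained so every locus stays rootable.
    """
    lo, hi = occupancy_range
    n = aln.n_taxa
    if lo < 4:
        raise ValueError("occupancy minimum must be >= 4")
    if lo > hi or hi > n:
        raise ValueError(f"occupancy range ({lo}, {hi}) invalid for {n} taxa")
    if outgroup is not None and outgroup not in aln.taxa:
        raise ValueError(f"outgroup {outgroup!r} absent from alignment")
    rng = np.random.default_rng(seed)
    n_keep = int(rng.integers(lo, hi + 1))
    pool = sorted(aln.taxa)
    if outgroup is not None:
        pool.remove(outgroup)
        chosen = list(rng.choice(pool, size=n_keep - 1, replace=False))
        chosen.append(outgroup)
    else:
        chosen = list(rng.choice(pool, size=n_keep, replace=False))
    chosen = sorted(chosen)
    if len(chosen) == n:
        return aln, tree
    return aln.subset(chosen), trim_to_common_taxa(tree, chosen)


# --------------------------------------------------------------------------
# locus bundles
# --------------------------------------------------------------------------
@dataclass
class SimulatedLocus:
    locus_id: str
    alignment: CodonAlignment
    gene_tree: PhyloTree  # coalescent units, full taxon set of the locus
    seed: int


def simulate_dataset(cfg: SimConfig, model=None,
                     outgroup: str | None = None) -> tuple[PhyloTree, list[SimulatedLocus]]:
    """End-to-end synthetic dataset: species tree plus per-locus alignments.

    Per locus: an MSC gene tree, a codon alignment simulated on it under
    ``model``, and occupancy thinning retaining the outgroup.  The default
    generating model is a mutation-selection codon model with amino-acid
    fitnesses drawn once per dataset (N(0,1), seeded) and omega = 0.3,
    emulating protein-coding loci under purifying selection.
    """
    cfg.validate()
    st = simulate_species_tree(cfg)
    if outgroup is None:
        outgroup = pick_outgroup(st)
    if model is None:
        from .models import FMutSel0Params
        fit_rng = np.random.default_rng(cfg.seed + 3)
        model = FMutSel0Params(fitness=fit_rng.normal(0.0, 1.0, 20),
                               omega=0.3, n_cat=1)
    gts = simulate_gene_trees(st, cfg.n_loci, seed=cfg.seed + 1)
    rng = np.random.default_rng(cfg.seed + 2)
    loci = []
    for i, gt in enumerate(gts):
        n_codons = int(rng.integers(cfg.n_codons_range[0],
                                    cfg.n_codons_range[1] + 1))
        locus_seed = int(rng.integers(2 ** 31 - 1))
        aln = simulate_codon_alignment(
            to_substitution_units(gt, cfg.subst_scale), model, n_codons,
            seed=locus_seed, locus_id=f"locus{i + 1:03d}")
        aln, gt_thin = thin_taxa(aln, gt, cfg.effective_occupancy(),
                                 seed=locus_seed + 1, outgroup=outgroup)
        loci.append(SimulatedLocus(aln.locus_id, aln, gt_thin, locus_seed))
    return st, loci


def write_dataset(outdir: str | Path, species_tree: PhyloTree,
                  loci: Sequence[SimulatedLocus]) -> None:
    """FASTA per locus, newick per tree, and a manifest TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "species_tree.nwk").write_text(species_tree.to_newick() + "\n")
    rows = ["locus_id\tn_taxa\tn_codons\tseed"]
    for locus in loci:
        locus.alignment.to_fasta(outdir / f"{locus.locus_id}.fasta")
        (outdir / f"{locus.locus_id}.genetree.nwk").write_text(
            locus.gene_tree.to_newick() + "\n")
        rows.append(f"{locus.locus_id}\t{locus.alignment.n_taxa}"
                    f"\t{locus.alignment.n_codons}\t{locus.seed}")
    (outdir / "manifest.tsv").write_text("\n".join(rows) + "\n")
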