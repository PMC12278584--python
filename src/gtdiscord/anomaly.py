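"""Anomaly-zone detection and difficult-node flagging.

A pair of contiguous internal branches (ancestor length x, descendant
length y, coalescent units) is in the anomaly zone when y < a(x) with

    a(x) = ln[ 2/3 + (3 e^{2x} - 2) / (18 (e^{3x} - e^{2x})) ],

the boundary below which the most probable gene tree differs from the
species tree.  a is strictly decreasing with a root near x = 0.2655: no
descendant branch can be anomalous under an ancestor longer than that.
Difficult nodes additionally require low gene concordance, low split
frequency and low node support.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize as spopt

from .speciestree import BranchMetrics
from .trees import PhyloTree, UNIT_COALESCENT


def a_of_x(x: float) -> float:
    """The anomaly-zone boundary a(x) for an ancestor branch of length x."""
    if x <= 0:
        raise ValueError("a(x) requires x > 0 (the limit diverges at 0)")
    e2 = math.exp(2.0 * x)
    e3 = math.exp(3.0 * x)
    return math.log(2.0 / 3.0 + (3.0 * e2 - 2.0) / (18.0 * (e3 - e2)))


def anomaly_threshold_root() -> float:
    """The root of a(x) = 0, i.e. of 9 e^{2x} - 6 e^{3x} = 2 (~0.2655)."""
    return float(spopt.brentq(
        lambda x: 9.0 * math.exp(2.0 * x) - 6.0 * math.exp(3.0 * x) - 2.0,
        0.01, 1.0, xtol=1e-12))


@dataclass
class BranchPair:
    parent_split: frozenset[str]
    child_split: frozenset[str]
    x: float
    y: float
    a_x: float
    anomalous: bool


@dataclass
class DifficultNode:
    split: frozenset[str]
    coalescent_length: float
    gcf: float | None
    split_frequency: float
    support: float
    flagged: bool


@dataclass
class AnomalyReport:
    pairs: list[BranchPair]
    anomalous_nodes: list[frozenset[str]]  # junction node of a flagged pair
    skipped_pairs: int
    difficult: list[DifficultNode] = field(default_factory=list)

    @property
    def n_anomalous_pairs(self) -> int:
        return sum(1 for p in self.pairs if p.anomalous)

    @property
    def n_anomalous_nodes(self) -> int:
        return len(self.anomalous_nodes)

    def to_dict(self) -> dict:
        return {
            "n_pairs_tested": len(self.pairs),
            "n_anomalous_pairs": self.n_anomalous_pairs,
            "n_anomalous_nodes": self.n_anomalous_nodes,
            "n_difficult_nodes": sum(1 for d in self.difficult if d.flagged),
            "skipped_pairs": self.skipped_pairs,
        }


def _internal_edges(tree: PhyloTree):
    """(node, split) for internal non-root edges of the rooted tree."""
    taxa = tree.taxa
    anchor = min(taxa)
    out = []
    for nd in tree.tree.preorder_node_iter():
        if nd is tree.tree.seed_node or nd.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        canon = (taxa - side) if anchor in side else side
        out.append((nd, canon))
    return out


def detect_anomalous_pairs(st: PhyloTree,
                           lengths: Mapping[frozenset, float] | None = None
                           ) -> AnomalyReport:
    """Scan every contiguous internal ancestor-descendant branch pair.

    Branch lengths come from the tree itself (coalescent units) unless a
    ``lengths`` map (canonical split -> coalescent length, e.g. inverted
    from quartet frequencies) is supplied.  A pair (x ancestor, y
    descendant) is anomalous iff y < a(x) with both finite and positive;
    pairs with missing lengths are skipped and counted.
    """
    if lengths is None and st.units != UNIT_COALESCENT:
        raise ValueError("species tree must carry coalescent-unit lengths "
                         "or a lengths map must be given")
    internal = _internal_edges(st)
    split_of = {id(nd): split for nd, split in internal}

    def branch_length(nd, split):
        if lengths is not None:
            return lengths.get(split)
        return None if nd.edge.length is None else float(nd.edge.length)

    pairs: list[BranchPair] = []
    nodes: list[frozenset[str]] = []
    skipped = 0
    for nd, split in internal:
        for child in nd.child_nodes():
            if child.is_leaf():
                continue
            child_split = split_of[id(child)]
            x = branch_length(nd, split)
            y = branch_length(child, child_split)
            if x is None or y is None or not np.isfinite(x) \
                    or not np.isfinite(y):
                skipped += 1
                continue
            if x <= 0:
                skipped += 1
                continue
            ax = a_of_x(x)
            anomalous = bool(y >= 0 and y < ax)
            pairs.append(BranchPair(split, child_split, x, y, ax, anomalous))
            if anomalous and split not in nodes:
                nodes.append(split)
    return AnomalyReport(pairs=pairs, anomalous_nodes=nodes,
                         skipped_pairs=skipped)


@dataclass
class DifficultThresholds:
    """The four difficult-node criteria (strict inequalities)."""

    coalescent_length: float = 0.1
    gcf: float = 0.10
    split_frequency: float = 0.10
    support: float = 0.5


def difficult_nodes(metrics: Sequence[BranchMetrics],
                    thresholds: DifficultThresholds | None = None
                    ) -> list[DifficultNode]:
    """Flag branches meeting all four criteria: short coalescent length,
    low gene concordance factor, low split frequency, low support.

    A branch with an undefined metric fails that criterion (conservative).
    """
    th = thresholds or DifficultThresholds()
    out = []
    for bm in metrics:
        ok_x = np.isfinite(bm.coalescent_length) \
            and bm.coalescent_length < th.coalescent_length
        ok_gcf = bm.gcf is not None and bm.gcf < th.gcf
        ok_sf = bm.split_frequency < th.split_frequency
        ok_sup = np.isfinite(bm.support) and bm.support < th.support
        out.append(DifficultNode(
            split=bm.split, coalescent_length=bm.coalescent_length,
            gcf=bm.gcf, split_frequency=bm.split_frequency,
            support=bm.support,
            flagged=bool(ok_x and ok_gcf and ok_sf and ok_sup)))
    return out
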