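"""Substitution models and phylogenetic likelihood.

Three model families are provided:

* ``GTRParams`` -- general time-reversible nucleotide model with discrete
  gamma rate heterogeneity (mean- or median-discretized);
* ``FMutSel0Params`` -- mutation-selection codon model: a GTR mutation layer
  over the 61 sense codons, amino-acid scaled fitnesses F, the fixation
  factor h(S) = S/(1 - e^-S), and a nonsynonymous multiplier omega;
* ``SelACParams`` -- stabilizing selection toward a site-specific optimal
  amino acid, with selection coefficients proportional to a weighted
  Grantham physicochemical distance scaled by a per-gene parameter psi.

Likelihood is Felsenstein pruning over 4 (nucleotide) or 61 (codon) states
with equal-weight gamma categories and per-pattern scaling; branch lengths
are optimized by coordinate ascent (Brent per edge) from multiple jittered
starts, declaring convergence when at least two starts agree within one
log-likelihood unit.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import optimize as spopt
from scipy import special
from scipy import stats

from .alignment import (AA_INDEX, AA_ORDER, CODON_AA, CODON_AA_INDEX,
                        MISSING, NUC_INDEX, SENSE_CODONS, CodonAlignment)
from .trees import PhyloTree, UNIT_SUBSTITUTION

MIN_BRANCH_LENGTH = 1e-8
MAX_BRANCH_LENGTH = 20.0

# --------------------------------------------------------------------------
# Grantham (1974) amino-acid properties: composition, polarity, volume.
# --------------------------------------------------------------------------
GRANTHAM_PROPERTIES: dict[str, tuple[float, float, float]] = {
    "A": (0.0, 8.1, 31.0), "R": (0.65, 10.5, 124.0), "N": (1.33, 11.6, 56.0),
    "D": (1.38, 13.0, 54.0), "C": (2.75, 5.5, 55.0), "Q": (0.89, 10.5, 85.0),
    "E": (0.92, 12.3, 83.0), "G": (0.74, 9.0, 3.0), "H": (0.58, 10.4, 96.0),
    "I": (0.0, 5.2, 111.0), "L": (0.0, 4.9, 111.0), "K": (0.33, 11.3, 119.0),
    "M": (0.0, 5.7, 105.0), "F": (0.0, 5.2, 132.0), "P": (0.39, 8.0, 32.5),
    "S": (1.42, 9.2, 32.0), "T": (0.71, 8.6, 61.0), "W": (0.13, 5.4, 170.0),
    "Y": (0.20, 6.2, 136.0), "V": (0.0, 5.9, 84.0),
}
# Grantham's published weights and the global scale putting the mean
# distance at 100 (so e.g. D(Ser, Leu) ~ 145).
GRANTHAM_WEIGHTS = (1.833, 0.1018, 0.000399)
GRANTHAM_RHO = 50.723


def grantham_distance(a: str, b: str,
                      weights: tuple[float, float, float] = GRANTHAM_WEIGHTS,
                      rho: float = GRANTHAM_RHO) -> float:
    """Weighted Euclidean physicochemical distance between amino acids."""
    try:
        ca, pa, va = GRANTHAM_PROPERTIES[a]
        cb, pb, vb = GRANTHAM_PROPERTIES[b]
    except KeyError as exc:
        raise ValueError(f"unknown amino acid code {exc.args[0]!r}") from None
    ac, ap, av = weights
    return rho * math.sqrt(ac * (ca - cb) ** 2 + ap * (pa - pb) ** 2
                           + av * (va - vb) ** 2)


def grantham_matrix(weights=GRANTHAM_WEIGHTS, rho=GRANTHAM_RHO) -> np.ndarray:
    """20x20 Grantham distance matrix in AA_ORDER."""
    G = np.zeros((20, 20))
    for i, a in enumerate(AA_ORDER):
        for j, b in enumerate(AA_ORDER):
            if i < j:
                G[i, j] = G[j, i] = grantham_distance(a, b, weights, rho)
    return G


# --------------------------------------------------------------------------
# discrete gamma rates
# --------------------------------------------------------------------------
def discrete_gamma(alpha: float, k: int = 4, method: str = "median") -> np.ndarray:
    """k equal-probability discrete gamma(alpha, alpha) rates.

    ``method="mean"`` returns bin conditional means (mean exactly 1);
    ``method="median"`` returns bin medians rescaled to mean 1.
    """
    if alpha <= 0:
        raise ValueError(f"gamma shape must be positive, got {alpha}")
    if k < 1:
        raise ValueError("need at least one rate category")
    if k == 1:
        return np.ones(1)
    if method == "median":
        p = (2 * np.arange(1, k + 1) - 1) / (2.0 * k)
        rates = stats.gamma.ppf(p, a=alpha, scale=1.0 / alpha)
        return rates / rates.mean()
    if method == "mean":
        bounds = stats.gamma.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
        upper = np.concatenate([special.gammainc(alpha + 1, alpha * bounds), [1.0]])
        lower = np.concatenate([[0.0], special.gammainc(alpha + 1, alpha * bounds)])
        return k * (upper - lower)
    raise ValueError(f"unknown discretization method {method!r}")


# --------------------------------------------------------------------------
# model parameter classes
# --------------------------------------------------------------------------
GTR_RATE_ORDER = ("AC", "AG", "AT", "CG", "CT", "GT")


def _exchange_matrix(rates: np.ndarray) -> np.ndarray:
    R = np.zeros((4, 4))
    for r, pair in zip(rates, GTR_RATE_ORDER):
        i, j = NUC_INDEX[pair[0]], NUC_INDEX[pair[1]]
        R[i, j] = R[j, i] = r
    return R


@dataclass
class GTRParams:
    """GTR nucleotide model with gamma rate heterogeneity.

    ``rates`` are the six symmetric exchangeabilities in the order
    AC, AG, AT, CG, CT, GT (conventionally r_GT = 1); ``freqs`` are the
    stationary nucleotide frequencies over A, C, G, T.
    """

    rates: np.ndarray = field(default_factory=lambda: np.ones(6))
    freqs: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    alpha: float = 1.0
    n_cat: int = 4
    discretization: str = "median"

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.rates.shape != (6,) or np.any(self.rates <= 0):
            raise ValueError("GTR needs six positive exchangeabilities")
        if self.freqs.shape != (4,) or np.any(self.freqs <= 0) \
                or abs(self.freqs.sum() - 1.0) > 1e-8:
            raise ValueError("nucleotide frequencies must be a positive simplex")
        if self.alpha <= 0:
            raise ValueError("gamma shape must be positive")

    @property
    def state_space(self) -> str:
        return "nucleotide"

    def rate_categories(self) -> np.ndarray:
        if self.n_cat == 1:
            return np.ones(1)
        return discrete_gamma(self.alpha, self.n_cat, self.discretization)

    def rate_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        R = _exchange_matrix(self.rates)
        Q = R * self.freqs[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mean_rate = -float(np.dot(self.freqs, np.diag(Q)))
        return Q / mean_rate, self.freqs.copy()


def codon_mutation_layer(gtr: GTRParams) -> tuple[np.ndarray, np.ndarray]:
    """Unscaled single-nucleotide mutation rates over sense codons.

    Returns the (61, 61) mutation matrix (off-diagonal only, no diagonal,
    no normalization) and the mutation-layer stationary codon frequencies
    (products of nucleotide frequencies restricted to sense codons).
    """
    R = _exchange_matrix(gtr.rates)
    mu = np.zeros((61, 61))
    mu[_NBR_I, _NBR_J] = R[_NBR_FROM, _NBR_TO] * gtr.freqs[_NBR_TO]
    pi_mut = np.array([np.prod([gtr.freqs[NUC_INDEX[c]] for c in codon])
                       for codon in SENSE_CODONS])
    return mu, pi_mut / pi_mut.sum()


def _codon_neighbors() -> tuple[np.ndarray, ...]:
    I, J, frm, to, nonsyn = [], [], [], [], []
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [p for p in range(3) if ci[p] != cj[p]]
            if len(diffs) != 1:
                continue
            p = diffs[0]
            I.append(i)
            J.append(j)
            frm.append(NUC_INDEX[ci[p]])
            to.append(NUC_INDEX[cj[p]])
            nonsyn.append(CODON_AA[ci] != CODON_AA[cj])
    return (np.array(I), np.array(J), np.array(frm), np.array(to),
            np.array(nonsyn, dtype=bool))


_NBR_I, _NBR_J, _NBR_FROM, _NBR_TO, _NBR_NONSYN = _codon_neighbors()


def fixation_factor(S: np.ndarray | float) -> np.ndarray:
    """h(S) = S / (1 - e^-S), the scaled fixation probability; h(0) = 1.

    Stable for large |S|: h(S) ~ S for S >> 0 and h(S) ~ -S e^S for S << 0.
    Satisfies h(S)/h(-S) = e^S, the identity behind detailed balance.
    """
    S = np.asarray(S, dtype=float)
    out = np.empty_like(S)
    small = np.abs(S) < 1e-8
    pos = (S >= 0) & ~small
    neg = (S < 0) & ~small
    out[small] = 1.0 + S[small] / 2.0
    out[pos] = S[pos] / (-np.expm1(-S[pos]))
    out[neg] = -S[neg] * np.exp(S[neg]) / (-np.expm1(S[neg]))
    return out


def _assemble_codon_q(mu: np.ndarray, pi_mut: np.ndarray,
                      codon_fitness: np.ndarray,
                      omega: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Build a normalized mutation-selection codon rate matrix.

    ``codon_fitness`` is the scaled fitness of each sense codon's amino
    acid; the stationary distribution is pi_mut * exp(F) renormalized.
    """
    Q = np.zeros((61, 61))
    S = codon_fitness[_NBR_J] - codon_fitness[_NBR_I]
    rate = mu[_NBR_I, _NBR_J] * fixation_factor(S)
    if omega != 1.0:
        rate = np.where(_NBR_NONSYN, rate * omega, rate)
    Q[_NBR_I, _NBR_J] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    with np.errstate(over="raise"):
        w = pi_mut * np.exp(codon_fitness - codon_fitness.max())
    pi = w / w.sum()
    mean_rate = -float(np.dot(pi, np.diag(Q)))
    if mean_rate <= 0:
        raise ValueError("degenerate rate matrix")
    return Q / mean_rate, pi


@dataclass
class FMutSel0Params:
    """FMutSel0: GTR mutation layer + amino-acid fitnesses + omega."""

    mutation: GTRParams = field(default_factory=GTRParams)
    fitness: np.ndarray = field(default_factory=lambda: np.zeros(20))
    omega: float = 1.0
    alpha: float = 1.0
    n_cat: int = 4
    discretization: str = "mean"

    def __post_init__(self) -> None:
        self.fitness = np.asarray(self.fitness, dtype=float)
        if self.fitness.shape != (20,) or not np.all(np.isfinite(self.fitness)):
            raise ValueError("need 20 finite amino-acid fitnesses")
        if self.omega <= 0:
            raise ValueError("omega must be positive")
        if self.alpha <= 0:
            raise ValueError("gamma shape must be positive")

    @property
    def state_space(self) -> str:
        return "codon"

    def rate_categories(self) -> np.ndarray:
        if self.n_cat == 1:
            return np.ones(1)
        return discrete_gamma(self.alpha, self.n_cat, self.discretization)

    def stationary(self) -> np.ndarray:
        _, pi_mut = codon_mutation_layer(self.mutation)
        F = self.fitness[CODON_AA_INDEX]
        w = pi_mut * np.exp(F - F.max())
        return w / w.sum()

    def rate_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        mu, pi_mut = codon_mutation_layer(self.mutation)
        return _assemble_codon_q(mu, pi_mut, self.fitness[CODON_AA_INDEX],
                                 self.omega)


def build_fmutsel0_Q(params: FMutSel0Params) -> tuple[np.ndarray, np.ndarray]:
    """The FMutSel0 rate matrix and its stationary distribution."""
    return params.rate_matrix()


@dataclass
class SelACParams:
    """Stabilizing selection toward site-specific optimal amino acids.

    Selection coefficients are S_ij = psi * (G(aa_i, a*) - G(aa_j, a*))
    with G the weighted Grantham distance to the site's optimal amino acid
    a*; psi absorbs gene expression / selection strength.  ``optimal_aa``
    may be given per site or derived by majority rule (default) or by
    maximum likelihood over the 20 candidates.
    """

    mutation: GTRParams = field(default_factory=GTRParams)
    weights: tuple[float, float, float] = GRANTHAM_WEIGHTS
    psi: float = 0.02
    optimal_aa: str | None = None  # one letter per codon site, or None
    optimal_rule: str = "majority"  # or "ml"
    alpha: float = 1.0
    n_cat: int = 4
    discretization: str = "mean"

    def __post_init__(self) -> None:
        if self.psi < 0:
            raise ValueError("psi must be non-negative")
        if self.alpha <= 0:
            raise ValueError("gamma shape must be positive")
        if self.optimal_aa is not None:
            bad = set(self.optimal_aa) - set(AA_ORDER)
            if bad:
                raise ValueError(f"unknown amino acid code(s) {sorted(bad)}")

    @property
    def state_space(self) -> str:
        return "codon"

    def rate_categories(self) -> np.ndarray:
        if self.n_cat == 1:
            return np.ones(1)
        return discrete_gamma(self.alpha, self.n_cat, self.discretization)

    def rate_matrix_for(self, optimal: str) -> tuple[np.ndarray, np.ndarray]:
        if optimal not in AA_INDEX:
            raise ValueError(f"unknown amino acid code {optimal!r}")
        mu, pi_mut = codon_mutation_layer(self.mutation)
        G = grantham_matrix(self.weights)[:, AA_INDEX[optimal]]
        fitness = -self.psi * G[CODON_AA_INDEX]
        return _assemble_codon_q(mu, pi_mut, fitness)


def build_selac_Q(params: SelACParams, optimal: str) -> tuple[np.ndarray, np.ndarray]:
    """The SelAC-style rate matrix for one optimal amino acid."""
    return params.rate_matrix_for(optimal)


def majority_optimal_aa(aln: CodonAlignment) -> str:
    """Per-site optimal amino acid by majority rule (ties broken by AA_ORDER)."""
    aas = aln.amino_acid_matrix()
    out = []
    for s in range(aln.n_codons):
        col = aas[:, s]
        col = col[col != MISSING]
        if col.size == 0:
            out.append("A")
            continue
        counts = np.bincount(col, minlength=20)
        out.append(AA_ORDER[int(np.argmax(counts))])
    return "".join(out)


@dataclass
class EmpiricalCodonParams:
    """A codon model from user-supplied 61x61 exchangeabilities.

    Stands in for externally published empirical codon exchangeability sets,
    which are loaded from file rather than bundled.
    """

    exchangeabilities: np.ndarray
    freqs: np.ndarray
    omega: float = 1.0
    alpha: float = 1.0
    n_cat: int = 4
    discretization: str = "mean"

    def __post_init__(self) -> None:
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.exchangeabilities.shape != (61, 61):
            raise ValueError("need a 61x61 exchangeability matrix")
        if not np.allclose(self.exchangeabilities, self.exchangeabilities.T):
            raise ValueError("exchangeabilities must be symmetric")
        if self.freqs.shape != (61,) or np.any(self.freqs <= 0) \
                or abs(self.freqs.sum() - 1) > 1e-8:
            raise ValueError("codon frequencies must be a positive simplex")

    @property
    def state_space(self) -> str:
        return "codon"

    def rate_categories(self) -> np.ndarray:
        if self.n_cat == 1:
            return np.ones(1)
        return discrete_gamma(self.alpha, self.n_cat, self.discretization)

    def rate_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        Q = self.exchangeabilities * self.freqs[None, :]
        if self.omega != 1.0:
            scale = np.ones((61, 61))
            scale[_NBR_I, _NBR_J] = np.where(_NBR_NONSYN, self.omega, 1.0)
            Q = Q * scale
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mean_rate = -float(np.dot(self.freqs, np.diag(Q)))
        return Q / mean_rate, self.freqs.copy()


def load_model_params(path: str | Path):
    """Read model parameters from a key = value text file.

    The ``family`` key selects GTR, FMutSel0 or SelAC; array-valued keys
    (rates, freqs, fitness, weights) are whitespace-separated numbers.
    Unknown keys are rejected so typos fail loudly.
    """
    fields: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"expected 'key = value', got {line!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        fields[key.lower()] = value
    family = fields.pop("family", "GTR")

    def arr(key, default=None):
        if key not in fields:
            return default
        return np.array([float(x) for x in fields.pop(key).split()])

    def num(key, default=None, cast=float):
        return cast(fields.pop(key)) if key in fields else default

    gtr = GTRParams(
        rates=arr("rates", np.ones(6)), freqs=arr("freqs", np.full(4, 0.25)),
        alpha=num("alpha", 1.0), n_cat=num("n_cat", 4, int),
        discretization=fields.pop("discretization", "median"))
    if family.lower() == "gtr":
        model = gtr
    elif family.lower() == "fmutsel0":
        model = FMutSel0Params(
            mutation=gtr, fitness=arr("fitness", np.zeros(20)),
            omega=num("omega", 1.0), alpha=gtr.alpha, n_cat=gtr.n_cat,
            discretization="mean")
    elif family.lower() == "selac":
        weights = arr("weights")
        model = SelACParams(
            mutation=gtr, psi=num("psi", 0.02),
            weights=tuple(weights) if weights is not None else GRANTHAM_WEIGHTS,
            optimal_aa=fields.pop("optimal_aa", None),
            alpha=gtr.alpha, n_cat=gtr.n_cat, discretization="mean")
    else:
        raise ValueError(f"unknown model family {family!r}")
    if fields:
        raise ValueError(f"unknown parameter key(s): {sorted(fields)}")
    return model


def load_codon_exchangeabilities(path: str | Path) -> np.ndarray:
    """Read a whitespace-separated 61x61 symmetric exchangeability file."""
    mat = np.loadtxt(path)
    if mat.shape != (61, 61):
        raise ValueError(f"expected a 61x61 matrix, got {mat.shape}")
    return mat


# --------------------------------------------------------------------------
# eigendecomposition of reversible rate matrices
# --------------------------------------------------------------------------
class EigenQ:
    """Symmetric-similarity eigendecomposition of a reversible Q.

    P(t) = D^-1/2 U exp(L t) U^T D^1/2 with D = diag(pi); probabilities are
    clipped at zero to absorb round-off.
    """

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        d = np.sqrt(pi)
        S = (Q * d[:, None]) / d[None, :]
        S = (S + S.T) / 2.0
        w, U = np.linalg.eigh(S)
        self.w = w
        self.A = U / d[:, None]
        self.B = U.T * d[None, :]
        self.pi = pi

    def P(self, t: float) -> np.ndarray:
        P = (self.A * np.exp(self.w * t)) @ self.B
        np.clip(P, 0.0, None, out=P)
        return P


# --------------------------------------------------------------------------
# likelihood blocks
# --------------------------------------------------------------------------
@dataclass
class _Block:
    eig: EigenQ
    pi: np.ndarray
    rates: np.ndarray
    leaf_partials: list[np.ndarray]  # per taxon row: (S, P)
    weights: np.ndarray  # (P,) pattern counts


def _compress(columns: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique site columns and counts; columns is (n_sites, n_taxa)."""
    patterns, counts = np.unique(columns, axis=0, return_counts=True)
    return patterns.T, counts.astype(float)  # (n_taxa, P), (P,)


def _leaf_partials(pattern_rows: np.ndarray, n_states: int) -> list[np.ndarray]:
    out = []
    for row in pattern_rows:
        part = np.zeros((n_states, row.size))
        miss = row == MISSING
        part[:, miss] = 1.0
        obs = ~miss
        part[row[obs], np.nonzero(obs)[0]] = 1.0
        out.append(part)
    return out


def make_blocks(aln: CodonAlignment, model, taxa: Sequence[str]) -> list[_Block]:
    """Build likelihood blocks for ``model`` over the rows ``taxa``."""
    sub = aln.subset(taxa)
    if model.state_space == "nucleotide":
        data = sub.nucleotide_matrix()
        n_states = 4
        groups = [(None, np.arange(data.shape[1]))]
    else:
        data = sub.codons
        n_states = 61
        if isinstance(model, SelACParams):
            optimal = model.optimal_aa or majority_optimal_aa(sub)
            if len(optimal) != sub.n_codons:
                raise ValueError("optimal_aa length does not match alignment")
            groups = [(aa, np.nonzero([o == aa for o in optimal])[0])
                      for aa in sorted(set(optimal))]
        else:
            groups = [(None, np.arange(data.shape[1]))]
    empty = np.all(data == MISSING, axis=0)
    if np.any(empty):
        raise ValueError(
            f"alignment column(s) with no resolved states: "
            f"{np.nonzero(empty)[0][:5].tolist()}")
    rates = model.rate_categories()
    blocks = []
    for key, sites in groups:
        if sites.size == 0:
            continue
        if isinstance(model, SelACParams):
            Q, pi = model.rate_matrix_for(key)
        else:
            Q, pi = model.rate_matrix()
        patterns, weights = _compress(data[:, sites].T)
        blocks.append(_Block(EigenQ(Q, pi), pi, rates,
                             _leaf_partials(patterns, n_states), weights))
    return blocks


# --------------------------------------------------------------------------
# pruning engine
# --------------------------------------------------------------------------
_TINY = 1e-300


class LikelihoodEngine:
    """Felsenstein pruning and per-edge branch-length optimization.

    The topology is held unrooted (derooted internally); likelihoods are
    therefore invariant to the rooting of the input tree for the reversible
    models used here.
    """

    def __init__(self, topology: PhyloTree, aln: CodonAlignment, model,
                 blocks: list[_Block] | None = None):
        missing = topology.taxa - set(aln.taxa)
        if missing:
            raise ValueError(f"tree taxa absent from alignment: {sorted(missing)}")
        self.model = model
        self.taxa = sorted(topology.taxa)
        self.aln = aln
        self.blocks = blocks if blocks is not None \
            else make_blocks(aln, model, self.taxa)
        self._build_tree(topology)

    def _build_tree(self, topology: PhyloTree) -> None:
        clone = topology.tree.clone(depth=1)
        clone.is_rooted = False
        clone.deroot()
        self.dtree = clone
        nodes = list(clone.postorder_node_iter())
        self.nodes = nodes
        index = {id(nd): i for i, nd in enumerate(nodes)}
        self.root = index[id(clone.seed_node)]
        self.parent = np.full(len(nodes), -1)
        self.children: list[list[int]] = [[] for _ in nodes]
        self.t0 = np.full(len(nodes), 0.1)
        self.leaf_row = np.full(len(nodes), -1)
        row_of = {lab: r for r, lab in enumerate(self.taxa)}
        for i, nd in enumerate(nodes):
            for ch in nd.child_nodes():
                j = index[id(ch)]
                self.parent[j] = i
                self.children[i].append(j)
            if nd.is_leaf():
                self.leaf_row[i] = row_of[nd.taxon.label]
            if nd.edge.length is not None:
                self.t0[i] = max(float(nd.edge.length), MIN_BRANCH_LENGTH)
        self.edges = [i for i in range(len(nodes)) if i != self.root]
        self.postorder = list(range(len(nodes)))  # nodes already postorder

    # ---------------------------------------------------------------- passes
    def _transported(self, block: _Block, down: np.ndarray, t: float) -> np.ndarray:
        """P(r_c t) @ down per category; down is (C, S, P)."""
        out = np.empty_like(down)
        for c, r in enumerate(block.rates):
            out[c] = block.eig.P(r * t) @ down[c]
        return out

    def _down_pass(self, block: _Block, t: np.ndarray):
        C = block.rates.size
        down: list[np.ndarray | None] = [None] * len(self.nodes)
        logsc: list[np.ndarray | None] = [None] * len(self.nodes)
        P = block.weights.size
        for i in self.postorder:
            if self.leaf_row[i] >= 0:
                lp = block.leaf_partials[self.leaf_row[i]]
                down[i] = np.broadcast_to(lp, (C,) + lp.shape)
                logsc[i] = np.zeros(P)
                continue
            prod = np.ones((C, block.pi.size, P))
            ls = np.zeros(P)
            for j in self.children[i]:
                prod *= self._transported(block, down[j], t[j])
                ls += logsc[j]
            m = np.maximum(prod.max(axis=(0, 1)), _TINY)
            prod /= m
            down[i] = prod
            logsc[i] = ls + np.log(m)
        return down, logsc

    def _up_pass(self, block: _Block, t: np.ndarray, down, logsc_down):
        """upE[v]: likelihood of data outside subtree(v) given the state at
        v's parent; scaled, with per-pattern log-scalers."""
        C = block.rates.size
        S = block.pi.size
        P = block.weights.size
        upE: list[np.ndarray | None] = [None] * len(self.nodes)
        lsE: list[np.ndarray | None] = [None] * len(self.nodes)
        up_node: list[np.ndarray | None] = [None] * len(self.nodes)
        ls_node: list[np.ndarray | None] = [None] * len(self.nodes)
        up_node[self.root] = np.ones((C, S, P))
        ls_node[self.root] = np.zeros(P)
        for i in reversed(self.postorder):
            if self.leaf_row[i] >= 0 and i != self.root:
                continue
            kids = self.children[i]
            if not kids:
                continue
            trans = {j: self._transported(block, down[j], t[j]) for j in kids}
            for j in kids:
                prod = up_node[i].copy()
                ls = ls_node[i].copy()
                for k in kids:
                    if k != j:
                        prod = prod * trans[k]
                        ls = ls + logsc_down[k]
                m = np.maximum(prod.max(axis=(0, 1)), _TINY)
                prod = prod / m
                upE[j] = prod
                lsE[j] = ls + np.log(m)
                if self.children[j]:  # j internal: push through its edge
                    nxt = np.empty_like(prod)
                    for c, r in enumerate(block.rates):
                        Pm = block.eig.P(r * t[j])
                        nxt[c] = (Pm.T @ (block.pi[:, None] * prod[c])) \
                            / block.pi[:, None]
                    up_node[j] = nxt
                    ls_node[j] = lsE[j]
        return upE, lsE

    # ------------------------------------------------------------ likelihood
    def lnL(self, t: np.ndarray | None = None) -> float:
        return float(sum(self._block_lnL(b, self.t0 if t is None else t)
                         for b in self.blocks))

    def _block_lnL(self, block: _Block, t: np.ndarray) -> float:
        down, logsc = self._down_pass(block, t)
        site = np.einsum("s,csp->p", block.pi, down[self.root]) / block.rates.size
        if np.any(site <= 0) or not np.all(np.isfinite(site)):
            raise FloatingPointError("non-finite site likelihood")
        return float(np.dot(block.weights, np.log(site) + logsc[self.root]))

    def site_log_likelihoods(self, t: np.ndarray | None = None) -> np.ndarray:
        """Per-pattern log-likelihoods and weights, concatenated over blocks."""
        t = self.t0 if t is None else t
        out = []
        for block in self.blocks:
            down, logsc = self._down_pass(block, t)
            site = np.einsum("s,csp->p", block.pi, down[self.root]) / block.rates.size
            out.append(np.log(site) + logsc[self.root])
        return np.concatenate(out)

    # ---------------------------------------------------------- optimization
    def _edge_objective(self, caches, v: int):
        """Closure lnL(t_v) for one edge with everything else cached.

        Uses the spectral form: site(p) = sum_k e^(w_k r_c t) H_kc(p) with
        H = (A^T @ (pi*upE)) * (B @ down), so each evaluation is one
        exp plus a matvec per category.
        """
        pre = []
        for block, (down, lsd, wup, lsE) in zip(self.blocks, caches):
            H = [(block.eig.A.T @ wup[v][c]) * (block.eig.B @ down[v][c])
                 for c in range(block.rates.size)]
            const = float(np.dot(block.weights, lsd[v] + lsE[v]))
            pre.append((block, H, const))

        def lnl(tv: float) -> float:
            total = 0.0
            for block, H, const in pre:
                site = 0.0
                for c, r in enumerate(block.rates):
                    site = site + np.exp(block.eig.w * (r * tv)) @ H[c]
                site = np.maximum(site / block.rates.size, _TINY)
                total += float(np.dot(block.weights, np.log(site))) + const
            return total

        return lnl

    def _edge_lnL(self, caches, v: int, tv: float) -> float:
        return self._edge_objective(caches, v)(tv)

    @staticmethod
    def _golden_max(f, lo: float, hi: float, xatol: float,
                    max_iter: int) -> float:
        """Golden-section maximization on [lo, hi]; cheap per-call (the
        scipy wrapper's overhead dominates edge optimization otherwise)."""
        invphi = 0.6180339887498949
        a, b = lo, hi
        h = b - a
        c = b - invphi * h
        d = a + invphi * h
        fc, fd = f(c), f(d)
        for _ in range(max_iter):
            if h < xatol:
                break
            if fc > fd:
                b, d, fd = d, c, fc
                h = b - a
                c = b - invphi * h
                fc = f(c)
            else:
                a, c, fc = c, d, fd
                h = b - a
                d = a + invphi * h
                fd = f(d)
        return c if fc > fd else d

    def _make_caches(self, t: np.ndarray):
        caches = []
        for block in self.blocks:
            down, lsd = self._down_pass(block, t)
            upE, lsE = self._up_pass(block, t, down, lsd)
            # pre-weight the outside partials by pi for the edge formula
            wup = [None if u is None else block.pi[None, :, None] * u
                   for u in upE]
            caches.append((down, lsd, wup, lsE))
        return caches

    def optimize(self, t_init: np.ndarray | None = None, tol: float = 1e-4,
                 max_sweeps: int = 30, xatol: float = 1e-6,
                 brent_maxiter: int = 100, t_max: float = MAX_BRANCH_LENGTH,
                 fresh_fallback: bool = True) -> tuple[np.ndarray, float]:
        """Coordinate-ascent branch-length optimization.

        Each sweep caches the conditional likelihoods once and Brent-optimizes
        every edge against them; staleness within a sweep is guarded by
        recomputing the true likelihood at sweep end and redoing the sweep
        edge-by-edge with fresh caches if it failed to improve.
        """
        t = (self.t0 if t_init is None else np.asarray(t_init, dtype=float)).copy()
        np.clip(t, MIN_BRANCH_LENGTH, MAX_BRANCH_LENGTH, out=t)
        lnl = self.lnL(t)
        for _ in range(max_sweeps):
            t_try = t.copy()
            caches = self._make_caches(t_try)
            # optimize in log-length space: short branches need relative,
            # not absolute, resolution
            lo, hi = np.log(MIN_BRANCH_LENGTH), np.log(t_max)
            for v in self.edges:
                f = self._edge_objective(caches, v)
                best = self._golden_max(lambda lx: f(np.exp(lx)), lo, hi,
                                        xatol, brent_maxiter)
                t_try[v] = np.exp(best)
            lnl_try = self.lnL(t_try)
            if lnl_try < lnl and fresh_fallback:
                # stale caches misled a step: redo edge-by-edge with fresh
                # caches, which is slower but monotone
                t_try = t.copy()
                for v in self.edges:
                    caches = self._make_caches(t_try)
                    f = self._edge_objective(caches, v)
                    best = self._golden_max(lambda lx: f(np.exp(lx)), lo,
                                            hi, xatol, brent_maxiter)
                    t_try[v] = np.exp(best)
                lnl_try = self.lnL(t_try)
            if lnl_try < lnl:
                break
            improved = lnl_try - lnl
            t, lnl = t_try, lnl_try
            if improved < tol:
                break
        return t, lnl

    def tree_with_lengths(self, t: np.ndarray) -> PhyloTree:
        clone = self.dtree.clone(depth=1)
        for nd_new, i in zip(clone.postorder_node_iter(), range(len(self.nodes))):
            if i != self.root:
                nd_new.edge.length = float(t[i])
        return PhyloTree(clone, UNIT_SUBSTITUTION)


def pruning_lnL(tree: PhyloTree, aln: CodonAlignment, model) -> float:
    """Log-likelihood of ``aln`` on ``tree`` (lengths as given) under ``model``."""
    engine = LikelihoodEngine(tree, aln, model)
    return engine.lnL()


# --------------------------------------------------------------------------
# fitted models and multi-start optimization
# --------------------------------------------------------------------------
@dataclass
class FittedModel:
    """Result of refitting one model on one fixed topology."""

    family: str
    params: dict
    tree: PhyloTree
    lnL: float
    start_lnLs: list[float]
    converged: bool

    def to_dict(self) -> dict:
        return {"family": self.family, "params": self.params,
                "lnL": self.lnL, "start_lnLs": self.start_lnLs,
                "converged": self.converged,
                "tree": self.tree.to_newick()}


def model_family_name(model) -> str:
    return type(model).__name__.replace("Params", "")


CONVERGENCE_LNL_WINDOW = 1.0


def _scalar_param_fit(engine: LikelihoodEngine, model, name: str,
                      t_start: np.ndarray, coarse: bool,
                      tol: float) -> tuple[float, np.ndarray, float]:
    """Optimize one scalar selection parameter (omega or psi) by Brent on a
    log10 scale, refitting branch lengths (warm-started) at each value."""
    lo, hi = (-2.0, 1.0) if name == "omega" else (-4.0, 0.5)
    state = {"t": t_start.copy()}
    sweeps = 4 if coarse else 12

    def objective(logv: float) -> float:
        setattr(engine.model, name, 10.0 ** logv)
        engine.blocks = make_blocks(engine.aln, engine.model, engine.taxa)
        t, lnl = engine.optimize(state["t"], tol=max(tol, 1e-3),
                                 max_sweeps=sweeps, xatol=1e-4)
        state["t"] = t
        return -lnl

    res = spopt.minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                                options={"xatol": 0.02})
    best = 10.0 ** float(res.x)
    setattr(engine.model, name, best)
    engine.blocks = make_blocks(engine.aln, engine.model, engine.taxa)
    t, lnl = engine.optimize(state["t"], tol=tol, max_sweeps=sweeps * 2)
    return best, t, lnl


def optimize_branch_lengths(topology: PhyloTree, aln: CodonAlignment, model,
                            n_starts: int = 4, seed: int = 0,
                            optimize_params: Sequence[str] = (),
                            tol: float = 1e-4, coarse: bool = False,
                            jitter_sd: float = 0.4) -> FittedModel:
    """Multi-start branch-length (and optional scalar-parameter) optimization
    on a fixed topology.

    Start 0 uses the topology's own branch lengths; further starts jitter
    them log-normally.  ``converged`` requires at least two starts within
    one log-likelihood unit of the best, the criterion used to decide that
    a likelihood had been maximized.
    """
    if n_starts < 1:
        raise ValueError("need at least one start")
    import copy as _copy
    model = _copy.deepcopy(model)
    engine = LikelihoodEngine(topology, aln, model)
    rng = np.random.default_rng(seed)
    max_sweeps = 3 if coarse else 30
    xatol = 2e-3 if coarse else 1e-6  # log-length units
    brent_maxiter = 20 if coarse else 60
    t_max = 10.0 if coarse else MAX_BRANCH_LENGTH
    results = []
    failures = []
    for s in range(n_starts):
        if s == 0:
            t_start = engine.t0.copy()
        else:
            t_start = engine.t0 * np.exp(rng.normal(0.0, jitter_sd, engine.t0.size))
        np.clip(t_start, MIN_BRANCH_LENGTH, MAX_BRANCH_LENGTH, out=t_start)
        try:
            fitted_params = {}
            if optimize_params:
                t, lnl = t_start, None
                for name in optimize_params:
                    val, t, lnl = _scalar_param_fit(engine, model, name,
                                                    t_start, coarse, tol)
                    fitted_params[name] = val
            else:
                t, lnl = engine.optimize(t_start, tol=tol,
                                         max_sweeps=max_sweeps, xatol=xatol,
                                         brent_maxiter=brent_maxiter,
                                         t_max=t_max)
            results.append((lnl, t, fitted_params))
        except FloatingPointError as exc:  # pragma: no cover - defensive
            failures.append(str(exc))
    if not results:
        raise RuntimeError(f"all optimization starts failed: {failures}")
    start_lnLs = [r[0] for r in results]
    best_lnl, best_t, best_params = max(results, key=lambda r: r[0])
    converged = sum(1 for l in start_lnLs
                    if best_lnl - l <= CONVERGENCE_LNL_WINDOW) >= 2
    params = {"alpha": getattr(model, "alpha", None),
              "n_cat": getattr(model, "n_cat", None)}
    for name in ("omega", "psi"):
        if hasattr(model, name):
            params[name] = float(getattr(model, name))
    params.update(best_params)
    return FittedModel(family=model_family_name(model), params=params,
                       tree=engine.tree_with_lengths(best_t),
                       lnL=float(best_lnl),
                       start_lnLs=[float(x) for x in start_lnLs],
                       converged=converged)


def fit_with_protocol(topology: PhyloTree, aln: CodonAlignment, model,
                      initial_starts: int = 4, extension_starts: int = 8,
                      seed: int = 0, **kwargs) -> FittedModel:
    """Multi-start fit with the 4-then-8 extension schedule: if the initial
    starts do not agree within one lnL unit, run the extension block and
    pool all starts."""
    first = optimize_branch_lengths(topology, aln, model,
                                    n_starts=initial_starts, seed=seed, **kwargs)
    if first.converged or extension_starts < 1:
        return first
    second = optimize_branch_lengths(topology, aln, model,
                                     n_starts=extension_starts,
                                     seed=seed + 10_000, **kwargs)
    all_lnls = first.start_lnLs + second.start_lnLs
    best = first if first.lnL >= second.lnL else second
    converged = sum(1 for l in all_lnls
                    if max(all_lnls) - l <= CONVERGENCE_LNL_WINDOW) >= 2
    return FittedModel(family=best.family, params=best.params, tree=best.tree,
                       lnL=best.lnL, start_lnLs=all_lnls, converged=converged)
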