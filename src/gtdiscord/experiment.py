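"""The discordance-preference experiment and its statistical battery.

Loci are filtered to those where RF and path distances agree on which
estimated gene tree is most discordant with the reference species tree,
then balanced so half the retained loci favor each model family.  Each
model's refitted log-likelihoods yield a binary outcome per locus (1 when
the maximum-likelihood topology is the least-discordant estimated gene
tree), tested against the coin-flip null with a one-sample z-test on the
binary outcomes (sample standard deviation in the denominator), backed by
sign and randomization tests, a Kolmogorov-Smirnov test of the observed
delta-lnL distribution against a resampled null, and linear regressions of
delta-lnL on topological distinctness.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .genetree import (EST1_LABEL, EST2_LABEL, REF_LABEL, GeneRecord,
                       LNL_TIE_TOLERANCE)

DEFAULT_ALPHA = 0.05


# --------------------------------------------------------------------------
# locus filtering and balancing
# --------------------------------------------------------------------------
def filter_and_balance(records: Sequence[GeneRecord], n_target: int,
                       seed: int = 0) -> list[GeneRecord]:
    """Drop metric-discordant loci and balance the two model families.

    Keeps n_target/2 loci whose least-discordant estimated gene tree came
    from each family, sampled uniformly under ``seed``; raises if either
    stratum is short.
    """
    if n_target % 2 != 0:
        raise ValueError("n_target must be even to balance the two families")
    survivors = [r for r in records if r.distances and r.distances.metrics_agree]
    strata = {EST1_LABEL: [], EST2_LABEL: []}
    for rec in survivors:
        strata[rec.distances.least_discordant].append(rec)
    half = n_target // 2
    rng = np.random.default_rng(seed)
    chosen: list[GeneRecord] = []
    for label in (EST1_LABEL, EST2_LABEL):
        pool = strata[label]
        if len(pool) < half:
            raise ValueError(
                f"stratum {label} has {len(pool)} loci, need {half}")
        idx = sorted(rng.choice(len(pool), size=half, replace=False))
        chosen.extend(pool[i] for i in idx)
    return chosen


# --------------------------------------------------------------------------
# binary preference scoring
# --------------------------------------------------------------------------
def preference_outcomes(records: Sequence[GeneRecord],
                        model_name: str) -> list[int]:
    """Per-locus outcome bits: 1 iff the model's best-lnL topology is the
    least-discordant *estimated* gene tree.

    The reference topology is not an estimated gene tree, so preferring it
    scores 0; lnL ties (within 1e-6) also score 0 (conservative toward the
    null) and are logged via warnings.
    """
    outcomes = []
    for rec in records:
        lnls = rec.lnls_for(model_name)
        if len(lnls) != 3:
            raise ValueError(
                f"locus {rec.locus_id} lacks refits for {model_name}")
        ordered = sorted(lnls.items(), key=lambda kv: -kv[1])
        if ordered[0][1] - ordered[1][1] < LNL_TIE_TOLERANCE:
            warnings.warn(f"lnL tie at locus {rec.locus_id} under "
                          f"{model_name}; scored 0")
            outcomes.append(0)
            continue
        best = ordered[0][0]
        outcomes.append(int(best != REF_LABEL
                            and best == rec.distances.least_discordant))
    return outcomes


def score_preferences(records: Sequence[GeneRecord],
                      model_name: str) -> tuple[int, int]:
    """(k successes, n trials) for one model over the retained loci."""
    outcomes = preference_outcomes(records, model_name)
    return int(sum(outcomes)), len(outcomes)


def rescore_against_reference(records: Sequence[GeneRecord], ref
                              ) -> tuple[list[GeneRecord], list[str]]:
    """Repeat the discordance ranking against a different reference tree.

    Each locus's distances are recomputed against ``ref`` trimmed to the
    locus's taxa; loci whose two metrics no longer agree on the ranking
    are dropped.  Returns the retained records (with updated
    DistanceRecords) and the dropped locus ids.  Stored model fits are
    kept: only the discordance labels change, so preference scores can be
    re-derived directly.
    """
    from .trees import rank_discordance, trim_to_common_taxa

    kept: list[GeneRecord] = []
    dropped: list[str] = []
    for rec in records:
        est1 = rec.topologies[EST1_LABEL]
        est2 = rec.topologies[EST2_LABEL]
        new_ref = trim_to_common_taxa(ref, est1.taxa)
        dist = rank_discordance(est1, est2, new_ref, locus_id=rec.locus_id)
        if not dist.metrics_agree:
            dropped.append(rec.locus_id)
            continue
        kept.append(GeneRecord(rec.locus_id, rec.alignment,
                               dict(rec.topologies), distances=dist,
                               fits=dict(rec.fits),
                               preferred=dict(rec.preferred)))
    return kept, dropped


# --------------------------------------------------------------------------
# tests
# --------------------------------------------------------------------------
def ztest_proportion(k: int, n: int, p0: float = 0.5) -> tuple[float, float]:
    """One-sample z-test on binary outcomes with a sample-SD denominator.

    z = (k/n - p0) / (s / sqrt(n)) with s the sample standard deviation of
    the 0/1 outcomes (denominator n-1); two-sided normal p.  This is the
    BSDA-style z-test that yields p = 0.33 for 22/38 and p = 0.04 for
    25/38.
    """
    if not (0 <= k <= n):
        raise ValueError("k must be between 0 and n")
    if n < 2:
        raise ValueError("need at least two trials")
    phat = k / n
    s2 = phat * (1 - phat) * n / (n - 1)
    if s2 == 0:
        warnings.warn("degenerate variance (all outcomes equal); p set to 0")
        return (np.inf if phat > p0 else -np.inf, 0.0)
    z = (phat - p0) / np.sqrt(s2 / n)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def sign_test(outcomes: Sequence[int], p0: float = 0.5) -> float:
    """Exact two-sided binomial sign test p-value."""
    outcomes = list(outcomes)
    if len(outcomes) < 2:
        raise ValueError("need at least two outcomes")
    k = int(sum(outcomes))
    return float(stats.binomtest(k, len(outcomes), p0,
                                 alternative="two-sided").pvalue)


def randomization_test(outcomes: Sequence[int], n_permutations: int = 10_000,
                       seed: int = 0) -> float:
    """Sign-flip randomization test on centered outcomes.

    Flips the sign of each outcome-minus-one-half independently and
    compares |mean| of the flipped samples to the observed |mean|.
    """
    x = np.asarray(outcomes, dtype=float) - 0.5
    if x.size < 2:
        raise ValueError("need at least two outcomes")
    rng = np.random.default_rng(seed)
    observed = abs(x.mean())
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, x.size))
    null = np.abs((signs * np.abs(x)).mean(axis=1))
    return float(np.mean(null >= observed - 1e-12))


def ks_vs_randomized_null(observed_dlnl: Sequence[float],
                          pooled_lnls: Sequence[float],
                          n_draws: int = 4000,
                          seed: int = 0) -> tuple[float, float]:
    """Two-sample KS test of observed delta-lnLs against a resampled null.

    The null sample is built by drawing ``n_draws`` pairs independently
    with replacement from the pooled per-topology lnLs and differencing
    them.
    """
    observed = np.asarray(observed_dlnl, dtype=float)
    pooled = np.asarray(pooled_lnls, dtype=float)
    if pooled.size == 0:
        raise ValueError("pooled lnL list is empty")
    if observed.size < 2:
        raise ValueError("need at least two observed delta-lnLs")
    rng = np.random.default_rng(seed)
    null = rng.choice(pooled, size=n_draws, replace=True) \
        - rng.choice(pooled, size=n_draws, replace=True)
    res = stats.ks_2samp(observed, null, mode="asymp")
    return float(res.statistic), float(res.pvalue)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    p: float
    n: int


def _ols(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    res = stats.linregress(x, y)
    return RegressionResult(float(res.slope), float(res.intercept),
                            float(res.rvalue ** 2), float(res.pvalue),
                            int(x.size))


def regress_dlnl(x: Sequence[float], y: Sequence[float],
                 drop_extreme: int = 0) -> tuple[RegressionResult,
                                                 RegressionResult | None]:
    """OLS of delta-lnL on distance, with an outlier-excluded refit.

    The second result drops the ``drop_extreme`` x-values farthest from
    the median of x (None when drop_extreme is 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matching x/y with at least 3 points")
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in x")
    full = _ols(x, y)
    trimmed = None
    if drop_extreme > 0:
        if x.size - drop_extreme < 3:
            raise ValueError("too few points left after dropping outliers")
        keep = np.argsort(-np.abs(x - np.median(x)))[drop_extreme:]
        trimmed = _ols(x[keep], y[keep])
    return full, trimmed


# --------------------------------------------------------------------------
# full battery
# --------------------------------------------------------------------------
@dataclass
class ModelTestResult:
    k: int
    n: int
    z: float
    p: float
    sign_p: float
    randomization_p: float
    ks_est_D: float
    ks_est_p: float
    ks_discord_D: float
    ks_discord_p: float
    regression_est: RegressionResult | None = None
    regression_discord: RegressionResult | None = None


@dataclass
class ExperimentResult:
    """Per-model preference outcomes, delta-lnLs and test statistics."""

    alpha: float
    outcomes: dict[str, list[int]]
    dlnl_est: dict[str, list[float]]  # lnL(Est.GT.1) - lnL(Est.GT.2)
    dlnl_discord: dict[str, list[float]]  # least - most discordant
    tests: dict[str, ModelTestResult]

    def to_dict(self) -> dict:
        out = {"alpha": self.alpha, "models": {}}
        for m, t in self.tests.items():
            entry = {"k": t.k, "n": t.n, "z": t.z, "p": t.p,
                     "sign_p": t.sign_p,
                     "randomization_p": t.randomization_p,
                     "ks_est": [t.ks_est_D, t.ks_est_p],
                     "ks_discord": [t.ks_discord_D, t.ks_discord_p]}
            for name, reg in (("regression_est", t.regression_est),
                              ("regression_discord", t.regression_discord)):
                if reg is not None:
                    entry[name] = {"slope": reg.slope, "r2": reg.r2,
                                   "p": reg.p, "n": reg.n}
            out["models"][m] = entry
        return out


def run_battery(records: Sequence[GeneRecord], model_names: Sequence[str],
                alpha: float = DEFAULT_ALPHA, seed: int = 0) -> ExperimentResult:
    """Run every test of the experiment for each model over retained loci."""
    outcomes: dict[str, list[int]] = {}
    dlnl_est: dict[str, list[float]] = {}
    dlnl_discord: dict[str, list[float]] = {}
    tests: dict[str, ModelTestResult] = {}
    pooled: list[float] = []
    for m in model_names:
        for rec in records:
            lnls = rec.lnls_for(m)
            pooled.extend([lnls[EST1_LABEL], lnls[EST2_LABEL]])
    for i, m in enumerate(model_names):
        outs = preference_outcomes(records, m)
        d_est, d_disc, x_est, x_disc = [], [], [], []
        for rec in records:
            lnls = rec.lnls_for(m)
            d_est.append(lnls[EST1_LABEL] - lnls[EST2_LABEL])
            least = rec.distances.least_discordant
            most = rec.distances.most_discordant
            d_disc.append(lnls[least] - lnls[most])
            x_est.append(rec.distances.rf_est1_est2)
            x_disc.append(rec.distances.rf_est1_ref - rec.distances.rf_est2_ref)
        k, n = int(sum(outs)), len(outs)
        z, p = ztest_proportion(k, n)
        ks_e = ks_vs_randomized_null(d_est, pooled, seed=seed + i)
        ks_d = ks_vs_randomized_null(d_disc, pooled, seed=seed + 50 + i)
        reg_e = reg_d = None
        try:
            reg_e = regress_dlnl(x_est, d_est)[0]
            reg_d = regress_dlnl(x_disc, d_est)[0]
        except ValueError:
            pass
        tests[m] = ModelTestResult(
            k=k, n=n, z=z, p=p, sign_p=sign_test(outs),
            randomization_p=randomization_test(outs, seed=seed + 100 + i),
            ks_est_D=ks_e[0], ks_est_p=ks_e[1],
            ks_discord_D=ks_d[0], ks_discord_p=ks_d[1],
            regression_est=reg_e, regression_discord=reg_d)
        outcomes[m] = outs
        dlnl_est[m] = d_est
        dlnl_discord[m] = d_disc
    return ExperimentResult(alpha=alpha, outcomes=outcomes,
                            dlnl_est=dlnl_est, dlnl_discord=dlnl_discord,
                            tests=tests)


# --------------------------------------------------------------------------
# calibration / power simulation of the whole preference experiment
# --------------------------------------------------------------------------
def simulate_preference_experiment(seed: int, mode: str = "null",
                                   n_taxa: int = 10, n_loci: int = 20,
                                   n_codons: int = 60,
                                   subst_scale: float = 0.25,
                                   null_nni_moves: int = 3,
                                   max_attempts_factor: int = 50
                                   ) -> tuple[int, int, float, float]:
    """One scaled-down replicate of the preference experiment.

    ``mode="null"``: the two candidate gene trees are the two symmetric
    NNI rearrangements of one randomly chosen internal edge of the locus's
    true gene tree, so both are equally wrong (one rearrangement away from
    the truth at the same edge); the distance reference is an independently
    simulated species-tree topology, redrawn per locus, so the discordance
    ranking carries no information about the data, the preference
    probability is exactly 1/2, and locus outcomes are independent.
    ``mode="power"``: the least-discordant
    candidate *is* the true topology, so a working experiment should score
    successes nearly always.  Loci are retained only when the two
    candidates and the reference are pairwise distinct topologies and the
    two distance metrics agree on the discordance ranking.

    Returns (k, n, z, p) from the sample-SD proportion z-test.  Likelihood
    settings are deliberately light (single start, short alignments, coarse
    convergence): both candidates are treated identically, which is all the
    calibration requires.
    """
    from .genetree import random_nni_walk
    from .models import GTRParams, LikelihoodEngine, make_blocks
    from .simulate import (SimConfig, simulate_codon_alignment,
                           simulate_gene_trees, simulate_species_tree,
                           to_substitution_units)
    from .trees import rank_discordance, rf_distance

    if mode not in ("null", "power"):
        raise ValueError("mode must be 'null' or 'power'")
    rng = np.random.default_rng(seed)
    cfg = SimConfig(n_taxa=n_taxa, n_loci=1, coal_scale=1.0,
                    short_branch_fraction=0.0,
                    seed=int(rng.integers(2 ** 31 - 1)))
    st = simulate_species_tree(cfg)

    def fresh_ref():
        # an independent reference topology, redrawn per locus in null
        # mode: discordance rank is then pure noise with respect to the
        # sequence data and locus outcomes are independent
        return simulate_species_tree(
            SimConfig(n_taxa=n_taxa, n_loci=1, coal_scale=1.0,
                      short_branch_fraction=0.0,
                      seed=int(rng.integers(2 ** 31 - 1))))

    ref = st
    gtr = GTRParams(n_cat=1)
    outcomes: list[int] = []
    attempts = 0
    while len(outcomes) < n_loci and attempts < max_attempts_factor * n_loci:
        attempts += 1
        locus_seed = int(rng.integers(2 ** 31 - 1))
        gt = simulate_gene_trees(st, 1, seed=locus_seed)[0]
        if mode == "null":
            ref = fresh_ref()
            # two equally-wrong candidates: independent random NNI walks
            # from the true gene tree
            cand1 = random_nni_walk(gt, null_nni_moves, rng)
            cand2 = random_nni_walk(gt, null_nni_moves, rng)
        else:
            cand1 = gt
            cand2 = random_nni_walk(gt, 1, rng)
        if rf_distance(cand1, cand2) == 0 or rf_distance(cand1, ref) == 0 \
                or rf_distance(cand2, ref) == 0:
            continue
        record = rank_discordance(cand1, cand2, ref)
        if not record.metrics_agree:
            continue
        if mode == "power" and record.least_discordant != EST1_LABEL:
            continue
        aln = simulate_codon_alignment(
            to_substitution_units(gt, subst_scale), gtr, n_codons,
            seed=locus_seed + 1)
        blocks = make_blocks(aln, gtr, sorted(aln.taxa))
        lnls = {}
        for label, topo in ((REF_LABEL, ref), (EST1_LABEL, cand1),
                            (EST2_LABEL, cand2)):
            engine = LikelihoodEngine(
                topo.scale_lengths(subst_scale, "substitution"), aln, gtr,
                blocks=blocks)
            _, lnl = engine.optimize(tol=1e-3, max_sweeps=2, xatol=3e-3,
                                     brent_maxiter=14, t_max=10.0)
            lnls[label] = lnl
        ordered = sorted(lnls.items(), key=lambda kv: -kv[1])
        if ordered[0][1] - ordered[1][1] < LNL_TIE_TOLERANCE:
            outcomes.append(0)
        else:
            best = ordered[0][0]
            outcomes.append(int(best != REF_LABEL
                                and best == record.least_discordant))
    if len(outcomes) < n_loci:
        raise RuntimeError("could not retain enough calibration loci")
    k, n = int(sum(outcomes)), len(outcomes)
    z, p = ztest_proportion(k, n)
    return k, n, z, p
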