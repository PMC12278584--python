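"""Rate matrices, discrete gamma, pruning likelihood and optimization."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from gtdiscord.alignment import (AA_INDEX, CODON_AA_INDEX, SENSE_CODONS,
                                 CodonAlignment)
from gtdiscord.models import (EmpiricalCodonParams, FMutSel0Params, GTRParams,
                              LikelihoodEngine, SelACParams, build_fmutsel0_Q,
                              build_selac_Q, codon_mutation_layer,
                              discrete_gamma, fit_with_protocol,
                              fixation_factor, grantham_distance,
                              load_codon_exchangeabilities,
                              optimize_branch_lengths, pruning_lnL)
from gtdiscord.simulate import simulate_codon_alignment
from gtdiscord.trees import PhyloTree


def random_gtr(seed: int, n_cat: int = 1) -> GTRParams:
    rng = np.random.default_rng(seed)
    freqs = rng.dirichlet(np.full(4, 10.0))
    return GTRParams(rates=rng.uniform(0.3, 3.0, 6), freqs=freqs,
                     alpha=rng.uniform(0.3, 2.0), n_cat=n_cat)


class TestDiscreteGamma:
    @pytest.mark.parametrize("alpha", [0.2, 1.0, 5.0])
    @pytest.mark.parametrize("method", ["mean", "median"])
    def test_single_category_is_one(self, alpha, method):
        assert discrete_gamma(alpha, 1, method) == pytest.approx([1.0])

    def test_exponential_medians(self):
        # alpha=1 is Exp(1): bin medians are -ln(1-p) at p = odd eighths
        expected = -np.log(1 - np.array([0.125, 0.375, 0.625, 0.875]))
        expected /= expected.mean()
        np.testing.assert_allclose(discrete_gamma(1.0, 4, "median"), expected,
                                   rtol=1e-12)

    @pytest.mark.parametrize("alpha", [0.3, 1.0, 2.7])
    def test_mean_rates_match_quadrature(self, alpha):
        rates = discrete_gamma(alpha, 4, "mean")
        bounds = stats.gamma.ppf([0, 0.25, 0.5, 0.75, 1.0], a=alpha,
                                 scale=1 / alpha)
        expected = []
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            val, _ = integrate.quad(
                lambda x: x * stats.gamma.pdf(x, a=alpha, scale=1 / alpha),
                lo, min(hi, 1e3))
            expected.append(4 * val)
        np.testing.assert_allclose(rates, expected, rtol=1e-6)
        assert rates.mean() == pytest.approx(1.0)

    def test_invalid_shape(self):
        with pytest.raises(ValueError):
            discrete_gamma(0.0, 4)


class TestFixationFactor:
    def test_values(self):
        assert fixation_factor(0.0) == pytest.approx(1.0)
        assert fixation_factor(2.0) == pytest.approx(2.0 / (1 - np.exp(-2.0)))
        assert fixation_factor(-2.0) == pytest.approx(
            fixation_factor(2.0) * np.exp(-2.0))

    @given(st.floats(-50, 50))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_detailed_balance_identity(self, s):
        # h(S)/h(-S) = e^S underlies reversibility of the codon models
        h1 = float(fixation_factor(s))
        h2 = float(fixation_factor(-s))
        assert h1 > 0 and h2 > 0
        assert np.log(h1) - np.log(h2) == pytest.approx(s, abs=1e-7)


class TestGrantham:
    def test_ser_leu_is_145(self):
        assert grantham_distance("S", "L") == pytest.approx(145.0, rel=0.01)

    def test_metric_properties(self):
        for a in "ACDE":
            assert grantham_distance(a, a) == 0.0
        assert grantham_distance("S", "L") == grantham_distance("L", "S")

    def test_unknown_code(self):
        with pytest.raises(ValueError):
            grantham_distance("S", "B")


class TestRateMatrices:
    @pytest.mark.parametrize("seed", range(5))
    def test_fmutsel0_properties(self, seed):
        rng = np.random.default_rng(seed)
        p = FMutSel0Params(mutation=random_gtr(seed),
                           fitness=rng.normal(0, 1.5, 20),
                           omega=rng.uniform(0.1, 2.0), n_cat=1)
        Q, pi = build_fmutsel0_Q(p)
        assert np.abs(Q.sum(axis=1)).max() < 1e-10
        off = Q[~np.eye(61, dtype=bool)]
        assert (off >= 0).all()
        # stationary distribution matches pi_mut * e^F analytically
        np.testing.assert_allclose(pi, p.stationary(), atol=1e-12)
        assert np.abs(pi @ Q).max() < 1e-8  # left null vector
        # reversibility
        flux = pi[:, None] * Q
        np.testing.assert_allclose(flux, flux.T, atol=1e-12)
        # unit mean rate at stationarity
        assert -float(pi @ np.diag(Q)) == pytest.approx(1.0)

    def test_equal_fitness_omega_one_is_mutation_layer(self):
        gtr = random_gtr(3)
        p = FMutSel0Params(mutation=gtr, fitness=np.full(20, 1.7), omega=1.0,
                           n_cat=1)
        Q, pi = build_fmutsel0_Q(p)
        mu, pi_mut = codon_mutation_layer(gtr)
        M = mu.copy()
        np.fill_diagonal(M, -M.sum(axis=1))
        M /= -float(pi_mut @ np.diag(M))
        np.testing.assert_allclose(Q, M, atol=1e-12)
        np.testing.assert_allclose(pi, pi_mut, atol=1e-12)

    def test_selac_psi_zero_is_mutation_layer(self):
        gtr = random_gtr(4)
        p = SelACParams(mutation=gtr, psi=0.0, n_cat=1)
        Q, pi = build_selac_Q(p, "L")
        mu, pi_mut = codon_mutation_layer(gtr)
        np.testing.assert_allclose(pi, pi_mut, atol=1e-12)

    def test_selac_optimum_has_max_fitness(self):
        p = SelACParams(psi=0.05, n_cat=1)
        Q, pi = build_selac_Q(p, "K")
        by_aa = {}
        for c, codon in enumerate(SENSE_CODONS):
            by_aa.setdefault(CODON_AA_INDEX[c], []).append(pi[c])
        # the optimal amino acid is the modal one at stationarity
        # (compare per-codon average to control for codon multiplicity)
        means = {aa: np.mean(v) for aa, v in by_aa.items()}
        assert max(means, key=means.get) == AA_INDEX["K"]

    def test_selac_rowsums_and_reversibility(self):
        p = SelACParams(mutation=random_gtr(9), psi=0.03, n_cat=1)
        Q, pi = build_selac_Q(p, "W")
        assert np.abs(Q.sum(axis=1)).max() < 1e-10
        flux = pi[:, None] * Q
        np.testing.assert_allclose(flux, flux.T, atol=1e-12)

    def test_empirical_codon_model_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        exch = rng.uniform(0.1, 1.0, (61, 61))
        exch = (exch + exch.T) / 2
        np.fill_diagonal(exch, 0.0)
        path = tmp_path / "ecm.txt"
        np.savetxt(path, exch)
        loaded = load_codon_exchangeabilities(path)
        freqs = rng.dirichlet(np.full(61, 5.0))
        p = EmpiricalCodonParams(exchangeabilities=loaded, freqs=freqs,
                                 n_cat=1)
        Q, pi = p.rate_matrix()
        assert np.abs(Q.sum(axis=1)).max() < 1e-10
        assert np.abs(pi @ Q).max() < 1e-8


class TestPruning:
    def test_identical_pair_zero_branch(self):
        aln = CodonAlignment.from_sequences({"A": "ATG", "B": "ATG"})
        p = FMutSel0Params(n_cat=1)
        tree = PhyloTree.from_newick("(A:0.0,B:0.0);")
        lnl = pruning_lnL(tree, aln, p)
        pi = p.stationary()
        assert lnl == pytest.approx(np.log(pi[SENSE_CODONS.index("ATG")]),
                                    abs=1e-6)

    def test_jukes_cantor_closed_form(self):
        # identical sequences at distance t: per-site likelihood
        # 1/4 * (1/4 + 3/4 e^{-4t/3})
        rng = np.random.default_rng(1)
        codons = rng.choice(len(SENSE_CODONS), 40)
        seq = "".join(SENSE_CODONS[c] for c in codons)
        aln = CodonAlignment.from_sequences({"A": seq, "B": seq})
        gtr = GTRParams(n_cat=1)
        for t in (0.1, 0.5, 1.7):
            tree = PhyloTree.from_newick(f"(A:{t/2},B:{t/2});")
            lnl = pruning_lnL(tree, aln, gtr)
            p_same = 0.25 + 0.75 * np.exp(-4.0 * t / 3.0)
            assert lnl == pytest.approx(120 * np.log(0.25 * p_same), abs=1e-8)

    def test_invariant_to_rerooting_and_taxon_order(self):
        tree = PhyloTree.from_newick(
            "((A:0.1,B:0.3):0.2,(C:0.15,D:0.25):0.1,E:0.4);")
        rng = np.random.default_rng(2)
        seqs = {t: "".join(rng.choice(SENSE_CODONS, 30)) for t in "ABCDE"}
        aln = CodonAlignment.from_sequences(seqs)
        aln_perm = CodonAlignment.from_sequences(
            {t: seqs[t] for t in "EDCBA"})
        model = FMutSel0Params(mutation=random_gtr(5), omega=0.5, n_cat=2)
        base = pruning_lnL(tree, aln, model)
        from gtdiscord.trees import root_on_outgroup
        rerooted = root_on_outgroup(tree, "C")
        assert pruning_lnL(rerooted, aln, model) == pytest.approx(base, abs=1e-8)
        assert pruning_lnL(tree, aln_perm, model) == pytest.approx(base, abs=1e-8)

    def test_edge_formula_matches_root_formula(self):
        tree = PhyloTree.from_newick(
            "((A:0.1,B:0.3):0.2,(C:0.15,D:0.25):0.1,E:0.4);")
        rng = np.random.default_rng(3)
        seqs = {t: "".join(rng.choice(SENSE_CODONS, 25)) for t in "ABCDE"}
        aln = CodonAlignment.from_sequences(seqs)
        eng = LikelihoodEngine(tree, aln, random_gtr(6, n_cat=4))
        base = eng.lnL()
        caches = eng._make_caches(eng.t0)
        for v in eng.edges:
            assert eng._edge_lnL(caches, v, eng.t0[v]) == pytest.approx(
                base, abs=1e-9)

    def test_gap_only_column_rejected(self):
        aln = CodonAlignment.from_sequences({"A": "ATG---", "B": "ATG---"})
        tree = PhyloTree.from_newick("(A:0.1,B:0.1);")
        with pytest.raises(ValueError, match="no resolved states"):
            pruning_lnL(tree, aln, GTRParams(n_cat=1))

    def test_selac_site_groups(self):
        # lnL must equal the sum of per-group pruning runs
        tree = PhyloTree.from_newick("((A:0.2,B:0.2):0.1,C:0.2,D:0.2);")
        rng = np.random.default_rng(8)
        seqs = {t: "".join(rng.choice(SENSE_CODONS, 20)) for t in "ABCD"}
        aln = CodonAlignment.from_sequences(seqs)
        p = SelACParams(psi=0.02, n_cat=1)
        total = pruning_lnL(tree, aln, p)
        from gtdiscord.models import majority_optimal_aa
        optimal = majority_optimal_aa(aln)
        parts = 0.0
        for aa in sorted(set(optimal)):
            cols = [i for i, o in enumerate(optimal) if o == aa]
            sub = CodonAlignment(aln.locus_id, aln.taxa,
                                 aln.codons[:, cols])
            p_aa = SelACParams(psi=0.02, n_cat=1, optimal_aa=aa * len(cols))
            parts += pruning_lnL(tree, sub, p_aa)
        assert total == pytest.approx(parts, abs=1e-8)


class TestOptimization:
    def test_recovery_gtr(self):
        # data simulated on a known tree: refitted lengths near truth
        true = PhyloTree.from_newick(
            "((A:0.2,B:0.3):0.15,(C:0.25,D:0.2):0.1,(E:0.3,F:0.2):0.12);",
            units="substitution")
        gtr = GTRParams(n_cat=1)
        aln = simulate_codon_alignment(true, gtr, 500, seed=4)
        fit = optimize_branch_lengths(true, aln, gtr, n_starts=2, seed=0)
        # simulation lengths are substitutions per codon site; the GTR fit
        # sees the nucleotide view, so its lengths are per nucleotide site
        # (one third of the codon-site scale)
        total_true = sum(e.length for e in true.tree.preorder_edge_iter()
                         if e.length)
        total_fit = 3.0 * sum(e.length
                              for e in fit.tree.tree.preorder_edge_iter()
                              if e.length)
        assert total_fit == pytest.approx(total_true, rel=0.10)
        assert fit.converged

    def test_deterministic_under_seed(self):
        tree = PhyloTree.from_newick("((A:0.2,B:0.2):0.1,C:0.2,D:0.3);",
                                     units="substitution")
        aln = simulate_codon_alignment(tree, GTRParams(n_cat=1), 100, seed=5)
        f1 = optimize_branch_lengths(tree, aln, GTRParams(n_cat=1),
                                     n_starts=3, seed=42)
        f2 = optimize_branch_lengths(tree, aln, GTRParams(n_cat=1),
                                     n_starts=3, seed=42)
        assert f1.start_lnLs == f2.start_lnLs
        assert f1.lnL == f2.lnL

    def test_convergence_flag_requires_agreeing_starts(self):
        tree = PhyloTree.from_newick("((A:0.2,B:0.2):0.1,C:0.2,D:0.3);",
                                     units="substitution")
        aln = simulate_codon_alignment(tree, GTRParams(n_cat=1), 80, seed=6)
        solo = optimize_branch_lengths(tree, aln, GTRParams(n_cat=1),
                                       n_starts=1, seed=0)
        assert not solo.converged  # one start can never satisfy the rule
        multi = optimize_branch_lengths(tree, aln, GTRParams(n_cat=1),
                                        n_starts=3, seed=0)
        assert multi.converged
        assert multi.lnL == pytest.approx(max(multi.start_lnLs))

    def test_protocol_extends_when_not_converged(self):
        tree = PhyloTree.from_newick("((A:0.2,B:0.2):0.1,C:0.2,D:0.3);",
                                     units="substitution")
        aln = simulate_codon_alignment(tree, GTRParams(n_cat=1), 60, seed=7)
        fit = fit_with_protocol(tree, aln, GTRParams(n_cat=1),
                                initial_starts=1, extension_starts=3, seed=0)
        assert len(fit.start_lnLs) == 4  # 1 initial + 3 extension

    def test_nested_model_never_beats_richer(self):
        # omega fixed at 1 (constraint) vs omega free: the constrained
        # maximum cannot exceed the free maximum beyond tolerance
        true = PhyloTree.from_newick(
            "((A:0.3,B:0.3):0.15,C:0.3,D:0.35);", units="substitution")
        gen = FMutSel0Params(omega=0.3, n_cat=1)
        aln = simulate_codon_alignment(true, gen, 150, seed=9)
        constrained = optimize_branch_lengths(
            true, aln, FMutSel0Params(omega=1.0, n_cat=1), n_starts=1, seed=0)
        free = optimize_branch_lengths(
            true, aln, FMutSel0Params(omega=1.0, n_cat=1), n_starts=1, seed=0,
            optimize_params=("omega",))
        assert free.lnL >= constrained.lnL - 0.05


class TestModelParameterFiles:
    def test_roundtrip_fmutsel0(self, tmp_path):
        from gtdiscord.models import load_model_params
        path = tmp_path / "model.txt"
        path.write_text(
            "family = FMutSel0\n"
            "rates = 1 2 1 1 2 1\n"
            "freqs = 0.3 0.2 0.3 0.2\n"
            "alpha = 0.7\n"
            "n_cat = 2\n"
            "omega = 0.4\n"
            "# a comment line\n")
        model = load_model_params(path)
        assert isinstance(model, FMutSel0Params)
        assert model.omega == pytest.approx(0.4)
        assert model.mutation.freqs[0] == pytest.approx(0.3)
        Q, pi = model.rate_matrix()
        assert np.abs(Q.sum(axis=1)).max() < 1e-10

    def test_unknown_key_rejected(self, tmp_path):
        from gtdiscord.models import load_model_params
        path = tmp_path / "model.txt"
        path.write_text("family = GTR\nbogus = 3\n")
        with pytest.raises(ValueError, match="bogus"):
            load_model_params(path)
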