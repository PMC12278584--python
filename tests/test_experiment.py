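"""Locus filtering, preference scoring and the statistical battery."""
import numpy as np
import pytest
from scipy import stats

from gtdiscord.alignment import CodonAlignment
from gtdiscord.experiment import (filter_and_balance, ks_vs_randomized_null,
                                  preference_outcomes, randomization_test,
                                  regress_dlnl, run_battery,
                                  score_preferences, sign_test,
                                  ztest_proportion)
from gtdiscord.genetree import (EST1_LABEL, EST2_LABEL, REF_LABEL, GeneRecord)
from gtdiscord.models import FittedModel
from gtdiscord.trees import DistanceRecord, PhyloTree


def make_record(locus_id, least, agree=True, lnls=None):
    """A minimal GeneRecord with synthetic distances and fits."""
    topo = PhyloTree.from_newick("((a,b),(c,d));")
    most = EST2_LABEL if least == EST1_LABEL else EST1_LABEL
    tie = "tie/ambiguous"
    dist = DistanceRecord(
        locus_id=locus_id, rf_est1_ref=2, rf_est2_ref=4, rf_est1_est2=2,
        path_est1_ref=1.0, path_est2_ref=2.0, path_est1_est2=1.0,
        normalized_rf_est1_ref=0.5, normalized_rf_est2_ref=1.0,
        normalized_rf_est1_est2=0.5,
        least_discordant_rf=least if agree else tie,
        least_discordant_path=least if agree else tie,
        least_discordant=least if agree else tie,
        most_discordant=most if agree else tie,
        metrics_agree=agree)
    rec = GeneRecord(locus_id, None, {REF_LABEL: topo, EST1_LABEL: topo,
                                      EST2_LABEL: topo}, distances=dist)
    if lnls:
        for topo_label, lnl in lnls.items():
            rec.fits[("M", topo_label)] = FittedModel(
                "M", {}, topo, lnl, [lnl], True)
    return rec


class TestFilterAndBalance:
    def test_identity_when_balanced(self):
        recs = [make_record(f"l{i}", EST1_LABEL if i % 2 else EST2_LABEL)
                for i in range(8)]
        out = filter_and_balance(recs, 8, seed=0)
        assert {r.locus_id for r in out} == {r.locus_id for r in recs}

    def test_drops_disagreeing_loci(self):
        recs = [make_record("bad", EST1_LABEL, agree=False)] + \
            [make_record(f"l{i}", EST1_LABEL if i % 2 else EST2_LABEL)
             for i in range(4)]
        out = filter_and_balance(recs, 4, seed=0)
        assert all(r.locus_id != "bad" for r in out)

    def test_shortfall_errors(self):
        recs = [make_record(f"l{i}", EST1_LABEL) for i in range(30)] + \
            [make_record(f"m{i}", EST2_LABEL) for i in range(10)]
        with pytest.raises(ValueError, match="stratum"):
            filter_and_balance(recs, 40, seed=0)

    def test_deterministic_under_seed(self):
        recs = [make_record(f"l{i}", EST1_LABEL if i % 2 else EST2_LABEL)
                for i in range(20)]
        a = [r.locus_id for r in filter_and_balance(recs, 8, seed=3)]
        b = [r.locus_id for r in filter_and_balance(recs, 8, seed=3)]
        assert a == b

    def test_odd_target_rejected(self):
        with pytest.raises(ValueError):
            filter_and_balance([], 5, seed=0)


class TestScorePreferences:
    def test_ref_preferred_scores_zero(self):
        rec = make_record("l1", EST1_LABEL,
                          lnls={REF_LABEL: -10.0, EST1_LABEL: -20.0,
                                EST2_LABEL: -30.0})
        assert preference_outcomes([rec], "M") == [0]

    def test_all_prefer_least_discordant(self):
        recs = [make_record(f"l{i}", EST1_LABEL,
                            lnls={REF_LABEL: -30.0, EST1_LABEL: -10.0,
                                  EST2_LABEL: -20.0}) for i in range(5)]
        assert score_preferences(recs, "M") == (5, 5)

    def test_manual_tally(self):
        specs = [
            (EST1_LABEL, {REF_LABEL: -3, EST1_LABEL: -1, EST2_LABEL: -2}, 1),
            (EST2_LABEL, {REF_LABEL: -3, EST1_LABEL: -1, EST2_LABEL: -2}, 0),
            (EST2_LABEL, {REF_LABEL: -3, EST1_LABEL: -2, EST2_LABEL: -1}, 1),
            (EST1_LABEL, {REF_LABEL: -1, EST1_LABEL: -2, EST2_LABEL: -3}, 0),
        ]
        recs = [make_record(f"l{i}", least, lnls=lnls)
                for i, (least, lnls, _) in enumerate(specs)]
        assert preference_outcomes(recs, "M") == [e for _, _, e in specs]

    def test_tie_scores_zero_with_warning(self):
        rec = make_record("l1", EST1_LABEL,
                          lnls={REF_LABEL: -30.0, EST1_LABEL: -10.0,
                                EST2_LABEL: -10.0 - 1e-9})
        with pytest.warns(UserWarning, match="tie"):
            assert preference_outcomes([rec], "M") == [0]


class TestZTest:
    def test_null_midpoint(self):
        z, p = ztest_proportion(19, 38)
        assert z == 0.0 and p == 1.0

    def test_printed_worked_examples(self):
        # the two published p-values from 38-locus counts
        assert ztest_proportion(22, 38)[1] == pytest.approx(0.33, abs=0.005)
        assert ztest_proportion(25, 38)[1] == pytest.approx(0.04, abs=0.005)

    def test_degenerate_variance_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            z, p = ztest_proportion(10, 10)
        assert p == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ztest_proportion(5, 4)
        with pytest.raises(ValueError):
            ztest_proportion(1, 1)


class TestSecondaryTests:
    def test_sign_test_all_ones_closed_form(self):
        assert sign_test([1] * 10) == pytest.approx(2 * 0.5 ** 10)

    def test_balanced_outcomes_not_significant(self):
        outs = [1, 0] * 10
        assert sign_test(outs) == pytest.approx(1.0)
        assert randomization_test(outs, seed=0) == pytest.approx(1.0, abs=0.05)

    def test_randomization_close_to_exact_binomial(self):
        outs = [1] * 25 + [0] * 13
        exact = sign_test(outs)
        approx = randomization_test(outs, n_permutations=20_000, seed=1)
        assert approx == pytest.approx(exact, abs=0.02)


class TestKS:
    def test_identical_to_null_sample(self):
        rng = np.random.default_rng(0)
        pooled = rng.normal(0, 5, 200)
        null = rng.choice(pooled, 4000) - rng.choice(pooled, 4000)
        D, p = ks_vs_randomized_null(null, pooled, seed=3)
        assert p > 0.05  # same distribution: no detectable difference

    def test_shifted_sample_rejected(self):
        rng = np.random.default_rng(1)
        pooled = rng.normal(0, 1, 200)
        observed = rng.normal(50, 1, 60)
        D, p = ks_vs_randomized_null(observed, pooled, seed=0)
        assert p < 1e-6

    def test_calibration_under_null(self):
        # observed drawn from the null construction itself: p-values should
        # reject at roughly the nominal rate
        rng = np.random.default_rng(2)
        rejections = 0
        n_reps = 200
        for rep in range(n_reps):
            pooled = rng.normal(0, 3, 160)
            observed = rng.choice(pooled, 40) - rng.choice(pooled, 40)
            _, p = ks_vs_randomized_null(observed, pooled, seed=rep)
            rejections += (p < 0.05)
        se = np.sqrt(0.05 * 0.95 / n_reps)
        assert rejections / n_reps == pytest.approx(0.05, abs=3 * se)

    def test_empty_pool_errors(self):
        with pytest.raises(ValueError):
            ks_vs_randomized_null([1.0, 2.0], [])


class TestRegression:
    def test_exact_line(self):
        full, _ = regress_dlnl([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert full.slope == pytest.approx(2.0)
        assert full.r2 == pytest.approx(1.0)
        assert full.p < 1e-10

    def test_textbook_normal_equations(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 7.0])
        y = np.array([2.1, 3.9, 8.3, 10.4, 13.0])
        full, _ = regress_dlnl(x, y)
        # closed-form OLS
        slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum(
            (x - x.mean()) ** 2)
        intercept = y.mean() - slope * x.mean()
        assert full.slope == pytest.approx(slope)
        assert full.intercept == pytest.approx(intercept)

    def test_outlier_refit_drops_extremes(self):
        x = [10.0, 1.0, 2.0, 3.0, 4.0, 5.0]
        y = [100.0, 2.0, 4.0, 6.0, 8.0, 10.0]
        full, trimmed = regress_dlnl(x, y, drop_extreme=1)
        assert trimmed.n == 5
        assert trimmed.slope == pytest.approx(2.0)

    def test_null_calibration(self):
        rng = np.random.default_rng(3)
        n_reps = 400
        rejections = 0
        for _ in range(n_reps):
            x = rng.normal(0, 1, 40)
            y = rng.normal(0, 1, 40)
            full, _ = regress_dlnl(x, y)
            rejections += (full.p < 0.05)
        se = np.sqrt(0.05 * 0.95 / n_reps)
        assert rejections / n_reps == pytest.approx(0.05, abs=3 * se)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            regress_dlnl([1, 1, 1], [1, 2, 3])


class TestBattery:
    def test_battery_over_synthetic_records(self):
        rng = np.random.default_rng(4)
        recs = []
        for i in range(10):
            least = EST1_LABEL if i % 2 else EST2_LABEL
            base = -1000 + rng.normal(0, 5)
            lnls = {REF_LABEL: base - 10,
                    EST1_LABEL: base + rng.normal(0, 2),
                    EST2_LABEL: base + rng.normal(0, 2)}
            recs.append(make_record(f"l{i}", least, lnls=lnls))
        res = run_battery(recs, ["M"], seed=0)
        t = res.tests["M"]
        assert t.n == 10 and 0 <= t.k <= 10
        assert 0.0 <= t.p <= 1.0
        assert 0.0 <= t.sign_p <= 1.0
        assert 0.0 <= t.ks_est_p <= 1.0
        assert len(res.dlnl_est["M"]) == 10
        d = res.to_dict()
        assert "M" in d["models"]


class TestSecondReference:
    def test_rescore_drops_changed_loci(self):
        from gtdiscord.experiment import rescore_against_reference
        t_ab = PhyloTree.from_newick("(((a,b),c),(d,e));")
        t_ad = PhyloTree.from_newick("(((a,d),c),(b,e));")
        t_ae = PhyloTree.from_newick("(((a,e),c),(b,d));")
        recs = []
        for i, (e1, e2) in enumerate([(t_ab, t_ad), (t_ad, t_ae)]):
            rec = make_record(f"l{i}", EST1_LABEL)
            rec.topologies = {REF_LABEL: t_ab, EST1_LABEL: e1.copy(),
                              EST2_LABEL: e2.copy()}
            recs.append(rec)
        kept, dropped = rescore_against_reference(recs, t_ab)
        # locus 0: est1 == new ref -> unambiguous; locus 1: both
        # candidates equally far from the reference -> dropped
        assert [r.locus_id for r in kept] == ["l0"]
        assert kept[0].distances.least_discordant == EST1_LABEL
        assert dropped == ["l1"]
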