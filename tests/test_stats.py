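import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from radiosurv.stats import (
    SurvivalRecord,
    chi_square_2x2,
    cox_single_covariate,
    hazard_ratio,
    holm_bonferroni,
    kaplan_meier,
    kruskal_wallis,
    logrank_test,
    median_split,
    univariate_screen,
    wilcoxon_rank_sum,
)
from radiosurv.synthetic import draw_survival_times


def recs(times, events=None):
    if events is None:
        events = [1] * len(times)
    return [SurvivalRecord(float(t), int(e)) for t, e in zip(times, events)]


def logrank_textbook(ta, ea, tb, eb):
    """Independent O-E/V tabulation of the two-group log-rank statistic."""
    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb])
    group = np.concatenate([np.zeros(len(ta)), np.ones(len(tb))])
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (group == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = o_minus_e**2 / var
    return chi2, sps.chi2.sf(chi2, 1)


class TestKaplanMeier:
    def test_all_events_hand_case(self):
        c = kaplan_meier(recs([1, 2, 3]))
        np.testing.assert_allclose(c.survival_probs, [2 / 3, 1 / 3, 0.0])

    def test_censored_hand_case(self):
        c = kaplan_meier(recs([1, 2, 3], [1, 0, 1]))
        np.testing.assert_allclose(c.event_times, [1, 3])
        np.testing.assert_allclose(c.survival_probs, [2 / 3, 0.0])

    def test_no_censoring_equals_empirical(self, rng):
        times = rng.exponential(10, size=40).round(3)
        c = kaplan_meier(recs(times))
        for t, s in zip(c.event_times, c.survival_probs):
            assert s == pytest.approx((times > t).mean(), abs=1e-12)

    def test_probs_non_increasing(self, rng):
        times = rng.exponential(10, size=30)
        events = rng.integers(0, 2, size=30)
        events[0] = 1
        c = kaplan_meier(recs(times, events))
        assert (np.diff(c.survival_probs) <= 1e-12).all()

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            kaplan_meier([])


class TestLogrank:
    def test_identical_groups(self):
        g = recs([1, 2, 3, 4])
        r = logrank_test(g, g)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_label_swap_symmetry(self, rng):
        a = recs(rng.exponential(10, 20))
        b = recs(rng.exponential(15, 25))
        r1 = logrank_test(a, b)
        r2 = logrank_test(b, a)
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-12)

    def test_matches_textbook_tabulation(self):
        ta, tb = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        chi2, p = logrank_textbook(ta, np.ones(3), tb, np.ones(3))
        r = logrank_test(recs(ta), recs(tb))
        assert r.statistic == pytest.approx(chi2, abs=1e-10)
        assert r.p_value == pytest.approx(p, abs=1e-10)

    def test_matches_textbook_with_censoring(self, rng):
        ta = rng.exponential(10, 30).round(1) + 0.1
        tb = rng.exponential(20, 25).round(1) + 0.1
        ea = rng.integers(0, 2, 30)
        eb = rng.integers(0, 2, 25)
        ea[0] = eb[0] = 1
        chi2, p = logrank_textbook(ta, ea, tb, eb)
        r = logrank_test(recs(ta, ea), recs(tb, eb))
        assert r.statistic == pytest.approx(chi2, rel=1e-8)

    def test_no_events_raises(self):
        with pytest.raises(ValueError):
            logrank_test(recs([1, 2], [0, 0]), recs([3], [0]))


class TestHazardRatio:
    def test_null_simulation_hr_near_one(self, rng):
        n = 500
        times = rng.exponential(300, n)
        groups = rng.integers(0, 2, n)
        r = hazard_ratio(groups, recs(times))
        assert 0.8 <= r.hr <= 1.25

    def test_planted_hr_two_recovery(self):
        rng = np.random.default_rng(7)
        n = 1000
        group = rng.permutation(np.repeat([0, 1], n // 2))
        hazards = (1 / 400) * np.exp(np.log(2) * group)
        t, e = draw_survival_times(hazards, 0.1, rng)
        r = hazard_ratio(group, recs(t, e))
        assert 1.8 <= r.hr <= 2.2
        assert r.ci_low <= 2.0 <= r.ci_high

    def test_relabel_antisymmetry(self, rng):
        n = 60
        times = rng.exponential(100, n)
        groups = rng.integers(0, 2, n)
        r1 = hazard_ratio(groups, recs(times))
        r2 = hazard_ratio(1 - groups, recs(times))
        assert r1.hr == pytest.approx(1.0 / r2.hr, abs=1e-8)

    def test_matches_lifelines_cox(self, rng):
        import pandas as pd
        from lifelines import CoxPHFitter

        n = 120
        groups = rng.integers(0, 2, n)
        times = rng.exponential(100 * (1 + groups), n).round(2) + 0.1
        events = rng.integers(0, 2, n)
        events[:5] = 1
        beta, se, conv = cox_single_covariate(
            groups.astype(float), times.astype(float), events
        )
        df = pd.DataFrame(dict(t=times, e=events, g=groups))
        cph = CoxPHFitter()
        cph.fit(df, duration_col="t", event_col="e")
        assert conv
        assert beta == pytest.approx(float(cph.params_["g"]), abs=1e-4)
        assert se == pytest.approx(float(cph.standard_errors_["g"]), abs=1e-4)

    def test_recovers_beta_within_two_se(self):
        hits = 0
        n_sim = 20
        for s in range(n_sim):
            rng = np.random.default_rng(100 + s)
            n = 500
            group = rng.integers(0, 2, n)
            hz = 0.01 * np.exp(0.5 * group)
            t, e = draw_survival_times(hz, 0.2, rng)
            beta, se, _ = cox_single_covariate(
                group.astype(float), t, e
            )
            if abs(beta - 0.5) <= 2 * se:
                hits += 1
        assert hits >= 0.9 * n_sim

    def test_complete_separation_flagged(self):
        r = hazard_ratio(
            np.array([0, 0, 0, 1, 1, 1]), recs([1, 2, 3, 100, 110, 120])
        )
        assert "nonconverged" in r.flags or r.ci_high > 1e6


class TestMedianSplit:
    def test_even_case(self):
        np.testing.assert_array_equal(
            median_split([5, 10, 15, 20]), [0, 0, 1, 1]
        )

    def test_ties_go_high(self):
        np.testing.assert_array_equal(median_split([1, 2, 2, 3]), [0, 1, 1, 1])

    def test_degenerate_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            median_split([3, 3, 3])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-100, 100, allow_nan=False), min_size=2, max_size=30))
    def test_both_groups_nonempty_unless_degenerate(self, vals):
        try:
            labels = median_split(vals)
        except ValueError:
            return
        assert 0 < labels.sum() < len(vals)


class TestHolm:
    def test_worked_example(self):
        np.testing.assert_allclose(
            holm_bonferroni([0.01, 0.02, 0.04]), [0.03, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert holm_bonferroni([0.5])[0] == 0.5

    def test_all_ones(self):
        assert (holm_bonferroni([1.0, 1.0, 1.0]) == 1.0).all()

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(25)
        _, adj, _, _ = multipletests(p, method="holm")
        np.testing.assert_allclose(holm_bonferroni(p), adj, atol=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=20))
    def test_dominates_raw_dominated_by_bonferroni(self, p):
        adj = holm_bonferroni(p)
        p = np.asarray(p)
        assert (adj >= p - 1e-15).all()
        bonf = np.minimum(1.0, p * len(p))
        assert (adj <= bonf + 1e-15).all()


class TestRankTests:
    def test_exact_small_sample(self):
        r = wilcoxon_rank_sum([1, 2], [3, 4])
        assert r.p_value == pytest.approx(2 / 6, abs=1e-12)

    def test_all_tied(self):
        assert wilcoxon_rank_sum([5, 5], [5, 5, 5]).p_value == 1.0
        assert kruskal_wallis([[2, 2], [2], [2, 2]]).statistic == 0.0

    def test_two_group_kruskal_equals_wilcoxon(self, rng):
        x = rng.normal(0, 1, 25)
        y = rng.normal(0.5, 1, 25)
        pw = wilcoxon_rank_sum(x, y).p_value
        pk = kruskal_wallis([x, y]).p_value
        assert pw == pytest.approx(pk, abs=1e-6)


class TestChiSquare:
    def test_perfect_association(self):
        r = chi_square_2x2([[10, 0], [0, 10]])
        assert r.statistic == pytest.approx(20.0)

    def test_independence(self):
        r = chi_square_2x2([[5, 5], [5, 5]])
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    def test_transpose_invariance(self):
        t = [[7, 3], [2, 9]]
        assert chi_square_2x2(t).statistic == pytest.approx(
            chi_square_2x2(np.transpose(t)).statistic
        )

    def test_zero_margin_raises(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[0, 0], [3, 4]])


class TestUnivariateScreen:
    def test_single_feature_adjusted_equals_raw(self, rng):
        import pandas as pd

        n = 60
        feats = pd.DataFrame({"f": rng.normal(size=n)})
        times = rng.exponential(100, n)
        res = univariate_screen(feats, recs(times))
        assert res["p_adjusted"].iloc[0] == pytest.approx(
            res["p_value"].iloc[0]
        )

    def test_null_familywise_error_controlled(self):
        import pandas as pd

        n_rep, n, n_feat = 20, 80, 15
        fw_errors = 0
        for s in range(n_rep):
            rng = np.random.default_rng(9000 + s)
            feats = pd.DataFrame(
                rng.normal(size=(n, n_feat)),
                columns=[f"f{i}" for i in range(n_feat)],
            )
            times = rng.exponential(100, n)
            res = univariate_screen(feats, recs(times))
            if (res["p_adjusted"] < 0.05).any():
                fw_errors += 1
        # Binomial(20, 0.05): P(X >= 4) < 0.02
        assert fw_errors <= 3

    def test_planted_feature_detected(self):
        import pandas as pd

        hits = 0
        n_rep = 10
        for s in range(n_rep):
            rng = np.random.default_rng(500 + s)
            n = 300
            z = rng.normal(size=n)
            noise = rng.normal(size=(n, 9))
            feats = pd.DataFrame(
                np.column_stack([z, noise]),
                columns=["planted"] + [f"n{i}" for i in range(9)],
            )
            hz = 0.01 * np.exp(np.log(2) * z)
            t, e = draw_survival_times(hz, 0.1, rng)
            res = univariate_screen(feats, recs(t, e))
            if res.loc["planted", "p_adjusted"] < 0.05:
                hits += 1
        assert hits >= 8

    def test_degenerate_feature_flagged_not_fatal(self, rng):
        import pandas as pd

        n = 40
        feats = pd.DataFrame(
            {"const": np.ones(n), "ok": rng.normal(size=n)}
        )
        res = univariate_screen(feats, recs(rng.exponential(50, n)))
        assert np.isnan(res.loc["const", "p_value"])
        assert res.loc["const", "flag"] != ""
        assert np.isfinite(res.loc["ok", "p_adjusted"])
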