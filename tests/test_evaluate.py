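"""IPCW metrics, decision analytics, competing risks and design calculators."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from aprs.evaluate import (
    SampleSizeSpec,
    achieved_power,
    competing_risk_cif,
    decision_curve,
    evaluate_model,
    ipcw_weights,
    km_logrank,
    nnt,
    panel_correlation_layout,
    sample_size,
    threshold_metrics,
    time_dependent_auc,
    weighted_mean_metrics,
)

from conftest import make_outcomes


class TestIpcwWeights:
    def test_no_censoring_all_weights_one(self):
        rng = np.random.default_rng(0)
        out = make_outcomes(rng.uniform(1, 10, 50), np.ones(50))
        w = ipcw_weights(out, 5.0)
        informative = (out["time_years"] <= 5.0) | (out["time_years"] > 5.0)
        assert np.allclose(w[informative.to_numpy()], 1.0)

    def test_exponential_censoring_mean_weight(self):
        # with ~50% independent censoring by t the mean control weight is ~2
        rng = np.random.default_rng(1)
        n = 4000
        T = rng.exponential(50.0, n)
        C = rng.exponential(5.0 / np.log(2.0), n)  # P(C > 5) = 0.5
        t = np.minimum(T, C)
        e = (T <= C).astype(int)
        out = make_outcomes(t, e)
        w = ipcw_weights(out, 5.0).to_numpy()
        ctrl = t > 5.0
        assert np.mean(w[ctrl]) == pytest.approx(2.0, rel=0.05)

    @given(st.floats(1.0, 8.0), st.floats(0.5, 1.9))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_weights_nondecreasing_in_t(self, t1, factor):
        t2 = t1 * (1.0 + (factor - 0.5))
        rng = np.random.default_rng(5)
        n = 200
        T = rng.exponential(12.0, n)
        C = rng.exponential(15.0, n)
        out = make_outcomes(np.minimum(T, C), (T <= C).astype(int))
        w1 = ipcw_weights(out, min(t1, out["time_years"].max() * 0.9)).to_numpy()
        w2 = ipcw_weights(out, min(t2, out["time_years"].max() * 0.9)).to_numpy()
        both = (w1 > 0) & (w2 > 0)
        assert np.all(w2[both] >= w1[both] - 1e-12)


class TestTimeDependentAuc:
    def test_perfect_separation_gives_100(self):
        t = np.arange(1.0, 21.0)
        out = make_outcomes(t, np.ones(20))
        s = -t  # higher risk -> earlier event, perfectly
        tab, tauc = time_dependent_auc(s, out, [5.0, 10.0, 15.0])
        assert np.allclose(tab["auc_pct"], 100.0)
        assert tauc == pytest.approx(100.0)

    def test_uninformative_score_near_50(self):
        rng = np.random.default_rng(2)
        aucs = []
        for rep in range(30):
            n = 120
            t = rng.uniform(0, 10, n)
            out = make_outcomes(t, (rng.random(n) < 0.7).astype(int))
            tab, tauc = time_dependent_auc(rng.normal(size=n), out, [5.0])
            aucs.append(tauc)
        assert abs(np.mean(aucs) - 50.0) < 3.0

    def test_small_uncensored_fixture_matches_brute_force(self):
        rng = np.random.default_rng(3)
        n = 12
        t = rng.uniform(1, 10, n)
        s = rng.normal(size=n)
        out = make_outcomes(t, np.ones(n))
        for horizon in (3.0, 5.0, 8.0):
            case = t <= horizon
            if case.sum() == 0 or case.sum() == n:
                continue
            wins = sum(
                (s[i] > s[j]) + 0.5 * (s[i] == s[j])
                for i in range(n) for j in range(n) if case[i] and not case[j]
            )
            brute = 100.0 * wins / (case.sum() * (n - case.sum()))
            tab, _ = time_dependent_auc(s, out, [horizon])
            assert tab["auc_pct"].iloc[0] == pytest.approx(brute, abs=1e-12)

    def test_censored_matches_independent_reimplementation(self):
        # independent IPCW estimator written from the weighted-Wilcoxon
        # definition, sharing no code with the implementation
        rng = np.random.default_rng(4)
        n = 80
        T = rng.exponential(8.0, n)
        C = rng.exponential(10.0, n)
        t = np.minimum(T, C)
        e = (T <= C).astype(int)
        s = 0.5 * -np.log(T) + rng.normal(size=n)
        out = make_outcomes(t, e)
        horizon = 5.0
        tab, _ = time_dependent_auc(s, out, [horizon])

        # reference: KM of censoring, weights, double loop
        from lifelines import KaplanMeierFitter

        kmc = KaplanMeierFitter().fit(t, 1 - e)

        def G(x):
            return float(kmc.predict(np.nextafter(x, -np.inf)))

        num = den = 0.0
        for i in range(n):
            if not (e[i] == 1 and t[i] <= horizon):
                continue
            wi = 1.0 / G(t[i])
            for j in range(n):
                if t[j] <= horizon:
                    continue
                wj = 1.0 / float(kmc.predict(horizon))
                num += wi * wj * ((s[i] > s[j]) + 0.5 * (s[i] == s[j]))
                den += wi * wj
        assert tab["auc_pct"].iloc[0] == pytest.approx(100.0 * num / den, abs=1e-10)

    def test_agrees_with_sksurv_cumulative_dynamic_auc(self):
        from sksurv.metrics import cumulative_dynamic_auc
        from sksurv.util import Surv

        rng = np.random.default_rng(5)
        n = 300
        x = rng.normal(size=n)
        T = rng.exponential(np.exp(-0.8 * x) * 8)
        C = rng.exponential(12.0, n)
        t = np.minimum(T, C)
        e = T <= C
        out = make_outcomes(t, e.astype(int))
        y = Surv.from_arrays(e, t)
        times = [3.0, 5.0]
        ref, _ = cumulative_dynamic_auc(y, y, x, times)
        tab, _ = time_dependent_auc(x, out, times)
        assert np.allclose(tab["auc_pct"].to_numpy(), 100.0 * ref, atol=1.0)


class TestThresholdMetrics:
    def test_printed_formulas_on_fixed_confusion_counts(self):
        # TP=8 FP=2 TN=18 FN=2 evaluated by hand
        tp, fp, tn, fn = 8.0, 2.0, 18.0, 2.0
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        ppv = tp / (tp + fp)
        npv = tn / (tn + fn)
        acc = (tp + tn) / 30.0
        f1 = 2 * ppv * sens / (ppv + sens)
        mcc = (tp * tn - fp * fn) / np.sqrt(
            (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        )
        assert (sens, spec, ppv, npv) == (0.8, 0.9, 0.8, 0.9)
        assert acc == pytest.approx(0.8667, abs=1e-4)
        assert f1 == pytest.approx(0.8)
        assert mcc == pytest.approx(0.7)
        # construct an uncensored dataset realizing exactly these counts
        # cases: 8 with high score, 2 with low; controls: 2 high, 18 low
        s = np.r_[np.ones(8), np.zeros(2), np.ones(2), np.zeros(18)]
        t = np.r_[np.full(10, 1.0), np.full(20, 9.0)]
        out = make_outcomes(t, np.r_[np.ones(10), np.zeros(20)].astype(int))
        out.loc[out.event == 0, "time_years"] = 9.0
        m = threshold_metrics(s, out, 5.0)
        assert (m.tp, m.fp, m.tn, m.fn) == (8.0, 2.0, 18.0, 2.0)
        assert m.sensitivity == pytest.approx(sens, abs=1e-12)
        assert m.specificity == pytest.approx(spec, abs=1e-12)
        assert m.f1 == pytest.approx(f1, abs=1e-12)
        assert m.accuracy == pytest.approx(acc, abs=1e-12)
        assert m.mcc == pytest.approx(mcc, abs=1e-12)
        assert m.ppv == pytest.approx(ppv, abs=1e-12)
        assert m.npv == pytest.approx(npv, abs=1e-12)

    def test_perfect_classifier_all_ones(self):
        t = np.r_[np.full(10, 2.0), np.full(10, 8.0)]
        s = np.r_[np.ones(10), np.zeros(10)]
        out = make_outcomes(t, np.r_[np.ones(10), np.zeros(10)].astype(int))
        m = threshold_metrics(s, out, 5.0)
        for name in ("sensitivity", "specificity", "f1", "accuracy", "mcc", "ppv", "npv"):
            assert getattr(m, name) == pytest.approx(1.0)

    def test_random_classifier_mcc_near_zero(self):
        rng = np.random.default_rng(6)
        mccs = []
        for rep in range(40):
            n = 100
            t = rng.uniform(0, 10, n)
            out = make_outcomes(t, np.ones(n))
            mccs.append(threshold_metrics(rng.normal(size=n), out, 5.0).mcc)
        # Youden optimization inflates |MCC| slightly upward per draw; the
        # average optimism at n=100 stays modest
        assert abs(np.mean(mccs)) < 0.25


class TestWeightedMeans:
    def test_single_timepoint_identity(self):
        m = pd.DataFrame({"sensitivity": [0.77]})
        r = weighted_mean_metrics(m, [0.4])
        assert r["sensitivity"] == pytest.approx(0.77)

    def test_constant_metric_unaffected_by_weights(self):
        m = pd.DataFrame({"x": [0.6, 0.6, 0.6]})
        r = weighted_mean_metrics(m, [0.9, 0.5, 0.1])
        assert r["x"] == pytest.approx(0.6)

    def test_hand_computed_example(self):
        m = pd.DataFrame({"x": [0.8, 0.6]})
        assert weighted_mean_metrics(m, [0.9, 0.3])["x"] == pytest.approx(0.75)

    def test_bounded_by_min_max(self):
        rng = np.random.default_rng(7)
        m = pd.DataFrame({"x": rng.random(6)})
        r = weighted_mean_metrics(m, rng.random(6) + 0.05)["x"]
        assert m["x"].min() - 1e-12 <= r <= m["x"].max() + 1e-12


class TestKmLogrank:
    def test_no_censoring_km_is_empirical_survival(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        out = make_outcomes(t, np.ones(5))
        res = km_logrank(out, ["g1", "g1", "g1", "g2", "g2"])
        km = res["curves"]["g1"]
        assert km.iloc[-1, 0] == pytest.approx(0.0)

    def test_identical_groups_give_null_statistic(self):
        rng = np.random.default_rng(8)
        t = rng.uniform(1, 10, 40)
        e = (rng.random(40) < 0.6).astype(int)
        out = make_outcomes(np.r_[t, t], np.r_[e, e])
        res = km_logrank(out, ["a"] * 40 + ["b"] * 40)
        assert res["statistic"] == pytest.approx(0.0, abs=1e-9)
        assert res["p"] > 0.99

    def test_textbook_two_group_example_matches_hand_calculation(self):
        # groups A: events at 1, 2; B: event at 3, censored at 4
        # hand log-rank: O_A = 2, E_A = 1/2 + 1/3 = 5/6, V = 1/4 + 2/9
        out = make_outcomes([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 0])
        res = km_logrank(out, ["A", "A", "B", "B"])
        O_minus_E = 2 - (0.5 + 1.0 / 3.0)
        V = 0.25 + 2.0 / 9.0
        assert res["statistic"] == pytest.approx(O_minus_E**2 / V, abs=1e-9)


class TestCompetingRisks:
    def test_single_cause_reduces_to_one_minus_km(self):
        rng = np.random.default_rng(9)
        n = 150
        t = rng.uniform(0.5, 10, n)
        e = (rng.random(n) < 0.5).astype(int)
        out = make_outcomes(t, e)  # all kidney
        with pytest.warns(UserWarning, match="single event type"):
            r = competing_risk_cif(out)
        from lifelines import KaplanMeierFitter

        km = KaplanMeierFitter().fit(t, e)
        cif = r["cif_kidney"]
        for tt in (3.0, 6.0):
            ours = cif[cif.index <= tt].iloc[-1, 0]
            assert ours == pytest.approx(1.0 - float(km.predict(tt)), abs=1e-9)

    def test_conservation_of_probability(self):
        rng = np.random.default_rng(10)
        n = 400
        t = rng.uniform(0.2, 10, n)
        e = (rng.random(n) < 0.6).astype(int)
        types = np.where(e == 1, np.where(rng.random(n) < 0.5, "kidney", "death"), "none")
        out = make_outcomes(t, e, types)
        r = competing_risk_cif(out)
        from lifelines import KaplanMeierFitter

        km = KaplanMeierFitter().fit(t, e)
        for tt in (2.0, 5.0, 8.0):
            ck = r["cif_kidney"][r["cif_kidney"].index <= tt].iloc[-1, 0]
            cd = r["cif_death"][r["cif_death"].index <= tt].iloc[-1, 0]
            assert ck + cd + float(km.predict(tt)) == pytest.approx(1.0, abs=1e-9)

    def test_two_cause_exponential_matches_closed_form(self):
        # cause hazards h1=0.10, h2=0.05: CIF_1(t) = h1/(h1+h2) * (1 - e^{-(h1+h2)t})
        rng = np.random.default_rng(11)
        n = 20000
        h1, h2 = 0.10, 0.05
        T = rng.exponential(1.0 / (h1 + h2), n)
        cause = np.where(rng.random(n) < h1 / (h1 + h2), "kidney", "death")
        out = make_outcomes(np.minimum(T, 30.0), (T <= 30.0).astype(int),
                            np.where(T <= 30.0, cause, "none"))
        r = competing_risk_cif(out)
        for tt in (5.0, 10.0):
            expect = h1 / (h1 + h2) * (1.0 - np.exp(-(h1 + h2) * tt))
            got = r["cif_kidney"][r["cif_kidney"].index <= tt].iloc[-1, 0]
            assert got == pytest.approx(expect, abs=0.01)


class TestDecisionCurve:
    def test_treat_none_zero_and_treat_all_limit(self):
        rng = np.random.default_rng(12)
        n = 200
        t = rng.uniform(0, 10, n)
        out = make_outcomes(t, np.ones(n))
        risks = rng.random(n)
        tab = decision_curve(risks, out, [0.0, 0.1, 0.3], t=5.0)
        assert (tab["treat_none"] == 0).all()
        prev = (t <= 5.0).mean()
        assert tab.loc[tab["threshold"] == 0.0, "treat_all"].iloc[0] == pytest.approx(prev)

    def test_hand_computed_toy_table(self):
        # 10 events, 90 non-events, uncensored; fixed risks
        risks = np.r_[np.full(10, 0.9), np.full(90, 0.1)]
        t = np.r_[np.full(10, 1.0), np.full(90, 9.0)]
        out = make_outcomes(t, np.r_[np.ones(10), np.zeros(90)].astype(int))
        tab = decision_curve(risks, out, [0.2], t=5.0)
        # all 10 events above threshold, no false positives
        assert tab["net_benefit"].iloc[0] == pytest.approx(10 / 100)
        assert tab["treat_all"].iloc[0] == pytest.approx(0.1 - 0.9 * 0.25)

    def test_invalid_inputs(self):
        out = make_outcomes([1, 2], [1, 0])
        with pytest.raises(ValueError):
            decision_curve([0.5, 1.5], out, [0.1])
        with pytest.raises(ValueError):
            decision_curve([0.5, 0.5], out, [1.0])


class TestDesignCalculators:
    def test_nnt_arithmetic_and_monotonicity(self):
        assert nnt(1.0, 1.0) == pytest.approx(1.0)
        assert nnt(0.5, 0.27) == pytest.approx(7.41, abs=0.01)
        rates = np.linspace(0.05, 0.95, 10)
        vals = [nnt(r) for r in rates]
        assert np.all(np.diff(vals) < 0)
        with pytest.raises(ValueError):
            nnt(0.0)

    def test_schoenfeld_reproduces_published_design(self):
        spec = SampleSizeSpec(alpha=0.05, power=0.85, hazard_ratio=1.648,
                              marker_positive=0.30, event_rate=0.25)
        assert sample_size(spec)["n"] == 685
        assert achieved_power(685, spec) == pytest.approx(0.85, abs=0.01)

    def test_required_n_decreasing_in_hazard_ratio(self):
        ns = [
            sample_size(SampleSizeSpec(hazard_ratio=hr))["n"]
            for hr in (1.3, 1.648, 2.2, 4.0)
        ]
        assert np.all(np.diff(ns) < 0)

    def test_epv_method(self):
        spec = SampleSizeSpec(epv=15, n_predictors=10, event_rate=0.25)
        r = sample_size(spec, "epv")
        assert r["events"] == 150 and r["n"] == 600

    def test_unit_hazard_ratio_rejected(self):
        with pytest.raises(ValueError):
            SampleSizeSpec(hazard_ratio=1.0)


class TestCorrelationLayout:
    def _corr(self):
        names = ["A", "B", "C", "X"]
        C = pd.DataFrame(np.eye(4), index=names, columns=names)
        C.loc["A", "B"] = C.loc["B", "A"] = 0.9
        C.loc["A", "C"] = C.loc["C", "A"] = 0.2
        C.loc["B", "C"] = C.loc["C", "B"] = 0.1
        C.loc["X", "B"] = C.loc["B", "X"] = 0.7
        return C

    def test_greedy_order_enumeration(self):
        lay = panel_correlation_layout(self._corr(), ["A", "B", "C"])
        assert lay["order"] == ["A", "B", "C"]  # A->B (0.9) then C

    def test_single_correlate_gets_exact_angle(self):
        lay = panel_correlation_layout(self._corr(), ["A", "B", "C"])
        assert lay["other_angles"]["X"] == pytest.approx(lay["panel_angles"]["B"])

    def test_ordering_invariant_under_monotone_weight_rescaling(self):
        C = self._corr()
        C2 = C.copy()
        off = ~np.eye(4, dtype=bool)
        C2.values[off] = np.sign(C.values[off]) * np.abs(C.values[off]) ** 2
        a = panel_correlation_layout(C, ["A", "B", "C"])["order"]
        b = panel_correlation_layout(C2, ["A", "B", "C"])["order"]
        assert a == b

    def test_asymmetric_matrix_rejected(self):
        C = self._corr()
        C.iloc[0, 1] = 0.123
        with pytest.raises(ValueError):
            panel_correlation_layout(C, ["A", "B"])


def test_evaluate_model_report_consistency(small_cohort):
    lp = small_cohort.proteome[small_cohort.truth["signal_proteins"]].to_numpy() @ np.array(
        list(small_cohort.truth["true_betas"].values())
    )
    rep = evaluate_model(lp, small_cohort.outcomes, [2, 4, 6, 8])
    assert 50.0 < rep.tauc <= 100.0
    assert 50.0 < rep.cindex <= 100.0
    for name, val in rep.weighted_means.items():
        col = [getattr(tp, name) for tp in rep.timepoints]
        assert 100.0 * min(col) - 1e-9 <= val <= 100.0 * max(col) + 1e-9
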