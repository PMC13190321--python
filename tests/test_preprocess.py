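"""Preprocessing: missingness filter, chained imputation, CKD-EPI, outcomes, splits."""

import numpy as np
import pandas as pd
import pytest

from aprs.preprocess import (
    ckd_epi_egfr_2021,
    creatinine_from_egfr,
    cross_platform_impute,
    derive_outcome,
    filter_missing,
    impute_chained,
    stratified_split,
)


def _matrix_with_missing(rng, n=60, p=10, planted=None):
    X = pd.DataFrame(rng.standard_normal((n, p)), columns=[f"c{j}" for j in range(p)])
    for col, frac in (planted or {}).items():
        k = int(round(frac * n))
        X.loc[X.index[:k], col] = np.nan
    return X


class TestFilterMissing:
    def test_strictly_more_than_threshold_dropped(self):
        rng = np.random.default_rng(0)
        X = _matrix_with_missing(rng, n=100, planted={"c1": 0.16, "c2": 0.15, "c3": 0.30})
        out, report = filter_missing(X)
        assert "c1" not in out.columns and "c3" not in out.columns
        assert "c2" in out.columns  # exactly at the threshold is retained
        assert report["n_kept"] == 8

    def test_planted_column_count(self):
        rng = np.random.default_rng(1)
        planted = {f"c{j}": 0.5 for j in range(7)}
        X = _matrix_with_missing(rng, n=100, p=100, planted=planted)
        out, report = filter_missing(X)
        assert out.shape[1] == 93

    def test_all_dropped_raises(self):
        X = pd.DataFrame({"a": [np.nan] * 10, "b": [np.nan] * 10})
        with pytest.raises(ValueError):
            filter_missing(X)


class TestImputeChained:
    def test_complete_data_identity(self):
        rng = np.random.default_rng(2)
        X = _matrix_with_missing(rng)
        res = impute_chained(X, seed=1)
        pd.testing.assert_frame_equal(res.first, X)

    def test_observed_values_never_modified_and_beats_mean_imputation(self):
        rng = np.random.default_rng(3)
        n = 200
        z = rng.standard_normal(n)
        X = pd.DataFrame(
            {"a": z + 0.3 * rng.standard_normal(n),
             "b": 0.8 * z + 0.3 * rng.standard_normal(n),
             "c": -0.7 * z + 0.3 * rng.standard_normal(n)}
        )
        truth = X.copy()
        mask = rng.random(n) < 0.2
        X.loc[mask, "a"] = np.nan
        res = impute_chained(X, seed=2)
        done = res.first
        obs = ~mask
        pd.testing.assert_series_equal(done.loc[obs, "a"], truth.loc[obs, "a"])
        rmse = np.sqrt(np.mean((done.loc[mask, "a"] - truth.loc[mask, "a"]) ** 2))
        rmse_mean = np.sqrt(np.mean((X["a"].mean() - truth.loc[mask, "a"]) ** 2))
        assert rmse < rmse_mean

    def test_no_leakage_between_folds(self):
        rng = np.random.default_rng(4)
        train = _matrix_with_missing(rng, planted={"c0": 0.2})
        test = _matrix_with_missing(rng, planted={"c0": 0.2})
        tr1, te1 = impute_chained(train, test, seed=3)
        # perturbing the test fold must not change train imputations
        test2 = test + 100.0
        tr2, _ = impute_chained(train, test2, seed=3)
        pd.testing.assert_frame_equal(tr1.first, tr2.first)

    def test_fully_missing_column_raises(self):
        X = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]})
        with pytest.raises(ValueError):
            impute_chained(X)


class TestCkdEpi:
    def test_matches_hand_evaluated_formula(self):
        # independent hand evaluation of the published 2021 constants
        expected = 142.0 * (0.6 / 0.7) ** (-0.241) * 0.9938**40 * 1.012
        assert ckd_epi_egfr_2021(0.6, 40, "female") == pytest.approx(expected, abs=1e-10)
        expected_m = 142.0 * (1.4 / 0.9) ** (-1.2) * 0.9938**60
        assert ckd_epi_egfr_2021(1.4, 60, "male") == pytest.approx(expected_m, abs=1e-10)

    def test_monotone_in_creatinine_and_age(self):
        scr = np.linspace(0.3, 4.0, 50)
        v = ckd_epi_egfr_2021(scr, np.full(50, 50.0), ["male"] * 50)
        assert np.all(np.diff(v) < 0)
        ages = np.linspace(18, 90, 40)
        v = ckd_epi_egfr_2021(np.full(40, 1.0), ages, ["female"] * 40)
        assert np.all(np.diff(v) < 0)

    def test_inverse_round_trip(self):
        egfr = np.array([15.0, 45.0, 60.0, 90.0, 120.0])
        scr = creatinine_from_egfr(egfr, np.full(5, 55.0), ["female"] * 5)
        back = ckd_epi_egfr_2021(scr, np.full(5, 55.0), ["female"] * 5)
        assert np.allclose(back, egfr, atol=1e-9)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            ckd_epi_egfr_2021(0.0, 40, "male")


class TestDeriveOutcome:
    def _traj(self, sid, pairs):
        return pd.DataFrame(
            [(sid, t, v) for t, v in pairs], columns=["subject_id", "visit_year", "egfr"]
        )

    def test_forty_percent_decline_thresholds(self):
        base = pd.Series({"A": 100.0, "B": 100.0})
        traj = pd.concat([
            self._traj("A", [(2.0, 80.0), (4.0, 59.0)]),   # 41% decline at year 4
            self._traj("B", [(2.0, 70.0), (4.0, 61.0)]),   # never reaches 40%
        ])
        out = derive_outcome(base, traj, None, which="kidney")
        a = out.set_index("subject_id")
        assert a.loc["A", "event"] == 1 and a.loc["A", "time_years"] == 4.0
        assert a.loc["B", "event"] == 0

    def test_death_censors_kidney_and_defines_composite(self):
        base = pd.Series({"A": 100.0})
        rec = pd.DataFrame({"subject_id": ["A"], "event_type": ["death"], "time_years": [3.0]})
        comp = derive_outcome(base, None, rec, which="composite").iloc[0]
        kid = derive_outcome(base, None, rec, which="kidney").iloc[0]
        assert comp["event"] == 1 and comp["time_years"] == 3.0 and comp["event_type"] == "death"
        assert kid["event"] == 0 and kid["time_years"] == 3.0

    def test_composite_is_pointwise_minimum(self):
        rng = np.random.default_rng(5)
        sids = [f"S{i}" for i in range(30)]
        base = pd.Series(100.0, index=sids)
        rec = []
        for s in sids:
            if rng.random() < 0.5:
                rec.append((s, "eskd", rng.uniform(0, 12)))
            if rng.random() < 0.5:
                rec.append((s, "death", rng.uniform(0, 12)))
        rec = pd.DataFrame(rec, columns=["subject_id", "event_type", "time_years"])
        comp = derive_outcome(base, None, rec, which="composite").set_index("subject_id")
        kid = derive_outcome(base, None, rec, which="kidney").set_index("subject_id")
        dth = derive_outcome(base, None, rec, which="death").set_index("subject_id")
        assert np.allclose(
            comp["time_years"], np.minimum(kid["time_years"], dth["time_years"])
        )

    def test_horizon_truncation(self):
        base = pd.Series({"A": 100.0})
        rec = pd.DataFrame({"subject_id": ["A"], "event_type": ["eskd"], "time_years": [11.0]})
        out = derive_outcome(base, None, rec, horizon=10.0).iloc[0]
        assert out["event"] == 0 and out["time_years"] == 10.0


class TestStratifiedSplit:
    def _outcomes(self, n, k_events, seed=0):
        rng = np.random.default_rng(seed)
        e = np.zeros(n, dtype=int)
        e[:k_events] = 1
        return pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(n)],
            "time_years": rng.uniform(1, 10, n),
            "event": e,
            "event_type": np.where(e == 1, "kidney", "none"),
        })

    def test_stratification_arithmetic(self):
        out = self._outcomes(100, 20)
        sp = stratified_split(out, 0.8, seed=1)
        tr = sp[sp.fold == "train"]["subject_id"]
        assert len(tr) == 80
        ev = out.set_index("subject_id").loc[tr, "event"].sum()
        assert abs(ev - 16) <= 1

    def test_seeded_reproducibility(self):
        out = self._outcomes(100, 20)
        pd.testing.assert_frame_equal(stratified_split(out, seed=5), stratified_split(out, seed=5))

    def test_event_rate_balance_across_seeds(self):
        out = self._outcomes(851, 153)  # cohort-sized fixture
        diffs = []
        for seed in range(100):
            sp = stratified_split(out, 0.8, seed=seed).set_index("subject_id")
            merged = out.set_index("subject_id").join(sp)
            rates = merged.groupby("fold")["event"].mean()
            diffs.append(abs(rates["train"] - rates["test"]))
        assert max(diffs) <= 0.02

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            stratified_split(self._outcomes(50, 10), fraction=1.2)


class TestCrossPlatformImpute:
    def test_duplicate_target_recovered_exactly_and_coefficients(self):
        rng = np.random.default_rng(6)
        n = 1000
        x1, x2 = rng.standard_normal(n), rng.standard_normal(n)
        y = 0.7 * x1 - 0.3 * x2 + 0.05 * rng.standard_normal(n)
        source = pd.DataFrame({"x1": x1, "x2": x2, "y": y})
        target = pd.DataFrame({"x1": x1 + 0.0, "x2": x2, "y": np.nan})
        done = cross_platform_impute(source, target, penalty=1e-6)
        r = np.corrcoef(done["y"], y)[0, 1]
        assert r > 0.99
        # recovered linear map close to truth
        coef = np.linalg.lstsq(
            np.c_[done["x1"], done["x2"]], done["y"], rcond=None
        )[0]
        assert np.allclose(coef, [0.7, -0.3], atol=0.1)

    def test_affine_rescaling_applied(self):
        rng = np.random.default_rng(7)
        src = pd.DataFrame({"a": rng.normal(10, 1, 500), "b": rng.normal(0, 1, 500)})
        tgt = pd.DataFrame({"a": (src["a"] - 10) * 3 + 50, "b": np.nan})
        done = cross_platform_impute(src, tgt)
        assert abs(done["a"].median() - src["a"].median()) < 0.1
        assert abs(done["a"].std() - src["a"].std()) < 0.2

    def test_zero_overlap_raises(self):
        src = pd.DataFrame({"a": [1.0, 2.0]})
        tgt = pd.DataFrame({"b": [np.nan, np.nan]})
        with pytest.raises(ValueError):
            cross_platform_impute(src, tgt)
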