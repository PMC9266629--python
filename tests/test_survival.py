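import numpy as np
import pandas as pd
import pytest

import ferroscore as fs
from ferroscore.survival import (
    cox_fit,
    km_estimate,
    logrank_test,
    risk_score,
    roc_auc,
    scan_cutoff,
)


def records(times, events, **cov):
    df = pd.DataFrame({"time": times, "event": events})
    for k, v in cov.items():
        df[k] = v
    df.index = [f"s{i}" for i in range(len(df))]
    return df


def km_at(km, t):
    """Survival just after time t from a (time, survival) step table."""
    rows = km[km["time"] <= t]
    return rows["survival"].iloc[-1] if len(rows) else 1.0


class TestKaplanMeier:
    def test_three_events_hand_product(self):
        km = km_estimate(records([1, 2, 3], [1, 1, 1]))
        assert km_at(km, 1) == pytest.approx(2 / 3)
        assert km_at(km, 2) == pytest.approx(1 / 3)
        assert km_at(km, 3) == pytest.approx(0.0)

    def test_all_censored_flat_one(self):
        km = km_estimate(records([1, 2, 3], [0, 0, 0]))
        assert (km["survival"] == 1.0).all()

    def test_censoring_shrinks_risk_set(self):
        km = km_estimate(records([1, 2, 3], [1, 0, 1]))
        assert km_at(km, 1) == pytest.approx(2 / 3)
        assert km_at(km, 3) == pytest.approx(0.0)  # risk set of 1 at t=3

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(10, size=40).round(1) + 0.1
        km = km_estimate(records(times, np.ones(40, dtype=int)))
        for t in np.quantile(times, [0.25, 0.5, 0.75]):
            assert km_at(km, t) == pytest.approx((times > t).mean(), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            km_estimate(records([], []))


def logrank_oracle(times_a, events_a, times_b, events_b):
    """Step-by-step O-E/V log-rank statistic (hypergeometric variance)."""
    all_times = sorted(
        {t for t, e in zip(list(times_a) + list(times_b),
                           list(events_a) + list(events_b)) if e == 1}
    )
    o_minus_e, var = 0.0, 0.0
    for t in all_times:
        n_a = sum(1 for x in times_a if x >= t)
        n_b = sum(1 for x in times_b if x >= t)
        d_a = sum(1 for x, e in zip(times_a, events_a) if x == t and e == 1)
        d_b = sum(1 for x, e in zip(times_b, events_b) if x == t and e == 1)
        n, d = n_a + n_b, d_a + d_b
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogrank:
    def test_identical_groups_null(self):
        g = records([1, 2, 3, 4], [1, 1, 0, 1])
        chi2, p = logrank_test(g, g.copy())
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_label_swap_symmetry(self):
        a = records([1, 3, 5], [1, 1, 0])
        b = records([2, 4, 6], [1, 0, 1])
        assert logrank_test(a, b)[1] == pytest.approx(logrank_test(b, a)[1])

    def test_four_sample_toy_matches_formula_oracle(self):
        a = records([1, 2], [1, 1])
        b = records([3, 4], [1, 1])
        chi2, _ = logrank_test(a, b)
        want = logrank_oracle([1, 2], [1, 1], [3, 4], [1, 1])
        assert chi2 == pytest.approx(want, abs=1e-10)

    def test_random_cohort_matches_formula_oracle(self):
        rng = np.random.default_rng(8)
        a = records(rng.integers(1, 15, 30), rng.integers(0, 2, 30))
        b = records(rng.integers(1, 15, 25), rng.integers(0, 2, 25))
        chi2, _ = logrank_test(a, b)
        want = logrank_oracle(
            a["time"].tolist(), a["event"].tolist(),
            b["time"].tolist(), b["event"].tolist(),
        )
        assert chi2 == pytest.approx(want, rel=1e-9)

    def test_invariant_under_monotone_time_transform(self):
        rng = np.random.default_rng(4)
        a = records(rng.exponential(5, 20) + 0.1, rng.integers(0, 2, 20))
        b = records(rng.exponential(9, 20) + 0.1, rng.integers(0, 2, 20))
        _, p = logrank_test(a, b)
        a2, b2 = a.copy(), b.copy()
        a2["time"], b2["time"] = np.log1p(a["time"]), np.log1p(b["time"])
        assert logrank_test(a2, b2)[1] == pytest.approx(p)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            logrank_test(records([1], [0]), records([2], [0]))


class TestScanCutoff:
    def _cohort_with_break(self, seed=0, n=120, gap=(1.0, 2.0)):
        """Two sub-populations with a survival break inside a known RFL gap."""
        rng = np.random.default_rng(seed)
        rfl = np.concatenate(
            [rng.uniform(0.2, gap[0], n // 2), rng.uniform(gap[1], 3.0, n // 2)]
        )
        rate = np.where(rfl < gap[0] + 1e-9, 0.2, 0.05)
        times = rng.exponential(1 / rate)
        recs = records(times, np.ones(n, dtype=int))
        return pd.Series(rfl, index=recs.index), recs

    def test_recovers_planted_break(self):
        """The selected cutoff reproduces the planted two-population split
        almost exactly (the break sits in the RFL gap between them)."""
        rfl, recs = self._cohort_with_break()
        res = scan_cutoff(rfl, recs)
        true_high = rfl >= 2.0
        chosen_high = rfl > res.best_cutoff
        agreement = (true_high == chosen_high).mean()
        assert agreement >= 0.95
        assert res.hazard_ratio < 1  # high RFL group has the lower hazard

    def test_minimum_beats_median_split(self):
        rfl, recs = self._cohort_with_break(seed=1)
        res = scan_cutoff(rfl, recs)
        median = float(rfl.median())
        p_med = res.scanned.loc[
            (res.scanned["cutoff"] - median).abs().idxmin(), "p"
        ]
        assert res.best_p <= p_med

    def test_best_p_is_reproduced_by_exhaustive_reevaluation(self):
        rfl, recs = self._cohort_with_break(seed=2)
        res = scan_cutoff(rfl, recs)
        for _, row in res.scanned.iterrows():
            high = rfl > row["cutoff"]
            _, p = logrank_test(recs[high.to_numpy()], recs[~high.to_numpy()])
            assert p == pytest.approx(row["p"], rel=1e-9)
        assert res.best_p == pytest.approx(res.scanned["p"].min())

    def test_constant_rfl_rejected(self):
        recs = records(np.arange(1, 21), np.ones(20, dtype=int))
        with pytest.raises(ValueError):
            scan_cutoff(pd.Series(np.ones(20), index=recs.index), recs)


def cox_loglik_1d(beta, times, events, x):
    """Breslow partial log-likelihood for a single covariate."""
    ll = 0.0
    for t in sorted({t for t, e in zip(times, events) if e == 1}):
        at_risk = [i for i, ti in enumerate(times) if ti >= t]
        deaths = [i for i, (ti, ei) in enumerate(zip(times, events))
                  if ti == t and ei == 1]
        denom = np.log(np.sum(np.exp([beta * x[i] for i in at_risk])))
        for i in deaths:
            ll += beta * x[i] - denom
    return ll


class TestCox:
    def test_two_group_exponential_recovers_log2(self):
        rng = np.random.default_rng(17)
        n = 200
        x = np.repeat([0, 1], n)
        lam = np.where(x == 1, 0.2, 0.1)  # true HR = 2
        recs = records(rng.exponential(1 / lam), np.ones(2 * n, dtype=int), g=x)
        fit = cox_fit(recs, ["g"])
        assert fit.coefficients["g"] == pytest.approx(np.log(2), abs=0.25)

    def test_matches_grid_search_of_partial_likelihood(self):
        rng = np.random.default_rng(2)
        n = 15
        x = rng.normal(size=n)
        times = rng.exponential(1 / np.exp(0.7 * x))
        recs = records(times, np.ones(n, dtype=int), g=x)
        fit = cox_fit(recs, ["g"])
        grid = np.linspace(-2, 3, 2001)
        lls = [cox_loglik_1d(b, times.tolist(), [1] * n, x) for b in grid]
        beta_grid = grid[int(np.argmax(lls))]
        assert fit.coefficients["g"] == pytest.approx(beta_grid, abs=5e-3)

    def test_null_covariate_small_effect(self):
        rng = np.random.default_rng(9)
        ps = []
        for _ in range(5):
            n = 150
            x = rng.normal(size=n)
            recs = records(rng.exponential(5, n), np.ones(n, dtype=int), g=x)
            fit = cox_fit(recs, ["g"])
            assert abs(fit.coefficients["g"]) < 0.5
            ps.append(fit.p_values["g"])
        assert min(ps) > 1e-4  # no spurious strong signal

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError):
            cox_fit(records([1, 2, 3], [0, 0, 0], g=[1.0, 2.0, 3.0]), ["g"])

    def test_constant_covariate_dropped_with_warning(self):
        rng = np.random.default_rng(1)
        recs = records(
            rng.exponential(5, 30), np.ones(30, dtype=int),
            g=rng.normal(size=30), k=np.ones(30),
        )
        with pytest.warns(UserWarning, match="constant"):
            fit = cox_fit(recs, ["g", "k"])
        assert "k" in fit.dropped
        assert list(fit.coefficients.index) == ["g"]

    def test_categorical_one_hot(self):
        rng = np.random.default_rng(6)
        n = 80
        stage = rng.choice(["I", "II", "III"], n)
        recs = records(rng.exponential(5, n), np.ones(n, dtype=int), stage=stage)
        fit = cox_fit(recs, ["stage"])
        assert set(fit.coefficients.index) == {"stage_II", "stage_III"}

    def test_significance_classification_convention(self):
        """HR>1 & P<0.05 reads poor survival, HR<1 & P<0.05 favorable."""
        res = fs.CoxResult(
            coefficients=pd.Series({"a": 0.7, "b": -0.7, "c": 0.01}),
            hazard_ratios=pd.Series({"a": 2.0, "b": 0.5, "c": 1.01}),
            p_values=pd.Series({"a": 0.01, "b": 0.01, "c": 0.8}),
            covariate_centers=pd.Series({"a": 0.0, "b": 0.0, "c": 0.0}),
        )
        assert res.classify().tolist() == ["poor", "favorable", "ns"]


class TestRiskScore:
    def _fit(self):
        rng = np.random.default_rng(21)
        n = 100
        x = rng.normal(size=n)
        recs = records(rng.exponential(1 / np.exp(0.8 * x)),
                       np.ones(n, dtype=int), g=x)
        return cox_fit(recs, ["g"]), recs

    def test_centered_covariates_give_zero(self):
        fit, recs = self._fit()
        X = pd.DataFrame({"g": [fit.covariate_centers["g"]] * 3},
                         index=["a", "b", "c"])
        rm = risk_score(fit, X)
        assert np.allclose(rm.risk_score, 0.0)

    def test_fitting_cohort_mean_zero_and_signs(self):
        fit, recs = self._fit()
        rm = risk_score(fit, recs[["g"]])
        assert rm.risk_score.mean() == pytest.approx(0.0, abs=1e-10)
        assert set(rm.group.unique()) == {"high", "low"}

    def test_unit_coefficient_linear(self):
        fit = fs.CoxResult(
            coefficients=pd.Series({"g": 1.0}),
            hazard_ratios=pd.Series({"g": np.e}),
            p_values=pd.Series({"g": 0.01}),
            covariate_centers=pd.Series({"g": 0.0}),
            design_columns=["g"],
        )
        rm = risk_score(fit, pd.DataFrame({"g": [-1.0, 1.0]}, index=["a", "b"]))
        assert rm.risk_score.tolist() == [-1.0, 1.0]
        assert rm.group.tolist() == ["low", "high"]

    def test_missing_values_rejected(self):
        fit, recs = self._fit()
        X = recs[["g"]].copy()
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            risk_score(fit, X)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0

    def test_constant_score_half(self):
        assert roc_auc([1, 1, 1, 1], [0, 1, 0, 1]) == 0.5

    def test_pair_counting(self):
        # pairs (event, non-event): (2,1)+, (2,3)-, (4,1)+, (4,3)+ -> 3/4
        assert roc_auc([1, 2, 3, 4], [0, 1, 0, 1]) == 0.75

    def test_negation_symmetry(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=30)
        y = rng.integers(0, 2, 30)
        assert roc_auc(s, y) + roc_auc(-s, y) == pytest.approx(1.0)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [1, 1])
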