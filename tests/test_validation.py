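"""Survival statistics: KM, person-time, Harrell's C, Cox, calibration, comparison."""

import math

import numpy as np
import pytest

from hivprognosis.validation import (
    SurvivalDataset,
    calibration_by_group,
    calibration_poisson,
    compare_scores,
    cox_risk_groups,
    harrells_c,
    kaplan_meier,
    person_time_rate,
    subgroup_discrimination,
)

from conftest import random_survival_dataset


def ds_of(time, event, marker=None):
    time = np.asarray(time, float)
    if marker is None:
        marker = np.zeros_like(time)
    return SurvivalDataset(time, np.asarray(event), np.asarray(marker))


# ---------------------------------------------------------------------------
# Kaplan-Meier


class TestKaplanMeier:
    def test_no_events_survival_stays_one(self):
        km = kaplan_meier(ds_of([1, 2, 3], [0, 0, 0]))
        assert km.survival_at(10.0) == 1.0

    def test_hand_computed_product_limit_steps(self):
        km = kaplan_meier(ds_of([2, 3, 4, 5, 6], [1, 0, 1, 1, 0]))
        assert km.survival == pytest.approx([0.8, 0.8 * 2 / 3, 0.8 * 2 / 3 * 0.5], abs=1e-12)
        assert km.survival_at(4.5) == pytest.approx(0.5333, abs=1e-4)
        assert km.survival_at(5.5) == pytest.approx(0.2667, abs=1e-4)

    def test_step_heights_reproduce_d_over_n(self):
        km = kaplan_meier(ds_of([1, 1, 2, 3, 4], [1, 1, 0, 1, 0]))
        surv_prev = np.concatenate([[1.0], km.survival[:-1]])
        np.testing.assert_allclose(km.survival / surv_prev, 1 - km.deaths / km.n_at_risk)

    def test_all_deaths_equal_empirical_survival(self):
        times = [1, 2, 3, 4, 5]
        km = kaplan_meier(ds_of(times, [1] * 5))
        np.testing.assert_allclose(km.survival, [0.8, 0.6, 0.4, 0.2, 0.0], atol=1e-12)

    def test_monotone_nonincreasing_with_valid_ci(self, rng):
        ds = random_survival_dataset(rng, 200)
        km = kaplan_meier(ds)
        assert (np.diff(km.survival) <= 1e-12).all()
        ok = ~np.isnan(km.ci_lower)
        assert ((km.ci_lower[ok] >= 0) & (km.ci_upper[ok] <= 1)).all()

    def test_matches_exponential_within_greenwood_tolerance(self, rng):
        lam, n = 0.3, 4000
        t = rng.exponential(1 / lam, n)
        c = rng.uniform(0, 8, n)
        km = kaplan_meier(ds_of(np.minimum(t, c), (t <= c).astype(int)))
        for q in (1.0, 2.0, 3.0):
            idx = np.searchsorted(km.event_times, q, side="right") - 1
            se = math.sqrt(km.variance[idx])
            assert abs(km.survival[idx] - math.exp(-lam * q)) < 4 * se

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            kaplan_meier(SurvivalDataset(np.array([]), np.array([]), np.array([])))


class TestPersonTime:
    def test_reported_rate_rounds_to_two_decimals(self):
        # 221 deaths / 5598 PY -> 3.95 per 100 PY
        ds = ds_of([5598.0], [0])
        ds.event = np.array([221])  # aggregate check of the arithmetic
        py, deaths, rate = float(ds.time.sum()), int(ds.event.sum()), round(100 * 221 / 5598.0, 2)
        assert rate == 3.95 and py == 5598.0 and deaths == 221

    def test_rate_via_function(self):
        ds = ds_of([2.0, 3.0, 5.0], [1, 0, 1])
        assert person_time_rate(ds) == (10.0, 2, 20.0)

    def test_no_deaths_rate_zero(self):
        assert person_time_rate(ds_of([1.0, 2.0], [0, 0]))[2] == 0.0

    def test_doubling_time_halves_rate(self, rng):
        ds = random_survival_dataset(rng, 50)
        _, _, r1 = person_time_rate(ds)
        ds2 = SurvivalDataset(ds.time * 2, ds.event, ds.marker)
        _, _, r2 = person_time_rate(ds2)
        assert r2 == pytest.approx(r1 / 2, abs=0.01)


# ---------------------------------------------------------------------------
# Harrell's C


def brute_force_c(time, event, marker):
    """O(n^2) pair enumeration, independent of the vectorized implementation."""
    num = den = 0.0
    n = len(time)
    for i in range(n):
        for j in range(n):
            if i == j or not (time[i] < time[j] and event[i] == 1):
                continue
            den += 1
            if marker[i] > marker[j]:
                num += 1
            elif marker[i] == marker[j]:
                num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den


class TestHarrellsC:
    def test_perfect_discrimination(self):
        res = harrells_c(ds_of([1, 2, 3], [1, 1, 1], [3, 2, 1]))
        assert res.c == 1.0 and res.comparable == 3

    def test_identical_markers_give_half(self):
        res = harrells_c(ds_of([1, 2, 3, 4], [1, 1, 1, 0], [5, 5, 5, 5]))
        assert res.c == 0.5 and res.tied_marker == res.comparable

    def test_pair_counts_consistent(self, rng):
        ds = random_survival_dataset(rng, 40)
        res = harrells_c(ds)
        assert res.concordant + res.discordant + res.tied_marker == res.comparable

    def test_matches_brute_force_on_random_fixtures(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 50))
            ds = random_survival_dataset(rng, n)
            try:
                expected = brute_force_c(ds.time, ds.event, ds.marker)
            except ValueError:
                continue
            assert harrells_c(ds).c == pytest.approx(expected, abs=1e-12)

    def test_matches_lifelines_on_tie_free_data(self, rng):
        from lifelines.utils import concordance_index

        t = rng.exponential(3, 300)
        e = (rng.random(300) < 0.6).astype(int)
        m = rng.normal(size=300)
        ours = harrells_c(SurvivalDataset(t, e, m)).c
        # lifelines orients markers toward survival, so negate
        assert ours == pytest.approx(concordance_index(t, -m, e), abs=1e-12)

    def test_reversing_marker_maps_c_to_one_minus_c(self, rng):
        t = rng.exponential(3, 100)
        e = (rng.random(100) < 0.7).astype(int)
        m = rng.normal(size=100)  # tie-free
        c_fwd = harrells_c(SurvivalDataset(t, e, m)).c
        c_rev = harrells_c(SurvivalDataset(t, e, -m)).c
        assert c_fwd + c_rev == pytest.approx(1.0, abs=1e-12)

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError):
            harrells_c(ds_of([1, 2, 3], [0, 0, 1], [1, 2, 3]))  # event only at longest time

    def test_jackknife_ci_contains_point_estimate(self, rng):
        ds = random_survival_dataset(rng, 120)
        res = harrells_c(ds)
        assert res.ci[0] <= res.c <= res.ci[1]
        assert 0 <= res.ci[0] and res.ci[1] <= 1


class TestSubgroups:
    def test_whole_cohort_row_equals_harrells_c(self, rng):
        ds = random_survival_dataset(rng, 80)
        tab = subgroup_discrimination(ds, [])
        assert tab.iloc[0]["c"] == pytest.approx(harrells_c(ds).c)

    def test_partition_levels_match_restricted_oracle(self, rng):
        ds = random_survival_dataset(rng, 80)
        labels = np.where(np.arange(80) % 2 == 0, "a", "b")
        ds.subgroups["parity"] = labels
        tab = subgroup_discrimination(ds, ["parity"]).set_index("level")
        for lev in ("a", "b"):
            sub = ds.restrict(labels == lev)
            expected = brute_force_c(sub.time, sub.event, sub.marker)
            assert tab.loc[lev, "c"] == pytest.approx(expected)

    def test_tiny_subgroup_skipped_with_warning(self, rng):
        ds = random_survival_dataset(rng, 40)
        labels = np.array(["big"] * 39 + ["tiny"])
        ds.subgroups["g"] = labels
        with pytest.warns(UserWarning, match="too few events"):
            tab = subgroup_discrimination(ds, ["g"])
        assert "tiny" not in set(tab["level"])


# ---------------------------------------------------------------------------
# Cox risk groups


def efron_free_loglik(beta, time, event, x):
    """Partial log-likelihood for a binary covariate, distinct event times
    (Efron == Breslow there); independent grid-search oracle."""
    ll = 0.0
    for i in np.where(event == 1)[0]:
        risk = time >= time[i]
        ll += beta * x[i] - math.log(np.sum(np.exp(beta * x[risk])))
    return ll


class TestCox:
    def test_symmetric_groups_give_hr_one(self):
        time = [1, 2, 3, 4, 1, 2, 3, 4]
        event = [1, 0, 1, 0, 1, 0, 1, 0]
        groups = ["a"] * 4 + ["b"] * 4
        fit = cox_risk_groups(SurvivalDataset(np.array(time, float), np.array(event),
                                              np.array(groups, dtype=object)), ["a", "b"])
        assert fit.summary.loc["b", "hr"] == pytest.approx(1.0, abs=1e-6)
        assert fit.summary.loc["a", "hr"] == 1.0  # reference

    def test_eight_subject_fixture_matches_grid_search(self):
        time = np.array([1.0, 3.0, 5.0, 7.0, 2.0, 4.0, 6.0, 8.0])
        event = np.array([1, 0, 1, 0, 1, 1, 0, 1])
        x = np.array([0, 0, 0, 0, 1, 1, 1, 1], float)
        groups = np.where(x == 0, "low", "high").astype(object)
        fit = cox_risk_groups(SurvivalDataset(time, event, groups), ["low", "high"])
        grid = np.arange(-3.0, 3.0, 0.001)
        lls = [efron_free_loglik(b, time, event, x) for b in grid]
        beta_grid = grid[int(np.argmax(lls))]
        beta_fit = fit.summary.loc["high", "coef"]
        assert beta_fit == pytest.approx(beta_grid, abs=2e-3)
        # score is (numerically) zero at the optimum: fit beats every grid point
        assert efron_free_loglik(beta_fit, time, event, x) >= max(lls) - 1e-6

    def test_simulated_hazard_ratio_recovered(self, rng):
        n = 2000
        x = rng.random(n) < 0.5
        lam = np.where(x, 0.3, 0.1)
        t = rng.exponential(1 / lam)
        c = np.full(n, 5.0)
        ds = SurvivalDataset(np.minimum(t, c), (t <= c).astype(int),
                             np.where(x, "exposed", "ref").astype(object))
        fit = cox_risk_groups(ds, ["ref", "exposed"])
        row = fit.summary.loc["exposed"]
        assert row["hr_ci_lower"] < 3.0 < row["hr_ci_upper"]

    def test_group_without_events_flagged_unstable(self):
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.array([1, 1, 1, 0, 0, 0])
        groups = np.array(["a", "a", "a", "b", "b", "b"], dtype=object)
        with pytest.warns(UserWarning, match="unstable"):
            fit = cox_risk_groups(SurvivalDataset(time, event, groups), ["a", "b"])
        assert fit.summary.loc["b", "unstable"]


# ---------------------------------------------------------------------------
# Calibration


class TestCalibration:
    def test_intercept_closed_form_zero_when_sums_match(self):
        # d=(1,0,1), H=(0.5,0.5,1.0): alpha = log(2/2) = 0
        event = np.array([1, 0, 1])
        h = np.array([0.5, 0.5, 1.0])
        res = calibration_poisson(np.ones(3), event, np.log(h), np.ones(3))
        assert res.intercept == pytest.approx(0.0, abs=1e-8)

    def test_intercept_closed_form_general(self, rng):
        event = (rng.random(200) < 0.3).astype(int)
        h = rng.uniform(0.05, 0.5, 200)
        res = calibration_poisson(np.ones(200), event, np.log(h), np.ones(200))
        assert res.intercept == pytest.approx(math.log(event.sum() / h.sum()), abs=1e-6)

    def test_self_consistent_data_recover_alpha0_beta1(self, rng):
        n = 4000
        r0 = 0.05
        pi = rng.normal(0.0, 0.8, n)
        t_death = rng.exponential(1.0 / (r0 * np.exp(pi)))
        censor = rng.uniform(1.0, 5.0, n)
        t = np.minimum(t_death, censor)
        d = (t_death <= censor).astype(int)
        res = calibration_poisson(t, d, pi, r0 * t)
        assert res.intercept == pytest.approx(0.0, abs=0.1)
        assert res.slope == pytest.approx(1.0, abs=0.1)
        assert res.slope_ci[0] < 1.0 < res.slope_ci[1]

    def test_doubled_hazard_shifts_intercept_minus_log2(self, rng):
        n = 4000
        r0 = 0.08
        pi = rng.normal(0.0, 0.5, n)
        t_death = rng.exponential(1.0 / (r0 * np.exp(pi)))
        t = np.minimum(t_death, 5.0)
        d = (t_death <= 5.0).astype(int)
        res = calibration_poisson(t, d, pi, 2 * r0 * t)  # predictions twice too hazardous
        assert res.intercept == pytest.approx(-math.log(2), abs=0.1)

    def test_nonpositive_baseline_hazard_rejected(self):
        with pytest.raises(ValueError):
            calibration_poisson(np.ones(2), np.array([1, 0]), np.zeros(2), np.array([0.5, 0.0]))


class TestCalibrationByGroup:
    def test_printed_example_five_point_gap(self):
        # predicted 0.90 vs observed 0.85 -> 5 percentage points
        assert 0.90 - 0.85 == pytest.approx(0.05)

    def test_groups_simulated_from_predictions_agree(self, rng):
        n = 6000
        pred = {"low": 0.95, "very_high": 0.53}
        groups = np.where(rng.random(n) < 0.5, "low", "very_high")
        lam = np.where(groups == "low", -math.log(0.95) / 5, -math.log(0.53) / 5)
        t_death = rng.exponential(1 / lam)
        t = np.minimum(t_death, 5.0)
        d = (t_death <= 5.0).astype(int)
        tab = calibration_by_group(SurvivalDataset(t, d, groups.astype(object)), pred)
        assert (tab["abs_difference"] < 0.03).all()

    def test_all_censored_group_observed_one(self):
        ds = SurvivalDataset(np.array([1.0, 2.0, 3.0, 4.0]), np.array([0, 0, 1, 1]),
                             np.array(["a", "a", "b", "b"], dtype=object))
        tab = calibration_by_group(ds, {"a": 0.9, "b": 0.8}).set_index("group")
        assert tab.loc["a", "observed"] == 1.0

    def test_empty_group_omitted_with_warning(self):
        ds = SurvivalDataset(np.array([1.0, 2.0]), np.array([1, 1]),
                             np.array(["a", "a"], dtype=object))
        with pytest.warns(UserWarning, match="no subjects"):
            tab = calibration_by_group(ds, {"a": 0.9, "ghost": 0.5})
        assert list(tab["group"]) == ["a"]


# ---------------------------------------------------------------------------
# Score comparison


class TestCompareScores:
    def test_identical_scores_give_identical_c(self, rng):
        ds = random_survival_dataset(rng, 100)
        ok = rng.random(100) < 0.8
        res = compare_scores(ds.time, ds.event, ds.marker, ds.marker, ok, ok)
        assert res["c_a"] == res["c_b"]

    def test_nested_computability_restricts_to_smaller_set(self, rng):
        ds = random_survival_dataset(rng, 100)
        ok_a = np.ones(100, bool)
        ok_b = rng.random(100) < 0.5
        res = compare_scores(ds.time, ds.event, ds.marker, ds.marker, ok_a, ok_b)
        assert res["n_common"] == int(ok_b.sum())

    def test_common_subset_matches_restricted_oracle(self, rng):
        ds = random_survival_dataset(rng, 60)
        mb = rng.integers(0, 5, 60).astype(float)
        ok_a = rng.random(60) < 0.9
        ok_b = rng.random(60) < 0.9
        res = compare_scores(ds.time, ds.event, ds.marker, mb, ok_a, ok_b)
        common = ok_a & ok_b
        assert res["c_a"] == pytest.approx(
            brute_force_c(ds.time[common], ds.event[common], ds.marker[common]))
        assert res["c_b"] == pytest.approx(
            brute_force_c(ds.time[common], ds.event[common], mb[common]))

    def test_empty_intersection_rejected(self, rng):
        ds = random_survival_dataset(rng, 10)
        with pytest.raises(ValueError):
            compare_scores(ds.time, ds.event, ds.marker, ds.marker,
                           np.zeros(10, bool), np.ones(10, bool))
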