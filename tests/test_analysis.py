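"""Statistical pipeline: exclusions, fits, inference, power."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import stats

from amprobe.analysis import (
    apply_exclusions,
    cohens_d_from_summary,
    compare_models,
    correlate,
    fit_linear,
    fit_logistic,
    fit_participants,
    one_sample_slope_test,
    power_one_sample_t,
    power_required_n,
    reconcile_exclusion_counts,
    split_group_welch,
)
from amprobe.analysis import PsychometricFit


def _responses_frame(pid, x, y, probe_correct=12, probe_total=12, task="judgment"):
    rows = [
        {"participant_id": pid, "kind": "testing", "task": task, "x_value": xi, "response": yi,
         "probe_correct": np.nan}
        for xi, yi in zip(x, y)
    ]
    rows += [
        {"participant_id": pid, "kind": "probe", "task": "probe", "x_value": np.nan,
         "response": np.nan, "probe_correct": i < probe_correct}
        for i in range(probe_total)
    ]
    return pd.DataFrame(rows)


class TestExclusions:
    def _participants(self, pids, **flags):
        return pd.DataFrame(
            {
                "participant_id": pids,
                "completed": flags.get("completed", [True] * len(pids)),
                "headphone_pass": flags.get("headphone_pass", [True] * len(pids)),
                "msi_general": 80.0,
            }
        )

    def test_constant_responder_excluded_under_all_same(self, rng):
        x = np.tile([1.0, 2.0, 3.0], 20)
        good = _responses_frame("good", x, rng.integers(0, 2, len(x)))
        const = _responses_frame("const", x, np.ones(len(x)))
        resp = pd.concat([good, const], ignore_index=True)
        included, ledger = apply_exclusions(resp, self._participants(["good", "const"]))
        assert included == ["good"]
        assert ledger["all_same"] == 1

    def test_probe_accuracy_threshold(self, rng):
        x = np.tile([1.0, 2.0, 3.0], 20)
        fail = _responses_frame("fail", x, rng.integers(0, 2, len(x)), probe_correct=10)  # 83.3%
        keep = _responses_frame("keep", x, rng.integers(0, 2, len(x)), probe_correct=11)  # 91.7%
        resp = pd.concat([fail, keep], ignore_index=True)
        included, ledger = apply_exclusions(resp, self._participants(["fail", "keep"]))
        assert included == ["keep"]
        assert ledger["probe_accuracy"] == 1

    def test_detection_task_bias_rule(self, rng):
        x = np.tile([1.0, 2.0, 3.0, 4.0, 5.0], 30)
        y_biased = (rng.random(len(x)) < 0.7).astype(int)  # 70% response rate
        while not 0.66 < y_biased.mean():
            y_biased = (rng.random(len(x)) < 0.75).astype(int)
        y_ok = (rng.random(len(x)) < 0.5).astype(int)
        biased = pd.concat(
            [_responses_frame("biased", x, y_biased, task="music"),
             _responses_frame("biased", x, y_ok, task="speech").iloc[:len(x)]],
            ignore_index=True,
        )
        fair = pd.concat(
            [_responses_frame("fair", x, y_ok, task="music"),
             _responses_frame("fair", x, y_ok, task="speech").iloc[:len(x)]],
            ignore_index=True,
        )
        resp = pd.concat([biased, fair], ignore_index=True)
        included, ledger = apply_exclusions(resp, self._participants(["biased", "fair"]))
        assert included == ["fair"]
        assert ledger["response_bias"] == 1

    def test_bias_rule_not_applied_to_judgment_task(self, rng):
        x = np.tile([1.0, 2.0, 3.0], 20)
        y = (rng.random(len(x)) < 0.8).astype(int)
        resp = _responses_frame("p", x, y)
        included, _ = apply_exclusions(resp, self._participants(["p"]))
        assert included == ["p"]

    def test_completion_and_headphone_precede_other_criteria(self, rng):
        x = np.tile([1.0, 2.0], 10)
        resp = _responses_frame("p", x, np.ones(len(x)))  # would also be all-same
        parts = self._participants(["p"], completed=[False])
        _, ledger = apply_exclusions(resp, parts)
        assert ledger["incomplete"] == 1 and ledger["all_same"] == 0

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            apply_exclusions(pd.DataFrame({"participant_id": []}), pd.DataFrame({"participant_id": []}))


class TestReconcileCounts:
    def test_published_accounting(self):
        assert reconcile_exclusion_counts(488, [41, 19, 31, 23, 16, 23]) == 335

    def test_zero_exclusions(self):
        assert reconcile_exclusion_counts(100, []) == 100

    def test_negative_result_rejected(self):
        with pytest.raises(ValueError):
            reconcile_exclusion_counts(10, [20])


class TestFitLinear:
    def test_closed_form_three_points(self):
        slope, intercept, r2 = fit_linear([1, 2, 3], [0, 1, 1])
        assert slope == pytest.approx(0.5)
        assert intercept == pytest.approx(-1.0 / 3.0)
        assert r2 == pytest.approx(0.75)

    def test_constant_responses_convention(self):
        slope, intercept, r2 = fit_linear([1, 2, 3], [1, 1, 1])
        assert slope == 0.0 and intercept == 1.0 and r2 == 0.0

    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            fit_linear([2, 2, 2], [0, 1, 0])

    def test_trial_level_equals_level_mean_slope_when_balanced(self, rng):
        levels = np.geomspace(0.6, 6.0, 10)
        x = np.tile(levels, 30)
        y = (rng.random(len(x)) < np.clip(0.3 + 0.08 * x, 0, 1)).astype(float)
        slope_trial, _, _ = fit_linear(x, y)
        means = [y[x == lv].mean() for lv in levels]
        slope_level = stats.linregress(levels, means).slope
        assert abs(slope_trial - slope_level) < 1e-10


class TestFitLogistic:
    def test_noiseless_recovery(self):
        x = np.tile(np.linspace(0.5, 4.0, 10), 20)
        y = 1.0 / (1.0 + np.exp(-3.0 * (x - 2.0)))
        a, s, r2, ok = fit_logistic(x, y, level_bounds=(0.5, 4.0))
        assert ok
        assert a == pytest.approx(2.0, abs=1e-3)
        assert s == pytest.approx(3.0, abs=1e-3)
        assert r2 == pytest.approx(1.0, abs=1e-6)

    def test_flat_data_zero_r2(self):
        x = np.tile([1.0, 2.0, 3.0, 4.0], 5)
        y = np.full_like(x, 0.5)
        *_, r2, _ = fit_logistic(x, y, level_bounds=(1.0, 4.0))
        assert r2 == pytest.approx(0.0, abs=1e-9)

    def test_midpoint_respects_bounds(self, rng):
        # all-one responses push the midpoint off to the left; the bound holds it
        x = np.tile(np.linspace(0.6, 6.0, 10), 5)
        y = np.ones_like(x)
        a, _, _, _ = fit_logistic(x, y, level_bounds=(0.6, 6.0))
        assert 0.6 <= a <= 6.0

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic([1, 2, 1, 2], [0, 1, 0, 1], (1, 2))


class TestCompareModels:
    @staticmethod
    def _fit(pid, r2_lin, r2_log):
        return PsychometricFit(pid, slope=0.1, intercept=0.0, r2_lin=r2_lin, r2_log=r2_log)

    def test_identical_r2_gives_zero(self):
        fits = [self._fit(f"p{i}", 0.5, 0.5) for i in range(5)]
        assert compare_models(fits) == 0.0

    def test_constant_offset(self):
        fits = [self._fit(f"p{i}", 0.4 + 0.19, 0.4) for i in range(5)]
        assert compare_models(fits) == pytest.approx(0.19)

    def test_linear_generative_data_favours_linear_model(self, rng):
        """A population with realistic bias spread defeats the bounded
        logistic (it must cross 50% inside the stimulus range) but not the
        line, so the mean R^2 difference comes out positive."""
        levels = np.geomspace(0.6, 6.0, 10)
        x = np.tile(levels, 30)
        frames = []
        for i in range(100):
            beta = rng.normal(0.05, 0.07)
            alpha = np.clip(rng.normal(0.5, 0.12), 0.05, 0.95)
            lapse = rng.uniform(0, 0.1)
            p = np.clip(alpha + beta * (x - x.mean()), 0, 1)
            p = lapse / 2 + (1 - lapse) * p
            y = (rng.random(len(x)) < p).astype(int)
            frames.append(_responses_frame(f"p{i:02d}", x, y))
        fits = fit_participants(pd.concat(frames, ignore_index=True))
        assert compare_models(fits) > 0


class TestGroupInference:
    def test_one_sample_t_hand_computed(self):
        res = one_sample_slope_test([0.1, 0.2, 0.3])
        assert res["t"] == pytest.approx(2 * math.sqrt(3), rel=1e-6)
        assert res["df"] == 2
        assert res["d"] == pytest.approx(2.0)

    def test_symmetric_slopes_null(self):
        res = one_sample_slope_test([-0.2, -0.1, 0.1, 0.2])
        assert res["t"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_perfect_self_correlation(self, rng):
        x = rng.standard_normal(20)
        assert correlate(x, x.copy())["r"] == pytest.approx(1.0)

    def test_pearson_hand_computed(self):
        res = correlate([1, 2, 3], [2, 1, 3])
        assert res["r"] == pytest.approx(0.5)
        assert res["df"] == 1

    def test_outlier_reported_both_ways(self, rng):
        x = np.linspace(0, 1, 40)
        y = 2 * x + rng.normal(0, 0.05, 40)
        y[7] += 3.0  # gross outlier
        res = correlate(x, y)
        assert res["n_outliers"] >= 1
        assert res["r_no_outlier"] > res["r"]
        assert res["df_no_outlier"] == res["df"] - res["n_outliers"]

    def test_welch_hand_computed(self):
        res = split_group_welch(
            slopes=np.array([-1, -1, -1, 1, 1, 1]),
            covariate=np.array([0, 1, 2, 1, 2, 3]),
        )
        assert res["t"] == pytest.approx(math.sqrt(1.5), rel=1e-9)  # 1 / sqrt(2/3)
        assert res["df"] == pytest.approx(4.0, rel=1e-9)
        assert res["d"] == pytest.approx(1.0)

    def test_identical_groups_null(self):
        res = split_group_welch(
            slopes=np.array([-1, -1, 1, 1]), covariate=np.array([1.0, 2.0, 1.0, 2.0])
        )
        assert res["t"] == pytest.approx(0.0, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            split_group_welch(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]))


class TestDefinitionalFormulas:
    """Inference outputs must match brute-force evaluation of the textbook
    formulas on arbitrary small samples."""

    @given(
        x=hnp.arrays(
            float, st.integers(5, 30),
            elements=st.floats(-10, 10, allow_nan=False, width=32),
        )
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_one_sample_t(self, x):
        sd = x.std(ddof=1)
        if sd < 1e-6:
            return
        res = one_sample_slope_test(x)
        t_manual = x.mean() / (sd / math.sqrt(len(x)))
        p_manual = 2 * stats.t.sf(abs(t_manual), len(x) - 1)
        assert res["t"] == pytest.approx(t_manual, rel=1e-9)
        assert res["p"] == pytest.approx(p_manual, rel=1e-9)
        assert res["d"] == pytest.approx(x.mean() / sd, rel=1e-9)

    @given(
        data=st.lists(
            st.tuples(st.floats(-5, 5, width=32), st.floats(-5, 5, width=32)),
            min_size=4, max_size=25,
        )
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_pearson(self, data):
        x = np.array([a for a, _ in data])
        y = np.array([b for _, b in data])
        if x.std() < 1e-6 or y.std() < 1e-6:
            return
        r_manual = np.sum((x - x.mean()) * (y - y.mean())) / math.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert correlate(x, y)["r"] == pytest.approx(r_manual, rel=1e-6, abs=1e-9)

    @given(
        a=hnp.arrays(float, st.integers(3, 15), elements=st.floats(-5, 5, width=32)),
        b=hnp.arrays(float, st.integers(3, 15), elements=st.floats(-5, 5, width=32)),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_welch(self, a, b):
        if a.var(ddof=1) < 1e-6 or b.var(ddof=1) < 1e-6:
            return
        slopes = np.concatenate([np.ones_like(a), -np.ones_like(b)])
        cov = np.concatenate([a, b])
        res = split_group_welch(slopes, cov)
        se = math.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
        assert res["t"] == pytest.approx((a.mean() - b.mean()) / se, rel=1e-9)


class TestPower:
    def test_noncentral_t_solutions_near_published_plan(self):
        assert abs(power_required_n(0.68, alpha=0.05, power=0.8) - 20) <= 1
        assert abs(power_required_n(0.68, alpha=0.01, power=0.9) - 36) <= 1

    def test_threshold_bracketing_against_monte_carlo(self, rng):
        """power(n) >= target > power(n-1), confirmed by simulation."""
        d, alpha, target = 0.68, 0.05, 0.8
        n = power_required_n(d, alpha, target)
        assert power_one_sample_t(n, d, alpha) >= target > power_one_sample_t(n - 1, d, alpha)

        def mc_power(nn, reps=100_000):
            x = rng.normal(d, 1.0, size=(reps, nn))
            t = x.mean(axis=1) / (x.std(axis=1, ddof=1) / math.sqrt(nn))
            crit = stats.t.ppf(1 - alpha / 2, nn - 1)
            return (np.abs(t) > crit).mean()

        se = math.sqrt(0.8 * 0.2 / 100_000)
        assert mc_power(n) >= target - 4 * se
        assert mc_power(n - 1) < target + 4 * se

    def test_monotonicity(self):
        assert power_required_n(0.5, 0.05, 0.8) >= power_required_n(0.8, 0.05, 0.8)
        assert power_required_n(0.68, 0.01, 0.8) >= power_required_n(0.68, 0.05, 0.8)
        assert power_required_n(0.68, 0.05, 0.9) >= power_required_n(0.68, 0.05, 0.8)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            power_required_n(-0.1, 0.05, 0.8)
        with pytest.raises(ValueError):
            power_required_n(0.5, 1.5, 0.8)


class TestCohensD:
    def test_norm_comparison(self):
        assert round(cohens_d_from_summary(81.58, 71.39, 20.62), 2) == 0.49

    def test_equal_means(self):
        assert cohens_d_from_summary(5.0, 5.0, 1.0) == 0.0

    def test_simple_ratio(self):
        assert cohens_d_from_summary(2.0, 1.0, 0.5) == 2.0

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            cohens_d_from_summary(1.0, 2.0, 0.0)


class TestGroupedFits:
    def test_one_slope_per_participant_and_group(self, rng):
        """Regressing on sigma separately under each peak frequency gives
        participants x peaks fits."""
        sigmas = np.geomspace(0.1, 1.0, 5)
        peaks = [1.0, 2.5, 4.0]
        frames = []
        for i in range(4):
            rows = []
            for m in peaks:
                for s in np.tile(sigmas, 10):
                    p = np.clip(0.5 + 0.5 * (s - 0.5), 0, 1)
                    rows.append(
                        {"participant_id": f"p{i}", "kind": "testing", "task": "judgment",
                         "m_hz": m, "x_value": s, "response": int(rng.random() < p),
                         "probe_correct": np.nan}
                    )
            frames.append(pd.DataFrame(rows))
        fits = fit_participants(pd.concat(frames, ignore_index=True), group_by="m_hz", with_logistic=False)
        assert len(fits) == 4 * 3
        assert {f.group for f in fits} == set(peaks)
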