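"""Backward curves and the constrained logistic-growth fitter."""

import numpy as np
import pytest

from xorvision import (
    LogisticGrowthCurve,
    Protocol,
    RandomStrategy,
    SymmetryOracleStrategy,
    TrialRecord,
    backward_curve,
    fit_linear,
    fit_logistic,
    logistic_growth,
    model_selection_report,
    simulate_cohort,
    nonlinear_task,
    terminal_curve,
)
from xorvision.behavior_sim import SimulatedSubject
from xorvision.learning_curves import BackwardCurve, species_bounds, species_start


def _subject_from_outcomes(outcomes, subject=0):
    recs = [TrialRecord(subject, 0, i + 1, "p", "left", "left" if ok else "right",
                        bool(ok), correction_trial=False) for i, ok in enumerate(outcomes)]
    return SimulatedSubject(subject, recs, True, None, [])


class TestBackwardCurve:
    def test_oracle_cohort_gives_flat_unit_curve(self):
        proto = Protocol.human()
        cohort = simulate_cohort(lambda: SymmetryOracleStrategy(), nonlinear_task,
                                 proto, 3, seed=0)
        curve = backward_curve(cohort, proto)
        np.testing.assert_allclose(curve.y, 1.0)
        np.testing.assert_allclose(curve.se, 0.0)
        assert curve.n_subjects == 3
        assert len(curve.x) == 20

    def test_single_subject_curve_is_their_series_with_zero_se(self):
        outcomes = [True] * 30
        subj = _subject_from_outcomes(outcomes)
        curve = backward_curve([subj], Protocol.human())
        assert curve.n_subjects == 1
        np.testing.assert_allclose(curve.se, 0.0)
        np.testing.assert_allclose(curve.y, 1.0)

    def test_non_learners_are_excluded_with_warning(self):
        proto = Protocol.human(max_trials=60)
        good = _subject_from_outcomes([True] * 40)
        bad = _subject_from_outcomes([True, False] * 30, subject=1)
        with pytest.warns(UserWarning):
            curve = backward_curve([good, bad], proto)
        assert curve.n_subjects == 1
        assert curve.n_excluded == 1

    def test_all_non_learners_is_an_error(self):
        bad = _subject_from_outcomes([True, False] * 30)
        with pytest.raises(ValueError):
            backward_curve([bad], Protocol.human())

    def test_curve_tracks_generating_accuracy_within_sampling_error(self):
        """Monte-Carlo: steep logistic learners, curve vs generating p(t)."""
        rng = np.random.default_rng(7)
        L, k, x0 = 0.8, 0.8, 25.0
        t = np.arange(1, 81)
        p = np.clip(logistic_growth(t, L, k, x0), 0, 1)
        proto = Protocol.human(max_trials=80)
        subjects, crits = [], []
        for s in range(30):
            outcomes = rng.random(80) < p
            subj = _subject_from_outcomes(outcomes, subject=s)
            from xorvision import apply_criterion
            crit = apply_criterion(subj.frame(), proto)
            if crit is not None and crit >= 20:
                subjects.append(subj)
                crits.append(crit)
        assert len(subjects) >= 20
        curve = backward_curve(subjects, proto)
        for j in range(20):
            expected = np.mean([p[c - 20 + j] for c in crits])
            se = max(np.sqrt(expected * (1 - expected) / len(subjects)), 1e-3)
            assert abs(curve.y[j] - expected) <= 3 * se + 0.05


class TestLogisticFit:
    def test_noiseless_parameters_recovered_exactly(self):
        x = np.arange(1, 10, dtype=float)
        y = logistic_growth(x, 0.68, 0.68, 6.65)
        fit = fit_logistic((x, y), species="rat")
        assert abs(fit.L - 0.68) <= 1e-3
        assert abs(fit.k - 0.68) <= 1e-3
        assert abs(fit.x0 - 6.65) <= 1e-3
        assert fit.sse <= 1e-10
        assert fit.converged

    def test_constant_baseline_curve_drives_asymptote_to_zero(self):
        x = np.arange(1, 21, dtype=float)
        y = np.full_like(x, 0.55)
        fit = fit_logistic((x, y), species="human")
        assert fit.L == pytest.approx(0.0, abs=1e-3)
        assert fit.sse == pytest.approx(0.0, abs=1e-8)

    def test_perturbed_starts_reach_same_optimum(self):
        x = np.arange(1, 21, dtype=float)
        y = logistic_growth(x, 0.54, 0.27, 2.68)
        ref = fit_logistic((x, y), species="human")
        for start in [(0.2, 0.1, 5.0), (0.9, 0.8, 15.0), (0.5, -0.5, 1.0)]:
            alt = fit_logistic((x, y), start=start, species="human")
            assert abs(alt.L - ref.L) <= 1e-3
            assert abs(alt.k - ref.k) <= 1e-3
            assert abs(alt.x0 - ref.x0) <= 1e-3

    def test_fitted_parameters_respect_bounds(self):
        rng = np.random.default_rng(11)
        x = np.arange(1, 21, dtype=float)
        lo, hi = species_bounds("human")
        for _ in range(20):
            y = np.clip(rng.normal(0.7, 0.15, size=x.size), 0, 1)
            fit = fit_logistic((x, y), species="human")
            for val, a, b in zip((fit.L, fit.k, fit.x0), lo, hi):
                assert a - 1e-9 <= val <= b + 1e-9

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic((np.arange(3.0), np.ones(3)))

    def test_inverted_bounds_rejected(self):
        est = LogisticGrowthCurve(bounds=((0, 1, 0), (1, -1, 20)))
        with pytest.raises(ValueError):
            est.fit(np.arange(1, 10.0), np.ones(9) * 0.6)

    def test_model_prediction_stays_in_unit_interval(self):
        x = np.linspace(-5, 40, 200)
        for L in (0.0, 0.4, 0.8):
            y = logistic_growth(x, L, 0.5, 10.0)
            assert (y >= 0).all() and (y <= 0.55 * (1 + L) + 1e-12).all()


class TestLinearFit:
    def test_flat_curve(self):
        x = np.arange(1, 10, dtype=float)
        fit = fit_linear((x, np.full(9, 0.5)))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.5)

    def test_exact_line_recovered(self):
        x = np.arange(1, 10, dtype=float)
        fit = fit_linear((x, 0.01 * x + 0.5))
        assert fit.slope == pytest.approx(0.01, abs=1e-12)
        assert fit.sse == pytest.approx(0.0, abs=1e-15)

    def test_chance_level_cohort_has_flat_slope(self):
        proto = Protocol.rat(session_size=48, max_sessions=12)
        cohort = simulate_cohort(lambda: RandomStrategy(), nonlinear_task, proto,
                                 5, seed=3)
        curve = terminal_curve(cohort, proto)
        fit = fit_linear(curve)
        # slope of a chance curve: within 3 SE of zero (binomial noise on 48 trials)
        se_point = 0.5 / np.sqrt(48 * 5)
        se_slope = se_point / np.sqrt(np.sum((curve.x - curve.x.mean()) ** 2))
        assert abs(fit.slope) <= 3 * se_slope


class TestModelSelectionReport:
    def test_empty_input_gives_empty_report(self):
        report = model_selection_report({})
        assert report.empty

    def test_learners_get_logistic_and_non_learners_linear(self):
        x = np.arange(1, 21, dtype=float)
        learner = BackwardCurve(x, logistic_growth(x, 0.8, 0.5, 10), np.zeros(20), 5, "trial")
        flat = BackwardCurve(x, np.full(20, 0.5), np.zeros(20), 5, "trial", aligned=False)
        report = model_selection_report({"a": (learner, "human"), "b": (flat, "human")})
        assert list(report["model"]) == ["logistic", "linear"]

    def test_fast_learners_have_larger_k_and_smaller_x0(self):
        x = np.arange(1, 21, dtype=float)
        fast = BackwardCurve(x, logistic_growth(x, 0.8, 0.8, 5), np.zeros(20), 5, "trial")
        slow = BackwardCurve(x, logistic_growth(x, 0.8, 0.2, 14), np.zeros(20), 5, "trial")
        report = model_selection_report(
            {"fast": (fast, "human"), "slow": (slow, "human")}).set_index("cohort")
        assert report.loc["fast", "k"] > report.loc["slow", "k"]
        assert report.loc["fast", "x0"] < report.loc["slow", "x0"]

    def test_oracle_cohort_hits_asymptote_immediately(self):
        proto = Protocol.human()
        cohort = simulate_cohort(lambda: SymmetryOracleStrategy(), nonlinear_task,
                                 proto, 3, seed=0)
        curve = backward_curve(cohort, proto)
        fit = fit_logistic(curve, species="human")
        assert fit.predict(curve.x[-1]) > 0.95
        assert fit.x0 <= 2.0
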