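"""Template models, per-pair binomial statistics, transfer analysis."""

import numpy as np
import pandas as pd
import pytest

from xorvision import (
    Protocol,
    RegionExemplarStrategy,
    StimulusPair,
    SymmetryOracleStrategy,
    TemplateModel,
    build_manipulated_pairs,
    chance_interval,
    default_cohort_strategy,
    experiment_a_stages,
    linear_task,
    nonlinear_task,
    per_pair_performance,
    prediction_matrix,
    prediction_performance_correlation,
    simulate_cohort,
    simulate_subject,
    template_prediction,
    transfer_analysis,
)
from xorvision.stimuli import StimulusConfig


@pytest.fixture(scope="module")
def pairs32():
    return build_manipulated_pairs(linear_task)


@pytest.fixture(scope="module")
def top_only_pair():
    """A pair differing exclusively in the upper field (left arm top vs none)."""
    return StimulusPair(StimulusConfig("top", "top"), StimulusConfig("none", "top"))


class TestTemplatePrediction:
    def test_lower_field_model_predicts_chance_for_top_difference(
            self, top_only_pair, geometry):
        pred = template_prediction(TemplateModel("lower_field"), top_only_pair, geometry)
        assert pred.predicted == 0.5

    def test_upper_field_model_predicts_discrimination_for_top_difference(
            self, top_only_pair, geometry):
        pred = template_prediction(TemplateModel("upper_field"), top_only_pair, geometry)
        assert pred.predicted == 1.0

    def test_identical_pair_is_chance_for_every_model(self, geometry):
        cfg = StimulusConfig("top", "bottom")
        pair = StimulusPair(cfg, cfg)
        for kind in ("full", "upper_field", "lower_field"):
            assert template_prediction(TemplateModel(kind), pair, geometry).predicted == 0.5

    def test_graded_mode_scales_with_in_region_difference(self, geometry):
        small = StimulusPair(StimulusConfig("top", "top"), StimulusConfig("none", "top"))
        large = StimulusPair(StimulusConfig("top", "top"), StimulusConfig("none", "none"))
        m = TemplateModel("upper_field")
        p_small = template_prediction(m, small, geometry, mode="graded").predicted
        p_large = template_prediction(m, large, geometry, mode="graded").predicted
        assert 0.5 < p_small < p_large <= 1.0

    def test_region_decomposition_determines_full_model(self, pairs32, geometry):
        """full = 1.0 iff either half differs (binary mode)."""
        preds = prediction_matrix(
            [TemplateModel("full"), TemplateModel("upper_field"),
             TemplateModel("lower_field")], pairs32, geometry, mode="binary")
        either = (preds["upper_field"] == 1.0) | (preds["lower_field"] == 1.0)
        np.testing.assert_array_equal(preds["full"] == 1.0, either)

    def test_upper_and_lower_masks_cover_full_canvas(self, geometry):
        shape = geometry.shape
        up = TemplateModel("upper_field").mask(shape)
        low = TemplateModel("lower_field").mask(shape)
        np.testing.assert_array_equal(up | low, TemplateModel("full").mask(shape))
        assert not (up & low).any()


class TestPredictionCorrelation:
    def test_perfect_agreement_gives_r_one(self):
        preds = {"a": 0.5, "b": 0.75, "c": 1.0}
        assert prediction_performance_correlation(preds, dict(preds))["r"] == pytest.approx(1.0)

    def test_degenerate_predictions_flagged(self):
        out = prediction_performance_correlation(
            {"a": 1.0, "b": 1.0, "c": 1.0}, {"a": 0.4, "b": 0.6, "c": 0.9})
        assert out["degenerate"]
        assert np.isnan(out["r"])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            prediction_performance_correlation({"a": 0.5, "b": 1.0}, {"a": 0.5, "b": 1.0})

    def test_permutation_p_calibrated_under_null(self):
        """Independent observations: permutation p should be roughly uniform."""
        rng = np.random.default_rng(0)
        ids = [str(i) for i in range(20)]
        ps = []
        for _ in range(40):
            preds = dict(zip(ids, rng.random(20)))
            obs = dict(zip(ids, rng.random(20)))
            out = prediction_performance_correlation(preds, obs, n_permutations=200, seed=1)
            ps.append(out["p_permutation"])
        assert 0.05 <= np.mean(np.array(ps) < 0.5) <= 0.95  # not degenerate
        assert np.mean(np.array(ps) < 0.1) <= 0.3  # ~10% nominal, generous band

    def test_upper_field_readers_recovered_by_upper_model(self, pairs32, geometry):
        """Cohort that only reads the top half: r(upper) > r(lower), r(lower) ~ 0."""
        mask = TemplateModel("upper_field").mask(geometry.shape)
        proto = Protocol.rat(session_size=len(pairs32) * 4, max_sessions=10,
                             block_length=len(pairs32), correction_trials=False)
        cohort = simulate_cohort(lambda: RegionExemplarStrategy(mask), linear_task,
                                 proto, 6, seed=21, pairs=pairs32, geometry=geometry)
        frame = pd.concat([s.frame() for s in cohort])
        perf = per_pair_performance(frame, last_sessions=5)
        obs = dict(zip(perf["pair_id"], perf["accuracy"]))
        preds = prediction_matrix(
            [TemplateModel("upper_field"), TemplateModel("lower_field")],
            pairs32, geometry, mode="graded")
        r_up = prediction_performance_correlation(preds["upper_field"].to_dict(), obs)
        r_low = prediction_performance_correlation(preds["lower_field"].to_dict(), obs)
        assert r_up["r"] > 0 > r_low["r"] or (r_up["r"] > r_low["r"] and r_low["p"] > 0.05)
        assert r_up["r"] > r_low["r"]


class TestPerPairPerformance:
    def _frame(self, pair_counts):
        rows = []
        t = 0
        for pair_id, (k, n) in pair_counts.items():
            for i in range(n):
                t += 1
                ok = i < k
                rows.append({"subject": 0, "session": 1, "trial": t, "pair_id": pair_id,
                             "target_side": "left", "chosen_side": "left" if ok else "right",
                             "correct": ok, "correction_trial": False, "stage": 0})
        return pd.DataFrame(rows)

    def test_half_successes_interval_contains_half(self):
        perf = per_pair_performance(self._frame({"p": (10, 20)}))
        row = perf.iloc[0]
        assert row["accuracy"] == 0.5
        assert row["ci_low"] <= 0.5 <= row["ci_high"]

    def test_perfect_performance_exact_interval(self):
        perf = per_pair_performance(self._frame({"p": (20, 20)}))
        row = perf.iloc[0]
        assert row["ci_high"] == pytest.approx(1.0)
        assert row["ci_low"] > 0.8  # Clopper-Pearson lower bound for 20/20 at 95%

    def test_intervals_shrink_with_trial_count(self):
        widths = []
        for n in (20, 80, 320):
            perf = per_pair_performance(self._frame({"p": (n // 2, n)}))
            widths.append(perf.iloc[0]["ci_high"] - perf.iloc[0]["ci_low"])
        assert widths[0] > widths[1] > widths[2]
        cw = [chance_interval(n)[1] - chance_interval(n)[0] for n in (20, 80, 320)]
        assert cw[0] > cw[1] > cw[2]

    def test_zero_trial_pairs_reported_not_dropped(self):
        df = self._frame({"p": (5, 10)})
        window = per_pair_performance(
            pd.concat([df, df.assign(pair_id="q", session=0)]), last_sessions=1)
        q = window.set_index("pair_id").loc["q"]
        assert q["trials"] == 0
        assert np.isnan(q["accuracy"])


class TestTransferAnalysis:
    def test_nonlinear_staging_shows_inverted_transfer(self):
        stages = experiment_a_stages(nonlinear_task)
        subj = simulate_subject(default_cohort_strategy("rat", "nonlinear"),
                                nonlinear_task, Protocol.rat(max_sessions=30),
                                seed=7, stages=stages)
        out = transfer_analysis(subj.frame(), stages[0][0].id, stages[1][1].id)
        assert out["old"]["accuracy"] > 0.5
        assert out["new"]["accuracy"] < 0.5

    def test_linear_staging_transfers_positively(self):
        stages = experiment_a_stages(linear_task)
        subj = simulate_subject(default_cohort_strategy("rat", "linear"),
                                linear_task, Protocol.rat(max_sessions=30),
                                seed=7, stages=stages)
        out = transfer_analysis(subj.frame(), stages[0][0].id, stages[1][1].id)
        assert out["old"]["accuracy"] > 0.5
        assert out["new"]["accuracy"] > 0.5

    def test_oracle_transfer_correlation_degenerate(self):
        stages = experiment_a_stages(nonlinear_task)
        subj = simulate_subject(SymmetryOracleStrategy(), nonlinear_task,
                                Protocol.rat(max_sessions=30), seed=8, stages=stages)
        out = transfer_analysis(subj.frame(), stages[0][0].id, stages[1][1].id)
        assert out["old"]["accuracy"] == 1.0
        assert out["new"]["accuracy"] == 1.0
        assert out["correlation"]["degenerate"]

    def test_unstaged_log_rejected(self):
        subj = simulate_subject(SymmetryOracleStrategy(), nonlinear_task,
                                Protocol.rat(max_sessions=3), seed=9)
        with pytest.raises(ValueError):
            transfer_analysis(subj.frame(), "a", "b")
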