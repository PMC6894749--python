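"""Simplified pooled assay: regression recovery, satiety-ratio baseline."""

import numpy as np
import pandas as pd
import pytest

from satiety import DEFAULT_PARAMS, simulate, termination_probability
from satiety.assay import (fit_bout_distributions, fit_imi_linear,
                           fit_termination_logistic, moving_window_imi,
                           pooled_records, run_assay, satiety_ratio)
from satiety.hierarchical import sample_group_prior
from satiety.io import label_meals


@pytest.fixture(scope="module")
def pooled_group(gut, narrow_hyper):
    """Ten simulated animals, one 24-h window each, pooled."""
    rng = np.random.default_rng(30)
    _, inds = sample_group_prior(narrow_hyper, 10, rng)
    seqs = [simulate(p, gut, (0.0, 24 * 3600.0), rng=rng, subject=f"r{j}")[0]
            for j, p in enumerate(inds)]
    return seqs, pooled_records(seqs, gut)


class TestTerminationLogistic:
    def test_parameter_identity_with_sigmoid(self):
        """logistic(intercept + slope*x) == sigmoid kernel with
        T1 = slope, T2 = -intercept/slope."""
        T1, T2 = 6.0, 2.0
        x = np.linspace(0, 4, 9)
        lhs = 1.0 / (1.0 + np.exp(-(-T1 * T2 + T1 * x)))
        assert np.allclose(lhs, termination_probability(x, T1, T2))

    def test_recovers_known_kernel(self):
        T1, T2 = 6.0, 2.0
        rng = np.random.default_rng(31)
        x = rng.uniform(0.5, 3.5, 5000)
        y = rng.random(5000) < termination_probability(x, T1, T2)
        fit = fit_termination_logistic(
            pd.DataFrame({"fullness": x, "terminated": y.astype(int)}))
        assert not fit.separated
        assert abs(fit.slope - T1) < 2.5 * fit.slope_se
        assert abs(fit.T2 - T2) < 0.1

    def test_null_case_slope_ci_contains_zero(self):
        rng = np.random.default_rng(32)
        x = rng.uniform(0, 3, 3000)
        y = rng.random(3000) < 0.5  # fullness-independent (T1 = 0)
        fit = fit_termination_logistic(
            pd.DataFrame({"fullness": x, "terminated": y.astype(int)}))
        assert abs(fit.slope) < 2.5 * fit.slope_se

    def test_complete_separation_flagged(self):
        x = np.concatenate([np.linspace(0, 1, 50), np.linspace(2, 3, 50)])
        y = (x > 1.5).astype(int)
        fit = fit_termination_logistic(
            pd.DataFrame({"fullness": x, "terminated": y}))
        assert fit.separated
        assert np.isfinite(fit.slope)

    def test_single_outcome_class_rejected(self):
        with pytest.raises(ValueError):
            fit_termination_logistic(
                pd.DataFrame({"fullness": [1.0, 2.0], "terminated": [1, 1]}))

    def test_recovery_on_simulated_group(self, gut, pooled_group):
        seqs, records = pooled_group
        fit = fit_termination_logistic(records)
        # pooled fit tracks the group-typical kernel
        assert 0.3 * DEFAULT_PARAMS.T1 < fit.T1 < 3 * DEFAULT_PARAMS.T1
        assert abs(fit.T2 - DEFAULT_PARAMS.T2) < 0.6


class TestIMILinear:
    def test_exact_collinear_points(self):
        rec = pd.DataFrame({"fullness": [0.0, 1.0, 2.0],
                            "imi": [100.0, 300.0, 500.0]})
        fit = fit_imi_linear(rec)
        assert fit.intercept == pytest.approx(100.0)
        assert fit.slope == pytest.approx(200.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_hazard_gives_flat_line_at_L1(self, gut):
        p = DEFAULT_PARAMS.replace(L2=0.0)
        rng = np.random.default_rng(33)
        seqs = [simulate(p, gut, (0.0, 24 * 3600.0), rng=rng)[0]
                for _ in range(6)]
        rec = pooled_records(seqs, gut)
        fit = fit_imi_linear(rec)
        assert abs(fit.slope) < 2.5 * fit.slope_se
        assert fit.intercept == pytest.approx(p.L1, rel=0.25)

    def test_tracks_model_mean_imi_curve(self, gut, pooled_group):
        """The pooled linear fit stays inside the Monte Carlo band of the
        generating model's mean intermeal interval."""
        from satiety import sample_imi_duration

        _, records = pooled_group
        fit = fit_imi_linear(records)
        rng = np.random.default_rng(34)
        for x0 in (1.5, 2.0, 2.5):
            sims = np.array([sample_imi_duration(x0, DEFAULT_PARAMS, gut, rng)
                             for _ in range(2000)])
            band = 3 * sims.std() / np.sqrt(len(sims)) + 0.35 * sims.mean()
            assert abs(fit.predict(x0) - sims.mean()) < band

    def test_too_few_intervals_rejected(self):
        with pytest.raises(ValueError):
            fit_imi_linear(pd.DataFrame({"fullness": [1.0], "imi": [10.0]}))


class TestDistributions:
    def test_pooled_exponential_and_normal_fits(self, gut):
        # homogeneous group: pooling across identical animals is unbiased
        rng = np.random.default_rng(37)
        seqs = [simulate(DEFAULT_PARAMS, gut, (0.0, 24 * 3600.0), rng=rng)[0]
                for _ in range(6)]
        fit = fit_bout_distributions(seqs)
        assert fit.lambda_F == pytest.approx(DEFAULT_PARAMS.lambda_F, rel=0.3)
        assert fit.lambda_S == pytest.approx(DEFAULT_PARAMS.lambda_S, rel=0.3)
        assert fit.rate_mean == pytest.approx(DEFAULT_PARAMS.mu_F, rel=0.2)

    def test_consistency_error_shrinks_with_n(self, gut, params):
        errs = []
        for hours, seed in ((4, 40), (40, 41), (400, 42)):
            seq, _ = simulate(params, gut, (0.0, hours * 3600.0),
                              rng=np.random.default_rng(seed))
            fit = fit_bout_distributions([seq])
            errs.append(abs(fit.lambda_F - params.lambda_F) / params.lambda_F)
        assert errs[2] < errs[0]
        assert errs[2] < 0.05


class TestSatietyRatio:
    def test_definition(self, gut):
        from satiety import EventRecord, FeedingSequence

        events = [EventRecord("bout", 0.0, 100.0, amount=2.0),
                  EventRecord("pause", 100.0, 3600.0, pause_class="L"),
                  EventRecord("bout", 3700.0, 50.0, amount=1.0),
                  EventRecord("pause", 3750.0, 1000.0, pause_class="L")]
        seq = FeedingSequence(subject="t", events=events, window=(0.0, 4750.0))
        res = satiety_ratio(seq)
        assert res.ratio == pytest.approx(1800.0)  # 3600 s / 2 g
        assert res.predictions["predicted_imi"].iloc[0] == pytest.approx(1800.0)

    def test_identical_meals_predicted_exactly(self, gut):
        from satiety import EventRecord, FeedingSequence

        events = []
        t = 0.0
        for _ in range(4):
            events.append(EventRecord("bout", t, 100.0, amount=1.5))
            events.append(EventRecord("pause", t + 100.0, 2000.0,
                                      pause_class="L"))
            t += 2100.0
        seq = FeedingSequence(subject="t", events=events, window=(0.0, t))
        res = satiety_ratio(seq)
        assert np.allclose(res.predictions["predicted_imi"],
                           res.predictions["observed_imi"])
        assert res.mean_abs_error == pytest.approx(0.0)

    def test_no_complete_first_meal_rejected(self, gut):
        from satiety import EventRecord, FeedingSequence

        seq = FeedingSequence(
            subject="t", events=[EventRecord("bout", 0.0, 60.0, amount=0.5)],
            window=(0.0, 60.0))
        with pytest.raises(ValueError):
            satiety_ratio(seq)

    def test_fullness_predictor_beats_satiety_ratio(self, gut, pooled_group):
        """On model-generated data the fullness regression predicts the
        intermeal interval better than the classical first-meal ratio."""
        seqs, records = pooled_group
        lin = fit_imi_linear(records)
        complete = records.dropna(subset=["imi"])
        lin_mae = np.mean(np.abs(lin.predict(complete["fullness"])
                                 - complete["imi"]))
        ratio_maes = []
        for seq in seqs:
            try:
                ratio_maes.append(satiety_ratio(seq).mean_abs_error)
            except ValueError:
                continue
        assert np.nanmean(ratio_maes) > lin_mae


class TestMovingWindow:
    def test_single_record_flat(self):
        rec = pd.DataFrame({"fullness": [2.0], "imi": [1500.0]})
        curve = moving_window_imi(rec)
        assert len(curve) == 1
        assert curve["mean_imi"].iloc[0] == 1500.0

    def test_flat_for_constant_hazard(self, gut):
        p = DEFAULT_PARAMS.replace(L2=0.0)
        rng = np.random.default_rng(35)
        seqs = [simulate(p, gut, (0.0, 24 * 3600.0), rng=rng)[0]
                for _ in range(12)]
        curve = moving_window_imi(pooled_records(seqs, gut), min_count=25)
        spread = curve["mean_imi"].max() - curve["mean_imi"].min()
        assert spread < 1.2 * p.L1  # noise-level variation, no trend
        slope = np.polyfit(curve["fullness"], curve["mean_imi"], 1)[0]
        assert abs(slope * np.ptp(curve["fullness"].to_numpy())) < p.L1

    def test_increasing_when_fullness_lengthens_imi(self, gut, pooled_group):
        _, records = pooled_group
        curve = moving_window_imi(records, min_count=30)
        third = len(curve) // 3
        assert curve["mean_imi"].iloc[-third:].mean() \
            > curve["mean_imi"].iloc[:third].mean()


class TestPipeline:
    def test_runs_from_events_and_gut_only(self, gut, pooled_group):
        seqs, _ = pooled_group
        result = run_assay(seqs, gut)
        implied = result.implied_params()
        assert set(implied) >= {"lambda_F", "mu_F", "T1", "T2"}
        assert result.n_records > 100

    def test_works_after_relabelling(self, gut, params):
        """End-to-end on label_meals output (classes from thresholds, not
        simulator truth)."""
        rng = np.random.default_rng(36)
        seq, _ = simulate(params, gut, (0.0, 24 * 3600.0), rng=rng)
        stripped = seq.to_frame()
        from satiety import EventRecord, FeedingSequence

        events = [EventRecord(r.kind, r.start_s, r.duration_s,
                              amount=r.amount_g,
                              pause_class="unknown" if r.kind == "pause" else None)
                  for r in stripped.itertuples()]
        unlabelled = FeedingSequence(subject="t", events=events,
                                     window=seq.window)
        relabelled = label_meals(unlabelled, 300.0)
        result = run_assay([relabelled], gut)
        assert result.distributions.lambda_F == pytest.approx(
            params.lambda_F, rel=0.35)
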