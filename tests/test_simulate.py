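"""PDMP simulator: samplers vs analytic laws, structural invariants."""

import numpy as np
import pytest
from scipy import stats as sps

from satiety import (DEFAULT_PARAMS, FeedingSequence, GutModel,
                     InterventionSpec, sample_bout, sample_imi_duration,
                     simulate, summarise, termination_probability)
from satiety.gut import integrated_imi_hazard


class TestTerminationKernel:
    def test_midpoint(self):
        assert termination_probability(1.75, 4.0, 1.75) == pytest.approx(0.5)

    def test_flat_when_T1_zero(self):
        x = np.linspace(-5, 5, 11)
        assert np.allclose(termination_probability(x, 0.0, 1.0), 0.5)

    def test_step_limit(self):
        assert termination_probability(2.0, 1e3, 1.0) == pytest.approx(1.0)
        assert termination_probability(0.5, 1e3, 1.0) == pytest.approx(0.0, abs=1e-12)


class TestSamplers:
    def test_bout_duration_mean(self, params):
        rng = np.random.default_rng(0)
        durs = np.array([sample_bout(params, rng)[0] for _ in range(20000)])
        mean = 1.0 / params.lambda_F
        se = mean / np.sqrt(len(durs))
        assert abs(durs.mean() - mean) < 3 * se

    def test_rate_degenerates_when_sigma_small(self, params):
        rng = np.random.default_rng(1)
        p = params.replace(sigma_F=1e-12)
        rates = [sample_bout(p, rng)[1] for _ in range(100)]
        assert np.allclose(rates, params.mu_F, rtol=1e-6)

    def test_rate_matches_truncated_normal(self, params):
        # heavier truncation: mu/sigma = 1.5 so the truncated shape matters
        p = params.replace(mu_F=0.003, sigma_F=0.002)
        rng = np.random.default_rng(2)
        rates = np.array([sample_bout(p, rng)[1] for _ in range(10000)])
        a = (0.0 - p.mu_F) / p.sigma_F
        ks = sps.kstest(rates, sps.truncnorm(a, np.inf, loc=p.mu_F,
                                             scale=p.sigma_F).cdf)
        assert ks.pvalue > 0.01
        assert np.all(rates > 0)

    def test_imi_exponential_limits(self, params, gut):
        rng = np.random.default_rng(3)
        # x0 = 0: hazard constant at 1/L1 from the start
        draws = np.array([sample_imi_duration(0.0, params, gut, rng)
                          for _ in range(10000)])
        assert sps.kstest(draws, sps.expon(scale=params.L1).cdf).pvalue > 0.01
        # L2 = 0: exponential regardless of fullness
        p0 = params.replace(L2=0.0)
        draws = np.array([sample_imi_duration(3.0, p0, gut, rng)
                          for _ in range(10000)])
        assert sps.kstest(draws, sps.expon(scale=p0.L1).cdf).pvalue > 0.01

    def test_imi_survival_matches_integrated_hazard(self, params, gut):
        rng = np.random.default_rng(4)
        x0 = 2.0
        draws = np.array([sample_imi_duration(x0, params, gut, rng)
                          for _ in range(10000)])

        def cdf(t):
            t = np.atleast_1d(t)
            return np.array([1.0 - np.exp(-integrated_imi_hazard(
                x0, ti, params.L1, params.L2, gut)) for ti in t])

        assert sps.kstest(draws, cdf).pvalue > 0.01


class TestSimulate:
    def test_zero_window(self, params, gut):
        seq, _ = simulate(params, gut, (0.0, 0.0), rng=np.random.default_rng(0))
        assert seq.events == []

    def test_always_terminate_kernel(self, gut):
        # certain termination: every meal is a single bout, no S pauses
        p = DEFAULT_PARAMS.replace(T1=1e3, T2=-10.0)
        seq, _ = simulate(p, gut, (0.0, 12 * 3600.0), rng=np.random.default_rng(1))
        assert all(ev.pause_class != "S" for ev in seq.pauses())
        s = summarise(seq)
        assert s.meal_count == s.bout_count

    def test_alternation_and_tiling(self, params, gut, day_sequence):
        evs = day_sequence.events
        for a, b in zip(evs[:-1], evs[1:]):
            assert a.kind != b.kind  # bouts and pauses alternate
            assert b.start == pytest.approx(a.end, abs=1e-9)
        assert all(ev.duration > 0 for ev in evs)
        assert all(ev.fullness_at_start >= 0 for ev in evs)

    def test_seed_determinism(self, params, gut):
        s1, _ = simulate(params, gut, (0.0, 6 * 3600.0),
                         rng=np.random.default_rng(11))
        s2, _ = simulate(params, gut, (0.0, 6 * 3600.0),
                         rng=np.random.default_rng(11))
        assert s1.to_frame().equals(s2.to_frame())

    def test_null_intervention_is_identity(self, params, gut):
        base, _ = simulate(params, gut, (0.0, 6 * 3600.0),
                           rng=np.random.default_rng(12))
        null_iv = InterventionSpec(refractory=0.0, sham=False)
        same, _ = simulate(params, gut, (0.0, 6 * 3600.0), intervention=null_iv,
                           rng=np.random.default_rng(12))
        assert base.to_frame().equals(same.to_frame())

    def test_meal_count_matches_termination_transitions(self, day_sequence):
        s = summarise(day_sequence)
        f_to_l = sum(1 for ev in day_sequence.events
                     if ev.kind == "bout" and ev.next_state == "L")
        # the final meal may be cut by the window before its termination
        open_tail = int(day_sequence.events[-1].kind == "bout"
                        or day_sequence.events[-1].pause_class == "S")
        assert s.meal_count == f_to_l + open_tail

    def test_censored_tail_flagged(self, params, gut):
        rng = np.random.default_rng(13)
        seq, _ = simulate(params, gut, (0.0, 3 * 3600.0), rng=rng)
        cens = [ev for ev in seq.events if ev.censored]
        assert len(cens) <= 1
        if cens:
            assert cens[0] is seq.events[-1]
            assert cens[0].end == pytest.approx(seq.window[1], abs=1e-9)

    def test_sham_keeps_fullness_flat(self, params, gut):
        seq, traj = simulate(params, gut, (0.0, 8 * 3600.0), x_init=0.0,
                             intervention=InterventionSpec(sham=True),
                             rng=np.random.default_rng(14))
        assert all(ev.fullness_at_start == 0.0 for ev in seq.events)
        assert np.all(traj.sample(200)[:, 1] == 0.0)
        assert sum(b.amount for b in seq.bouts()) > 0

    def test_parameter_switch_changes_only_later_draws(self, params, gut):
        fast = params.replace(lambda_F=params.lambda_F * 3)
        sched = [(0.0, params), (6 * 3600.0, fast)]
        seq, _ = simulate(sched, gut, (0.0, 12 * 3600.0),
                          rng=np.random.default_rng(15))
        base, _ = simulate(params, gut, (0.0, 12 * 3600.0),
                           rng=np.random.default_rng(15))
        # identical prefix before the switch
        pre = [e for e in seq.events if e.end < 6 * 3600.0]
        pre_base = [e for e in base.events if e.end < 6 * 3600.0]
        for a, b in zip(pre, pre_base):
            assert a.start == b.start and a.duration == b.duration

    def test_schedule_switch_outside_window_raises(self, params, gut):
        with pytest.raises(ValueError):
            simulate([(0.0, params), (1e6, params)], gut, (0.0, 3600.0),
                     rng=np.random.default_rng(0))

    def test_meal_size_monotone_in_termination_shift(self, gut):
        # lowering T2 raises p_term at all x -> stochastically smaller meals
        rng_seeds = range(40)
        hi, lo = [], []
        for s in rng_seeds:
            q_hi, _ = simulate(DEFAULT_PARAMS, gut, (0.0, 12 * 3600.0),
                               rng=np.random.default_rng(1000 + s))
            q_lo, _ = simulate(DEFAULT_PARAMS.replace(T2=DEFAULT_PARAMS.T2 - 0.6),
                               gut, (0.0, 12 * 3600.0),
                               rng=np.random.default_rng(1000 + s))
            hi.append(np.mean(summarise(q_hi).meal_sizes))
            lo.append(np.mean(summarise(q_lo).meal_sizes))
        assert np.mean(hi) > np.mean(lo)


class TestSummarise:
    def test_single_bout(self, gut):
        from satiety import EventRecord

        seq = FeedingSequence(
            subject="t", events=[EventRecord("bout", 0.0, 60.0, amount=0.5)],
            window=(0.0, 3600.0))
        s = summarise(seq)
        assert s.total_intake == pytest.approx(0.5)
        assert s.meal_count == 1
        assert s.normalised_intake == pytest.approx(0.5)  # g per hour

    def test_concatenation_additivity(self, params, gut):
        rng = np.random.default_rng(20)
        a, _ = simulate(params, gut, (0.0, 6 * 3600.0), rng=rng)
        b, _ = simulate(params, gut, (6 * 3600.0, 12 * 3600.0), rng=rng)
        joined = a.concat(b)
        assert summarise(joined).total_intake == pytest.approx(
            summarise(a).total_intake + summarise(b).total_intake)

    def test_unresolved_classes_error(self, gut):
        from satiety import EventRecord

        seq = FeedingSequence(
            subject="t",
            events=[EventRecord("bout", 0.0, 60.0, amount=0.5),
                    EventRecord("pause", 60.0, 600.0, pause_class="unknown")],
            window=(0.0, 3600.0))
        with pytest.raises(ValueError, match="label_meals"):
            summarise(seq)

    def test_renewal_reward_long_run_rate(self, gut):
        # T1 = 0 and L2 = 0 make the process a renewal process with
        # analytic cycle statistics: p_term = 1/2, E[bouts/meal] = 2,
        # E[meal] = 2 E[rho] E[d]; cycle = 2/lF + 1/lS + L1.
        p = DEFAULT_PARAMS.replace(T1=0.0, L2=0.0)
        seq, _ = simulate(p, gut, (0.0, 50 * 24 * 3600.0),
                          rng=np.random.default_rng(21))
        from scipy.stats import truncnorm

        a = -p.mu_F / p.sigma_F
        e_rho = truncnorm(a, np.inf, loc=p.mu_F, scale=p.sigma_F).mean()
        rate_expected = (2 * e_rho / p.lambda_F) / (
            2 / p.lambda_F + 1 / p.lambda_S + p.L1)
        s = summarise(seq)
        observed = s.total_intake / (50 * 24 * 3600.0)
        assert observed == pytest.approx(rate_expected, rel=0.03)
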