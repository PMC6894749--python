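"""Event-sequence likelihood: normalisation, hand-computed values, gradients."""

import numpy as np
import pytest
from scipy import stats as sps
from scipy.integrate import quad

from satiety import (DEFAULT_PARAMS, EventRecord, FeedingSequence, GutModel,
                     fit_mle, imi_logpdf, imi_logsurvival, sequence_loglik)
from satiety.gut import time_to_empty
from satiety.likelihood import (PooledStats, SequenceStats, per_event_loglik,
                                pooled_loglik_and_grad,
                                sequence_loglik_and_grad)
from satiety.params import PARAM_NAMES
from satiety.simulate import simulate, termination_probability


class TestIMIDensity:
    def test_exponential_limit(self, gut, params):
        p = params.replace(L2=0.0)
        ts = np.array([100.0, 1000.0, 5000.0])
        expected = sps.expon(scale=p.L1).logpdf(ts)
        got = np.array([imi_logpdf(t, 3.0, p, gut) for t in ts])
        assert np.allclose(got, expected, rtol=1e-12)

    def test_normalises_to_one(self, gut):
        rng = np.random.default_rng(0)
        for _ in range(5):
            p = DEFAULT_PARAMS.replace(L1=rng.uniform(300, 2000),
                                       L2=rng.uniform(0, 3000))
            x0 = rng.uniform(0, 4)
            te = time_to_empty(x0, gut)
            # mass before emptying by quadrature + exact survival tail
            head = quad(lambda t: np.exp(imi_logpdf(t, x0, p, gut)),
                        1e-9, te, limit=400)[0] if te > 0 else 0.0
            tail = np.exp(imi_logsurvival(te, x0, p, gut))
            assert head + tail == pytest.approx(1.0, abs=1e-6)

    def test_density_is_negative_survival_derivative(self, gut, params):
        x0, h = 2.0, 1e-3
        for t in (500.0, 3000.0, 9000.0):
            s_plus = np.exp(imi_logsurvival(t + h, x0, params, gut))
            s_minus = np.exp(imi_logsurvival(t - h, x0, params, gut))
            fd = -(s_plus - s_minus) / (2 * h)
            assert np.exp(imi_logpdf(t, x0, params, gut)) \
                == pytest.approx(fd, rel=1e-5)

    def test_survival_properties(self, gut, params):
        assert imi_logsurvival(0.0, 2.0, params, gut) == 0.0
        p0 = params.replace(L2=0.0)
        assert imi_logsurvival(1234.0, 2.0, p0, gut) \
            == pytest.approx(-1234.0 / p0.L1)
        ts = np.linspace(0, 2e4, 40)
        s = np.array([imi_logsurvival(t, 2.0, params, gut) for t in ts])
        assert np.all(np.diff(s) < 0)
        assert np.all(s <= 0)


class TestSequenceLoglik:
    def _toy(self):
        """One bout then one complete intermeal interval."""
        return FeedingSequence(
            subject="t",
            events=[EventRecord("bout", 0.0, 100.0, amount=0.5),
                    EventRecord("pause", 100.0, 2000.0, pause_class="L")],
            window=(0.0, 2100.0), x_init=0.0)

    def test_two_event_toy_hand_summed(self, gut, params):
        seq = self._toy()
        rho = 0.5 / 100.0
        a = -params.mu_F / params.sigma_F
        expected = (
            sps.expon(scale=1 / params.lambda_F).logpdf(100.0)
            + sps.truncnorm(a, np.inf, loc=params.mu_F,
                            scale=params.sigma_F).logpdf(rho)
            + np.log(termination_probability(0.5, params.T1, params.T2))
            + imi_logpdf(2000.0, 0.5, params, gut))
        assert sequence_loglik(seq, params, gut) == pytest.approx(expected, rel=1e-10)

    def test_tiny_censored_pause_is_free(self, gut, params):
        seq = self._toy()
        ll0 = sequence_loglik(seq, params, gut)
        seq2 = FeedingSequence(
            subject="t",
            events=seq.events + [EventRecord("pause", 2100.0, 1e-7,
                                             pause_class="L", censored=True)],
            window=(0.0, 2100.0 + 1e-7), x_init=0.0)
        # survival at ~0 elapsed time contributes ~0
        assert sequence_loglik(seq2, params, gut) == pytest.approx(ll0, abs=1e-9)

    def test_factorises_over_events(self, gut, params, day_sequence):
        breakdown = per_event_loglik(day_sequence, params, gut)
        total = breakdown["loglik_total"].sum()
        assert total == pytest.approx(
            sequence_loglik(day_sequence, params, gut), rel=1e-9)
        # order of summation is immaterial
        shuffled = breakdown.sample(frac=1.0, random_state=0)["loglik_total"].sum()
        assert shuffled == pytest.approx(total, rel=1e-9)

    def test_gradient_matches_finite_differences(self, gut, day_sequence):
        st = SequenceStats.from_sequence(day_sequence, gut)
        rng = np.random.default_rng(5)
        for _ in range(3):
            th = DEFAULT_PARAMS.as_array() * rng.uniform(0.7, 1.4, 8)
            _, g = sequence_loglik_and_grad(st, th, gut)
            for i in range(8):
                h = max(abs(th[i]), 1e-4) * 1e-6
                tp, tm = th.copy(), th.copy()
                tp[i] += h
                tm[i] -= h
                fd = (sequence_loglik_and_grad(st, tp, gut)[0]
                      - sequence_loglik_and_grad(st, tm, gut)[0]) / (2 * h)
                assert g[i] == pytest.approx(fd, rel=2e-4, abs=1e-8)

    def test_time_rescaling_invariance(self, gut, params, day_sequence):
        """Rescaling time units shifts the log-likelihood by the exact
        deterministic Jacobian constant only."""
        c = 60.0  # seconds -> minutes
        st = SequenceStats.from_sequence(day_sequence, gut)
        ll = sequence_loglik(day_sequence, params, gut)

        scaled_events = []
        for ev in day_sequence.events:
            scaled_events.append(EventRecord(
                ev.kind, ev.start / c, ev.duration / c, amount=ev.amount,
                pause_class=ev.pause_class, censored=ev.censored))
        seq_c = FeedingSequence(
            subject="t", events=scaled_events,
            window=(day_sequence.window[0] / c, day_sequence.window[1] / c))
        gut_c = GutModel(law=gut.law, k=gut.k * c, epsilon_empty=gut.epsilon_empty)
        p_c = params.replace(lambda_F=params.lambda_F * c, mu_F=params.mu_F * c,
                             sigma_F=params.sigma_F * c,
                             lambda_S=params.lambda_S * c,
                             L1=params.L1 / c, L2=params.L2 / c)
        ll_c = sequence_loglik(seq_c, p_c, gut_c)
        n_dur = (len(st.bout_durations) + len(st.s_durations)
                 + len(st.l_durations))
        n_rate = len(st.rates)
        # durations shrink by c (+log c each), rates grow by c (-log c each)
        assert ll_c - ll == pytest.approx((n_dur - n_rate) * np.log(c), rel=1e-9)

    def test_unresolved_pause_classes_rejected(self, gut, params):
        seq = FeedingSequence(
            subject="t",
            events=[EventRecord("bout", 0.0, 60.0, amount=0.3),
                    EventRecord("pause", 60.0, 900.0, pause_class="unknown")],
            window=(0.0, 1000.0))
        with pytest.raises(ValueError, match="label_meals"):
            sequence_loglik(seq, params, gut)

    def test_pooled_matches_per_individual(self, gut, params):
        rng = np.random.default_rng(9)
        stats = []
        for j in range(3):
            seq, _ = simulate(params, gut, (0.0, 12 * 3600.0), rng=rng)
            stats.append([SequenceStats.from_sequence(seq, gut)])
        pool = PooledStats.from_stats(stats)
        theta = np.vstack([params.as_array() * f for f in (0.9, 1.0, 1.2)])
        ll_pool, g_pool = pooled_loglik_and_grad(pool, theta, gut)
        ll_ref, g_ref = 0.0, []
        for j in range(3):
            lli, gi = sequence_loglik_and_grad(stats[j][0], theta[j], gut)
            ll_ref += lli
            g_ref.append(gi)
        assert ll_pool == pytest.approx(ll_ref, rel=1e-12)
        assert np.allclose(g_pool, np.vstack(g_ref), rtol=1e-10)


class TestMLE:
    def test_generating_params_beat_neighbours(self, gut, params, long_sequence):
        """Average log-likelihood is maximised near the generating values."""
        st = SequenceStats.from_sequence(long_sequence, gut)
        ll0, _ = sequence_loglik_and_grad(st, params, gut)
        for i, scale in [(0, 1.3), (1, 0.8), (6, 1.5), (7, 0.6)]:
            th = params.as_array()
            th[i] *= scale
            ll, _ = sequence_loglik_and_grad(st, th, gut)
            assert ll < ll0

    def test_recovery_within_tolerances(self, gut, params, long_sequence):
        st = SequenceStats.from_sequence(long_sequence, gut)
        assert st.n_meals >= 500
        est, res = fit_mle(st, gut)
        assert res.success
        tru = params.as_array()
        got = est.as_array()
        rel = np.abs(got - tru) / np.abs(tru)
        for i, name in enumerate(PARAM_NAMES):
            tol = 0.05 if name in ("lambda_F", "mu_F", "sigma_F", "lambda_S") else 0.15
            assert rel[i] < tol, f"{name}: {rel[i]:.3f} > {tol}"


class TestLawSwap:
    def test_likelihood_under_alternative_emptying_laws(self, params):
        """Swapping the emptying law keeps the likelihood machinery intact:
        finite values, correct L1/L2 gradients (quadrature path), and a
        sane density."""
        rng = np.random.default_rng(13)
        gut_lin = GutModel(law="linear", epsilon_empty=1e-9)
        seq, _ = simulate(params, gut_lin, (0.0, 6 * 3600.0), rng=rng)
        st = SequenceStats.from_sequence(seq, gut_lin)
        th = params.as_array()
        ll, g = sequence_loglik_and_grad(st, th, gut_lin)
        assert np.isfinite(ll)
        for i in (6, 7):  # L1, L2 use the numerical hazard path
            h = th[i] * 1e-5
            tp, tm = th.copy(), th.copy()
            tp[i] += h
            tm[i] -= h
            fd = (sequence_loglik_and_grad(st, tp, gut_lin)[0]
                  - sequence_loglik_and_grad(st, tm, gut_lin)[0]) / (2 * h)
            assert g[i] == pytest.approx(fd, rel=1e-3)
        # density still normalises under the swapped law
        x0 = 2.0
        mass = quad(lambda t: np.exp(imi_logpdf(t, x0, params, gut_lin)),
                    1e-6, 5e5, limit=300)[0]
        assert mass == pytest.approx(1.0, abs=1e-4)
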