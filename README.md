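# satiety

Stochastic modelling of rodent feeding microstructure: simulation, exact
event-sequence likelihoods, hierarchical Bayesian inference, and in-silico
intervention experiments.

## The problem

Automated feeding monitors (CLAMS, BioDAQ) record feeding at the level of
individual **bouts** — short episodes of ingestion with a duration and an
amount — which cluster into **meals** separated by long **intermeal
intervals**. Because feeding is homeostatic, the rates of transition between
behavioural states are not constant: they are modulated by how much food is
already in the gut. Classical ethogram-style analysis (fixed transition
rates) and the classical satiety ratio (first meal size vs the following
interval) both ignore this, which limits what meal-pattern data can say
about how a drug, a diet or a lesion changes behaviour.

`satiety` implements a piecewise deterministic Markov process (PDMP) model
of feeding for people who analyse bout-level rodent feeding data:
pharmacologists quantifying how anorectic agents restructure feeding,
physiologists studying gastric emptying and satiation, and modellers who
need a generative model to design interventions in silico.

## The model

A single physiological state, *fullness* x (g of upper-gut contents),
evolves deterministically given the behavioural state s ∈ {F, S, L}
(feeding bout, short within-meal pause, long intermeal interval):

    dx/dt = ρ          while feeding (linear filling at the bout's rate)
    dx/dt = −k √x      otherwise     (square-root emptying law)

The behavioural state switches stochastically:

* bout duration ~ Exponential(λ_F); per-bout rate ρ ~ Normal(μ_F, σ_F)
  truncated at 0; amount = ρ × duration;
* at each bout end the meal terminates (F → L) with probability
  σ(T1 (x − T2)) = 1 / (1 + e^{−T1 (x − T2)}), else a short pause follows
  (F → S) with duration ~ Exponential(λ_S);
* the intermeal interval has the time-varying hazard
  λ_L(x) = 1 / (L1 + L2 x) evaluated along the emptying trajectory, so a
  full gut suppresses meal initiation (satiety) while meal termination
  rises with fullness (satiation).

Everything downstream is exact: interval sampling inverts the closed-form
integrated hazard Λ(t) = ∫ dτ/(L1 + L2 x(τ)) (an arctan expression under
the square-root law), and the log-likelihood of an observed sequence —
including right-censoring at the window edges — is a closed form with
analytic gradients in all eight parameters (λ_F, μ_F, σ_F, λ_S, T1, T2,
L1, L2).

Across animals, parameters are pooled with a Bayesian hierarchical model
on a transformed scale (log10 for the positive parameters):
θ̃_j ~ N(μ, Σ) with Σ = diag(τ) Ω diag(τ), τ_i ~ HalfCauchy(2.5),
Ω ~ LKJ(η), μ ~ N(μ*, 2), sampled by the package's own No-U-Turn sampler
(non-centred parametrisation, analytic gradients, dual-averaging step-size
and diagonal metric adaptation, divergence and R̂/ESS diagnostics via
ArviZ).

## Worked example

Simulate a 12-h dark-period window for the built-in reference rat, then
recover the parameters from a 14-day recording:

```python
import numpy as np
from satiety import DEFAULT_PARAMS, GutModel, simulate, summarise, fit_mle

gut = GutModel()                      # sqrt emptying, k = 0.00055
rng = np.random.default_rng(7)
seq, traj = simulate(DEFAULT_PARAMS, gut, (0.0, 12 * 3600.0), rng=rng)
print(summarise(seq).to_dict())
```

```
{'total_intake_g': 25.62, 'normalised_intake': 2.135, 'meal_count': 20,
 'bout_count': 45, 'mean_meal_size_g': 1.281, 'mean_meal_duration_s': 343.7,
 'mean_imi_s': 1804.2, 'mean_bout_duration_s': 119.7,
 'mean_bout_rate_g_per_s': 0.00465}
```

The simulated rat ate 25.6 g in 12 h in 20 meals of ~1.3 g; bouts averaged
2 min at 0.28 g/min. Fitting the model to a 14-day simulation from the
same parameters (≈540 meals):

```python
seq14, _ = simulate(DEFAULT_PARAMS, gut, (0.0, 14 * 24 * 3600.0),
                    rng=np.random.default_rng(7))
est, _ = fit_mle(seq14, gut)
```

recovers λ_F = 0.00857 (truth 0.00833), μ_F = 0.00500 (0.005),
T2 = 1.81 g (1.75), L1 = 608 s (600), L2 = 1107 s/g (1100) — the
ingestion parameters within ~3% and the termination/interval parameters
within ~5%.

For groups of animals, `fit_hierarchical` pools individuals and
`posterior_predictive_intake` turns the posterior into intake forecasts;
`satiety.assay.run_assay` provides the MCMC-free simplified pipeline
(logistic regression for termination, linear regression for the intermeal
interval, exponential/normal fits within bouts); `satiety.experiments`
contains the intervention battery (refractory period, dosing-schedule
optimisation, gut-motility sweep, meal-termination perturbation, sham
feeding). A `satiety` command-line tool wraps the common workflows
(`simulate`, `fit`, `assay`, `clean`, `experiment`).

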