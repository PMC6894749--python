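# Methods

## Model

Feeding is modelled as a piecewise deterministic Markov process with three
behavioural states — feeding bout (F), short within-meal pause (S) and
intermeal interval (L) — coupled to a single continuous physiological
state, fullness x(t) (grams of upper-gut contents). Within a state the
physiology is deterministic: x rises linearly at the bout's realised rate
ρ while feeding and decays as dx/dt = −k x^γ otherwise. The behavioural
state switches stochastically with rates that may depend on x:

| element | law | parameters |
|---|---|---|
| bout duration | Exponential(λ_F) | λ_F (1/s) |
| per-bout rate | Normal(μ_F, σ_F) truncated at 0 | μ_F, σ_F (g/s) |
| meal termination at bout end | Bernoulli(σ(T1 (x − T2))) | T1 (1/g), T2 (g) |
| short pause | Exponential(λ_S) | λ_S (1/s) |
| intermeal interval | hazard λ_L(x) = 1/(L1 + L2 x) | L1 (s), L2 (s/g) |

Digestion during feeding is neglected. This keeps every state-lifetime
law analytically solvable (bouts are minutes; emptying acts over hours)
and makes fullness at any event boundary an exact function of the
observed bouts.

### Emptying law

The default is the square-root law γ = ½, x(t) = (√x0 − k t/2)², which
empties in finite time t_e = 2√x0/k; with the default k = 0.00055
(g^½/s) a 4-g load clears in about two hours, in the physiological range
for rats eating standard chow. A linear law (γ = 1, exponential decay
with an ε-floor of 10⁻⁹ g so that "empty" is well defined) and general
power laws γ ∈ (0, 1) are first-class alternatives; every downstream
computation accepts any of them, so conclusions can be checked for
robustness to the emptying model. Units are seconds and grams
throughout.

### Integrated intermeal hazard

All interval sampling and likelihood evaluation runs through
Λ(t) = ∫₀ᵗ dτ/(L1 + L2 x(τ)). Under the square-root law Λ is piecewise
closed form — (2/(k√(L1L2)))·[arctan(u√(L2/L1))] in u = √x while the gut
empties, then (t − t_e)/L1 — and so are its partial derivatives in L1
and L2 (rational/arctan antiderivatives via the same substitution).
A series branch handles L2·x0 ≪ L1 stably. Interval draws invert Λ
exactly (closed form for sqrt and linear laws; bracketed root-finding at
10⁻⁶ s otherwise), so the simulator is exact, not discretised.

## Likelihood

The log-likelihood of an event sequence factorises over events: the
exponential terms for durations, the truncated-normal term for rates
(matching the simulator's truncation exactly — a mismatch here biases
recovery of μ_F and σ_F), the log-sigmoid routing terms at bout-end
fullness, and log λ_L(x(t)) − Λ(t) for complete intermeal intervals.
Window-censored terminal events contribute their survival terms
(−λ·t and −Λ(t)). Fullness at every boundary is recomputed from the
observed bouts given the gut model; file metadata is never trusted.
Discarding censored intervals instead of using their survival terms
leaves L1 nearly unbiased in our experiments but attenuates the
fullness-dependence L2 by ~20% (the censored intervals are precisely the
long ones launched at high fullness), which is why censoring support is
not optional. Gradients of every term in all eight parameters are
analytic; the MLE runs L-BFGS-B on the transformed scale (log10 for the
six positive parameters) with those gradients.

For hierarchical runs the per-individual event arrays are concatenated
and evaluated with segmented sums, making the cost of a joint
log-posterior gradient nearly independent of group size.

## Hierarchical model and sampler

Individuals j in a condition group share a multivariate normal on the
transformed scale: θ̃_j ~ N(μ, Σ), Σ = diag(τ) Ω diag(τ),
τ_i ~ HalfCauchy(2.5), Ω ~ LKJ(η = 2), μ ~ N(μ*, sd 2) with
μ* = (−3, −3, −3, 1, 1, −1, 3, 3) in the order
(λ_F, μ_F, σ_F, λ_S, T1, T2, L1, L2); T1 and T2 stay on the raw scale
and may be negative (a negative T1 inverts the fullness dependence of
termination — the prior does not forbid it, and the data decide). The
LKJ shape η = 2 weakly favours moderate correlations; it and every other
hyperparameter are configurable.

Ω is parametrised through the canonical partial correlations of its
Cholesky factor, tanh-mapped to the real line. In that parametrisation
the LKJ density times the transform Jacobian collapses to independent
per-coordinate terms ∝ (1 − tanh²y)^c with c = η + (d − j − 2)/2 for
column j, so prior gradient and ancestral sampling (z = 2·Beta(c, c) − 1)
are exact and mutually consistent; a prior-only NUTS run reproducing the
ancestral marginals is part of the test suite, validating the Jacobian
end to end.

Sampling uses the package's own No-U-Turn sampler (slice variant with
recursive doubling, dual-averaging step size targeting 0.8–0.9
acceptance, diagonal metric adapted over expanding warmup windows,
divergence threshold ΔH > 1000). The default parametrisation is
non-centred (θ̃_j = μ + diag(τ) L z_j), which suits the weakly-informed
per-individual regime typical of overnight recordings (5–40 meals per
animal). A centred variant is available and agrees with the non-centred
one on test problems; with long recordings per individual and small
groups, both parametrisations can develop stiff directions that a
diagonal metric cannot absorb (the usual funnel trade-off), which shows
up honestly as depth-capped trees, low ESS and split-R̂ > 1.01 — the
diagnostics are always attached to the posterior and a configurable
divergence fraction makes the fit fail loudly. MAP initialisation is
deliberately not used; chains start from a crude moment-matching point
(or the hyperprior mean) with per-chain jitter.

Default sampler budgets in the test suite are reduced (hundreds of
draws); production fits should use the configurable budgets
(thousands of draws, ≥ 2 chains).

## Synthetic data and what the tests show

The reference study condition (`DEFAULT_PARAMS`) is a dark-period,
ad-libitum rat: 2-min bouts at 0.3 g/min, short pauses of 1 min, meal
termination centred at 1.75 g with sharpness 4 /g, and intermeal hazard
1/(600 s + 1100 s/g · x). It yields ~26 g/day in ~1.3-g meals with
30–45-min intermeal intervals — realistic meal patterning for a Wistar
rat on chow. Group datasets draw individuals from the hierarchical prior
centred on this condition with τ-scale 0.1 (≈ 25–40% interindividual
spread) and LKJ η = 2.

The generator reproduces the model's statistical structure exactly, so
passing tests demonstrate internal correctness (samplers match their
laws; estimators recover generating parameters; credible intervals are
calibrated against the matched prior) — not that the model fits any
particular animal. Real data add artefacts the generator deliberately
omits: sensor noise and cancelling readings (handled by the cleaning
rules), circadian nonstationarity within a window (handled by fitting
photoperiods separately), day-to-day adaptation, and ambiguity in the
meal-definition criterion.

Problem sizes used by the automated checks were chosen to exercise each
claim at desk scale: single-subject recovery on 14 simulated days
(≈540 meals; ingestion parameters within 5%, termination/interval within
15%); hierarchical diagnostics on 6 individuals × 8 h with 500 + 800
draws × 2 chains (R̂ < 1.01, no divergences); interval coverage over
8 replicate groups of 5 (90% intervals, pooled coverage within a
binomial-plus-MCMC-noise band of 0.9); predictive-intake correlation on
10 individuals × 2 days (r > 0.8); intervention experiments at 200–1000
Monte Carlo repeats with coupled seeds across arms.

## In-silico experiments

Every experiment is a pure function of (configuration, seed); replicate
seeds are shared across arms so contrasts are variance-reduced and
re-running reproduces tables bit-identically. Standard errors are
s.e.m. over repeats.

* **Refractory period** — the intermeal interval is enforced to be at
  least R (food access blocked after meal termination; the initial
  pre-feeding interval is exempt). An alternative semantics (hazard
  suppressed for R, then resumed along the emptying trajectory) is
  provided because the two differ subtly in the short-R regime.
* **Dosing schedules** — drugs are parameter-set switches for fixed
  slots (default four 2-h slots, ≥ 2 saline) with no pharmacokinetic
  decay; switches apply to draws initiated after the switch time, and
  in-progress intervals are never resampled. The objective is mean total
  intake; ties rank fewer drug slots first.
* **Gut motility** — k is scaled over 0.5–1.5× with behavioural
  parameters fixed; mean intake responds near-linearly (R² > 0.95 on the
  reference condition).
* **Meal-termination perturbation** — raising T2 (≈ 2×) while lowering
  μ_F (≈ 0.4–0.55×) enlarges and extends meals by 50–90% while the
  fullness feedback on the intermeal interval compensates total 24-h
  intake to within a few percent, reproducing the compensation seen
  after silencing of CGRP-expressing neurons.
* **Sham feeding** — ingestion is recorded but the gut never fills, so
  the termination probability stays at its zero-fullness floor
  σ(−T1·T2) and, when L2 > 0, intervals also stay short. The intake
  ratio is extremely sensitive to that floor: with the reference
  condition's floor of ~10⁻³ sham meals balloon and intake rises
  several-fold, while conditions with flatter termination kernels show
  the ~tens-of-percent increases typical of sham-feeding preparations.
  When neither termination nor initiation sees fullness (T1 = 0 and
  L2 = 0) sham and normal arms are event-identical by construction.

## Data handling

Bout CSVs are read per subject; inter-bout gaps become unlabelled pauses.
Cleaning applies, in order: adjacent equal-magnitude opposite-sign bout
pairs (both dropped as one cancelling artefact), non-positive amounts,
then configurable amount (>10 g) and implied-rate (>0.2 g/s) outlier
bounds; the order matters — cancelling pairs must be removed before the
sign rule or they would be double-counted. Cleaning is idempotent and
every drop is itemised. Meal labelling uses a threshold on pause duration
(shipped default 300 s — a field convention, recorded in the sequence
metadata because λ_S, T1, T2, L1, L2 all depend on it) or a two-component
mixture split on log-duration. Short intermeal intervals are an
irreducible source of label error: with the reference condition ~9% of
intervals fall under 300 s, so threshold labelling is near-perfect only
when the fullness feedback strongly suppresses early meal initiation.

## Numerical choices

* Closed forms are validated against ODE/quadrature oracles at 10⁻⁸
  relative tolerance; the interval density integrates to 1 ± 10⁻⁶.
* The truncated-normal rate density uses `log_ndtr` for the
  normalisation; the hazard ratio φ/Φ is computed in log space.
* Hazard inversion tolerance for non-closed-form laws: 10⁻⁶ s.
* ε_empty = 10⁻⁹ g defines "empty" for laws that only reach zero
  asymptotically.
* Seeds: every stochastic entry point takes a `numpy.random.Generator`;
  experiment replicates derive child seeds from a `SeedSequence`, and
  identical seeds give bit-identical outputs.

## Known limitations

* One fullness compartment; no hormone kinetics, no drug effects on k
  (k modulation exists only as an explicit experiment), no learning or
  adaptation across days, no circadian modulation within a window.
* The pooled simplified assay deliberately discards interindividual
  variation; pooling across heterogeneous animals overweights frequent
  eaters, so its estimates describe the "typical event", not the typical
  animal.
* The diagonal-metric NUTS can mix slowly on datasets whose posteriors
  have strongly correlated stiff directions (long recordings, few
  individuals); diagnostics expose this, and the centred parametrisation
  or longer adaptation are the remedies.
* Fullness is treated as known given the gut model; uncertainty in k or
  γ is not propagated into the behavioural posterior.
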