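# Methods

This note records the modelling assumptions, default parameter choices and
numerical conventions behind `serotrace`, and states what the bundled
scenarios can and cannot demonstrate about real serological data.

## Generative model

The simulator is an individual-based discrete-time process. Time steps are
abstract; the user chooses the resolution and must scale all rates to it
(the quickstart is monthly, so waning rates are per month). For each
individual *i*, step *t* and exposure type *x* the engine computes

- p_e = P(E = 1), from the exposure model and the force-of-exposure grid
  λ[g, t, x];
- p_s = P(Z = 1 | E = 1), from the immunity model;

and draws the latent success state Z ~ Bernoulli(p_e · p_s). Drawing from
the product is distributionally identical to drawing E and then Z | E, and
the intermediate exposure indicator is never needed downstream, so it is
not materialized. Each success triggers a draw of per-event kinetics
parameters; after the event loop the latent biomarker quantities
A[i, t, b] are evaluated, and the observation design and model produce the
measured values Y.

### Conventions and tie-breaks

- **Activity** is half-open: an individual is exposable and observable for
  birth_time ≤ t < removal_time. Grid outputs carry NaN (the absent
  sentinel) exactly where an individual is inactive; the CSV serializations
  write absent as an empty field.
- **Within-step causality**: the immunity model conditions only on events
  strictly before *t*. Two successes in the same step (e.g. infection and
  vaccination at the same month) do not protect against each other; the
  prior-event counts and the protective titer are snapshotted before the
  per-step exposure loop.
- **Iteration order and reproducibility**: t outer, individual ascending,
  exposure type ascending, one sequential generator seeded by `rng_seed`.
  Identical configuration and seed give byte-identical outputs. One
  Bernoulli uniform is consumed per simulated (active, non-fixed) cell
  regardless of φ, so event outcomes at one cell never shift the stream
  alignment of later cells.
- **Fixed histories** are taken verbatim, are never overwritten, and their
  φ entries are recorded as absent with a `fixed` flag raised, since no
  model produced a probability there. Fixed successes still draw kinetics
  parameters, in stream order.

## Exposure models

`simple_foe` maps the hazard to a probability with 1 − e^(−λ), guaranteeing
output in [0, 1) and monotonicity in λ. `dem_mod` composes demographic
multipliers on λ (not on the probability) before the same transform, so the
result remains a valid probability for any multiplier product; a multiplier
of zero annihilates exposure. Only the three-axis (group, time, exposure)
grid is supported as the force-of-exposure container; transmission-model
output is incorporated either through that grid or through fixed histories.

## Immunity models

- `all_successful` returns 1 — useful for pure force-of-exposure studies.
- `vacc_ifxn_simple` gates on per-type success caps and a per-type minimum
  age for vaccine exposures (age = t − birth_time in steps; the age gate is
  inclusive, so `vacc_age = 9` first allows success at age exactly 9).
  Parameters accept either mappings keyed by exposure id or R-style
  positional sequences with None/NaN for "no constraint".
- `biomarker_protection` makes success probability decrease in the current
  summed quantity of the biomarkers linked to the exposure type. The
  functional form is a design choice of this package: a two-parameter
  logistic 1 − logistic(steepness · (a − midpoint)) plus a hard-threshold
  mode (success iff a < midpoint). The threshold mode is the pointwise
  steepness → ∞ limit of the logistic mode except at a = midpoint. When the
  biomarker map carries antigenic distances, an optional `protection_sigma`
  down-weights each linked biomarker by e^(−σ·d); by default the sum is
  unweighted. The logistic is evaluated in an overflow-safe form.

## Antibody kinetics

The monophasic model sums per-event contributions
boost · max(0, 1 − wane · Δt): linear waning of each event's contribution,
floored at zero, additive across events. Linear-floored waning was chosen
as the simplest shape consistent with a "boost then wane" description and
with waning rates of order 0.003/month over a 120-month window (≈ 40%
decay); an exponential variant would differ only between anchor points and
can be registered as a user model. The biphasic model adds a second
(short-lived) component per event and reduces exactly to the monophasic one
when boost_short = 0.

Two boost modifiers are available: titer-ceiling attenuation
boost · max(0, 1 − gradient · A_current), applied at the event time before
the draw is stored (so the stored draw is the realized boost), and
cross-reactive weighting e^(−σ · distance) applied at evaluation time using
per-pair antigenic distances on the biomarker map.

### Parameter draws

Kinetics hyperparameters live in a table keyed by (exposure, biomarker,
parameter name) with mean, sd and distribution columns. Fixed effects
return the mean verbatim. Random effects draw per successful event (not
once per individual), so repeated events realize independent parameters;
fixed effects collapse that distinction. Log-normal rows are interpreted on
the natural scale and moment-matched: σ² = ln(1 + (sd/mean)²),
μ = ln(mean) − σ²/2, so sample means of many draws converge to the table's
mean column. Rows with sd = 0 or an empty distribution are degenerate
(always the mean); normal rows draw Normal(mean, sd). An `obs_sd` row with
empty ids may carry the assay noise sd.

## Observation model

True positives (A > 0 at sampling time) are detected with probability
`sensitivity`; detected values get Gaussian noise N(A, noise_sd) and are
clamped (not rejection-resampled) into the detection limits; undetected
values are reported as exactly 0 — even when the lower limit is above 0,
the false-negative code stays 0, which follows the stated reporting
contract literally and is worth remembering when tabulating values below
the limit of detection. True negatives (A = 0) are reported as 0 with
probability `specificity` and otherwise drawn uniformly from the observable
range; uniform is the minimal assumption given no stated distribution, and
it is why bounds are required whenever specificity < 1 and negatives are
sampled. The check fires at sampling time, so all-positive batches can be
observed without bounds. The discrete assay floors non-zero readouts and
clamps them into the integer range of the bounds; dilution-ladder (HAI
style) assays are represented by working in log-dilution units upstream.

"True positive" means A > 0 at the sampling time — an individual whose
titer waned to exactly zero is a true negative for the assay even if they
were once infected. The threshold-evaluation module, by contrast, defines
truth as "ever had a successful infection-type event at or before the
sampling time"; the difference between the two notions (seroreversion,
vaccination) is precisely what the sweep is designed to expose.

## Threshold evaluation

`threshold_sweep` runs replicate simulations (replicate seeds derived from
one master seed via a seed sequence), classifies each observed individual
by Y ≥ threshold (ties positive), and scores against the infection-history
truth. Sensitivity/specificity are reported per replicate and pooled
(micro-averaged across replicates), the pooled row being the headline
number. Vaccination never counts as truth-positive, so
vaccinated-uninfected individuals act as false-positive pressure at
permissive thresholds.

## Quickstart scenario defaults

The quickstart is the package's reference study: N = 100 individuals,
t = 1..120 (monthly over ten years), uniform random birth months, no
removal; infection FOE 0.01/month and vaccination FOE 0.1/month, both
boosting one IgG biomarker; caps of one infection and one vaccination,
vaccine eligibility from nine months of age; monophasic random-effects
kinetics (infection boost 4 ± 2, waning 0.0033 ± 0.0005/month; vaccination
boost 2 ± 1, waning 0.0016 ± 0.0005/month, all log-normal); continuous
assay with noise sd 0.25, sensitivity 85%, specificity 90%; everyone
sampled at month 120. The observable range is set to [0, 10] titer units:
a range is required for false-positive sampling, and 10 is comfortably
above any reachable quickstart titer (maximum ≈ one infection plus one
vaccination boost ≈ 6), so the clamp is inert for true positives.

## Synthetic data: what it does and does not show

The generator emulates staggered cohort entry, competing
infection/vaccination event streams, individual kinetic heterogeneity and
assay misclassification. It does not emulate transmission dynamics
(exposure is externally forced), waning of *protection* separate from
biomarker quantity, assay batch effects, or cross-channel noise in
multiplex panels. Tests passing on these simulations therefore validate
the bookkeeping and the stated distributional contracts — they do not
validate any particular pathogen's kinetics, which enter only through
user-supplied parameters.

## Problem sizes and tolerances

Stochastic calibration checks use 100,000 Monte-Carlo samples and three
standard errors of the relevant estimator (binomial for rates, sd/√(2n)
for the noise sd, sd/√n for means); structural invariants are asserted
exactly. Replicate-based checks use 100 quickstart runs for the immunity
gates and 20 for the vaccination-age minimum, sizes at which every
replicate contains dozens of vaccination events so the age floor is hit
with near certainty.

## Known limitations

- Exposure probabilities with λ ≳ 37 round to exactly 1.0 in double
  precision; the mathematical guarantee P(E) < 1 holds only while e^(−λ)
  is representable.
- The engine is a pure-Python event loop: ~50 ms for the quickstart
  (100 × 120 × 2 cells). Populations of 10⁵+ individuals would need a
  vectorized or compiled kernel, which is out of scope.
- One biomarker map per run; time-varying maps (antigenic drift) are
  approximated by per-pair distances, not modelled dynamically.
- The observation stage consumes random numbers in design order after the
  event loop, so changing the observation design changes the observed draws
  (but never the latent history, which is generated first).
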