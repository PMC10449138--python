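# serotrace

Individual-based simulation of serological survey data.

Serosurveys measure biomarkers of past exposure — typically antibody titers —
and are analyzed with models that must untangle several layered processes:
who was exposed and when, whether each exposure produced an immunological
response, how the resulting biomarker rose and waned, and how the assay
distorted what was finally measured. `serotrace` simulates all four layers
explicitly, so that researchers designing serological studies or validating
inference methods can generate data from a fully known ground truth.

The package is aimed at epidemiologists and biostatisticians who want to
plan sampling designs (sample sizes, sampling times, assay choices), probe
how latent immunological processes shape observed titer distributions, or
benchmark seroprevalence and force-of-infection estimators against data with
a known generative process.

## Model

For individual *i*, time step *t*, exposure type *x* (infection, vaccine
dose, ...) and biomarker *b*, the simulation composes four pluggable models:

1. **Exposure model** — probability of encountering exposure *x*:
   P(E<sub>i,t,x</sub> = 1) = h(λ<sub>g,t,x</sub>, D<sub>i</sub>), where λ is
   the force of exposure for the individual's group *g* and D<sub>i</sub> is
   demographic data. The built-in models use
   P(E = 1) = 1 − e<sup>−λ</sup>, optionally with multiplicative demographic
   modifiers on λ.
2. **Immunity model** — probability the encounter produces a measurable
   response, conditional on history:
   P(Z<sub>i,t,x</sub> = 1 | E = 1) = m(Z<sub>i,j&lt;t</sub>, Θ<sub>i</sub>,
   D<sub>i</sub>). Built-ins: always-successful; per-type event caps with
   vaccine age eligibility; and biomarker-mediated protection (logistic or
   hard-threshold in the current titer).
3. **Antibody model** — the latent biomarker quantity
   A<sub>i,t,b</sub> = f(Z<sub>i,j≤t,x</sub>, Θ<sub>i</sub>, D<sub>i</sub>)
   as a sum of per-event boost–wane contributions (monophasic or biphasic
   linear waning, floored at zero), with per-event kinetics parameters drawn
   as fixed or random effects (log-normal draws are moment-matched on the
   natural scale). Titer-ceiling boosting and antigenic-distance
   cross-reactivity are available as modifiers.
4. **Observation model** — the measured value
   Y<sub>i,t,b</sub> ~ q(A<sub>i,t,b</sub>, Θ): Gaussian assay noise,
   sensitivity/specificity misclassification, detection limits, and
   optionally discretized output.

The engine combines 1 and 2 into the per-cell success probability
φ<sub>i,t,x</sub> = P(E = 1) · P(Z = 1 | E = 1) and draws
Z<sub>i,t,x</sub> ~ Bernoulli(φ<sub>i,t,x</sub>) in a fixed iteration order
from a single seeded random stream, so every run is exactly reproducible.
User-supplied fixed immune histories (known vaccination dates, output of an
external transmission model) override the draw cell by cell.

A separate evaluation module scores seropositivity thresholds: it runs
replicate simulations, labels individuals by their true infection history,
and reports confusion matrices with pooled sensitivity and specificity per
threshold.

## Worked example

The bundled quickstart scenario simulates 100 individuals over 120 monthly
time steps: a constant monthly force of infection of 0.01 and force of
vaccination of 0.1, both boosting one IgG biomarker; at most one infection
and one vaccination per person, vaccine eligibility from nine months of age;
monophasic kinetics with log-normal random effects (infection boost mean 4,
sd 2; infection waning 0.0033/month; vaccination boost mean 2, sd 1); a
continuous assay with noise sd 0.25, 85% sensitivity, 90% specificity and
observable range 0–10; everyone sampled once at month 120.

```python
import serotrace as st

out = st.run_quickstart(rng_seed=1)
summary = st.summarize_run(out, seropositivity_threshold=1.0)
print(summary["event_counts"])      # {1: 43, 2: 84}
print(summary["n_observations"])    # 100
print(summary["seroprevalence"])    # 0.65
```

With seed 1, 43 of 100 individuals were infected and 84 vaccinated during
the decade, and 65% of the end-of-study samples read at or above a titer of
1.0 — the rest are genuinely naive, seroreverted, or false negatives of the
assay.

The same run from the shell:

```bash
serotrace quickstart --out quickstart/
serotrace simulate --config quickstart/config.yaml --out run/ --seed 1
serotrace sweep --config quickstart/config.yaml --thresholds 0.5,1,2,4 \
    --replicates 5 --out sweep/ --seed 1
```

`simulate` writes the five long-format output tables (exposure
probabilities, immune histories, latent biomarker states, kinetics draws,
observed biomarkers) plus run metadata. `sweep` prints the pooled confusion
matrix per threshold; over five replicates of the quickstart it shows the
expected trade-off — sensitivity falls from 0.86 at a threshold of 0.5 to
0.55 at 4.0 while specificity rises from 0.38 to 0.96, the low specificity
at permissive thresholds being driven by vaccinated-but-never-infected
individuals whose titers are indistinguishable from post-infection ones.

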