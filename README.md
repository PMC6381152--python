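# circschema

Circular mixture modelling of **schema updating** in continuous-report
location memory.

## The problem

In continuous-report (delayed-estimation) memory experiments, participants
study objects placed on an invisible circle and later recreate each location
with an analog dial, giving a circular error on every trial instead of a
binary hit/miss. When most items of a category cluster in a 90° arc, people
abstract a *location schema* for that category. The scientific question this
package addresses: when the schema suddenly shifts (new items appear 90°
clockwise of the old arc), do people update the schema, or do they keep
reverting to the old one — and how does overnight **consolidation** before
the shift change that? The design compares two groups of 32 participants:
one learns the shifted material immediately after initial study
(no-consolidation), the other after a 24 h delay (consolidation); everything
is re-tested 48 h later in a final test.

## The models

Responses on a trial set are modelled as a mixture of von Mises ("circular
normal") and uniform components. The standard mixture model is

p(θ) = (1 − p_g) · φ(θ; θ*, κ) + p_g / 360,

where θ* is the trial's target, κ the concentration (memory precision) and
p_g the guessing rate. The schema models add a third von Mises component
with the *same* κ, centred on a schema mean, with weight p_s:

| model | extra component centred on          | free parameters |
|-------|-------------------------------------|-----------------|
| M1/M3 | — (standard mixture)                | p_g, κ          |
| M2    | current schema mean                 | p_g, κ, p_s     |
| M4    | **original (old) schema mean**      | p_g, κ, p_s     |
| M5    | new schema mean                     | p_g, κ, p_s     |

M1/M2 are applied to final-test critical items of the *consistent* category,
M3/M4/M5 to those of the *inconsistent* (shifted) category. Models are fitted
by multi-start maximum likelihood (an EM fitter over the same likelihood
serves as an independent cross-check) and compared by AIC/BIC. Given a fit,
every response gets posterior *responsibilities* over the components; the
group difference in mean old-schema responsibility is tested with a
participant-level permutation test in which the model is refitted to each
permuted group's pooled data. Schema-strength analyses relate each
participant's initial schema strength (outside- minus inside-quadrant
absolute error at initial study) to later old-schema responding via Pearson
correlations, a Fisher r-to-z comparison of independent correlations, and a
standardized two-predictor regression.

Because the original participant data are not publicly deposited, the
package ships a first-class synthetic-data module that rebuilds the full
two-group design (4 phases, 28-trial blocks with 22 inside- and 6
outside-quadrant trials, 336 studied items per participant, a 90° clockwise
schema shift, 6×56-trial final test) and simulates responses from the
generative mixture the analysis assumes.

## Worked example

```python
import circschema as cs

# simulate a scaled-down version of the experiment (8 participants per group)
trials = cs.simulate_experiment(cs.DesignConfig(n_per_group=8, seed=7))

# pooled model comparison on the inconsistent-category critical items
from circschema.pipeline import critical_trials
nc = critical_trials(trials, "inconsistent", "no_consolidation")
co = critical_trials(trials, "inconsistent", "consolidation")
cmp = cs.compare_models(nc, ["M3", "M4", "M5"], seed=0)
print("preferred model:", cmp.preferred)
print("AIC delta (M3 - M4): %.1f" % cmp.aic_delta("M3", "M4"))
fit = cmp.fits["M4"]
print("M4 fit: p_target=%.3f p_old_schema=%.3f p_guess=%.3f kappa=%.1f"
      % (fit.p_target, fit.p_schema, fit.p_guess, fit.kappa))

# group difference in old-schema responding, permutation test
res = cs.permutation_test(nc, co, "M4", n_iter=2000, seed=7)
print("mean old-schema responsibility: %.3f (no-consolidation) vs %.3f (consolidation)"
      % (res.observed_a, res.observed_b))
print("permutation p = %.4f" % res.p_two_tailed)
```

Output:

```
preferred model: M4
AIC delta (M3 - M4): 503.2
M4 fit: p_target=0.427 p_old_schema=0.468 p_guess=0.105 kappa=14.7
mean old-schema responsibility: 0.468 (no-consolidation) vs 0.311 (consolidation)
permutation p = 0.0010
```

Read: on the no-consolidation group's pooled data the old-schema model M4
beats the standard mixture by ~500 AIC points, and nearly half of that
group's responses are attributed to the old, superseded schema mean, versus
about a third in the consolidation group — the old-schema bias the design is
built to detect; the permutation test puts the group difference well outside
the null distribution.

The same pipeline is available from the shell:

```bash
circschema simulate --config cfg.yml --out trials.csv --seed 7
circschema analyze  --config cfg.yml --trials trials.csv --outdir out/
circschema report   --outdir out/
circschema simulate --show-defaults     # full default configuration
```

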