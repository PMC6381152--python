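# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limitations of the `circschema` package.

## Circular conventions

Locations are degrees in `[0, 360)`; signed errors live in `[-180, 180)`,
closed at −180 so the antipode has a unique representative; clockwise is
negative. Densities are reported **per degree** (uniform = 1/360), so
log-likelihoods from different tools are comparable only after accounting
for the `π/180` Jacobian; internally the von Mises density is evaluated in
radians with exponentially scaled Bessel functions (`i0e`), which is stable
up to the rejection guard at κ = 700. The response dial is treated as
real-valued: the hardware quantized at 1°, but nothing in the analysis
depends on integer angles, and accepting real angles keeps the simulator and
fitted densities on a common footing.

## The mixture models

All models share a von Mises component centred on the trial's target and a
uniform guessing component; the schema models (M2, M4, M5) add one more von
Mises component centred on a schema mean. The schema component shares κ with
the target component — this is forced by the parameter count (three free
parameters for the schema models: `p_guess`, κ, `p_schema`), and is
scientifically sensible: a response recalled *to the wrong attractor* is not
expected to be less precise than one recalled to the right one. Which schema
mean the third component uses is the entire difference between M2/M4/M5:
the current mean (consistent category), the original pre-shift mean, or the
new post-shift mean, per trial, taken from the trial table's
`schema_mean_current` / `schema_mean_original` columns.

`schema_mean_current` is defined as the schema mean in effect **when the
item was studied**. Final-test rows therefore carry the at-learning mean,
which is what "new schema mean relevant at the time of learning" requires
for M5, and which keeps the inside/outside classification of a target
meaningful for re-tested items.

### Fitting

Maximum likelihood via L-BFGS-B on transformed parameters — log κ and
softmax logits for the weight simplex (target logit pinned at 0) — with an
analytic gradient: the weight gradient is the classic
responsibility-minus-weight form, the κ gradient uses the Bessel ratio
A(κ) = I₁/I₀. Defaults: 10 starts (4 deterministic spanning
low/high-guess and near-zero-schema regimes, the rest random), convergence
to ~1e-10 relative likelihood. κ is bounded in `[1e-4, 200]`: above ~200 the
von Mises is sharper than a 1° dial step, so larger values are
observationally indistinguishable; a fit ending on the bound is flagged
degenerate. `compare_models` fits the 2-parameter models first and feeds
their solutions to the 3-parameter models as extra starts, which guarantees
the likelihood nesting (M4 ≥ M3 etc.) in practice, not just in theory.

An EM fitter over the identical likelihood (closed-form weight updates;
κ via Newton-refined inversion of A(κ), Best–Fisher initialisation) serves
as an independent cross-check; tests require the two optima to agree.

### Comparison and attribution

AIC = 2k − 2 logL, BIC = k ln n − 2 logL, with n the number of scored
trials. Deltas are reported alternative-minus-preferred, so positive values
mean the preferred (schema) model wins. Posterior responsibilities are
computed at the fitted parameters; at an interior MLE the mean
responsibility of a component equals its mixing weight (the EM fixed
point), which the tests verify to 1e-3. The group statistic "mean old-schema
responsibility" is therefore interchangeable with the pooled fitted weight;
the responsibility route is primary because it extends to held-out trials.

## Permutation test

Participants are reassigned to two groups of the original sizes; the model
is refitted to each permuted group's pooled trials; the two-tailed p is the
plain proportion of permutations whose |group difference| is at least the
observed one (ties count as exceeding — conservative). The Phipson–Smyth
add-one p is reported alongside for the p = 0 case. Default 5000 iterations.

The observed statistic uses the primary multi-start optimizer per group. The
null refits run through a vectorised EM engine that updates *all*
permutations in parallel: the expensive exp(κ·cosΔ) kernels are evaluated in
float32 (parameters stay float64), each κ update is amortised over three
weight-only sub-iterations, and permutations whose parameters have stopped
moving (relative change < 1e-6) leave the active set. Warm-starting every
permutation from the all-data pooled fit is what makes 5000-iteration runs
take seconds rather than hours; since EM is monotone from a consistent
starting point and the null fits are exchangeable across permutations, this
does not bias the null distribution. Calibration is checked empirically:
type-I error at α = 0.05 sits in 0.05 ± 0.02 over 200 simulated null
replicates (500 iterations each), and power against the 0.49-vs-0.32
old-schema difference at full design scale exceeds 90%.

## Schema strength and correlational analyses

Initial schema strength = mean absolute error (outside) − mean absolute
error (inside) over a participant's Initial Study trials of one category,
in degrees. Correlations are ordinary Pearson r; two independent
correlations are compared with the Fisher r-to-z statistic
z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)) — this method reproduces
both published worked examples (z = 2.12 and z = 0.306) to ±0.005, which is
what pins it down as the right comparison. The regression z-scores all
variables and reports OLS betas (standardized), overall F and R² via
statsmodels. The 2-SD participant exclusion rule (overall final-test error
more than 2 SD worse than the sample mean) is implemented as an optional
pre-filter, off by default for synthetic data.

## The synthetic-data generator

`build_design` reproduces the study structure exactly: 2 groups × 32
participants; 4 categories in quadrants 90° apart (assignment counterbalanced
per participant under the seed); two relevant categories (one from each
natural/human-made pair) and two irrelevant fillers; per study phase 4
blocks × 28 trials, two categories intermixed at 14 trials each, 11 inside +
3 outside per category per block (preserving the 22/6 block quota and the
22:6 ratio per category); inside targets uniform within ±45° of the schema
mean, outside targets uniform on the 210° arc at least 30° beyond the
quadrant (uniformity on the allowed arcs is the maximum-entropy choice — only
the margin is specified by the design); one relevant category's mean shifted
exactly 90° clockwise in the relevant NL phase; 336 studied items per
participant, all re-tested in a 6×56 final test. Items studied in the
relevant NL phase (56 per relevant category) are the critical items. Every
participant's trials derive from an own child RNG stream, so any participant
is reproducible in isolation.

`simulate_responses` draws, per trial, a component from the cell-specific
(group × category-role × phase-kind) weights — target, old-schema, or guess —
then a von Mises (or uniform) response. Response timeouts are modelled as a
configurable missing-response probability (default 0; timeout counts were
not reported for the original task) and missing responses are excluded from
all fits. Default generative parameters are the study conditions: old-schema
weights 0.49/0.32 at final test and 0.03/0.00 at new learning for the
no-consolidation/consolidation groups (the published group-level attribution
means); elsewhere, values a practitioner would call realistic for this
paradigm, chosen once — immediate tests precise (κ = 25, 5% guesses, schema
weight 0.10 at IS and 0.08 at NL for unshifted categories), the 48 h final
test noisier (κ = 15, 10% guesses, schema weight 0.20 for consistent
categories). The IS-phase schema weight is what makes initial schema
strength positive on average, as required for the strength analyses to have
a defined sign.

### What the generator does not emulate

- **No individual differences**: weights are constant within a cell, so on
  default synthetic data the schema-strength correlations are ~0 in
  expectation. Passing correlation/regression tests therefore demonstrates
  the *statistics* (on constructed data with known effects), not that the
  generator reproduces the published individual-difference structure.
- A genuine 0.03-vs-0.00 generative difference at NL is statistically
  detectable at pooled design scale, so the NL permutation p on synthetic
  data is small — unlike the published non-significant check, where those
  two numbers were noisy estimates, not true cell means.
- No response-time structure, no practice session, no stimulus identity or
  image-level effects, no cross-category exclusion of outside targets
  (whether outside locations also avoided *other* categories' quadrants is
  unspecified; none is imposed).

## Problem sizes

The test suite runs recovery at the design's native scale (64 participants
× 56 critical trials) where that is what is being claimed, and scales
Monte-Carlo replicate counts to what a default test run can afford: 20
replicates for weight recovery, 100/50 for model-selection recovery, 200
null + 50 alternative replicates at 500 permutation iterations for
calibration. The acceptance script runs the full pipeline once at default
scale with the full 5000 permutation iterations.

## Known limitations

- Pooled fitting ignores participant heterogeneity by design (it is the
  published procedure); per-subject fits on 56 trials are noisy, which is
  inherent to the 3-parameter model at that n.
- The kappa guard at 200 means truly near-deterministic data are reported
  at the bound with a degeneracy flag rather than an unbounded estimate.
- The permutation engine assumes the model has an interior optimum on every
  permuted pool; with pathological data (e.g. all responses identical) the
  observed-fit stage will already flag degeneracy.
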