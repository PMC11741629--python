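# Methods

## The model

`casesurv` treats right-censored time-to-event data as a discrete-time
classification problem. Each subject `i` with covariates `x_i`, observed
time `t_i` (period units, possibly fractional) and event flag `δ_i` is
replicated into person-period rows `(x_i, τ, y_iτ)`:

* an **event** record contributes one row for every period `τ = 1..P`
  (the study horizon), labelled `y = 1` while the subject was alive
  (`τ ≤ ⌊t_i⌋`) and `y = 0` afterwards;
* a **censored** record contributes rows only for its observed periods
  (`min(P, ⌊t_i⌋)` rows, all `y = 1`) — nothing is asserted about the
  unobserved future.

A subject observed at a fractional time has verifiably survived only
`⌊t⌋` whole periods, so times are floored for labelling; the raw time is
kept for the evaluation metrics. The label rule is deliberately *closed*
at the event time (`τ ≤ ⌊t⌋` for events too): a subject recorded as an
event at `t = 6` counts as having survived six whole periods. The
published description of this construction states a strict inequality for
censored records, but its own worked example labels all six replicates of
a `t = 6` censored record positive; we follow the worked example and note
the discrepancy here.

Any probabilistic binary classifier `M` can then be trained on the
augmented table (covariates plus the period feature). The per-period
positive-class probability is the discrete survival function: scoring a
new subject at `τ = 1..P` yields an individual survival profile without a
proportional-hazards assumption and without forcing monotonicity — real
cohorts can show non-monotone risk (late survival bumps), which is
precisely what population product-limit curves cannot express.

### Class balance

Every record contributes `min(⌊t⌋, P)` positive rows while only events
contribute negatives, so the positive-class ratio is

    ratio(P) = Σ_i min(⌊t_i⌋, P) / (|E|·P + Σ_censored min(⌊t_i⌋, P)).

Two regimes matter. With *minimal censoring* inside the study window the
ratio drifts only slowly with `P`. With *censoring dominance* (heavy early
censoring) the augmented table is almost all-positive at short horizons
and lengthening `P` dilutes that dominance toward balance. Note the ratio
moves *toward 0.5 from above* in that regime — it does not increase with
`P`; for a fixed dataset the number of positive rows is capped while event
negatives grow linearly in `P`.

### ABBQ calibration

Raw classifier scores are calibrated by adjusted Bayesian
binning-in-quantiles: scores are sorted into `M` equal-occupancy bins;
each bin stores its empirical survival rate `p_emp = n_survive/n` and
score range, and a score `s` in bin `m` maps to
`p_emp,m + (1/M)·(s − min_m)/(max_m − min_m)`. The intra-bin term
preserves within-bin ordering. Numerical choices:

* the additive term can push the output above 1; outputs are clipped to
  [0, 1] (an optional *centered* mode subtracts `0.5/M`, off by default
  to match the published formula);
* a degenerate bin (zero score range, e.g. heavy ties) uses 0.5 as the
  within-bin position;
* out-of-range scores at prediction time clamp to the first/last bin;
* `M` is tuned by exhaustive search over a small candidate grid
  (default 5–50), minimizing expected calibration error on a held-out
  fold, ties toward smaller `M`. A black-box optimizer over the same grid
  could return nothing different, so the exhaustive search is used for
  determinism. "Calibration performance" is not pinned down in the
  published description; ECE is our choice of objective.

Calibration is fitted once on pooled all-period scores (a per-period
variant is out of scope). In the pipeline it is fitted on *out-of-fold*
scores so the map never sees scores produced by a model trained on the
same rows.

### Curves, interpolation and the KM baseline

The survival curve is the vector `S_i(τ) = p̂_iτ`, `τ = 1..P`, linearly
interpolated between integer periods with the convention `S(0) = 1`
(everyone alive at the origin, which the published formulation leaves
undefined). Queries outside `[0, P]` are range errors — extrapolation
beyond the horizon is undefined. The published interpolation formula
omits division by `τ₂ − τ₁`; consecutive periods differ by exactly one,
so it coincides with standard linear interpolation, which is what we
implement. The Kaplan-Meier product-limit estimator is implemented
in-package as the population baseline and cross-checked against
`lifelines` in the tests.

### Survival-time point estimation

Three estimators over a curve: *threshold* (last `τ` with `p̂_τ > θ`,
0 if none), *gradient* (the period where the largest one-period drop
lands, ties toward the earliest; a non-decreasing or flat curve returns
`P` since no transition is visible), and *regression* (a gradient-boosted
regressor on `D_survival` — original features plus the `P` probability
columns — trained on events only, where the target is observed).
Censored subjects are excluded from regressor training but remain
predictable. Windowed accuracy counts `|T̂ − T| ≤ window/2` by default
("a five-year window" read as a total width centred on the truth); the
looser `|T̂ − T| ≤ window` reading is exposed as a mode. Curves are
discrete, so the gradient uses raw first differences without smoothing.

### TSK-fold validation

Rows are stratified jointly on (period, label): shuffled within each
stratum by the seed, then dealt round-robin to `k` folds from a random
starting fold, so per-stratum fold sizes differ by at most one and strata
smaller than `k` spread over a subset of folds without error. Default is
row-level assignment, reproducing the original protocol — note this lets
one subject's replicates appear in both train and test folds; a
`grouped` mode assigns whole subjects (stratified by replicate signature,
i.e. by `(⌊t⌋, δ)`) and eliminates that leakage. Period intervals default
to width 1; wider intervals are available for sparse-event settings.

### iAUSC / mAUSC

For an event subject, the predicted curve is compared against the
survival step function `1[t ≤ T_i]` (closed at the event time, matching
the label rule) by absolute deviation, weighted by
`w(t) = exp(−|t − min(T_i, P)|/P)` and normalised by `∫w`. The published
equation defines this as an error (lower better) while the surrounding
comparisons treat higher as better; we report the score `1 − error` as
iAUSC and expose the raw error. Likewise the printed ideal-model sigmoid
increases with time, contradicting the accompanying figure of a
decreasing ideal survival curve; we use the decreasing sign
`1/(1 + exp(M_s (t − T_i)))` and treat the printed form as a sign typo.
Both resolutions are documented decisions, not silent corrections.
Integration is trapezoidal on a uniform grid (default step 0.01 periods;
halving the step moves smooth-curve scores by < 1e−4). mAUSC averages
iAUSC over event subjects only — censored subjects have no comparable
step function.

ECE uses 10 equal-width probability bins:
`Σ_b (n_b/n)·|mean predicted − observed rate|`.

### Temporal importance

For each period `τ`, the fitted classifier is explained on the rows
`(x_i, τ)` of the observed survivors `I_τ = {i : ⌊t_i⌋ ≥ τ}` (observed,
not model-predicted, survivors). Attributions for the default
gradient-boosted family use xgboost's exact tree-path additive
attribution (TreeSHAP), reported in log-odds margin space where the
additive decomposition is exact; other families fall back to a seeded
Monte-Carlo permutation Shapley estimate on the probability output. The
period feature's attribution is tracked separately from the covariates.
Per-period means over `I_τ` give the population profile; per-subject
trajectories are retained. Because each period re-explains up to the full
cohort, subjects are capped by a seeded subsample (default 2,000).

## The synthetic-data generator

The generator emulates the statistical structure of a long-horizon
registry cohort: standard-normal covariates act on a per-period hazard
through a logistic link, `h_i(τ) = expit(α_τ + Σ_j β_{jτ} x_{ij})`, with
optionally time-varying coefficients; follow-up is administratively
censored (entry-time censoring: `C ~ Uniform(lo, hi)`, mimicking subjects
entering a registry at different calendar times before a data freeze),
with optional geometric dropout. A subject dying in period `u` receives a
death time uniform within `(u−1, u)`, so it has survived exactly `u − 1`
whole periods; with that convention the person-period label probability,
the cohort Kaplan-Meier value, and the returned ground-truth surface
`S_i(τ) = Π_{u≤τ}(1 − h_i(u))` are all the same object, which is what
makes the recovery tests clean.

Default scenario parameters (chosen once, as what a practitioner would
call realistic for a registry-style cohort):

* `minimal_censoring`: constant hazard 0.02 per period, follow-up far
  beyond the horizon — events dominate the observable window, and the
  class ratio drifts slowly with `P`;
* `censoring_dominance`: hazard 0.05, follow-up uniform on 1–6 periods —
  heavy early censoring, class ratio near 1 at short horizons;
* the late-bump configuration raises the hazard again in the last fifth
  of the study, reproducing a second late mode in observed survival
  times (a non-monotone density);
* the sharp-event configuration makes the hazard jump from ~0 to ~1 as
  `τ` crosses a per-subject threshold `center + spread·x₀`, the regime in
  which the point estimators can be ranked cleanly.

What the generator does **not** emulate: within-subject time-varying
covariates (the feature vector is copied to every period), missingness
patterns, categorical structure of real registries, or informative
censoring. Passing recovery tests therefore demonstrate correctness of
the machinery under the stated generative model, not clinical performance
on registry data.

## Study problem sizes

The test suite and the acceptance script use cohorts of 400–4,000
subjects with horizons of 8–20 periods, 5–10 folds and up to 50,000
subjects for distributional closed-form checks — sizes at which every
property under test is comfortably resolved while a full run stays in the
minutes range on a single CPU. The default classifier is xgboost
(200 trees, depth 4, learning rate 0.1, histogram method, single thread)
with a fixed seed; single-threading makes repeated runs bit-identical.

## Known limitations

* Row-level TSK-fold reproduces the original protocol's leakage of
  subject replicates across folds; use `grouped=True` for honest
  subject-level error estimates.
* The ABBQ intra-bin term only adds to the bin estimate (mean bias
  `+0.5/M` in the default mode); the centered mode removes it at the cost
  of departing from the published formula.
* mAUSC evaluates observed events only and is weak in cohorts with few
  events.
* The regression time estimator inherits whatever bias the curves carry;
  its targets are not clipped to the horizon.
* Monte-Carlo attributions for non-tree families are noisy at small
  permutation counts; the default tree path is exact.
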