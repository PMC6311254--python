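# Methods

## Model and procedure

`lncsurv` fits a multiple linear regression of per-patient survival time on
a sparse subset of candidate lncRNA transcripts. The response *La* assigns
each patient a single positive number of days: time of death for deceased
patients, time of last follow-up for alive patients. Formally, with the
indicator pair (α, β) = (1, 0) for dead and (0, 1) for alive,
*La*ᵢ = *Dd*ᵢ·α + *Dl*ᵢ·β. Treating follow-up time as the response for
alive patients is a deliberate simplification of the procedure being
implemented — it ignores right-censoring, so coefficient estimates are
biased toward the follow-up process whenever censoring correlates with
expression. No Kaplan–Meier or Cox machinery is applied anywhere, by
design; this is a stated non-goal, not an oversight.

Candidate transcripts are those that differ between the normal and tumor
groups at raw two-sided *P* < α (default 0.001, no multiple-testing
correction — the procedure filters on raw *P*), ordered by ascending *P*
with ties broken lexicographically on transcript ID. The ordering is
load-bearing: all later machinery indexes candidates by position in it, and
the retention step privileges small positions, so the ordering must be
total and reproducible. Welch's unequal-variance *t* test is the default
screen (the conservative two-group default when no statistic is mandated);
a Mann–Whitney rank-sum alternative is selectable.

### The Γ search

The selection state is a binary inclusion vector *X* of length *C* over the
ranked candidates. One search runs *D* iterations (default 10):

* **Variation center.** *Center* = C/2 at d = 1, then
  C/2 + (C/D)·(−1)^(d−1)·⌊d/2⌋: the centers alternate around the midpoint
  with linearly growing offset, covering the index line evenly so every
  candidate falls inside some window.
* **Decay coefficient.** ξ(d) = tanh(2(D−d)/(D+1)) for early iterations,
  with a floor of exactly 0.1 at the final iteration (and from d = 10
  onward for long schedules). ξ starts at 0.927 for D = 10 — wide,
  exploratory windows — and shrinks monotonically. Two alternatives are
  selectable: a `"literal"` variant tanh(0.75(D−d)/(D+1)) with a shallower
  start, and an explicit per-iteration lookup table, because no single
  closed form reproduces every historical trace of the procedure.
* **Variation range.** The raw window is
  [Center − ξC/2, Center + ξC/2 − 1]; endpoints are rounded half-up
  (C/2 is fractional for odd C, so a rounding convention is required;
  half-up keeps the documented examples exact) and clipped to [1, C]. A
  window that clips to empty raises a degenerate-range condition and the
  iteration is skipped with a log entry rather than aborting.
* **Γ operation.** Bits inside the window are inverted.
* **Stagnation kick.** If the leading θ bits equal the previous iteration's
  leading θ bits, those positions are flipped — a deterministic escape from
  repeated states. The comparison partner at d = 1 is the seed vector.
* **Γ correction.** At most θ one-bits survive, keeping the smallest
  indices (the most significant screen *P* values). θ is fixed at
  initialization to the seed population count and never updated.
* **Stepwise reduction.** The active set is reduced by a bidirectional
  add/remove loop (below); the reduced set's AIC is compared against a
  best-so-far bulletin board, which is therefore non-increasing over
  iterations. The stepwise result does **not** overwrite the vector the
  next Γ operation acts on — the search trajectory and the quality
  assessment are decoupled, which is the only reading consistent with the
  documented two-round trace.

The search contains no random number generation: identical inputs give
identical selections, bit for bit.

The seed vector sets the bits of all candidates with screen *P* below
10⁻¹² (the ultra-significant stratum). If no candidate qualifies, the seed
falls back to the max(10, C/10) smallest-*P* candidates with a warning,
since an empty seed would make θ = 0 and stall the search.

### Stepwise-AIC reduction

"Significant effect" is operationalized as a strict AIC decrease: among all
single additions (then all single removals) the one with the largest AIC
decrease is applied, both stall flags reset on any successful move, and the
loop ends only when a forward pass and a backward pass both stall.
Strictness plus a finite subset lattice guarantees termination. Ties break
toward the smaller candidate index for determinism. The AIC convention is
the full Gaussian likelihood counting the error variance,
n·ln(2π·RSS/n) + n + 2(k+2) — comparable across common statistical
software; only differences matter for selection. A numerically perfect fit
(RSS below 10⁻¹² of the total sum of squares) is assigned −∞ so it
dominates any penalty. Rank-deficient designs are fit on a maximal
independent column basis with the effective parameter count reduced and a
warning issued. Candidate sets with fewer than three residual degrees of
freedom are truncated to the smallest-index members.

### Final fit and scores

The bulletin-board optimum becomes *Led*<sup>sub</sup>; ordinary least
squares with intercept (via statsmodels) gives Θ, standard errors, the
residual standard error on n − Δ − 1 degrees of freedom, and the overall
F-test *P* value. Collinear columns are dropped before the final fit
(smaller-*P* columns kept), and a selection larger than n − 2 is truncated
with a warning. `fit_subset` fits a prescribed subset without the search —
used for refitting a known selection and for significance calibration,
since post-selection *P* values are not uniform under the null.

The association score of transcript *j* is |Θⱼ|·SD(gⱼ), the absolute
standardized coefficient: the expected shift in predicted survival per one
standard deviation of expression. How a fitted survival model should rank
disease associations is genuinely open; the scorer is therefore a pluggable
argument of the LOOCV evaluator, with the standardized-coefficient default.

### Evaluation

ROC curves are computed over all distinct score thresholds and integrated
by the trapezoid rule, which equals the Mann–Whitney probability that a
random positive outscores a random negative (ties one half). Survival
prediction is evaluated at a fixed horizon (default 1825 days = 5 years):
dead patients label positive/negative by death time versus horizon; alive
patients label negative only when follow-up exceeds the horizon and are
otherwise excluded as indeterminate, since a fixed-horizon binary label is
undefined for them. The clinical fields record death/follow-up, not
disease-specific recurrence, so "survival" here means overall survival.
LOOCV over known association pairs withholds each pair in turn, retrains
the scorer on the rest, and pools the held-out pair (positive) against all
never-known pairs (negatives).

## Synthetic cohorts

The generator emulates the data shape the pipeline assumes: 44 normal and
176 tumor samples by default, 600 transcripts of which 481 carry a true
group shift and 60 a true survival effect. Expression is log-normal
(meanlog 1, sdlog 0.5) — nonnegative, right-skewed, RPKM-like; differential
transcripts get an additive shift of `effect_size` (default 3.0 expression
units, roughly 1.8 baseline SDs) in the tumor group. Survival is
intercept + Σⱼ coeffⱼ·exprᵢⱼ + N(0, noise_sd), rounded to whole days and
floored at 1 day; defaults are intercept 2500 days and noise 30 days.
Default coefficients come in ±pairs of equal magnitude, magnitudes uniform
on [150, 450]/√n_causal days: the pairing cancels the planted effects in
expectation so survival centers on the intercept (keeping the 1-day floor
an edge case and the default 5-year horizon inside the survival
distribution), and the 1/√n_causal scaling keeps the spread stable as the
causal set grows. A `censor_fraction` (default 0.7) of tumor samples is
marked alive, assigned independently of survival time — mirroring the
response's indifference to censoring. Ground truth (causal IDs,
coefficients, intercept) is emitted to a sidecar so tests never re-derive
it from the data.

What the generator does **not** emulate: censoring that depends on risk,
proportional-hazards event generation, expression correlation structure
(transcripts are independent), batch effects, or library-size variation.
Passing parameter-recovery tests therefore demonstrates correctness of the
selection and fitting machinery under the model's own assumptions, not
robustness on real cohorts.

## Problem sizes used in the test suite

Recovery and end-to-end tests run a 44 + 176-sample cohort with 300
transcripts (40 differential, 10 causal, effect 5.0, survival noise 10
days) — small enough for a fast default test run while preserving the
n ≫ Δ regime of the reference configuration. The null-calibration check
uses 1000 single-predictor fits at n = 100 in the acceptance suite (300 in
the unit suite). The exhaustive best-subset oracle is exercised up to 8
candidates (256 subsets).

## Known limitations

* Recovery of a planted causal transcript requires it to enter the
  candidate seed or an explored window **and** survive retention; a causal
  transcript with a mediocre differential-expression rank can be starved by
  the smallest-index retention rule. This is a property of the procedure
  itself — it presumes survival-relevant transcripts are among the most
  differentially expressed.
* The bulletin board keeps a single best reduced set; causal transcripts
  recovered only in other iterations are not merged in.
* Later historical iterations of the procedure's published trace are not
  reproducible from the stated operators (the first two rounds are, and are
  regression-tested); where the record is internally inconsistent the
  implementation follows the operator definitions.
* Survival times shorter than a day are clamped; cohorts whose linear
  predictor frequently crosses zero violate the model and bias Θ (the
  default generator makes this rare).
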