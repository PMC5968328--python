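# Methods

## The test model

The package models a rapid, automated speech-on-speech masking test built
on the Coordinate Response Measure (CRM) closed set: on each trial a target
phrase ("Ready Charlie, go to <color> <number> now") is presented with two
masking phrases, and the listener reports the color (4 alternatives) and
number (8 alternatives), so chance performance is 1/32 and a response is
correct only when both coordinates match.

A run is a *progressive track*: 20 trials at ten target-to-masker ratios
(TMRs) descending from +10 to −8 dB in 2-dB steps, two trials per level.
Because performance moves from near-ceiling to near-chance across the
ladder, the correct-response count is a direct estimate of where the
psychometric function crosses 50%:

    threshold = start_TMR − n_correct  (dB)

This count estimator is deliberate: it is order-invariant, needs no fitting,
and moves by exactly 1 dB per additional correct response, so its value is
always an integer offset from the starting TMR, bounded by
[start − total_trials, start]. Spatial release from masking (SRM) is the
per-listener, per-run difference

    SRM = threshold(colocated) − threshold(separated)  (dB),

so mean SRM over listeners equals mean colocated minus mean separated
threshold for the same run (an identity the summary code preserves by
computing release per listener first).

The two test variants differ only in geometry and calibration. The
headphone variant offers maskers colocated (0°) or at ±45° and presents the
target at 39.5 dB SL re the listener's speech reception threshold. The
loudspeaker variant offers 0°, ±15°, ±30°, ±45°, ±90°, ±135° and presents
30 dB above a *just audible level* measured by a one-up/one-down staircase:
level falls after a correct response and rises after an error; the first
two reversals, taken at a 4-dB step, are discarded, and the next six, at a
2-dB step, are averaged. A one-up/one-down rule targets the 50% point of a
symmetric psychometric function, which is what the averaged reversals
estimate. Maskers are always `target − TMR`; any configuration whose
maskers would exceed 85 dB SPL carries an exclusion flag and is never
emitted without it. Levels are treated as opaque affine dB references —
the package claims no acoustic calibration.

Staircase conventions the protocol leaves open were fixed as follows: the
reversal is logged at the turnaround level itself; the starting level
defaults to 30 dB above the (simulated) 50% point so the track begins in
the always-correct region and the discarded reversals absorb the descent;
a staircase trial uses the same color+number criterion as the main task.
A safety cap (400 trials) turns a non-terminating track — e.g. a responder
that is always correct, which never produces an upward reversal — into an
explicit non-convergence error.

## Virtual listeners

Each listener × condition has a true threshold θ (dB TMR) and responds
through a logistic psychometric function

    P(correct | x) = γ + (1 − γ − λ) · σ((x − x₀)/s)

with guess floor γ = 1/32 (the CRM closed set), lapse rate λ = 0.01, and
scale s chosen so that P(θ) = 0.5 exactly — the midpoint parameter and the
count estimator's target coincide by construction. The closed-form oracle
used throughout the tests follows directly: over the fixed ladder,
E[threshold] = start_TMR − Σ_levels trials_per_level · P(TMR_level).

Defaults, with units and rationale:

* `slope_db = 2.0` (logistic scale, dB): gives a noise-free track
  threshold SD of ≈1.5 dB, at the lower edge of the 1.5–2 dB test–retest
  spread the simulator is meant to emulate before run-to-run jitter is
  added. (`slope_db = 0` is the step-function limit, used in deterministic
  tests.)
* `run_jitter_sd_db = 1.0`: Gaussian midpoint jitter per listener × run ×
  condition, the residual session-to-session variability.
* `practice_colocated_db = 1.3`, `practice_separated_db = 2.0`: added to
  the midpoint on run 1 only, reproducing the observed pattern that run-1
  thresholds are worst and later runs are mutually stable.
* Condition intercepts: run-averaged group mean thresholds per test ×
  separation (e.g. +1.97 dB colocated and −4.04 dB at ±45° over
  headphones; −6.50 dB at ±90° in the chamber).
* `threshold_scale_db = 2.5`: between-listener SD of true thresholds,
  matching the 2–3 dB between-listener spread typical of the test's
  condition summaries.

Covariates (age; standard PTA = 0.5/1/2 kHz average; high-frequency PTA =
2/4/8 kHz average, dB HL) are drawn from a correlated Gaussian and
rejection-sampled against the cohort screen (ages 21–77 and standard PTA
< 30 dB HL for the validity-cohort factory; 22–79 and < 41 dB HL for the
test–retest factory). The default correlation structure keeps age and
standard PTA weakly related (r ≈ 0.21) — the recruitment design that makes
age and hearing effects separable — with both moderately related to
high-frequency PTA (r ≈ 0.64). The first cohort factory uses a
high-frequency-PTA SD of 14.1 dB: a spread of that order is what a
57.5 dB screening ceiling implies, and it sits close to the second
cohort's 17.26 dB.

True thresholds are `intercept + scale · (β·z + ε)`, where **z are the
covariates standardized by the *screened* population's moments** (computed
from the truncated-normal marginals). This matters: standardized effect
sizes in a study are defined on the screened sample, and standardizing by
the untruncated moments would shrink every realized coefficient (we
measured ≈0.08 attenuation of a 0.54 age effect before adopting this
convention). With correlated covariates the marginal truncation moments
are an approximation to the joint ones; with independent covariates (the
parameter-recovery configuration) they are exact. The default effect
pattern assigns age to colocated thresholds, high-frequency PTA to small
separations (15°–30°), and standard PTA to large separations, with
residual SD √(1 − βᵀRβ) so generated thresholds have unit variance on the
standardized scale.

The simulator emulates threshold-level structure only. It does not model
binaural mechanisms (ITD/ILD), glimpsing, talker confusions (wrong
responses are uniform over the 31 non-target coordinates rather than
biased toward masker coordinates), trial-to-trial learning within a run,
or listener lapses beyond a constant rate. Passing tests therefore show
that the scoring and statistics behave correctly on data with the right
covariance structure — not that real listeners behave like the generator.

## Statistical battery

* **Summaries** group thresholds by test × separation × run; release is
  computed per listener per run, then averaged. Grand means are unweighted
  means of per-run means.
* **Relative change** is the per-listener mean |run 1 − run k| for
  k = 2..K, summarized by group mean and SD; listeners with missing runs
  are excluded with a logged warning rather than imputed.
* **Repeated-measures ANOVA** is delegated to `pingouin.rm_anova` with
  Greenhouse–Geisser correction; the design must be complete and balanced
  (no imputation — unbalanced input is an explicit error). Partial η² is
  derived from the F identity F·df₁/(F·df₁ + df₂) =
  SS_effect/(SS_effect + SS_error); a hand-coded sums-of-squares + GG
  epsilon oracle on small one-way tables cross-checks the backend in the
  test suite. For a two-level factor epsilon is exactly 1 (sphericity is
  trivial).
* **Stepwise regression** mirrors SPSS defaults: response and predictors
  are z-scored, forward entry at probability-of-F .05, backward removal at
  .10, iterated to a fixed point. Excluded candidates are reported with
  their "beta-in" (coefficient and p if added to the final model), so the
  report covers all three predictors the way standard regression tables
  do. Two numerical guards exist for degenerate data: forward entry stops
  once the model's R² is within 1e-10 of 1 (no residual variance left, and
  floating-point residuals would otherwise let junk predictors "enter"),
  and a repeated selection state terminates the loop (entry/removal
  cycling). A constant covariate raises a degenerate-design error. Under
  the null, some predictor enters at roughly the familywise rate
  1 − 0.95³ ≈ 14%, which the tests check as a property of the entry
  threshold.
* **Correlation matrices** use Pearson r over all pairs with a Bonferroni
  criterion α/m (m defaults to the number of pairs; for 39 correlations at
  α = .05 the critical p is .0013). Constant variables are flagged as
  undefined instead of propagating NaN silently.

## Problem sizes and numerical choices

Monte-Carlo checks use 10,000 tracks for the closed-form threshold oracle
(3-SE agreement), 2,000 staircase runs for convergence (within 1 dB of the
50% point), and 100 replicates of n = 500 cohorts for parameter recovery
(coefficient within ±0.08 and correct predictor selected in ≥95% of
replicates) — sizes at which the sampling error of each check is several
times smaller than its tolerance. Seeds are explicit everywhere;
`simulate_study` is byte-deterministic given (cohort, schedule, seed).

## Known limitations

* The count estimator is mildly biased for midpoints near the ladder's
  edges (the ladder no longer spans ceiling to floor) and carries a small
  negative offset (≈1 dB at default slope) from the guess floor inflating
  the correct count at low TMRs; the closed-form expectation, not the raw
  midpoint, is the correct reference for simulated tracks.
* Practice offsets are recovered exactly by run differences only in the
  noise-free, step-function limit and when the offset is a multiple of the
  2-dB level spacing; otherwise the 2-dB quantization of the ladder blurs
  them, as it would in the real test.
* Release is always recomputed from threshold columns, never read from a
  precomputed release column: per-listener release averaged over a group
  equals the difference of the group's threshold means only when both are
  computed on the same listeners, so stored release columns can drift out
  of sync with their threshold columns.
* dB HL / dB SPL / dB SL are tracked symbolically; the 85 dB SPL masker cap
  is enforced on these symbolic levels.
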