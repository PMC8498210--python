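# Methods

This note records the models, parameter choices, and numerical
conventions behind `fallsway`, and what the synthetic-data tests do and
do not establish about real data.

## COP signal processing

A quiet-stance test is a two-axis COP displacement series (mediolateral,
anteroposterior; mm), nominally 100 Hz for 60 s.  Traces of other
durations are accepted with a logged warning and analyzed as measured.

Preprocessing demeans per axis by default and can apply a 4th-order
Butterworth low-pass run forward-backward (zero phase); 10 Hz is the
conventional cutoff for postural sway, but no filter is applied unless
requested, since the downstream metrics are defined on the recorded
signal.  Non-finite samples are rejected, never imputed.

Linear sway metrics: path length is the sum of absolute per-axis
increments (Euclidean increments for the planar value); mean velocity is
path length over trial duration; acceleration and jerk are second and
third derivatives by central finite differences (one-sided at the ends),
summarized as RMS.  The choice of RMS is a declared convention — the
quantities themselves are standard but the summary statistic is not
fixed by usage in the field.  These definitions make every metric
exactly homogeneous of degree 1 in trace amplitude, which the tests
assert as an exact property.

## Sway HMM

The observation sequence is the per-sample increment vector
(Δml, Δap): increments are approximately stationary over a trial while
position is not.  Emissions are diagonal Gaussians — at observation
dimension 2 a full covariance adds little and destabilizes small-state
fits.  Defaults: 3 states, 5 seeded restarts, 100 Baum–Welch iterations,
relative log-likelihood tolerance 1e-4.  Every fit checks the EM
guarantee (non-decreasing log-likelihood); restarts violating it beyond
1e-6 are discarded.

Extracted descriptors: Viterbi occupancy, the stationary distribution
(left Perron eigenvector; for a reducible chain, one recurrent class
with a logged warning), mean dwell times dt/(1 − P_ii), the transition
entropy rate −Σ_i π_i Σ_j P_ij ln P_ij, and the per-sample
log-likelihood.  Descriptors that should not depend on state labeling
(entropy rate, log-likelihood, largest emission scale) are tested for
permutation invariance.

## The stand-in balance score

The score mapping used by the commercial instrument this pipeline
mirrors is unpublished.  The package's mapping is therefore an openly
documented stand-in with the same interface and band semantics: an
instability composite Σ_j w_j (x_j − μ_j)/σ_j over six features (planar
mean velocity, RMS jerk per axis, negated HMM log-likelihood per sample,
transition entropy rate, largest-state emission scale), decile-binned
against a reference population of 1,000 simulated traces spanning
stability levels 0.15–1.0 (`analysis/00_build_score_reference.py`,
deterministic).  Weights default to 1.  The quietest reference decile
maps to score 10, the most unstable to 1; bands are 1–3 high, 4–6
moderate, 7–10 low risk.  All score-dependent conclusions in this
package are claims about this stand-in, not about any proprietary
score.

## Fall epidemiology

Conventions, chosen to match the printed formulas exactly:

* the year is 365 days (the exposure formula divides by 365, not
  365.25);
* the z-multiplier is the literal 1.96;
* retrospective exposure is one person-year per participant for the
  12-month recall, half for the 6-month recall;
* the CI uses the *normalized* prospective count
  k_norm = k_p · PY_retro / PY_pros inside the radical;
* zero prospective events give a defined point estimate with the CI
  flagged undefined (no continuity correction is invented); zero
  retrospective events are an error;
* rates and ratios print to 3 decimals, percents to 1.

Two identities are asserted on every result rather than tested once:
CI log-symmetry (√(lo·hi) = IRR to 1e-9) and
percent reduction = 100·(1 − IRR).

Matched-period comparisons take participants monitored at least 6 or
12 calendar months, count prospective falls within the first window
(boundary day inclusive), and compare raw counts — no person-year
normalization, as the periods match by construction.  A `normalize`
flag computes an alternative reading (all prospective falls over full
enrollment, rescaled by the subset's person-year ratio) for sensitivity
analysis.

The reference-cohort aggregates ship as a fixture
(`reference_cohort_ledger`).  On those inputs the fallers IRR computes
to 0.458; the externally reported 0.438 is inconsistent with its own
interval [0.213, 0.982], whose log-midpoint is 0.458.  The report
carries this as a flag and retains the computed estimate — reported
values are cross-checks here, never substitutes for computation.

### CI calibration

The closed form is validated two ways (`fallsway.calibration`):

* **Parametric bootstrap.**  Poisson counts are simulated at the
  observed rates and the sampling SE of ln IRR is estimated from the
  replicates' relative spread (std/mean per arm, in quadrature).  The
  raw log-moments of the replicates are deliberately not used:
  Var(ln K) ≈ 1/μ + 1/(2μ²) exceeds the delta-method variance at small
  counts, and the percentile interval of the raw ratio is skewed — both
  would measure properties of those estimators rather than of the CI
  under test.  Agreement within ±15% per endpoint holds for counts ≥ 5
  with exposure ratios in [0.8, 1.25]; outside that exposure range the
  closed form's normalized count makes its SE genuinely diverge from a
  plain-count bootstrap, so the comparison is run in its domain of
  validity.
* **Coverage.**  Over 2,000 simulated cohorts at a true rate ratio of
  0.5 with matched exposure (one year per participant in both periods),
  the 95% CI covers the truth ≈ 94–95% of the time.  Matched exposure
  is the appropriate regime for this check: the construction then
  reduces to the standard Poisson log-IRR interval.  When prospective
  exposure is shorter than retrospective (as in the reference cohort,
  0.73 y mean follow-up), the normalized count shrinks the SE and
  coverage drops to roughly 92% — a property of the published
  construction worth knowing when interpreting its intervals.

## Risk shifts

Baseline band from the first score; subsequent band from the median of
all later scores.  Even-count medians can land on half-integers between
bands; the declared rule — high < 3.5 ≤ moderate < 6.5 ≤ low — resolves
half-points toward the lower-risk band, consistent with reading a shift
as *entering* a band.  On integer medians this coincides exactly with
the integer band rule.  Time-to-shift is defined as days from baseline
to the first test scoring in a lower-risk band (the first band
crossing); other definitions (e.g. time to the median crossing) are
possible but not implemented.  Single-test participants are
unclassifiable and excluded from summaries with a logged count.

## Synthetic data

The stabilogram generator is a per-axis Euler–Maruyama discretization
of an Ornstein–Uhlenbeck process (mean reversion 1 s⁻¹) whose
innovation scale is `base_noise_scale / stability_level` modulated by a
3-state sticky Markov regime chain (self-transition 0.95, regime
multipliers 0.6/1.0/1.8, shared between axes, mediolateral attenuated
×0.7).  The generator is deliberately matched to the analysis HMM so
that latent structure is recoverable by construction; passing recovery
tests therefore validates the fitting machinery, not the claim that
real sway is a 3-regime OU process.  At stability 0.8 the traces show
planar mean velocities near 15 mm/s, within the range reported for
older adults in quiet stance.

The cohort generator defaults are the calibrated study conditions: 53
participants, 57% at a senior living facility (monthly testing) and 43%
at a community center (bimonthly), site ages 86.7 ± 6.0 and 72.1 ± 4.8
years, 0.70 retrospective falls/person-year, true rate ratio 0.26,
follow-up duration truncated-normal 0.73 ± 0.6 years, 42.9% of
high-risk baselines improving, and at most one prospective fall per
participant.  Retrospective falls are dated uniformly over the year
before enrollment (the last-183-day subset gives the 6-month recall);
prospective falls are Poisson in actual monitored time.  Participation
ends at the last scheduled test inside the drawn duration, so short
draws yield single-test participants with zero prospective exposure —
mirroring how open-access designs actually censor.

Score trajectories start from a baseline drawn over 1–10 (≈ 26% high /
40% moderate / 34% low risk); improvers relax exponentially toward the
moderate band with a 20-day timescale, and repeat-test variability is
modeled as occasional ±1 integer excursions (8% of tests).  That noise
model keeps the median-band classifier's false-shift rate near 0.4%,
making the configured improving fraction identifiable; real repeat
scores fluctuate more, so the generator isolates trajectory drift
rather than reproducing full test-retest noise.  The single-fall cap
mirrors the reference cohort's observation that no participant fell
more than once, but truncates the Poisson process (at null rates it
removes ≈ 20% of events); recovery and coverage studies that rely on
Poisson behavior therefore run with the cap off.

Two further generator choices matter for interpretation: improver
assignment is independent of participation duration, so the reference
observation that shifters participated about twice as long is *not*
reproduced by default — building that correlation in would bias
fraction recovery through informative censoring; and the
improving-fraction, shift-timing, and participation-length figures of
the reference study are generator calibrations, not quantities this
package can verify, since the underlying individual trajectories are
not public.

## Problem sizes

Recovery experiments use cohorts of 2,000 participants (rate-ratio
bands [0.22, 0.30] at truth 0.26 under the cap, [0.9, 1.1] at null with
the cap off, improving fraction ±0.05); the coverage study uses 2,000
cohorts of 100; bootstrap comparisons use 100,000 replicates per
configuration; sway contrasts use 200 traces per stability level.
These sizes put Monte-Carlo error comfortably inside each stated band
while keeping the full suite and the acceptance script fast on one CPU.

## Known limitations

* The score mapping is a stand-in; absolute score values are not
  comparable to any commercial instrument, only the band semantics are.
* The HMM's state count and observation definition are declared
  decisions, not reconstructions of any particular deployed model.
* The generator's fall processes are homogeneous Poisson given
  exposure; no seasonality, frailty heterogeneity beyond site, or
  fall-risk dependence of the fall rate on the concurrent score.
* Retrospective recall is simulated as exact; real 12-month recall
  under-reports falls, which would bias an IRR of this design upward
  (toward the null), not downward.
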