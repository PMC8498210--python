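# fallsway

Posturographic balance scoring and retrospective-vs-prospective
fall-rate analysis for self-monitored balance cohorts.

## The problem

Falls are the leading cause of accidental death in older adults, and
postural instability is one of their strongest modifiable correlates.
One monitoring design gives older adults open access to a force-plate
balance test: a 60 s quiet-stance trial yields a center-of-pressure
(COP) trajectory, summarized as a 1–10 *balance score* with three risk
bands (1–3 high / "red", 4–6 moderate / "yellow", 7–10 low / "green").
Each participant's 12-month fall history is collected at enrollment and
prospective falls are logged during follow-up, so the design can ask:
does self-monitoring of balance coincide with a lower fall rate?

`fallsway` implements that computational chain as a tested library:

* **`cop_signal`** — COP preprocessing (demeaning, zero-phase low-pass)
  and the linear sway metrics of posturography: path length, mean
  velocity, RMS acceleration and jerk, per axis (mediolateral /
  anteroposterior) and planar; plus a documented stand-in score mapping
  (weighted z-composite, decile-binned against a simulated reference
  population — **not** any commercial score) with the standard band
  semantics.
* **`sway_hmm`** — Gaussian hidden Markov characterization of sway
  increment dynamics (Baum–Welch fitting with seeded restarts, Viterbi
  decoding, occupancy / stationary distribution / dwell times /
  entropy rate).
* **`fall_epi`** — the epidemiological core: person-years, incidence
  rates, the incidence rate ratio with its two-tailed 95% CI, percent
  reductions, per-site strata, and matched-period subset comparisons.
* **`risk_shift`** — baseline band versus the band of the median of all
  subsequent scores, shift timing, and group summaries.
* **`synthetic_data`** — generators with known ground truth for every
  stage: regime-switching Ornstein–Uhlenbeck stabilograms and Poisson
  fall cohorts calibrated to the reference study's margins.
* **`io` / `cli`** — validating CSV/JSON readers and writers and a
  `fallsway` subcommand CLI.

## The statistics

With `n` participants, retrospective exposure is one person-year each
(12-month recall): `PY_retro = n`.  Prospective exposure sums enrollment
from first to last test: `PY_pros = Σ_i days_i / 365`.  For an event
count pair (retrospective `k_r`, prospective `k_p`):

```
IR_retro = k_r / PY_retro          IR_pros = k_p / PY_pros
IRR      = IR_pros / IR_retro      k_norm  = k_p · PY_retro / PY_pros
95% CI   = exp( ln IRR ± 1.96 · sqrt(1/k_r + 1/k_norm) )
% reduction = 100 · (k_r − k_norm) / k_r  =  100 · (1 − IRR)
```

computed separately for *falls* (events) and *fallers* (people with ≥ 1
event), with syncope-related episodes excluded before any counting.
The CI is log-symmetric about the point estimate by construction —
`sqrt(lo·hi) = IRR` — which the package asserts on every result.

## Worked example

```python
from fallsway import fall_epi, synthetic_data

ledger = synthetic_data.reference_cohort_ledger()   # n=53, 37 vs 7 falls
report = fall_epi.analyze_cohort_ledger(
    ledger, published_reference=synthetic_data.PUBLISHED_REFERENCE)
print(f"falls IRR {report.falls.irr:.3f} "
      f"[{report.falls.ci_low:.3f}-{report.falls.ci_high:.3f}], "
      f"reduction {report.falls.percent_reduction:.1f}%")
print(f"fallers IRR {report.fallers.irr:.3f} "
      f"[{report.fallers.ci_low:.3f}-{report.fallers.ci_high:.3f}]")
```

prints

```
falls IRR 0.260 [0.128-0.528], reduction 74.0%
fallers IRR 0.458 [0.213-0.982]
```

i.e. the prospective fall rate is 0.260 times the retrospective rate
(a 74.0% reduction after normalizing exposures), with a CI excluding 1;
the fallers ratio is 0.458 with a CI just excluding 1.  The report's
`notes` also flag that the externally reported fallers point estimate
(0.438) is inconsistent with its own interval, whose log-midpoint is
0.458.

The numbered scripts under `analysis/` run the full narrative on
synthetic data: `01` simulates a study-calibrated cohort, `02` scores
stabilograms across the stability range, `03` produces the rate
reports, `04` the risk-shift summary and trajectory plot, `05` the
CI-calibration studies.  Outputs land under `results/`.

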