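# Methods

## Scope and model

The package quantifies cumulative intracranial-pressure burden from
30-min-sampled postoperative ICP records (up to 72 h after decompressive
craniectomy) and relates it to a dichotomized discharge outcome (death,
mRS = 6, vs. survival, mRS < 6).  The object of interest is the piecewise-
linear interpolant of the recorded samples; every burden metric is a
functional of that interpolant:

- ICP-AUC: trapezoid rule, exact for the interpolant by construction.
- Normalized AUC: AUC / (max ICP × monitoring time).  A dimensionless
  relative burden in (0, 1] for positive traces; invariant under pressure
  rescaling.
- Dose above θ: ∫ max(ICP − θ, 0) dt, the pressure-time dose.  Crossing
  times are found by linear interpolation inside each sampling interval so
  that dose and time-above are consistent with the trapezoidal areas.
- Fraction of time above θ: time strictly above θ divided by monitored
  time.

"Above" is strict: an interval lying exactly at θ contributes neither dose
nor time.  Maximum ICP is taken over the recorded samples (identical to the
interpolant's extremum).

### Gaps and monitoring duration

Real monitors drop samples and monitoring stops at different times per
patient.  A trace is split into maximal contiguous segments wherever
consecutive samples are further apart than a gap tolerance (default 1 h,
i.e. twice the nominal interval).  Integrals and time-above are computed
per segment and summed; monitored time is the sum of segment spans.  Gaps
therefore contribute neither area nor time — interpolating across a long
gap would fabricate burden.  A trace with no segment of at least two
samples is rejected as unusable.  Duplicate timestamps are rejected rather
than averaged: ambiguity in a clinical pipeline should fail loudly.

### Normalization denominator

Two modes exist for the normalized AUC.  The default, `actual`, divides by
the patient's monitored duration, so a 50-h record is normalized by 50 h.
`fixed72` divides by the nominal 72-h window instead; it makes values
comparable on an absolute scale but understates the relative burden of
short records.  The default was chosen because monitoring duration is
informative censoring in this population (monitoring stops early for both
improvement and deterioration), and dividing a short record by 72 h mixes
burden with record length.

### Dose interpretation

"AUC above a threshold" admits two readings: the excess area
∫ max(ICP − θ, 0) dt (default, `excess`), which is the established
pressure-time-dose concept, or the full area during supra-threshold epochs
(`epoch`).  Both are implemented; they satisfy the identity
epoch = excess + θ × time-above, which is tested.

## Risk stratification

Bands on normalized AUC: low below cutoff − δ, intermediate in
[cutoff − δ, cutoff + δ), high at or above cutoff + δ, with cutoff 0.5 and
δ = 0.05.  The grey zone's width is a package choice — the underlying
observation ("outcomes do not clearly correlate near 0.5") is qualitative —
so δ is configurable.  Two flags: `certain_poor` at normalized AUC ≥ 0.6
(the region where every observed patient died) and the time rule at
> 30 % of monitored time above 20 mmHg.  Escalating cutoffs are left-closed
(≥); the time rule is strict (>), matching "more than 30 %".

## Association battery

Implemented from formulas so small-sample behaviour is explicit; SciPy
supplies only reference distributions and midranks:

- Spearman: Pearson on midranks; p from t = r√((n−2)/(1−r²)) with n−2 df.
  The t approximation is used even at n = 17 (its type-I error there is
  verified by simulation, see below).
- Pearson: product-moment r, same t-based p.
- Two-group test: Welch by default (robust to unequal variances and group
  sizes at n ≈ 17); Student's pooled-variance variant available.
- Chi-square (2×2): closed form n(ad−bc)²/(row·column products), 1 df;
  Yates correction off by default, switchable.
- Mann–Whitney U: min(U_a, U_b) convention, two-sided.  Exact p by the
  rank-sum counting recurrence when n_a + n_b ≤ 12 and there are no ties
  (verified against full enumeration); otherwise the tie-corrected normal
  approximation with continuity correction.
- ROC: tie groups collapse to one cutpoint; trapezoidal AUC, which then
  equals the concordance probability with ties counted ½ (tested to 1e-12).

No multiplicity adjustment is applied by default, mirroring raw-α reporting
in small exploratory cohorts; a Holm option exists.  Degenerate inputs
(single outcome class, zero variance) mark the affected test as
not-computable and the battery continues.

## Outcome classifiers

Random forest (100 trees, unlimited depth) and gradient boosting
(100 rounds, depth 3, learning rate 0.1), seeded, on exactly three
predictors: normalized AUC, max ICP, fraction of time above the configured
threshold.  Hyperparameters are pinned; tuning at n ≈ 17 would only fit
noise.  Default validation is leave-one-out with metrics pooled over folds
(precision, recall, harmonic-mean F1, and ROC-AUC of the pooled
out-of-fold probabilities) at a fixed probability cutoff of 0.5.
Stratified 5-fold (falling back to leave-one-out when a class has fewer
members than folds) and resubstitution ("apparent") schemes exist for
comparison.  F1 is the harmonic mean — the only definition consistent with
the triple (precision 1.00, recall 0.67, F1 0.80).  Undefined ratios are
reported as 0 with an explicit flag.

Known bias: pooled leave-one-out ROC-AUC is pessimistic under the null.
Removing a positive case from a tiny training fold lowers that fold's
predicted probability for the held-out positive, anti-correlating
predictions with labels; at n = 17 the mean null out-of-fold AUC sits near
0.39 rather than 0.5 (measured over 200 simulated null cohorts).  This is a
property of the validation scheme, not of the classifiers.

## Synthetic cohort generator

Each patient's trace is baseline + plateau-wave episodes + noise on the
nominal 0.5-h grid:

| parameter | default | meaning |
|---|---|---|
| baseline | N(12, 4) mmHg | per-patient resting post-craniectomy ICP |
| episodes | Poisson(2 per 72 h) | plateau-wave (Lundberg-A-like) events |
| amplitude | N(12, 5) mmHg, floored at 0 | episode height |
| duration | Gamma(shape 2, mean 6 h) | episode length; right-tailed, no hard floor |
| shape | raised cosine | smooth rise/fall so threshold crossings fall between samples |
| noise | N(0, 1.5) mmHg per sample | sensor noise; trace floored at 0 |
| censoring | p = 0.2, end ~ U(40, 72) h | early termination of monitoring |

Outcomes couple to the *realized* (post-noise, post-censoring) normalized
AUC: logistic link P(death) = expit(α + β·nAUC) with defaults α = −4,
β = 8, or a deterministic rule link (death iff nAUC ≥ 0.6).  Survivors get
an mRS drawn uniformly from 0–5; only the death dichotomy is analyzed.
Per-patient and outcome random streams are spawned from the single seed, so
cohorts are bit-reproducible and individual traces independently
regenerable.

What the generator does *not* emulate: CSF dynamics or autoregulation,
treatment effects on ICP, waveform-resolution structure, non-physiological
artifacts, or clinically realistic correlations between monitoring duration
and outcome.  Passing tests on synthetic cohorts therefore demonstrate
correctness of the computations and recoverability of a known coupling —
not clinical validity of any threshold.

### Generative ceiling

Under the default logistic link the label retains Bernoulli noise, so the
best possible ROC-AUC of normalized AUC against death is bounded by the
population concordance, ≈ 0.77 for the default generator parameters
(computed analytically from the realized nAUC distribution).  Observed
ROC-AUCs near 0.77 at large n mean the association stage recovers
essentially all recoverable signal.

### Null simulations

Calibration studies (type-I error of the Spearman test; null classifier
AUC) use β = 0 with α = 0.  The default α = −4 would give a ~2 % death rate
and leave most n = 17 replicates without a single death, making the tests
undefined; a balanced null is the designed study condition for calibration.
Measured type-I error of the Spearman t-approximation at n = 17, α = 0.05:
0.061 over 1000 replicates (binomial SE ≈ 0.007).

## Problem sizes and numerical checks

The test suite verifies, among others: area metrics against a Δt = 1e-3 h
midpoint-Riemann oracle on 1000 seeded traces (tolerances 1e-3 mmHg·h and
1e-4 in fractions; the oracle resolves a crossing only to Δt/2, so these
traces are slow oscillations with few crossings per record); ROC-AUC ≡
concordance on 200 tied score sets to 1e-12; exact Mann–Whitney p against
full enumeration for all splits of up to 10 observations; type-I error over
1000 null cohorts at n = 17; classifier recovery at n = 200 and null
calibration over 200 replicates at n = 17; and byte-identical reruns of the
full pipeline.  Simulation sizes (n = 200–5000 where distributional claims
are made, n = 17 where the small-cohort regime itself is the subject) were
chosen so sampling error is small relative to the asserted bands.

## Pipeline and reproducibility

`run_pipeline` consumes either CSVs or a simulation config (never both),
writes summaries, labels, association and model reports plus a manifest
with the config hash, seed, package version and SHA-256 of every output.
All writes are atomic; JSON keys are sorted; reruns of an identical config
are byte-identical.  Patients present in only one of the traces/outcomes
tables are excluded from association and modelling (complete-case
analysis), with exclusions logged.

## Limitations

- The 30-min sampling floor means brief ICP spikes are invisible; dose
  metrics are lower bounds with respect to finer sampling.
- Normalized AUC divides by the per-patient maximum, so a patient with a
  uniformly low but flat trace can score higher than one with large
  transient peaks; it must be read together with max ICP and dose.
- Small-cohort classifier metrics are seed-sensitive and the pooled-LOO
  AUC bias (above) makes null comparisons conservative.
- No confidence intervals for ROC-AUC and no survival or regression
  modelling are provided; the battery reports raw two-sided p-values.
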