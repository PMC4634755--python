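# Methods

## Scope and model

`combatmet` estimates how the three energy systems share the cost of a
round-based combat bout (default: three 2-min rounds with 1-min passive
rests, a 5-min warm-up, and a 6-min seated recovery), and quantifies
post-exercise parasympathetic reactivation, time-motion structure, and
the two-condition crossover inference over all of it.  Time is measured
in seconds from the start of round 1; all phase windows are half-open
`[start, end)` so boundary samples have a unique phase.

### Energy partitioning

For one bout with resting uptake `VO2rest` (mean over the 5 min before
the warm-up):

* **Oxidative, W_AER** (per round): trapezoidal integral of
  `max(VO2(t) − VO2rest, 0)` over the round.  Breath-by-breath data are
  linearly interpolated to a 1-s grid before any integration; the grid
  is finer than breath spacing, so the interpolation error is bounded
  by the signal's curvature, and on exponential test signals the
  integral sits within 0.5% of the closed form.  The integrand is
  floored at zero because negative instantaneous aerobic energy is
  unphysical.
* **ATP-PCr, W_PCR**: for rounds followed by a rest interval, the same
  net-VO2 integral over that 60-s interval (also floored at zero, for
  the same reason).  For the final round, the bout ends in recovery, so
  the fast component of excess post-exercise oxygen consumption stands
  in: recovery VO2 is fitted as
  `VO2(t) = baseline + A·exp(−t/τ)` and the fast-component volume is
  the analytic area `A·τ` over `[0, ∞)` — noise-robust, and exact for
  the model.  The fit is multistart nonlinear least squares (τ started
  at 20/40/80 s, non-negative bounds).  A bi-exponential extension is
  tried; it is reported only when (a) a nested-model F-test shows the
  slow term improves the fit beyond noise (p < 0.01), (b) the slow
  amplitude reaches 5% of the fast amplitude, and (c) the slow τ is
  shorter than the fit window.  Guard (c) exists because a slow term
  with τ much longer than the 6-min window is indistinguishable from
  the free baseline and silently corrupts the fast term.  Even when
  the bi model is kept, W_PCR uses the fast term only.  A flat
  recovery is flagged degenerate (amplitude 0, τ unidentifiable)
  rather than fitted.
* **Glycolytic, W_[La-]** (per round): the round's blood-lactate
  accumulation Δ[La-] (post-round value minus the value at the round's
  start; post-warm-up for round 1), converted at 3 mL O2 per kg body
  mass per mmol·L⁻¹.  Negative deltas (net clearance) contribute zero:
  energy supplied cannot be negative.

All O2 volumes convert to energy at 20.92 kJ per litre.  `W_TOTAL` is
the exact sum of the three components, and relative contributions are
percentages of it per round (undefined and flagged when a round's
total is zero).  Report tables round to one decimal, half-to-even.

One textual ambiguity is worth recording: the source protocol describes
glycolytic energy both as a per-bout quantity ("after combat") and as a
per-round table.  We implement per-round deltas, which is the only
reading consistent with the per-round table and the Δ[La-] definition.
We also do not subtract interval-phase net VO2 from the following
round's W_AER; the two phases are integrated independently.

### Heart-rate recovery and vagal reactivation

R-R intervals are converted to an instantaneous-HR tachogram
(`60000/RR` at each beat, linearly interpolated to a 1-s grid, t = 0 at
exercise cessation).  From it:

* **HRR_60s** — mean HR over the last 5 s of exercise minus the mean
  over a 5-s window at 60 s of recovery.  The placement of that window
  is not standardised; we centre it (57.5–62.5 s) for symmetry.
* **HRR_τ / HRR_amp** — `HR(t) = asymptote + amp·exp(−t/τ)` fitted to
  the 6-min recovery by multistart least squares (asymptote started at
  the minimum HR, amplitude at the range, τ at 30/60/120 s).
* **T30** — ordinary least squares of `ln HR` on time over seconds
  10–40 of recovery, natural log; `T30 = −1/slope`.  T30 is defined
  through the −1/slope identity, which only holds with the natural
  log.  The regression uses the 1-s grid samples (deterministic sample
  count) rather than beat-wise samples.  When HR is not falling the
  slope is non-negative and T30 is reported as +∞ with a flag.  For a
  signal with a non-zero asymptote T30 systematically exceeds the
  fitted τ (the log of a shifted exponential is flatter than the log
  of a pure one); this bias is a property of the index, verified
  against closed forms in the tests.
* **RMSSD_30s** — RMSSD of successive R-R differences per consecutive
  30-s recovery segment.  Beats belong to the segment containing their
  R wave; each segment's first difference pairs its first beat with
  the last beat of the preceding segment, so no successive pair is
  dropped.  Segments with fewer than 3 beats are flagged invalid.  The
  trace is then smoothed with a 3-point median filter that leaves the
  first and last segments untouched.  We apply the filter *in place*
  (each interior value is replaced by the median of the already
  smoothed left neighbour, itself, and the right neighbour): the
  sliding variant is not idempotent, while the in-place variant
  reaches a root signal in one pass, so filtering is a projection —
  a property the tests assert.
* **HR_mean / HR_peak** per round — mean of the tachogram over the
  round, and the maximum 5-s rolling mean (a 1-s spike cannot set the
  peak).

### Time-motion analysis

Bouts are coded as attack / stepping / pause events on a 0.1-s grid;
durations are held internally as integer tenths so aggregation cannot
drift.  Per round: mean and summed attack and stepping times, attack
count, and the AT:ST ratio computed from the per-round *mean*
durations (the summed-time ratio has a different scale; the
mean-duration ratio reproduces the reported 0.4–0.6 magnitude).
Overlapping events within a round are a coding error and are rejected
by name.  Inter-pass reliability is a single-measure intraclass
correlation computed from the two-way ANOVA mean squares; ICC(3,1)
(two-way mixed, consistency) is the default with ICC(2,1) (absolute
agreement) behind a flag, since reliability reports rarely state the
form.  Both match `pingouin.intraclass_corr` to 1e-9 in the tests.

### Inference

The design is a complete two-condition crossover, so every ANOVA is
fully within-subjects: condition (2) × time (k rounds or segments),
each effect tested against its own effect-by-subject interaction.
Sphericity of the time factor is assessed with Mauchly's W on the
orthonormal-contrast covariance; when violated (p < 0.05) the time and
interaction p-values are recomputed with Greenhouse–Geisser-scaled
degrees of freedom (ε clipped to [1/(k−1), 1]; ε ≡ 1 for k = 2).
Effect size is classical η² (SS_effect / SS_total); partial η² is also
reported because published tables sometimes mix the two.  Pairwise
follow-ups are Bonferroni-multiplied paired t-tests capped at 1.
Single comparisons (the four recovery indices) use a paired t with
Cohen's d_z (mean difference / SD of differences) and a 95% CI.
Kolmogorov–Smirnov (against the fitted normal) and Levene checks are
reported but never branched on: the analysis plan is complete-case
parametric, and missing cells are rejected rather than imputed.

F statistics agree with `pingouin.rm_anova` to 1e-8 and with a
brute-force cell-mean SS decomposition on random small designs; the SS
decomposition recomposes SS_total to 1e-9 relative.

## Synthetic data: what it emulates, what it does not

The generator produces the full input set with analytic ground truth.

* **VO2**: a piecewise first-order relaxation — toward
  `baseline + amplitude` (τ_on = 25 s) in rounds, back toward baseline
  (τ_off = 50 s) in rests and recovery — sampled at irregular
  gamma-distributed breath times (~30 breaths/min) with additive
  Gaussian noise (SD 80 mL·min⁻¹).  Every phase integral has a closed
  form, recorded as truth.  Defaults put round means at ≈36–38
  mL·kg⁻¹·min⁻¹ for a 71-kg athlete, inside the reported 34–44 band.
* **Heart rate**: rising round plateaus (5 bpm per round, final round
  ending at 180 bpm) and a mono-exponential recovery toward 105 bpm.
  A mono-exponential cannot simultaneously reproduce the reported
  HRR_60s (≈34–38 bpm) and the reported HRR_τ (≈160–183 s) with a
  ~75-bpm amplitude — real recoveries are bi-phasic.  The defaults
  (τ = 90 s) are chosen to land HRR_60s in its reported band; the
  generator's τ is therefore *not* in the reported HRR_τ range, and
  recovery-index tests compare against the generator's own truth, not
  the published values.  R-R jitter follows a programmed per-30-s
  RMSSD profile (4 → 12.5 ms across the 6-min recovery, the usual
  direction of vagal reactivation).
* **Lactate**: post-warm-up 2.5 mmol·L⁻¹, per-round increments
  (3.0, 1.7, 1.3) mmol·L⁻¹ — decreasing across rounds, and sized so a
  71-kg placebo bout yields per-round glycolytic energies matching the
  reported magnitudes — plus 0.3 mmol·L⁻¹ measurement noise per
  sample.  The caffeine condition adds a programmed offset to every
  round's increment, specified in kJ (default +3.6 kJ/round, the
  reported condition difference) and converted to mmol·L⁻¹ through
  each subject's own body mass, so the programmed cohort effect is
  exactly the configured value.
* **Events**: alternating stepping (mean 3.3 s) and attack (mean
  1.3 s) segments with occasional referee pauses, on the 0.1-s grid;
  ≈25–30 attacks per round.
* **Cohort**: body mass ~ N(71, 12.9) kg, subject-level scalings of
  aerobic amplitude, lactate response and HR level are shared across a
  subject's two conditions (crossover), while signal noise streams are
  independent.  All streams are split from one master seed per signal
  type, so changing one generator never perturbs another's draws.

The generator is deliberately structural, not biophysical: no
VO2-kinetics slow component during rounds, no ectopy or respiratory
sinus arrhythmia in the R-R series, no tactical structure in events,
and no RPE model.  Passing tests therefore demonstrate that the
estimators recover what the model family encodes (exponential
kinetics, programmed offsets, coded events) at realistic noise — not
that they are robust to every artefact of field recordings.

## Numerical choices

* Integration grid 1 s; windows evaluated exactly at their endpoints
  by interpolation, so half-open phase bookkeeping never loses the
  boundary sliver.
* All curve fits: `scipy.optimize.curve_fit` with bounds and fixed
  multistarts; degenerate (flat) inputs are flagged, not fitted;
  non-convergence raises carrying the best residual.
* Structurally absent ANOVA effects are clamped to exactly zero SS
  when below 1e-12 of SS_total, so "no variation → F = 0" holds in
  floating point.
* Report rounding is half-to-even at one decimal.
* Reproducibility: every stochastic routine takes a seed;
  `SeedSequence([master, stream, subject, condition])` isolates
  streams.

## Problem sizes in the shipped studies

The validation drivers use 50 cohorts of n = 10 (two conditions each)
for effect recovery, 10,000 replicates for paired-t calibration and
1,000 for RM-ANOVA calibration — sizes at which the binomial
uncertainty of an empirical rate at α = 0.05 is ≈0.002 and ≈0.007
respectively, small against the ±0.01 acceptance band.

## Known limitations

* The final-round W_PCR depends on the mono-exponential EPOC model;
  with strongly bi-phasic recoveries the fast-term-only convention
  underestimates total EPOC by design (the slow component is excluded
  deliberately, as resynthesis-unrelated).
* T30's asymptote bias means it is comparable across conditions but
  not an unbiased estimate of the recovery time constant.
* The ICC form actually used in published reliability figures is
  often unstated; ICC(3,1) vs ICC(2,1) can differ materially when
  passes disagree systematically.
* Between-condition environmental effects (temperature, humidity,
  opponent behaviour) are outside the generator's model.
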