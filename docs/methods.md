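# Methods

This note documents the generative model behind the synthetic cohorts, the
measurement conventions of the difference-wave pipeline, the statistical
procedures, and the design choices that were genuinely open.

## Synthetic sessions

One session emulates a 5-minute active auditory oddball run on a two-channel
prefrontal montage (Fp1, Fp2; 250 Hz):

* **Stimulus sequence.** 64 target tones (2,000 Hz) and 256 standards
  (750 Hz), randomized with no two consecutive targets (standard oddball
  practice; configurable off). Targets are placed by drawing 64 of the 257
  gaps around the standards uniformly without replacement, which samples the
  no-adjacency arrangements uniformly. Inter-stimulus onset intervals are
  uniform on [900, 1100] ms (the run length then matches a ~5-minute block;
  the true interval of the reference protocol is not published, so this is a
  documented default, configurable). Onsets are snapped to the 250 Hz sample
  grid, the way a trigger locked to the acquisition clock fires.
* **Background EEG.** Per channel: 1/f (pink) noise scaled to
  `noise_sd_uv` (default mean 10 µV — a realistic prefrontal amplitude) plus
  a 10 Hz alpha sinusoid of amplitude `alpha_power` (default mean 2 µV) with
  random phase. Channels share the evoked components but have independent
  noise.
* **Evoked components.** Every stimulus adds a negative Gaussian N100
  (default 2.5 µV at 100 ms, fixed 16 ms SD); every target adds a positive
  Gaussian P300 (`p300_amplitude_uv`, `p300_latency_ms`, `p300_width_ms`).
  The amplitude parameter is defined as the peak the measurement pipeline
  reads off in the noiseless case: because the pipeline's mandatory
  nine-point moving average attenuates a Gaussian bump by the analytic gain
  g(σ) = (1/9)Σₖ exp(−(4k)²/2σ²), k = −4…4, the injected raw amplitude is
  `p300_amplitude_uv / g(width)`. This makes the noiseless identity
  (measured AMP = configured amplitude, LAT = configured latency) exact and
  keeps parameter-recovery simulations unbiased.
* **Behaviour.** Each target is answered with probability `hit_rate`, each
  standard with probability `commission_rate`; latencies are ex-Gaussian
  (μ, σ, τ), re-drawn until they fall inside the (100, 1000) ms attribution
  window so a generated press stays attributable to its own stimulus.

Subject-level parameters are truncated normals per group (Bernoulli for
sex), with group means/SDs taken from the bundled reference cohort summaries
where a measure is published directly (age, education, MMSE, five SNSB
domain z-scores, hit rate = ACC/100, commission rate = NI/256, response-time
moments solved from RT = μ+τ and RTSD² = σ²+τ²). Latent waveform parameters
have no published counterpart; P300 width (55 ms CN vs 66 ms MCI SD) and the
noise level were chosen so the measured component duration and its group
difference fall in the reference range, and amplitude/latency means follow
the reference AMP/LAT rows. Correlations between subject parameters default
to zero. Truncation to parameter invariants (e.g. hit_rate ≤ 1 with CN mean
0.988) shifts the realized mean of near-boundary parameters; calibration
checks therefore compare against the analytic truncated-normal mean.

A master seed spawns per-subject `SeedSequence` children in subject order
(CN block first), each split into parameter/sequence/session streams, so
cohorts are bit-reproducible and stable under subsetting of leading
subjects.

### What the generator does not emulate

No eye-blink/EMG artifacts, drowsiness, electrode drift, or
trial-to-trial latency jitter of the P300; stimulus-parameter correlations
default to zero; alpha is a pure sinusoid. Passing tests therefore
demonstrate the correctness and calibration of the *measurement and
statistics* machinery under the stated generative model — not that the
generator reproduces every property of clinical recordings.

## Measurement pipeline

Fixed conventions: epochs are half-open [−200, 800) ms windows, 250 samples
at 4 ms, stimulus onset at index 50; baseline is the mean over [−200, 0)
(50 samples); only correct trials enter (hits for targets, correct
rejections for standards; a press is attributed to the most recent stimulus
preceding it by 100–1000 ms inclusive, first press per stimulus wins, the
rest are stray). Channel averaging, per-epoch baseline correction and
condition averaging are linear, so their order is immaterial (tested);
smoothing — a centered nine-point moving average with reflection padding —
is applied to each *averaged* trace before the difference is formed, reading
"applied to the final ERP traces" as the condition averages.

On the difference wave: the peak is the global maximum over the samples in
[300, 600] ms and must be strictly positive; T1/T2 are the nearest sign
changes before/after the peak, searched over the whole epoch (component
onset regularly precedes 300 ms), linearly interpolated between samples; an
exactly-zero sample is itself the crossing, ties broken toward the peak.
AUC integrates the piecewise-linear wave between the crossings
(trapezoidal, with the interpolated partial end segments); between
bracketing crossings of a positive peak the signed and positive-part
integrals coincide, which settles the sign question. FAL inverts the
cumulative-area equation *exactly* within the bracketing sample interval —
the cumulative of a piecewise-linear wave is piecewise quadratic, and
solving the quadratic (rather than interpolating the cumulative linearly)
is what lets closed-form test waves reproduce analytic FAL values to 1e-6.
Interval measures are exact subtractions, so T2T1 = FALT1 + T2FAL holds to
machine precision whenever a subject is valid.

Validity gates, mirroring the inclusion rules of the reference protocol:
no correct trial in either condition; no positive peak; a missing crossing
("no discernible peak"); zero hits ("no target responses"); ER > 1
("extreme errors"). Excluded subjects are listed per category in the
pipeline's exclusion ledger, and generated = included + excluded always.

## Statistics

* Pooled-variance Student t (df = n₁+n₂−2), sign convention CN − MCI,
  two-sided p; a summary-statistic form reproduces printed t values from
  printed means/SDs. Zero pooled variance with equal means gives t = 0;
  with unequal means an infinite-t flag.
* Pearson chi-squared without continuity correction (df = 1) for sex — the
  uncorrected variant reproduces the reference statistic (0.217).
* Logistic models by Newton maximum likelihood (tolerance 1e-8, ≤ 100
  iterations), Wald CIs. Predictors are z-scored over the analysis sample
  by default, so odds ratios are per SD: the reference table's OR
  magnitudes (e.g. 1.27 for a feature whose SD is hundreds of µV·ms) are
  only possible per SD, so the per-SD scale is the default and the raw
  scale remains available (`standardize=False` / `--raw-scale`). In the
  full battery a degenerate fit (perfect separation in a tiny cohort) is
  reported as a failed row rather than aborting the battery.
* Partial correlations by least-squares residualization on covariates plus
  intercept; p from t = r√((n−2−k)/(1−r²)). A variable fully explained by
  the covariates correlates 0 by convention. The inverse-correlation-matrix
  identity is kept as an independent cross-check route, and pingouin serves
  as a third-party oracle in the tests.
* α = 0.05, two-sided, no multiplicity correction; stars *** p<0.001,
  ** p<0.01, * p≤0.05, ns otherwise. Sex coded female=0/male=1, group
  CN=0/MCI=1.

## Problem sizes

The default test suite and the acceptance script run: a full 239/95
calibrated cohort (~20 s) for the direction/structure checks; 200 subjects
for parameter recovery, with per-subject noise levels spread 0.5–4 µV
(near-noiseless to moderate) so crossings exist for most subjects while the
peak estimate stays unbiased; 500 replicates at n = 334 for Wald coverage;
2,000 replicates for the t-test's type-I error; 30 replicates at n = 5,000
for odds-ratio recovery. These sizes give Monte-Carlo error comfortably
inside each check's band while keeping a full run around a minute.

## Known limitations

* Measured T1/T2 (and hence AUC, T2T1) depend on where the component sinks
  into the residual noise floor of the averaged difference wave, so their
  absolute scale varies with trial counts and noise level; only their group
  ordering is calibrated, not their absolute reference means.
* The group difference in T1 is the weakest calibrated effect (expected
  |t| ≈ 1–2 at full cohort size); its direction check can in principle flip
  under an unlucky seed.
* ER and WER summary statistics of a cohort are means of per-subject
  ratios, which exceed the ratio at the group-mean operating point
  (Jensen's inequality, skewed hit rates); reconstructions at the
  calibration point match the reference means to one printed unit.
* The reference table's MCI T2T1 (285.35) differs from the exact
  subtraction of its own T1/T2 means (285.34) by one print unit — a
  rounding artifact of the source summaries, asserted as such in the tests.
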