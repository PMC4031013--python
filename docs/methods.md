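# Methods

## Wave-intensity computation

The non-invasive wave-intensity curve is the pointwise product of the time
derivatives of the pressure-surrogate and velocity channels,
`WI(t) = dP/dt · dU/dt`, with derivatives taken as central differences on
interior samples and one-sided differences at series ends
(`numpy.gradient`). At the 5 ms echo-tracking interval the discrete
derivative of a sinusoid at heart frequency underestimates the true slope
by a factor `sinc(ω·dt)` per derivative — below 0.2% error for heart rates
up to 130 beats/min — so no smoothing is applied by default. For noisy
inputs an optional Savitzky–Golay pre-filter (window 5 samples, order 2) is
provided and is what the cohort-level analyses in the examples, tests and
acceptance script use, since differentiation amplifies white measurement
noise by `√2/(2·dt)`.

Exact invariants of the product form, enforced by tests: bilinearity
(`WI(kP, mU) = km·WI(P, U)`), annihilation by any constant input, and
time-reversal symmetry (both derivatives negate, the product is unchanged).

### Pressure calibration

The echo-tracked wall-displacement waveform is linearly rescaled **per
beat** so its minimum maps to diastolic and its maximum to systolic cuff
pressure. Whether clinical systems apply this calibration or work on raw
displacement varies by device, so both modes exist: with pressures absent
the displacement (converted mm → m) is differentiated directly and the
result flagged as displacement-based; β is then undefined (NaN).

### Beat segmentation

Feet are found on the displacement channel: upstrokes are prominent maxima
of the displacement derivative (≥40% of the global maximum, separated by at
least 0.6 periods, the period coming from the autocorrelation maximum over
lags corresponding to 30–200 beats/min); each foot is the earliest minimum
within a quarter period before its upstroke (ties break to the earliest
sample). Beats run foot-to-foot, so fragments at the recording edges are
discarded, and heart rate is `60 / median(inter-foot interval)`. With few
beats and a flat diastolic baseline the foot position carries sample-level
jitter, which makes the reported heart rate noticeably noisier than the
peak estimates (a few percent at five beats); peaks are window maxima and
are insensitive to this jitter.

### Peak detection and averaging

W1 is the WI maximum over the early-systolic window (first 40% of the
beat); W2 is the maximum of the remainder after a refractory gap of 25% of
the beat, guaranteeing `t(W1) < t(W2)`. Non-positive window maxima are
floored at zero and flagged rather than reported negative, matching the
physical reading of the two peaks as forward-wave energy. Per-beat results
are averaged over the first five complete beats by default — the
echocardiographic convention of recording and averaging five cardiac
cycles — and the ensemble size is configurable.

### β stiffness index

The study summaries report β but not its formula; the standard single-point
stiffness parameter is adopted:
`β = ln(Ps/Pd) / ((Ds − Dd)/Dd)`, with the per-beat displacement extremes
standing in for the diastolic/systolic diameters (the synthetic waveforms
ride on a 7 mm diastolic-diameter baseline so this is well defined).

## Synthetic cohort

The generator emulates the measurement situation of a two-class
dilated-cardiomyopathy study population; its defaults are the study
conditions, not tuning knobs.

**Waveform shape.** Each beat is a 20% diastolic lead followed by two
raised-cosine (Hann) lobes shared by both channels and in phase: a systolic
lobe of width `2 × upstroke_fraction` of the beat (default 0.15, i.e. the
rise occupies 15% of the beat) and a dicrotic lobe of the same width
starting 1.2 lobe-widths after systolic onset. This produces the two-peaked
WI morphology of a real ejection without a closed-loop circulation model
(explicitly out of scope). For in-phase lobes the compression peak has the
closed form `W1 = ¼·ΔP·Av·ω²` with `ω = 2π / lobe width`, which seeds the
calibration. White Gaussian noise models echo-tracking and Doppler error;
the defaults (1 µm RMS displacement, 3 mm/s velocity) reflect the
sub-sample precision of carotid echo tracking and an averaged Doppler
envelope. Real recordings differ in ways the generator deliberately omits:
beat-to-beat period variability, baseline drift, reflected-wave shoulders
and phase lag between pressure and flow — so passing tests demonstrate
correct recovery of the model's structure, not robustness to every clinical
artifact.

**Calibration.** `calibrate_params` inverts the waveform model so that the
*analyzed* noiseless peaks hit per-patient targets: the analytic first
guess is refined by a measured-ratio rescale, which is exact because the WI
curve is linear in the velocity amplitude and the second peak exactly
quadratic in the dicrotic fraction (this replaces iterative bisection — the
linearity makes one step sufficient). Targets with `W2 ≥ W1` are infeasible
for a monotone two-lobe shape and raise a calibration error. The
displacement amplitude is set from the β target
(`A = D·ln(Ps/Pd)/β`, D = 7 mm), and class-specific cuff pressures
(104/64 mmHg ambulatory, 84/60 decompensated) scale the pressure channel.

**Class distributions.** Per-patient W1 is drawn log-normal with moments
matched to the class mean ± SD (5400 ± 3500 ambulatory, 2900 ± 1200
decompensated, in mmHg·m/s³). A normal distribution is unusable here: an
SD/mean ratio of 0.65 would produce negative — physically impossible —
compression peaks. W2 targets (1900 ± 1200 / 1800 ± 900) are drawn the same
way but redrawn when they reach 90% of the patient's W1 (clipped to 0.6·W1
after 100 tries), since the shape requires W2 < W1. Heart rates are
truncated normal per class (77 ± 15 on 50–130; 89 ± 11 on 69–110
beats/min), β is truncated normal 15 ± 7 on (2, 40), and hemodynamic
covariates (PAP, PCP, cardiac index, LVEDD, LVEF, E/A) are sampled around
the class summaries for realism; they are carried as metadata only.

**Outcomes.** The composite event (cardiac death / VAD / urgent
transplant) is Bernoulli per patient: probability 0.75 when the drawn W1
lies below the 4100 mmHg·m/s³ threshold, 0.05 otherwise. The two rates are
a design choice — documented as tunable — selected so that expected cell
counts give an odds ratio of the order observed in this clinical setting
(tens); the rate ordering is validated, which makes the high-risk stratum
stochastically dominate in event incidence. A single-probability model
(rather than a time-varying hazard) mirrors a study design that reports one
odds ratio, not hazard ratios. Follow-up is truncated normal 31 ± 8 months
bounded below at 1; event-free patients are right-censored at their
follow-up time. Event types are multinomial 15:10:19 (death:VAD:HTx).
Seeds are mandatory; patient-level draws use a random stream separate from
waveform synthesis, so skipping waveform generation
(`include_waveforms=False`) leaves the drawn cohort unchanged.

## Risk stratification

* Cutoff: reference-group mean + sample SD (n−1 denominator), or directly
  from a published mean ± SD summary. Classification is `high_risk` iff
  `W1 < cutoff`; a value exactly at the cutoff is low-risk ("at or above"
  reading of the threshold).
* Odds ratio: `(a·d)/(b·c)` on the low/high × event-free/event table, with
  the Woolf log-normal CI `exp(ln OR ± z·√(1/a+1/b+1/c+1/d))` and a
  two-sided p from the log-OR z statistic. Any zero cell triggers the
  Haldane–Anscombe +0.5 correction on all four cells (flagged); with
  correction disabled a zero `b` or `c` raises. Woolf was chosen over exact
  conditional intervals because it is closed-form and matches the style of
  CI reported in this literature.
* Survival: Kaplan–Meier product-limit via lifelines, events before
  censorings at tied times; curves are reported at distinct event times
  with at-risk and event counts. No competing-risks model: the endpoint is
  the composite, and the type breakdown is reporting only.
* Group comparison: Welch unequal-variance t-test from summary statistics
  (scipy), with Satterthwaite degrees of freedom.
* Report percentages are computed (not copied) and printed to one decimal.

## Numerical and design notes

* Sampling grid: 5 ms everywhere (the echo-tracking interval); uniform
  grids validated to 1e−9 relative tolerance on read.
* Windows are half-open `[start, end)`, indices 0-based; tie-breaks are
  documented (earliest minimum for feet, first maximum for peaks).
* Heart rates whose period is not an integer number of samples make
  nominally identical beats sample at different phases; the ensemble mean
  absorbs this, but single-beat results can differ at the 0.2% level.
* Problem sizes used in the test suite and acceptance script — one
  151-patient cohort for the ambulatory class, fifty 11-patient replicates
  for the decompensated class, and 200 cohort replicates for the odds-ratio
  study — were chosen so sampling error on each reported mean is well below
  the tolerance being checked.
* All text outputs use fixed numeric formats so repeated runs are
  byte-identical under a fixed seed.

## Known limitations

* The waveform model is phenomenological: no Windkessel physics, no wave
  separation, no wave-speed estimation (all out of scope by design).
* Heart-rate estimates from few noisy beats carry foot-jitter (see above).
* The outcome model ties events to the *drawn* W1, not the analyzed one, so
  classification near the threshold attenuates the realized odds ratio
  slightly relative to the generating rates — visible when stratifying by
  analyzed W1 with a reference-derived cutoff.
* β is undefined (NaN) for uncalibrated recordings or non-positive
  displacement baselines.
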