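# nwistrat

Non-invasive wave-intensity analysis and event-risk stratification for
end-stage heart failure cohorts.

## The problem

Patients with end-stage dilated cardiomyopathy who are listed for
transplantation can deteriorate suddenly ("true decompensation") with little
warning from ejection fraction or symptoms. One informative marker is how
well the failing ventricle couples to the arterial tree. **Wave intensity**
(WI) measures that coupling in the time domain:

```
WI(t) = dP/dt · dU/dt
```

the product of the time derivatives of arterial pressure `P` and blood
velocity `U`. Measured non-invasively in the common carotid artery — with
the echo-tracked wall-displacement waveform substituting for pressure
(rescaled per beat to cuff systolic/diastolic pressure) and continuous-wave
Doppler supplying velocity at 5 ms resolution — the WI curve of each beat
shows two positive peaks:

* **W1 (compression wave)** — early-systolic maximum, the "vigor" with which
  the ventricle accelerates blood into the artery;
* **W2 (expansion wave)** — late-systolic maximum as ejection decelerates.

A truly decompensated reference group defines a risk threshold as its W1
**mean + SD** (2900 + 1200 = 4100 mmHg·m/s³ for the study summaries this
package ships as defaults). Ambulatory patients whose W1 falls below the
threshold are classified *high risk* for the composite endpoint — cardiac
death, ventricular-assist-device implantation, or urgent transplantation.
Prognostic value is quantified with a 2×2 odds ratio (Woolf log-normal CI,
Haldane–Anscombe correction for empty cells) and event-free Kaplan–Meier
curves per risk stratum. The β stiffness index
`ln(Ps/Pd) / ((Ds − Dd)/Dd)` is computed from the same beats.

Because no per-patient waveforms are publicly deposited for studies of this
kind, the package includes a first-class synthetic-cohort generator: paired
displacement/velocity waveforms shaped as two raised-cosine lobes per beat,
calibrated so the *analyzed* peaks follow the class distributions
(log-normal, moment-matched to the published mean ± SD), plus an outcome
model with high/low event rates on either side of the threshold.

## Worked example

`examples/01_wave_intensity_single_patient.py` builds one noisy recording
calibrated to true peaks W1 = 5400 / W2 = 1900 mmHg·m/s³ and analyzes it:

```
beats used        : 5
heart rate        :   72.7 beats/min
W1 compression    :    5598 mmHg·m/s³  (true 5400)
W2 expansion      :    2008 mmHg·m/s³  (true 1900)
beta stiffness    :    14.8
pressure range    : 64-104 mmHg
```

The 5-beat ensemble average recovers the true compression peak within a few
percent of measurement noise. `examples/02_cutoff_and_odds_ratio.py` shows
the threshold derivation and odds-ratio arithmetic:

```
risk threshold    : 4100 mmHg·m/s³ (mean + SD)
odds ratio        : 46.13 (95% CI 16.6-128.0, p = 1.9e-13)
```

and `examples/03_cohort_pipeline.py` runs the full simulate → analyze →
stratify chain on a 151-patient virtual cohort, printing the report
(contingency table, OR, event percentages, per-stratum survival).

The same pipeline is scriptable from the shell:

```
nwistrat run --seed 7 --n-stable 107 --n-decompensated 44 --output-dir out/
```

which writes `out/waveforms/*.csv`, `cohort.csv`, `results.csv`,
`report.txt` and the Kaplan–Meier tables.

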