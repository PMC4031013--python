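"""Virtual-cohort generator for carotid wave-intensity studies.

Emulates the measurement situation of a two-class dilated-cardiomyopathy
cohort: a large ambulatory ("stable") class and a small truly decompensated
class awaiting mechanical support.  Each virtual patient carries

* a paired carotid wall-displacement / Doppler-velocity recording sampled
  every 5 ms, shaped as two raised-cosine lobes per beat (systolic upstroke
  plus a smaller dicrotic wave) and calibrated so that the analyzed WI
  peaks hit per-patient targets drawn from the class distributions
  (log-normal, moment-matched to the class mean ± SD);
* an outcome: a composite event (cardiac death / assist-device implantation
  / urgent transplantation) drawn with a high rate when the drawn W1 falls
  below the 4100 mmHg·m/s³ decompensation threshold and a low rate
  otherwise, with truncated-normal follow-up times.

All entry points take explicit seeds; identical inputs give identical
cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.stats import truncnorm

from .errors import CalibrationError, ParameterError
from .wi import WaveformRecording, analyze_recording

__all__ = [
    "WaveformParams",
    "CohortConfig",
    "VirtualPatient",
    "generate_waveform",
    "calibrate_params",
    "generate_cohort",
    "W1_DECOMPENSATION_THRESHOLD",
]

# Decompensation threshold on the compression-wave peak (mmHg·m/s³):
# decompensated-class mean + SD (2900 + 1200).
W1_DECOMPENSATION_THRESHOLD = 4100.0

# Phase layout of one beat (fractions of the beat period): a diastolic lead
# before the systolic lobe, and the dicrotic lobe starting 1.2 lobe-widths
# after systolic onset.  Both lobes share the same width (2*upstroke_fraction).
_DIASTOLE_LEAD = 0.2
_DICROTIC_DELAY = 1.2


@dataclass(frozen=True)
class WaveformParams:
    """Shape parameters of the synthetic carotid waveform pair."""

    heart_rate: float                       # beats/min
    dt: float = 0.005                       # s (echo-tracking interval)
    n_beats: int = 6
    displacement_amplitude: float = 0.23    # mm peak-to-trough wall excursion
    upstroke_fraction: float = 0.15         # fraction of beat in systolic rise
    velocity_baseline: float = 0.01         # m/s
    velocity_amplitude: float = 0.6         # m/s
    dicrotic_amplitude_fraction: float = 0.55
    noise_sd_displacement: float = 0.001    # mm (echo-tracking precision)
    noise_sd_velocity: float = 0.003        # m/s (Doppler envelope noise)
    systolic_pressure: float = 104.0        # mmHg
    diastolic_pressure: float = 64.0        # mmHg
    diameter_baseline: float = 7.0          # mm diastolic carotid diameter

    def validate(self) -> None:
        if self.heart_rate <= 0:
            raise ParameterError("heart_rate must be positive")
        if self.dt <= 0:
            raise ParameterError("dt must be positive")
        if self.n_beats < 1:
            raise ParameterError("n_beats must be >= 1")
        for name in ("displacement_amplitude", "velocity_amplitude",
                     "dicrotic_amplitude_fraction", "noise_sd_displacement",
                     "noise_sd_velocity"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if not self.systolic_pressure > self.diastolic_pressure > 0:
            raise ParameterError("need systolic > diastolic > 0 mmHg")
        if not 0 < self.upstroke_fraction < 0.5:
            raise ParameterError("upstroke_fraction must lie in (0, 0.5)")
        width = 2.0 * self.upstroke_fraction
        if _DIASTOLE_LEAD + (1.0 + _DICROTIC_DELAY) * width > 1.0:
            raise ParameterError(
                "upstroke_fraction too large: dicrotic lobe would wrap past the beat end")
        if self.diameter_baseline <= 0:
            raise ParameterError("diameter_baseline must be positive")


@dataclass(frozen=True)
class CohortConfig:
    """Statistical structure of the two-class virtual cohort.

    WI-peak targets default to the class summaries of the study population
    (stable 5400 ± 3500 / 1900 ± 1200; decompensated 2900 ± 1200 /
    1800 ± 900 mmHg·m/s³), follow-up to 31 ± 8 months, and event types to
    the 15:10:19 death/VAD/transplant mix.
    """

    n_stable: int
    n_decompensated: int
    seed: int
    w1_target_mean_stable: float = 5400.0
    w1_target_sd_stable: float = 3500.0
    w1_target_mean_decomp: float = 2900.0
    w1_target_sd_decomp: float = 1200.0
    w2_target_mean_stable: float = 1900.0
    w2_target_sd_stable: float = 1200.0
    w2_target_mean_decomp: float = 1800.0
    w2_target_sd_decomp: float = 900.0
    event_rate_high_risk: float = 0.75
    event_rate_low_risk: float = 0.05
    followup_mean_months: float = 31.0
    followup_sd_months: float = 8.0
    event_type_weights: tuple[float, float, float] = (15.0, 10.0, 19.0)
    # Class heart-rate distributions (truncated normal), medians and ranges
    # from the study groups.
    hr_mean_stable: float = 77.0
    hr_sd_stable: float = 15.0
    hr_range_stable: tuple[float, float] = (50.0, 130.0)
    hr_mean_decomp: float = 89.0
    hr_sd_decomp: float = 11.0
    hr_range_decomp: tuple[float, float] = (69.0, 110.0)
    # Class brachial pressures used for calibration (mmHg).
    pressures_stable: tuple[float, float] = (104.0, 64.0)
    pressures_decomp: tuple[float, float] = (84.0, 60.0)
    beta_mean: float = 15.0
    beta_sd: float = 7.0
    n_beats: int = 6

    def validate(self) -> None:
        if self.n_stable < 0 or self.n_decompensated < 0:
            raise ParameterError("cohort sizes must be non-negative")
        for name in ("w1_target_sd_stable", "w1_target_sd_decomp",
                     "w2_target_sd_stable", "w2_target_sd_decomp"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        for name in ("event_rate_high_risk", "event_rate_low_risk"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1]")
        if self.event_rate_low_risk > self.event_rate_high_risk:
            raise ParameterError(
                "event_rate_low_risk must not exceed event_rate_high_risk")
        if any(w < 0 for w in self.event_type_weights) or sum(self.event_type_weights) <= 0:
            raise ParameterError("event_type_weights must be non-negative with positive sum")
        if self.followup_sd_months <= 0 or self.followup_mean_months <= 0:
            raise ParameterError("follow-up moments must be positive")

    @property
    def normalized_event_weights(self) -> np.ndarray:
        w = np.asarray(self.event_type_weights, dtype=float)
        return w / w.sum()


@dataclass
class VirtualPatient:
    """One simulated patient: recording, ground truth and outcome."""

    patient_id: str
    group: str                               # "stable" | "decompensated"
    event: bool
    event_type: str                          # "none" | "death" | "vad" | "htx"
    followup_months: float
    w1_true: float
    w2_true: float
    beta_true: float
    heart_rate: float
    recording: Optional[WaveformRecording] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.followup_months <= 0:
            raise ParameterError("followup_months must be positive")
        if self.event != (self.event_type != "none"):
            raise ParameterError("event_type must be 'none' iff event is False")


def _hann_lobe(phase: np.ndarray, start: float, width: float) -> np.ndarray:
    """Raised-cosine lobe on [start, start+width) of the unit beat phase."""
    u = (phase - start) / width
    lobe = 0.5 * (1.0 - np.cos(2.0 * np.pi * u))
    return np.where((u >= 0.0) & (u < 1.0), lobe, 0.0)


def _pulse_shape(phase: np.ndarray, params: WaveformParams) -> np.ndarray:
    width = 2.0 * params.upstroke_fraction
    shape = _hann_lobe(phase, _DIASTOLE_LEAD, width)
    shape += params.dicrotic_amplitude_fraction * _hann_lobe(
        phase, _DIASTOLE_LEAD + _DICROTIC_DELAY * width, width)
    return shape


def generate_waveform(params: WaveformParams, seed: int) -> WaveformRecording:
    """Synthesize one paired displacement/velocity recording.

    Both channels share the two-lobe pulse shape (in phase); displacement
    rides on the diastolic diameter baseline so its per-beat extremes double
    as diastolic/systolic diameters.  Additive white Gaussian noise models
    echo-tracking and Doppler measurement error.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    period = 60.0 / params.heart_rate
    n = int(round(params.n_beats * period / params.dt))
    t = np.arange(n) * params.dt
    phase = (t / period) % 1.0
    shape = _pulse_shape(phase, params)
    disp = params.diameter_baseline + params.displacement_amplitude * shape
    vel = params.velocity_baseline + params.velocity_amplitude * shape
    if params.noise_sd_displacement > 0:
        disp = disp + rng.normal(0.0, params.noise_sd_displacement, n)
    if params.noise_sd_velocity > 0:
        vel = vel + rng.normal(0.0, params.noise_sd_velocity, n)
    return WaveformRecording(
        dt=params.dt, time=t, displacement=disp, velocity=vel,
        systolic_pressure=params.systolic_pressure,
        diastolic_pressure=params.diastolic_pressure)


def _analytic_velocity_amplitude(w1: float, pulse_pressure: float,
                                 heart_rate: float, upstroke_fraction: float) -> float:
    """Closed-form first guess: W1 = 0.25 · ΔP · Av · ω² for in-phase lobes."""
    period = 60.0 / heart_rate
    omega = 2.0 * np.pi / (2.0 * upstroke_fraction * period)
    return w1 / (0.25 * pulse_pressure * omega ** 2)


def _measure_noiseless(params: WaveformParams) -> tuple[float, float]:
    clean = replace(params, noise_sd_displacement=0.0, noise_sd_velocity=0.0)
    result = analyze_recording(generate_waveform(clean, seed=0))
    return result.w1, result.w2


def calibrate_params(w1_target: float, w2_target: float, heart_rate: float,
                     systolic_pressure: float = 104.0,
                     diastolic_pressure: float = 64.0,
                     beta_target: float = 15.0,
                     dt: float = 0.005, n_beats: int = 6,
                     upstroke_fraction: float = 0.15,
                     noise_sd_displacement: float = 0.001,
                     noise_sd_velocity: float = 0.003) -> WaveformParams:
    """Invert the waveform model so analysis recovers the requested peaks.

    Starts from the closed-form relation W1 ≈ 0.25·ΔP·Av·ω² (ω the lobe
    angular frequency), then removes the residual discretization error by a
    measured-ratio rescale — exact because the WI curve is linear in the
    velocity amplitude and the 2nd peak quadratic in the dicrotic fraction.
    The displacement amplitude is set so the β stiffness index equals
    ``beta_target``.
    """
    if w1_target <= 0 or w2_target <= 0:
        raise CalibrationError("peak targets must be positive")
    if w2_target >= w1_target:
        raise CalibrationError(
            "w2_target must be below w1_target for the two-lobe pulse shape")
    if not systolic_pressure > diastolic_pressure > 0:
        raise CalibrationError("need systolic > diastolic > 0 mmHg")
    if beta_target <= 0:
        raise CalibrationError("beta_target must be positive")

    pulse_pressure = systolic_pressure - diastolic_pressure
    baseline = 7.0
    disp_amp = baseline * math.log(systolic_pressure / diastolic_pressure) / beta_target
    vel_amp = _analytic_velocity_amplitude(w1_target, pulse_pressure,
                                           heart_rate, upstroke_fraction)
    dicro = math.sqrt(w2_target / w1_target)
    params = WaveformParams(
        heart_rate=heart_rate, dt=dt, n_beats=n_beats,
        displacement_amplitude=disp_amp, upstroke_fraction=upstroke_fraction,
        velocity_amplitude=vel_amp, dicrotic_amplitude_fraction=dicro,
        noise_sd_displacement=noise_sd_displacement,
        noise_sd_velocity=noise_sd_velocity,
        systolic_pressure=systolic_pressure,
        diastolic_pressure=diastolic_pressure,
        diameter_baseline=baseline)

    m1, m2 = _measure_noiseless(params)
    if m1 <= 0 or m2 <= 0:
        raise CalibrationError("noiseless analysis found no positive peaks")
    vel_amp *= w1_target / m1
    dicro *= math.sqrt(w2_target / (m2 * (w1_target / m1)))
    if not dicro < 0.95:
        raise CalibrationError(
            "w2_target too close to w1_target: dicrotic wave would rival the systolic lobe")
    return replace(params, velocity_amplitude=vel_amp,
                   dicrotic_amplitude_fraction=dicro)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched (mu, sigma) of a log-normal with given mean and SD."""
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - 0.5 * sigma2, math.sqrt(sigma2)


def _truncnorm_rvs(rng, mean, sd, lower, upper=np.inf, size=None):
    a = (lower - mean) / sd
    b = (upper - mean) / sd if np.isfinite(upper) else np.inf
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _draw_metadata(rng: np.random.Generator, group: str) -> dict:
    """Hemodynamic covariates sampled around the class summaries."""
    if group == "stable":
        vals = dict(pap_mean=(27.0, 11.0), pcp=(18.0, 10.0), ci=(2.4, 0.81),
                    lvedd=(72.0, 10.0), lvef=(20.0, 6.0), e_a=(1.3, 0.5))
    else:
        vals = dict(pap_mean=(36.0, 6.0), pcp=(27.0, 3.3), ci=(2.0, 0.3),
                    lvedd=(75.0, 8.0), lvef=(19.0, 3.0), e_a=(1.8, 0.8))
    out = {}
    for key, (m, s) in vals.items():
        out[key] = float(_truncnorm_rvs(rng, m, s, 0.1 * m))
    return out


def _draw_w2(rng: np.random.Generator, w1: float, mu: float, sigma: float) -> float:
    # the two-lobe shape needs W2 strictly below W1
    for _ in range(100):
        w2 = float(rng.lognormal(mu, sigma))
        if w2 < 0.9 * w1:
            return w2
    return 0.6 * w1


def generate_cohort(config: CohortConfig,
                    include_waveforms: bool = True) -> list[VirtualPatient]:
    """Generate the full two-class virtual cohort.

    Per patient: W1/W2 peak targets are drawn from the class log-normal
    distributions, the waveform is calibrated to hit them, and the composite
    event is Bernoulli with the high-risk rate when the drawn W1 falls below
    the 4100 mmHg·m/s³ threshold.  Patient-level draws are identical whether
    or not waveforms are synthesized (separate random streams), so
    ``include_waveforms=False`` is a fast mode for outcome-level studies.
    """
    config.validate()
    scalar_rng = np.random.default_rng([config.seed, 0])
    seed_rng = np.random.default_rng([config.seed, 1])
    weights = config.normalized_event_weights
    patients: list[VirtualPatient] = []

    groups = (
        ("stable", "S", config.n_stable,
         config.w1_target_mean_stable, config.w1_target_sd_stable,
         config.w2_target_mean_stable, config.w2_target_sd_stable,
         config.hr_mean_stable, config.hr_sd_stable, config.hr_range_stable,
         config.pressures_stable),
        ("decompensated", "D", config.n_decompensated,
         config.w1_target_mean_decomp, config.w1_target_sd_decomp,
         config.w2_target_mean_decomp, config.w2_target_sd_decomp,
         config.hr_mean_decomp, config.hr_sd_decomp, config.hr_range_decomp,
         config.pressures_decomp),
    )
    for (group, prefix, n, w1_mean, w1_sd, w2_mean, w2_sd,
         hr_mean, hr_sd, hr_range, pressures) in groups:
        mu1, s1 = _lognormal_params(w1_mean, w1_sd)
        mu2, s2 = _lognormal_params(w2_mean, w2_sd)
        ps, pd = pressures
        for i in range(n):
            hr = float(_truncnorm_rvs(scalar_rng, hr_mean, hr_sd, *hr_range))
            w1 = float(scalar_rng.lognormal(mu1, s1))
            w2 = _draw_w2(scalar_rng, w1, mu2, s2)
            beta = float(_truncnorm_rvs(scalar_rng, config.beta_mean,
                                        config.beta_sd, 2.0, 40.0))
            high_risk = w1 < W1_DECOMPENSATION_THRESHOLD
            rate = config.event_rate_high_risk if high_risk else config.event_rate_low_risk
            event = bool(scalar_rng.random() < rate)
            if event:
                event_type = ["death", "vad", "htx"][int(scalar_rng.choice(3, p=weights))]
            else:
                scalar_rng.choice(3, p=weights)  # keep the stream aligned
                event_type = "none"
            followup = float(_truncnorm_rvs(scalar_rng, config.followup_mean_months,
                                            config.followup_sd_months, 1.0))
            metadata = _draw_metadata(scalar_rng, group)
            waveform_seed = int(seed_rng.integers(2 ** 31))
            recording = None
            if include_waveforms:
                params = calibrate_params(
                    w1, w2, hr, systolic_pressure=ps, diastolic_pressure=pd,
                    beta_target=beta, n_beats=config.n_beats)
                rec = generate_waveform(params, seed=waveform_seed)
                pid = f"{prefix}{i + 1:03d}"
                recording = WaveformRecording(
                    dt=rec.dt, time=rec.time, displacement=rec.displacement,
                    velocity=rec.velocity, systolic_pressure=rec.systolic_pressure,
                    diastolic_pressure=rec.diastolic_pressure, patient_id=pid)
            patients.append(VirtualPatient(
                patient_id=f"{prefix}{i + 1:03d}", group=group, event=event,
                event_type=event_type, followup_months=followup,
                w1_true=w1, w2_true=w2, beta_true=beta, heart_rate=hr,
                recording=recording, metadata=metadata))
    return patients
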