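"""Non-invasive wave-intensity (WI) core.

Wave intensity is the product of the time derivatives of arterial pressure
and blood velocity, ``WI(t) = dP/dt * dV/dt``.  In the non-invasive variant
implemented here the pressure waveform is a carotid wall-displacement curve
from ultrasound echo tracking, linearly rescaled per beat to brachial
systolic/diastolic pressure.  The WI curve of a healthy ejection shows two
positive peaks: an early-systolic *compression wave* (W1), generated as the
ventricle accelerates blood into the artery, and a late-systolic *expansion
wave* (W2) as ejection decelerates.  W1 is the prognostic quantity of
interest; the β stiffness index is computed from the same beat as
``ln(Ps/Pd) / ((Ds - Dd)/Dd)``.

Units follow clinical convention: pressure mmHg, velocity m/s, time s, so
WI peaks are in mmHg·m/s³.  When no calibration pressures are available the
displacement channel (mm) is converted to metres and differentiated as-is;
results are then flagged as displacement-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.signal import correlate, find_peaks, savgol_filter

from .errors import (
    AnalysisError,
    CalibrationError,
    DetectionError,
    DomainError,
    InputError,
    ParameterError,
    SegmentationError,
)

__all__ = [
    "WaveformRecording",
    "BeatWindow",
    "PeakPair",
    "WIBeatResult",
    "WIPatientResult",
    "estimate_period",
    "segment_beats",
    "calibrate_pressure",
    "compute_wi_curve",
    "detect_peaks",
    "compute_beta",
    "analyze_beats",
    "analyze_recording",
]

MM_TO_M = 1e-3


@dataclass(frozen=True)
class WaveformRecording:
    """Paired displacement/velocity time series for one patient.

    ``displacement`` is the echo-tracking wall-displacement waveform in mm
    (the pressure surrogate); ``velocity`` is Doppler blood velocity in m/s.
    Optional cuff pressures enable per-beat pressure calibration.
    """

    dt: float
    time: np.ndarray
    displacement: np.ndarray
    velocity: np.ndarray
    systolic_pressure: Optional[float] = None
    diastolic_pressure: Optional[float] = None
    patient_id: str = ""

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        disp = np.asarray(self.displacement, dtype=float)
        vel = np.asarray(self.velocity, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "displacement", disp)
        object.__setattr__(self, "velocity", vel)
        if self.dt <= 0:
            raise ParameterError("dt must be positive")
        if not (len(time) == len(disp) == len(vel)):
            raise InputError("time, displacement and velocity must have equal length")
        if len(time) < 3:
            raise InputError("recording needs at least 3 samples")
        steps = np.diff(time)
        if np.any(steps <= 0):
            raise InputError("time must be strictly increasing")
        if not np.allclose(steps, self.dt, rtol=1e-9, atol=1e-12):
            raise InputError("time grid is not uniform at the declared dt")
        if self.systolic_pressure is not None and self.diastolic_pressure is not None:
            if not self.systolic_pressure > self.diastolic_pressure > 0:
                raise ParameterError("need systolic > diastolic > 0 mmHg")

    @property
    def n_samples(self) -> int:
        return len(self.time)

    @property
    def duration(self) -> float:
        return self.n_samples * self.dt

    @property
    def has_pressures(self) -> bool:
        return self.systolic_pressure is not None and self.diastolic_pressure is not None


@dataclass(frozen=True)
class BeatWindow:
    """Half-open sample window [start, end) of one cardiac beat.

    ``foot`` is the diastolic minimum preceding the systolic upstroke;
    windows produced by :func:`segment_beats` start at their foot.
    """

    start: int
    end: int
    foot: int

    def __post_init__(self) -> None:
        if not (self.start <= self.foot < self.end):
            raise InputError("need start <= foot < end")
        if self.end - self.start < 10:
            raise InputError("beat window shorter than 10 samples")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PeakPair:
    """W1/W2 peak heights (mmHg·m/s³) and times (s from beat foot)."""

    w1: float
    w1_time: float
    w2: float
    w2_time: float
    w1_floored: bool = False
    w2_floored: bool = False

    @property
    def warning(self) -> bool:
        return self.w1_floored or self.w2_floored


@dataclass(frozen=True)
class WIBeatResult:
    """Per-beat WI summary: peaks, β, and pressure/velocity extrema."""

    w1: float
    w1_time: float
    w2: float
    w2_time: float
    beta: float
    p_max: float
    p_min: float
    v_max: float
    v_min: float
    warning: bool = False


@dataclass(frozen=True)
class WIPatientResult:
    """Ensemble-averaged WI result for one patient.

    Fields are means of the per-beat values over the first ``n_beats_used``
    complete beats; ``calibrated`` records whether displacement was rescaled
    to cuff pressures (if False, w1/w2 are displacement-based and β is NaN).
    """

    patient_id: str
    n_beats_used: int
    heart_rate: float
    w1: float
    w2: float
    beta: float
    p_max: float
    p_min: float
    v_max: float
    v_min: float
    calibrated: bool = True


def estimate_period(x: np.ndarray, dt: float, min_hr: float = 30.0,
                    max_hr: float = 200.0) -> int:
    """Dominant period of a quasi-periodic signal, in samples.

    Uses the autocorrelation maximum restricted to lags compatible with
    heart rates in [min_hr, max_hr] beats/min.
    """
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    if np.allclose(x, 0.0):
        raise SegmentationError("signal is constant; no period")
    ac = correlate(x, x, mode="full")[len(x) - 1:]
    lo = max(1, int(round(60.0 / max_hr / dt)))
    hi = min(len(ac) - 1, int(round(60.0 / min_hr / dt)))
    if hi <= lo:
        raise SegmentationError("recording too short to estimate a cardiac period")
    return lo + int(np.argmax(ac[lo:hi + 1]))


def segment_beats(recording: WaveformRecording) -> list[BeatWindow]:
    """Segment a recording into complete beats on the displacement channel.

    Upstrokes are located as prominent maxima of the displacement
    derivative; each beat foot is the earliest minimum within a quarter
    period before its upstroke.  Windows run foot-to-foot, so partial beats
    at the recording edges are discarded.
    """
    if recording.duration < 2.0:
        raise SegmentationError("recording shorter than 2 s")
    disp = recording.displacement
    period = estimate_period(disp, recording.dt)
    slope = np.gradient(disp, recording.dt)
    max_slope = slope.max()
    if max_slope <= 0:
        raise SegmentationError("no rising displacement edge found")
    upstrokes, _ = find_peaks(slope, height=0.4 * max_slope,
                              distance=max(1, int(0.6 * period)))
    if len(upstrokes) < 2:
        raise SegmentationError("fewer than one complete beat")
    back = max(1, int(round(0.25 * period)))
    feet: list[int] = []
    for u in upstrokes:
        lo = max(0, u - back)
        foot = lo + int(np.argmin(disp[lo:u + 1]))  # ties -> earliest sample
        if not feet or foot > feet[-1]:
            feet.append(foot)
    windows = []
    for s, e in zip(feet[:-1], feet[1:]):
        if e - s >= max(10, int(0.5 * period)):
            windows.append(BeatWindow(start=s, end=e, foot=s))
    if not windows:
        raise SegmentationError("fewer than one complete beat")
    return windows


def heart_rate_from_beats(beats: Sequence[BeatWindow], dt: float) -> float:
    """Heart rate in beats/min from the median inter-foot interval."""
    feet = np.array([b.foot for b in beats] + [beats[-1].end])
    return 60.0 / (float(np.median(np.diff(feet))) * dt)


def calibrate_pressure(displacement: np.ndarray,
                       systolic_pressure: Optional[float] = None,
                       diastolic_pressure: Optional[float] = None) -> np.ndarray:
    """Rescale one beat of displacement to a pressure waveform (mmHg).

    The beat minimum maps to diastolic and the maximum to systolic pressure.
    With either pressure absent the displacement is returned unchanged
    (analysis then proceeds on displacement units).
    """
    disp = np.asarray(displacement, dtype=float)
    if systolic_pressure is None or diastolic_pressure is None:
        return disp.copy()
    if not systolic_pressure > diastolic_pressure:
        raise CalibrationError("systolic pressure must exceed diastolic")
    lo, hi = float(disp.min()), float(disp.max())
    if hi - lo <= 0:
        raise CalibrationError("displacement is constant within the beat")
    return diastolic_pressure + (systolic_pressure - diastolic_pressure) * (disp - lo) / (hi - lo)


def compute_wi_curve(pressure: np.ndarray, velocity: np.ndarray, dt: float,
                     smooth: bool = False, window: int = 5,
                     polyorder: int = 2) -> np.ndarray:
    """Wave-intensity curve ``(dP/dt)·(dV/dt)``, same length as the inputs.

    Derivatives are central differences on interior points and one-sided at
    the ends.  Optional Savitzky–Golay pre-smoothing (off by default) tames
    derivative noise on noisy recordings.
    """
    p = np.asarray(pressure, dtype=float)
    v = np.asarray(velocity, dtype=float)
    if p.shape != v.shape:
        raise InputError("pressure and velocity lengths differ")
    if p.ndim != 1 or len(p) < 3:
        raise InputError("need 1-D series of length >= 3")
    if dt <= 0:
        raise ParameterError("dt must be positive")
    if smooth and len(p) >= window:
        p = savgol_filter(p, window, polyorder)
        v = savgol_filter(v, window, polyorder)
    return np.gradient(p, dt) * np.gradient(v, dt)


def detect_peaks(wi: np.ndarray, beat: BeatWindow, dt: float,
                 early_fraction: float = 0.4,
                 refractory_fraction: float = 0.25) -> PeakPair:
    """Locate the compression (W1) and expansion (W2) peaks in one beat.

    W1 is the WI maximum in the early-systolic window covering the first
    ``early_fraction`` of the beat; W2 is the maximum of the remainder,
    separated from W1 by a refractory gap of ``refractory_fraction`` of the
    beat.  Non-positive window maxima are floored at 0 and flagged.
    """
    wi = np.asarray(wi, dtype=float)
    if beat.end > len(wi):
        raise InputError("beat window exceeds WI series")
    length = len(beat)
    gap = int(round(refractory_fraction * length))
    if length <= gap:
        raise DetectionError("beat shorter than the refractory gap")
    early_end = beat.start + max(1, int(round(early_fraction * length)))
    early = wi[beat.start:early_end]
    i1 = beat.start + int(np.argmax(early))
    w1 = float(wi[i1])
    w1_floored = w1 <= 0
    w1 = max(w1, 0.0)

    late_start = i1 + gap
    if late_start >= beat.end:
        return PeakPair(w1, (i1 - beat.foot) * dt, 0.0,
                        (beat.end - 1 - beat.foot) * dt, w1_floored, True)
    late = wi[late_start:beat.end]
    i2 = late_start + int(np.argmax(late))
    w2 = float(wi[i2])
    w2_floored = w2 <= 0
    w2 = max(w2, 0.0)
    return PeakPair(w1, (i1 - beat.foot) * dt, w2, (i2 - beat.foot) * dt,
                    w1_floored, w2_floored)


def compute_beta(p_systolic: float, p_diastolic: float,
                 d_systolic: float, d_diastolic: float) -> float:
    """β stiffness index: ``ln(Ps/Pd) / ((Ds − Dd)/Dd)`` (dimensionless)."""
    if p_systolic <= 0 or p_diastolic <= 0:
        raise DomainError("pressures must be positive")
    if d_diastolic <= 0:
        raise DomainError("diastolic diameter must be positive")
    if d_systolic <= d_diastolic:
        raise DomainError("systolic diameter must exceed diastolic diameter")
    return math.log(p_systolic / p_diastolic) / ((d_systolic - d_diastolic) / d_diastolic)


def analyze_beats(recording: WaveformRecording, beats: Sequence[BeatWindow],
                  smooth: bool = False, early_fraction: float = 0.4,
                  refractory_fraction: float = 0.25) -> list[WIBeatResult]:
    """Per-beat WI analysis: calibrate, differentiate, detect peaks, β."""
    calibrated = recording.has_pressures
    results = []
    for beat in beats:
        d = recording.displacement[beat.start:beat.end]
        v = recording.velocity[beat.start:beat.end]
        if calibrated:
            p = calibrate_pressure(d, recording.systolic_pressure,
                                   recording.diastolic_pressure)
        else:
            p = d * MM_TO_M
        wi = compute_wi_curve(p, v, recording.dt, smooth=smooth)
        local = BeatWindow(start=0, end=len(beat), foot=0)
        peaks = detect_peaks(wi, local, recording.dt,
                             early_fraction=early_fraction,
                             refractory_fraction=refractory_fraction)
        d_min, d_max = float(d.min()), float(d.max())
        if calibrated and d_min > 0 and d_max > d_min:
            beta = compute_beta(recording.systolic_pressure,
                                recording.diastolic_pressure, d_max, d_min)
        else:
            beta = float("nan")
        results.append(WIBeatResult(
            w1=peaks.w1, w1_time=peaks.w1_time, w2=peaks.w2,
            w2_time=peaks.w2_time, beta=beta,
            p_max=float(p.max()), p_min=float(p.min()),
            v_max=float(v.max()), v_min=float(v.min()),
            warning=peaks.warning))
    return results


def analyze_recording(recording: WaveformRecording, n_ensemble: int = 5,
                      smooth: bool = False, early_fraction: float = 0.4,
                      refractory_fraction: float = 0.25) -> WIPatientResult:
    """Full single-patient analysis, ensemble-averaged over beats.

    Beats are segmented, each beat is calibrated and analyzed, and the
    per-beat peaks, β and extrema are averaged over up to the first
    ``n_ensemble`` complete beats (clinical convention: five cycles).
    """
    if n_ensemble < 1:
        raise ParameterError("n_ensemble must be >= 1")
    try:
        beats = segment_beats(recording)
    except SegmentationError as exc:
        raise AnalysisError(f"recording {recording.patient_id!r}: {exc}") from exc
    hr = heart_rate_from_beats(beats, recording.dt)
    used = beats[:n_ensemble]
    per_beat = analyze_beats(recording, used, smooth=smooth,
                             early_fraction=early_fraction,
                             refractory_fraction=refractory_fraction)
    mean = lambda attr: float(np.mean([getattr(b, attr) for b in per_beat]))
    return WIPatientResult(
        patient_id=recording.patient_id,
        n_beats_used=len(used),
        heart_rate=hr,
        w1=mean("w1"), w2=mean("w2"), beta=mean("beta"),
        p_max=mean("p_max"), p_min=mean("p_min"),
        v_max=mean("v_max"), v_min=mean("v_min"),
        calibrated=recording.has_pressures)
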