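"""Delimited-text readers and writers.

All artifacts are plain text so fixtures and outputs stay human-auditable:
one waveform CSV per patient (`time_s,displacement_mm,velocity_m_s` with
``# key: value`` header comments), a cohort metadata CSV, a per-patient
results CSV, and a key-value report.  Writers use fixed numeric formats so
repeated runs diff clean; readers validate what the writers promise
(uniform time grid, required columns).
"""

from __future__ import annotations

import io as _stdio
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError
from .risk import StratificationReport, SurvivalCurve
from .simulate import CohortConfig, VirtualPatient
from .wi import WaveformRecording, WIPatientResult

__all__ = [
    "read_waveform", "write_waveform",
    "read_cohort", "write_cohort", "cohort_to_frame",
    "read_results", "write_results",
    "write_survival_curve", "write_report", "report_text",
    "read_config_file",
]

WAVEFORM_COLUMNS = ["time_s", "displacement_mm", "velocity_m_s"]
RESULT_COLUMNS = ["patient_id", "n_beats_used", "heart_rate", "w1", "w2",
                  "beta", "p_max", "p_min", "v_max", "v_min"]
COHORT_COLUMNS = ["patient_id", "group", "event", "event_type", "followup_months"]

_FLOAT_FMT = "%.12g"


def write_waveform(recording: WaveformRecording, path: Union[str, Path]) -> None:
    """Write one waveform file; patient id and pressures go in `#` comments."""
    path = Path(path)
    lines = [f"# patient_id: {recording.patient_id}"]
    if recording.has_pressures:
        lines.append(f"# systolic_pressure_mmhg: {recording.systolic_pressure:.12g}")
        lines.append(f"# diastolic_pressure_mmhg: {recording.diastolic_pressure:.12g}")
    frame = pd.DataFrame({
        "time_s": recording.time,
        "displacement_mm": recording.displacement,
        "velocity_m_s": recording.velocity,
    })
    buf = _stdio.StringIO()
    frame.to_csv(buf, index=False, float_format=_FLOAT_FMT)
    path.write_text("\n".join(lines) + "\n" + buf.getvalue())


def read_waveform(path: Union[str, Path],
                  patient_id: Optional[str] = None) -> WaveformRecording:
    """Read a waveform file, validating the header and the time grid.

    The grid must be uniform within 1e-9 relative tolerance; the patient id
    comes from the ``# patient_id`` comment, the argument, or the filename
    stem, in that order of preference.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, value = body.split(":", 1)
                meta[key.strip()] = value.strip()
    frame = pd.read_csv(path, comment="#")
    missing = [c for c in WAVEFORM_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path.name}: missing column(s) {missing}")
    time = frame["time_s"].to_numpy(dtype=float)
    if len(time) < 3:
        raise FormatError(f"{path.name}: fewer than 3 samples")
    steps = np.diff(time)
    bad = np.flatnonzero(steps <= 0)
    if len(bad):
        raise FormatError(f"{path.name}: non-monotonic time at row {int(bad[0]) + 2}")
    dt = float(np.median(steps))
    off = np.flatnonzero(np.abs(steps - dt) > 1e-9 * max(dt, 1.0))
    if len(off):
        raise FormatError(f"{path.name}: non-uniform time grid at row {int(off[0]) + 2}")
    ps = meta.get("systolic_pressure_mmhg")
    pd_ = meta.get("diastolic_pressure_mmhg")
    return WaveformRecording(
        dt=dt, time=time,
        displacement=frame["displacement_mm"].to_numpy(dtype=float),
        velocity=frame["velocity_m_s"].to_numpy(dtype=float),
        systolic_pressure=float(ps) if ps is not None else None,
        diastolic_pressure=float(pd_) if pd_ is not None else None,
        patient_id=meta.get("patient_id") or patient_id or path.stem)


def cohort_to_frame(patients: Sequence[VirtualPatient]) -> pd.DataFrame:
    """Cohort metadata table (one row per patient, covariates included)."""
    rows = []
    for p in patients:
        row = {"patient_id": p.patient_id, "group": p.group,
               "event": int(p.event), "event_type": p.event_type,
               "followup_months": p.followup_months}
        row.update({k: p.metadata[k] for k in sorted(p.metadata)})
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(patients_or_frame, path: Union[str, Path]) -> None:
    frame = (patients_or_frame if isinstance(patients_or_frame, pd.DataFrame)
             else cohort_to_frame(patients_or_frame))
    frame.to_csv(path, index=False, float_format="%.6f")


def read_cohort(path: Union[str, Path]) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{Path(path).name}: missing column(s) {missing}")
    frame["event"] = frame["event"].astype(bool)
    return frame


def write_results(results: Sequence[WIPatientResult], path: Union[str, Path]) -> None:
    frame = pd.DataFrame([{c: getattr(r, c) for c in RESULT_COLUMNS}
                          for r in results])
    frame.to_csv(path, index=False, float_format="%.6f")


def read_results(path: Union[str, Path]) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in RESULT_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{Path(path).name}: missing column(s) {missing}")
    return frame


def write_survival_curve(curve: SurvivalCurve, path: Union[str, Path]) -> None:
    frame = pd.DataFrame({
        "time_months": curve.times,
        "n_at_risk": curve.n_at_risk,
        "n_events": curve.n_events,
        "survival": curve.survival,
    })
    frame.to_csv(path, index=False, float_format="%.6f")


def report_text(report: StratificationReport) -> str:
    """Render a stratification report as deterministic key-value text."""
    lines = [
        f"n_patients: {report.n_patients}",
        f"cutoff_mmHg_m_s3: {report.cutoff.cutoff:.1f}",
        f"reference_mean: {report.cutoff.reference_mean:.1f}",
        f"reference_sd: {report.cutoff.reference_sd:.1f}",
        f"n_reference: {report.cutoff.n_reference}",
        f"n_low_risk: {report.n_low_risk}",
        f"n_high_risk: {report.n_high_risk}",
        "contingency_a_low_risk_event_free: %d" % report.table.a,
        "contingency_b_high_risk_event_free: %d" % report.table.b,
        "contingency_c_low_risk_event: %d" % report.table.c,
        "contingency_d_high_risk_event: %d" % report.table.d,
        f"odds_ratio: {report.odds_ratio.odds_ratio:.2f}",
        f"or_ci_low: {report.odds_ratio.ci_low:.2f}",
        f"or_ci_high: {report.odds_ratio.ci_high:.2f}",
        f"or_ci_level: {report.odds_ratio.level:.2f}",
        f"or_p_value: {report.odds_ratio.p_value:.3g}",
        f"or_corrected: {str(report.odds_ratio.corrected).lower()}",
        f"total_events: {report.events['total_events']}",
        f"total_event_pct: {report.events['total_event_pct']:.1f}",
        f"event_free_n: {report.events['event_free_n']}",
    ]
    for etype in ("death", "vad", "htx"):
        lines.append(f"events_{etype}: {report.events['counts'][etype]}")
        lines.append(f"events_{etype}_pct: {report.events['percentages'][etype]:.1f}")
    return "\n".join(lines) + "\n"


def write_report(report: StratificationReport, path: Union[str, Path]) -> None:
    Path(path).write_text(report_text(report))


def read_config_file(path: Union[str, Path]) -> dict:
    """Flat key-value (YAML) configuration file."""
    data = yaml.safe_load(Path(path).read_text())
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise FormatError("config file must be a flat key-value mapping")
    return data
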