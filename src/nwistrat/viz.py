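"""Optional static plot export (no interactive GUI)."""

from __future__ import annotations

from pathlib import Path
from typing import Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .risk import StratificationReport, SurvivalCurve  # noqa: E402

__all__ = ["plot_survival"]


def _step(ax, curve: SurvivalCurve, label: str, color: str) -> None:
    times = [0.0, *curve.times]
    surv = [1.0, *curve.survival]
    ax.step(times, surv, where="post", label=label, color=color)


def plot_survival(report: StratificationReport, path: Union[str, Path]) -> None:
    """Write the per-stratum event-free Kaplan–Meier curves as a PNG/PDF."""
    fig, ax = plt.subplots(figsize=(6, 4))
    if report.km_low_risk is not None:
        _step(ax, report.km_low_risk,
              f"low risk (n={report.n_low_risk})", "tab:green")
    if report.km_high_risk is not None:
        _step(ax, report.km_high_risk,
              f"high risk (n={report.n_high_risk})", "tab:blue")
    ax.set_xlabel("follow-up (months)")
    ax.set_ylabel("event-free survival")
    ax.set_ylim(0.0, 1.05)
    ax.legend(loc="lower left")
    ax.set_title(f"W1 cutoff {report.cutoff.cutoff:.0f} mmHg·m/s³, "
                 f"OR {report.odds_ratio.odds_ratio:.1f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
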