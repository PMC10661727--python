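"""Steady-state exposure metrics from simulated IgG profiles.

Metrics are evaluated over a standardized 28-day steady-state window — the
final four weekly intervals or the final 4-weekly interval of the horizon —
so that AUC_ss and C_ave,ss are directly comparable between the weekly and
every-4-week regimens.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ExposureMetrics", "SS_WINDOW_DAYS", "ss_window",
           "compute_metrics", "threshold_fraction"]

SS_WINDOW_DAYS = 28.0
_MAX_GRID_STEP = 0.25  # days


@dataclass(frozen=True)
class ExposureMetrics:
    """Per-subject steady-state exposure over the 28-day window."""

    auc_ss: float    # g*days/L over the window
    cmax_ss: float   # g/L
    cmin_ss: float   # g/L
    cave_ss: float   # g/L, auc_ss / 28
    window: tuple    # (start, end) days

    def __post_init__(self) -> None:
        if not (0 <= self.cmin_ss <= self.cave_ss + 1e-9
                and self.cave_ss <= self.cmax_ss + 1e-9):
            raise ValueError("require 0 <= cmin <= cave <= cmax")
        width = self.window[1] - self.window[0]
        if not np.isclose(self.cave_ss, self.auc_ss / width, rtol=1e-9):
            raise ValueError("cave_ss must equal auc_ss / window width")


def ss_window(regimen) -> tuple[float, float]:
    """The final 28 days of the horizon, aligned to dose times.

    Raises if the horizon is not a whole number of dosing intervals or the
    window would not span whole intervals.
    """
    if regimen.horizon < SS_WINDOW_DAYS:
        raise ValueError("horizon must cover at least one 28-day window")
    n_int = regimen.horizon / regimen.interval
    if abs(n_int - round(n_int)) > 1e-9:
        raise ValueError(
            f"horizon {regimen.horizon} d is not a multiple of the "
            f"dosing interval {regimen.interval} d"
        )
    n_win = SS_WINDOW_DAYS / regimen.interval
    if abs(n_win - round(n_win)) > 1e-9:
        raise ValueError(
            f"28-day window does not align with interval {regimen.interval} d"
        )
    return (regimen.horizon - SS_WINDOW_DAYS, float(regimen.horizon))


def compute_metrics(profile, window) -> ExposureMetrics:
    """Trapezoidal AUC and extrema of total IgG over the window."""
    t = np.asarray(profile.times, dtype=float)
    lo, hi = window
    sel = (t >= lo - 1e-9) & (t <= hi + 1e-9)
    if sel.sum() < 2:
        raise ValueError("profile grid does not cover the window")
    tw, cw = t[sel], profile.conc_total[sel]
    if tw[0] > lo + 1e-9 or tw[-1] < hi - 1e-9 or np.max(np.diff(tw)) > _MAX_GRID_STEP + 1e-9:
        raise ValueError(
            f"grid must cover [{lo}, {hi}] with step <= {_MAX_GRID_STEP} d"
        )
    auc = float(np.trapezoid(cw, tw))
    width = hi - lo
    return ExposureMetrics(
        auc_ss=auc,
        cmax_ss=float(np.max(cw)),
        cmin_ss=float(np.min(cw)),
        cave_ss=auc / width,
        window=(float(lo), float(hi)),
    )


def threshold_fraction(metrics, threshold: float = 7.0) -> float:
    """Percentage of subjects whose trough C_min,ss is >= threshold (g/L)."""
    if len(metrics) == 0:
        raise ValueError("metrics list is empty")
    n_above = sum(1 for m in metrics if m.cmin_ss >= threshold)
    return 100.0 * n_above / len(metrics)
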