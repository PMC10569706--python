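"""Tissue-to-blood ratios, Patlak graphical analysis, and SUV change summaries."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BloodCurve, InvalidInputError, TissueTAC

__all__ = ["tbr", "patlak", "percent_change", "PatlakResult"]

#: Blood concentrations below this floor (kBq/ml) are masked in ratios.
BLOOD_FLOOR = 1e-9


def tbr(tissue: TissueTAC, blood: TissueTAC, floor: float = BLOOD_FLOOR) -> np.ndarray:
    """Per-frame tissue-to-blood ratio ``C_T / C_p``.

    Frames where the blood value is below ``floor`` are returned as NaN rather
    than divided through.  Both TACs must share the same framing schedule.
    """
    if not tissue.schedule.same_as(blood.schedule):
        raise InvalidInputError("tissue and blood TACs are on different schedules")
    out = np.full(len(tissue.schedule), np.nan)
    ok = blood.values > floor
    out[ok] = tissue.values[ok] / blood.values[ok]
    return out


@dataclass(frozen=True)
class PatlakResult:
    """Patlak regression: slope (Ki estimate under irreversibility) and intercept."""

    slope: float
    intercept: float
    x: np.ndarray  # normalized time of every frame (min)
    y: np.ndarray  # TBR of every frame
    window: np.ndarray  # boolean mask of frames used in the regression


def patlak(
    tissue: TissueTAC,
    input_curve: BloodCurve,
    window: np.ndarray | None = None,
    window_start_min: float = 30.0,
) -> PatlakResult:
    """Patlak plot of a tissue TAC against the fitted input function.

    ``x_i = integral_0^{t_mid,i} Cp / Cp(t_mid,i)`` (normalized time) and
    ``y_i = C_T,i / Cp(t_mid,i)``, both using the analytic triexponential for
    the denominator and the integral.  Ordinary least squares over the window
    (default: all frames with midpoint >= ``window_start_min``) returns the
    slope and intercept.  The equilibrium window is a caller choice, not
    auto-selected.
    """
    mid = tissue.schedule.mid
    cp = input_curve.at(mid)
    if np.any(cp <= 0):
        raise InvalidInputError("input function must be positive at all frame midpoints")
    x = input_curve.cumulative_integral(mid) / cp
    y = tissue.values / cp
    mask = np.asarray(window, dtype=bool) if window is not None else mid >= window_start_min
    if mask.shape != mid.shape:
        raise InvalidInputError("window mask must align with the TAC frames")
    if mask.sum() < 2:
        raise InvalidInputError("Patlak regression needs at least 2 frames in the window")
    slope, intercept = np.polyfit(x[mask], y[mask], 1)
    return PatlakResult(slope=float(slope), intercept=float(intercept), x=x, y=y, window=mask)


def percent_change(value_late: float, value_baseline: float) -> float:
    """Percent change of a late value relative to a baseline value."""
    if value_baseline == 0:
        raise InvalidInputError("percent change undefined for a zero baseline")
    return 100.0 * (value_late - value_baseline) / value_baseline
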