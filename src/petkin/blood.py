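"""Triexponential input-function fitting and evaluation.

The whole-blood clearance of the tracer is modeled as
``Cp(t) = A1 e^{-l1 t} + A2 e^{-l2 t} + A3 e^{-l3 t}`` and fitted to a
frame-averaged blood TAC by weighted least squares.  Because triexponential
fitting is multimodal, the fit is multi-started: candidate rate triplets are
drawn from a log-spaced grid, amplitudes are solved by non-negative least
squares at fixed rates, and the best candidates are refined jointly.
"""
from __future__ import annotations

from dataclasses import dataclass

import itertools
import math

import numpy as np
from scipy.optimize import least_squares, nnls

from .compartments import frame_weights
from .core import (
    ZR89_HALF_LIFE_HOURS,
    BloodCurve,
    FitFailureError,
    FramingSchedule,
    InvalidInputError,
    TissueTAC,
)

__all__ = ["TriexpFit", "fit_triexponential", "eval_blood", "integral_blood"]

_N_COMPONENTS = 3
#: Log-spaced candidate rate grid for multi-start (1/min).
_RATE_GRID = np.geomspace(1.0 / 2000.0, 1.0, 8)


@dataclass(frozen=True)
class TriexpFit:
    """Fitted triexponential input function.

    ``curve`` stores rates sorted descending (fastest component first);
    ``half_lives_min`` on the curve reports them ascending.  ``stderr`` holds
    per-parameter standard errors ordered (A1..A3, l1..l3), NaN where the
    covariance is singular.
    """

    curve: BloodCurve
    wrss: float
    stderr: np.ndarray
    converged: bool
    degenerate: bool

    @property
    def half_lives_min(self) -> np.ndarray:
        return self.curve.half_lives_min


def _exp_frame_avg(rate: float, schedule: FramingSchedule) -> np.ndarray:
    """Frame average of ``e^{-rate t}``."""
    if rate <= 0:
        return np.ones(len(schedule))
    a, b = schedule.start, schedule.end
    return (np.exp(-rate * a) - np.exp(-rate * b)) / (rate * schedule.duration)


def _model_avg(theta: np.ndarray, schedule: FramingSchedule) -> np.ndarray:
    amps, rates = theta[:_N_COMPONENTS], theta[_N_COMPONENTS:]
    cols = np.column_stack([_exp_frame_avg(r, schedule) for r in rates])
    return cols @ amps


def fit_triexponential(
    blood_tac: TissueTAC,
    weights: np.ndarray | None = None,
    isotope_half_life_h: float = ZR89_HALF_LIFE_HOURS,
    late_downweight: float = 10.0,
    n_refine: int = 6,
) -> TriexpFit:
    """Weighted least-squares triexponential fit of a blood TAC.

    Requires at least 7 frames spanning both early (< 90 min) and late
    (> 300 min) times.  The model prediction is frame-averaged (not sampled at
    midpoints), matching how scanner frames integrate a rapidly changing early
    blood curve.  Raises :class:`FitFailureError` (carrying the best partial
    result) if no refinement start converges.
    """
    schedule = blood_tac.schedule
    y = blood_tac.values
    if len(schedule) < 7:
        raise InvalidInputError("need at least 7 frames for a triexponential fit")
    mid = schedule.mid
    if not ((mid < 90).any() and (mid > 300).any()):
        raise InvalidInputError("blood TAC must span early (<90 min) and late (>300 min) times")
    w = (
        frame_weights(schedule, isotope_half_life_h, late_downweight)
        if weights is None
        else np.asarray(weights, dtype=float)
    )
    if w.shape != y.shape:
        raise InvalidInputError("weights must align with the TAC frames")
    sqrt_w = np.sqrt(w)

    # Stage 1: NNLS amplitudes on every rate triplet from the log-spaced grid.
    cols = {r: _exp_frame_avg(r, schedule) for r in _RATE_GRID}
    candidates = []
    for rates in itertools.combinations(_RATE_GRID, _N_COMPONENTS):
        design = np.column_stack([cols[r] for r in rates])
        amps, _ = nnls(sqrt_w[:, None] * design, sqrt_w * y)
        resid = sqrt_w * (y - design @ amps)
        candidates.append((float(resid @ resid), np.concatenate([amps, rates])))
    candidates.sort(key=lambda c: c[0])

    # Stage 2: joint refinement of the best candidates.
    def residual(theta):
        return sqrt_w * (y - _model_avg(theta, schedule))

    best = None
    best_wrss = np.inf
    any_converged = False
    for _, theta0 in candidates[:n_refine]:
        res = least_squares(
            residual, np.clip(theta0, 0.0, None),
            bounds=(0.0, np.inf), ftol=1e-14, xtol=1e-14, gtol=1e-14, max_nfev=4000,
        )
        wrss = float(res.cost * 2.0)
        any_converged = any_converged or res.status > 0
        if wrss < best_wrss:
            best_wrss = wrss
            best = res

    amps, rates = best.x[:_N_COMPONENTS], best.x[_N_COMPONENTS:]
    order = np.argsort(rates)[::-1]  # fastest first
    amps, rates = amps[order], rates[order]

    # Standard errors from the weighted Jacobian at the solution.
    n, k = len(y), 2 * _N_COMPONENTS
    stderr = np.full(k, np.nan)
    if n > k:
        jtj = best.jac.T @ best.jac
        try:
            cov = np.linalg.inv(jtj) * best_wrss / (n - k)
            stderr_unsorted = np.sqrt(np.clip(np.diag(cov), 0.0, None))
            stderr = np.concatenate([stderr_unsorted[:_N_COMPONENTS][order],
                                     stderr_unsorted[_N_COMPONENTS:][order]])
        except np.linalg.LinAlgError:
            pass

    # Degeneracy: a component with (numerically) zero amplitude, a zero rate
    # carrying real amplitude, or two components with indistinguishable rates
    # (the data support fewer than three exponentials).
    total = amps.sum()
    amp_tol = 1e-6 * max(total, 1e-300)
    sorted_rates = np.sort(rates)
    duplicate = bool(
        np.any(sorted_rates[1:] - sorted_rates[:-1] <= 0.01 * sorted_rates[1:])
    )
    degenerate = bool(
        np.any(amps <= amp_tol)
        or np.any((rates <= 1e-12) & (amps > amp_tol))
        or duplicate
    )

    fit = TriexpFit(
        curve=BloodCurve(amplitudes=amps, rates=rates),
        wrss=best_wrss,
        stderr=stderr,
        converged=bool(any_converged),
        degenerate=degenerate,
    )
    if not any_converged:
        raise FitFailureError("triexponential fit did not converge", best=fit)
    return fit


def eval_blood(curve: BloodCurve, t, frame: tuple[float, float] | None = None):
    """Point evaluation ``Cp(t)``, or the frame average over ``frame=(a, b)``."""
    if frame is not None:
        a, b = frame
        sched = FramingSchedule(np.array([a]), np.array([b]))
        return float(curve.frame_average(sched)[0])
    return curve.at(t)


def integral_blood(curve: BloodCurve, t):
    """Analytic ``integral_0^t Cp dtau`` (kBq*min/ml)."""
    return curve.cumulative_integral(t)
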