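"""Forward modeling and weighted fitting of 1T/2T compartment models.

The tissue response to a multi-exponential input is computed in closed form:
the impulse response of the one- and two-tissue models is a sum of (at most
two) exponentials, and the convolution of ``A e^{-lam t}`` with ``B e^{-a t}``
is again a combination of exponentials (or ``t e^{-a t}`` in the confluent
case).  Every model TAC is therefore an exact exponential mixture which can be
evaluated pointwise, integrated, and frame-averaged analytically — there is no
ODE solver or numerical convolution anywhere in the fitting path.

The measured signal model is ``C_model(t) = C_tissue(t) + vb Cp(t)`` with
``Cp`` the whole-blood curve: the extravascular compartments plus a fractional
whole-blood contribution.  Under this convention the net influx macroparameter
``Ki = K1 k3 / (k2 + k3)`` is exactly the late-time Patlak slope of the
measured TAC for irreversible (k4 = 0) kinetics.
"""
from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .core import (
    ZR89_HALF_LIFE_HOURS,
    BloodCurve,
    FitFailureError,
    FramingSchedule,
    InvalidInputError,
    KineticFit,
    KineticParams,
    MODEL_PARAMS,
    TissueTAC,
    decay_constant_per_min,
)
from .selection import aicc

__all__ = [
    "ModelSpec",
    "CompartmentCurves",
    "ExpMix",
    "DEFAULT_BOUNDS",
    "model_tac",
    "model_values",
    "tissue_mix",
    "compartment_curves",
    "frame_weights",
    "fit_model",
    "ki_macro",
]

#: Physiologic fitting bounds (lower, upper) per microparameter.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "vb": (0.0, 0.6),
    "K1": (0.0, 2.0),
    "k2": (0.0, 1.0),
    "k3": (0.0, 1.0),
    "k4": (0.0, 1.0),
}

#: Default single-start initialization (log-uniform multi-start around it).
DEFAULT_INIT: dict[str, float] = {
    "vb": 0.05,
    "K1": 0.01,
    "k2": 0.01,
    "k3": 0.001,
    "k4": 0.0001,
}

# Frames starting at or after this time belong to a late static session and
# receive the late down-weighting (the dynamic scan ends at 90 min, the first
# late session starts at 360 min).
LATE_SESSION_THRESHOLD_MIN = 120.0


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of one compartment-model fit."""

    model: str = "2T5P"
    fixed: Mapping[str, float] = field(default_factory=dict)
    bounds: Mapping[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    late_downweight: float = 10.0
    n_starts: int = 5

    def __post_init__(self):
        if self.model not in MODEL_PARAMS:
            raise InvalidInputError(f"unknown model {self.model!r}")
        for name, value in self.fixed.items():
            if name not in MODEL_PARAMS[self.model]:
                raise InvalidInputError(f"{self.model} has no parameter {name!r}")
            lo, hi = self.bounds.get(name, DEFAULT_BOUNDS[name])
            if not lo <= value <= hi:
                raise InvalidInputError(f"fixed {name}={value} outside bounds [{lo}, {hi}]")
        for name, (lo, hi) in self.bounds.items():
            if lo < 0 or hi <= lo:
                raise InvalidInputError(f"invalid bounds for {name}: [{lo}, {hi}]")
        if self.n_starts < 1:
            raise InvalidInputError("n_starts must be >= 1")

    @property
    def free_names(self) -> tuple[str, ...]:
        return tuple(p for p in MODEL_PARAMS[self.model] if p not in self.fixed)


# ---------------------------------------------------------------------------
# Exponential mixtures
# ---------------------------------------------------------------------------

# Rates closer than this (absolute, 1/min) are treated as confluent and use
# the t*exp limit form; avoids catastrophic cancellation in (e^-a - e^-b)/(b-a).
_CONFLUENT_TOL = 1e-9


@dataclass(frozen=True)
class ExpMix:
    """A finite mixture ``sum_i c_i t^{p_i} e^{-r_i t}`` with ``p_i`` in {0, 1}."""

    terms: tuple[tuple[float, float, int], ...]

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for c, r, p in self.terms:
            e = np.exp(-r * t)
            out = out + (c * t * e if p else c * e)
        return out

    def antiderivative(self, t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for c, r, p in self.terms:
            if p == 0:
                out = out + (-c / r * np.exp(-r * t) if r > 0 else c * t)
            else:
                if r > 0:
                    out = out + (-c * np.exp(-r * t) * (t / r + 1.0 / r**2))
                else:
                    out = out + 0.5 * c * t**2
        return out

    def integral(self, a, b):
        return self.antiderivative(b) - self.antiderivative(a)

    def frame_average(self, schedule: FramingSchedule) -> np.ndarray:
        return self.integral(schedule.start, schedule.end) / schedule.duration


def _convolve_exp(a_amp: float, a_rate: float, b_amp: float, b_rate: float):
    """Terms of ``(a_amp e^{-a_rate t}) * (b_amp e^{-b_rate t})`` (convolution)."""
    if abs(a_rate - b_rate) > _CONFLUENT_TOL * max(1.0, a_rate, b_rate):
        c = a_amp * b_amp / (b_rate - a_rate)
        return [(c, a_rate, 0), (-c, b_rate, 0)]
    return [(a_amp * b_amp, 0.5 * (a_rate + b_rate), 1)]


def _impulse_terms(params: KineticParams) -> tuple[list, list]:
    """Exponential terms of the impulse responses of C1 and C2.

    For the two-tissue model the eigenvalues are
    ``alpha_{1,2} = [(k2+k3+k4) -/+ sqrt((k2+k3+k4)^2 - 4 k2 k4)] / 2``.
    With ``k3 = 0`` the second compartment never fills and the model reduces
    exactly to the one-tissue response ``K1 e^{-k2 t}``.
    """
    K1, k2, k3, k4 = params.K1, params.k2, params.k3, params.k4
    if k3 <= 0.0:
        return [(K1, k2)], []
    s = k2 + k3 + k4
    disc = s * s - 4.0 * k2 * k4
    # disc = (k2 - k4)^2 + k3 (k3 + 2 k2 + 2 k4) >= 0 for non-negative rates
    assert disc >= -1e-15
    sq = math.sqrt(max(disc, 0.0))
    a1 = 0.5 * (s - sq)
    a2 = 0.5 * (s + sq)
    if a2 - a1 < _CONFLUENT_TOL:  # unreachable with k3 > 0; guard regardless
        a2 = a1 + _CONFLUENT_TOL
    c1_terms = [(K1 * (k4 - a1) / (a2 - a1), a1), (K1 * (a2 - k4) / (a2 - a1), a2)]
    c = K1 * k3 / (a2 - a1)
    c2_terms = [(c, a1), (-c, a2)]
    return c1_terms, c2_terms


def _mix_from_impulse(impulse_terms, input_curve: BloodCurve) -> ExpMix:
    terms = []
    for b_amp, b_rate in impulse_terms:
        if b_amp == 0.0:
            continue
        for a_amp, a_rate in zip(input_curve.amplitudes, input_curve.rates):
            if a_amp == 0.0:
                continue
            terms.extend(_convolve_exp(a_amp, a_rate, b_amp, b_rate))
    return ExpMix(tuple(terms))


def tissue_mix(params: KineticParams, input_curve: BloodCurve) -> ExpMix:
    """Extravascular tissue concentration ``C1 + C2`` as an exponential mixture."""
    c1_terms, c2_terms = _impulse_terms(params)
    return _mix_from_impulse(c1_terms + c2_terms, input_curve)


def model_values(
    params: KineticParams, input_curve: BloodCurve, schedule: FramingSchedule
) -> np.ndarray:
    """Frame-averaged model TAC ``C_tissue + vb C_wb`` (kBq/ml)."""
    tissue = tissue_mix(params, input_curve).frame_average(schedule)
    blood = input_curve.frame_average(schedule)
    return tissue + params.vb * blood


def model_tac(
    params: KineticParams,
    input_curve: BloodCurve,
    schedule: FramingSchedule,
    region: str = "model",
    subject_id: str = "",
) -> TissueTAC:
    """Noiseless model TAC on a framing schedule (frame-averaged)."""
    if input_curve.value_at_zero <= 0:
        raise InvalidInputError("input function needs at least one positive amplitude")
    values = np.clip(model_values(params, input_curve, schedule), 0.0, None)
    return TissueTAC(region=region, schedule=schedule, values=values, subject_id=subject_id)


@dataclass(frozen=True)
class CompartmentCurves:
    """Free (C1) and bound (C2) compartment concentrations on a time grid."""

    t: np.ndarray
    c1: np.ndarray
    c2: np.ndarray

    @property
    def total_tissue(self) -> np.ndarray:
        return self.c1 + self.c2


def compartment_curves(
    params: KineticParams, input_curve: BloodCurve, grid
) -> CompartmentCurves:
    """Pointwise C1(t) and C2(t); their sum equals the tissue part of the model."""
    t = np.asarray(grid, dtype=float)
    if np.any(t < 0):
        raise InvalidInputError("time grid must be non-negative")
    c1_terms, c2_terms = _impulse_terms(params)
    c1 = _mix_from_impulse(c1_terms, input_curve)(t)
    c2 = _mix_from_impulse(c2_terms, input_curve)(t) if c2_terms else np.zeros_like(t)
    return CompartmentCurves(t=t, c1=c1, c2=c2)


# ---------------------------------------------------------------------------
# Weights
# ---------------------------------------------------------------------------

def frame_weights(
    schedule: FramingSchedule,
    isotope_half_life_h: float = ZR89_HALF_LIFE_HOURS,
    late_downweight: float = 10.0,
    late_session_threshold_min: float = LATE_SESSION_THRESHOLD_MIN,
) -> np.ndarray:
    """Per-frame weights from frame duration and physical decay.

    ``w_i = dt_i * exp(-lambda_phys * t_mid,i)``; frames of the late static
    sessions are divided by ``late_downweight``; the result is normalized to
    sum to the number of frames.
    """
    lam = decay_constant_per_min(isotope_half_life_h)
    w = schedule.duration * np.exp(-lam * schedule.mid)
    late = schedule.start >= late_session_threshold_min
    w = np.where(late, w / late_downweight, w)
    return w * (len(schedule) / w.sum())


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def ki_macro(params: KineticParams) -> float:
    """Net influx rate macroparameter ``Ki = K1 k3 / (k2 + k3)``; 0 when k3 = 0."""
    if params.k3 == 0.0:
        return 0.0
    if params.k2 + params.k3 <= 0.0:
        # k2 = k3 = 0 with K1 > 0: degenerate trapping with no exchange
        return 0.0
    return params.K1 * params.k3 / (params.k2 + params.k3)


def _data_key(values: np.ndarray, weights: np.ndarray) -> int:
    return zlib.crc32(np.round(values, 12).tobytes() + np.round(weights, 12).tobytes())


def _build_params(model: str, fixed: Mapping[str, float], free_names, theta) -> KineticParams:
    values = {name: 0.0 for name in MODEL_PARAMS[model]}
    values.update(fixed)
    values.update(dict(zip(free_names, theta)))
    return KineticParams.for_model(model, fixed=fixed.keys(), **values)


def _starts(spec: ModelSpec, rng: np.random.Generator, extra=None, include_default=True):
    """Default start plus log-uniform random starts within bounds."""
    free = spec.free_names
    starts = []
    if extra is not None:
        starts.extend(extra)
    if include_default:
        starts.append([min(max(DEFAULT_INIT[p], spec.bounds[p][0]), spec.bounds[p][1]) for p in free])
    while len(starts) < spec.n_starts + (len(extra) if extra else 0):
        theta = []
        for p in free:
            lo, hi = spec.bounds[p]
            if p == "vb":
                theta.append(rng.uniform(lo, hi))
            else:
                lo_eff = max(lo, 1e-4)
                theta.append(math.exp(rng.uniform(math.log(lo_eff), math.log(max(hi, lo_eff * 10)))))
        starts.append(theta)
    return starts


def fit_model(
    tac: TissueTAC,
    input_curve: BloodCurve,
    spec: ModelSpec,
    weights: np.ndarray | None = None,
    isotope_half_life_h: float = ZR89_HALF_LIFE_HOURS,
    seed: int = 0,
    starts: Sequence[Sequence[float]] | None = None,
    include_default_start: bool = True,
) -> KineticFit:
    """Weighted nonlinear least-squares fit of one compartment model.

    Minimizes ``sum_i w_i (C_meas,i - C_model,i)^2`` over the free parameters
    with physiologic bounds, multi-start initialization, and the frame-duration
    / decay weighting scheme (late sessions down-weighted by ``late_downweight``).
    ``starts``, when given, are additional explicit initializations (one list of
    free-parameter values each).
    """
    schedule = tac.schedule
    y = tac.values
    w = frame_weights(schedule, isotope_half_life_h, spec.late_downweight) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != y.shape:
        raise InvalidInputError("weights must align with the TAC frames")
    sqrt_w = np.sqrt(w)
    free = spec.free_names
    fixed = dict(spec.fixed)
    lo = np.array([spec.bounds[p][0] for p in free])
    hi = np.array([spec.bounds[p][1] for p in free])

    blood_avg = input_curve.frame_average(schedule)

    def predict(theta):
        p = _build_params(spec.model, fixed, free, theta)
        tissue = tissue_mix(p, input_curve).frame_average(schedule)
        return tissue + p.vb * blood_avg

    def residual(theta):
        return sqrt_w * (y - predict(theta))

    rng = np.random.default_rng(seed)
    best = None
    best_wrss = np.inf
    any_converged = False
    for theta0 in _starts(spec, rng, extra=starts, include_default=include_default_start):
        theta0 = np.clip(np.asarray(theta0, dtype=float), lo, hi)
        try:
            res = least_squares(
                residual, theta0, bounds=(lo, hi),
                ftol=1e-12, xtol=1e-12, gtol=1e-12, max_nfev=2000,
            )
        except Exception:  # pragma: no cover - optimizer-internal failures
            continue
        wrss = float(res.cost * 2.0)
        converged = res.status > 0
        any_converged = any_converged or converged
        if wrss < best_wrss:
            best_wrss = wrss
            best = (res, converged)

    if best is None:
        raise FitFailureError("no optimizer start produced a result")

    res, converged = best
    params = _build_params(spec.model, fixed, free, res.x)
    tol = 1e-8 * (hi - lo) + 1e-12
    at_bounds = tuple(
        name for name, v, l, h, t in zip(free, res.x, lo, hi, tol)
        if v - l < t or h - v < t
    )
    n = len(schedule)
    k = len(free)
    fit = KineticFit(
        model=spec.model,
        params=params,
        wrss=best_wrss,
        aicc=aicc(max(best_wrss, 1e-300), n, k),
        ki=ki_macro(params),
        converged=converged,
        n_points=n,
        at_bounds=at_bounds,
        data_key=_data_key(y, w),
    )
    if not any_converged:
        raise FitFailureError("no optimizer start converged", best=fit)
    return fit
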