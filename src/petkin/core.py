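"""Core data model for dynamic PET kinetic analysis.

Conventions used throughout the package:

* time is measured in **minutes post-injection** (p.i.); frames are stored as
  ``(t_start, t_end)`` pairs and the representative time of a frame is its
  midpoint,
* activity concentrations are **kBq/ml, decay-corrected to injection time**,
* rate constants are **1/min**; ``K1`` is ml/cm^3/min,
* the fractional blood volume ``vb`` is unitless in [0, 1].
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ZR89_HALF_LIFE_HOURS",
    "InvalidInputError",
    "FitFailureError",
    "FramingSchedule",
    "TissueTAC",
    "BloodCurve",
    "KineticParams",
    "KineticFit",
    "SubjectRecord",
    "MODEL_PARAMS",
    "make_study_schedule",
    "suv",
    "suv_peak",
    "peak_support_volume_ml",
    "decay_constant_per_min",
    "decay_correct",
]

#: Physical half-life of Zirconium-89 in hours.
ZR89_HALF_LIFE_HOURS = 78.4


class InvalidInputError(ValueError):
    """An input violates a documented precondition."""


class FitFailureError(RuntimeError):
    """No optimizer start converged.  ``best`` carries the best partial result."""

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


def decay_constant_per_min(half_life_hours: float) -> float:
    """Physical decay constant (1/min) from a half-life in hours."""
    if half_life_hours <= 0:
        raise InvalidInputError("half-life must be positive")
    return math.log(2.0) / (half_life_hours * 60.0)


def decay_correct(values, t_mid_min, half_life_hours: float = ZR89_HALF_LIFE_HOURS):
    """Correct measured (decayed) concentrations back to injection time.

    Multiplies each value by ``exp(lambda_phys * t)``; the inverse operation
    (un-correcting) is division by the same factor.
    """
    lam = decay_constant_per_min(half_life_hours)
    return np.asarray(values, dtype=float) * np.exp(lam * np.asarray(t_mid_min, dtype=float))


# ---------------------------------------------------------------------------
# Framing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FramingSchedule:
    """Ordered scan frames ``(t_start, t_end)`` in minutes p.i.

    Frames must be strictly ordered and non-overlapping; gaps are allowed
    (late static scans are separate sessions).
    """

    start: np.ndarray
    end: np.ndarray

    def __post_init__(self):
        start = np.atleast_1d(np.asarray(self.start, dtype=float)).copy()
        end = np.atleast_1d(np.asarray(self.end, dtype=float)).copy()
        if start.shape != end.shape or start.ndim != 1 or start.size == 0:
            raise InvalidInputError("start/end must be matching non-empty 1-d arrays")
        if not np.all(np.isfinite(start)) or not np.all(np.isfinite(end)):
            raise InvalidInputError("frame times must be finite")
        if np.any(end <= start):
            raise InvalidInputError("every frame needs t_end > t_start")
        if np.any(np.diff(start) <= 0):
            raise InvalidInputError("frames must be strictly ordered by t_start")
        if np.any(start[1:] < end[:-1] - 1e-12):
            raise InvalidInputError("frames must not overlap")
        start.setflags(write=False)
        end.setflags(write=False)
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "end", end)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[float, float]]) -> "FramingSchedule":
        pairs = list(pairs)
        return cls(np.array([p[0] for p in pairs]), np.array([p[1] for p in pairs]))

    def __len__(self) -> int:
        return int(self.start.size)

    @property
    def n(self) -> int:
        return len(self)

    @property
    def mid(self) -> np.ndarray:
        """Frame midpoints (minutes)."""
        return 0.5 * (self.start + self.end)

    @property
    def duration(self) -> np.ndarray:
        """Frame durations (minutes)."""
        return self.end - self.start

    def subset(self, mask) -> "FramingSchedule":
        mask = np.asarray(mask)
        return FramingSchedule(self.start[mask], self.end[mask])

    def same_as(self, other: "FramingSchedule", tol: float = 1e-9) -> bool:
        return (
            len(self) == len(other)
            and np.allclose(self.start, other.start, atol=tol, rtol=0)
            and np.allclose(self.end, other.end, atol=tol, rtol=0)
        )


#: Dynamic framing of the acquisition protocol, as (count, frame seconds).
DYNAMIC_FRAMING_S: tuple[tuple[int, int], ...] = ((6, 60), (16, 30), (2, 60), (12, 120), (10, 300))

#: Start times (minutes p.i.) and duration (minutes) of the two late static scans.
LATE_SESSION_STARTS_MIN: tuple[float, float] = (360.0, 2880.0)
LATE_SESSION_DURATION_MIN: float = 60.0


def make_study_schedule(include_late: bool = True) -> FramingSchedule:
    """The study acquisition protocol as a :class:`FramingSchedule`.

    46 dynamic frames (6x60, 16x30, 2x60, 12x120, 10x300 s) covering 0-90 min,
    plus — when ``include_late`` — one 60-min frame starting at 6 h and one at
    48 h p.i.
    """
    durations_s = np.concatenate([np.full(n, d) for n, d in DYNAMIC_FRAMING_S])
    edges_min = np.concatenate([[0.0], np.cumsum(durations_s)]) / 60.0
    start = edges_min[:-1]
    end = edges_min[1:]
    if include_late:
        late_start = np.asarray(LATE_SESSION_STARTS_MIN)
        start = np.concatenate([start, late_start])
        end = np.concatenate([end, late_start + LATE_SESSION_DURATION_MIN])
    return FramingSchedule(start, end)


# ---------------------------------------------------------------------------
# Measurements
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TissueTAC:
    """Decay-corrected activity concentration per frame for one region."""

    region: str
    schedule: FramingSchedule
    values: np.ndarray  # kBq/ml, decay-corrected to injection time
    subject_id: str = ""

    def __post_init__(self):
        values = np.atleast_1d(np.asarray(self.values, dtype=float)).copy()
        if values.shape != (len(self.schedule),):
            raise InvalidInputError("need exactly one value per frame")
        if not np.all(np.isfinite(values)):
            raise InvalidInputError("TAC values must be finite")
        if np.any(values < 0):
            raise InvalidInputError("TAC values must be non-negative")
        values.setflags(write=False)
        object.__setattr__(self, "values", values)

    def with_values(self, values) -> "TissueTAC":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass(frozen=True)
class BloodCurve:
    """Triexponential whole-blood input function.

    ``Cp(t) = sum_j A_j exp(-lambda_j t)`` with amplitudes in kBq/ml and rate
    constants in 1/min, all non-negative.
    """

    amplitudes: np.ndarray
    rates: np.ndarray

    def __post_init__(self):
        amp = np.atleast_1d(np.asarray(self.amplitudes, dtype=float)).copy()
        lam = np.atleast_1d(np.asarray(self.rates, dtype=float)).copy()
        if amp.shape != lam.shape or amp.ndim != 1 or amp.size == 0:
            raise InvalidInputError("amplitudes and rates must be matching 1-d arrays")
        if np.any(amp < 0) or np.any(lam < 0) or not (np.all(np.isfinite(amp)) and np.all(np.isfinite(lam))):
            raise InvalidInputError("amplitudes and rates must be finite and non-negative")
        amp.setflags(write=False)
        lam.setflags(write=False)
        object.__setattr__(self, "amplitudes", amp)
        object.__setattr__(self, "rates", lam)

    @property
    def value_at_zero(self) -> float:
        return float(self.amplitudes.sum())

    @property
    def half_lives_min(self) -> np.ndarray:
        """Component half-lives ln2/lambda in minutes, sorted ascending."""
        with np.errstate(divide="ignore"):
            hl = np.where(self.rates > 0, math.log(2.0) / self.rates, np.inf)
        return np.sort(hl)

    def _check_t(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if np.any(t < -1e-9):
            raise InvalidInputError("time must be non-negative")
        return np.clip(t, 0.0, None)

    def at(self, t):
        """Point evaluation Cp(t) (kBq/ml)."""
        t = self._check_t(t)
        return np.exp(-np.multiply.outer(t, self.rates)) @ self.amplitudes

    def cumulative_integral(self, t):
        """Analytic integral of Cp from 0 to t (kBq*min/ml).

        Terms with lambda_j = 0 contribute ``A_j * t``.
        """
        t = self._check_t(t)
        out = np.zeros_like(t, dtype=float)
        for a, lam in zip(self.amplitudes, self.rates):
            if lam > 0:
                out = out + (a / lam) * (1.0 - np.exp(-lam * t))
            else:
                out = out + a * t
        return out

    def frame_average(self, schedule: FramingSchedule) -> np.ndarray:
        """Mean of Cp over each frame via the analytic antiderivative."""
        upper = self.cumulative_integral(schedule.end)
        lower = self.cumulative_integral(schedule.start)
        return (upper - lower) / schedule.duration

    def normalized_time(self, t):
        """Patlak normalized time: integral of Cp over [0, t] divided by Cp(t)."""
        return self.cumulative_integral(t) / self.at(t)


# ---------------------------------------------------------------------------
# Kinetic parameters and fits
# ---------------------------------------------------------------------------

#: Fit parameters of each compartment model, in canonical order.
MODEL_PARAMS: dict[str, tuple[str, ...]] = {
    "1T3P": ("vb", "K1", "k2"),
    "2T4P": ("vb", "K1", "k2", "k3"),
    "2T5P": ("vb", "K1", "k2", "k3", "k4"),
}

PARAM_NAMES: tuple[str, ...] = ("vb", "K1", "k2", "k3", "k4")


@dataclass(frozen=True)
class KineticParams:
    """Microparameters of the 1T/2T compartment models.

    ``fixed`` lists parameter names held constant during fitting (the
    fixed-parameter mask); it does not change the forward model.
    """

    vb: float = 0.0
    K1: float = 0.0
    k2: float = 0.0
    k3: float = 0.0
    k4: float = 0.0
    fixed: frozenset = frozenset()

    def __post_init__(self):
        if not 0.0 <= self.vb <= 1.0:
            raise InvalidInputError("vb must lie in [0, 1]")
        for name in ("K1", "k2", "k3", "k4"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be non-negative")
        unknown = set(self.fixed) - set(PARAM_NAMES)
        if unknown:
            raise InvalidInputError(f"unknown fixed parameters: {sorted(unknown)}")
        object.__setattr__(self, "fixed", frozenset(self.fixed))

    @classmethod
    def for_model(cls, model: str, fixed: Iterable[str] = (), **values) -> "KineticParams":
        """Build parameters for a named model, forcing the nested zeros.

        1T3P forces ``k3 = k4 = 0``; 2T4P forces ``k4 = 0``.
        """
        if model not in MODEL_PARAMS:
            raise InvalidInputError(f"unknown model {model!r}")
        allowed = MODEL_PARAMS[model]
        extra = set(values) - set(allowed)
        if extra:
            raise InvalidInputError(f"{model} does not take parameters {sorted(extra)}")
        return cls(fixed=frozenset(fixed), **values)

    def free_names(self, model: str) -> tuple[str, ...]:
        return tuple(p for p in MODEL_PARAMS[model] if p not in self.fixed)

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in PARAM_NAMES}

    def with_updates(self, **values) -> "KineticParams":
        return replace(self, **values)


@dataclass(frozen=True)
class KineticFit:
    """Result of fitting one compartment model to one TAC."""

    model: str
    params: KineticParams
    wrss: float
    aicc: float
    ki: float
    converged: bool
    n_points: int
    at_bounds: tuple[str, ...] = ()
    data_key: int = 0

    @property
    def n_free(self) -> int:
        return len(self.params.free_names(self.model))


@dataclass(frozen=True)
class SubjectRecord:
    """Subject metadata needed for SUV and decay handling."""

    subject_id: str
    group: str = ""
    injected_mbq: float = 18.5
    weight_kg: float = 70.0
    injection_time: str = ""
    isotope_half_life_h: float = ZR89_HALF_LIFE_HOURS

    def __post_init__(self):
        if self.injected_mbq <= 0:
            raise InvalidInputError("injected activity must be positive")
        if self.weight_kg <= 0:
            raise InvalidInputError("body weight must be positive")
        if self.isotope_half_life_h <= 0:
            raise InvalidInputError("isotope half-life must be positive")


# ---------------------------------------------------------------------------
# SUV
# ---------------------------------------------------------------------------

def suv(concentration_kbq_ml, dose_mbq: float, weight_kg: float):
    """Standardized uptake value.

    ``SUV = concentration / (dose / weight)`` with body weight interpreted as a
    water-equivalent distribution volume (1 kg = 1000 ml), so the result is
    unitless: ``conc [kBq/ml] * weight [kg] * 1000 [ml/kg] / dose [MBq] / 1000
    [kBq/MBq] = conc * weight / dose``.
    """
    if dose_mbq <= 0 or weight_kg <= 0:
        raise InvalidInputError("dose and weight must be positive")
    conc = np.asarray(concentration_kbq_ml, dtype=float)
    out = conc * weight_kg / dose_mbq
    return float(out) if out.ndim == 0 else out


def suv_peak(voxel_values: Sequence[float], n_hottest: int = 8) -> float:
    """Mean of the ``n_hottest`` largest voxel values within a VOI."""
    values = np.asarray(voxel_values, dtype=float).ravel()
    if n_hottest < 1:
        raise InvalidInputError("n_hottest must be at least 1")
    if values.size < n_hottest:
        raise InvalidInputError(
            f"need at least {n_hottest} voxel values, got {values.size}"
        )
    hottest = np.sort(values)[-n_hottest:]
    return float(hottest.mean())


def peak_support_volume_ml(voxel_mm: float = 2.344, n_voxels: int = 8) -> float:
    """Volume (ml) of the SUVpeak support: ``n`` isotropic voxels of given edge."""
    return n_voxels * (voxel_mm / 10.0) ** 3
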