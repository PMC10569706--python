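"""Synthetic blood curves, tissue TACs, and two-group cohorts.

The generator emulates the study conditions the analysis assumes: a
triexponential whole-blood input with half-lives on the printed minute/hour
scales, tissue TACs produced by the 1T/2T compartment models on the dynamic
framing protocol plus 6-h and 48-h static frames, and frame-based count noise
whose variance scales with frame duration and radioactive decay.  Cohorts
draw per-subject parameters log-normally around region-archetype means, with
a "case" group carrying elevated bone-marrow ``k3`` (higher net influx), so
that every downstream stage — input fitting, model selection, Patlak, group
statistics — can be exercised end to end without any imaging data.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .compartments import ki_macro, model_values
from .core import (
    BloodCurve,
    FramingSchedule,
    InvalidInputError,
    KineticParams,
    SubjectRecord,
    TissueTAC,
    ZR89_HALF_LIFE_HOURS,
    make_study_schedule,
)
from .identifiability import noise_sigma

__all__ = [
    "BLOOD_HALF_LIVES_MIN",
    "BLOOD_FRACTIONS",
    "REGION_ARCHETYPES",
    "CohortConfig",
    "Cohort",
    "generate_blood",
    "generate_tissue",
    "generate_cohort",
]

#: Reference blood-clearance half-lives (minutes): 5.1 min, 55.9 min, 22.1 h.
BLOOD_HALF_LIVES_MIN: tuple[float, float, float] = (5.1, 55.9, 22.1 * 60.0)
#: Reference amplitude fractions of the three components.
BLOOD_FRACTIONS: tuple[float, float, float] = (0.6, 0.3, 0.1)
#: Reference peak blood concentration, ~18.5 MBq into a ~5-liter blood pool.
BLOOD_SCALE_KBQ_ML = 4.0

#: Region parameter archetypes (vb unitless, K1 ml/cm^3/min, k's 1/min).
#: Scenario parameters chosen to exhibit the qualitative organ patterns the
#: analysis is designed around: spleen-like — high flow/permeability with fast
#: free-compartment equilibration and reversible trafficking (true 2T5P);
#: bone-marrow-like — moderate delivery, small k4 (true 2T5P); lung-like — low
#: delivery, irreversible (true 2T4P); lymph-node-like — slow delivery with
#: high binding availability (true 1T3P with slow washout).
REGION_ARCHETYPES: dict[str, KineticParams] = {
    "spleen": KineticParams(vb=0.40, K1=1.5, k2=0.85, k3=0.1, k4=0.001),
    "bone_marrow": KineticParams(vb=0.15, K1=0.25, k2=0.2, k3=0.05, k4=0.001),
    "lung": KineticParams(vb=0.15, K1=0.03, k2=0.08, k3=0.01, k4=0.0),
    "lymph_node": KineticParams(vb=0.03, K1=0.02, k2=0.01, k3=0.0, k4=0.0),
}

#: True generating model of each archetype.
REGION_TRUE_MODEL: dict[str, str] = {
    "spleen": "2T5P",
    "bone_marrow": "2T5P",
    "lung": "2T4P",
    "lymph_node": "1T3P",
}


def generate_blood(
    half_lives_min: Sequence[float] = BLOOD_HALF_LIVES_MIN,
    fractions: Sequence[float] = BLOOD_FRACTIONS,
    scale: float = BLOOD_SCALE_KBQ_ML,
) -> BloodCurve:
    """Triexponential blood curve from half-lives (minutes) and amplitude fractions.

    ``A_j = scale * f_j`` and ``lambda_j = ln2 / half_life_j``; fractions must
    be positive and sum to 1, half-lives strictly increasing.
    """
    hl = np.asarray(half_lives_min, dtype=float)
    f = np.asarray(fractions, dtype=float)
    if hl.shape != f.shape:
        raise InvalidInputError("half_lives and fractions must have matching lengths")
    if np.any(np.diff(hl) <= 0):
        raise InvalidInputError("half-lives must be strictly increasing")
    if np.any(f <= 0) or abs(f.sum() - 1.0) > 1e-9:
        raise InvalidInputError("fractions must be positive and sum to 1")
    if scale <= 0:
        raise InvalidInputError("scale must be positive")
    return BloodCurve(amplitudes=scale * f, rates=math.log(2.0) / hl)


def generate_tissue(
    params: KineticParams,
    input_curve: BloodCurve,
    schedule: FramingSchedule,
    noise_scale: float,
    seed: int,
    region: str = "sim",
    subject_id: str = "sim",
    isotope_half_life_h: float = ZR89_HALF_LIFE_HOURS,
) -> tuple[TissueTAC, dict]:
    """One noisy tissue TAC plus its ground-truth record.

    Gaussian frame noise with SD from the frame-based variance model
    (``sigma_i^2 = Sc^2 C_model e^{lambda t}/dt``); negative draws are clipped
    to zero.  ``noise_scale = 0`` returns the noiseless model TAC exactly.
    """
    rng = np.random.default_rng(seed)
    clean = model_values(params, input_curve, schedule)
    if noise_scale > 0:
        sigma = noise_sigma(clean, schedule, noise_scale, isotope_half_life_h)
        values = np.clip(clean + rng.normal(size=clean.shape) * sigma, 0.0, None)
    else:
        values = np.clip(clean, 0.0, None)
    tac = TissueTAC(region=region, schedule=schedule, values=values, subject_id=subject_id)
    truth = {
        "subject_id": subject_id,
        "region": region,
        **params.as_dict(),
        "Ki": ki_macro(params),
        "noise_scale": noise_scale,
        "seed": seed,
    }
    return tac, truth


class CohortConfig(BaseModel):
    """Configuration of a synthetic two-group cohort (seed mandatory)."""

    seed: int
    n_case: int = Field(default=5, ge=1)
    n_control: int = Field(default=3, ge=1)
    regions: tuple[str, ...] = tuple(REGION_ARCHETYPES)
    cv: float = Field(default=0.15, ge=0.0)  # between-subject CV of kinetic params
    blood_cv: float = Field(default=0.10, ge=0.0)  # CV of blood half-lives
    noise_scale: float = Field(default=0.05, ge=0.0)
    case_k3_multiplier: float = Field(default=1.5, gt=0.0)  # applied to bone marrow
    scale_kbq_ml: float = Field(default=BLOOD_SCALE_KBQ_ML, gt=0.0)
    injected_mbq: float = Field(default=18.5, gt=0.0)
    weight_kg: float = Field(default=70.0, gt=0.0)

    def model_post_init(self, _ctx):
        unknown = set(self.regions) - set(REGION_ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown region archetypes: {sorted(unknown)}")


@dataclass(frozen=True)
class Cohort:
    """A generated cohort: subjects, per-subject blood curves, TACs, and truth."""

    config: CohortConfig
    schedule: FramingSchedule
    subjects: tuple[SubjectRecord, ...]
    blood: Mapping[str, BloodCurve]
    tacs: Mapping[tuple[str, str], TissueTAC]  # (subject_id, region) -> TAC
    truth: pd.DataFrame

    def group_of(self, subject_id: str) -> str:
        return next(s.group for s in self.subjects if s.subject_id == subject_id)


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean log-normal multiplier with coefficient of variation ``cv``."""
    if cv <= 0:
        return 1.0
    s2 = math.log(1.0 + cv * cv)
    return float(rng.lognormal(mean=-0.5 * s2, sigma=math.sqrt(s2)))


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw a full synthetic cohort with the configured group structure.

    Per-subject kinetic parameters are log-normal around the region-archetype
    means (``vb`` clipped to [0, 0.6]); case subjects carry bone-marrow ``k3``
    multiplied by ``case_k3_multiplier`` (elevated net influx).  Each subject
    gets its own blood curve with log-normally perturbed half-lives and
    per-region TACs over the full three-session schedule.
    """
    rng = np.random.default_rng(config.seed)
    schedule = make_study_schedule()
    labels = [("case", i + 1) for i in range(config.n_case)] + [
        ("control", i + 1) for i in range(config.n_control)
    ]
    subjects = []
    blood: dict[str, BloodCurve] = {}
    tacs: dict[tuple[str, str], TissueTAC] = {}
    truth_rows = []
    for group, idx in labels:
        sid = f"{group}{idx:02d}"
        subjects.append(
            SubjectRecord(
                subject_id=sid, group=group,
                injected_mbq=config.injected_mbq, weight_kg=config.weight_kg,
            )
        )
        hl = np.array(BLOOD_HALF_LIVES_MIN) * np.array(
            [_lognormal_factor(rng, config.blood_cv) for _ in range(3)]
        )
        hl = np.sort(hl)
        if np.any(np.diff(hl) <= 0):  # pathological draw; nudge apart
            hl = hl * np.array([1.0, 1.001, 1.002])
        curve = generate_blood(hl, BLOOD_FRACTIONS, config.scale_kbq_ml)
        blood[sid] = curve
        for region in config.regions:
            base = REGION_ARCHETYPES[region]
            drawn = {}
            for name, value in base.as_dict().items():
                drawn[name] = value * _lognormal_factor(rng, config.cv)
            drawn["vb"] = min(max(drawn["vb"], 0.0), 0.6)
            if group == "case" and region == "bone_marrow":
                drawn["k3"] *= config.case_k3_multiplier
            params = KineticParams(**drawn)
            tac, truth = generate_tissue(
                params, curve, schedule, config.noise_scale,
                seed=int(rng.integers(2**31 - 1)), region=region, subject_id=sid,
            )
            truth["group"] = group
            tacs[(sid, region)] = tac
            truth_rows.append(truth)
    truth_df = pd.DataFrame(truth_rows)
    return Cohort(
        config=config, schedule=schedule, subjects=tuple(subjects),
        blood=blood, tacs=tacs, truth=truth_df,
    )
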