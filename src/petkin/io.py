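"""Plain-text interchange formats.

TACs travel as CSV with columns ``subject_id, region, t_start_s, t_end_s,
conc_kBq_ml`` (times in integer seconds); blood curves, fit reports, and
subject metadata as JSON.  Headers are validated strictly.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    BloodCurve,
    FramingSchedule,
    InvalidInputError,
    KineticFit,
    SubjectRecord,
    TissueTAC,
)

__all__ = [
    "TAC_COLUMNS",
    "read_tacs_csv",
    "write_tacs_csv",
    "read_blood_json",
    "write_blood_json",
    "read_subjects_json",
    "write_subjects_json",
    "fit_to_dict",
    "write_fit_json",
]

TAC_COLUMNS = ["subject_id", "region", "t_start_s", "t_end_s", "conc_kBq_ml"]


def write_tacs_csv(tacs: Iterable[TissueTAC], path) -> None:
    rows = []
    for tac in tacs:
        start_s = np.rint(tac.schedule.start * 60.0).astype(int)
        end_s = np.rint(tac.schedule.end * 60.0).astype(int)
        for s, e, v in zip(start_s, end_s, tac.values):
            rows.append((tac.subject_id, tac.region, int(s), int(e), repr(float(v))))
    pd.DataFrame(rows, columns=TAC_COLUMNS).to_csv(path, index=False)


def read_tacs_csv(path) -> list[TissueTAC]:
    """Read a TAC interchange CSV; one TAC per (subject, region), order preserved."""
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != TAC_COLUMNS:
        raise InvalidInputError(
            f"TAC CSV must have columns {TAC_COLUMNS}, got {list(df.columns)}"
        )
    tacs = []
    for (sid, region), chunk in df.groupby(["subject_id", "region"], sort=False):
        schedule = FramingSchedule(
            chunk["t_start_s"].to_numpy(dtype=float) / 60.0,
            chunk["t_end_s"].to_numpy(dtype=float) / 60.0,
        )
        tacs.append(
            TissueTAC(
                region=str(region),
                schedule=schedule,
                values=chunk["conc_kBq_ml"].to_numpy(dtype=float),
                subject_id=str(sid),
            )
        )
    return tacs


def write_blood_json(curve: BloodCurve, path, extra: dict | None = None) -> None:
    payload = {
        "format": "petkin.blood_curve/1",
        "version": __version__,
        "amplitudes_kBq_ml": [float(a) for a in curve.amplitudes],
        "rates_per_min": [float(r) for r in curve.rates],
        "half_lives_min": [float(h) for h in curve.half_lives_min],
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_blood_json(path) -> BloodCurve:
    payload = json.loads(Path(path).read_text())
    for key in ("amplitudes_kBq_ml", "rates_per_min"):
        if key not in payload:
            raise InvalidInputError(f"blood JSON missing key {key!r}")
    return BloodCurve(
        amplitudes=np.asarray(payload["amplitudes_kBq_ml"], dtype=float),
        rates=np.asarray(payload["rates_per_min"], dtype=float),
    )


def write_subjects_json(subjects: Sequence[SubjectRecord], path) -> None:
    payload = [dataclasses.asdict(s) for s in subjects]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_subjects_json(path) -> list[SubjectRecord]:
    payload = json.loads(Path(path).read_text())
    return [SubjectRecord(**entry) for entry in payload]


def fit_to_dict(fit: KineticFit) -> dict:
    return {
        "format": "petkin.kinetic_fit/1",
        "version": __version__,
        "model": fit.model,
        "params": fit.params.as_dict(),
        "fixed": sorted(fit.params.fixed),
        "wrss": fit.wrss,
        "aicc": fit.aicc,
        "Ki": fit.ki,
        "converged": fit.converged,
        "n_points": fit.n_points,
        "at_bounds": list(fit.at_bounds),
    }


def write_fit_json(fit: KineticFit, path) -> None:
    Path(path).write_text(json.dumps(fit_to_dict(fit), indent=2) + "\n")
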