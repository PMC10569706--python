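"""Small-sample-corrected AIC scoring and model selection."""
from __future__ import annotations

from dataclasses import dataclass

import math
from typing import Sequence

import pandas as pd

from .core import InvalidInputError

__all__ = ["aicc", "select_model", "SelectionResult"]

#: AICc differences below this are treated as exact ties.
_TIE_TOL = 1e-9


def aicc(wrss: float, n: int, k: int) -> float:
    """AIC with small-sample correction for a Gaussian least-squares fit.

    ``AICc = n ln(WRSS/n) + 2k + 2k(k+1)/(n-k-1)`` where ``n`` is the number of
    fitted frames and ``k`` the number of free parameters (the Gaussian noise
    variance is profiled out, so it is not counted in ``k``).
    """
    if n <= k + 1:
        raise InvalidInputError(f"AICc undefined for n={n} <= k+1={k + 1}")
    if wrss <= 0:
        raise InvalidInputError("wrss must be positive")
    return n * math.log(wrss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


@dataclass(frozen=True)
class SelectionResult:
    """Lowest-AICc fit plus the ranking table (model, k, wrss, aicc, delta_aicc)."""

    best: object  # KineticFit
    table: pd.DataFrame


def select_model(fits: Sequence) -> SelectionResult:
    """Pick the lowest-AICc fit among fits of the same data.

    Ties (|dAICc| below 1e-9) are broken toward the model with fewer free
    parameters.  All fits must have been computed on identical data and
    weights (checked via the fit's data fingerprint).
    """
    fits = list(fits)
    if len(fits) < 2:
        raise InvalidInputError("need at least two fits to select among")
    keys = {f.data_key for f in fits}
    ns = {f.n_points for f in fits}
    if len(keys) != 1 or len(ns) != 1:
        raise InvalidInputError("fits were not computed on identical data/weights")

    best = min(fits, key=lambda f: (f.aicc, f.n_free))
    for f in fits:
        if f is not best and abs(f.aicc - best.aicc) < _TIE_TOL and f.n_free < best.n_free:
            best = f
    table = pd.DataFrame(
        {
            "model": [f.model for f in fits],
            "k": [f.n_free for f in fits],
            "wrss": [f.wrss for f in fits],
            "aicc": [f.aicc for f in fits],
        }
    )
    table["delta_aicc"] = table["aicc"] - best.aicc
    table["selected"] = [f is best for f in fits]
    return SelectionResult(best=best, table=table)
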