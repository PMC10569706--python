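"""Exact small-sample rank statistics for two-group comparisons.

The group comparisons of a desk-scale cohort (a handful of subjects per arm)
need the *exact* null distribution of the Mann-Whitney U statistic: with 3-8
subjects per group the normal approximation is meaningless, and complete
separation yields the minimum attainable two-tailed p of ``2 / C(n1+n2, n1)``
(0.0357 for 5-vs-3, 0.0571 for 4-vs-3, 0.1 for 3-vs-3).

The exact null is computed by the standard counting recursion, equivalent to
enumerating all ``C(n1+n2, n1)`` group assignments.  The two-tailed p-value is
the doubled smaller tail, ``2 * min(P(U <= u), P(U >= u))``, capped at 1.
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import rankdata, t as t_dist

from .core import InvalidInputError

__all__ = [
    "TieError",
    "MannWhitneyResult",
    "SpearmanResult",
    "exact_mann_whitney",
    "spearman",
    "cohort_compare",
    "min_attainable_p",
]


class TieError(InvalidInputError):
    """Tied values in a test that assumes continuous measurements."""


@lru_cache(maxsize=None)
def _u_counts(n1: int, n2: int) -> tuple[int, ...]:
    """Number of arrangements with U = u, for u = 0..n1*n2.

    Recursion ``N(u; n1, n2) = N(u - n2; n1 - 1, n2) + N(u; n1, n2 - 1)``
    (the largest pooled observation belongs to group 1 or group 2); the total
    equals C(n1+n2, n1), i.e. this is full enumeration in counting form.
    """
    if n1 == 0 or n2 == 0:
        return (1,)
    shorter = _u_counts(n1 - 1, n2)
    longer = _u_counts(n1, n2 - 1)
    counts = []
    for u in range(n1 * n2 + 1):
        c = 0
        if 0 <= u - n2 <= (n1 - 1) * n2:
            c += shorter[u - n2]
        if u <= n1 * (n2 - 1):
            c += longer[u]
        counts.append(c)
    return tuple(counts)


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float  # U statistic of the first sample (number of (x > y) wins)
    p: float  # exact two-tailed p


def exact_mann_whitney(x, y) -> MannWhitneyResult:
    """Exact two-tailed unpaired Mann-Whitney U test.

    Assumes continuous data: any tie across the pooled sample raises
    :class:`TieError` (no tie correction is implemented).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise InvalidInputError("both groups need at least one observation")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size != pooled.size:
        raise TieError("tied values in the pooled sample")
    u = int(sum(xi > yi for xi in x for yi in y))
    counts = np.array(_u_counts(x.size, y.size), dtype=float)
    total = counts.sum()
    lower = counts[: u + 1].sum() / total
    upper = counts[u:].sum() / total
    p = min(1.0, 2.0 * min(lower, upper))
    return MannWhitneyResult(u=float(u), p=float(p))


def min_attainable_p(n1: int, n2: int) -> float:
    """Smallest two-tailed p reachable at these group sizes: 2/C(n1+n2, n1)."""
    return 2.0 / math.comb(n1 + n2, n1)


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p: float
    exact: bool  # True when p came from exact permutation enumeration


def _rho_from_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        return 0.0
    return float(rx @ ry) / denom


def spearman(x, y, exact_max_n: int = 9) -> SpearmanResult:
    """Spearman rank correlation with exact permutation p for small n.

    For ``n <= exact_max_n`` the two-sided p is the fraction of the n!
    permutations with ``|rho| >= |rho_observed|``; for larger n the usual
    t-approximation with n-2 degrees of freedom is used.  Ties are handled
    with mid-ranks and a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("x and y must be matching 1-d arrays")
    n = x.size
    if n < 3:
        raise InvalidInputError("need at least 3 pairs")
    ties = np.unique(x).size != n or np.unique(y).size != n
    if ties:
        warnings.warn("ties present; using mid-ranks")
    rx = rankdata(x)
    ry = rankdata(y)
    rho = _rho_from_ranks(rx, ry)

    if n <= exact_max_n and not ties:
        perms = np.array(list(itertools.permutations(range(1, n + 1))), dtype=float)
        rxc = rx - rx.mean()
        sc = math.sqrt(float(rxc @ rxc))
        pc = perms - perms.mean(axis=1, keepdims=True)
        rhos = (pc @ rxc) / (np.sqrt((pc * pc).sum(axis=1)) * sc)
        # count against the observed rho computed the same way (pair ry with rx)
        obs = abs(rho)
        p = float(np.mean(np.abs(rhos) >= obs - 1e-12))
        return SpearmanResult(rho=rho, p=p, exact=True)

    if abs(rho) >= 1.0:
        return SpearmanResult(rho=rho, p=0.0, exact=False)
    tstat = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = float(2.0 * t_dist.sf(abs(tstat), df=n - 2))
    return SpearmanResult(rho=rho, p=p, exact=False)


def cohort_compare(
    table: pd.DataFrame,
    metrics: list[str],
    group_col: str = "group",
    case_label: str | None = None,
    on_ties: str = "raise",
) -> pd.DataFrame:
    """Per-metric exact group comparison of a cohort table.

    ``table`` holds one row per subject with a group label column and metric
    columns.  Returns one row per metric with group medians, the U statistic,
    the exact two-tailed p, and a Bonferroni-adjusted column (reported as a
    sensitivity note; the ``significant`` flag uses the unadjusted p < 0.05).
    ``on_ties`` controls metrics with tied pooled values (the exact test
    assumes continuous data): ``"raise"`` propagates :class:`TieError`,
    ``"skip"`` reports the metric with NaN statistics instead.
    """
    if on_ties not in ("raise", "skip"):
        raise InvalidInputError("on_ties must be 'raise' or 'skip'")
    groups = sorted(table[group_col].unique())
    if len(groups) != 2:
        raise InvalidInputError("cohort comparison needs exactly two groups")
    if case_label is not None:
        if case_label not in groups:
            raise InvalidInputError(f"no group labelled {case_label!r}")
        groups = [case_label] + [g for g in groups if g != case_label]
    a, b = groups
    xa = table[table[group_col] == a]
    xb = table[table[group_col] == b]
    if len(xa) == 0 or len(xb) == 0:
        raise InvalidInputError("both groups need at least one subject")
    rows = []
    m = len(metrics)
    for metric in metrics:
        va = xa[metric].to_numpy(dtype=float)
        vb = xb[metric].to_numpy(dtype=float)
        try:
            res = exact_mann_whitney(va, vb)
            u, p = res.u, res.p
        except TieError:
            if on_ties == "raise":
                raise
            u = p = float("nan")
        rows.append(
            {
                "metric": metric,
                f"median_{a}": float(np.median(va)),
                f"median_{b}": float(np.median(vb)),
                "U": u,
                "p": p,
                "p_bonferroni": min(1.0, p * m) if p == p else float("nan"),
                "significant": bool(p < 0.05) if p == p else False,
            }
        )
    return pd.DataFrame(rows)
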