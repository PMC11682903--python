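"""Observed-vs-expected b/tsDMARD treatment-difficulty index.

For each patient the actual b/tsDMARD count is the number of previous
(failed) b/tsDMARDs plus one for the ongoing therapy.  Dividing by the
patient's follow-up time gives a rate of failure (ROF, drugs per month); the
cohort's 75th ROF percentile calibrates how many drugs a hard-to-manage
patient is *expected* to have cycled in the same time:

    expected = ceil(rate75 * months)

The observed/expected ratio flags patients: ratio <= 1 respondent,
1 < ratio <= 1.5 potential D2T, ratio > 1.5 highly potential D2T.  Because
expected >= rate75 * months, a ratio above 1 requires an ROF strictly above
the cut-off, so the flagged fraction can never materially exceed 25%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "compute_actual_count",
    "rate75",
    "expected_count",
    "difficulty_ratio",
    "compute_index",
    "CohortIndexSummary",
    "FLAG_LEVELS",
]

FLAG_LEVELS = ("respondent", "potential_d2t", "high_potential_d2t")

#: numpy quantile estimators accepted for the cut-off
QUANTILE_METHODS = (
    "linear",
    "lower",
    "higher",
    "nearest",
    "midpoint",
    "median_unbiased",
    "normal_unbiased",
    "hazen",
    "weibull",
)


def compute_actual_count(n_prev_btsdmards):
    """Actual b/tsDMARD count: previous (failed) drugs + 1 for the current one."""
    arr = np.asarray(n_prev_btsdmards)
    if np.any(arr < 0):
        raise ValueError("number of previous b/tsDMARDs cannot be negative")
    result = arr + 1
    return result.item() if np.isscalar(n_prev_btsdmards) else result


def rate75(rofs, method: str = "linear") -> float:
    """Cohort 75th percentile of the rate-of-failure distribution."""
    arr = np.asarray(rofs, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot take the 75th percentile of an empty cohort")
    if method not in QUANTILE_METHODS:
        raise ValueError(f"unknown quantile method {method!r}; choose from {QUANTILE_METHODS}")
    return float(np.quantile(arr, 0.75, method=method))


def expected_count(rate75_value: float, months: float) -> int:
    """Expected b/tsDMARD count over the patient's follow-up, rounded up.

    Strict ceiling — an exact integer stays itself — and never below 1.
    """
    if rate75_value <= 0 or months <= 0:
        raise ValueError("rate75 and follow-up months must both be positive")
    return max(1, math.ceil(rate75_value * months))


def difficulty_ratio(actual: int, expected: int) -> tuple[float, str]:
    """Observed/expected ratio and its D2T flag.

    Ties go to the respondent side: ratio exactly 1 is not flagged.
    """
    if actual < 1 or expected < 1:
        raise ValueError("actual and expected counts must both be >= 1")
    ratio = actual / expected
    if ratio <= 1.0:
        flag = "respondent"
    elif ratio <= 1.5:
        flag = "potential_d2t"
    else:
        flag = "high_potential_d2t"
    return ratio, flag


@dataclass(frozen=True)
class CohortIndexSummary:
    rate75: float
    quantile_method: str
    n_patients: int
    n_ratio_gt1: int
    prop_ratio_gt1: float
    n_ratio_gt15: int


def compute_index(
    cohort: pd.DataFrame,
    time_col: str = "months_since_diagnosis",
    method: str = "linear",
    frozen_rate75: float | None = None,
) -> tuple[pd.DataFrame, CohortIndexSummary]:
    """Per-patient difficulty index for a whole cohort.

    The 75th-percentile cut-off is recomputed from this cohort unless a
    frozen reference value is supplied (for applying one cohort's calibration
    to another).  ``time_col`` selects the follow-up definition; the default
    is months since PsA diagnosis, the duration the cohort schema records.
    """
    if cohort.empty:
        raise ValueError("empty cohort")
    months = cohort[time_col].to_numpy(dtype=float)
    if np.any(~np.isfinite(months)) or np.any(months <= 0):
        raise ValueError("follow-up months must be positive and non-missing")
    actual = compute_actual_count(cohort["n_prev_btsdmards"].to_numpy(dtype=int))
    rof = actual / months
    cut = rate75(rof, method=method) if frozen_rate75 is None else float(frozen_rate75)
    expected = np.array([expected_count(cut, m) for m in months])
    pairs = [difficulty_ratio(int(a), int(e)) for a, e in zip(actual, expected)]
    ratios = np.array([p[0] for p in pairs])
    flags = [p[1] for p in pairs]
    table = pd.DataFrame(
        {
            "patient_id": cohort["patient_id"].to_numpy(),
            "actual_count": actual,
            "follow_up_months": months,
            "rof": rof,
            "expected_count": expected,
            "ratio": ratios,
            "flag": flags,
        }
    )
    summary = CohortIndexSummary(
        rate75=cut,
        quantile_method=method if frozen_rate75 is None else "frozen",
        n_patients=len(table),
        n_ratio_gt1=int((ratios > 1).sum()),
        prop_ratio_gt1=float((ratios > 1).mean()),
        n_ratio_gt15=int((ratios > 1.5).sum()),
    )
    return table, summary
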