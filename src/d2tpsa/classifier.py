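"""Rule-based difficult-to-treat (D2T) classification and Firth-penalized
univariate association analysis.

The classifier applies the preliminary, RA-adapted three-criterion D2T
definition to each patient: (1) failure of at least ``min_failed_btsdmards``
b/tsDMARDs (the count excludes the ongoing therapy), (2) at-least-moderate
disease activity by DAPSA, and (3) disease management perceived as
problematic.  All three must hold.  Because D2T patients are rare, univariate
associations with D2T status are estimated by logistic regression with the
Firth (Jeffreys-prior) penalty, which stays finite under complete separation
and reduces small-sample bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "D2TCriteria",
    "D2TStatus",
    "EffectEstimate",
    "dapsa_category",
    "classify_d2t",
    "classify_cohort",
    "firth_logistic",
    "firth_univariate",
    "FirthFit",
    "EstimationError",
]

DAPSA_CATEGORIES = ("remission", "low", "moderate", "high")
DEFAULT_DAPSA_CUTPOINTS = (4.0, 14.0, 28.0)


class EstimationError(RuntimeError):
    """Raised when an association model cannot be estimated."""


def dapsa_category(dapsa, cutpoints: Sequence[float] = DEFAULT_DAPSA_CUTPOINTS):
    """DAPSA disease-activity category.

    Boundaries belong to the lower category: with the default cutpoints
    (4, 14, 28), DAPSA <= 4 is remission, <= 14 low, <= 28 moderate, > 28
    high.  A missing DAPSA yields a missing category (``None``) — it is never
    silently treated as remission.
    """
    if dapsa is None or (isinstance(dapsa, float) and np.isnan(dapsa)):
        return None
    if dapsa < 0:
        raise ValueError("DAPSA must be nonnegative")
    cut = tuple(cutpoints)
    if any(b <= a for a, b in zip(cut, cut[1:])):
        raise ValueError("cutpoints must be strictly increasing")
    for bound, cat in zip(cut, DAPSA_CATEGORIES):
        if dapsa <= bound:
            return cat
    return DAPSA_CATEGORIES[-1]


@dataclass(frozen=True)
class D2TCriteria:
    """Configurable three-criterion D2T rule.

    ``require_distinct_moa`` is honoured only when per-drug mechanism data
    exist; the cohort schema carries none, so the failure criterion is
    count-only by default.
    """

    min_failed_btsdmards: int = 2
    require_distinct_moa: bool = True
    dapsa_activity_threshold: float = 14.0
    management_problematic_required: bool = True

    def __post_init__(self):
        if self.min_failed_btsdmards < 1:
            raise ValueError("min_failed_btsdmards must be >= 1")
        if self.dapsa_activity_threshold < 0:
            raise ValueError("DAPSA threshold must be nonnegative")


@dataclass(frozen=True)
class D2TStatus:
    is_d2t: bool
    criterion_breakdown: Mapping[str, bool | None]
    dapsa_category: str | None
    indeterminate: bool = False


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and np.isnan(value))


def classify_d2t(patient: Mapping, criteria: D2TCriteria = D2TCriteria()) -> D2TStatus:
    """Evaluate the three D2T criteria on one patient.

    A missing field needed by an enabled criterion makes the status
    indeterminate: the patient is not counted as D2T and the breakdown marks
    the criterion ``None``.
    """
    breakdown: dict[str, bool | None] = {}

    n_prev = patient.get("n_prev_btsdmards")
    breakdown["failed_btsdmards"] = (
        None if _is_missing(n_prev) else bool(n_prev >= criteria.min_failed_btsdmards)
    )

    dapsa = patient.get("dapsa")
    cat = dapsa_category(dapsa) if not _is_missing(dapsa) else None
    breakdown["active_disease"] = (
        None if _is_missing(dapsa) else bool(dapsa > criteria.dapsa_activity_threshold)
    )

    if criteria.management_problematic_required:
        mp = patient.get("management_problematic")
        breakdown["management_problematic"] = None if _is_missing(mp) else bool(mp)
    else:
        breakdown["management_problematic"] = True

    indeterminate = any(v is None for v in breakdown.values())
    is_d2t = (not indeterminate) and all(breakdown.values())
    return D2TStatus(is_d2t, breakdown, cat, indeterminate)


def classify_cohort(cohort: pd.DataFrame, criteria: D2TCriteria = D2TCriteria()) -> pd.DataFrame:
    """Apply :func:`classify_d2t` row-wise; returns the per-patient flag table."""
    rows = []
    for _, row in cohort.iterrows():
        status = classify_d2t(row, criteria)
        rows.append(
            {
                "patient_id": row["patient_id"],
                "is_d2t": int(status.is_d2t),
                "indeterminate": int(status.indeterminate),
                "dapsa_category": status.dapsa_category,
                **{f"criterion_{k}": status.criterion_breakdown[k]
                   for k in status.criterion_breakdown},
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Firth-penalized logistic regression
# ---------------------------------------------------------------------------

@dataclass
class FirthFit:
    params: pd.Series
    cov: pd.DataFrame
    loglik_penalized: float
    n_iter: int
    converged: bool


def _penalized_loglik(beta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    eta = X @ beta
    ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
    pi = expit(eta)
    W = pi * (1.0 - pi)
    info = X.T @ (X * W[:, None])
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


def firth_logistic(
    X,
    y,
    names: Sequence[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> FirthFit:
    """Maximize the Jeffreys-penalized logistic likelihood by Newton steps.

    The penalty 0.5*log det I(beta) yields the bias-reduced (Firth)
    estimator; its modified score is U*(b) = X'(y - pi + h(0.5 - pi)) with h
    the hat diagonal.  Step-halving guards against overshooting.  Estimates
    are finite for any data configuration, including complete separation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    beta = np.zeros(p)
    ll = _penalized_loglik(beta, X, y)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        pi = expit(X @ beta)
        W = pi * (1.0 - pi)
        info = X.T @ (X * W[:, None])
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError as exc:
            raise EstimationError("singular information matrix") from exc
        # hat diagonal of W^1/2 X (X'WX)^-1 X' W^1/2
        h = np.einsum("ij,jk,ik->i", X * W[:, None], info_inv, X)
        score = X.T @ (y - pi + h * (0.5 - pi))
        step = info_inv @ score
        # step-halving on the penalized log-likelihood
        for _ in range(25):
            candidate = beta + step
            ll_new = _penalized_loglik(candidate, X, y)
            if ll_new >= ll - 1e-12:
                break
            step = step / 2.0
        beta, ll = candidate, ll_new
        if np.max(np.abs(score)) < tol or np.max(np.abs(step)) < tol:
            converged = True
            break
    pi = expit(X @ beta)
    W = pi * (1.0 - pi)
    info = X.T @ (X * W[:, None])
    cov = np.linalg.inv(info)
    return FirthFit(
        params=pd.Series(beta, index=list(names)),
        cov=pd.DataFrame(cov, index=list(names), columns=list(names)),
        loglik_penalized=ll,
        n_iter=it,
        converged=converged,
    )


@dataclass(frozen=True)
class EffectEstimate:
    covariate: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    scale: str  # "per unit" for continuous, "presence vs absence" for binary


def firth_univariate(
    cohort: pd.DataFrame,
    outcome: Sequence[int] | np.ndarray,
    covariate: str,
    level: float = 0.95,
) -> EffectEstimate:
    """Single-covariate Firth logistic association with D2T status.

    Returns the odds ratio exp(beta) with a Wald interval from the penalized
    information.  Rows with a missing covariate are dropped pairwise.
    """
    from scipy.stats import norm

    y = np.asarray(outcome, dtype=float)
    x = cohort[covariate].to_numpy(dtype=float)
    keep = ~np.isnan(x)
    x, y = x[keep], y[keep]
    if y.sum() < 1:
        raise EstimationError("outcome has no events")
    if np.ptp(x) == 0:
        raise EstimationError(f"covariate {covariate!r} has zero variance")
    X = np.column_stack([np.ones_like(x), x])
    fit = firth_logistic(X, y, names=["const", covariate])
    beta = fit.params[covariate]
    se = float(np.sqrt(fit.cov.loc[covariate, covariate]))
    z = norm.ppf(0.5 + level / 2.0)
    is_binary = set(np.unique(x)) <= {0.0, 1.0}
    return EffectEstimate(
        covariate=covariate,
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z * se)),
        ci_high=float(np.exp(beta + z * se)),
        scale="presence vs absence" if is_binary else "per unit",
    )
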