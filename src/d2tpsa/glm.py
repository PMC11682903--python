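"""Poisson-offset relative-difficulty model.

The treatment-difficulty regression treats the actual b/tsDMARD count A_i as
a Poisson response with log link and the log of the expected count as an
offset, so that exp(eta_i - offset_i) models the observed/expected ratio and
each exp(beta) is a relative-difficulty ratio.  Categorical covariates enter
as dummy codes against a named reference level; continuous covariates enter
linearly or through a restricted (natural) cubic spline basis, with the
nonlinear terms testable by Wald statistics.

Fitting is delegated to statsmodels' IRLS GLM; this module owns the design
construction (dummy blocks, Harrell-knot spline bases), the covariate-block
bookkeeping used by backward selection and bagging, and the exponentiated
effect reporting (per-level rate ratios; inter-quartile contrasts for
splined covariates).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "SplineSpec",
    "Covariate",
    "ModelSpec",
    "Design",
    "GLMFit",
    "WaldResult",
    "rcs_basis",
    "rcs_knots",
    "build_design",
    "freeze_splines",
    "fit_poisson_offset",
    "fit_model",
    "wald_test",
    "relative_difficulty",
    "DesignError",
]

Z95 = 1.959964  # normal quantile for 95% intervals


class DesignError(ValueError):
    """Unusable design matrix (rank deficiency, bad spline spec, ...)."""


# ---------------------------------------------------------------------------
# Restricted cubic splines (Harrell convention)
# ---------------------------------------------------------------------------

#: default knot placement quantiles, by number of knots
_KNOT_QUANTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
    6: (0.05, 0.23, 0.41, 0.59, 0.77, 0.95),
    7: (0.025, 0.18333, 0.34167, 0.50, 0.65833, 0.81667, 0.975),
}


def rcs_knots(x, n_knots: int = 3) -> np.ndarray:
    """Quantile-based knot locations for a restricted cubic spline."""
    if n_knots not in _KNOT_QUANTILES:
        raise DesignError(f"n_knots must be one of {sorted(_KNOT_QUANTILES)}, got {n_knots}")
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    knots = np.quantile(x, _KNOT_QUANTILES[n_knots])
    if np.any(np.diff(knots) <= 0):
        raise DesignError(
            "knot locations are not strictly increasing; too few distinct values "
            "— consider linear coding for this covariate"
        )
    return knots


def rcs_basis(x, knots: Sequence[float]) -> np.ndarray:
    """Restricted (natural) cubic spline basis with k knots -> k-1 columns.

    Column 0 is x itself; columns 1..k-2 are the nonlinear terms

        C_j(x) = [ (x-t_j)+^3 - (x-t_{k-1})+^3 (t_k-t_j)/(t_k-t_{k-1})
                   + (x-t_k)+^3 (t_{k-1}-t_j)/(t_k-t_{k-1}) ] / (t_k-t_1)^2

    which are 0 below the first knot and linear in x above the last, so the
    fitted curve is linear beyond the boundary knots.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    k = t.size
    if k < 3:
        raise DesignError("a restricted cubic spline needs at least 3 knots")
    if np.any(np.diff(t) <= 0):
        raise DesignError("knots must be strictly increasing")
    norm = (t[-1] - t[0]) ** 2
    cols = [x]
    for j in range(k - 2):
        term = (
            np.maximum(x - t[j], 0.0) ** 3
            - np.maximum(x - t[-2], 0.0) ** 3 * (t[-1] - t[j]) / (t[-1] - t[-2])
            + np.maximum(x - t[-1], 0.0) ** 3 * (t[-2] - t[j]) / (t[-1] - t[-2])
        )
        cols.append(term / norm)
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# Model specification and design construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplineSpec:
    n_knots: int = 3
    knots: tuple[float, ...] | None = None  # explicit locations override quantiles


@dataclass(frozen=True)
class Covariate:
    """One model covariate with its coding.

    kind: "binary" (0/1 column), "categorical" (string column, dummy-coded
    against ``ref``), or "continuous" ("linear" or "rcs" coding).
    """

    name: str
    kind: str = "binary"
    coding: str = "linear"
    ref: str | None = None
    spline: SplineSpec = field(default_factory=SplineSpec)
    label: str | None = None


@dataclass(frozen=True)
class ModelSpec:
    response: str
    offset: str  # column holding the *expected count*; its log is the offset
    covariates: tuple[Covariate, ...]

    def names(self) -> list[str]:
        return [c.name for c in self.covariates]

    def drop(self, name: str) -> "ModelSpec":
        return replace(self, covariates=tuple(c for c in self.covariates if c.name != name))


@dataclass
class Design:
    y: np.ndarray
    X: pd.DataFrame          # includes leading "const" column
    offset: np.ndarray       # log expected count
    blocks: dict[str, list[str]]  # covariate -> its design columns
    knots: dict[str, np.ndarray]  # splined covariate -> knot locations used


def _dummy_columns(series: pd.Series, name: str, ref: str) -> pd.DataFrame:
    levels = [lv for lv in pd.unique(series.dropna()) if lv != ref]
    if ref not in set(series.dropna()):
        raise DesignError(f"reference level {ref!r} absent from {name!r}")
    out = {}
    for lv in sorted(map(str, levels)):
        out[f"{name}[{lv}]"] = (series.astype(str) == lv).astype(float).to_numpy()
    return pd.DataFrame(out, index=series.index)


def build_design(df: pd.DataFrame, spec: ModelSpec) -> Design:
    """Assemble response, offset and dummy/spline design blocks.

    Spline knots default to data quantiles of the supplied frame; call
    :func:`freeze_splines` first when the same coding must be reused across
    bootstrap resamples or new cohorts.
    """
    y = df[spec.response].to_numpy(dtype=float)
    expected = df[spec.offset].to_numpy(dtype=float)
    if np.any(expected <= 0):
        raise DesignError("offset column must hold strictly positive expected counts")
    offset = np.log(expected)

    cols = {"const": np.ones(len(df))}
    blocks: dict[str, list[str]] = {}
    knots_used: dict[str, np.ndarray] = {}
    for cov in spec.covariates:
        s = df[cov.name]
        if cov.kind == "categorical":
            if cov.ref is None:
                raise DesignError(f"categorical covariate {cov.name!r} needs a reference level")
            dummies = _dummy_columns(s, cov.name, cov.ref)
            for c in dummies.columns:
                cols[c] = dummies[c].to_numpy()
            blocks[cov.name] = list(dummies.columns)
        elif cov.kind == "binary" or (cov.kind == "continuous" and cov.coding == "linear"):
            cols[cov.name] = s.to_numpy(dtype=float)
            blocks[cov.name] = [cov.name]
        elif cov.kind == "continuous" and cov.coding == "rcs":
            knots = (
                np.asarray(cov.spline.knots, dtype=float)
                if cov.spline.knots is not None
                else rcs_knots(s.to_numpy(dtype=float), cov.spline.n_knots)
            )
            xv = s.to_numpy(dtype=float)
            if np.unique(xv[~np.isnan(xv)]).size < len(knots):
                raise DesignError(
                    f"{cov.name!r} has fewer distinct values than knots — "
                    "consider linear coding"
                )
            basis = rcs_basis(xv, knots)
            names = [cov.name + "'" * j for j in range(basis.shape[1])]
            for j, nm in enumerate(names):
                cols[nm] = basis[:, j]
            blocks[cov.name] = names
            knots_used[cov.name] = knots
        else:
            raise DesignError(f"unknown coding {cov.kind}/{cov.coding} for {cov.name!r}")
    X = pd.DataFrame(cols, index=df.index)
    return Design(y=y, X=X, offset=offset, blocks=blocks, knots=knots_used)


def resolve_codings(df: pd.DataFrame, spec: ModelSpec) -> ModelSpec:
    """Downgrade spline codings the data cannot support to linear.

    Heavily zero-inflated scores (e.g. a physician global assessment whose
    median is 0) can place coincident quantile knots; such covariates are
    recoded linear, with a log record, rather than aborting the model.
    """
    import logging

    new = []
    for cov in spec.covariates:
        if cov.kind == "continuous" and cov.coding == "rcs" and cov.spline.knots is None:
            x = df[cov.name].to_numpy(dtype=float)
            try:
                rcs_knots(x, cov.spline.n_knots)
            except DesignError:
                logging.getLogger("d2tpsa").info(
                    "recoding %r linear: spline knots cannot be placed", cov.name
                )
                cov = replace(cov, coding="linear")
        new.append(cov)
    return replace(spec, covariates=tuple(new))


def freeze_splines(df: pd.DataFrame, spec: ModelSpec) -> ModelSpec:
    """Resolve data-dependent spline knots once, returning a spec with
    explicit knot locations (stable across resamples)."""
    new = []
    for cov in spec.covariates:
        if cov.kind == "continuous" and cov.coding == "rcs" and cov.spline.knots is None:
            knots = rcs_knots(df[cov.name].to_numpy(dtype=float), cov.spline.n_knots)
            cov = replace(cov, spline=SplineSpec(cov.spline.n_knots, tuple(knots)))
        new.append(cov)
    return replace(spec, covariates=tuple(new))


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class GLMFit:
    params: pd.Series
    cov: pd.DataFrame
    loglik: float
    aic: float
    fitted: np.ndarray
    n_iter: int
    converged: bool
    nobs: int


def _aliased_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    return [names[j] for j in range(len(names)) if diag[j] <= tol]


def fit_poisson_offset(y, X: pd.DataFrame, offset) -> GLMFit:
    """Maximum-likelihood Poisson GLM with log link and fixed offset (IRLS).

    Converges on relative deviance change below 1e-8 (at most 100
    iterations); the covariance is the inverse Fisher information at the
    optimum and the AIC is -2 loglik + 2 (number of coefficients).
    """
    y = np.asarray(y, dtype=float)
    offset = np.asarray(offset, dtype=float)
    Xv = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
        raise DesignError(f"rank-deficient design; aliased columns: {_aliased_columns(Xv, list(X.columns))}")
    model = sm.GLM(y, Xv, family=sm.families.Poisson(), offset=offset)
    res = model.fit(maxiter=100, tol=1e-8, tol_criterion="deviance")
    names = list(X.columns)
    return GLMFit(
        params=pd.Series(res.params, index=names),
        cov=pd.DataFrame(res.cov_params(), index=names, columns=names),
        loglik=float(res.llf),
        aic=float(res.aic),
        fitted=np.asarray(res.fittedvalues),
        n_iter=int(getattr(res, "fit_history", {}).get("iteration", 0) or len(getattr(res, "fit_history", {}).get("deviance", []))),
        converged=bool(res.converged),
        nobs=int(res.nobs),
    )


def fit_model(df: pd.DataFrame, spec: ModelSpec) -> tuple[GLMFit, Design]:
    design = build_design(df, spec)
    return fit_poisson_offset(design.y, design.X, design.offset), design


# ---------------------------------------------------------------------------
# Inference and reporting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaldResult:
    statistic: float
    df: int
    p_value: float


def wald_test(fit: GLMFit, terms: Sequence[str]) -> WaldResult:
    """Joint Wald chi-square test that the named coefficients are all zero."""
    terms = list(terms)
    if not terms:
        return WaldResult(0.0, 0, 1.0)
    b = fit.params[terms].to_numpy()
    V = fit.cov.loc[terms, terms].to_numpy()
    try:
        stat = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError as exc:
        raise DesignError("singular covariance sub-matrix in Wald test") from exc
    dfree = len(terms)
    return WaldResult(stat, dfree, float(stats.chi2.sf(stat, dfree)))


def relative_difficulty(
    fit: GLMFit,
    design: Design,
    spec: ModelSpec,
    df: pd.DataFrame,
    z: float = Z95,
) -> pd.DataFrame:
    """Exponentiated effects: relative-difficulty ratios with 95% CIs.

    Binary and dummy-coded covariates are reported per level versus the
    reference; linear continuous covariates per unit; splined covariates as
    the 75th-vs-25th-percentile contrast of the fitted curve (a single
    exp(beta) is undefined for a multi-column term), with a delta-method
    interval.  The p-value is the block Wald test; splined covariates also
    carry the nonlinearity test on their nonlinear columns.
    """
    rows = []
    for cov in spec.covariates:
        block = design.blocks[cov.name]
        block_p = wald_test(fit, block).p_value
        if cov.kind == "continuous" and cov.coding == "rcs":
            knots = design.knots.get(cov.name)
            if knots is None and cov.spline.knots is not None:
                knots = np.asarray(cov.spline.knots)
            x = df[cov.name].to_numpy(dtype=float)
            q25, q75 = np.nanquantile(x, [0.25, 0.75])
            contrast = rcs_basis(np.array([q75]), knots)[0] - rcs_basis(np.array([q25]), knots)[0]
            b = fit.params[block].to_numpy()
            V = fit.cov.loc[block, block].to_numpy()
            est = float(contrast @ b)
            se = float(np.sqrt(contrast @ V @ contrast))
            nonlin = wald_test(fit, block[1:])
            rows.append(
                {
                    "covariate": cov.name,
                    "term": f"{cov.name} (Q3 vs Q1)",
                    "effect": float(np.exp(est)),
                    "ci_low": float(np.exp(est - z * se)),
                    "ci_high": float(np.exp(est + z * se)),
                    "p_value": block_p,
                    "p_nonlinear": nonlin.p_value,
                    "scale": f"contrast {q75:.3g} vs {q25:.3g}",
                }
            )
        else:
            for col in block:
                b = float(fit.params[col])
                se = float(np.sqrt(fit.cov.loc[col, col]))
                rows.append(
                    {
                        "covariate": cov.name,
                        "term": col,
                        "effect": float(np.exp(b)),
                        "ci_low": float(np.exp(b - z * se)),
                        "ci_high": float(np.exp(b + z * se)),
                        "p_value": block_p,
                        "p_nonlinear": np.nan,
                        "scale": "per unit" if cov.kind == "continuous" else "vs reference",
                    }
                )
    return pd.DataFrame(rows)
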