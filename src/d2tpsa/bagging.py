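"""Bootstrap-bagged backward-AIC variable selection and model averaging.

The multivariable procedure: restrict to complete cases, run backward
elimination on covariate *blocks* (all dummy/spline columns of one covariate
move together) using the Akaike Information Criterion, and repeat the
selection on B bootstrap resamples (default 1000).  Every covariate stays in
the final model: its averaged coefficient is the mean of its per-resample
coefficients with zeros imputed whenever the backward step dropped it, which
equals (selection frequency) x (mean coefficient conditional on selection) —
an automatic shrinkage of weakly supported effects toward zero.

The final model predicts each patient's observed/expected difficulty ratio
as exp(x' beta_bar) (the offset cancels by construction) and feeds a
points-based nomogram of per-covariate contributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glm import (
    Design,
    DesignError,
    GLMFit,
    ModelSpec,
    build_design,
    fit_poisson_offset,
    freeze_splines,
)

__all__ = [
    "BaggingConfig",
    "BaggingResult",
    "FinalModel",
    "complete_cases",
    "backward_aic",
    "bootstrap_bag",
    "average_coefficients",
    "predict_and_stratify",
    "nomogram_table",
]

logger = logging.getLogger("d2tpsa")


def complete_cases(cohort: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Rows with no missing value in any listed covariate.

    Index fields (counts, follow-up) are never missing by construction, so
    only model covariates decide retention.
    """
    if not covariates:
        raise ValueError("covariate list must be nonempty")
    kept = cohort.dropna(subset=covariates)
    logger.info("complete cases: retained %d of %d rows", len(kept), len(cohort))
    if kept.empty:
        raise ValueError(
            "no complete cases for the requested covariates; reduce the covariate set"
        )
    return kept


# ---------------------------------------------------------------------------
# Backward AIC on covariate blocks
# ---------------------------------------------------------------------------

def backward_aic(
    df: pd.DataFrame, spec: ModelSpec
) -> tuple[ModelSpec, GLMFit, list[tuple[str, float]]]:
    """Backward elimination of covariate blocks while the AIC decreases.

    At each step the block whose removal lowers the AIC the most is dropped
    (ties broken in favour of the block earliest in the specification
    order); elimination stops when no removal improves the AIC.  The
    intercept and the offset are never candidates.  Returns the selected
    spec, its fit, and the accepted AIC path [(dropped_name_or_"<full>",
    aic), ...], strictly decreasing after the first entry.
    """
    current = spec
    fit, _ = _fit(df, current)
    path = [("<full>", fit.aic)]
    while current.covariates:
        best_name, best_fit, best_aic = None, None, fit.aic
        for cov in current.covariates:
            candidate = current.drop(cov.name)
            try:
                cand_fit, _ = _fit(df, candidate)
            except DesignError:
                continue
            # strict improvement required; first (spec-order) block wins ties
            if cand_fit.aic < best_aic - 1e-12:
                best_name, best_fit, best_aic = cov.name, cand_fit, cand_fit.aic
        if best_name is None:
            break
        current, fit = current.drop(best_name), best_fit
        path.append((best_name, best_aic))
    return current, fit, path


def _fit(df: pd.DataFrame, spec: ModelSpec) -> tuple[GLMFit, Design]:
    design = build_design(df, spec)
    return fit_poisson_offset(design.y, design.X, design.offset), design


# ---------------------------------------------------------------------------
# Bagging
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BaggingConfig:
    n_resamples: int = 1000
    seed: int = 0
    no_resample: bool = False  # diagnostic mode: every "resample" is the data itself

    def __post_init__(self):
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")


@dataclass
class BaggingResult:
    column_names: list[str]               # full design columns, const first
    blocks: dict[str, list[str]]          # covariate -> design columns
    selection_frequency: pd.Series        # per covariate
    coefficient_draws: pd.DataFrame       # B x columns, zeros when unselected
    averaged_coefficients: pd.Series      # per design column
    resample_log: list[dict] = field(default_factory=list)
    n_degenerate: int = 0


def bootstrap_bag(
    df: pd.DataFrame, spec: ModelSpec, config: BaggingConfig
) -> BaggingResult:
    """Backward-AIC selection on B bootstrap resamples of the complete-case data.

    Spline knots are frozen on the full data so coefficients stay
    conformable across resamples.  A resample on which the full model cannot
    be fitted (a dummy level or binary covariate absent, rank deficiency) is
    recorded as degenerate and re-drawn; more than 20% degenerate draws
    aborts with advice to prune the covariate set.
    """
    spec = freeze_splines(df, spec)
    full_design = build_design(df, spec)
    columns = list(full_design.X.columns)
    blocks = full_design.blocks
    B = config.n_resamples
    rng = np.random.default_rng(config.seed)
    n = len(df)

    draws = np.zeros((B, len(columns)))
    selected_sets: list[frozenset] = []
    log: list[dict] = []
    n_degenerate = 0
    max_degenerate = max(1, int(np.ceil(0.2 * B)))

    for b in range(B):
        while True:
            if config.no_resample:
                sample = df
            else:
                idx = rng.integers(0, n, size=n)
                sample = df.iloc[idx]
            try:
                sel_spec, sel_fit, path = backward_aic(sample, spec)
            except DesignError:
                n_degenerate += 1
                if n_degenerate > max_degenerate:
                    raise RuntimeError(
                        f"more than 20% of bootstrap resamples were degenerate "
                        f"({n_degenerate} of ~{b + 1}); prune rare covariate levels"
                    )
                continue
            break
        retained = frozenset(sel_spec.names())
        selected_sets.append(retained)
        draws[b, 0] = sel_fit.params["const"]
        for cov_name in retained:
            for col in blocks[cov_name]:
                draws[b, columns.index(col)] = sel_fit.params[col]
        log.append({"resample": b, "retained": sorted(retained),
                    "aic": sel_fit.aic, "steps": len(path) - 1})

    freq = pd.Series(
        {name: np.mean([name in s for s in selected_sets]) for name in blocks},
        name="selection_frequency",
    )
    result = BaggingResult(
        column_names=columns,
        blocks=blocks,
        selection_frequency=freq,
        coefficient_draws=pd.DataFrame(draws, columns=columns),
        averaged_coefficients=pd.Series(draws.mean(axis=0), index=columns),
        resample_log=log,
        n_degenerate=n_degenerate,
    )
    if n_degenerate:
        logger.info("bootstrap_bag: %d degenerate resamples re-drawn", n_degenerate)
    return result


@dataclass
class FinalModel:
    spec: ModelSpec
    coefficients: pd.Series        # averaged, over all design columns
    blocks: dict[str, list[str]]
    selection_frequency: pd.Series


def average_coefficients(spec: ModelSpec, result: BaggingResult) -> FinalModel:
    """Zero-imputed bagged coefficient means -> the final (all-covariate) model.

    Per design column the average equals selection frequency times the mean
    coefficient conditional on selection; a never-selected covariate
    averages to exactly 0 yet remains part of the model.
    """
    return FinalModel(
        spec=spec,
        coefficients=result.averaged_coefficients.copy(),
        blocks=result.blocks,
        selection_frequency=result.selection_frequency.copy(),
    )


# ---------------------------------------------------------------------------
# Prediction, stratification, nomogram
# ---------------------------------------------------------------------------

STRATA = ("<=1", "(1,1.5]", ">1.5")


def predict_and_stratify(
    final: FinalModel, cohort: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Predicted observed/expected ratio exp(x' beta_bar) and its stratum.

    Because the model's linear predictor is offset by the log expected
    count, exp(eta - offset) = exp(x' beta) is exactly the modelled ratio,
    so no offset enters prediction.  Patients missing a model covariate are
    skipped (logged).  Also returns the per-stratum conditional covariate
    distribution table (medians/means by predicted stratum).
    """
    usable, design = _design_for(final, cohort)
    n_skipped = len(cohort) - len(usable)
    if n_skipped:
        logger.info("predict_and_stratify: skipped %d rows with missing covariates", n_skipped)
    eta = design.X.to_numpy() @ final.coefficients[list(design.X.columns)].to_numpy()
    ratio = np.exp(eta)
    stratum = np.where(ratio <= 1.0, STRATA[0], np.where(ratio <= 1.5, STRATA[1], STRATA[2]))
    pred = pd.DataFrame(
        {
            "patient_id": usable["patient_id"].to_numpy(),
            "predicted_ratio": ratio,
            "stratum": stratum,
        }
    )
    dist = _stratified_distributions(usable.assign(stratum=stratum), final)
    return pred, dist


def _stratified_distributions(df: pd.DataFrame, final: FinalModel) -> pd.DataFrame:
    rows = []
    for cov in final.spec.covariates:
        for stratum in STRATA:
            sub = df.loc[df["stratum"] == stratum, cov.name]
            if cov.kind in ("binary",):
                rows.append({"covariate": cov.name, "stratum": stratum,
                             "n": int(sub.notna().sum()),
                             "summary": f"{sub.mean() * 100:.1f}%" if len(sub) else ""})
            elif cov.kind == "categorical":
                top = sub.mode()
                rows.append({"covariate": cov.name, "stratum": stratum,
                             "n": int(sub.notna().sum()),
                             "summary": str(top.iloc[0]) if len(top) else ""})
            else:
                rows.append({"covariate": cov.name, "stratum": stratum,
                             "n": int(sub.notna().sum()),
                             "summary": f"{sub.median():.3g} [{sub.quantile(0.25):.3g}, {sub.quantile(0.75):.3g}]"
                             if len(sub) else ""})
    return pd.DataFrame(rows)


def _design_for(final: FinalModel, cohort: pd.DataFrame) -> tuple[pd.DataFrame, Design]:
    usable = cohort.dropna(subset=[c.name for c in final.spec.covariates])
    spec = freeze_splines(usable, final.spec)
    work = usable.copy()
    for needed in (spec.response, spec.offset):
        if needed not in work.columns:
            work[needed] = 1.0
    return usable, build_design(work, spec)


def nomogram_table(final: FinalModel, cohort: pd.DataFrame) -> pd.DataFrame:
    """Points-based decomposition of the final model's linear predictor.

    Each covariate's contribution range (over the values observed in the
    cohort; exactly |beta| for a binary flag) is rescaled so the widest
    covariate spans 100 points; a patient's total points map linearly back
    to the linear predictor and exponentially to the predicted ratio:

        LP = intercept + sum(min contributions) + total_points * unit
        predicted ratio = exp(LP),   unit = max_range / 100.

    The mapping constants are emitted as ``_scale`` rows so the round trip
    is exact.
    """
    usable, design = _design_for(final, cohort)
    contribs = {}
    for name, cols in final.blocks.items():
        block = design.X[cols].to_numpy() @ final.coefficients[cols].to_numpy()
        contribs[name] = (float(block.min()), float(block.max()))
    ranges = {name: hi - lo for name, (lo, hi) in contribs.items()}
    max_range = max(ranges.values())
    if max_range <= 0:
        raise ValueError("all averaged coefficients are zero; nomogram undefined")
    unit = max_range / 100.0
    rows = [
        {
            "covariate": name,
            "contribution_min": lo,
            "contribution_max": hi,
            "points": (hi - lo) / unit,
        }
        for name, (lo, hi) in contribs.items()
    ]
    base = float(final.coefficients["const"]) + sum(lo for lo, _ in contribs.values())
    rows.append({"covariate": "_scale.points_per_lp_unit", "contribution_min": np.nan,
                 "contribution_max": np.nan, "points": 1.0 / unit})
    rows.append({"covariate": "_scale.lp_at_zero_points", "contribution_min": np.nan,
                 "contribution_max": np.nan, "points": base})
    return pd.DataFrame(rows)


def patient_points(final: FinalModel, cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-patient nomogram points by covariate, plus the total."""
    usable, design = _design_for(final, cohort)
    contribs = {}
    for name, cols in final.blocks.items():
        contribs[name] = design.X[cols].to_numpy() @ final.coefficients[cols].to_numpy()
    mins = {name: v.min() for name, v in contribs.items()}
    max_range = max(v.max() - v.min() for v in contribs.values())
    unit = max_range / 100.0
    out = pd.DataFrame({"patient_id": usable["patient_id"].to_numpy()})
    total = np.zeros(len(usable))
    for name, v in contribs.items():
        pts = (v - mins[name]) / unit
        out[f"points[{name}]"] = pts
        total += pts
    out["total_points"] = total
    base = float(final.coefficients["const"]) + sum(mins.values())
    out["predicted_ratio"] = np.exp(base + total * unit)
    return out
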