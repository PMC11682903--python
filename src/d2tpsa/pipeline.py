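"""End-to-end analysis pipeline.

Orchestrates: simulate (or load) a cohort -> rule-based D2T classification
with Firth univariate associations -> observed/expected difficulty index ->
univariate Poisson-offset screen -> bagged backward-AIC multivariable model
-> predictions, strata and nomogram.  Every stage writes delimited text
(CSV, empty cell = missing) into the output directory, and a YAML manifest
records seeds, counts at each stage and output filenames.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortConfig, EffectSpec, ScoreSpec, generate_cohort, read_cohort
from .classifier import D2TCriteria, EstimationError, classify_cohort, firth_univariate
from .index import compute_index
from .glm import (
    Covariate,
    ModelSpec,
    fit_model,
    freeze_splines,
    relative_difficulty,
    resolve_codings,
)
from .bagging import (
    BaggingConfig,
    average_coefficients,
    backward_aic,
    bootstrap_bag,
    complete_cases,
    nomogram_table,
    predict_and_stratify,
)

__all__ = [
    "RunConfig",
    "default_covariates",
    "default_model_spec",
    "format_percent",
    "summarize_cohort",
    "run_pipeline",
    "load_config",
]

logger = logging.getLogger("d2tpsa")

#: covariates screened for association with treatment difficulty, in
#: specification order (also the backward-elimination tie-break order)
DEFAULT_MODEL_COVARIATES = (
    Covariate("sex", kind="categorical", ref="M"),
    Covariate("psa_subset", kind="categorical", ref="peripheral"),
    Covariate("has_psoriasis", kind="binary"),
    Covariate("pso_plaque", kind="binary"),
    Covariate("pso_scalp", kind="binary"),
    Covariate("pso_nail", kind="binary"),
    Covariate("pso_palmoplantar", kind="binary"),
    Covariate("pso_guttate", kind="binary"),
    Covariate("obesity", kind="binary"),
    Covariate("smoker", kind="binary"),
    Covariate("dactylitis_history", kind="binary"),
    Covariate("osteoarthritis", kind="binary"),
    Covariate("fibromyalgia", kind="binary"),
    Covariate("ibd", kind="binary"),
    Covariate("steroid_use", kind="binary"),
    Covariate("dapsa", kind="continuous", coding="rcs"),
    Covariate("phga", kind="continuous", coding="rcs"),
    Covariate("haq", kind="continuous", coding="rcs"),
)

#: covariates additionally screened in the Firth D2T association analysis
FIRTH_COVARIATES = (
    "fibromyalgia",
    "osteoarthritis",
    "steroid_use",
    "obesity",
    "smoker",
    "pso_nail",
    "pso_palmoplantar",
    "pga",
    "phga",
    "dapsa",
    "haq",
)


def default_covariates() -> tuple[Covariate, ...]:
    return DEFAULT_MODEL_COVARIATES


def default_model_spec() -> ModelSpec:
    return ModelSpec(
        response="actual_count", offset="expected_count",
        covariates=DEFAULT_MODEL_COVARIATES,
    )


@dataclass
class RunConfig:
    cohort_path: str | None = None          # load a cohort table ...
    cohort: CohortConfig = field(default_factory=CohortConfig)  # ... or simulate one
    criteria: D2TCriteria = field(default_factory=D2TCriteria)
    quantile_method: str = "linear"
    time_col: str = "months_since_diagnosis"
    frozen_rate75: float | None = None
    bagging: BaggingConfig = field(default_factory=BaggingConfig)
    outdir: str = "d2tpsa_output"


def format_percent(count: int, denominator: int) -> str:
    """Percentage to one decimal on the nonmissing denominator (e.g. 8/267 -> '3.0')."""
    if denominator <= 0:
        return ""
    return f"{100.0 * count / denominator:.1f}"


def summarize_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-variable descriptives: n (%) for categoricals, median [Q1, Q3]
    for continuous columns, on nonmissing denominators."""
    if cohort.empty:
        raise ValueError("empty cohort")
    rows = [{"variable": "N", "summary": str(len(cohort)), "n_nonmissing": len(cohort)}]
    for col in cohort.columns:
        if col == "patient_id":
            continue
        s = cohort[col]
        n_ok = int(s.notna().sum())
        if n_ok == 0:
            rows.append({"variable": col, "summary": "missing", "n_nonmissing": 0})
            continue
        if s.dtype == object:
            for level, cnt in s.value_counts().items():
                rows.append({
                    "variable": f"{col} = {level}",
                    "summary": f"{cnt} ({format_percent(int(cnt), n_ok)})",
                    "n_nonmissing": n_ok,
                })
        elif set(pd.unique(s.dropna())) <= {0, 1, 0.0, 1.0}:
            cnt = int(s.sum())
            rows.append({
                "variable": f"{col} (%)",
                "summary": f"{cnt} ({format_percent(cnt, n_ok)})",
                "n_nonmissing": n_ok,
            })
        else:
            q1, med, q3 = s.quantile([0.25, 0.5, 0.75])
            rows.append({
                "variable": f"{col} (median [Q1, Q3])",
                "summary": f"{med:.2f} [{q1:.2f}, {q3:.2f}]",
                "n_nonmissing": n_ok,
            })
    return pd.DataFrame(rows)


def prune_sparse_covariates(
    df: pd.DataFrame, spec: ModelSpec, min_count: int = 4
) -> tuple[ModelSpec, list[str]]:
    """Drop covariates the complete-case data cannot support.

    A binary covariate needs at least ``min_count`` patients in each class,
    and every level of a categorical covariate needs at least ``min_count``
    patients; otherwise most bootstrap resamples would lose the level
    entirely and the covariate's coefficient would be unidentifiable.
    Returns the reduced spec and the names pruned.
    """
    pruned: list[str] = []
    kept = []
    for cov in spec.covariates:
        s = df[cov.name]
        if cov.kind == "binary":
            n1 = int((s == 1).sum())
            ok = min(n1, len(s) - n1) >= min_count
        elif cov.kind == "categorical":
            ok = bool((s.value_counts() >= min_count).all())
        else:
            ok = s.nunique() >= min_count
        if ok:
            kept.append(cov)
        else:
            pruned.append(cov.name)
    if pruned:
        logger.info("pruned sparse covariates: %s", ", ".join(pruned))
    return ModelSpec(spec.response, spec.offset, tuple(kept)), pruned


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the output bundle; returns the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"package_version": __version__, "stages": {}, "outputs": {}}

    def emit(name: str, frame: pd.DataFrame) -> None:
        path = outdir / f"{name}.csv"
        frame.to_csv(path, index=False, na_rep="")
        manifest["outputs"][name] = path.name

    stage = "simulate"
    try:
        # --- cohort -------------------------------------------------------
        if config.cohort_path is not None:
            cohort = read_cohort(config.cohort_path)
            manifest["stages"]["input"] = {"path": str(config.cohort_path), "n": len(cohort)}
        else:
            cohort = generate_cohort(config.cohort)
            manifest["stages"]["simulate"] = {"seed": config.cohort.seed, "n": len(cohort)}
        emit("cohort", cohort)
        emit("cohort_summary", summarize_cohort(cohort))

        # --- D2T classification + Firth univariates -----------------------
        stage = "classify"
        flags = classify_cohort(cohort, config.criteria)
        n_d2t = int(flags["is_d2t"].sum())
        manifest["stages"]["classify"] = {
            "n": len(flags),
            "n_d2t": n_d2t,
            "n_indeterminate": int(flags["indeterminate"].sum()),
            "d2t_percent": format_percent(n_d2t, len(flags)),
        }
        emit("d2t_flags", cohort.merge(flags[["patient_id", "is_d2t"]], on="patient_id"))
        firth_rows = []
        for cov in FIRTH_COVARIATES:
            try:
                est = firth_univariate(cohort, flags["is_d2t"].to_numpy(), cov)
            except EstimationError as exc:
                logger.warning("firth univariate skipped for %s: %s", cov, exc)
                continue
            firth_rows.append({"covariate": est.covariate, "odds_ratio": est.odds_ratio,
                               "ci_low": est.ci_low, "ci_high": est.ci_high, "scale": est.scale})
        emit("firth_univariate", pd.DataFrame(firth_rows))

        # --- difficulty index ---------------------------------------------
        stage = "index"
        index_df, summary = compute_index(
            cohort, time_col=config.time_col, method=config.quantile_method,
            frozen_rate75=config.frozen_rate75,
        )
        emit("index", index_df)
        emit("index_summary", pd.DataFrame([asdict(summary)]))
        manifest["stages"]["index"] = {
            "rate75": summary.rate75,
            "n_ratio_gt1": summary.n_ratio_gt1,
            "percent_ratio_gt1": format_percent(summary.n_ratio_gt1, summary.n_patients),
        }
        analysis = cohort.merge(
            index_df[["patient_id", "actual_count", "expected_count", "ratio"]],
            on="patient_id",
        )

        # --- univariate Poisson-offset screen -----------------------------
        stage = "univariate"
        uni_rows = []
        for cov in DEFAULT_MODEL_COVARIATES:
            sub = analysis.dropna(subset=[cov.name])
            if sub[cov.name].nunique() < 2:
                logger.warning("univariate screen skipped %s: no variation", cov.name)
                continue
            spec1 = resolve_codings(sub, ModelSpec("actual_count", "expected_count", (cov,)))
            fit, design = fit_model(sub, spec1)
            tab = relative_difficulty(fit, design, spec1, sub)
            tab.insert(0, "adjustment", "unadjusted")
            uni_rows.append(tab)
        emit("univariate_effects", pd.concat(uni_rows, ignore_index=True))

        # --- multivariable: complete cases, bagging ------------------------
        stage = "bag"
        spec = default_model_spec()
        cc = complete_cases(analysis, [c.name for c in spec.covariates])
        manifest["stages"]["complete_cases"] = {
            "n_in": len(analysis), "n_retained": len(cc),
            "n_dropped": len(analysis) - len(cc),
            "retained_percent": format_percent(len(cc), len(analysis)),
        }
        spec, pruned = prune_sparse_covariates(cc, spec)
        manifest["stages"]["complete_cases"]["pruned_covariates"] = pruned
        spec = freeze_splines(cc, resolve_codings(cc, spec))
        fit_full, design_full = fit_model(cc, spec)
        adj = relative_difficulty(fit_full, design_full, spec, cc)
        adj.insert(0, "adjustment", "adjusted")
        emit("multivariable_effects", adj)
        sel_spec, sel_fit, path = backward_aic(cc, spec)
        manifest["stages"]["backward_aic"] = {
            "retained": sel_spec.names(), "aic": sel_fit.aic,
            "path": [{"dropped": d, "aic": a} for d, a in path],
        }
        result = bootstrap_bag(cc, spec, config.bagging)
        emit("selection_frequencies",
             result.selection_frequency.rename_axis("covariate").reset_index())
        emit("coefficient_draw_histograms", _histogram_table(result.coefficient_draws))
        final = average_coefficients(spec, result)
        emit("final_coefficients",
             final.coefficients.rename("averaged_coefficient")
             .rename_axis("term").reset_index())
        manifest["stages"]["bagging"] = {
            "n_resamples": config.bagging.n_resamples,
            "seed": config.bagging.seed,
            "n_degenerate": result.n_degenerate,
        }

        # --- prediction, strata, nomogram ----------------------------------
        stage = "report"
        pred, dist = predict_and_stratify(final, cc)
        emit("predictions", pred)
        emit("strata_distributions", dist)
        n_gt1 = int((pred["predicted_ratio"] > 1).sum())
        manifest["stages"]["predict"] = {
            "n": len(pred),
            "n_predicted_gt1": n_gt1,
            "percent_predicted_gt1": format_percent(n_gt1, len(pred)),
            "n_predicted_gt15": int((pred["predicted_ratio"] > 1.5).sum()),
        }
        emit("nomogram", nomogram_table(final, cc))
    except Exception:
        manifest["failed_stage"] = stage
        (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
        raise

    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest


def _histogram_table(draws: pd.DataFrame, bins: int = 30) -> pd.DataFrame:
    """Binned coefficient-draw distributions (one row per column per bin)."""
    rows = []
    for col in draws.columns:
        v = draws[col].to_numpy()
        counts, edges = np.histogram(v, bins=bins)
        for c, lo, hi in zip(counts, edges[:-1], edges[1:]):
            rows.append({"term": col, "bin_low": lo, "bin_high": hi, "count": int(c)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

def load_config(path, overrides: dict | None = None) -> RunConfig:
    """Build a RunConfig from a YAML file mirroring its dataclass fields.

    Score distributions appear as e.g.
    ``dapsa: {kind: gamma, quartiles: [1.11, 4.2, 9.25]}``.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        raw.update(overrides)
    cohort_raw = dict(raw.get("cohort", {}))
    if "score_distributions" in cohort_raw:
        cohort_raw["score_distributions"] = {
            name: ScoreSpec(**{**spec, "quartiles": tuple(spec["quartiles"])})
            for name, spec in cohort_raw["score_distributions"].items()
        }
    if "effect_spec" in cohort_raw:
        cohort_raw["effect_spec"] = EffectSpec(**cohort_raw["effect_spec"])
    cfg = RunConfig(
        cohort_path=raw.get("cohort_path"),
        cohort=CohortConfig(**cohort_raw),
        criteria=D2TCriteria(**raw.get("criteria", {})),
        quantile_method=raw.get("quantile_method", "linear"),
        time_col=raw.get("time_col", "months_since_diagnosis"),
        frozen_rate75=raw.get("frozen_rate75"),
        bagging=BaggingConfig(**raw.get("bagging", {})),
        outdir=raw.get("outdir", "d2tpsa_output"),
    )
    return cfg
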