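"""Poisson-offset GLM core: spline basis, closed-form oracles, Wald tests,
effect reporting."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import make_count_data
from d2tpsa.glm import (
    Covariate,
    DesignError,
    ModelSpec,
    fit_model,
    fit_poisson_offset,
    rcs_basis,
    rcs_knots,
    relative_difficulty,
    resolve_codings,
    wald_test,
)


# ---------------------------------------------------------------------------
# Restricted cubic splines
# ---------------------------------------------------------------------------

def test_rcs_three_knots_give_two_columns():
    x = np.linspace(0, 10, 50)
    basis = rcs_basis(x, [1.0, 5.0, 9.0])
    assert basis.shape == (50, 2)
    assert np.array_equal(basis[:, 0], x)


def test_rcs_nonlinear_terms_vanish_below_first_knot():
    x = np.linspace(-5, 0.9, 30)
    basis = rcs_basis(x, [1.0, 5.0, 9.0])
    assert np.all(basis[:, 1:] == 0.0)


def test_rcs_is_linear_beyond_boundary_knots():
    """Numerical second derivative outside the knot span is zero."""
    knots = [2.0, 5.0, 7.0, 9.0]
    h = 1e-3
    for x0 in (0.5, 1.2, 9.5, 14.0):
        pts = np.array([x0 - h, x0, x0 + h])
        b = rcs_basis(pts, knots)
        second = (b[0] - 2 * b[1] + b[2]) / h**2
        assert np.all(np.abs(second) < 1e-8)


def test_rcs_reproduces_a_straight_line_exactly():
    rng = np.random.default_rng(1)
    x = rng.uniform(0, 10, 200)
    basis = rcs_basis(x, rcs_knots(x, 3))
    y = 3.0 - 0.7 * x
    coef, *_ = np.linalg.lstsq(np.column_stack([np.ones_like(x), basis]), y, rcond=None)
    assert coef[1] == pytest.approx(-0.7, abs=1e-10)
    assert abs(coef[2]) < 1e-9  # nonlinear coefficient identically zero


def test_rcs_rejects_bad_knots():
    with pytest.raises(DesignError):
        rcs_basis(np.arange(10.0), [1.0, 1.0, 3.0])
    with pytest.raises(DesignError):
        rcs_knots(np.array([1.0, 1.0, 1.0, 2.0]), 3)


def test_resolve_codings_downgrades_zero_inflated_score_to_linear():
    df = pd.DataFrame({"s": np.r_[np.zeros(80), np.arange(20.0)]})
    spec = ModelSpec("y", "e", (Covariate("s", kind="continuous", coding="rcs"),))
    resolved = resolve_codings(df, spec)
    assert resolved.covariates[0].coding == "linear"


# ---------------------------------------------------------------------------
# Poisson-offset closed forms
# ---------------------------------------------------------------------------

def test_intercept_only_rate_is_total_observed_over_total_expected():
    rng = np.random.default_rng(5)
    y = rng.poisson(2.0, size=200).astype(float)
    expected = rng.uniform(0.5, 4.0, size=200)
    X = pd.DataFrame({"const": np.ones(200)})
    fit = fit_poisson_offset(y, X, np.log(expected))
    assert math.exp(fit.params["const"]) == pytest.approx(y.sum() / expected.sum(), abs=1e-10)


def test_single_binary_covariate_recovers_stratified_rate_ratio():
    rng = np.random.default_rng(6)
    g = (rng.random(500) < 0.4).astype(float)
    expected = rng.uniform(0.5, 3.0, size=500)
    y = rng.poisson(expected * np.where(g == 1, 1.8, 0.9)).astype(float)
    X = pd.DataFrame({"const": np.ones(500), "g": g})
    fit = fit_poisson_offset(y, X, np.log(expected))
    oracle = (y[g == 1].sum() / expected[g == 1].sum()) / (
        y[g == 0].sum() / expected[g == 0].sum()
    )
    assert math.exp(fit.params["g"]) == pytest.approx(oracle, abs=1e-8)


def test_score_equations_hold_at_convergence():
    df = make_count_data(800, 3, {"a": 0.5, "b": -0.3}, {"a": 0.3, "b": 0.5})
    X = pd.DataFrame({"const": 1.0, "a": df["a"], "b": df["b"]})
    fit = fit_poisson_offset(df["y"], X, np.log(df["exposure"]))
    score = X.to_numpy().T @ (df["y"].to_numpy() - fit.fitted)
    assert np.all(np.abs(score) < 1e-6)


def test_rescaling_the_offset_shifts_only_the_intercept():
    df = make_count_data(600, 9, {"a": 0.4}, {"a": 0.4})
    X = pd.DataFrame({"const": 1.0, "a": df["a"]})
    fit1 = fit_poisson_offset(df["y"], X, np.log(df["exposure"]))
    fit2 = fit_poisson_offset(df["y"], X, np.log(df["exposure"] * 7.0))
    assert fit2.params["a"] == pytest.approx(fit1.params["a"], abs=1e-10)
    assert fit2.params["const"] == pytest.approx(fit1.params["const"] - math.log(7.0), abs=1e-10)


def test_noise_column_cannot_reduce_loglik_and_aic_is_consistent():
    df = make_count_data(400, 12, {"a": 0.6}, {"a": 0.5})
    X = pd.DataFrame({"const": 1.0, "a": df["a"]})
    fit = fit_poisson_offset(df["y"], X, np.log(df["exposure"]))
    rng = np.random.default_rng(0)
    X2 = X.assign(noise=rng.normal(size=len(X)))
    fit2 = fit_poisson_offset(df["y"], X2, np.log(df["exposure"]))
    assert fit2.loglik >= fit.loglik - 1e-9
    assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * len(fit.params), abs=1e-9)
    assert fit2.aic == pytest.approx(-2 * fit2.loglik + 2 * len(fit2.params), abs=1e-9)


def test_rank_deficient_design_names_aliased_column():
    df = make_count_data(100, 2, {}, {"a": 0.5})
    X = pd.DataFrame({"const": 1.0, "a": df["a"], "copy": df["a"]})
    with pytest.raises(DesignError, match="copy"):
        fit_poisson_offset(df["y"], X, np.log(df["exposure"]))


# ---------------------------------------------------------------------------
# Wald tests and effect reporting
# ---------------------------------------------------------------------------

def test_single_term_wald_is_squared_z():
    df = make_count_data(500, 4, {"a": 0.5}, {"a": 0.4})
    X = pd.DataFrame({"const": 1.0, "a": df["a"]})
    fit = fit_poisson_offset(df["y"], X, np.log(df["exposure"]))
    w = wald_test(fit, ["a"])
    z2 = (fit.params["a"] / math.sqrt(fit.cov.loc["a", "a"])) ** 2
    assert w.statistic == pytest.approx(z2, abs=1e-10)
    assert w.df == 1


def test_empty_wald_set_is_null_test():
    df = make_count_data(100, 4, {}, {"a": 0.4})
    X = pd.DataFrame({"const": 1.0, "a": df["a"]})
    fit = fit_poisson_offset(df["y"], X, np.log(df["exposure"]))
    w = wald_test(fit, [])
    assert (w.statistic, w.df, w.p_value) == (0.0, 0, 1.0)


def test_planted_rate_ratio_reported_with_interval():
    df = make_count_data(
        5000, 21, {"fibro": math.log(2.0)}, {"fibro": 0.3, "noise": 0.4}, base_rate=0.02
    )
    df = df.rename(columns={"y": "actual_count", "exposure": "expected_count"})
    spec = ModelSpec(
        "actual_count", "expected_count",
        (Covariate("fibro"), Covariate("noise")),
    )
    fit, design = fit_model(df, spec)
    table = relative_difficulty(fit, design, spec, df)
    fibro = table[table["covariate"] == "fibro"].iloc[0]
    assert 1.8 <= fibro["effect"] <= 2.2
    assert fibro["ci_low"] <= fibro["effect"] <= fibro["ci_high"]
    noise = table[table["covariate"] == "noise"].iloc[0]
    assert noise["ci_low"] <= 1.0 <= noise["ci_high"]


def test_categorical_dummy_block_against_reference():
    rng = np.random.default_rng(30)
    n = 2000
    level = rng.choice(["peripheral", "axial", "enthesitic"], size=n, p=[0.6, 0.3, 0.1])
    expected = rng.uniform(1.0, 2.0, size=n)
    rate = np.select([level == "axial", level == "enthesitic"], [1.5, 0.7], default=1.0)
    y = rng.poisson(expected * rate)
    df = pd.DataFrame({"actual_count": y, "expected_count": expected, "psa_subset": level})
    spec = ModelSpec(
        "actual_count", "expected_count",
        (Covariate("psa_subset", kind="categorical", ref="peripheral"),),
    )
    fit, design = fit_model(df, spec)
    assert design.blocks["psa_subset"] == ["psa_subset[axial]", "psa_subset[enthesitic]"]
    table = relative_difficulty(fit, design, spec, df)
    axial = table[table["term"] == "psa_subset[axial]"].iloc[0]
    assert axial["effect"] == pytest.approx(1.5, rel=0.1)


def test_spline_effect_reported_as_interquartile_contrast():
    rng = np.random.default_rng(31)
    n = 3000
    x = rng.gamma(2.0, 3.0, size=n)
    expected = rng.uniform(1.0, 2.0, size=n)
    y = rng.poisson(expected * np.exp(0.08 * x))
    df = pd.DataFrame({"actual_count": y, "expected_count": expected, "dapsa": x})
    spec = ModelSpec(
        "actual_count", "expected_count",
        (Covariate("dapsa", kind="continuous", coding="rcs"),),
    )
    fit, design = fit_model(df, spec)
    table = relative_difficulty(fit, design, spec, df)
    row = table.iloc[0]
    q25, q75 = np.quantile(x, [0.25, 0.75])
    truth = math.exp(0.08 * (q75 - q25))
    assert row["effect"] == pytest.approx(truth, rel=0.1)
    assert not math.isnan(row["p_nonlinear"])
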