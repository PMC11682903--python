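"""Synthetic psoriatic-arthritis cohort generation.

Emulates the marginal structure of a single-centre PsA registry cohort of
b/tsDMARD-treated patients (n = 267): demographics, disease subset, psoriasis
subtypes, comorbidities, clinimetric scores, corticosteroid use, drug-failure
counts and disease duration.  The generator is the testbed for every
downstream stage — the difficulty index, the Poisson-offset difficulty model
and the bagged variable selection — so it plants a *known* generative model
for the b/tsDMARD counts:

    A_i = 1 + Poisson(T_i * lambda0 * exp(x_i' beta))

where T_i is follow-up in months, lambda0 a base failure rate per month and
beta planted log rate ratios.  The "+1" is the current (ongoing) therapy;
``n_prev_btsdmards`` stores A_i - 1.

Covariates are sampled independently (the emulated cohort is described only
through marginals); continuous scores are drawn from gamma distributions
matched numerically to published median/quartiles, with a point mass at zero
mixed in where the published quartiles require it; follow-up is log-normal.
Missingness is MCAR, per-field, and never touches drug counts or follow-up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "CohortConfigError",
    "ScoreSpec",
    "EffectSpec",
    "CohortConfig",
    "PatientRecord",
    "generate_cohort",
    "simulate_drug_counts",
    "apply_missingness",
    "write_cohort",
    "read_cohort",
    "COHORT_COLUMNS",
]


class CohortConfigError(ValueError):
    """Invalid cohort configuration (a probability, rate or size out of range)."""


# ---------------------------------------------------------------------------
# Schema
# ---------------------------------------------------------------------------

SEX_LEVELS = ("M", "F")
PSA_SUBSETS = ("axial", "peripheral", "axial+peripheral", "enthesitic")

#: binary flags drawn independently (probability of 1)
BINARY_COVARIATES = (
    "obesity",
    "smoker",
    "osteoarthritis",
    "fibromyalgia",
    "dactylitis_history",
    "ibd",
    "steroid_use",
    "management_problematic",
)

#: psoriasis subtypes, drawn independently *conditional on* has_psoriasis
PSORIASIS_TYPES = ("pso_plaque", "pso_scalp", "pso_nail", "pso_palmoplantar", "pso_guttate")

#: continuous clinimetric scores eligible for MCAR missingness
SCORE_COVARIATES = ("dapsa", "phga", "pga", "haq", "rdci", "bsa_pct")

#: fields that may never be set missing (the index must stay computable)
PROTECTED_FIELDS = ("patient_id", "n_prev_btsdmards", "months_since_diagnosis")

COHORT_COLUMNS = (
    ("patient_id", "sex", "age_years", "psa_subset", "has_psoriasis")
    + PSORIASIS_TYPES
    + BINARY_COVARIATES[:-1]
    + ("management_problematic", "steroid_dose_mg")
    + SCORE_COVARIATES
    + ("n_prev_btsdmards", "months_since_diagnosis")
)


# ---------------------------------------------------------------------------
# Score distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoreSpec:
    """Parametric sampler for a nonnegative, right-skewed score.

    ``kind``:
      * ``"gamma"``        — gamma(shape, scale), parameters solved so the
                             distribution's quartiles match ``quartiles``;
      * ``"zero_gamma"``   — mixture: point mass ``p_zero`` at 0, gamma for
                             the positive part, matched to the nonzero
                             quartile targets;
      * ``"lognormal"``    — log-normal with median = ``quartiles[1]`` and
                             sigma solved from the Q3/Q1 ratio.
    """

    kind: str
    quartiles: tuple[float, float, float]
    p_zero: float = 0.0
    lower: float = 0.0
    upper: float | None = None

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "gamma":
            shape, scale = _match_gamma_quartiles(self.quartiles)
            x = rng.gamma(shape, scale, size=n)
        elif self.kind == "zero_gamma":
            shape, scale = _match_conditional_gamma(self.quartiles, self.p_zero)
            x = rng.gamma(shape, scale, size=n)
            x[rng.random(n) < self.p_zero] = 0.0
        elif self.kind == "lognormal":
            q1, med, q3 = self.quartiles
            sigma = math.log(q3 / q1) / (2.0 * stats.norm.ppf(0.75))
            x = rng.lognormal(math.log(med), sigma, size=n)
        else:  # pragma: no cover - guarded by CohortConfig validation
            raise CohortConfigError(f"unknown score kind {self.kind!r}")
        x = np.maximum(x, self.lower)
        if self.upper is not None:
            x = np.minimum(x, self.upper)
        return x


@lru_cache(maxsize=None)
def _match_gamma_quartiles(quartiles: tuple[float, float, float]) -> tuple[float, float]:
    """Gamma (shape, scale) whose quartiles best match the targets (log-least-squares)."""
    targets = np.asarray(quartiles, dtype=float)
    if np.any(targets <= 0) or np.any(np.diff(targets) <= 0):
        raise CohortConfigError(
            f"gamma quartile targets must be positive and increasing, got {quartiles}"
        )

    def loss(theta: np.ndarray) -> float:
        shape, scale = np.exp(theta)
        q = stats.gamma.ppf([0.25, 0.5, 0.75], shape, scale=scale)
        return float(np.sum((np.log(q) - np.log(targets)) ** 2))

    res = optimize.minimize(loss, x0=[1.0, math.log(targets[1])], method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
    shape, scale = np.exp(res.x)
    return float(shape), float(scale)


@lru_cache(maxsize=None)
def _match_conditional_gamma(
    quartiles: tuple[float, float, float], p_zero: float
) -> tuple[float, float]:
    """Gamma parameters of the positive part of a zero-inflated score.

    An overall quantile target q at level p with p > p_zero corresponds to the
    conditional (positive-part) quantile at level (p - p_zero) / (1 - p_zero).
    Zero targets at levels at or below p_zero carry no information and are
    dropped; one remaining target pins an exponential, two or more a gamma.
    """
    levels = np.array([0.25, 0.5, 0.75])
    targets = np.asarray(quartiles, dtype=float)
    keep = (targets > 0) & (levels > p_zero)
    if not np.any(keep):
        raise CohortConfigError(
            f"zero-inflated score needs at least one positive quartile target, got {quartiles}"
        )
    cond_levels = (levels[keep] - p_zero) / (1.0 - p_zero)
    cond_targets = targets[keep]
    if keep.sum() == 1:
        # exponential: single quantile pins the rate
        scale = float(cond_targets[0] / -math.log1p(-cond_levels[0]))
        return 1.0, scale

    def loss(theta: np.ndarray) -> float:
        shape, scale = np.exp(theta)
        q = stats.gamma.ppf(cond_levels, shape, scale=scale)
        return float(np.sum((np.log(q) - np.log(cond_targets)) ** 2))

    res = optimize.minimize(loss, x0=[0.0, math.log(cond_targets[-1])], method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
    shape, scale = np.exp(res.x)
    return float(shape), float(scale)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def _default_prevalences() -> dict:
    # published cohort marginals; PsA-subset probabilities proportional to
    # the printed counts (29/193/37/12), psoriasis subtypes conditional on
    # skin involvement
    return {
        "sex": {"M": 0.524, "F": 0.476},
        "psa_subset": {
            "axial": 29 / 271,
            "peripheral": 193 / 271,
            "axial+peripheral": 37 / 271,
            "enthesitic": 12 / 271,
        },
        "has_psoriasis": 205 / 267,
        "pso_plaque": 0.814,
        "pso_scalp": 0.176,
        "pso_nail": 0.147,
        "pso_palmoplantar": 0.083,
        "pso_guttate": 0.010,
        "obesity": 29 / 267,
        "smoker": 70 / 267,
        "osteoarthritis": 69 / 267,
        "fibromyalgia": 42 / 267,
        "dactylitis_history": 40 / 267,
        "ibd": 4 / 267,
        "steroid_use": 31 / 267,
        "management_problematic": 0.20,
    }


def _default_scores() -> dict:
    return {
        "age_years": ScoreSpec("gamma", (46.0, 53.0, 61.0), lower=18.0),
        "dapsa": ScoreSpec("gamma", (1.11, 4.20, 9.25)),
        "phga": ScoreSpec("zero_gamma", (0.0, 0.0, 1.0), p_zero=0.55, upper=10.0),
        "pga": ScoreSpec("zero_gamma", (0.0, 2.0, 4.0), p_zero=0.30, upper=10.0),
        "haq": ScoreSpec("zero_gamma", (0.0, 0.12, 0.38), p_zero=0.30, upper=3.0),
        "rdci": ScoreSpec("zero_gamma", (0.0, 0.0, 1.0), p_zero=0.55),
        "bsa_pct": ScoreSpec("zero_gamma", (0.0, 1.0, 3.0), p_zero=0.40, upper=100.0),
        "steroid_dose_mg": ScoreSpec("gamma", (2.5, 5.0, 7.5)),  # among users only
        "months_since_diagnosis": ScoreSpec(
            "lognormal", (89.0, 154.5, 249.25), lower=3.0
        ),
    }


@dataclass(frozen=True)
class EffectSpec:
    """Planted log-linear model for the monthly b/tsDMARD failure rate.

    ``base_rate_per_month`` is the failure rate of a covariate-free patient;
    ``coefficients`` maps cohort columns to log rate ratios.  Defaults plant
    rate ratios 2.0 (fibromyalgia), 1.5 (steroid use) and 1.4 (nail
    psoriasis), with every other covariate null.
    """

    base_rate_per_month: float = 0.003
    coefficients: Mapping[str, float] = field(
        default_factory=lambda: {
            "fibromyalgia": math.log(2.0),
            "steroid_use": math.log(1.5),
            "pso_nail": math.log(1.4),
        }
    )


@dataclass
class CohortConfig:
    n_patients: int = 267
    prevalences: dict = field(default_factory=_default_prevalences)
    score_distributions: dict = field(default_factory=_default_scores)
    effect_spec: EffectSpec = field(default_factory=EffectSpec)
    missingness: dict = field(
        default_factory=lambda: {name: 0.128 for name in SCORE_COVARIATES}
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise CohortConfigError("n_patients must be >= 1")
        for name, p in self.prevalences.items():
            if isinstance(p, Mapping):
                vec = np.array(list(p.values()), dtype=float)
                if np.any(vec < 0) or np.any(vec > 1):
                    raise CohortConfigError(f"probability out of [0, 1] for {name!r}")
                if not math.isclose(vec.sum(), 1.0, abs_tol=1e-6):
                    raise CohortConfigError(
                        f"categorical probabilities for {name!r} sum to {vec.sum():.6f}, not 1"
                    )
            elif not 0.0 <= float(p) <= 1.0:
                raise CohortConfigError(f"probability out of [0, 1] for {name!r}")
        for name, rate in self.missingness.items():
            if not 0.0 <= float(rate) <= 1.0:
                raise CohortConfigError(f"missingness rate out of [0, 1] for {name!r}")
            if name in PROTECTED_FIELDS:
                raise CohortConfigError(f"{name!r} may never be set missing")
        if self.effect_spec.base_rate_per_month < 0:
            raise CohortConfigError("base_rate_per_month must be nonnegative")


@dataclass
class PatientRecord:
    """One patient's row, as a typed object (the cohort's canonical container
    is the DataFrame; this view serves rule-engine code and doctests)."""

    patient_id: int
    sex: str
    age_years: float
    psa_subset: str
    has_psoriasis: bool
    psoriasis_types: tuple[str, ...]
    obesity: bool
    smoker: bool
    osteoarthritis: bool
    fibromyalgia: bool
    dactylitis_history: bool
    ibd: bool
    steroid_use: bool
    steroid_dose_mg: float
    dapsa: float
    phga: float
    pga: float
    haq: float
    rdci: float
    bsa_pct: float
    n_prev_btsdmards: int
    months_since_diagnosis: float
    management_problematic: bool

    @classmethod
    def from_row(cls, row: Mapping) -> "PatientRecord":
        types = tuple(t for t in PSORIASIS_TYPES if row.get(t))
        return cls(
            patient_id=int(row["patient_id"]),
            sex=str(row["sex"]),
            age_years=float(row["age_years"]),
            psa_subset=str(row["psa_subset"]),
            has_psoriasis=bool(row["has_psoriasis"]),
            psoriasis_types=types,
            obesity=bool(row["obesity"]),
            smoker=bool(row["smoker"]),
            osteoarthritis=bool(row["osteoarthritis"]),
            fibromyalgia=bool(row["fibromyalgia"]),
            dactylitis_history=bool(row["dactylitis_history"]),
            ibd=bool(row["ibd"]),
            steroid_use=bool(row["steroid_use"]),
            steroid_dose_mg=float(row["steroid_dose_mg"]),
            dapsa=float(row["dapsa"]),
            phga=float(row["phga"]),
            pga=float(row["pga"]),
            haq=float(row["haq"]),
            rdci=float(row["rdci"]),
            bsa_pct=float(row["bsa_pct"]),
            n_prev_btsdmards=int(row["n_prev_btsdmards"]),
            months_since_diagnosis=float(row["months_since_diagnosis"]),
            management_problematic=bool(row["management_problematic"]),
        )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a full synthetic cohort: covariates, drug counts, missingness.

    Same config (including seed) always yields the identical table.
    """
    config.validate()
    seeds = np.random.SeedSequence(config.seed).spawn(3)
    rng = np.random.default_rng(seeds[0])
    n = config.n_patients
    prev = config.prevalences
    scores = config.score_distributions

    df = pd.DataFrame({"patient_id": np.arange(1, n + 1)})
    sex_p = prev["sex"]
    df["sex"] = rng.choice(list(sex_p), size=n, p=list(sex_p.values()))
    df["age_years"] = scores["age_years"].sample(n, rng)
    subset_p = prev["psa_subset"]
    probs = np.array(list(subset_p.values()), dtype=float)
    df["psa_subset"] = rng.choice(list(subset_p), size=n, p=probs / probs.sum())
    df["has_psoriasis"] = (rng.random(n) < prev["has_psoriasis"]).astype(int)
    for t in PSORIASIS_TYPES:
        df[t] = ((rng.random(n) < prev[t]) & (df["has_psoriasis"] == 1)).astype(int)
    for name in BINARY_COVARIATES:
        df[name] = (rng.random(n) < prev[name]).astype(int)
    df["steroid_dose_mg"] = np.where(
        df["steroid_use"] == 1, scores["steroid_dose_mg"].sample(n, rng), 0.0
    )
    for name in SCORE_COVARIATES:
        df[name] = scores[name].sample(n, rng)
    df["months_since_diagnosis"] = scores["months_since_diagnosis"].sample(n, rng)

    df = simulate_drug_counts(df, config.effect_spec, seed=seeds[1])
    df = apply_missingness(df, config.missingness, seed=seeds[2])
    return df[list(COHORT_COLUMNS)]


def simulate_drug_counts(cohort: pd.DataFrame, effect_spec: EffectSpec, seed) -> pd.DataFrame:
    """Fill ``n_prev_btsdmards`` from the planted count model.

    The actual count is A = 1 + Poisson(T * lambda0 * exp(x'beta)); every
    patient carries at least the ongoing therapy, and the stored column is
    A - 1 (previous, i.e. failed, b/tsDMARDs).
    """
    if effect_spec.base_rate_per_month < 0:
        raise CohortConfigError("base_rate_per_month must be nonnegative")
    rng = np.random.default_rng(seed)
    cohort = cohort.copy()
    eta = np.zeros(len(cohort))
    for name, beta in effect_spec.coefficients.items():
        if name not in cohort.columns:
            raise CohortConfigError(f"effect coefficient for unknown covariate {name!r}")
        eta += beta * cohort[name].to_numpy(dtype=float)
    mean = (
        cohort["months_since_diagnosis"].to_numpy(dtype=float)
        * effect_spec.base_rate_per_month
        * np.exp(eta)
    )
    cohort["n_prev_btsdmards"] = rng.poisson(mean)
    return cohort


def apply_missingness(cohort: pd.DataFrame, missingness: Mapping[str, float], seed) -> pd.DataFrame:
    """Set fields missing completely at random, per-field, at the given rates."""
    rng = np.random.default_rng(seed)
    cohort = cohort.copy()
    for name, rate in missingness.items():
        if not 0.0 <= float(rate) <= 1.0:
            raise CohortConfigError(f"missingness rate out of [0, 1] for {name!r}")
        if name in PROTECTED_FIELDS:
            raise CohortConfigError(f"{name!r} may never be set missing")
        if name not in cohort.columns:
            raise CohortConfigError(f"missingness rate for unknown field {name!r}")
        mask = rng.random(len(cohort)) < rate
        if mask.any():
            col = cohort[name].astype(float) if cohort[name].dtype.kind in "iub" else cohort[name]
            col = col.where(~mask)
            cohort[name] = col
    return cohort


# ---------------------------------------------------------------------------
# I/O — delimited text, empty cell = missing
# ---------------------------------------------------------------------------

def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False, na_rep="")


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("patient_id", "n_prev_btsdmards", "months_since_diagnosis")
               if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table lacks required columns: {missing}")
    return df
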