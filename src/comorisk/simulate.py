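"""Synthetic screenee-cohort generator.

No individual-level data are released with the reference study, so every
downstream stage is exercised on cohorts generated here with the statistical
structure the analysis assumes:

* food-group intakes follow a Gaussian copula whose latent 16-dimensional
  normal has a prescribed partial-correlation matrix (default: the published
  dietary network) and log-normal marginals moment-matched to the published
  daily-intake means and SDs;
* comorbidity-marker categories are drawn from the published category
  prevalences, with continuous measurements and self-report flags generated
  so that clinical classification reproduces the drawn category;
* event times are exponential with log-hazard
  ``beta_age * age + sum of category log-hazards`` (default: published risk
  point x beta_age), under staggered-entry administrative censoring;
* configurable fractions of unrealistic energy records, prior-cancer flags,
  missing covariates, and forced early cases exercise the exclusion cascade.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import reference
from .network import partial_correlations

__all__ = [
    "SimulationConfig",
    "latent_pcor_to_covariance",
    "generate_cohort",
    "sample_partial_correlations",
    "expected_event_time",
]

INTAKE_COLUMNS = [f"intake_{g}" for g in reference.FOOD_GROUPS]


def _default_pcor() -> np.ndarray:
    return reference.reference_network_matrix().to_numpy()


def _default_log_marginals() -> dict[str, tuple[float, float]]:
    """Log-normal (mu, sigma) per food group, moment-matched to the published
    arithmetic mean and SD."""
    out = {}
    for g, (mean, sd) in reference.INTAKE_MEAN_SD.items():
        sigma2 = np.log1p((sd / mean) ** 2)
        out[g] = (np.log(mean) - sigma2 / 2, np.sqrt(sigma2))
    return out


def _default_log_hazards() -> dict[str, dict[str, float]]:
    return {
        marker: {cat: pt * reference.DEFAULT_BETA_AGE for cat, pt in cats.items()}
        for marker, cats in reference.RISK_POINTS_MAIN.items()
    }


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults emulate the reference screenee cohort: 13,644 recruited
    subjects, the published food-group network and intake marginals, the
    published marker-category mixture, proportional hazards driven by the
    published risk points (at ``beta_age`` = 0.0556 per year), and exclusion
    fractions matched to the published recruitment flowchart.
    """

    n_subjects: int = 13_644
    seed: int = 0
    target_pcor: np.ndarray = field(default_factory=_default_pcor)
    intake_marginals: dict[str, tuple[float, float]] = field(
        default_factory=_default_log_marginals
    )
    marker_mixture: dict[str, dict[str, float]] = field(
        default_factory=reference.marker_prevalences
    )
    beta_age: float = reference.DEFAULT_BETA_AGE
    category_log_hazards: dict[str, dict[str, float]] = field(
        default_factory=_default_log_hazards
    )
    # events/year at age 0 in all-reference categories; calibrated so the
    # post-exclusion analysis cohort carries ~176 incident cancers, the
    # reference study's observed count
    baseline_hazard: float = 1.85e-4
    horizon_years: float = 9.25  # administrative censoring horizon
    entry_spread_years: float = 7.0  # staggered enrollment window
    energy_bounds_violation_rate: float = 0.37
    missingness_rate: float = 0.293
    prior_cancer_rate: float = 0.071
    early_case_rate: float = 0.0066

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        P = np.asarray(self.target_pcor, dtype=float)
        if P.shape != (16, 16):
            raise ValueError("target_pcor must be 16x16")
        if not np.allclose(P, P.T, atol=1e-12):
            raise ValueError("target_pcor must be symmetric")
        if np.any(np.abs(np.diag(P)) > 0):
            raise ValueError("target_pcor diagonal must be zero")
        if np.any(np.abs(P) >= 1):
            raise ValueError("target_pcor entries must satisfy |rho| < 1")
        self.target_pcor = P
        for rate in (
            self.energy_bounds_violation_rate,
            self.missingness_rate,
            self.prior_cancer_rate,
            self.early_case_rate,
        ):
            if not 0 <= rate <= 1:
                raise ValueError("exclusion-cascade rates must lie in [0, 1]")
        for marker, mix in self.marker_mixture.items():
            total = sum(mix.values())
            if not np.isclose(total, 1.0, atol=1e-8):
                raise ValueError(f"{marker} mixture sums to {total}, not 1")
            if any(p < 0 for p in mix.values()):
                raise ValueError(f"{marker} mixture has negative prevalence")
        if self.baseline_hazard <= 0 or self.horizon_years <= 0:
            raise ValueError("baseline_hazard and horizon_years must be positive")
        if not 0 <= self.entry_spread_years < self.horizon_years:
            raise ValueError("entry_spread_years must lie in [0, horizon_years)")


def latent_pcor_to_covariance(pcor: np.ndarray) -> np.ndarray:
    """Covariance of a latent Gaussian whose partial correlations equal ``pcor``.

    Builds the precision ``Omega`` with unit diagonal and off-diagonal
    ``-rho_ij`` and inverts it.  If ``Omega`` is not positive definite the
    diagonal is inflated by ``|lambda_min| + 1e-6`` (with a warning; the
    realized partial correlations are then uniformly shrunk), and the function
    fails if the repaired matrix is still not positive definite.
    """
    P = np.asarray(pcor, dtype=float)
    if not np.allclose(P, P.T, atol=1e-12) or np.any(np.abs(np.diag(P)) > 0):
        raise ValueError("pcor must be symmetric with a zero diagonal")
    if np.any(np.abs(P) >= 1):
        raise ValueError("pcor entries must satisfy |rho| < 1")
    omega = np.eye(P.shape[0]) - P
    lam_min = float(np.linalg.eigvalsh(omega).min())
    if lam_min <= 1e-10:
        warnings.warn(
            f"implied precision not positive definite (lambda_min={lam_min:.3g}); "
            "inflating the diagonal, partial correlations will shrink",
            stacklevel=2,
        )
        omega = omega + (abs(lam_min) + 1e-6) * np.eye(P.shape[0])
        if np.linalg.eigvalsh(omega).min() <= 0:
            raise np.linalg.LinAlgError(
                "precision matrix not positive definite after diagonal loading"
            )
    return np.linalg.inv(omega)


def _sample_categories(rng, mixture: dict[str, float], n: int) -> np.ndarray:
    cats = list(mixture)
    probs = np.array([mixture[c] for c in cats], dtype=float)
    return rng.choice(np.array(cats, dtype=object), size=n, p=probs / probs.sum())


def _linear_predictor(
    config: SimulationConfig, age: np.ndarray, categories: dict[str, np.ndarray]
) -> np.ndarray:
    lp = config.beta_age * np.asarray(age, dtype=float)
    for marker, cats in categories.items():
        lookup = config.category_log_hazards.get(marker, {})
        lp = lp + np.array([lookup.get(c, 0.0) for c in cats])
    return lp


def expected_event_time(
    config: SimulationConfig, age: float, categories: dict[str, str]
) -> float:
    """Closed-form expected event time for one subject (1 / hazard)."""
    lp = _linear_predictor(config, np.array([age]), {m: np.array([c], dtype=object) for m, c in categories.items()})
    return float(1.0 / (config.baseline_hazard * np.exp(lp[0])))


def sample_partial_correlations(X: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Sample partial-correlation matrix (direct covariance-inversion path)."""
    x = np.asarray(X, dtype=float)
    return partial_correlations(np.cov(x, rowvar=False))


def _draw_blood_pressure(rng, cats: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = len(cats)
    sbp = np.empty(n)
    dbp = np.empty(n)
    flag = np.zeros(n, dtype=bool)
    for i, c in enumerate(cats):
        if c == "normal":
            sbp[i] = rng.uniform(100, 119.5)
            dbp[i] = rng.uniform(60, 79.5)
        elif c == "elevated":
            sbp[i] = rng.uniform(120, 139.5)
            dbp[i] = rng.uniform(70, 89.5)
        else:  # hypertension: half by measurement, half by self-report
            if rng.random() < 0.5:
                sbp[i] = rng.uniform(140, 180)
                dbp[i] = rng.uniform(85, 105)
            else:
                flag[i] = True
                sbp[i] = rng.uniform(105, 139.5)
                dbp[i] = rng.uniform(65, 88)
    return sbp, dbp, flag


def _draw_cholesterol(rng, cats: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = len(cats)
    tc = np.empty(n)
    flag = np.zeros(n, dtype=bool)
    for i, c in enumerate(cats):
        if c == "low":
            tc[i] = rng.uniform(130, 179.5)
        elif c == "normal":
            tc[i] = rng.uniform(180, 200)
        else:
            if rng.random() < 0.5:
                tc[i] = rng.uniform(200.5, 280)
            else:
                flag[i] = True
                tc[i] = rng.uniform(150, 260)
    return tc, flag


def _draw_glucose(rng, cats: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = len(cats)
    fg = np.empty(n)
    flag = np.zeros(n, dtype=bool)
    for i, c in enumerate(cats):
        if c == "normal":
            fg[i] = rng.uniform(80, 109.5)
        else:
            if rng.random() < 0.5:
                fg[i] = rng.uniform(110, 180)
            else:
                flag[i] = True
                fg[i] = rng.uniform(85, 170)
    return fg, flag


def _draw_creatinine(rng, cats, age, female) -> np.ndarray:
    lo_hi = {"ge90": (90.0, 120.0), "b60_89": (60.0, 89.5), "lt60": (35.0, 59.5)}
    target = np.array([rng.uniform(*lo_hi[c]) for c in cats])
    sex_factor = np.where(female, 0.742, 1.0)
    # invert the MDRD equation for serum creatinine
    return (175.0 * age ** -0.203 * sex_factor / target) ** (1.0 / 1.154)


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Generate one synthetic cohort as a tidy one-row-per-subject table.

    Deterministic given ``config.seed``.  Columns follow the cohort data
    dictionary in the package docs: demographics, energy, 16 ``intake_*``
    columns (g/day), marker measurements and self-report flags, and follow-up
    (``followup_years``, ``cancer_event``, ``time_to_diagnosis_years``).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    # --- latent Gaussian copula for the 16 food-group intakes
    sigma = latent_pcor_to_covariance(config.target_pcor)
    d = np.sqrt(np.diag(sigma))
    corr = sigma / np.outer(d, d)
    L = np.linalg.cholesky(corr)
    Z = rng.standard_normal((n, 16)) @ L.T
    intakes = np.empty((n, 16))
    for j, g in enumerate(reference.FOOD_GROUPS):
        mu, s = config.intake_marginals[g]
        intakes[:, j] = np.exp(mu + s * Z[:, j])

    # --- demographics
    age = np.clip(rng.normal(52.5, 8.2, n), 30, 80)
    sex = np.where(rng.random(n) < 0.37, "male", "female").astype(object)
    marital = rng.choice(
        np.array(["married_cohabitant", "others"], dtype=object), n, p=[0.862, 0.138]
    )
    education = rng.choice(
        np.array(["lt_high_school", "high_school", "ge_college"], dtype=object),
        n,
        p=[0.132, 0.378, 0.490],
    )
    employment = rng.choice(
        np.array(["employed", "unemployed"], dtype=object), n, p=[0.92, 0.08]
    )
    income = rng.choice(
        np.array(["lt_2m", "2_4m", "ge_4m"], dtype=object), n, p=[0.220, 0.405, 0.375]
    )
    smoking = rng.choice(
        np.array(["never", "past", "current"], dtype=object), n, p=[0.660, 0.215, 0.125]
    )
    drinking = rng.choice(
        np.array(["never", "past", "current"], dtype=object), n, p=[0.390, 0.067, 0.543]
    )
    physical = rng.choice(np.array(["no", "yes"], dtype=object), n, p=[0.443, 0.557])
    bmi = np.clip(rng.normal(23.8, 3.2, n), 16, 40)
    energy = np.clip(rng.normal(2000, 450, n), 510, 3990)

    # --- comorbidity markers, consistent with their drawn category
    mix = config.marker_mixture
    bp_cat = _sample_categories(rng, mix["blood_pressure"], n)
    ch_cat = _sample_categories(rng, mix["cholesterol"], n)
    gl_cat = _sample_categories(rng, mix["glucose"], n)
    gf_cat = _sample_categories(rng, mix["gfr"], n)
    sbp, dbp, bp_flag = _draw_blood_pressure(rng, bp_cat)
    tc, ch_flag = _draw_cholesterol(rng, ch_cat)
    fg, gl_flag = _draw_glucose(rng, gl_cat)
    female = sex == "female"
    scr = _draw_creatinine(rng, gf_cat, age, female)

    # self-reported "diagnosed" vs "treated" split of a positive flag
    dx_split = rng.random(n) < 0.5

    # --- proportional-hazards event times with administrative censoring
    categories = {
        "blood_pressure": bp_cat,
        "cholesterol": ch_cat,
        "glucose": gl_cat,
        "gfr": gf_cat,
    }
    lp = _linear_predictor(config, age, categories)
    rate = config.baseline_hazard * np.exp(lp)
    T = rng.exponential(1.0 / rate)
    entry = rng.uniform(0.0, config.entry_spread_years, n)
    censor = config.horizon_years - entry
    event = T <= censor
    followup = np.minimum(T, censor)

    # forced early cases (diagnosis within the first year of follow-up)
    early = rng.random(n) < config.early_case_rate
    t_early = rng.uniform(0.05, 0.95, n)
    event = event | early
    followup = np.where(early, t_early, followup)
    time_to_dx = np.where(event, followup, np.nan)

    # --- exclusion-cascade material
    bad_energy = rng.random(n) < config.energy_bounds_violation_rate
    low_side = rng.random(n) < 0.5
    energy = np.where(
        bad_energy,
        np.where(low_side, rng.uniform(150, 480, n), rng.uniform(4050, 6000, n)),
        energy,
    )
    prior_cancer = rng.random(n) < config.prior_cancer_rate

    df = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "age": age,
            "sex": sex,
            "marital_status": marital,
            "education": education,
            "employment": employment,
            "income": income,
            "smoking": smoking,
            "drinking": drinking,
            "physical_activity": physical,
            "bmi": bmi,
            "energy": energy,
        }
    )
    for j, col in enumerate(INTAKE_COLUMNS):
        df[col] = intakes[:, j]
    df["sbp"] = sbp
    df["dbp"] = dbp
    df["total_cholesterol"] = tc
    df["fasting_glucose"] = fg
    df["serum_creatinine"] = scr
    df["dx_hypertension"] = bp_flag & dx_split
    df["rx_hypertension"] = bp_flag & ~dx_split
    df["dx_dyslipidemia"] = ch_flag & dx_split
    df["rx_dyslipidemia"] = ch_flag & ~dx_split
    df["dx_diabetes"] = gl_flag & dx_split
    df["rx_diabetes"] = gl_flag & ~dx_split
    df["prior_cancer"] = prior_cancer
    df["followup_years"] = followup
    df["cancer_event"] = event
    df["time_to_diagnosis_years"] = time_to_dx

    # missing covariates, completely at random, one field per hit subject
    if config.missingness_rate > 0:
        hit = rng.random(n) < config.missingness_rate
        numeric_targets = ["bmi", "sbp", "total_cholesterol", "fasting_glucose", "serum_creatinine"]
        which = rng.integers(0, len(numeric_targets), n)
        for k, col in enumerate(numeric_targets):
            df.loc[hit & (which == k), col] = np.nan

    return df
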