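"""Clinical categorization of comorbidity markers and the exclusion cascade.

Blood pressure, total cholesterol, fasting glucose, and MDRD-estimated
glomerular filtration rate (GFR) are each mapped to the closed clinical
categories used for risk scoring.  A self-reported "treated or previously
diagnosed" flag dominates the measured value for blood pressure (->
hypertension), cholesterol (-> elevated), and glucose (-> prediabetes and
diabetes).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

BP_CATEGORIES = ("normal", "elevated", "hypertension")
CHOL_CATEGORIES = ("low", "normal", "elevated")
GLUCOSE_CATEGORIES = ("normal", "prediabetes_diabetes")
GFR_CATEGORIES = ("lt60", "b60_89", "ge90")

#: Covariates that must be complete for a subject to enter the analysis.
REQUIRED_COVARIATES = [
    "age",
    "sex",
    "marital_status",
    "education",
    "employment",
    "income",
    "smoking",
    "drinking",
    "physical_activity",
    "bmi",
    "sbp",
    "dbp",
    "total_cholesterol",
    "fasting_glucose",
    "serum_creatinine",
]


def classify_blood_pressure(sbp: float, dbp: float, treated_or_diagnosed: bool) -> str:
    """JNC blood-pressure category: normal (<120/80), elevated (120-139/80-89),
    hypertension (>=140/90, or treated/previously diagnosed)."""
    if not (sbp > dbp > 0):
        raise ValueError(f"require sbp > dbp > 0, got {sbp}/{dbp}")
    if sbp > 300 or dbp > 200:
        raise ValueError(f"non-physiological blood pressure {sbp}/{dbp}")
    if treated_or_diagnosed or sbp >= 140 or dbp >= 90:
        return "hypertension"
    if sbp >= 120 or dbp >= 80:
        return "elevated"
    return "normal"


def classify_cholesterol(tc: float, treated_or_diagnosed: bool) -> str:
    """Total-cholesterol category: low (<180), normal (180-200, boundary 200
    included), elevated (>200, or treated/previously diagnosed)."""
    if tc <= 0:
        raise ValueError(f"total cholesterol must be positive, got {tc}")
    if treated_or_diagnosed or tc > 200:
        return "elevated"
    if tc < 180:
        return "low"
    return "normal"


def classify_glucose(fg: float, treated_or_diagnosed: bool) -> str:
    """Fasting-glucose category: normal (<110) or prediabetes and diabetes
    (>=110, or treated/previously diagnosed)."""
    if fg <= 0:
        raise ValueError(f"fasting glucose must be positive, got {fg}")
    if treated_or_diagnosed or fg >= 110:
        return "prediabetes_diabetes"
    return "normal"


def mdrd_gfr(serum_creatinine, age, female, black=False):
    """Estimated GFR (mL/min/1.73 m^2) by the 4-variable MDRD study equation.

    ``175 * SCr^-1.154 * age^-0.203 * (0.742 if female) [* 1.212 if black]``.
    The race coefficient is off by default (the reference cohort is Korean).
    Accepts scalars or arrays.
    """
    scr = np.asarray(serum_creatinine, dtype=float)
    a = np.asarray(age, dtype=float)
    if np.any(scr <= 0) or np.any(a <= 0):
        raise ValueError("serum creatinine and age must be positive")
    gfr = 175.0 * scr ** -1.154 * a ** -0.203
    gfr = np.where(np.asarray(female, dtype=bool), gfr * 0.742, gfr)
    if np.any(black):
        gfr = np.where(np.asarray(black, dtype=bool), gfr * 1.212, gfr)
    return gfr if gfr.ndim else float(gfr)


def gfr_category(gfr) -> str | np.ndarray:
    """GFR category at the boundaries >=90 / 60-89 / <60 mL/min/1.73 m^2."""
    g = np.asarray(gfr, dtype=float)
    cat = np.where(g >= 90, "ge90", np.where(g >= 60, "b60_89", "lt60")).astype(object)
    return cat if cat.ndim else str(cat)


@dataclass
class ComorbidityProfile:
    """One subject's marker categories (plus the continuous GFR value)."""

    bp_category: str
    chol_category: str
    glucose_category: str
    gfr_value: float
    gfr_category: str

    def __post_init__(self) -> None:
        checks = [
            (self.bp_category, BP_CATEGORIES),
            (self.chol_category, CHOL_CATEGORIES),
            (self.glucose_category, GLUCOSE_CATEGORIES),
            (self.gfr_category, GFR_CATEGORIES),
        ]
        for value, allowed in checks:
            if value not in allowed:
                raise ValueError(f"{value!r} not in {allowed}")
        if gfr_category(self.gfr_value) != self.gfr_category:
            raise ValueError("gfr_category inconsistent with gfr_value")


def classify_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Append marker-category columns to a cohort table.

    Expects sbp/dbp, total_cholesterol, fasting_glucose, serum_creatinine,
    age, sex, and the dx_/rx_ self-report flags; adds ``bp_category``,
    ``chol_category``, ``glucose_category``, ``gfr_value``, ``gfr_category``.
    """
    df = cohort.copy()
    bp_flag = df["dx_hypertension"].astype(bool) | df["rx_hypertension"].astype(bool)
    ch_flag = df["dx_dyslipidemia"].astype(bool) | df["rx_dyslipidemia"].astype(bool)
    gl_flag = df["dx_diabetes"].astype(bool) | df["rx_diabetes"].astype(bool)
    df["bp_category"] = [
        classify_blood_pressure(s, d, f)
        for s, d, f in zip(df["sbp"], df["dbp"], bp_flag)
    ]
    df["chol_category"] = [
        classify_cholesterol(t, f) for t, f in zip(df["total_cholesterol"], ch_flag)
    ]
    df["glucose_category"] = [
        classify_glucose(g, f) for g, f in zip(df["fasting_glucose"], gl_flag)
    ]
    df["gfr_value"] = mdrd_gfr(
        df["serum_creatinine"].to_numpy(),
        df["age"].to_numpy(),
        (df["sex"] == "female").to_numpy(),
    )
    df["gfr_category"] = gfr_category(df["gfr_value"].to_numpy())
    return df


@dataclass
class ExclusionReport:
    """Sequential gate counts of the subject exclusion cascade."""

    n_input: int
    n_energy_excluded: int
    n_prior_cancer_excluded: int
    n_missing_excluded: int
    n_early_case_excluded: int
    n_final: int

    def __post_init__(self) -> None:
        removed = (
            self.n_energy_excluded
            + self.n_prior_cancer_excluded
            + self.n_missing_excluded
            + self.n_early_case_excluded
        )
        if self.n_final != self.n_input - removed:
            raise ValueError("gate counts do not add up to n_final")

    def to_dict(self) -> dict[str, int]:
        return asdict(self)


def apply_exclusions(
    cohort: pd.DataFrame, latency_years: float = 1.0
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the four sequential exclusion gates and report per-gate counts.

    Gates, in order (a subject is counted once, at the first gate it fails):
    missing or unrealistic energy intake (<500 or >4000 kcal/day); prior
    cancer diagnosis; missing demographics or comorbidity measurements;
    cancer diagnosed within ``latency_years`` of enrollment (the reverse-
    causality guard; 0 keeps all early cases).
    """
    df = cohort
    n_input = len(df)

    energy = df["energy"]
    bad_energy = energy.isna() | (energy < 500) | (energy > 4000)
    df = df[~bad_energy]

    prior = df["prior_cancer"].astype(bool)
    df = df[~prior]

    present = [c for c in REQUIRED_COVARIATES if c in df.columns]
    missing = df[present].isna().any(axis=1)
    df = df[~missing]

    if latency_years > 0:
        early = df["cancer_event"].astype(bool) & (
            df["time_to_diagnosis_years"] <= latency_years
        )
    else:
        early = pd.Series(False, index=df.index)
    df = df[~early]

    report = ExclusionReport(
        n_input=n_input,
        n_energy_excluded=int(bad_energy.sum()),
        n_prior_cancer_excluded=int(prior.sum()),
        n_missing_excluded=int(missing.sum()),
        n_early_case_excluded=int(early.sum()),
        n_final=len(df),
    )
    return df.copy(), report
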