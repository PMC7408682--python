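"""Cox models for comorbidity markers and the additive risk-point score.

The comorbidity risk score follows the Framingham-style points procedure of
Sullivan: fit a proportional-hazards model for cancer incidence containing
age (per year) and indicator terms for each non-reference comorbidity
category, divide each category coefficient by the age coefficient, and round
to the nearest integer.  A subject's score is the sum of the points of their
four marker categories; strata of the score are configuration (printed
labels by default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.duration.hazard_regression import PHReg

from . import reference
from .markers import ComorbidityProfile

logger = logging.getLogger(__name__)

__all__ = [
    "CoxModelFit",
    "RiskPointTable",
    "fit_cox",
    "fit_comorbidity_model",
    "sullivan_points",
    "comorbidity_score",
    "score_cohort_points",
    "stratify",
    "round_half_away",
    "bmi_category",
]

#: Reference level and coding order per categorical model term.
CATEGORY_LEVELS: dict[str, list[str]] = {
    "sex": ["female", "male"],
    "marital_status": ["married_cohabitant", "others"],
    "education": ["lt_high_school", "high_school", "ge_college"],
    "employment": ["employed", "unemployed"],
    "income": ["lt_2m", "2_4m", "ge_4m"],
    "smoking": ["never", "past", "current"],
    "drinking": ["never", "past", "current"],
    "physical_activity": ["no", "yes"],
    "bmi_category": ["lt23", "23_24.9", "ge25"],
    "eating_behavior": ["light", "normal", "heavy"],
    "bp_category": ["normal", "elevated", "hypertension"],
    "chol_category": ["elevated", "low", "normal"],
    "glucose_category": ["normal", "prediabetes_diabetes"],
    "gfr_category": ["lt60", "b60_89", "ge90"],
}

#: Marker name -> (category column, reference level).
MARKER_COLUMNS: dict[str, tuple[str, str]] = {
    "blood_pressure": ("bp_category", "normal"),
    "cholesterol": ("chol_category", "elevated"),
    "glucose": ("glucose_category", "normal"),
    "gfr": ("gfr_category", "lt60"),
}

#: Covariate sets of the comorbidity Cox model presets.
COMORBIDITY_MODEL_PRESETS: dict[str, list[str]] = {
    "adjusted": ["age"],
    "fully_adjusted": [
        "age",
        "sex",
        "marital_status",
        "education",
        "employment",
        "income",
        "smoking",
        "drinking",
        "physical_activity",
        "bmi_category",
        "dietary_score",
    ],
}


def bmi_category(bmi: np.ndarray | pd.Series) -> np.ndarray:
    """BMI bands <23 / 23-24.9 / >=25 kg/m^2 used as a model covariate."""
    b = np.asarray(bmi, dtype=float)
    return np.where(b < 23, "lt23", np.where(b < 25, "23_24.9", "ge25")).astype(object)


def round_half_away(x: np.ndarray | float) -> np.ndarray | float:
    """Round to the nearest integer, halves away from zero."""
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.floor(np.abs(x) + 0.5)
    return out if out.ndim else float(out)


def build_design(df: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    """Numeric design matrix for the given terms.

    Continuous columns pass through; categorical columns expand to indicator
    columns named ``col[level]`` for every non-reference level in
    :data:`CATEGORY_LEVELS` order.
    """
    cols: dict[str, np.ndarray] = {}
    for term in terms:
        if term == "bmi_category" and term not in df.columns:
            values = pd.Series(bmi_category(df["bmi"]), index=df.index)
        elif term not in df.columns:
            raise KeyError(f"model term {term!r} not found in data")
        else:
            values = df[term]
        if term in CATEGORY_LEVELS:
            levels = CATEGORY_LEVELS[term]
            observed = set(pd.unique(values.dropna()))
            unknown = observed - set(levels)
            if unknown:
                raise ValueError(f"unknown levels {unknown} in {term!r}")
            for level in levels[1:]:
                cols[f"{term}[{level}]"] = (values == level).to_numpy(dtype=float)
        else:
            cols[term] = pd.to_numeric(values).to_numpy(dtype=float)
    return pd.DataFrame(cols, index=df.index)


@dataclass
class CoxModelFit:
    """Named coefficients and Wald machinery of one Cox fit."""

    terms: pd.Series
    standard_errors: pd.Series
    log_likelihood: float
    n_events: int
    ties_method: str

    @property
    def params(self) -> pd.Series:
        return self.terms

    def hazard_ratios(self, z: float = 1.959963984540054) -> pd.DataFrame:
        """HR with Wald 95% CI per term."""
        hr = np.exp(self.terms)
        lo = np.exp(self.terms - z * self.standard_errors)
        hi = np.exp(self.terms + z * self.standard_errors)
        p = 2 * _norm_sf(np.abs(self.terms / self.standard_errors))
        return pd.DataFrame({"hr": hr, "ci_low": lo, "ci_high": hi, "p": p})


def _norm_sf(z):
    from scipy.stats import norm

    return norm.sf(z)


def fit_cox_design(
    X: pd.DataFrame,
    durations: np.ndarray,
    events: np.ndarray,
    ties: str = "efron",
    separation_guard: bool = True,
) -> CoxModelFit:
    """Fit a Cox model on an already-built numeric design matrix."""
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=bool)
    if np.any(durations <= 0):
        raise ValueError("durations must be positive")
    if events.sum() < 1:
        raise ValueError("at least one event is required")
    if X.isna().any().any():
        raise ValueError("missing covariate values in the Cox design matrix")
    model = PHReg(durations, X.to_numpy(), status=events.astype(int), ties=ties)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(maxiter=200)
    except np.linalg.LinAlgError as err:
        raise RuntimeError(
            "Cox information matrix is singular; check for empty or "
            f"event-free covariate patterns (terms: {list(X.columns)})"
        ) from err
    params = np.asarray(res.params, dtype=float)
    if not np.all(np.isfinite(params)):
        grad = np.linalg.norm(model.score(res.params))
        raise RuntimeError(f"Cox fit did not converge (gradient norm {grad:.3g})")
    big = np.abs(params) > 50
    if np.any(big):
        offending = [X.columns[i] for i in np.flatnonzero(big)]
        if separation_guard:
            raise RuntimeError(f"complete separation suspected for terms {offending}")
        warnings.warn(f"extreme coefficients for terms {offending}", stacklevel=2)
    return CoxModelFit(
        terms=pd.Series(params, index=X.columns),
        standard_errors=pd.Series(np.asarray(res.bse, dtype=float), index=X.columns),
        log_likelihood=float(model.loglike(res.params)),
        n_events=int(events.sum()),
        ties_method=ties,
    )


def fit_cox(
    df: pd.DataFrame,
    terms: list[str],
    duration_col: str = "followup_years",
    event_col: str = "cancer_event",
    ties: str = "efron",
) -> CoxModelFit:
    """Maximize the Cox partial likelihood for the given model terms.

    Uses the Efron tie correction by default (screening cohorts carry tied
    event times); ``ties="breslow"`` is available.  Standard errors come from
    the observed information.
    """
    durations = pd.to_numeric(df[duration_col]).to_numpy(dtype=float)
    events = df[event_col].astype(bool).to_numpy()
    X = build_design(df, terms)
    return fit_cox_design(X, durations, events, ties=ties)


def fit_comorbidity_model(
    df: pd.DataFrame,
    model: str = "fully_adjusted",
    markers: tuple[str, ...] = tuple(MARKER_COLUMNS),
    ties: str = "efron",
) -> CoxModelFit:
    """One joint Cox model with all (included) marker categories plus the
    preset covariates, so a single age coefficient serves the points rule."""
    if model not in COMORBIDITY_MODEL_PRESETS:
        raise ValueError(f"unknown model preset {model!r}")
    terms = list(COMORBIDITY_MODEL_PRESETS[model])
    terms += [MARKER_COLUMNS[m][0] for m in markers]
    return fit_cox(df, terms, ties=ties)


@dataclass
class RiskPointTable:
    """Integer risk point per comorbidity category; references carry 0."""

    points: dict[str, dict[str, int]]
    included_markers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.included_markers:
            self.included_markers = tuple(self.points)
        for marker in self.included_markers:
            if marker not in self.points:
                raise ValueError(f"no points for included marker {marker!r}")
            for cat, pt in self.points[marker].items():
                if pt != int(pt):
                    raise ValueError(f"point for {marker}/{cat} is not an integer")

    @property
    def max_score(self) -> int:
        return int(
            sum(max(self.points[m].values()) for m in self.included_markers)
        )

    @classmethod
    def from_reference(cls, variant: str = "main") -> "RiskPointTable":
        """Published point tables: ``main`` or ``no_cholesterol``."""
        tables = {
            "main": reference.RISK_POINTS_MAIN,
            "no_cholesterol": reference.RISK_POINTS_NO_CHOLESTEROL,
        }
        if variant not in tables:
            raise ValueError(f"unknown variant {variant!r}")
        pts = {m: dict(cats) for m, cats in tables[variant].items()}
        return cls(points=pts)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (m, cat, pt)
            for m in self.included_markers
            for cat, pt in self.points[m].items()
        ]
        return pd.DataFrame(rows, columns=["marker", "category", "point"])

    def to_dict(self) -> dict:
        return {
            "points": {m: dict(c) for m, c in self.points.items()},
            "included_markers": list(self.included_markers),
            "max_score": self.max_score,
        }


def sullivan_points(
    fit: CoxModelFit, markers: tuple[str, ...] = tuple(MARKER_COLUMNS)
) -> RiskPointTable:
    """Convert Cox coefficients into integer risk points.

    ``point = round(beta_category / beta_age)``, halves away from zero;
    reference categories score 0.  Negative points are retained (and logged),
    not clamped.  Fails if the fitted age coefficient is not positive, since
    the ratio rule is then undefined.
    """
    if "age" not in fit.terms.index:
        raise ValueError("fit must contain an 'age' term")
    beta_age = float(fit.terms["age"])
    if beta_age <= 0:
        raise ValueError(f"age coefficient must be positive, got {beta_age:.4g}")
    points: dict[str, dict[str, int]] = {}
    for marker in markers:
        col, ref = MARKER_COLUMNS[marker]
        marker_points = {ref: 0}
        for level in CATEGORY_LEVELS[col]:
            if level == ref:
                continue
            term = f"{col}[{level}]"
            if term not in fit.terms.index:
                raise ValueError(f"fit lacks the comorbidity term {term!r}")
            pt = int(round_half_away(fit.terms[term] / beta_age))
            if pt < 0:
                logger.warning("negative risk point %d for %s/%s", pt, marker, level)
            marker_points[level] = pt
        points[marker] = marker_points
    return RiskPointTable(points=points, included_markers=tuple(markers))


def comorbidity_score(
    profile: ComorbidityProfile | dict[str, str], table: RiskPointTable
) -> int:
    """Sum of the risk points of a subject's categories over included markers."""
    if isinstance(profile, ComorbidityProfile):
        cats = {
            "blood_pressure": profile.bp_category,
            "cholesterol": profile.chol_category,
            "glucose": profile.glucose_category,
            "gfr": profile.gfr_category,
        }
    else:
        cats = dict(profile)
    total = 0
    for marker in table.included_markers:
        cat = cats.get(marker)
        if cat not in table.points[marker]:
            raise KeyError(f"unknown category {cat!r} for marker {marker!r}")
        total += table.points[marker][cat]
    return int(total)


def score_cohort_points(df: pd.DataFrame, table: RiskPointTable) -> pd.Series:
    """Vectorized comorbidity score over a classified cohort table."""
    total = np.zeros(len(df), dtype=int)
    for marker in table.included_markers:
        col, _ = MARKER_COLUMNS[marker]
        mapped = df[col].map(table.points[marker])
        if mapped.isna().any():
            bad = df[col][mapped.isna()].unique()
            raise KeyError(f"unknown categories {bad} in column {col!r}")
        total += mapped.to_numpy(dtype=int)
    return pd.Series(total, index=df.index, name="comorbidity_score")


def stratify(
    scores: np.ndarray | pd.Series,
    cutpoints: list[tuple[str, int, int]] = reference.STRATA_MAIN,
) -> np.ndarray:
    """Map integer scores to stratum labels with inclusive integer bounds."""
    s = np.asarray(scores)
    if s.size == 0:
        return np.array([], dtype=object)
    bounds = [(lo, hi) for _, lo, hi in cutpoints]
    for (_, hi_prev), (lo, _) in zip(bounds, bounds[1:]):
        if lo != hi_prev + 1:
            raise ValueError("strata must be contiguous and strictly increasing")
    lo_all, hi_all = bounds[0][0], bounds[-1][1]
    if s.min() < lo_all or s.max() > hi_all:
        raise ValueError(
            f"scores outside the configured strata [{lo_all}, {hi_all}]: "
            f"min={s.min()}, max={s.max()}"
        )
    out = np.empty(s.shape, dtype=object)
    for label, lo, hi in cutpoints:
        out[(s >= lo) & (s <= hi)] = label
    return out
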