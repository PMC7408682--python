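"""Association between comorbidity-score strata and cancer incidence.

Kaplan-Meier curves per stratum, crude / adjusted / fully adjusted Cox
hazard ratios against the lowest stratum, a mean-score linear-trend test,
sex subgroups, and the two sensitivity pipelines (cholesterol excluded from
the score; early cases retained).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy.stats import norm

from . import reference
from .markers import apply_exclusions, classify_cohort
from .network import eigenvector_centrality, estimate_ggm, score_cohort
from .scoring import (
    MARKER_COLUMNS,
    RiskPointTable,
    build_design,
    fit_comorbidity_model,
    fit_cox_design,
    score_cohort_points,
    stratify,
    sullivan_points,
)
from .simulate import INTAKE_COLUMNS

__all__ = [
    "SurvivalCurve",
    "AssociationResult",
    "ASSOCIATION_PRESETS",
    "kaplan_meier",
    "association",
    "trend_test",
    "resolve_strata",
    "sensitivity_suite",
]

#: Covariate sets of the stratum-association Cox model presets.
ASSOCIATION_PRESETS: dict[str, list[str]] = {
    "crude": [],
    "adjusted": [
        "age",
        "sex",
        "education",
        "employment",
        "income",
        "smoking",
        "drinking",
        "bmi_category",
    ],
    "fully_adjusted": [
        "age",
        "sex",
        "education",
        "employment",
        "income",
        "smoking",
        "drinking",
        "bmi_category",
        "marital_status",
        "physical_activity",
        "eating_behavior",
    ],
}

_Z95 = float(norm.ppf(0.975))


@dataclass
class SurvivalCurve:
    """Product-limit estimate of the cancer-free probability for one stratum."""

    stratum: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median_time: float | None

    def __post_init__(self) -> None:
        s = np.asarray(self.survival, dtype=float)
        if s.size and (np.any(s > 1 + 1e-12) or np.any(s < -1e-12)):
            raise ValueError("survival probabilities must lie in [0, 1]")
        if np.any(np.diff(s) > 1e-12):
            raise ValueError("survival must be non-increasing")


@dataclass
class AssociationResult:
    """Per-stratum hazard ratios (reference stratum HR = 1) and trend p."""

    model: str
    subgroup: str
    table: pd.DataFrame  # index: stratum; columns: n, events, hr, ci_low, ci_high
    p_trend: float

    def __post_init__(self) -> None:
        if not 0 <= self.p_trend <= 1:
            raise ValueError("p_trend must lie in [0, 1]")


def kaplan_meier(
    times: np.ndarray | pd.Series,
    events: np.ndarray | pd.Series,
    strata: np.ndarray | pd.Series,
) -> dict[str, SurvivalCurve]:
    """Kaplan-Meier curve per stratum; empty strata are omitted with a warning."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    s = np.asarray(strata, dtype=object)
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    out: dict[str, SurvivalCurve] = {}
    for label in pd.unique(s):
        mask = s == label
        if mask.sum() == 0:  # pragma: no cover - unique() precludes this
            warnings.warn(f"stratum {label!r} is empty; omitted", stacklevel=2)
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], event_observed=e[mask])
        surv = kmf.survival_function_["KM_estimate"]
        med = kmf.median_survival_time_
        out[str(label)] = SurvivalCurve(
            stratum=str(label),
            times=surv.index.to_numpy(dtype=float),
            survival=surv.to_numpy(dtype=float),
            at_risk=kmf.event_table["at_risk"].to_numpy(),
            median_time=None if np.isinf(med) else float(med),
        )
    return out


def _subset_terms(model: str, subgroup: str) -> list[str]:
    if model not in ASSOCIATION_PRESETS:
        raise ValueError(f"unknown model preset {model!r}")
    terms = list(ASSOCIATION_PRESETS[model])
    if subgroup != "all" and "sex" in terms:
        terms.remove("sex")  # sex subgroups are not adjusted for sex
    return terms


def _subset_rows(df: pd.DataFrame, subgroup: str) -> pd.DataFrame:
    if subgroup == "all":
        return df
    if subgroup not in ("male", "female"):
        raise ValueError(f"unknown subgroup {subgroup!r}")
    return df[df["sex"] == subgroup]


def association(
    df: pd.DataFrame,
    model: str = "fully_adjusted",
    subgroup: str = "all",
    stratum_col: str = "score_stratum",
    score_col: str = "comorbidity_score",
    strata_order: list[str] | None = None,
    duration_col: str = "followup_years",
    event_col: str = "cancer_event",
) -> AssociationResult:
    """Cox hazard ratios of the score strata against the lowest stratum.

    The lowest stratum is the reference (HR exactly 1); the other strata
    enter as indicators.  Wald 95% CIs; the trend p-value re-enters the
    strata as their mean comorbidity score (see :func:`trend_test`).
    """
    data = _subset_rows(df, subgroup)
    terms = _subset_terms(model, subgroup)
    if strata_order is None:
        strata_order = sorted(
            pd.unique(data[stratum_col]), key=lambda s: data.loc[data[stratum_col] == s, score_col].min()
        )
    ref = strata_order[0]

    X = build_design(data, terms)
    rows = []
    events_by = {}
    for label in strata_order:
        mask = data[stratum_col] == label
        events_by[label] = int(data.loc[mask, event_col].astype(bool).sum())
        if events_by[label] == 0:
            warnings.warn(f"stratum {label!r} has zero events", stacklevel=2)
        rows.append((label, int(mask.sum()), events_by[label]))

    # event-free strata have divergent partial-likelihood MLEs for their
    # indicator; exclude them from the fit and report the limiting HR (0
    # against an eventful reference, infinity when the reference itself is
    # event-free) with an infinite CI bound
    fitted: list[str] = []
    if events_by[ref] > 0:
        for label in strata_order:
            if label != ref and events_by[label] > 0:
                X[f"stratum[{label}]"] = (data[stratum_col] == label).to_numpy(float)
                fitted.append(label)
    if X.shape[1] > 0:
        fit = fit_cox_design(
            X,
            pd.to_numeric(data[duration_col]).to_numpy(dtype=float),
            data[event_col].astype(bool).to_numpy(),
            separation_guard=False,
        )
    else:  # crude model with nothing estimable beyond the reference
        fit = None
    table = pd.DataFrame(rows, columns=["stratum", "n", "events"]).set_index("stratum")
    hr, lo, hi = [], [], []
    for label in strata_order:
        if label == ref:
            hr.append(1.0), lo.append(np.nan), hi.append(np.nan)
        elif label in fitted:
            b = fit.terms[f"stratum[{label}]"]
            se = fit.standard_errors[f"stratum[{label}]"]
            with np.errstate(over="ignore"):
                hr.append(float(np.exp(b)))
                lo.append(float(np.exp(b - _Z95 * se)))
                hi.append(float(np.exp(b + _Z95 * se)))
        elif events_by[label] == 0:
            hr.append(0.0), lo.append(0.0), hi.append(np.inf)
        else:  # eventful stratum against an event-free reference
            hr.append(np.inf), lo.append(0.0), hi.append(np.inf)
    table["hr"], table["ci_low"], table["ci_high"] = hr, lo, hi

    p = trend_test(
        df,
        model=model,
        subgroup=subgroup,
        stratum_col=stratum_col,
        score_col=score_col,
        duration_col=duration_col,
        event_col=event_col,
    )
    return AssociationResult(model=model, subgroup=subgroup, table=table, p_trend=p)


def trend_test(
    df: pd.DataFrame,
    model: str = "fully_adjusted",
    subgroup: str = "all",
    stratum_col: str = "score_stratum",
    score_col: str = "comorbidity_score",
    duration_col: str = "followup_years",
    event_col: str = "cancer_event",
) -> float:
    """Dose-response (linear trend) test across score strata.

    Each subject's stratum is replaced by the stratum's mean comorbidity
    score, the preset Cox model is refit with that single continuous term,
    and the Wald p-value of the term is returned.
    """
    data = _subset_rows(df, subgroup)
    events_per_stratum = data.groupby(stratum_col)[event_col].apply(
        lambda e: e.astype(bool).sum()
    )
    if (events_per_stratum > 0).sum() < 2:
        raise ValueError("trend test requires at least two strata with events")
    if data[stratum_col].nunique() < 2:
        raise ValueError("trend test undefined for a single stratum")
    means = data.groupby(stratum_col)[score_col].mean()
    X = build_design(data, _subset_terms(model, subgroup))
    X["score_trend"] = data[stratum_col].map(means).to_numpy(dtype=float)
    fit = fit_cox_design(
        X,
        pd.to_numeric(data[duration_col]).to_numpy(dtype=float),
        data[event_col].astype(bool).to_numpy(),
        separation_guard=False,
    )
    z = fit.terms["score_trend"] / fit.standard_errors["score_trend"]
    return float(2 * norm.sf(abs(z)))


def resolve_strata(
    template: list[tuple[str, int, int]], scores: np.ndarray | pd.Series
) -> list[tuple[str, int, int]]:
    """Adapt stratum cutpoints to the observed score range.

    Keeps the template's interior cutpoints but widens the first (last) bin
    when refit point tables produce scores below (above) the printed bounds,
    relabelling the widened bin accordingly.
    """
    s = np.asarray(scores)
    out = [list(row) for row in template]
    if s.min() < out[0][1]:
        out[0][1] = int(min(out[0][1], s.min()))
        out[0][0] = f"{out[0][1]}-{out[0][2]}"
    if s.max() > out[-1][2]:
        out[-1][2] = int(s.max())
        out[-1][0] = f"{out[-1][1]}-{out[-1][2]}"
    return [tuple(row) for row in out]  # type: ignore[return-value]


def _score_pipeline(
    analysis: pd.DataFrame,
    markers: tuple[str, ...],
    strata_template: list[tuple[str, int, int]],
    ggm_gamma: float,
) -> tuple[pd.DataFrame, RiskPointTable, list[tuple[str, int, int]]]:
    """Classify markers, build the dietary score, refit points, stratify."""
    df = classify_cohort(analysis)
    net = estimate_ggm(df[INTAKE_COLUMNS].rename(columns=dict(zip(INTAKE_COLUMNS, reference.FOOD_GROUPS))), gamma=ggm_gamma)
    weights = eigenvector_centrality(net)
    diet = score_cohort(
        df[INTAKE_COLUMNS].rename(columns=dict(zip(INTAKE_COLUMNS, reference.FOOD_GROUPS))),
        weights,
    )
    df = pd.concat([df, diet], axis=1)
    fit = fit_comorbidity_model(df, model="fully_adjusted", markers=markers)
    table = sullivan_points(fit, markers=markers)
    df["comorbidity_score"] = score_cohort_points(df, table)
    strata = resolve_strata(strata_template, df["comorbidity_score"])
    df["score_stratum"] = stratify(df["comorbidity_score"].to_numpy(), strata)
    return df, table, strata


def sensitivity_suite(
    raw_cohort: pd.DataFrame,
    model: str = "fully_adjusted",
    subgroups: tuple[str, ...] = ("all", "male", "female"),
    ggm_gamma: float = 0.5,
) -> dict[str, dict]:
    """Run the two sensitivity pipelines end to end on a raw cohort.

    Variant ``no_cholesterol`` drops total cholesterol from the joint model
    and the score (1-year latency exclusion retained); ``early_included``
    keeps cancers diagnosed within the first year (latency 0) and refits all
    four markers.  Each variant reports the refit point table, the resolved
    strata, and an :class:`AssociationResult` per subgroup.
    """
    variants = {
        "no_cholesterol": dict(
            latency=1.0,
            markers=tuple(m for m in MARKER_COLUMNS if m != "cholesterol"),
            template=reference.STRATA_NO_CHOLESTEROL,
        ),
        "early_included": dict(
            latency=0.0,
            markers=tuple(MARKER_COLUMNS),
            template=reference.STRATA_EARLY_INCLUDED,
        ),
    }
    out: dict[str, dict] = {}
    for name, spec in variants.items():
        analysis, report = apply_exclusions(raw_cohort, latency_years=spec["latency"])
        scored, table, strata = _score_pipeline(
            analysis, spec["markers"], spec["template"], ggm_gamma
        )
        results = {
            sg: association(scored, model=model, subgroup=sg, strata_order=[s[0] for s in strata])
            for sg in subgroups
        }
        out[name] = {
            "exclusions": report,
            "point_table": table,
            "strata": strata,
            "results": results,
        }
    return out
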