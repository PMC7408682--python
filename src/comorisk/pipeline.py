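"""One-shot orchestration: simulate -> exclude -> classify -> network ->
dietary score -> risk points -> strata -> association, with every
intermediate artifact persisted and a single deterministic JSON run report."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import reference
from .association import association, resolve_strata
from .markers import apply_exclusions, classify_cohort
from .network import eigenvector_centrality, estimate_ggm, score_cohort
from .scoring import (
    MARKER_COLUMNS,
    fit_comorbidity_model,
    score_cohort_points,
    stratify,
    sullivan_points,
)
from .simulate import INTAKE_COLUMNS, SimulationConfig, generate_cohort

logger = logging.getLogger(__name__)

_STRATA_TEMPLATES = {
    "main": reference.STRATA_MAIN,
    "no_cholesterol": reference.STRATA_NO_CHOLESTEROL,
    "early_included": reference.STRATA_EARLY_INCLUDED,
}


@dataclass
class RunConfig:
    """Serializable configuration of one full pipeline run."""

    seed: int = 0
    n_subjects: int = 13_644
    ebic_gamma: float = 0.5
    latency_years: float = 1.0
    centrality_convention: str = "positive"
    grid_size: int = 100
    model: str = "fully_adjusted"
    included_markers: tuple[str, ...] = tuple(MARKER_COLUMNS)
    strata_variant: str = "main"
    subgroups: tuple[str, ...] = ("all", "male", "female")

    def __post_init__(self) -> None:
        if self.strata_variant not in _STRATA_TEMPLATES:
            raise ValueError(f"unknown strata variant {self.strata_variant!r}")
        unknown = set(self.included_markers) - set(MARKER_COLUMNS)
        if unknown:
            raise ValueError(f"unknown markers {unknown}")
        self.included_markers = tuple(self.included_markers)
        self.subgroups = tuple(self.subgroups)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))


def _intakes(df: pd.DataFrame) -> pd.DataFrame:
    return df[INTAKE_COLUMNS].rename(
        columns=dict(zip(INTAKE_COLUMNS, reference.FOOD_GROUPS))
    )


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute every stage in order and return the run report.

    Identical ``config`` (including seed) yields an identical report.  When
    ``out_dir`` is given, the cohort, network adjacency, centrality weights,
    dietary scores, point table, association tables, and the report itself
    are written there as CSV/JSON.
    """
    t0 = time.time()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def _save_df(df: pd.DataFrame, name: str, **kw) -> None:
        if out is not None:
            df.to_csv(out / name, **kw)

    stage = "simulate"
    try:
        sim = SimulationConfig(n_subjects=config.n_subjects, seed=config.seed)
        cohort = generate_cohort(sim)
        _save_df(cohort, "cohort.csv", index=False)

        stage = "exclusions"
        analysis, report = apply_exclusions(cohort, latency_years=config.latency_years)

        stage = "classify"
        analysis = classify_cohort(analysis)

        stage = "network"
        net = estimate_ggm(
            _intakes(analysis), gamma=config.ebic_gamma, grid_size=config.grid_size
        )
        _save_df(net.to_frame(), "network_adjacency.csv")
        if out is not None:
            import networkx as nx

            nx.write_graphml(net.to_graph(), out / "network.graphml")

        stage = "centrality"
        weights = eigenvector_centrality(net, convention=config.centrality_convention)
        _save_df(weights.to_series().to_frame(), "centrality_weights.csv")

        stage = "dietary_score"
        diet = score_cohort(_intakes(analysis), weights)
        analysis = pd.concat([analysis, diet], axis=1)
        _save_df(analysis[["id", "dietary_score", "eating_behavior"]], "dietary_scores.csv", index=False)

        stage = "risk_points"
        fit = fit_comorbidity_model(
            analysis, model="fully_adjusted", markers=config.included_markers
        )
        table = sullivan_points(fit, markers=config.included_markers)
        if out is not None:
            (out / "risk_points.json").write_text(json.dumps(table.to_dict(), indent=2, sort_keys=True))
            table.to_frame().to_csv(out / "risk_points.csv", index=False)

        stage = "comorbidity_score"
        analysis["comorbidity_score"] = score_cohort_points(analysis, table)
        strata = resolve_strata(
            _STRATA_TEMPLATES[config.strata_variant], analysis["comorbidity_score"]
        )
        analysis["score_stratum"] = stratify(
            analysis["comorbidity_score"].to_numpy(), strata
        )
        _save_df(
            analysis[["id", "comorbidity_score", "score_stratum"]],
            "comorbidity_scores.csv",
            index=False,
        )

        stage = "association"
        strata_labels = [s[0] for s in strata]
        assoc: dict[str, dict] = {}
        for preset in ("crude", "adjusted", "fully_adjusted"):
            for sg in config.subgroups:
                if preset != config.model and sg != "all":
                    continue
                res = association(
                    analysis, model=preset, subgroup=sg, strata_order=strata_labels
                )
                key = f"{preset}:{sg}"
                assoc[key] = {
                    "table": json.loads(res.table.to_json(orient="index")),
                    "p_trend": res.p_trend,
                }
                _save_df(res.table, f"association_{preset}_{sg}.csv")
    except Exception:
        logger.exception("pipeline failed at stage %r", stage)
        raise

    report_dict = {
        "config": dataclasses.asdict(config),
        "exclusions": report.to_dict(),
        "n_food_groups": len(reference.FOOD_GROUPS),
        "n_markers": len(config.included_markers),
        "selected_penalty": net.selected_penalty,
        "ebic": net.ebic_value,
        "n_edges": net.n_edges,
        "centrality": {l: float(w) for l, w in zip(weights.labels, weights.weight)},
        "risk_points": table.to_dict(),
        "strata": [list(s) for s in strata],
        "n_strata": len(strata),
        "association": assoc,
        "runtime_s": None,  # filled below, excluded from determinism checks
    }
    # determinism: the report content (minus wall time) is a pure function of config
    report_dict["runtime_s"] = round(time.time() - t0, 3)
    if out is not None:
        payload = dict(report_dict)
        payload.pop("runtime_s")
        (out / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    return report_dict
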