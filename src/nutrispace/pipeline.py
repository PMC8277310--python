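"""End-to-end study workflow on synthetic data.

``run_study`` executes the full intervention-study pipeline in measurement
order: simulate the cohort (weeks 0/8/16), screen for MetS risk factors,
score diet quality, build the two health-space reference groups (healthy
pool filtered and RRA-ranked, full-syndrome pool rule-selected), fit the
health-space model and project participant scores (weeks 0 and 16),
generate stage-1 advice (weeks 0 and 8), attach behavior-change
strategies, and evaluate every outcome longitudinally. Stage outputs are
pure functions of upstream outputs plus the config and seed, so re-running
with the same inputs reproduces the report bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .advice import AdviceRuleSet, compose_advice, evaluate_diet_sufficiency, \
    map_metabolic_abnormalities
from .config import load_defaults, merge_config
from .diet import CATEGORIES, DietProfile
from .evaluation import fit_ordinal_mixed, fit_time_mixed_model, subset_by_strategy
from .healthspace import fit_health_space, predict_score, \
    select_healthy_reference, select_mets_reference
from .screening import HomaFormula, RiskThresholds, harmonize_panel, screen_table
from .synthetic import CohortSpec, TrajectorySpec, generate_intervention_cohort, \
    generate_reference_pool

__all__ = ["RunConfig", "StudyReport", "run_study", "printed_changes",
           "visit_profiles", "evaluate_outcomes"]

#: Outcomes evaluated with the linear mixed model, in report order.
CONTINUOUS_OUTCOMES = (
    "glucose", "c_peptide", "homa_ir", "triglycerides", "total_cholesterol",
    "hdl", "ldl", "sbp", "dbp", "bmi", "waist", "health_score",
    "dhdi_total", "carotenoids",
)
LIKERT_OUTCOMES = ("self_perceived_health", "diet_healthiness",
                   "diet_satisfaction")


@dataclass(frozen=True)
class RunConfig:
    """Reproducible run description: seed, cohort size, reference-pool
    sizes and config overrides (merged over the shipped defaults)."""

    seed: int = 0
    n_participants: int = 34
    n_healthy_pool: int = 400
    n_mets_pool: int = 100
    overrides: Mapping = field(default_factory=dict)

    def config(self) -> dict:
        return merge_config(load_defaults(), self.overrides)


@dataclass
class StudyReport:
    """All stage outputs plus a provenance block."""

    visits: pd.DataFrame
    strategies: dict[str, tuple[str, ...]]
    flags: pd.DataFrame
    scores: pd.DataFrame          # participant_id, week, health_score
    model_json: dict
    advice: dict[str, dict[int, dict]]   # participant -> week -> plan dict
    evaluation: pd.DataFrame      # Tables 3-5-shaped summary
    provenance: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.visits.to_csv(out / "visits.csv", index=False)
        self.flags.to_csv(out / "flags.csv", index=False)
        self.scores.to_csv(out / "health_scores.csv", index=False)
        self.evaluation.to_csv(out / "evaluation.csv", index=False)
        (out / "model.json").write_text(json.dumps(self.model_json, indent=2))
        (out / "advice.json").write_text(json.dumps(self.advice, indent=2))
        (out / "strategies.json").write_text(json.dumps(
            {k: list(v) for k, v in self.strategies.items()}, indent=2))
        (out / "provenance.json").write_text(json.dumps(self.provenance, indent=2))


def visit_profiles(visits: pd.DataFrame) -> dict[tuple[str, int], DietProfile]:
    """DietProfiles keyed by (participant, week) from a visit table."""
    out = {}
    for rec in visits.to_dict("records"):
        scores = {c: rec[c] for c in CATEGORIES}
        if any(pd.isna(v) for v in scores.values()):
            continue
        caro = rec.get("carotenoids")
        out[(rec["participant_id"], int(rec["week"]))] = DietProfile(
            scores={c: float(np.clip(v, 1.0, 10.0)) for c, v in scores.items()},
            carotenoids=None if pd.isna(caro) else float(caro))
    return out


def printed_changes(cfg: Mapping | None = None,
                    outcomes: tuple[str, ...] | None = None) -> dict[str, float]:
    """Last-week minus week-0 change for each outcome in the shipped study
    tables — the study's reported longitudinal changes, recomputed from
    the per-week means."""
    cfg = cfg or load_defaults()
    tables = cfg["study_tables"]
    names = outcomes or tuple(tables)
    return {name: float(tables[name]["means"][-1] - tables[name]["means"][0])
            for name in names}


def evaluate_outcomes(visits: pd.DataFrame, strategies: Mapping,
                      scores: pd.DataFrame) -> pd.DataFrame:
    """Tables-3/4/5-shaped longitudinal summary: one row per outcome with
    per-week estimated means, the overall time-effect p-value and the
    BH-adjusted week-0-to-end contrast; per-category diet outcomes are
    restricted to strategy participants and skipped below n=4."""
    data = visits.merge(scores, on=["participant_id", "week"], how="left")
    rows = []
    for outcome in CONTINUOUS_OUTCOMES + LIKERT_OUTCOMES:
        if outcome not in data.columns:
            continue
        sub = data[["participant_id", "week", outcome]].rename(
            columns={outcome: "value"}).dropna()
        if outcome in CATEGORIES:
            sub = subset_by_strategy(sub, strategies, outcome)
        if sub.empty:
            continue
        try:
            if outcome in LIKERT_OUTCOMES:
                res = fit_ordinal_mixed(sub, outcome=outcome)
                mean_by_week = sub.groupby("week")["value"].mean()
                row = {"outcome": outcome, "kind": "ordinal",
                       "n": res.n_subjects, "overall_p": res.overall_p}
                for w in res.weeks:
                    row[f"mean_w{w}"] = float(mean_by_week[w])
            else:
                res = fit_time_mixed_model(sub, outcome=outcome)
                row = {"outcome": outcome, "kind": "linear",
                       "n": res.n_subjects, "overall_p": res.overall_p,
                       "rmse": res.rmse, "n_outliers": len(res.outlier_ids)}
                for w, m in res.emmeans.items():
                    row[f"mean_w{w}"] = m
                last = res.contrast(res.weeks[0], res.weeks[-1])
                row["change_w0_to_end"] = last.estimate
                row["p_change_adj"] = last.p_adj
        except ValueError as err:
            row = {"outcome": outcome, "kind": "skipped", "note": str(err)}
        rows.append(row)
    # per-category diet rows, subset to strategy participants
    for cat in CATEGORIES:
        sub = data[["participant_id", "week", cat]].rename(
            columns={cat: "value"}).dropna()
        sub = subset_by_strategy(sub, strategies, cat)
        n_subj = sub["participant_id"].nunique()
        if n_subj < 4:
            rows.append({"outcome": cat, "kind": "skipped", "n": n_subj,
                         "note": "sample size not sufficient"})
            continue
        res = fit_time_mixed_model(sub, outcome=cat)
        row = {"outcome": cat, "kind": "linear", "n": res.n_subjects,
               "overall_p": res.overall_p, "rmse": res.rmse,
               "n_outliers": len(res.outlier_ids)}
        for w, m in res.emmeans.items():
            row[f"mean_w{w}"] = m
        last = res.contrast(res.weeks[0], res.weeks[-1])
        row["change_w0_to_end"] = last.estimate
        row["p_change_adj"] = last.p_adj
        rows.append(row)
    return pd.DataFrame(rows)


def run_study(run: RunConfig | None = None) -> StudyReport:
    """Execute the full pipeline; see the module docstring for the stage
    ordering. Deterministic for a fixed ``RunConfig``."""
    run = run or RunConfig()
    cfg = run.config()
    rng = np.random.default_rng(run.seed)
    seeds = {name: int(s) for name, s in zip(
        ("cohort", "healthy_pool", "mets_pool"),
        rng.integers(0, 2**31 - 1, size=3))}

    thresholds = RiskThresholds.from_config(cfg)
    rules = AdviceRuleSet.from_config(cfg)
    homa = HomaFormula(**cfg["homa_ir"])
    hs_cfg = cfg["health_space"]

    # 1. simulate the intervention cohort
    cohort_spec = CohortSpec.from_config(cfg, "intervention")
    traj = TrajectorySpec.from_config(cfg)
    cohort = generate_intervention_cohort(cohort_spec, traj,
                                          run.n_participants, seeds["cohort"])
    visits = harmonize_panel(cohort.visits)
    visits["homa_ir"] = [
        homa(g, c) if g > 0 and c > 0 else np.nan
        for g, c in zip(visits["glucose"], visits["c_peptide"])]

    # 2. screening
    flags = screen_table(visits, thresholds)

    # 3. reference groups and the health-space model
    healthy_pool = harmonize_panel(generate_reference_pool(
        CohortSpec.from_config(cfg, "healthy"), run.n_healthy_pool,
        seeds["healthy_pool"]))
    mets_pool = harmonize_panel(generate_reference_pool(
        CohortSpec.from_config(cfg, "mets"), run.n_mets_pool,
        seeds["mets_pool"]))
    healthy_ref = select_healthy_reference(
        healthy_pool, n_top=hs_cfg["n_top_healthy"],
        bmi_range=tuple(hs_cfg["healthy_bmi_range"]), thresholds=thresholds,
        directions=hs_cfg["higher_is_healthier"])
    mets_ref = select_mets_reference(mets_pool, thresholds)
    model = fit_health_space(
        healthy_ref, mets_ref, features=tuple(hs_cfg["features"]),
        random_structure=hs_cfg["random_structure"],
        class_codes=hs_cfg["class_codes"], threshold=hs_cfg["threshold"])

    score_weeks = cfg["schedule"]["health_score_weeks"]
    score_rows = visits[visits["week"].isin(score_weeks)]
    scores = pd.DataFrame({
        "participant_id": score_rows["participant_id"].to_numpy(),
        "week": score_rows["week"].to_numpy(),
        "health_score": predict_score(model, score_rows).to_numpy()})

    # 4. stage-1 advice at the advice weeks
    profiles = visit_profiles(visits)
    flag_lookup = {(r["participant_id"], r["week"]): r
                   for r in flags.to_dict("records")}
    advice: dict[str, dict[int, dict]] = {}
    from .screening import RiskFlags
    for (pid, week), profile in profiles.items():
        if week not in cfg["schedule"]["advice_weeks"]:
            continue
        f = flag_lookup[(pid, week)]
        rf = RiskFlags(waist_excessive=bool(f["waist_excessive"]),
                       tg_high=bool(f["tg_high"]), hdl_low=bool(f["hdl_low"]),
                       bp_high=bool(f["bp_high"]),
                       glucose_high=bool(f["glucose_high"]))
        plan = compose_advice(evaluate_diet_sufficiency(profile, rules),
                              map_metabolic_abnormalities(rf, rules), rules)
        advice.setdefault(pid, {})[week] = plan.as_dict()

    # 5. longitudinal evaluation
    evaluation = evaluate_outcomes(visits, cohort.strategies, scores)

    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]
    provenance = {"seed": run.seed, "stage_seeds": seeds,
                  "n_participants": run.n_participants,
                  "config_sha256": cfg_hash, "version": __version__}

    model_json = {
        "features": list(model.features), "means": model.means,
        "sds": model.sds, "intercept": model.intercept,
        "coefficients": model.coefficients,
        "sex_adjustments": model.sex_adjustments,
        "class_codes": model.class_codes, "threshold": model.threshold,
        "random_structure": model.random_structure,
        "n_healthy": len(healthy_ref), "n_mets": len(mets_ref)}

    return StudyReport(visits=visits, strategies=cohort.strategies,
                       flags=flags, scores=scores, model_json=model_json,
                       advice=advice, evaluation=evaluation,
                       provenance=provenance)
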