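#!/usr/bin/env python
"""Evaluate the intervention longitudinally.

Fits the time-effect linear mixed model (subject random intercept, BH-
adjusted pairwise contrasts, 3xRMSE outlier pass) to every metabolic and
diet outcome — per-category diet analyses restricted to participants whose
strategy includes the category — the cumulative-link mixed model to the
Likert items, and Pearson correlations between per-subject week-0-to-16
changes. Writes results/evaluation/.
"""

import json
from pathlib import Path

import pandas as pd

from nutrispace.evaluation import correlation_table
from nutrispace.pipeline import evaluate_outcomes

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    visits = pd.read_csv(ROOT / "cohort" / "visits.csv")
    strategies = {k: tuple(v) for k, v in json.loads(
        (ROOT / "cohort" / "cohort.json").read_text())["strategies"].items()}
    scores = pd.read_csv(ROOT / "health_space" / "scores.csv")

    table = evaluate_outcomes(visits, strategies, scores)
    out = ROOT / "evaluation"
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "outcomes.csv", index=False)

    # per-subject week-0 -> week-16 deltas for the correlation screen
    merged = visits.merge(scores, on=["participant_id", "week"], how="left")
    wide0 = merged[merged.week == 0].set_index("participant_id")
    wide16 = merged[merged.week == 16].set_index("participant_id")
    diet_cols = ["dhdi_total", "vegetables", "fruit", "oils_and_fats", "fish",
                 "wholegrain", "dairy", "nuts", "sugar_beverages"]
    metab_cols = ["health_score", "hdl", "ldl", "triglycerides", "glucose",
                  "c_peptide", "waist", "bmi"]
    deltas = (wide16[diet_cols + metab_cols]
              - wide0[diet_cols + metab_cols]).dropna()
    corr = correlation_table(deltas, diet_cols, metab_cols)
    corr = pd.concat([corr, correlation_table(deltas, ["health_score"],
                                              [c for c in metab_cols
                                               if c != "health_score"])])
    corr.to_csv(out / "delta_correlations.csv", index=False)

    shown = table[table.kind != "skipped"]
    print("time effects (overall LRT p, week-0 -> end change):")
    for row in shown.itertuples():
        change = getattr(row, "change_w0_to_end", float("nan"))
        change_txt = "" if pd.isna(change) else f", change {change:+.2f}"
        print(f"  {row.outcome}: p={row.overall_p:.3g}{change_txt}")
    skipped = table[table.kind == "skipped"]["outcome"].tolist()
    if skipped:
        print(f"skipped (insufficient strategy subset): {skipped}")
    sig = corr[(corr.p < 0.05)].sort_values("p")
    print("significant delta correlations (influence-screened):")
    for row in sig.head(8).itertuples():
        tag = " [fragile]" if row.fragile else ""
        print(f"  {row.var_a} vs {row.var_b}: rho={row.rho:.2f}, "
              f"p={row.p:.3g}{tag}")


if __name__ == "__main__":
    main()
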