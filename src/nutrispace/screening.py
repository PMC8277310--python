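"""Metabolic-syndrome risk screening.

Implements the study's risk-factor flags and eligibility rules: central
obesity (waist circumference at or above the sex-specific cut-off) combined
with secondary factors — elevated fasting triglycerides (>= 1.7 mmol/L),
reduced HDL cholesterol (< 1.03 mmol/L men, < 1.29 mmol/L women), elevated
blood pressure (systolic >= 130 or diastolic >= 85 mm Hg) and elevated
fasting glucose (> 5.6 mmol/L). "At risk" means central obesity plus at
least one secondary factor; the full-syndrome rule used for reference-group
selection requires central obesity plus at least two (an IDF-style
definition expressed with this study's thresholds; both counts are
configurable).

Boundary semantics follow the printed inequalities exactly: ``>=`` for
waist, triglycerides and blood pressure, strict ``<`` for HDL, strict ``>``
for glucose. Missing fields raise rather than silently passing a subject.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Callable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "VisitMeasurement",
    "harmonize_panel",
    "RiskFlags",
    "RiskThresholds",
    "MissingDataError",
    "flag_risk_factors",
    "classify_at_risk",
    "classify_mets",
    "average_duplicates",
    "homa_ir",
    "HomaFormula",
    "motivated",
    "screen_table",
]


class MissingDataError(ValueError):
    """A field required by a screening rule is absent."""


def _missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass(frozen=True)
class VisitMeasurement:
    """One participant-visit metabolic panel.

    Concentrations in mmol/L (C-peptide nmol/L), pressures in mm Hg, waist
    in cm, BMI in kg/m^2. ``weight`` (kg) is optional and unused by the
    screening rules.
    """

    participant_id: str
    week: int
    sex: str  # 'M' | 'F'
    waist: float
    bmi: float
    sbp: float
    dbp: float
    total_cholesterol: float
    hdl: float
    ldl: float
    triglycerides: float
    glucose: float
    c_peptide: float
    weight: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        for name in ("total_cholesterol", "hdl", "ldl", "triglycerides",
                     "glucose", "c_peptide"):
            v = getattr(self, name)
            if not _missing(v) and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if not _missing(self.waist) and self.waist <= 0:
            raise ValueError(f"waist must be > 0, got {self.waist}")
        if not _missing(self.sbp) and not _missing(self.dbp) and self.sbp <= self.dbp:
            raise ValueError(f"systolic ({self.sbp}) must exceed diastolic ({self.dbp})")


@dataclass(frozen=True)
class RiskThresholds:
    """Risk-factor cut-offs; defaults are the study's printed values."""

    waist: Mapping[str, float] = field(default_factory=lambda: {"M": 102.0, "F": 88.0})
    triglycerides: float = 1.7
    hdl: Mapping[str, float] = field(default_factory=lambda: {"M": 1.03, "F": 1.29})
    sbp: float = 130.0
    dbp: float = 85.0
    glucose: float = 5.6
    at_risk_min_secondary: int = 1
    mets_min_secondary: int = 2

    @classmethod
    def from_config(cls, cfg: Mapping) -> "RiskThresholds":
        s = cfg["screening"]
        return cls(
            waist=dict(s["waist_cm"]),
            triglycerides=s["triglycerides_mmol_l"],
            hdl=dict(s["hdl_mmol_l"]),
            sbp=s["sbp_mm_hg"],
            dbp=s["dbp_mm_hg"],
            glucose=s["glucose_mmol_l"],
            at_risk_min_secondary=s["at_risk_min_secondary"],
            mets_min_secondary=s["mets_min_secondary"],
        )


@dataclass(frozen=True)
class RiskFlags:
    waist_excessive: bool
    tg_high: bool
    hdl_low: bool
    bp_high: bool
    glucose_high: bool

    @property
    def n_secondary(self) -> int:
        return sum((self.tg_high, self.hdl_low, self.bp_high, self.glucose_high))

    def as_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["n_secondary"] = self.n_secondary
        return d


def flag_risk_factors(m: VisitMeasurement,
                      thresholds: RiskThresholds | None = None) -> RiskFlags:
    """Evaluate the five MetS risk-factor flags for one measurement."""
    t = thresholds or RiskThresholds()
    for name in ("waist", "triglycerides", "hdl", "sbp", "dbp", "glucose"):
        if _missing(getattr(m, name)):
            raise MissingDataError(f"{name} missing for participant {m.participant_id}")
    return RiskFlags(
        waist_excessive=m.waist >= t.waist[m.sex],
        tg_high=m.triglycerides >= t.triglycerides,
        hdl_low=m.hdl < t.hdl[m.sex],
        bp_high=m.sbp >= t.sbp or m.dbp >= t.dbp,
        glucose_high=m.glucose > t.glucose,
    )


def classify_at_risk(flags: RiskFlags, min_secondary: int = 1) -> bool:
    """Central obesity plus at least ``min_secondary`` secondary factors."""
    return flags.waist_excessive and flags.n_secondary >= min_secondary


def classify_mets(flags: RiskFlags, min_secondary: int = 2) -> bool:
    """Full-syndrome rule: central obesity plus >= ``min_secondary`` factors."""
    return flags.waist_excessive and flags.n_secondary >= min_secondary


def average_duplicates(x1: float, x2: float) -> float:
    """Arithmetic mean of duplicate readings (glucose and blood pressure
    are measured twice per visit and averaged)."""
    if _missing(x1) or _missing(x2):
        raise MissingDataError("both duplicate readings must be present")
    if x1 < 0 or x2 < 0:
        raise ValueError("readings must be >= 0")
    return (x1 + x2) / 2.0


@dataclass(frozen=True)
class HomaFormula:
    """Multiplicative C-peptide-based HOMA-IR form.

    HOMA-IR = glucose [mmol/L] x (C-peptide [nmol/L] x insulin_equiv
    [uU/mL per nmol/L]) / denominator. The exact C-peptide-based formula
    used by the study is not published; this form is an explicit,
    configurable assumption.
    """

    insulin_equiv: float = 6.0
    denominator: float = 22.5

    def __call__(self, glucose: float, c_peptide: float) -> float:
        return glucose * c_peptide * self.insulin_equiv / self.denominator


def homa_ir(glucose: float, c_peptide: float,
            formula: HomaFormula | Callable[[float, float], float] | None = None) -> float:
    """Insulin-resistance index from fasting glucose and C-peptide."""
    if _missing(glucose) or _missing(c_peptide):
        raise MissingDataError("glucose and C-peptide required for HOMA-IR")
    if glucose <= 0 or c_peptide <= 0:
        raise ValueError("glucose and C-peptide must be > 0")
    f = formula or HomaFormula()
    return f(glucose, c_peptide)


def motivated(item_scores, min_mean: float = 5.0) -> bool:
    """Inclusion rule for the 3-item behavior-change motivation scale
    (7-point Likert): mean score at or above ``min_mean``."""
    scores = list(item_scores)
    if not scores:
        raise ValueError("at least one item score required")
    return sum(scores) / len(scores) >= min_mean


_PANEL_COLUMNS = ("waist", "bmi", "sbp", "dbp", "total_cholesterol", "hdl",
                  "ldl", "triglycerides", "glucose", "c_peptide")

_CONCENTRATIONS = ("total_cholesterol", "hdl", "ldl", "triglycerides",
                   "glucose", "c_peptide")


def harmonize_panel(visits: pd.DataFrame, floor: float = 0.01) -> pd.DataFrame:
    """Impose measurement plausibility on a visit table.

    Concentrations are floored at ``floor`` (an assay detection limit) and
    diastolic pressure is capped just below systolic, so that every row is
    a physically valid panel. Returns a copy.
    """
    out = visits.copy()
    for col in _CONCENTRATIONS:
        if col in out.columns:
            out[col] = out[col].clip(lower=floor)
    if "sbp" in out.columns and "dbp" in out.columns:
        out["dbp"] = np.minimum(out["dbp"], out["sbp"] - 1.0)
    return out


def screen_table(visits: pd.DataFrame,
                 thresholds: RiskThresholds | None = None) -> pd.DataFrame:
    """Screen a participant-visit table.

    Expects columns ``participant_id, week, sex`` plus the metabolic panel;
    returns one row per input row with the five flags, ``n_secondary``,
    ``at_risk`` and ``mets``.
    """
    t = thresholds or RiskThresholds()
    rows = []
    for rec in visits.to_dict("records"):
        m = VisitMeasurement(
            participant_id=str(rec["participant_id"]), week=int(rec["week"]),
            sex=rec["sex"], **{c: rec[c] for c in _PANEL_COLUMNS})
        flags = flag_risk_factors(m, t)
        row = {"participant_id": m.participant_id, "week": m.week}
        row.update(flags.as_dict())
        row["at_risk"] = classify_at_risk(flags, t.at_risk_min_secondary)
        row["mets"] = classify_mets(flags, t.mets_min_secondary)
        rows.append(row)
    return pd.DataFrame(rows)
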