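"""The personal "health space" score.

A continuous, unitless score locating an individual's metabolic biomarker
panel (triglycerides, LDL, HDL, fasting glucose, C-peptide) on an axis
anchored at a metabolic-syndrome reference group (code 1) and a healthy
reference group (code 2). The healthy reference is distilled from a larger
pool by robust rank aggregation (RRA): each biomarker ranks the pool with
the healthiest extreme first, and a subject's rho score is the minimum
beta order-statistic probability of their sorted normalized ranks —
subjects consistently near the top across biomarkers get small rho. The
scoring function itself is a linear mixed-effects regression of the 1/2
class code on the standardized biomarkers, with sex as a random effect
(random intercept and slopes by default) so coefficients may differ by sex.
Scores are not clipped to [1, 2].
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import accuracy_score, cohen_kappa_score
from statsmodels.regression.mixed_linear_model import MixedLM

from .screening import RiskThresholds, flag_risk_factors, classify_mets, VisitMeasurement

__all__ = [
    "FEATURES",
    "HIGHER_IS_HEALTHIER",
    "HealthSpaceModel",
    "normalize_ranks",
    "rra_rho",
    "select_healthy_reference",
    "select_mets_reference",
    "fit_health_space",
    "predict_score",
    "classification_metrics",
]

#: Biomarkers entering the model, in canonical order.
FEATURES: tuple[str, ...] = ("triglycerides", "ldl", "hdl", "glucose", "c_peptide")

#: Which extreme of each biomarker counts as healthiest when ranking.
HIGHER_IS_HEALTHIER: dict[str, bool] = {
    "triglycerides": False,
    "ldl": False,
    "hdl": True,
    "glucose": False,
    "c_peptide": False,
}


def normalize_ranks(values: Sequence[float], higher_is_healthier: bool) -> np.ndarray:
    """Normalized ranks in (0, 1] with the healthiest value ranked first.

    Ranks are position/n; ties share the mean position (scipy 'average').
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty pool")
    if np.isnan(arr).any():
        raise ValueError("missing values in pool")
    key = -arr if higher_is_healthier else arr
    return stats.rankdata(key, method="average") / arr.size


def rra_rho(ranks: Sequence[float]) -> float:
    """Robust-rank-aggregation rho score.

    For sorted normalized ranks r_(1) <= ... <= r_(m), rho is the minimum
    over k of P(Beta(k, m-k+1) <= r_(k)) — the probability that the k-th
    order statistic of m independent uniforms falls at or below r_(k).
    Small rho means the subject sits unusually close to the top across
    the ranked lists.
    """
    r = np.sort(np.asarray(ranks, dtype=float))
    if r.size == 0:
        raise ValueError("at least one rank required")
    if (r <= 0).any() or (r > 1).any():
        raise ValueError("normalized ranks must lie in (0, 1]")
    m = r.size
    k = np.arange(1, m + 1)
    return float(stats.beta.cdf(r, k, m - k + 1).min())


def _rho_per_subject(pool: pd.DataFrame,
                     directions: Mapping[str, bool]) -> pd.Series:
    rank_cols = {f: normalize_ranks(pool[f].to_numpy(), directions[f])
                 for f in directions}
    mat = np.column_stack(list(rank_cols.values()))
    return pd.Series([rra_rho(row) for row in mat], index=pool.index)


def select_healthy_reference(pool: pd.DataFrame,
                             n_top: int = 10,
                             bmi_range: tuple[float, float] = (18.0, 25.0),
                             thresholds: RiskThresholds | None = None,
                             directions: Mapping[str, bool] | None = None) -> pd.DataFrame:
    """Select the healthy reference group from a screened population pool.

    Subjects are filtered to BMI within ``bmi_range`` and no risk-factor
    flags at all; the remaining subjects are ranked on each biomarker
    (healthiest first), aggregated with RRA, and the ``n_top`` smallest
    rho scores are returned (ties broken by subject id).
    """
    directions = dict(directions or HIGHER_IS_HEALTHIER)
    t = thresholds or RiskThresholds()
    eligible_idx = []
    for idx, rec in pool.iterrows():
        if not (bmi_range[0] <= rec["bmi"] <= bmi_range[1]):
            continue
        m = VisitMeasurement(
            participant_id=str(rec.get("subject_id", idx)), week=0, sex=rec["sex"],
            waist=rec["waist"], bmi=rec["bmi"], sbp=rec["sbp"], dbp=rec["dbp"],
            total_cholesterol=rec["total_cholesterol"], hdl=rec["hdl"],
            ldl=rec["ldl"], triglycerides=rec["triglycerides"],
            glucose=rec["glucose"], c_peptide=rec["c_peptide"])
        flags = flag_risk_factors(m, t)
        if flags.waist_excessive or flags.n_secondary > 0:
            continue
        eligible_idx.append(idx)
    eligible = pool.loc[eligible_idx]
    if len(eligible) < n_top:
        raise ValueError(f"only {len(eligible)} eligible subjects, need {n_top}")
    rho = _rho_per_subject(eligible, directions)
    out = eligible.assign(rra_rho=rho)
    key = out["subject_id"] if "subject_id" in out.columns else out.index
    order = np.lexsort((np.asarray(key), out["rra_rho"].to_numpy()))
    return out.iloc[order[:n_top]]


def select_mets_reference(pool: pd.DataFrame,
                          thresholds: RiskThresholds | None = None) -> pd.DataFrame:
    """Subjects meeting the full-syndrome rule (central obesity + >=2
    secondary factors under the configured thresholds)."""
    t = thresholds or RiskThresholds()
    keep = []
    for idx, rec in pool.iterrows():
        m = VisitMeasurement(
            participant_id=str(rec.get("subject_id", idx)), week=0, sex=rec["sex"],
            waist=rec["waist"], bmi=rec["bmi"], sbp=rec["sbp"], dbp=rec["dbp"],
            total_cholesterol=rec["total_cholesterol"], hdl=rec["hdl"],
            ldl=rec["ldl"], triglycerides=rec["triglycerides"],
            glucose=rec["glucose"], c_peptide=rec["c_peptide"])
        if classify_mets(flag_risk_factors(m, t), t.mets_min_secondary):
            keep.append(idx)
    return pool.loc[keep]


@dataclass
class HealthSpaceModel:
    """Fitted health-space scoring function.

    Stores everything needed to project a new individual: per-feature
    standardization (pooled training mean/SD), population fixed-effect
    coefficients, per-sex coefficient adjustments (empty when no random
    effect was estimable), the class coding and the classification
    threshold.
    """

    features: tuple[str, ...]
    means: dict[str, float]
    sds: dict[str, float]
    intercept: float
    coefficients: dict[str, float]
    sex_adjustments: dict[str, dict[str, float]] = field(default_factory=dict)
    class_codes: dict[str, float] = field(default_factory=lambda: {"mets": 1.0, "healthy": 2.0})
    threshold: float = 1.5
    random_structure: str = "intercept_slopes"

    def standardize(self, df: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(
            {f: (df[f] - self.means[f]) / self.sds[f] for f in self.features})

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"features": list(self.features), "means": self.means, "sds": self.sds,
             "intercept": self.intercept, "coefficients": self.coefficients,
             "sex_adjustments": self.sex_adjustments, "class_codes": self.class_codes,
             "threshold": self.threshold, "random_structure": self.random_structure},
            indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "HealthSpaceModel":
        d = json.loads(Path(path).read_text())
        d["features"] = tuple(d["features"])
        return cls(**d)


def fit_health_space(healthy: pd.DataFrame, mets: pd.DataFrame,
                     features: Sequence[str] = FEATURES,
                     random_structure: str = "intercept_slopes",
                     class_codes: Mapping[str, float] | None = None,
                     threshold: float = 1.5) -> HealthSpaceModel:
    """Fit the two-group health-space model.

    The outcome is the class code (MetS = 1, healthy = 2); predictors are
    the biomarkers standardized with pooled training mean/SD; sex enters
    as a random effect (``intercept_slopes`` by default, ``intercept`` or
    ``none`` as alternatives). When only one sex is present the random
    effect is degenerate and the model silently falls back to fixed
    effects only, with a warning.
    """
    if len(healthy) == 0 or len(mets) == 0:
        raise ValueError("both reference groups must be non-empty")
    codes = dict(class_codes or {"mets": 1.0, "healthy": 2.0})
    features = tuple(features)

    train = pd.concat([healthy, mets], ignore_index=True)
    y = np.r_[np.full(len(healthy), codes["healthy"]),
              np.full(len(mets), codes["mets"])]
    means = {f: float(train[f].mean()) for f in features}
    sds = {f: float(train[f].std(ddof=1)) for f in features}
    if any(s <= 0 for s in sds.values()):
        raise ValueError("singular design: a feature has zero variance")
    Xs = np.column_stack([(train[f] - means[f]) / sds[f] for f in features])
    exog = np.column_stack([np.ones(len(train)), Xs])

    sexes = train["sex"].to_numpy()
    structure = random_structure
    if structure != "none" and len(np.unique(sexes)) < 2:
        warnings.warn("only one sex present; sex random effect degenerates "
                      "to fixed effects only")
        structure = "none"

    sex_adjustments: dict[str, dict[str, float]] = {}
    if structure == "none":
        beta, *_ = np.linalg.lstsq(exog, y, rcond=None)
    else:
        exog_re = exog if structure == "intercept_slopes" else np.ones((len(train), 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = MixedLM(y, exog, groups=sexes, exog_re=exog_re).fit(reml=True)
                beta = np.asarray(res.fe_params)
                names = ["intercept"] + list(features)
                for sex, re in res.random_effects.items():
                    vals = np.asarray(re, dtype=float)
                    if structure == "intercept_slopes":
                        sex_adjustments[str(sex)] = dict(zip(names, vals.tolist()))
                    else:
                        sex_adjustments[str(sex)] = {"intercept": float(vals[0])}
            except (np.linalg.LinAlgError, ValueError) as err:  # pragma: no cover
                warnings.warn(f"mixed fit failed ({err}); falling back to "
                              "fixed effects only")
                beta, *_ = np.linalg.lstsq(exog, y, rcond=None)
                structure = "none"

    return HealthSpaceModel(
        features=features, means=means, sds=sds,
        intercept=float(beta[0]),
        coefficients={f: float(b) for f, b in zip(features, beta[1:])},
        sex_adjustments=sex_adjustments, class_codes=codes,
        threshold=threshold, random_structure=structure)


def predict_score(model: HealthSpaceModel, data: pd.DataFrame | Mapping) -> pd.Series:
    """Project individuals into the health space.

    ``data`` needs the model's biomarker columns and (when the model has
    sex-specific adjustments) a ``sex`` column; unknown sexes fall back to
    the population coefficients with a warning. Returns one unclipped
    score per row.
    """
    df = pd.DataFrame([data]) if isinstance(data, Mapping) else data
    Xs = model.standardize(df)
    scores = np.full(len(df), model.intercept, dtype=float)
    for f in model.features:
        scores += model.coefficients[f] * Xs[f].to_numpy()
    if model.sex_adjustments:
        sexes = df["sex"] if "sex" in df.columns else pd.Series([None] * len(df))
        unknown = set()
        for i, sex in enumerate(sexes):
            adj = model.sex_adjustments.get(str(sex))
            if adj is None:
                unknown.add(sex)
                continue
            scores[i] += adj.get("intercept", 0.0)
            for f in model.features:
                scores[i] += adj.get(f, 0.0) * Xs[f].iloc[i]
        if unknown:
            warnings.warn(f"unknown sex values {sorted(map(str, unknown))}; "
                          "used population coefficients")
    return pd.Series(scores, index=df.index, name="health_score")


def classification_metrics(true_healthy, scores, threshold: float = 1.5
                           ) -> tuple[float, float]:
    """Accuracy and Cohen kappa of thresholded scores.

    ``true_healthy`` is boolean (or 0/1) with True = healthy; predicted
    healthy iff score > threshold.
    """
    truth = np.asarray(true_healthy, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if truth.all() or not truth.any():
        raise ValueError("Cohen kappa undefined for single-class truth")
    pred = scores > threshold
    return (float(accuracy_score(truth, pred)),
            float(cohen_kappa_score(truth, pred)))
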