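"""Synthetic cohort generation.

Two generators back every downstream stage without any external data
download:

* :func:`generate_reference_pool` draws cross-sectional subject pools with
  the first and second moments of the published reference-group tables —
  truncated-normal marginals (optionally log-normal for right-skewed
  biomarkers) coupled through a Gaussian copula so that a configurable
  feature correlation (default: HDL vs triglycerides, r = -0.3) is
  respected.
* :func:`generate_intervention_cohort` builds week-0/8/16 longitudinal
  records mirroring the intervention cohort: per-outcome mean trajectories,
  a subject-level random intercept inducing the requested within-subject
  correlation, 7-point Likert items thresholded from a latent normal, and
  a fixed per-subject behavior-change strategy drawn from per-category
  inclusion probabilities. Food-category scores move only for subjects
  whose strategy includes the category (the published category means are
  conditional on inclusion); cohort-level outcomes move for everyone.

Both generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from functools import lru_cache

from .diet import CATEGORIES

__all__ = [
    "FeatureSpec",
    "CohortSpec",
    "OutcomeTrajectory",
    "TrajectorySpec",
    "InterventionCohort",
    "generate_reference_pool",
    "generate_intervention_cohort",
    "write_cohort",
]


@lru_cache(maxsize=256)
def _calibrated_loc(mean: float, sd: float, lower: float, upper: float) -> float:
    """Location parameter such that the truncated normal's realized mean
    equals ``mean`` (plain truncation would bias it toward the far bound)."""
    if not (np.isfinite(lower) or np.isfinite(upper)):
        return mean

    def realized(loc: float) -> float:
        a, b = (lower - loc) / sd, (upper - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd)

    from scipy.optimize import brentq
    lo, hi = mean - 5 * sd, mean + 5 * sd
    if realized(lo) > mean or realized(hi) < mean:  # pragma: no cover
        return mean  # unsatisfiable within the bounds; fall back
    return float(brentq(lambda loc: realized(loc) - mean, lo, hi, xtol=1e-10))


@dataclass(frozen=True)
class FeatureSpec:
    """Marginal distribution of one feature: mean, SD and physiological
    truncation bounds (location calibrated so the truncated mean equals
    ``mean``); ``log_normal`` switches the marginal to a moment-matched
    log-normal for right-skewed biomarkers."""

    mean: float
    sd: float
    lower: float = -np.inf
    upper: float = np.inf
    log_normal: bool = False

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"SD must be >= 0, got {self.sd}")
        if not (self.lower <= self.mean <= self.upper):
            raise ValueError(
                f"truncation bounds [{self.lower}, {self.upper}] must contain "
                f"the mean {self.mean}")

    def ppf(self, u: np.ndarray) -> np.ndarray:
        """Quantile function of the marginal, applied to uniforms."""
        if self.sd == 0:
            return np.full_like(u, self.mean, dtype=float)
        if self.log_normal:
            # moment-matched log-normal, then hard truncation by clipping
            s2 = np.log1p((self.sd / self.mean) ** 2)
            mu = np.log(self.mean) - s2 / 2
            x = stats.lognorm.ppf(u, np.sqrt(s2), scale=np.exp(mu))
            return np.clip(x, self.lower, self.upper)
        loc = _calibrated_loc(self.mean, self.sd, self.lower, self.upper)
        a = (self.lower - loc) / self.sd
        b = (self.upper - loc) / self.sd
        return stats.truncnorm.ppf(u, a, b, loc=loc, scale=self.sd)


@dataclass(frozen=True)
class CohortSpec:
    """Cross-sectional moments of one group (reference pool or the
    intervention cohort baseline)."""

    label: str
    features: Mapping[str, FeatureSpec]
    male_fraction: float = 0.5
    correlations: tuple[tuple[str, str, float], ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.male_fraction <= 1.0):
            raise ValueError("male_fraction must lie in [0, 1]")
        for a, b, r in self.correlations:
            if not (-1.0 < r < 1.0):
                raise ValueError(f"correlation {a}-{b} must lie in (-1, 1)")

    @classmethod
    def from_config(cls, cfg: Mapping, group: str) -> "CohortSpec":
        grp = cfg["reference_groups"][group]
        bounds = cfg.get("truncation_bounds", {})
        feats = {}
        for name, ms in grp["features"].items():
            lo, hi = bounds.get(name, (-np.inf, np.inf))
            feats[name] = FeatureSpec(mean=ms["mean"], sd=ms["sd"],
                                      lower=lo, upper=hi)
        corr = tuple((c["a"], c["b"], c["r"])
                     for c in cfg.get("feature_correlations", []))
        return cls(label=group, features=feats,
                   male_fraction=grp["male_fraction"], correlations=corr)

    def correlation_matrix(self) -> tuple[list[str], np.ndarray]:
        names = list(self.features)
        k = len(names)
        R = np.eye(k)
        idx = {n: i for i, n in enumerate(names)}
        for a, b, r in self.correlations:
            if a in idx and b in idx:
                R[idx[a], idx[b]] = R[idx[b], idx[a]] = r
        return names, R


def generate_reference_pool(spec: CohortSpec, n: int, seed: int) -> pd.DataFrame:
    """Draw ``n`` subjects from ``spec``.

    Gaussian-copula draw: correlated standard normals are mapped through
    the normal CDF to uniforms, then through each feature's truncated
    marginal quantile function. Returns ``subject_id``, ``sex`` and one
    column per feature; reproducible for a fixed seed.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    names, R = spec.correlation_matrix()
    L = np.linalg.cholesky(R)
    z = rng.standard_normal((n, len(names))) @ L.T
    u = stats.norm.cdf(z)
    data = {"subject_id": np.arange(1, n + 1)}
    data["sex"] = np.where(rng.random(n) < spec.male_fraction, "M", "F")
    for j, name in enumerate(names):
        data[name] = spec.features[name].ppf(u[:, j])
    return pd.DataFrame(data)


@dataclass(frozen=True)
class OutcomeTrajectory:
    """Mean trajectory of one longitudinal outcome.

    ``means`` holds the expected value at each week in ``weeks``; ``sd``
    is the total between+within SD at a single visit. ``kind`` is
    ``continuous`` (shift applies to every subject), ``category`` (shift
    applies only to subjects whose strategy includes the category) or
    ``likert`` (latent normal thresholded to the integer 1-7 scale).
    """

    kind: str
    weeks: tuple[int, ...]
    means: tuple[float, ...]
    sd: float

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "category", "likert"):
            raise ValueError(f"unknown outcome kind {self.kind!r}")
        if len(self.weeks) != len(self.means):
            raise ValueError("weeks and means must have equal length")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    def delta(self, week: int) -> float:
        return self.means[self.weeks.index(week)] - self.means[0]


@dataclass(frozen=True)
class TrajectorySpec:
    """Longitudinal design: outcome trajectories, the within-subject
    correlation of repeated measures, per-category strategy-inclusion
    probabilities, and the number of post-baseline dropouts."""

    outcomes: Mapping[str, OutcomeTrajectory]
    within_subject_corr: float = 0.7
    strategy_probabilities: Mapping[str, float] = field(default_factory=dict)
    dropout: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.within_subject_corr < 1.0):
            raise ValueError("within-subject correlation must lie in [0, 1)")
        for cat, p in self.strategy_probabilities.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"inclusion probability for {cat!r} outside [0, 1]")
        if self.dropout < 0:
            raise ValueError("dropout count must be >= 0")

    @classmethod
    def from_config(cls, cfg: Mapping) -> "TrajectorySpec":
        opts = cfg.get("trajectory_options", {})
        outcomes = {}
        for name, row in cfg["study_tables"].items():
            if row["kind"] == "derived":
                continue  # computed by the pipeline, not generated
            outcomes[name] = OutcomeTrajectory(
                kind=row["kind"], weeks=tuple(row["weeks"]),
                means=tuple(row["means"]), sd=row["sd"])
        return cls(outcomes=outcomes,
                   within_subject_corr=opts.get("within_subject_corr", 0.7),
                   strategy_probabilities=dict(cfg.get("strategy_probabilities", {})),
                   dropout=opts.get("dropout", 0))


@dataclass(frozen=True)
class InterventionCohort:
    """Longitudinal visit table plus the fixed per-subject strategies."""

    visits: pd.DataFrame
    strategies: dict[str, tuple[str, ...]]


def _draw_strategies(n: int, probs: Mapping[str, float], rng: np.random.Generator
                     ) -> list[tuple[str, ...]]:
    cats = [c for c in CATEGORIES if c in probs] or list(CATEGORIES)
    out = []
    for _ in range(n):
        chosen = tuple(c for c in cats if rng.random() < probs.get(c, 0.5))
        if not chosen:
            chosen = (max(cats, key=lambda c: (probs.get(c, 0.5), c)),)
        out.append(chosen)
    return out


def generate_intervention_cohort(cohort: CohortSpec, traj: TrajectorySpec,
                                 n: int, seed: int) -> InterventionCohort:
    """Simulate the one-group pretest-posttest cohort.

    Each subject receives baseline demographics from ``cohort`` (sex, age
    and any feature not tracked longitudinally), a fixed strategy, and for
    every outcome a subject random intercept b_i ~ N(0, rho * sd^2) plus
    visit noise e ~ N(0, (1 - rho) * sd^2), so repeated measures correlate
    at ``rho`` and the single-visit variance is sd^2. Dropouts keep only
    their week-0 row.
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    rng = np.random.default_rng(seed)
    ids = [f"P{i:03d}" for i in range(1, n + 1)]
    sex = np.where(rng.random(n) < cohort.male_fraction, "M", "F")

    # baseline-only features (e.g. age): anything in the cohort spec that
    # is not generated longitudinally
    static = {name: fs.ppf(stats.norm.cdf(rng.standard_normal(n)))
              for name, fs in cohort.features.items()
              if name not in traj.outcomes}

    strategies = dict(zip(ids, _draw_strategies(n, traj.strategy_probabilities, rng)))
    rho = traj.within_subject_corr
    all_weeks = sorted({w for o in traj.outcomes.values() for w in o.weeks})

    frame = {
        "participant_id": np.repeat(ids, len(all_weeks)),
        "sex": np.repeat(sex, len(all_weeks)),
        "week": np.tile(all_weeks, n),
    }
    for name, vals in static.items():
        frame[name] = np.repeat(vals, len(all_weeks))
    df = pd.DataFrame(frame)

    for name, out in traj.outcomes.items():
        sd_b = out.sd * np.sqrt(rho)
        sd_e = out.sd * np.sqrt(1.0 - rho)
        b = rng.normal(0.0, sd_b, n) if sd_b > 0 else np.zeros(n)
        col = np.full(len(df), np.nan)
        for wi, week in enumerate(all_weeks):
            if week not in out.weeks:
                continue
            shift = out.delta(week)
            if out.kind == "category" and shift != 0.0:
                included = np.array([name in strategies[i] for i in ids])
                mean_w = out.means[0] + shift * included
            else:
                mean_w = np.full(n, out.means[0] + shift)
            e = rng.normal(0.0, sd_e, n) if sd_e > 0 else np.zeros(n)
            col[wi::len(all_weeks)] = mean_w + b + e
        if out.kind == "likert":
            observed = np.clip(np.round(col), 1, 7)
            observed[np.isnan(col)] = np.nan
            col = observed
        df[name] = col

    if traj.dropout > 0:
        dropped = list(rng.choice(ids, size=min(traj.dropout, n), replace=False))
        df = df[~(df["participant_id"].isin(dropped) & (df["week"] > 0))]
        df = df.reset_index(drop=True)

    return InterventionCohort(visits=df, strategies=strategies)


def write_cohort(cohort: InterventionCohort, out_dir: str | Path,
                 spec_info: Mapping | None = None, seed: int | None = None) -> None:
    """Write the visit table as CSV plus a JSON sidecar with strategies,
    the generating spec summary and the seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.visits.to_csv(out / "visits.csv", index=False)
    sidecar = {"seed": seed,
               "strategies": {k: list(v) for k, v in cohort.strategies.items()}}
    if spec_info is not None:
        sidecar["spec"] = dict(spec_info)
    (out / "cohort.json").write_text(json.dumps(sidecar, indent=2))
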