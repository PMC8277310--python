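"""Longitudinal evaluation statistics.

The study design is one-group pretest-posttest: every outcome is measured
at weeks 0, 8 and 16 (Likert items at 0 and 16) and evaluated with a
linear mixed model — time as a categorical fixed effect, subject as a
random intercept, maximum likelihood estimation, the overall time effect
tested by a likelihood-ratio test. Observations with an absolute residual
above three times the model RMSE are flagged as statistical outliers and
the model is refitted once without them. Pairwise timepoint contrasts are
Wald tests, Benjamini-Hochberg-adjusted within outcome. Self-perceived
health items (7-point Likert) use a cumulative-link (proportional-odds)
mixed model with a subject random intercept, integrated by Gauss-Hermite
quadrature. Per-category analyses subset to participants whose
behavior-change strategy includes the category.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.power import TTestPower

__all__ = [
    "Contrast",
    "TimeEffectResult",
    "fit_time_mixed_model",
    "flag_outliers",
    "bh_adjust",
    "OrdinalTimeResult",
    "fit_ordinal_mixed",
    "delta_correlations",
    "correlation_table",
    "subset_by_strategy",
    "required_sample_size",
]


@dataclass(frozen=True)
class Contrast:
    week_a: int
    week_b: int
    estimate: float  # mean(week_b) - mean(week_a)
    p_raw: float
    p_adj: float


@dataclass(frozen=True)
class TimeEffectResult:
    """Fitted time-effect summary for one outcome."""

    outcome: str
    weeks: tuple[int, ...]
    emmeans: Mapping[int, float]
    overall_p: float
    contrasts: tuple[Contrast, ...]
    outlier_ids: tuple[int, ...]  # positional index into the input frame
    rmse: float
    n_subjects: int
    n_obs: int
    residuals: pd.Series | None = None

    def contrast(self, week_a: int, week_b: int) -> Contrast:
        for c in self.contrasts:
            if (c.week_a, c.week_b) == (week_a, week_b):
                return c
        raise KeyError(f"no contrast {week_a} vs {week_b}")


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr
    if (arr < 0).any() or (arr > 1).any() or np.isnan(arr).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def _mixed_fit(df: pd.DataFrame, weeks: list[int]):
    """ML fit of value ~ C(week) with subject random intercept; returns
    (result_full, result_null, exog columns order)."""
    y = df["value"].to_numpy(dtype=float)
    groups = df["participant_id"].to_numpy()
    exog = np.column_stack(
        [np.ones(len(df))] + [(df["week"] == w).to_numpy(float) for w in weeks[1:]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = MixedLM(y, exog, groups=groups).fit(reml=False)
        null = MixedLM(y, np.ones((len(df), 1)), groups=groups).fit(reml=False)
    return full, null


def fit_time_mixed_model(data: pd.DataFrame, outcome: str = "",
                         remove_outliers: bool = True,
                         outlier_sd_multiple: float = 3.0) -> TimeEffectResult:
    """Fit the study's time-effect model for one outcome.

    ``data`` needs columns ``participant_id``, ``week`` and ``value``
    (missing values dropped). Time is categorical with the earliest week
    as reference; the overall time effect is a likelihood-ratio test of
    the ML fits with and without the time dummies. When
    ``remove_outliers`` is set, observations with |residual| > 3 x RMSE
    are removed and the model refitted once (single pass).
    """
    df = data.dropna(subset=["value"]).reset_index(drop=True)
    weeks = sorted(df["week"].unique())
    if len(weeks) < 2:
        raise ValueError("at least two timepoints required")
    if df["participant_id"].nunique() < 2:
        raise ValueError("at least two subjects required")
    if np.ptp(df["value"].to_numpy(dtype=float)) == 0:
        raise ValueError("outcome is constant; time-effect model is degenerate")

    full, null = _mixed_fit(df, weeks)
    resid = np.asarray(full.resid, dtype=float)
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    outliers: tuple[int, ...] = ()
    if remove_outliers and rmse > 0:
        mask = np.abs(resid) > outlier_sd_multiple * rmse
        if mask.any():
            outliers = tuple(int(i) for i in np.flatnonzero(mask))
            df = df.loc[~mask].reset_index(drop=True)
            weeks = sorted(df["week"].unique())
            full, null = _mixed_fit(df, weeks)
            resid = np.asarray(full.resid, dtype=float)
            rmse = float(np.sqrt(np.mean(resid ** 2)))

    lr = 2.0 * (full.llf - null.llf)
    overall_p = float(stats.chi2.sf(max(lr, 0.0), df=len(weeks) - 1))

    k = len(weeks)
    beta = np.asarray(full.fe_params, dtype=float)
    cov = np.asarray(full.cov_params())[:k, :k]
    emmeans = {weeks[0]: float(beta[0])}
    for j, w in enumerate(weeks[1:], start=1):
        emmeans[w] = float(beta[0] + beta[j])

    # pairwise Wald contrasts; week dummy j corresponds to weeks[j]
    contrasts = []
    raw_ps = []
    pairs = list(combinations(range(k), 2))
    for i, j in pairs:
        vec = np.zeros(k)
        if i > 0:
            vec[i] = -1.0
        if j > 0:
            vec[j] = 1.0
        est = float(vec @ beta)
        se = float(np.sqrt(vec @ cov @ vec))
        p = 2.0 * stats.norm.sf(abs(est) / se) if se > 0 else 1.0
        contrasts.append((weeks[i], weeks[j], est))
        raw_ps.append(p)
    adj = bh_adjust(raw_ps)
    contrast_objs = tuple(
        Contrast(a, b, est, float(p), float(q))
        for (a, b, est), p, q in zip(contrasts, raw_ps, adj))

    return TimeEffectResult(
        outcome=outcome, weeks=tuple(weeks), emmeans=emmeans,
        overall_p=overall_p, contrasts=contrast_objs, outlier_ids=outliers,
        rmse=rmse, n_subjects=int(df["participant_id"].nunique()),
        n_obs=len(df), residuals=pd.Series(resid))


def flag_outliers(residuals: Sequence[float], rmse: float | None = None,
                  multiple: float = 3.0) -> np.ndarray:
    """Positions whose |residual| strictly exceeds ``multiple`` x RMSE."""
    r = np.asarray(residuals, dtype=float)
    if rmse is None:
        rmse = float(np.sqrt(np.mean(r ** 2)))
    return np.flatnonzero(np.abs(r) > multiple * rmse)


# --------------------------------------------------------------------------
# Cumulative-link mixed model for Likert outcomes


@dataclass(frozen=True)
class OrdinalTimeResult:
    outcome: str
    weeks: tuple[int, ...]
    coefficients: Mapping[int, float]  # latent shift per non-reference week
    overall_p: float
    thresholds: tuple[float, ...]
    sigma: float  # random-intercept SD on the latent scale
    n_subjects: int
    n_obs: int


def _clmm_loglik(params: np.ndarray, y: np.ndarray, X: np.ndarray,
                 subj_idx: np.ndarray, n_subj: int, n_levels: int,
                 nodes: np.ndarray, weights: np.ndarray,
                 random: bool) -> float:
    n_thresh = n_levels - 1
    theta = np.empty(n_thresh)
    theta[0] = params[0]
    if n_thresh > 1:
        theta[1:] = params[0] + np.cumsum(np.exp(params[1:n_thresh]))
    beta = params[n_thresh:n_thresh + X.shape[1]]
    sigma = np.exp(params[-1]) if random else 0.0

    eta = X @ beta
    pad = np.concatenate(([-np.inf], theta, [np.inf]))
    if not random:
        p = stats.logistic.cdf(pad[y + 1] - eta) - stats.logistic.cdf(pad[y] - eta)
        return float(np.sum(np.log(np.clip(p, 1e-300, None))))
    # Gauss-Hermite: b = sqrt(2) * sigma * node
    b_vals = np.sqrt(2.0) * sigma * nodes
    log_w = np.log(weights / np.sqrt(np.pi))
    per_subj = np.zeros((n_subj, nodes.size))
    for q, b in enumerate(b_vals):
        p = (stats.logistic.cdf(pad[y + 1] - eta - b)
             - stats.logistic.cdf(pad[y] - eta - b))
        logp = np.log(np.clip(p, 1e-300, None))
        per_subj[:, q] = np.bincount(subj_idx, weights=logp, minlength=n_subj)
    m = per_subj.max(axis=1, keepdims=True)
    ll = m[:, 0] + np.log(np.exp(per_subj - m) @ np.exp(log_w))
    return float(ll.sum())


def _fit_clmm(y, X, subj_idx, n_subj, n_levels, nodes, weights, random):
    n_thresh = n_levels - 1
    # start: marginal cumulative logits, zero slopes, sigma = 1
    cum = np.cumsum(np.bincount(y, minlength=n_levels))[:-1] / y.size
    theta0 = stats.logistic.ppf(np.clip(cum, 1e-3, 1 - 1e-3))
    start = [theta0[0]]
    if n_thresh > 1:
        start += list(np.log(np.clip(np.diff(theta0), 1e-2, None)))
    start += [0.0] * X.shape[1]
    start += [0.0]  # log sigma (ignored when random=False)
    start = np.asarray(start)

    def nll(p):
        return -_clmm_loglik(p, y, X, subj_idx, n_subj, n_levels,
                             nodes, weights, random)

    res = optimize.minimize(nll, start, method="BFGS",
                            options={"maxiter": 500, "gtol": 1e-6})
    return res


def fit_ordinal_mixed(data: pd.DataFrame, outcome: str = "",
                      n_quadrature: int = 15,
                      random_intercept: bool = True) -> OrdinalTimeResult:
    """Cumulative-link (proportional-odds) mixed model for a Likert outcome.

    ``data`` needs ``participant_id``, ``week`` and integer ``value``.
    Time is a categorical fixed effect on the latent scale, subject a
    random intercept integrated with Gauss-Hermite quadrature; the overall
    time effect is a likelihood-ratio test. Response levels with zero
    observations are collapsed (with a warning). A constant response
    raises, as the thresholds are then unidentifiable.
    """
    df = data.dropna(subset=["value"]).reset_index(drop=True)
    weeks = sorted(df["week"].unique())
    if len(weeks) < 2:
        raise ValueError("at least two timepoints required")
    values = df["value"].to_numpy()
    levels = np.unique(values)
    if levels.size < 2:
        raise ValueError("all responses identical; ordinal model is degenerate")
    if levels.size < len(np.arange(values.min(), values.max() + 1)):
        warnings.warn("response levels with zero observations collapsed")
    y = np.searchsorted(levels, values)

    subj_codes, subj_idx = np.unique(df["participant_id"], return_inverse=True)
    X = np.column_stack([(df["week"] == w).to_numpy(float) for w in weeks[1:]])
    nodes, weights = np.polynomial.hermite.hermgauss(n_quadrature)

    full = _fit_clmm(y, X, subj_idx, subj_codes.size, levels.size,
                     nodes, weights, random_intercept)
    null = _fit_clmm(y, np.zeros((len(df), 0)), subj_idx, subj_codes.size,
                     levels.size, nodes, weights, random_intercept)
    lr = 2.0 * (-full.fun + null.fun)
    overall_p = float(stats.chi2.sf(max(lr, 0.0), df=len(weeks) - 1))

    n_thresh = levels.size - 1
    theta = np.empty(n_thresh)
    theta[0] = full.x[0]
    if n_thresh > 1:
        theta[1:] = full.x[0] + np.cumsum(np.exp(full.x[1:n_thresh]))
    beta = full.x[n_thresh:n_thresh + X.shape[1]]
    sigma = float(np.exp(full.x[-1])) if random_intercept else 0.0
    return OrdinalTimeResult(
        outcome=outcome, weeks=tuple(weeks),
        coefficients={w: float(b) for w, b in zip(weeks[1:], beta)},
        overall_p=overall_p, thresholds=tuple(theta), sigma=sigma,
        n_subjects=int(subj_codes.size), n_obs=len(df))


# --------------------------------------------------------------------------
# Delta correlations and strategy subsetting


def delta_correlations(deltas_a: Sequence[float], deltas_b: Sequence[float]
                       ) -> tuple[float, float]:
    """Pearson correlation (rho, two-sided p) between paired per-subject
    change scores."""
    a = np.asarray(deltas_a, dtype=float)
    b = np.asarray(deltas_b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired vectors must have equal length")
    if a.size < 3:
        raise ValueError("at least three subjects required")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in a change-score vector")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def correlation_table(deltas: pd.DataFrame, cols_a: Sequence[str],
                      cols_b: Sequence[str], alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise delta correlations with an influence diagnostic.

    For each pair the most influential subject (whose removal changes rho
    the most) is dropped and the correlation recomputed; a significant
    correlation whose significance vanishes without that subject is
    flagged ``fragile`` — a scatterplot-confirmation step made explicit.
    """
    rows = []
    for ca in cols_a:
        for cb in cols_b:
            if ca == cb:
                continue
            sub = deltas[[ca, cb]].dropna()
            a, b = sub[ca].to_numpy(), sub[cb].to_numpy()
            try:
                r, p = delta_correlations(a, b)
            except ValueError:
                continue
            drop_r = np.array([stats.pearsonr(np.delete(a, i), np.delete(b, i))[0]
                               for i in range(a.size)])
            infl = int(np.argmax(np.abs(drop_r - r)))
            r2, p2 = stats.pearsonr(np.delete(a, infl), np.delete(b, infl))
            rows.append({"var_a": ca, "var_b": cb, "n": a.size, "rho": r,
                         "p": p, "rho_drop1": float(r2), "p_drop1": float(p2),
                         "fragile": bool(p < alpha <= p2)})
    return pd.DataFrame(rows)


def subset_by_strategy(records: pd.DataFrame,
                       strategies: Mapping[str, Sequence[str]],
                       category: str) -> pd.DataFrame:
    """Rows of participants whose behavior-change strategy includes
    ``category`` (per-category analyses use only these subjects)."""
    keep = {pid for pid, cats in strategies.items() if category in cats}
    return records[records["participant_id"].isin(keep)]


def required_sample_size(delta: float, sd: float, alpha: float = 0.05,
                         power: float = 0.8, alternative: str = "two-sided") -> int:
    """Paired-t sample size for a mean change ``delta`` with change-score
    SD ``sd`` (documented utility; the power level the study assumed for
    its own calculation is unstated)."""
    if sd <= 0:
        raise ValueError("sd must be > 0")
    n = TTestPower().solve_power(effect_size=abs(delta) / sd, alpha=alpha,
                                 power=power, alternative=alternative)
    return int(np.ceil(n))
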