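"""Stage-1 automated personalized dietary advice.

Two evaluation passes compose the advice plan. First, each of the eight
food categories is checked for sufficiency: a DHDI category score below its
cut-off (default 8 of 10) triggers the category, and a blood carotenoid
level below its cut-off (default 1.0 µmol/L) triggers fruit and vegetables
as the biomarker of their intake. Second, present metabolic abnormalities
add categories to emphasize: each risk flag maps to a configurable set of
food categories. Every plan entry carries machine-readable reason tags so a
plan can be audited and regenerated from its logged triggers. Stage 2
(the dietitian consultation) is modeled only as selection of a non-empty
subset of the plan — the participant's behavior-change strategy.

The shipped cut-offs and flag-to-category map are explicit assumptions
(the study's own values are unpublished); results depending on them are
config-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .diet import CATEGORIES, DietProfile
from .screening import RiskFlags

__all__ = [
    "AdviceRuleSet",
    "Reason",
    "AdvicePlan",
    "BehaviorStrategy",
    "evaluate_diet_sufficiency",
    "map_metabolic_abnormalities",
    "compose_advice",
    "select_strategy",
]

DEFAULT_FLAG_MAP: dict[str, tuple[str, ...]] = {
    "tg_high": ("fish", "sugar_beverages", "oils_and_fats"),
    "hdl_low": ("fish", "nuts", "oils_and_fats"),
    "glucose_high": ("wholegrain", "sugar_beverages"),
    "bp_high": ("vegetables", "dairy"),
    "waist_excessive": ("sugar_beverages", "oils_and_fats", "nuts"),
}


@dataclass(frozen=True)
class AdviceRuleSet:
    dhdi_cutoffs: Mapping[str, float] = field(
        default_factory=lambda: {c: 8.0 for c in CATEGORIES})
    carotenoid_cutoff: float = 1.0  # µmol/L, applies to fruit and vegetables
    flag_map: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_FLAG_MAP))
    max_categories: int | None = None

    def __post_init__(self) -> None:
        for cat, cut in self.dhdi_cutoffs.items():
            if cat not in CATEGORIES:
                raise ValueError(f"unknown category {cat!r} in cut-offs")
            if not (1.0 <= cut <= 10.0):
                raise ValueError(f"cut-off for {cat!r} outside score range [1, 10]")
        for flag, cats in self.flag_map.items():
            bad = set(cats) - set(CATEGORIES)
            if bad:
                raise ValueError(f"flag {flag!r} maps to unknown categories {sorted(bad)}")

    @classmethod
    def from_config(cls, cfg: Mapping) -> "AdviceRuleSet":
        a = cfg["advice"]
        return cls(
            dhdi_cutoffs=dict(a["dhdi_cutoffs"]),
            carotenoid_cutoff=a["carotenoid_cutoff_umol_l"],
            flag_map={k: tuple(v) for k, v in a["flag_map"].items()},
            max_categories=a.get("max_categories"))


@dataclass(frozen=True)
class Reason:
    """Why a category entered the plan: the rule kind, the trigger name
    (score/biomarker/flag) and the value that fired it."""

    kind: str  # insufficient-diet-score | insufficient-biomarker | metabolic-emphasis
    trigger: str
    value: float | bool

    def as_dict(self) -> dict:
        return {"kind": self.kind, "trigger": self.trigger, "value": self.value}


@dataclass(frozen=True)
class AdvicePlan:
    """Ordered advised categories with their reasons (canonical category
    order; no duplicates; every entry has at least one reason)."""

    entries: tuple[tuple[str, tuple[Reason, ...]], ...]

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(cat for cat, _ in self.entries)

    def as_dict(self) -> dict:
        return {cat: [r.as_dict() for r in reasons] for cat, reasons in self.entries}


@dataclass(frozen=True)
class BehaviorStrategy:
    participant_id: str
    categories: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.categories:
            raise ValueError("strategy must contain at least one category")


def evaluate_diet_sufficiency(profile: DietProfile,
                              rules: AdviceRuleSet | None = None
                              ) -> dict[str, list[Reason]]:
    """Categories with insufficient intake or nutrient status.

    A category is insufficient when its DHDI score falls below its cut-off;
    fruit and vegetables are additionally insufficient when blood
    carotenoids (if measured) fall below the biomarker cut-off.
    """
    rules = rules or AdviceRuleSet()
    out: dict[str, list[Reason]] = {}
    for cat in CATEGORIES:
        score = profile.scores[cat]
        if score < rules.dhdi_cutoffs[cat]:
            out.setdefault(cat, []).append(
                Reason("insufficient-diet-score", f"dhdi_{cat}", score))
    if profile.carotenoids is not None and profile.carotenoids < rules.carotenoid_cutoff:
        for cat in ("fruit", "vegetables"):
            out.setdefault(cat, []).append(
                Reason("insufficient-biomarker", "carotenoids", profile.carotenoids))
    return out


def map_metabolic_abnormalities(flags: RiskFlags,
                                rules: AdviceRuleSet | None = None
                                ) -> dict[str, list[Reason]]:
    """Categories emphasized because of present metabolic abnormalities."""
    rules = rules or AdviceRuleSet()
    out: dict[str, list[Reason]] = {}
    for flag_name in ("tg_high", "hdl_low", "bp_high", "glucose_high",
                      "waist_excessive"):
        if not getattr(flags, flag_name):
            continue
        if flag_name not in rules.flag_map:
            raise KeyError(f"flag {flag_name!r} missing from the advice flag map")
        for cat in rules.flag_map[flag_name]:
            out.setdefault(cat, []).append(
                Reason("metabolic-emphasis", flag_name, True))
    return out


def compose_advice(diet_insufficient: Mapping[str, Sequence[Reason]],
                   metabolic_emphasis: Mapping[str, Sequence[Reason]],
                   rules: AdviceRuleSet | None = None) -> AdvicePlan:
    """Union of both passes, reasons merged per category, in canonical
    category order. ``max_categories`` (when set) truncates in that order."""
    rules = rules or AdviceRuleSet()
    entries = []
    for cat in CATEGORIES:
        reasons = tuple(diet_insufficient.get(cat, ())) + tuple(
            metabolic_emphasis.get(cat, ()))
        if reasons:
            entries.append((cat, reasons))
    if rules.max_categories is not None:
        entries = entries[: rules.max_categories]
    return AdvicePlan(entries=tuple(entries))


def select_strategy(plan: AdvicePlan,
                    participant_id: str = "",
                    chosen: Sequence[str] | None = None,
                    probabilities: Mapping[str, float] | None = None,
                    seed: int | None = None) -> BehaviorStrategy:
    """Stage-2 proxy: pick a non-empty subset of the advised categories.

    Either an explicit ``chosen`` subset (participant preference) or
    per-category inclusion ``probabilities`` with a seed. A probabilistic
    draw that comes up empty keeps the advised category with the highest
    inclusion probability, so the strategy is never empty.
    """
    if not plan.categories:
        raise ValueError("cannot select a strategy from an empty plan")
    if chosen is not None:
        bad = set(chosen) - set(plan.categories)
        if bad:
            raise ValueError(f"chosen categories not in plan: {sorted(bad)}")
        cats = tuple(c for c in plan.categories if c in set(chosen))
        return BehaviorStrategy(participant_id, cats)
    probabilities = probabilities or {}
    rng = np.random.default_rng(seed)
    draws = rng.random(len(plan.categories))
    cats = tuple(c for c, u in zip(plan.categories, draws)
                 if u < probabilities.get(c, 0.5))
    if not cats:
        best = max(plan.categories, key=lambda c: (probabilities.get(c, 0.5), c))
        cats = (best,)
    return BehaviorStrategy(participant_id, cats)
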