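"""Diet-quality (DHDI) scoring.

The Dutch Healthy Diet Index scores adherence to the Dutch dietary
guidelines per food category on a 1-10 scale; the total over the eight
categories used here spans 8-80. The pipeline's canonical input is the
per-category score itself (the FFQ instrument that produces it is
external); :func:`score_component` is a convenience for turning synthetic
intake amounts into guideline-style scores. Blood carotenoids (µmol/L)
ride along as an independent fruit/vegetable-intake biomarker.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

__all__ = [
    "CATEGORIES",
    "DietProfile",
    "DietDelta",
    "total_dhdi",
    "score_component",
    "diet_delta",
]

#: The eight DHDI food categories, in canonical order.
CATEGORIES: tuple[str, ...] = (
    "vegetables",
    "fruit",
    "oils_and_fats",
    "fish",
    "wholegrain",
    "dairy",
    "nuts",
    "sugar_beverages",
)

SCORE_MIN, SCORE_MAX = 1.0, 10.0


def _check_scores(scores: Mapping[str, float]) -> dict[str, float]:
    missing = set(CATEGORIES) - set(scores)
    extra = set(scores) - set(CATEGORIES)
    if missing or extra:
        raise ValueError(f"expected exactly the 8 DHDI categories; "
                         f"missing={sorted(missing)} unexpected={sorted(extra)}")
    for cat in CATEGORIES:
        s = scores[cat]
        if not (SCORE_MIN <= s <= SCORE_MAX):
            raise ValueError(f"category {cat!r} score {s} outside [1, 10]")
    return {cat: float(scores[cat]) for cat in CATEGORIES}


def total_dhdi(scores: Mapping[str, float]) -> float:
    """Sum of the 8 category scores (range 8-80)."""
    return sum(_check_scores(scores).values())


@dataclass(frozen=True)
class DietProfile:
    """Per-category DHDI scores plus the optional carotenoid biomarker."""

    scores: Mapping[str, float]
    carotenoids: float | None = None  # µmol/L

    def __post_init__(self) -> None:
        object.__setattr__(self, "scores", _check_scores(self.scores))

    @property
    def total(self) -> float:
        return sum(self.scores.values())


@dataclass(frozen=True)
class DietDelta:
    """Signed category and total differences between two visits."""

    categories: Mapping[str, float]
    total: float
    carotenoids: float | None = None


def score_component(intake: float, lower: float, upper: float,
                    direction: str = "adequacy") -> float:
    """Map an intake amount onto a 1-10 guideline-adherence score.

    ``adequacy`` components score 1 at/below the lower guideline bound and
    10 at/above the upper, linearly in between; ``moderation`` components
    are mirrored (10 at/below lower, 1 at/above upper).
    """
    if upper <= lower:
        raise ValueError(f"upper bound ({upper}) must exceed lower ({lower})")
    if direction not in ("adequacy", "moderation"):
        raise ValueError(f"unknown direction {direction!r}")
    frac = (intake - lower) / (upper - lower)
    frac = min(1.0, max(0.0, frac))
    if direction == "moderation":
        frac = 1.0 - frac
    return SCORE_MIN + frac * (SCORE_MAX - SCORE_MIN)


def diet_delta(p0: DietProfile, p1: DietProfile) -> DietDelta:
    """Change from ``p0`` to ``p1`` (later minus earlier), per category,
    total, and carotenoids when present at both visits."""
    cats = {cat: p1.scores[cat] - p0.scores[cat] for cat in CATEGORIES}
    caro = None
    if p0.carotenoids is not None and p1.carotenoids is not None:
        caro = p1.carotenoids - p0.carotenoids
    return DietDelta(categories=cats, total=p1.total - p0.total, carotenoids=caro)
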