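"""Adapted Fried frailty phenotype: five criteria, a 0–5 score, a category.

The five clinical criteria (unintentional weight loss, exhaustion, low
physical activity, low grip strength, slow walking speed) enter as
already-adjudicated booleans; their clinical operationalization (cutoffs
by sex, BMI, …) happens upstream of this package.  The score is the
count of positive criteria; 0 positives is robust (R), 1–2 pre-frail
(P), 3 or more frail (F).
"""

from __future__ import annotations

from dataclasses import dataclass, fields

from .errors import ValidationError

CRITERIA = (
    "weight_loss",
    "exhaustion",
    "low_physical_activity",
    "low_grip_strength",
    "slow_walking_speed",
)

CATEGORIES = ("R", "P", "F")


@dataclass(frozen=True)
class FriedCriteria:
    """Outcome of the five adapted Fried criteria (True = criterion failed)."""

    weight_loss: bool
    exhaustion: bool
    low_physical_activity: bool
    low_grip_strength: bool
    slow_walking_speed: bool

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v is None or not isinstance(v, (bool, int)) or v not in (0, 1):
                raise ValidationError(
                    f"criterion {f.name!r} must be a 0/1 boolean, got {v!r}"
                )


@dataclass(frozen=True)
class FrailtyAssessment:
    """Score (0–5) and category (R/P/F) of one participant."""

    score: int
    category: str

    def __post_init__(self) -> None:
        if categorize(self.score) != self.category:
            raise ValidationError(
                f"category {self.category!r} inconsistent with score {self.score}"
            )


def score(criteria: FriedCriteria) -> int:
    """Number of positive criteria, 0–5."""
    return int(sum(bool(getattr(criteria, name)) for name in CRITERIA))


def categorize(value: int) -> str:
    """Map a 0–5 score to R (0), P (1–2), or F (3–5)."""
    if not isinstance(value, (int,)) or isinstance(value, bool):
        raise ValidationError(f"score must be an integer, got {value!r}")
    if not 0 <= value <= 5:
        raise ValidationError(f"score must be in 0..5, got {value}")
    if value == 0:
        return "R"
    if value <= 2:
        return "P"
    return "F"


def assess(criteria: FriedCriteria) -> FrailtyAssessment:
    """Score and categorize in one step."""
    s = score(criteria)
    return FrailtyAssessment(score=s, category=categorize(s))
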