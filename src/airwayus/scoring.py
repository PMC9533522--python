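"""Dichotomization rules and the 0-3 multiparameter ultrasound score.

The composite score awards one point for each of three sonographic signs of
a difficult airway: a thick tongue (midsagittal thickness > 61 mm), restricted
mandibular condylar translation (<= 10 mm between closed and maximally open
mouth), and a short hyomental distance (<= 51 mm).  Three conventional bedside
tests (modified Mallampati grade > 2, thyromental distance < 65 mm, mouth
opening < 30 mm) are encoded with the same rule machinery so every predictor
can be dichotomized and ranked uniformly.

All lengths are millimetres; the Mallampati grade is an ordinal 1-4.
Boundary values are resolved by the comparator exactly as written --
no rounding happens before a comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

__all__ = [
    "Comparator",
    "CutoffRule",
    "IndicatorPanel",
    "UltrasoundScore",
    "DEFAULT_RULES",
    "ULTRASOUND_VARIABLES",
    "CONVENTIONAL_VARIABLES",
    "HIGHER_IS_DIFFICULT",
    "apply_cutoff",
    "score_record",
    "score_values",
    "classify_positive",
]


class Comparator:
    """Admissible comparison operators for a cutoff rule."""

    GREATER_THAN = "greater_than"
    LESS_OR_EQUAL = "less_or_equal"
    LESS_THAN = "less_than"

    ALL = frozenset({GREATER_THAN, LESS_OR_EQUAL, LESS_THAN})


@dataclass(frozen=True)
class CutoffRule:
    """A single dichotomization rule: ``value <comparator> threshold`` flags difficulty.

    Parameters
    ----------
    variable
        Field name of the measurement the rule applies to.
    threshold
        Cut point, in mm for distances and in grade units for Mallampati.
    comparator
        One of :class:`Comparator`; strictness follows the clinical definition
        of each test and is never altered by rounding.
    description
        Human-readable form used in report tables.
    """

    variable: str
    threshold: float
    comparator: str
    description: str = ""

    def __post_init__(self) -> None:
        if self.comparator not in Comparator.ALL:
            raise ValueError(f"unknown comparator: {self.comparator!r}")
        if not (self.threshold > 0):
            raise ValueError("threshold must be positive")

    def __call__(self, value: float) -> bool:
        return apply_cutoff(value, self)


#: Positive direction of each predictor for ranking purposes.  ``True`` means
#: larger values indicate a more difficult airway (tongue thickness,
#: Mallampati grade, composite score); ``False`` means smaller values do
#: (mobility and distance measures).
HIGHER_IS_DIFFICULT: Mapping[str, bool] = {
    "tongue_thickness": True,
    "condylar_mobility": False,
    "hyomental": False,
    "mallampati": True,
    "thyromental": False,
    "mouth_opening": False,
    "score": True,
}

ULTRASOUND_VARIABLES = ("condylar_mobility", "hyomental", "tongue_thickness")
CONVENTIONAL_VARIABLES = ("mallampati", "thyromental", "mouth_opening")

DEFAULT_RULES: Mapping[str, CutoffRule] = {
    "tongue_thickness": CutoffRule(
        "tongue_thickness", 61.0, Comparator.GREATER_THAN, "Tongue thickness (> 61 mm)"
    ),
    "condylar_mobility": CutoffRule(
        "condylar_mobility", 10.0, Comparator.LESS_OR_EQUAL,
        "Mandibular condylar mobility (<= 10 mm)",
    ),
    "hyomental": CutoffRule(
        "hyomental", 51.0, Comparator.LESS_OR_EQUAL, "Hyomental distance (<= 51 mm)"
    ),
    "mallampati": CutoffRule(
        "mallampati", 2.0, Comparator.GREATER_THAN, "Modified Mallampati tests (> 2)"
    ),
    "thyromental": CutoffRule(
        "thyromental", 65.0, Comparator.LESS_THAN, "Thyromental distance (< 6.5 cm)"
    ),
    "mouth_opening": CutoffRule(
        "mouth_opening", 30.0, Comparator.LESS_THAN, "Mouth opening (< 3 cm)"
    ),
}


@dataclass(frozen=True)
class IndicatorPanel:
    """Boolean outcome of every dichotomization rule for one patient."""

    tongue_positive: bool
    condylar_positive: bool
    hyomental_positive: bool
    mallampati_positive: bool
    thyromental_positive: bool
    mouth_positive: bool


@dataclass(frozen=True)
class UltrasoundScore:
    """The 0-3 composite: one point per positive ultrasound indicator."""

    points: int

    def __post_init__(self) -> None:
        if self.points not in (0, 1, 2, 3):
            raise ValueError("score must be an integer in {0,1,2,3}")


def apply_cutoff(value: float, rule: CutoffRule) -> bool:
    """Apply one rule to one measurement.

    Comparisons are exact: 61.0 is not ``> 61``, 10.0 is ``<= 10``,
    30.0 is not ``< 30``.
    """
    if not math.isfinite(value):
        raise ValueError(f"non-finite value for {rule.variable}: {value!r}")
    if rule.comparator == Comparator.GREATER_THAN:
        return value > rule.threshold
    if rule.comparator == Comparator.LESS_OR_EQUAL:
        return value <= rule.threshold
    return value < rule.threshold


def score_record(record, rules: Mapping[str, CutoffRule] = DEFAULT_RULES):
    """Score one patient record.

    Accepts any object with attribute or mapping access to the six predictor
    fields.  Returns ``(UltrasoundScore, IndicatorPanel)``; the score counts
    positives among the three ultrasound indicators only.
    """

    def get(name: str) -> float:
        if hasattr(record, name):
            return getattr(record, name)
        return record[name]

    pos = {v: apply_cutoff(get(v), rules[v]) for v in rules}
    panel = IndicatorPanel(
        tongue_positive=pos["tongue_thickness"],
        condylar_positive=pos["condylar_mobility"],
        hyomental_positive=pos["hyomental"],
        mallampati_positive=pos["mallampati"],
        thyromental_positive=pos["thyromental"],
        mouth_positive=pos["mouth_opening"],
    )
    points = sum(pos[v] for v in ULTRASOUND_VARIABLES)
    return UltrasoundScore(points), panel


def score_values(tongue_thickness, condylar_mobility, hyomental,
                 rules: Mapping[str, CutoffRule] = DEFAULT_RULES):
    """Vectorized 0-3 score from the three ultrasound measurements.

    Arrays broadcast; returns an integer array of the same shape.
    """
    import numpy as np

    t = np.asarray(tongue_thickness, dtype=float)
    c = np.asarray(condylar_mobility, dtype=float)
    h = np.asarray(hyomental, dtype=float)
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(c)) and np.all(np.isfinite(h))):
        raise ValueError("non-finite ultrasound measurement")
    score = (
        _vec_apply(t, rules["tongue_thickness"]).astype(int)
        + _vec_apply(c, rules["condylar_mobility"]).astype(int)
        + _vec_apply(h, rules["hyomental"]).astype(int)
    )
    return score


def _vec_apply(values, rule: CutoffRule):
    if rule.comparator == Comparator.GREATER_THAN:
        return values > rule.threshold
    if rule.comparator == Comparator.LESS_OR_EQUAL:
        return values <= rule.threshold
    return values < rule.threshold


def classify_positive(score, threshold: int = 1) -> bool:
    """Classify a score as screen-positive: positive iff ``points > threshold``.

    The default threshold of 1 implements the published decision rule
    "positive at more than 1 point", i.e. scores of 2 or 3 are positive.
    """
    if threshold not in (0, 1, 2, 3):
        raise ValueError("threshold must be in {0,1,2,3}")
    points = score.points if isinstance(score, UltrasoundScore) else int(score)
    return points > threshold
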