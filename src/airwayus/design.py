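"""Sample-size design for testing one AUC against a null value.

The design asks: how many cases (positives) and controls (negatives) are
needed to reject, with two-sided type-I error alpha and power 1-beta, the
null hypothesis that a test's AUC equals ``auc_null`` when the true AUC is
``auc_alt``, given kappa controls per case?  The AUC standard error uses the
Hanley-McNeil exponential approximation

    SE^2 = [A(1-A) + (n+ - 1)(Q1 - A^2) + (n- - 1)(Q2 - A^2)] / (n+ n-),
    Q1 = A / (2 - A),   Q2 = 2 A^2 / (1 + A),

and the smallest integer number of positives satisfying

    z_{alpha/2} SE(auc_null) + z_{power} SE(auc_alt) <= auc_alt - auc_null

is found by direct search.  With alpha 0.05, power 0.80, AUC 0.9 against a
null of 0.8 and 19 negatives per positive this returns 50 positives and 950
negatives, a total of 1000 patients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

__all__ = ["SampleSizeSpec", "SampleSizeResult", "hanley_mcneil_se",
           "required_sample_size", "achieved_power"]


@dataclass(frozen=True)
class SampleSizeSpec:
    """AUC-versus-null design parameters.

    ``neg_pos_ratio`` (kappa) is the number of negatives enrolled per
    positive, reflecting the condition's prevalence in the stream of
    eligible patients.
    """

    auc_alt: float = 0.9
    auc_null: float = 0.8
    alpha: float = 0.05
    power: float = 0.8
    neg_pos_ratio: float = 19.0

    def __post_init__(self) -> None:
        for name in ("auc_alt", "auc_null"):
            v = getattr(self, name)
            if not 0.5 < v < 1:
                raise ValueError(f"{name} must lie in (0.5, 1)")
        if self.auc_alt <= self.auc_null:
            raise ValueError("auc_alt must exceed auc_null")
        for name in ("alpha", "power"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0,1)")
        if self.neg_pos_ratio < 1:
            raise ValueError("neg_pos_ratio must be >= 1")


@dataclass(frozen=True)
class SampleSizeResult:
    n_pos: int
    n_neg: int
    total: int
    achieved_power: float


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil standard error of an AUC estimate."""
    if not 0 < auc < 1:
        raise ValueError("auc must lie in (0,1)")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("group sizes must be >= 1")
    a = auc
    q1 = a / (2 - a)
    q2 = 2 * a * a / (1 + a)
    var = (a * (1 - a) + (n_pos - 1) * (q1 - a * a)
           + (n_neg - 1) * (q2 - a * a)) / (n_pos * n_neg)
    return math.sqrt(var)


def _condition(spec: SampleSizeSpec, n_pos: int, n_neg: int) -> float:
    z_a = stats.norm.ppf(1 - spec.alpha / 2)
    z_b = stats.norm.ppf(spec.power)
    return (z_a * hanley_mcneil_se(spec.auc_null, n_pos, n_neg)
            + z_b * hanley_mcneil_se(spec.auc_alt, n_pos, n_neg))


def required_sample_size(spec: SampleSizeSpec, max_n_pos: int = 10**6) -> SampleSizeResult:
    """Smallest design meeting the spec; returns positives, negatives, total.

    Searches the minimal integer ``n_pos`` (with ``n_neg = ceil(kappa *
    n_pos)``) for which the noncentrality condition holds.
    """
    delta = spec.auc_alt - spec.auc_null
    if delta < 1e-9:
        raise ValueError("AUC difference too small; required n is unbounded")
    for n_pos in range(1, max_n_pos + 1):
        n_neg = math.ceil(spec.neg_pos_ratio * n_pos)
        if _condition(spec, n_pos, n_neg) <= delta:
            return SampleSizeResult(
                n_pos=n_pos, n_neg=n_neg, total=n_pos + n_neg,
                achieved_power=achieved_power(spec, n_pos, n_neg),
            )
    raise ValueError(f"no design with at most {max_n_pos} positives meets the spec")


def achieved_power(spec: SampleSizeSpec, n_pos: int, n_neg: int) -> float:
    """Power of the AUC-versus-null test at given group sizes."""
    delta = spec.auc_alt - spec.auc_null
    z_a = stats.norm.ppf(1 - spec.alpha / 2)
    se_null = hanley_mcneil_se(spec.auc_null, n_pos, n_neg)
    se_alt = hanley_mcneil_se(spec.auc_alt, n_pos, n_neg)
    return float(stats.norm.cdf((delta - z_a * se_null) / se_alt))
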