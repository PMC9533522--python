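"""Diagnostic-accuracy statistics for dichotomous and ordinal predictors.

Covers the full evaluation toolkit for a screening test study: 2x2 confusion
tables; sensitivity/specificity/PPV/NPV with exact (Clopper-Pearson) or
Wilson confidence intervals; prevalence-adjusted predictive values by Bayes'
rule; empirical ROC curves with tie-aware Mann-Whitney AUC; DeLong
variance estimation and paired AUC comparison for correlated curves; Youden
cutoff selection; and exact enumeration of the 0-3 composite-score
distribution implied by per-indicator positivity rates, which serves as an
analytic oracle for the simulated cohorts.

Conventions: higher score = more likely positive (invert measurements where
smaller values flag difficulty before calling in here); classification rules
are always of the form "positive iff score > t"; ties receive half credit in
the AUC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ConfusionTable",
    "ProportionEstimate",
    "RocCurve",
    "AucEstimate",
    "PairedAucComparison",
    "ScorePmf",
    "confusion_table",
    "proportion_ci",
    "predictive_values",
    "empirical_roc",
    "auc_mann_whitney",
    "delong_auc",
    "delong_paired",
    "youden_optimal",
    "youden_from_pmfs",
    "score_pmf",
    "score_pmf_correlated",
    "pmf_auc",
]


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 cross-classification of a binary prediction against the truth."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_cases(self) -> int:
        return self.tp + self.fn

    @property
    def n_controls(self) -> int:
        return self.fp + self.tn

    @property
    def sensitivity(self) -> float:
        return self.tp / self.n_cases if self.n_cases else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / self.n_controls if self.n_controls else float("nan")

    @property
    def ppv(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else float("nan")

    @property
    def npv(self) -> float:
        d = self.tn + self.fn
        return self.tn / d if d else float("nan")


@dataclass(frozen=True)
class ProportionEstimate:
    """A proportion with a confidence interval."""

    point: float
    ci_low: float
    ci_high: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if not (0 <= self.ci_low <= self.point + 1e-12
                and self.point - 1e-12 <= self.ci_high <= 1):
            raise ValueError("interval must satisfy 0 <= low <= point <= high <= 1")


@dataclass(frozen=True)
class AucEstimate:
    """AUC with standard error and a Wald CI truncated to [0,1]."""

    auc: float
    se: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    degenerate: bool = False


@dataclass(frozen=True)
class PairedAucComparison:
    """DeLong comparison of two AUCs computed on the same patients."""

    auc_a: float
    auc_b: float
    difference: float
    se_difference: float
    z_statistic: float
    p_value: float
    degenerate: bool = False


def confusion_table(predictions: Sequence[bool], labels: Sequence[bool]) -> ConfusionTable:
    """Tabulate binary predictions against binary outcome labels."""
    pred = np.asarray(predictions, dtype=bool)
    lab = np.asarray(labels, dtype=bool)
    if pred.size == 0 or pred.shape != lab.shape:
        raise ValueError("predictions and labels must be equal-length, non-empty")
    return ConfusionTable(
        tp=int(np.sum(pred & lab)),
        fp=int(np.sum(pred & ~lab)),
        fn=int(np.sum(~pred & lab)),
        tn=int(np.sum(~pred & ~lab)),
    )


def proportion_ci(successes: int, trials: int, level: float = 0.95,
                  method: str = "clopper-pearson") -> ProportionEstimate:
    """Confidence interval for a binomial proportion.

    Default is the exact Clopper-Pearson interval (beta quantiles), the
    convention of the clinical diagnostic-accuracy literature; ``wilson`` is
    available as a shorter-interval alternative.
    """
    if not (0 <= successes <= trials and trials >= 1):
        raise ValueError("need 0 <= successes <= trials and trials >= 1")
    sm_method = {"clopper-pearson": "beta", "wilson": "wilson"}.get(method)
    if sm_method is None:
        raise ValueError(f"unknown CI method {method!r}")
    low, high = proportion_confint(successes, trials, alpha=1 - level, method=sm_method)
    return ProportionEstimate(successes / trials, float(low), float(high), level)


def predictive_values(sens: float, spec: float, prevalence: float) -> tuple[float, float]:
    """Prevalence-adjusted (PPV, NPV) by Bayes' rule.

    PPV = sens*prev / (sens*prev + (1-spec)(1-prev));
    NPV = spec*(1-prev) / (spec*(1-prev) + (1-sens)*prev).
    A zero denominator yields ``nan`` for the affected value.
    """
    for name, v in (("sens", sens), ("spec", spec), ("prevalence", prevalence)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0,1]")
    ppv_den = sens * prevalence + (1 - spec) * (1 - prevalence)
    npv_den = spec * (1 - prevalence) + (1 - sens) * prevalence
    ppv = sens * prevalence / ppv_den if ppv_den > 0 else float("nan")
    npv = spec * (1 - prevalence) / npv_den if npv_den > 0 else float("nan")
    return ppv, npv


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC curve swept over the rule "positive iff score > t".

    ``thresholds[j]`` is the cut t whose rule "score > t" attains the point
    ``(fpr[j], tpr[j])``: the distinct observed scores in decreasing order
    (the maximum giving the (0,0) corner) followed by -inf for the
    all-positive (1,1) corner.
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray

    def auc(self) -> float:
        """Trapezoidal area; with the tie-aware sweep this equals the
        Mann-Whitney statistic."""
        return float(np.trapezoid(self.tpr, self.fpr))


def _validate_scores_labels(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1 or s.size == 0:
        raise ValueError("scores and labels must be equal-length 1-d arrays")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if y.all() or not y.any():
        raise ValueError("labels contain a single class; need cases and controls")
    return s, y


def empirical_roc(scores, labels) -> RocCurve:
    """Empirical ROC of an ordinal/continuous score (higher = more positive)."""
    s, y = _validate_scores_labels(scores, labels)
    order = np.argsort(-s, kind="mergesort")
    s_sorted, y_sorted = s[order], y[order]
    n1, n0 = int(y.sum()), int((~y).sum())
    distinct = np.r_[True, np.diff(s_sorted) != 0]
    idx = np.nonzero(distinct)[0]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(~y_sorted)
    # block ends: counts after including every observation tied at a threshold
    ends = np.r_[idx[1:] - 1, s.size - 1]
    tpr = np.r_[0.0, tp[ends] / n1]
    fpr = np.r_[0.0, fp[ends] / n0]
    # under the rule "positive iff score > t", the point admitting the top j
    # distinct blocks has t equal to the j-th largest distinct score; the
    # all-positive corner needs any t below the minimum
    thresholds = np.r_[s_sorted[idx], -np.inf]
    return RocCurve(thresholds=thresholds, tpr=tpr, fpr=fpr)


def auc_mann_whitney(scores, labels) -> float:
    """AUC as P(case > control) + 0.5 P(tie), by midranks."""
    s, y = _validate_scores_labels(scores, labels)
    n1, n0 = int(y.sum()), int((~y).sum())
    ranks = stats.rankdata(s)
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _delong_components(s, y):
    """DeLong structural components (placement values) for one score vector."""
    cases, controls = s[y], s[~y]
    n1, n0 = cases.size, controls.size
    # V10[i]: fraction of controls below case i (+ half ties); V01 analogous
    order = np.argsort(controls, kind="mergesort")
    cs = controls[order]
    v10 = ((np.searchsorted(cs, cases, side="left")
            + np.searchsorted(cs, cases, side="right")) / 2) / n0
    order = np.argsort(cases, kind="mergesort")
    ca = cases[order]
    v01 = (n1 - (np.searchsorted(ca, controls, side="left")
                 + np.searchsorted(ca, controls, side="right")) / 2) / n1
    return v10, v01


def delong_auc(scores, labels, level: float = 0.95) -> AucEstimate:
    """AUC with DeLong standard error and a Wald CI truncated to [0,1].

    Degenerate inputs (constant scores within both groups) are returned with
    ``degenerate=True`` and a zero SE rather than raising.
    """
    s, y = _validate_scores_labels(scores, labels)
    v10, v01 = _delong_components(s, y)
    auc = float(v10.mean())
    n1, n0 = v10.size, v01.size
    var = (v10.var(ddof=1) / n1 if n1 > 1 else 0.0) + \
          (v01.var(ddof=1) / n0 if n0 > 1 else 0.0)
    se = float(np.sqrt(max(var, 0.0)))
    degenerate = se == 0.0
    z = stats.norm.ppf(0.5 + level / 2)
    return AucEstimate(
        auc=auc, se=se,
        ci_low=max(0.0, auc - z * se), ci_high=min(1.0, auc + z * se),
        degenerate=degenerate,
    )


def delong_paired(scores_a, scores_b, labels) -> PairedAucComparison:
    """DeLong test for two correlated AUCs sharing the same labels.

    Returns the AUC difference, its SE from the DeLong covariance of the
    paired placement values, the z statistic, and a two-sided normal p value.
    Zero variance of the difference is flagged (p=1 when the AUCs are equal,
    p=0 otherwise) instead of raising.
    """
    sa, y = _validate_scores_labels(scores_a, labels)
    sb, y2 = _validate_scores_labels(scores_b, labels)
    if sa.shape != sb.shape:
        raise ValueError("paired score vectors must have equal length")
    v10a, v01a = _delong_components(sa, y)
    v10b, v01b = _delong_components(sb, y)
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    n1, n0 = v10a.size, v01a.size
    var = 0.0
    if n1 > 1:
        c10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
        var += (c10[0, 0] + c10[1, 1] - 2 * c10[0, 1]) / n1
    if n0 > 1:
        c01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
        var += (c01[0, 0] + c01[1, 1] - 2 * c01[0, 1]) / n0
    se = float(np.sqrt(max(var, 0.0)))
    diff = auc_a - auc_b
    if se == 0.0:
        return PairedAucComparison(auc_a, auc_b, diff, 0.0,
                                   z_statistic=float("nan"),
                                   p_value=1.0 if diff == 0 else 0.0,
                                   degenerate=True)
    z = diff / se
    p = float(2 * stats.norm.sf(abs(z)))
    return PairedAucComparison(auc_a, auc_b, diff, se, float(z), p)


def youden_optimal(scores, labels) -> tuple[float, float]:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    The classification rule is "positive iff score > t" with t swept over the
    distinct observed scores; ties in J are broken toward the higher
    threshold, i.e. the more specific rule.
    """
    s, y = _validate_scores_labels(scores, labels)
    curve = empirical_roc(s, y)
    j = curve.tpr - curve.fpr
    # interior thresholds only: t equal to the max score means nothing positive
    best = 0
    for i in range(1, j.size):
        if j[i] > j[best] + 1e-15:
            best = i
    if best == 0:  # constant scores: J = 0 everywhere
        return float(curve.thresholds[0]), 0.0
    return float(curve.thresholds[best]), float(j[best])


@dataclass(frozen=True)
class ScorePmf:
    """Probability mass function of the 0-3 composite score."""

    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", p)
        if p.shape != (4,) or np.any(p < -1e-15) or abs(p.sum() - 1) > 1e-12:
            raise ValueError("pmf must be 4 non-negative masses summing to 1")

    @property
    def support(self) -> np.ndarray:
        return np.arange(4)

    def mean(self) -> float:
        return float(self.probabilities @ self.support)

    def sensitivity_above(self, t: int) -> float:
        """P(score > t) -- sensitivity when this is the case pmf."""
        return float(self.probabilities[t + 1:].sum())

    def specificity_at_or_below(self, t: int) -> float:
        """P(score <= t) -- specificity when this is the control pmf."""
        return float(self.probabilities[: t + 1].sum())


def score_pmf(rates: Sequence[float]) -> ScorePmf:
    """Exact pmf of the sum of three independent Bernoulli indicators.

    Enumerates the 8 joint outcomes; this is the analytic oracle for the
    composite score when the latent correlation is zero.
    """
    r = np.asarray(rates, dtype=float)
    if r.shape != (3,) or np.any(r < 0) or np.any(r > 1):
        raise ValueError("rates must be three proportions in [0,1]")
    p = np.zeros(4)
    for bits in range(8):
        states = [(bits >> k) & 1 for k in range(3)]
        mass = np.prod([ri if s else 1 - ri for ri, s in zip(r, states)])
        p[sum(states)] += mass
    return ScorePmf(p)


def score_pmf_correlated(rates: Sequence[float], latent_correlation: float,
                         n_nodes: int = 80) -> ScorePmf:
    """Score pmf under the exchangeable Gaussian-copula dependence model.

    Conditional on the shared latent factor W ~ N(0,1), the indicators are
    independent with rates Phi((Phi^{-1}(r_i) - sqrt(rho) w) / sqrt(1-rho));
    the marginal pmf integrates the conditional enumeration over W by
    Gauss-Hermite quadrature.  Reduces to :func:`score_pmf` at rho = 0.
    """
    r = np.asarray(rates, dtype=float)
    rho = float(latent_correlation)
    if not 0 <= rho < 1:
        raise ValueError("latent correlation must lie in [0,1)")
    if rho == 0:
        return score_pmf(r)
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    w = np.sqrt(2.0) * nodes                    # N(0,1) abscissae
    wt = weights / np.sqrt(np.pi)
    with np.errstate(divide="ignore"):
        c = stats.norm.ppf(np.clip(r, 0.0, 1.0))
    cond = stats.norm.cdf((c[None, :] - np.sqrt(rho) * w[:, None]) / np.sqrt(1 - rho))
    p = np.zeros(4)
    for bits in range(8):
        states = np.array([(bits >> k) & 1 for k in range(3)], dtype=bool)
        mass = np.prod(np.where(states, cond, 1 - cond), axis=1)
        p[int(states.sum())] += float(wt @ mass)
    return ScorePmf(p / p.sum())


def pmf_auc(case_pmf: ScorePmf, control_pmf: ScorePmf) -> float:
    """Analytic AUC between two score pmfs with half credit for ties."""
    a, b = case_pmf.probabilities, control_pmf.probabilities
    auc = 0.0
    for k in range(4):
        auc += a[k] * b[:k].sum() + 0.5 * a[k] * b[k]
    return float(auc)


def youden_from_pmfs(case_pmf: ScorePmf, control_pmf: ScorePmf) -> tuple[int, float]:
    """Youden-optimal integer threshold for "positive iff score > t".

    Evaluates J over t in {0, 1, 2}; ties break toward the higher threshold.
    """
    js = [case_pmf.sensitivity_above(t)
          + control_pmf.specificity_at_or_below(t) - 1 for t in (0, 1, 2)]
    best = max(range(3), key=lambda t: (js[t], t))
    return best, float(js[best])
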