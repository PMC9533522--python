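"""Study-level model and results objects.

:class:`AirwayStudy` wraps a patient cohort and one outcome definition
(difficult tracheal intubation, DTI, or difficult laryngoscopy, DL);
``fit()`` runs the complete evaluation -- group comparisons, per-predictor
diagnostic accuracy at the fixed clinical cutoffs, ROC/AUC with DeLong
uncertainty, and paired DeLong comparisons of the composite ultrasound score
against every single predictor -- and returns an :class:`AirwayStudyResults`
carrying unrounded estimates, rendered tables, and a text ``summary()``.

Rounding happens only at rendering (half away from zero, two decimals); all
stored numbers are exact, so the machine-readable JSON twin can reproduce
any rendered table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .accuracy import (
    AucEstimate,
    PairedAucComparison,
    confusion_table,
    delong_auc,
    delong_paired,
    empirical_roc,
    proportion_ci,
)
from .cohort import PatientRecord, cohort_to_frame, read_cohort
from .scoring import (
    CONVENTIONAL_VARIABLES,
    DEFAULT_RULES,
    HIGHER_IS_DIFFICULT,
    ULTRASOUND_VARIABLES,
    CutoffRule,
    classify_positive,
    score_values,
)

__all__ = ["AirwayStudy", "AirwayStudyResults", "round_half_away"]

_FRAME_FIELDS = {
    "mouth_opening": "mouth_opening_mm", "thyromental": "thyromental_mm",
    "tongue_thickness": "tongue_thickness_mm", "hyomental": "hyomental_mm",
    "condylar_mobility": "condylar_mobility_mm", "mallampati": "mallampati",
}

#: Accuracy-table rows in the published order: the six single predictors
#: followed by the composite ultrasound model.
PREDICTOR_ORDER = ("mallampati", "thyromental", "mouth_opening",
                   "condylar_mobility", "hyomental", "tongue_thickness",
                   "score")


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (report-rendering convention)."""
    if not np.isfinite(x):
        return float(x)
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


class AirwayStudy:
    """Diagnostic-accuracy study of airway predictors against one outcome.

    Parameters
    ----------
    cohort
        A DataFrame in the cohort CSV schema or a sequence of
        :class:`~airwayus.cohort.PatientRecord`.
    outcome
        ``"DTI"`` or ``"DL"``: which label column defines cases.
    rules
        Dichotomization rules; defaults to the published cutoffs.
    score_threshold
        Screen-positivity threshold for the composite score (positive iff
        score > threshold); default 1.
    welch
        Use Welch's unequal-variance t test for continuous group
        comparisons (default); ``False`` selects the pooled-variance test.
    bonferroni
        Add a Bonferroni-adjusted p column to the paired AUC comparisons;
        off by default (per-comparison reporting).
    """

    def __init__(self, cohort, outcome: str = "DTI",
                 rules: Mapping[str, CutoffRule] = DEFAULT_RULES,
                 score_threshold: int = 1, welch: bool = True,
                 bonferroni: bool = False):
        if outcome not in ("DTI", "DL"):
            raise ValueError(f"outcome must be 'DTI' or 'DL', got {outcome!r}")
        if isinstance(cohort, pd.DataFrame):
            frame = cohort.copy()
        else:
            frame = cohort_to_frame(list(cohort))
        if frame.empty:
            raise ValueError("cohort is empty")
        self.frame = frame.reset_index(drop=True)
        self.outcome = outcome
        self.rules = dict(rules)
        self.score_threshold = int(score_threshold)
        self.welch = bool(welch)
        self.bonferroni = bool(bonferroni)
        label_col = "dti_label" if outcome == "DTI" else "dl_label"
        self.labels = self.frame[label_col].astype(int).to_numpy().astype(bool)
        if self.labels.all() or not self.labels.any():
            raise ValueError(
                f"cohort contains a single {outcome} class; need both cases and controls"
            )
        self.score = score_values(
            self.frame["tongue_thickness_mm"].astype(float),
            self.frame["condylar_mobility_mm"].astype(float),
            self.frame["hyomental_mm"].astype(float),
            rules=self.rules,
        )

    @classmethod
    def from_records(cls, records: Sequence[PatientRecord], **kwargs) -> "AirwayStudy":
        return cls(cohort_to_frame(records), **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "AirwayStudy":
        """Build a study from a cohort CSV, dropping incomplete/invalid rows."""
        result = read_cohort(path)
        study = cls.from_records(result.records, **kwargs)
        study.read_result = result
        return study

    # ------------------------------------------------------------------ fit

    def fit(self) -> "AirwayStudyResults":
        """Run the full evaluation and return a results object."""
        return AirwayStudyResults(
            study=self,
            cohort_summary=self._cohort_summary(),
            group_comparison=self._group_comparison(),
            accuracy=self._accuracy_table(),
            paired_auc=self._paired_comparisons(),
            provenance={
                "outcome": self.outcome,
                "n_patients": int(len(self.frame)),
                "score_threshold": self.score_threshold,
                "welch": self.welch,
                "version": __version__,
            },
        )

    # ------------------------------------------------------- fit internals

    def _oriented(self, predictor: str) -> np.ndarray:
        """Predictor values oriented so larger means more difficult."""
        if predictor == "score":
            vals = self.score.astype(float)
        else:
            vals = self.frame[_FRAME_FIELDS[predictor]].astype(float).to_numpy()
        return vals if HIGHER_IS_DIFFICULT[predictor] else -vals

    def _predictions(self, predictor: str) -> np.ndarray:
        if predictor == "score":
            return self.score > self.score_threshold
        rule = self.rules[predictor]
        vals = self.frame[_FRAME_FIELDS[predictor]].astype(float).to_numpy()
        from .scoring import _vec_apply

        return _vec_apply(vals, rule)

    def _cohort_summary(self) -> dict:
        n = int(len(self.frame))
        n_cases = int(self.labels.sum())
        return {
            "n_patients": n,
            "outcome": self.outcome,
            "n_cases": n_cases,
            "n_controls": n - n_cases,
            "prevalence": n_cases / n,
            "n_dl": int(self.frame["dl_label"].astype(int).sum()),
            "n_dti": int(self.frame["dti_label"].astype(int).sum()),
        }

    def _group_comparison(self) -> pd.DataFrame:
        y = self.labels
        rows = []
        continuous = [
            ("age", "age"), ("height_cm", "height"), ("weight_kg", "weight"),
            ("bmi", "bmi"), ("mouth_opening_mm", "mouth_opening"),
            ("thyromental_mm", "thyromental"),
        ]
        for col, name in continuous:
            v = self.frame[col].astype(float).to_numpy()
            a, b = v[y], v[~y]
            stat, p = stats.ttest_ind(a, b, equal_var=not self.welch)
            rows.append(self._cmp_row(name, a, b, float(stat), float(p),
                                      "welch_t" if self.welch else "pooled_t"))
        mall = self.frame["mallampati"].astype(float).to_numpy()
        a, b = mall[y], mall[~y]
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append(self._cmp_row("mallampati", a, b, float(stat), float(p),
                                  "rank_sum"))
        sc = self.score.astype(float)
        a, b = sc[y], sc[~y]
        stat, p = stats.ttest_ind(a, b, equal_var=not self.welch)
        rows.append(self._cmp_row("score", a, b, float(stat), float(p),
                                  "welch_t" if self.welch else "pooled_t"))
        male = (self.frame["sex"].astype(str) == "M").to_numpy()
        table = np.array([
            [int((male & y).sum()), int((~male & y).sum())],
            [int((male & ~y).sum()), int((~male & ~y).sum())],
        ])
        if (table.sum(axis=0) > 0).all() and (table.sum(axis=1) > 0).all():
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        else:
            chi2, p = float("nan"), float("nan")
        rows.append({
            "variable": "sex", "test": "chi_square",
            "case_mean": float(table[0, 0]), "case_sd": float(table[0, 1]),
            "control_mean": float(table[1, 0]), "control_sd": float(table[1, 1]),
            "statistic": float(chi2), "p_value": float(p),
        })
        return pd.DataFrame(rows)

    @staticmethod
    def _cmp_row(name, a, b, stat, p, test) -> dict:
        return {
            "variable": name, "test": test,
            "case_mean": float(np.mean(a)),
            "case_sd": float(np.std(a, ddof=1)) if a.size > 1 else float("nan"),
            "control_mean": float(np.mean(b)),
            "control_sd": float(np.std(b, ddof=1)) if b.size > 1 else float("nan"),
            "statistic": stat, "p_value": p,
        }

    def _accuracy_table(self) -> pd.DataFrame:
        y = self.labels
        prevalence = float(y.mean())
        rows = []
        for predictor in PREDICTOR_ORDER:
            pred = self._predictions(predictor)
            ct = confusion_table(pred, y)
            sens = proportion_ci(ct.tp, ct.n_cases)
            spec = proportion_ci(ct.tn, ct.n_controls)
            npos, nneg = ct.tp + ct.fp, ct.tn + ct.fn
            ppv = proportion_ci(ct.tp, npos) if npos else None
            npv = proportion_ci(ct.tn, nneg) if nneg else None
            auc = delong_auc(self._oriented(predictor), y)
            if predictor == "score":
                description = f"Ultrasound model (> {self.score_threshold})"
            else:
                description = self.rules[predictor].description
            rows.append({
                "predictor": predictor, "description": description,
                "tp": ct.tp, "fp": ct.fp, "fn": ct.fn, "tn": ct.tn,
                "sensitivity": sens.point, "sens_low": sens.ci_low,
                "sens_high": sens.ci_high,
                "specificity": spec.point, "spec_low": spec.ci_low,
                "spec_high": spec.ci_high,
                "ppv": ppv.point if ppv else float("nan"),
                "ppv_low": ppv.ci_low if ppv else float("nan"),
                "ppv_high": ppv.ci_high if ppv else float("nan"),
                "npv": npv.point if npv else float("nan"),
                "npv_low": npv.ci_low if npv else float("nan"),
                "npv_high": npv.ci_high if npv else float("nan"),
                "auc": auc.auc, "auc_se": auc.se,
                "auc_low": auc.ci_low, "auc_high": auc.ci_high,
                "prevalence": prevalence,
            })
        return pd.DataFrame(rows)

    def _paired_comparisons(self) -> pd.DataFrame:
        y = self.labels
        model_scores = self._oriented("score")
        rows = []
        for predictor in PREDICTOR_ORDER[:-1]:
            cmp = delong_paired(model_scores, self._oriented(predictor), y)
            rows.append({
                "comparator": predictor,
                "auc_model": cmp.auc_a, "auc_comparator": cmp.auc_b,
                "difference": cmp.difference, "se_difference": cmp.se_difference,
                "z_statistic": cmp.z_statistic, "p_value": cmp.p_value,
                "degenerate": cmp.degenerate,
            })
        frame = pd.DataFrame(rows)
        if self.bonferroni:
            frame["p_value_adjusted"] = np.minimum(frame["p_value"] * len(frame), 1.0)
        return frame


@dataclass
class AirwayStudyResults:
    """Estimates and tables from a fitted :class:`AirwayStudy`.

    Attributes hold unrounded values; ``rendered_accuracy()`` and
    ``summary()`` round half away from zero to two decimals at display time
    only.
    """

    study: AirwayStudy
    cohort_summary: dict
    group_comparison: pd.DataFrame
    accuracy: pd.DataFrame
    paired_auc: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    # ----------------------------------------------------------- rendering

    @staticmethod
    def _fmt_est(point, low, high) -> str:
        f = lambda v: f"{round_half_away(v):.2f}"
        return f"{f(point)} ({f(low)}-{f(high)})"

    @staticmethod
    def _fmt_p(p: float) -> str:
        if not np.isfinite(p):
            return "NA"
        return "< 0.001" if p < 0.001 else f"{round_half_away(p, 3):.3f}"

    def rendered_accuracy(self) -> pd.DataFrame:
        """Accuracy table with ``point (low-high)`` strings, published layout."""
        rows = []
        for r in self.accuracy.to_dict("records"):
            rows.append({
                "parameter": r["description"],
                "sensitivity_95ci": self._fmt_est(r["sensitivity"], r["sens_low"], r["sens_high"]),
                "specificity_95ci": self._fmt_est(r["specificity"], r["spec_low"], r["spec_high"]),
                "ppv_95ci": self._fmt_est(r["ppv"], r["ppv_low"], r["ppv_high"]),
                "npv_95ci": self._fmt_est(r["npv"], r["npv_low"], r["npv_high"]),
                "auc_95ci": self._fmt_est(r["auc"], r["auc_low"], r["auc_high"]),
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable report: cohort, group comparison, accuracy, AUC tests."""
        s = self.cohort_summary
        lines = [
            "Difficult-airway diagnostic accuracy study",
            "=" * 58,
            f"Outcome: {s['outcome']}   patients: {s['n_patients']}   "
            f"cases: {s['n_cases']} ({100 * s['prevalence']:.1f}%)",
            "",
            "Group comparison (cases vs controls)",
            "-" * 58,
        ]
        for r in self.group_comparison.to_dict("records"):
            if r["variable"] == "sex":
                desc = (f"M/F {int(r['case_mean'])}/{int(r['case_sd'])} vs "
                        f"{int(r['control_mean'])}/{int(r['control_sd'])}")
            else:
                desc = (f"{r['case_mean']:.2f} ± {r['case_sd']:.2f} vs "
                        f"{r['control_mean']:.2f} ± {r['control_sd']:.2f}")
            lines.append(f"{r['variable']:<18} {desc:<34} p {self._fmt_p(r['p_value'])}")
        lines += ["", "Diagnostic accuracy", "-" * 58]
        rendered = self.rendered_accuracy()
        for r in rendered.to_dict("records"):
            lines.append(f"{r['parameter']:<42} AUC {r['auc_95ci']}")
            lines.append(f"    sens {r['sensitivity_95ci']}  spec {r['specificity_95ci']}")
            lines.append(f"    PPV  {r['ppv_95ci']}  NPV  {r['npv_95ci']}")
        lines += ["", "Paired AUC comparisons (ultrasound model vs single tests)",
                  "-" * 58]
        for r in self.paired_auc.to_dict("records"):
            lines.append(
                f"{r['comparator']:<18} dAUC {r['difference']:+.3f}  "
                f"z {r['z_statistic']:.2f}  p {self._fmt_p(r['p_value'])}"
            )
        return "\n".join(lines)

    # --------------------------------------------------------------- export

    def to_dict(self) -> dict:
        return {
            "cohort_summary": self.cohort_summary,
            "group_comparison": self.group_comparison.to_dict("records"),
            "accuracy": self.accuracy.to_dict("records"),
            "paired_auc": self.paired_auc.to_dict("records"),
            "provenance": self.provenance,
        }

    def to_json(self, path=None, **kwargs) -> str:
        """Unrounded machine-readable twin of the rendered report."""
        payload = json.dumps(self.to_dict(), indent=2, sort_keys=True,
                             allow_nan=True, **kwargs)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(payload)
        return payload

    # ------------------------------------------------------------- plotting

    def plot_roc(self, predictors: Sequence[str] = ("score", "mallampati",
                                                    "thyromental", "mouth_opening"),
                 ax=None):
        """ROC curves for the composite score and selected single predictors."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        for predictor in predictors:
            curve = empirical_roc(self.study._oriented(predictor),
                                  self.study.labels)
            row = self.accuracy.loc[self.accuracy["predictor"] == predictor]
            label = predictor if row.empty else \
                f"{row.iloc[0]['description']} (AUC {row.iloc[0]['auc']:.2f})"
            ax.plot(curve.fpr, curve.tpr, drawstyle="steps-post", label=label)
        ax.plot([0, 1], [0, 1], "k:", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("Sensitivity")
        ax.set_title(f"ROC: {self.cohort_summary['outcome']}")
        ax.legend(loc="lower right", fontsize=8)
        return ax
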