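"""Synthetic difficult-airway cohorts and delimited-table I/O.

No individual-level data accompany the published study, so analyses here run
on synthetic cohorts engineered to match its printed summary statistics: a
cohort of 1000 adults with difficult-tracheal-intubation (DTI) prevalence
26/1000 and difficult-laryngoscopy (DL) prevalence 51/1000, per-indicator
positivity rates equal to the published sensitivities (cases) and one minus
the specificities (controls), and group demographics matching the published
means and SDs.

Binary indicators are drawn through a Gaussian copula with an exchangeable
latent correlation: each patient has three latent standard normals sharing a
single correlation ``rho``, thresholded at the normal quantile of the target
rate, so marginal positivity is exact in expectation at any ``rho`` while
``rho`` tunes how often indicators co-occur.  Continuous measurements are then
back-filled from truncated normals on the side of each cutoff implied by the
binary state, so re-dichotomizing a generated cohort reproduces its
indicators exactly.

The generator is calibrated for one outcome at a time (``outcome_mode``); the
other label is produced by a nested-severity rule (every DTI patient is also
DL) and should be treated as approximate.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, asdict, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import (
    CONVENTIONAL_VARIABLES,
    DEFAULT_RULES,
    ULTRASOUND_VARIABLES,
    Comparator,
    CutoffRule,
)

__all__ = [
    "PatientRecord",
    "GeneratorConfig",
    "CohortReadResult",
    "COHORT_COLUMNS",
    "default_config",
    "sample_indicators",
    "backfill_continuous",
    "generate_cohort",
    "cohort_to_frame",
    "frame_to_cohort",
    "write_cohort",
    "read_cohort",
]

#: Fixed column order of the cohort CSV schema.
COHORT_COLUMNS = [
    "patient_id", "age", "sex", "height_cm", "weight_kg", "bmi",
    "mouth_opening_mm", "mallampati", "thyromental_mm", "tongue_thickness_mm",
    "hyomental_mm", "condylar_mobility_mm", "dl_label", "dti_label",
]

_FIELD_FOR_COLUMN = {
    "height_cm": "height", "weight_kg": "weight", "mouth_opening_mm": "mouth_opening",
    "thyromental_mm": "thyromental", "tongue_thickness_mm": "tongue_thickness",
    "hyomental_mm": "hyomental", "condylar_mobility_mm": "condylar_mobility",
}


@dataclass(frozen=True)
class PatientRecord:
    """One patient: airway measurements (mm), demographics, outcome labels."""

    patient_id: str
    age: float
    sex: str                   # "male" | "female"
    height: float              # cm
    weight: float              # kg
    bmi: float                 # kg/m^2
    mouth_opening: float       # mm
    mallampati: int            # ordinal grade 1-4
    thyromental: float         # mm
    tongue_thickness: float    # mm
    hyomental: float           # mm
    condylar_mobility: float   # mm
    dl_label: bool
    dti_label: bool

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if int(self.mallampati) != self.mallampati or self.mallampati not in (1, 2, 3, 4):
            raise ValueError(f"mallampati must be an integer in 1..4, got {self.mallampati!r}")
        for name in ("age", "height", "weight", "bmi", "mouth_opening",
                     "thyromental", "tongue_thickness", "hyomental",
                     "condylar_mobility"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and positive, got {v!r}")


# Published group moments, one (mean, sd) pair per (variable, group).
# Mouth opening and thyromental distance carry cm labels in the source tables
# but mm-magnitude values; they are treated as mm throughout.
_TABLE1_MOMENTS = {
    "DTI": {
        "case": {"age": (57.77, 11.51), "height": (164.77, 7.15),
                 "weight": (62.40, 10.03), "mouth_opening": (33.27, 6.87),
                 "thyromental": (66.73, 7.80)},
        "control": {"age": (51.15, 14.12), "height": (164.54, 7.36),
                    "weight": (63.21, 10.65), "mouth_opening": (40.21, 5.22),
                    "thyromental": (78.20, 8.15)},
        "male_fraction": {"case": 15 / 26, "control": 504 / 974},
    },
    "DL": {
        "case": {"age": (58.58, 12.41), "height": (165.28, 7.05),
                 "weight": (62.29, 11.36), "mouth_opening": (34.52, 6.08),
                 "thyromental": (69.74, 8.50)},
        "control": {"age": (50.92, 14.08), "height": (164.50, 7.37),
                    "weight": (63.23, 10.60), "mouth_opening": (40.31, 5.18),
                    "thyromental": (78.34, 8.10)},
        "male_fraction": {"case": 33 / 51, "control": 486 / 949},
    },
}

# Ultrasound indicator rates in the fixed order (condylar, hyomental, tongue):
# case rates are the published sensitivities, control rates 1 - specificity.
_CALIBRATION = {
    "DTI": {
        "prevalence": 26 / 1000, "other_prevalence": 51 / 1000,
        "case_rates": (0.81, 0.77, 0.78), "control_rates": (0.20, 0.25, 0.39),
        "conventional_case_rates": (0.88, 0.46, 0.38),
        "conventional_control_rates": (0.42, 0.07, 0.03),
    },
    "DL": {
        "prevalence": 51 / 1000, "other_prevalence": 26 / 1000,
        "case_rates": (0.76, 0.67, 0.65), "control_rates": (0.19, 0.25, 0.39),
        "conventional_case_rates": (0.80, 0.35, 0.25),
        "conventional_control_rates": (0.41, 0.07, 0.02),
    },
}

# Truncated-normal back-fill location/scale per ultrasound variable (mm);
# centred on the cutoff so only the dichotomized rates carry signal.
_DEFAULT_BACKFILL = {
    "condylar_mobility": (10.0, 3.0),
    "hyomental": (51.0, 6.0),
    "tongue_thickness": (61.0, 5.0),
}

# Within-side Mallampati grade distributions used for ordinal back-fill.
_MALLAMPATI_POSITIVE = ((3, 4), (0.75, 0.25))
_MALLAMPATI_NEGATIVE = ((1, 2), (0.30, 0.70))


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterization of a synthetic cohort.

    ``case_rates`` / ``control_rates`` are indicator positivity rates for the
    three ultrasound signs in the order (condylar mobility <= 10 mm,
    hyomental <= 51 mm, tongue > 61 mm); the conventional triples follow the
    order (Mallampati > 2, thyromental < 65 mm, mouth opening < 30 mm).
    ``latent_correlation`` is the exchangeable Gaussian-copula correlation
    shared by each indicator triple.  With ``exact_counts`` the number of
    cases is fixed at ``round(n_patients * prevalence)`` instead of drawn
    binomially.
    """

    n_patients: int = 1000
    outcome_mode: str = "DTI"
    prevalence: float = 26 / 1000
    other_prevalence: float = 51 / 1000
    case_rates: tuple[float, float, float] = (0.81, 0.77, 0.78)
    control_rates: tuple[float, float, float] = (0.20, 0.25, 0.39)
    latent_correlation: float = 0.3
    conventional_case_rates: tuple[float, float, float] = (0.88, 0.46, 0.38)
    conventional_control_rates: tuple[float, float, float] = (0.42, 0.07, 0.03)
    demographic_moments: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: _TABLE1_MOMENTS["DTI"]
    )
    backfill: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_BACKFILL)
    )
    exact_counts: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outcome_mode not in ("DTI", "DL"):
            raise ValueError(f"outcome_mode must be 'DTI' or 'DL', got {self.outcome_mode!r}")
        for name in ("prevalence", "other_prevalence"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must lie in [0,1]")
        for name in ("case_rates", "control_rates",
                     "conventional_case_rates", "conventional_control_rates"):
            r = getattr(self, name)
            if len(r) != 3 or any(not 0 <= x <= 1 for x in r):
                raise ValueError(f"{name} must be three proportions in [0,1]")
        if any(c < k for c, k in zip(self.case_rates, self.control_rates)):
            raise ValueError("case_rates must be elementwise >= control_rates")
        if not 0 <= self.latent_correlation < 1:
            raise ValueError("latent_correlation must lie in [0,1)")
        for var, (loc, scale) in self.backfill.items():
            if scale <= 0:
                raise ValueError(f"backfill scale for {var} must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["demographic_moments"] = {
            g: dict(v) if isinstance(v, Mapping) else v
            for g, v in self.demographic_moments.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        d = dict(d)
        for key in ("case_rates", "control_rates",
                    "conventional_case_rates", "conventional_control_rates"):
            if key in d:
                d[key] = tuple(d[key])
        if "backfill" in d:
            d["backfill"] = {k: tuple(v) for k, v in d["backfill"].items()}
        return cls(**d)

    def replace(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)


def default_config(outcome_mode: str = "DTI", **overrides) -> GeneratorConfig:
    """The published-study preset for one outcome.

    n=1000 patients; DTI prevalence 0.026 with ultrasound case rates
    (0.81, 0.77, 0.78) and control rates (0.20, 0.25, 0.39); DL prevalence
    0.051 with case rates (0.76, 0.67, 0.65) and control rates
    (0.19, 0.25, 0.39); demographics from the published group moments;
    latent correlation 0.3.
    """
    if outcome_mode not in _CALIBRATION:
        raise ValueError(f"outcome_mode must be 'DTI' or 'DL', got {outcome_mode!r}")
    cal = _CALIBRATION[outcome_mode]
    cfg = GeneratorConfig(
        outcome_mode=outcome_mode,
        demographic_moments=_TABLE1_MOMENTS[outcome_mode],
        **cal,
    )
    return cfg.replace(**overrides) if overrides else cfg


def sample_indicators(
    rates: Sequence[float],
    latent_correlation: float,
    n: int,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Draw ``n`` correlated Bernoulli triples with exact marginal rates.

    Latent variables ``Z_i = sqrt(rho) W + sqrt(1-rho) eps_i`` share the
    common factor ``W``; indicator ``i`` is positive when
    ``Z_i <= Phi^{-1}(rate_i)``, so each margin hits its rate in expectation
    regardless of ``rho``.  Returns an ``(n, 3)`` boolean array.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.ndim != 1 or np.any(rates < 0) or np.any(rates > 1):
        raise ValueError("rates must be proportions in [0,1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    k = rates.size
    # exchangeable correlation matrix is PSD iff rho >= -1/(k-1)
    if not (-1.0 / max(k - 1, 1) <= latent_correlation <= 1.0):
        raise ValueError(
            f"latent correlation {latent_correlation} yields a non-positive-"
            f"semidefinite {k}x{k} exchangeable matrix"
        )
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rho = float(latent_correlation)
    w = rng.standard_normal((n, 1))
    eps = rng.standard_normal((n, k))
    z = np.sqrt(max(rho, 0.0)) * w + np.sqrt(1 - max(rho, 0.0)) * eps
    if rho < 0:  # negative exchangeable dependence via explicit covariance
        cov = np.full((k, k), rho)
        np.fill_diagonal(cov, 1.0)
        z = rng.multivariate_normal(np.zeros(k), cov, size=n, method="eigh")
    with np.errstate(divide="ignore"):
        thresholds = stats.norm.ppf(rates)
    return z <= thresholds


def backfill_continuous(
    indicator,
    rule: CutoffRule,
    loc: float,
    scale: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw continuous measurements consistent with binary indicator states.

    Values come from a normal(``loc``, ``scale``) truncated to the side of
    ``rule``'s threshold matching each indicator (positive side for ``True``),
    and bounded below by zero since all measurements are lengths.  Boundary
    semantics follow the comparator: a positive draw under a ``<=`` rule may
    equal the threshold exactly, while a negative draw never does.
    """
    if scale <= 0:
        raise ValueError("backfill scale must be positive")
    ind = np.atleast_1d(np.asarray(indicator, dtype=bool))
    thr = rule.threshold
    out = np.empty(ind.shape, dtype=float)
    # (low, high) bounds per side; open endpoints handled by post-hoc nudging
    if rule.comparator == Comparator.GREATER_THAN:
        pos_lo, pos_hi, neg_lo, neg_hi = thr, np.inf, 0.0, thr
    elif rule.comparator == Comparator.LESS_OR_EQUAL:
        pos_lo, pos_hi, neg_lo, neg_hi = 0.0, thr, thr, np.inf
    else:  # LESS_THAN
        pos_lo, pos_hi, neg_lo, neg_hi = 0.0, thr, thr, np.inf
    for side, (lo, hi) in ((True, (pos_lo, pos_hi)), (False, (neg_lo, neg_hi))):
        m = ind == side
        if not m.any():
            continue
        a, b = (lo - loc) / scale, (hi - loc) / scale
        out[m] = stats.truncnorm.rvs(a, b, loc=loc, scale=scale,
                                     size=int(m.sum()), random_state=rng)
    # enforce strict side membership against floating-point boundary hits
    from .scoring import _vec_apply

    wrong = _vec_apply(out, rule) != ind
    if wrong.any():
        direction = np.where(ind == (rule.comparator == Comparator.GREATER_THAN),
                             np.inf, -np.inf)
        out[wrong] = np.nextafter(thr, direction[wrong])
    return out if np.ndim(indicator) else float(out[0])


def _sample_group(cfg: GeneratorConfig, n: int, is_case: bool,
                  rng: np.random.Generator) -> dict:
    """Draw all measurements for one outcome group; returns column arrays."""
    group = "case" if is_case else "control"
    us_rates = cfg.case_rates if is_case else cfg.control_rates
    cv_rates = (cfg.conventional_case_rates if is_case
                else cfg.conventional_control_rates)
    rho = cfg.latent_correlation

    us = sample_indicators(us_rates, rho, n, rng)   # condylar, hyomental, tongue
    cv = sample_indicators(cv_rates, rho, n, rng)   # mallampati, thyromental, mouth

    cols: dict[str, np.ndarray] = {}
    for j, var in enumerate(ULTRASOUND_VARIABLES):
        loc, scale = cfg.backfill[var]
        cols[var] = backfill_continuous(us[:, j], DEFAULT_RULES[var], loc, scale, rng)

    moments = cfg.demographic_moments[group]
    # thyromental / mouth opening: truncated normal at the group's published
    # moments, on the side fixed by the binary state
    for j, var in ((1, "thyromental"), (2, "mouth_opening")):
        loc, scale = moments[var]
        cols[var] = backfill_continuous(cv[:, j], DEFAULT_RULES[var], loc, scale, rng)
    grades, probs = np.empty(n), cv[:, 0]
    pos_g, pos_p = _MALLAMPATI_POSITIVE
    neg_g, neg_p = _MALLAMPATI_NEGATIVE
    grades[probs] = rng.choice(pos_g, size=int(probs.sum()), p=pos_p)
    grades[~probs] = rng.choice(neg_g, size=int((~probs).sum()), p=neg_p)
    cols["mallampati"] = grades.astype(int)

    age_m, age_s = moments["age"]
    cols["age"] = np.clip(rng.normal(age_m, age_s, n), 18.0, 90.0)
    h_m, h_s = moments["height"]
    w_m, w_s = moments["weight"]
    cols["height"] = np.clip(rng.normal(h_m, h_s, n), 120.0, None)
    cols["weight"] = np.clip(rng.normal(w_m, w_s, n), 30.0, None)
    cols["bmi"] = cols["weight"] / (cols["height"] / 100.0) ** 2
    male_p = cfg.demographic_moments["male_fraction"][group]
    cols["sex"] = np.where(rng.random(n) < male_p, "male", "female")
    return cols


def generate_cohort(config: GeneratorConfig) -> list[PatientRecord]:
    """Generate a synthetic cohort of ``config.n_patients`` records.

    Case labels for the configured outcome follow the prevalence (binomial by
    default, fixed at ``round(n * prevalence)`` with ``exact_counts``); each
    group's indicators come from its configured rates through the shared
    latent correlation and are back-filled to continuous mm values.  The
    non-selected outcome label is set by the nested-severity fallback
    (DTI implies DL) and is approximate.  Identical ``(config, seed)`` pairs
    reproduce an identical cohort.
    """
    cfg = config
    n = cfg.n_patients
    if n < 2:
        warnings.warn("cohort of fewer than 2 patients", stacklevel=2)
    if 0 < n * cfg.prevalence < 1:
        warnings.warn("expected case count below 1; cohort may have no cases",
                      stacklevel=2)
    rng = np.random.default_rng(cfg.seed)

    if cfg.exact_counts:
        n_cases = int(round(n * cfg.prevalence))
        is_case = np.zeros(n, dtype=bool)
        is_case[rng.permutation(n)[:n_cases]] = True
    else:
        is_case = rng.random(n) < cfg.prevalence
    if is_case.sum() == 0 and cfg.prevalence > 0:
        warnings.warn("realized cohort has zero cases", stacklevel=2)

    parts = {}
    for flag in (True, False):
        m = is_case == flag
        if m.any():
            parts[flag] = (m, _sample_group(cfg, int(m.sum()), flag, rng))
    merged: dict[str, np.ndarray] = {}
    template = next(iter(parts.values()))[1]
    for key in template:
        dtype = template[key].dtype
        arr = np.empty(n, dtype=object if dtype.kind in "US" else dtype)
        for m, group_cols in parts.values():
            arr[m] = group_cols[key]
        merged[key] = arr

    # nested severity: DTI is the rarer, more severe outcome, so DTI => DL
    if cfg.outcome_mode == "DTI":
        dti = is_case
        p_extra = 0.0
        if cfg.other_prevalence > cfg.prevalence and cfg.prevalence < 1:
            p_extra = ((cfg.other_prevalence - cfg.prevalence)
                       / (1 - cfg.prevalence))
        dl = dti | (~dti & (rng.random(n) < p_extra))
    else:
        dl = is_case
        p_sub = min(cfg.other_prevalence / cfg.prevalence, 1.0) if cfg.prevalence else 0.0
        dti = dl & (rng.random(n) < p_sub)

    width = max(4, len(str(n)))
    return [
        PatientRecord(
            patient_id=f"P{i + 1:0{width}d}",
            age=float(merged["age"][i]),
            sex=str(merged["sex"][i]),
            height=float(merged["height"][i]),
            weight=float(merged["weight"][i]),
            bmi=float(merged["bmi"][i]),
            mouth_opening=float(merged["mouth_opening"][i]),
            mallampati=int(merged["mallampati"][i]),
            thyromental=float(merged["thyromental"][i]),
            tongue_thickness=float(merged["tongue_thickness"][i]),
            hyomental=float(merged["hyomental"][i]),
            condylar_mobility=float(merged["condylar_mobility"][i]),
            dl_label=bool(dl[i]),
            dti_label=bool(dti[i]),
        )
        for i in range(n)
    ]


def cohort_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    """Cohort as a DataFrame in the fixed CSV column schema."""
    rows = [
        {
            "patient_id": r.patient_id, "age": r.age,
            "sex": "M" if r.sex == "male" else "F",
            "height_cm": r.height, "weight_kg": r.weight, "bmi": r.bmi,
            "mouth_opening_mm": r.mouth_opening, "mallampati": r.mallampati,
            "thyromental_mm": r.thyromental,
            "tongue_thickness_mm": r.tongue_thickness,
            "hyomental_mm": r.hyomental,
            "condylar_mobility_mm": r.condylar_mobility,
            "dl_label": int(r.dl_label), "dti_label": int(r.dti_label),
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def frame_to_cohort(frame: pd.DataFrame) -> list[PatientRecord]:
    """Build validated records from a DataFrame in the CSV schema."""
    records = []
    for row in frame.itertuples(index=False):
        records.append(_record_from_fields(row._asdict()))
    return records


def _record_from_fields(d: Mapping) -> PatientRecord:
    sex = str(d["sex"]).strip()
    sex_full = {"M": "male", "F": "female", "male": "male", "female": "female"}.get(sex)
    if sex_full is None:
        raise ValueError(f"sex must be M or F, got {sex!r}")
    mall = float(d["mallampati"])
    if mall != int(mall):
        raise ValueError(f"mallampati must be integral, got {mall}")
    return PatientRecord(
        patient_id=str(d["patient_id"]),
        age=float(d["age"]),
        sex=sex_full,
        height=float(d["height_cm"]),
        weight=float(d["weight_kg"]),
        bmi=float(d["bmi"]),
        mouth_opening=float(d["mouth_opening_mm"]),
        mallampati=int(mall),
        thyromental=float(d["thyromental_mm"]),
        tongue_thickness=float(d["tongue_thickness_mm"]),
        hyomental=float(d["hyomental_mm"]),
        condylar_mobility=float(d["condylar_mobility_mm"]),
        dl_label=_parse_label(d["dl_label"], "dl_label"),
        dti_label=_parse_label(d["dti_label"], "dti_label"),
    )


def _parse_label(v, name: str) -> bool:
    s = str(v).strip()
    if s not in ("0", "1"):
        raise ValueError(f"{name} must be 0 or 1, got {v!r}")
    return s == "1"


def write_cohort(records: Iterable[PatientRecord], path) -> None:
    """Write a cohort CSV (UTF-8, dot decimal, fixed header, sex M/F, labels 0/1)."""
    cohort_to_frame(records).to_csv(path, index=False, lineterminator="\n")


@dataclass
class CohortReadResult:
    """Outcome of reading a cohort file.

    ``n_incomplete`` counts rows dropped for missing required fields,
    ``n_invalid`` rows dropped for failed validation; ``messages`` carries one
    line-numbered diagnostic per dropped row.
    """

    records: list[PatientRecord]
    n_incomplete: int = 0
    n_invalid: int = 0
    messages: list[str] = field(default_factory=list)

    @property
    def n_excluded(self) -> int:
        return self.n_incomplete + self.n_invalid


def read_cohort(path) -> CohortReadResult:
    """Read a cohort CSV, excluding and counting incomplete or invalid rows.

    Missing required columns raise; individual bad rows are reported with
    their 1-based file line numbers and excluded from the record list,
    mirroring how incomplete patients are dropped from a real study flow.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"cohort file missing required columns: {', '.join(missing)}")
    result = CohortReadResult(records=[])
    for idx, row in enumerate(frame.to_dict("records")):
        line_no = idx + 2  # header is line 1
        empty = [c for c in COHORT_COLUMNS if str(row[c]).strip() == ""]
        if empty:
            result.n_incomplete += 1
            result.messages.append(
                f"line {line_no}: incomplete record (missing {', '.join(empty)})"
            )
            continue
        try:
            result.records.append(_record_from_fields(row))
        except (ValueError, TypeError) as exc:
            result.n_invalid += 1
            result.messages.append(f"line {line_no}: invalid record ({exc})")
    return result
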