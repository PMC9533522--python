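import numpy as np
import pytest

from airwayus import AirwayStudy, default_config, generate_cohort


@pytest.fixture(scope="session")
def dti_cohort_exact():
    """Default-calibration DTI cohort, exact 26/974 split, fixed seed."""
    return generate_cohort(default_config("DTI", exact_counts=True, seed=7))


@pytest.fixture(scope="session")
def dti_study(dti_cohort_exact):
    return AirwayStudy.from_records(dti_cohort_exact, outcome="DTI")


@pytest.fixture(scope="session")
def dti_results(dti_study):
    return dti_study.fit()


def toy_cohort_frame(scores, labels):
    """Minimal cohort frame whose ultrasound score equals ``scores``.

    Score k is realized as k positive indicators (tongue first, then
    condylar, then hyomental); every other field is held fixed.
    """
    import pandas as pd

    rows = []
    for i, (k, lab) in enumerate(zip(scores, labels)):
        tongue = 65.0 if k >= 1 else 50.0
        condylar = 8.0 if k >= 2 else 14.0
        hyomental = 48.0 if k >= 3 else 60.0
        height, weight = 160.0 + i % 5, 60.0 + i % 7
        rows.append({
            "patient_id": f"T{i:03d}", "age": 40.0 + i,
            "sex": "M" if i % 2 == 0 else "F",
            "height_cm": height, "weight_kg": weight,
            "bmi": weight / (height / 100) ** 2,
            "mouth_opening_mm": 40.0, "mallampati": (i % 4) + 1,
            "thyromental_mm": 75.0, "tongue_thickness_mm": tongue,
            "hyomental_mm": hyomental, "condylar_mobility_mm": condylar,
            "dl_label": int(lab), "dti_label": int(lab),
        })
    return pd.DataFrame(rows)
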