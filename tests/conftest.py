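from __future__ import annotations

import numpy as np
import pytest

from alcsofa.cohort import ClinicalDay1Record, SurvivalOutcome, VasopressorExposure


def make_record(patient_id: str = "p1", **overrides) -> ClinicalDay1Record:
    """A clean, all-normal patient; override any field."""
    defaults = dict(
        patient_id=patient_id,
        age=60.0,
        sex="female",
        pf_ratio=450.0,
        respiratory_support=False,
        platelets=250.0,
        bilirubin=0.5,
        map=85.0,
        vasopressors=VasopressorExposure(),
        gcs=15,
        creatinine=0.8,
        urine_output_24h=2000.0,
        alc=1.5,
        icu_los_hours=100.0,
        repeat_admission=False,
        outcome=SurvivalOutcome(time_days=90.0, event=False),
    )
    defaults.update(overrides)
    return ClinicalDay1Record(**defaults)


@pytest.fixture
def worst_record() -> ClinicalDay1Record:
    """Worst category in every organ system, lymphocytes < 0.36."""
    return make_record(
        "worst",
        pf_ratio=80.0,
        respiratory_support=True,
        platelets=10.0,
        bilirubin=15.0,
        map=60.0,
        vasopressors=VasopressorExposure(norepinephrine=0.5, norepinephrine_ge_1h=True),
        gcs=3,
        creatinine=6.0,
        urine_output_24h=None,
        alc=0.1,
        outcome=SurvivalOutcome(time_days=2.0, event=True),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
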