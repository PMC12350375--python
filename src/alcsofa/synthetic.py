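"""Synthetic sepsis-like cohort generator with known ground truth.

Two correlated latent axes drive each patient: organ-failure severity ``z``
and immune deficit ``w``.  The six organ-system sub-scores follow a
proportional-odds shift in ``z``; raw measurements are then drawn uniformly
inside the band for the selected sub-score, so re-scoring the raw values
recovers the intended sub-score exactly (band inversion).  The lymphocyte
count is lognormal with a negative loading on ``w``.  Death times are
exponential with rate ``baseline_hazard * exp(beta_severity*SOFA +
beta_immune*w)``, administratively censored.

Default parameters are calibrated so that, at large n, 28-day mortality is
about 21.3% and the lymphocyte count has mean ~1.07 and SD ~0.68 x10^9/L,
with nonsurvivors averaging lower counts than survivors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .cohort import ClinicalDay1Record, SurvivalOutcome, VasopressorExposure

__all__ = ["GeneratorParams", "SyntheticTruth", "generate_cohort", "inject_exclusion_cases"]


# Proportional-odds cutpoints shared by all six components: the latent
# component propensity is z + Logistic(0,1); the sub-score counts the
# cutpoints exceeded.
_COMPONENT_CUTPOINTS = np.array([0.2, 1.2, 2.2, 3.2])

# Uniform sampling band (low, high) per component and sub-score; drawing
# raw values inside the band guarantees re-scoring returns the sub-score.
_PF_BANDS = [(400.0, 500.0), (300.0, 400.0), (200.0, 300.0), (100.0, 200.0), (40.0, 100.0)]
_PLT_BANDS = [(150.0, 450.0), (100.0, 150.0), (50.0, 100.0), (20.0, 50.0), (2.0, 20.0)]
_BILI_BANDS = [(0.1, 1.2), (1.2, 2.0), (2.0, 6.0), (6.0, 12.0), (12.0, 25.0)]
_CREAT_BANDS = [(0.4, 1.2), (1.2, 2.0), (2.0, 3.5), (3.5, 5.0), (5.0, 9.0)]
_GCS_CHOICES = [(15,), (13, 14), (10, 11, 12), (6, 7, 8, 9), (3, 4, 5)]


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the cohort generator; defaults are the calibrated set-points."""

    n: int = 1000
    beta_severity: float = 0.15  # log-hazard per SOFA point
    beta_immune: float = 0.25  # log-hazard per unit immune deficit
    baseline_hazard: float = 0.00313  # per-day rate at SOFA 0, w 0
    alc_logmean: float = -0.1021
    alc_logsd: float = 0.3702  # residual log-scale noise
    immune_alc_loading: float = 0.45  # log-ALC drop per unit immune deficit
    severity_immune_corr: float = 0.2
    censor_day: float = 90.0
    missing_rates: dict[str, float] = field(default_factory=dict)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if not -1.0 <= self.severity_immune_corr <= 1.0:
            raise ValueError("severity_immune_corr must be in [-1, 1]")
        for name, rate in self.missing_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missing rate for {name!r} not in [0, 1]")


@dataclass(frozen=True)
class SyntheticTruth:
    """Latent variables and intended sub-scores, kept for recovery tests."""

    z: np.ndarray
    w: np.ndarray
    component_scores: np.ndarray  # (n, 6): resp, coag, hepatic, cardio, cns, renal
    sofa_total: np.ndarray
    alc_score: np.ndarray
    params: GeneratorParams


_MISSABLE = ("pf_ratio", "platelets", "bilirubin", "map", "gcs", "creatinine", "urine_output_24h")


def _draw_in_band(rng: np.random.Generator, bands, scores: np.ndarray) -> np.ndarray:
    lows = np.array([b[0] for b in bands])
    highs = np.array([b[1] for b in bands])
    return rng.uniform(lows[scores], highs[scores])


def generate_cohort(params: GeneratorParams) -> tuple[list[ClinicalDay1Record], SyntheticTruth]:
    """Generate a cohort plus its ground truth; deterministic given seed."""
    rng = np.random.default_rng(params.seed)
    n = params.n
    rho = params.severity_immune_corr

    z = rng.standard_normal(n)
    w = rho * z + np.sqrt(1 - rho**2) * rng.standard_normal(n)

    # six ordinal sub-scores via a shared proportional-odds shift in z
    noise = rng.logistic(size=(n, 6))
    latent = z[:, None] + noise
    comp = (latent[:, :, None] > _COMPONENT_CUTPOINTS[None, None, :]).sum(axis=2)
    sofa = comp.sum(axis=1)

    pf = _draw_in_band(rng, _PF_BANDS, comp[:, 0])
    resp_support = comp[:, 0] >= 3
    plt = _draw_in_band(rng, _PLT_BANDS, comp[:, 1])
    bili = _draw_in_band(rng, _BILI_BANDS, comp[:, 2])
    creat = _draw_in_band(rng, _CREAT_BANDS, comp[:, 5])
    urine = rng.uniform(1000.0, 3000.0, size=n)
    gcs = np.array([rng.choice(_GCS_CHOICES[s]) for s in comp[:, 4]])

    # cardiovascular: MAP plus agent doses chosen per band
    cv = comp[:, 3]
    map_mmhg = np.where(cv == 1, rng.uniform(45, 70, n), rng.uniform(70, 95, n))
    map_mmhg = np.where(cv >= 2, rng.uniform(55, 90, n), map_mmhg)
    dop = np.where(cv == 2, rng.uniform(0.5, 5.0, n), 0.0)
    nor = np.where(cv == 3, rng.uniform(0.02, 0.1, n), 0.0)
    nor = np.where(cv == 4, rng.uniform(0.12, 0.6, n), nor)

    alc = np.exp(
        params.alc_logmean
        - params.immune_alc_loading * w
        + params.alc_logsd * rng.standard_normal(n)
    )
    alc = np.round(np.maximum(alc, 1e-3), 3)  # rounded before binning so records re-score identically
    alc_score = np.digitize(-alc, -np.array([1.0, 0.78, 0.58, 0.36]), right=True)

    rate = params.baseline_hazard * np.exp(params.beta_severity * sofa + params.beta_immune * w)
    death_time = rng.exponential(1.0 / rate)
    event = death_time <= params.censor_day
    time_days = np.minimum(death_time, params.censor_day)

    age = np.clip(rng.normal(67.0, 14.0, n), 18.0, 100.0)
    sex = np.where(rng.random(n) < 0.577, "male", "female")
    icu_los = rng.uniform(30.0, 700.0, n)

    miss = {
        name: rng.random(n) < params.missing_rates.get(name, 0.0) for name in _MISSABLE
    }

    records: list[ClinicalDay1Record] = []
    for i in range(n):
        vaso = VasopressorExposure(
            dopamine=float(dop[i]),
            norepinephrine=float(nor[i]),
            dopamine_ge_1h=True if dop[i] > 0 else None,
            norepinephrine_ge_1h=True if nor[i] > 0 else None,
        )
        records.append(
            ClinicalDay1Record(
                patient_id=f"synth-{i:06d}",
                age=float(np.round(age[i], 2)),
                sex=str(sex[i]),
                pf_ratio=None if miss["pf_ratio"][i] else float(pf[i]),
                respiratory_support=bool(resp_support[i]),
                platelets=None if miss["platelets"][i] else float(plt[i]),
                bilirubin=None if miss["bilirubin"][i] else float(bili[i]),
                map=None if miss["map"][i] else float(map_mmhg[i]),
                vasopressors=vaso,
                gcs=None if miss["gcs"][i] else int(gcs[i]),
                creatinine=None if miss["creatinine"][i] else float(creat[i]),
                urine_output_24h=None if miss["urine_output_24h"][i] else float(urine[i]),
                alc=float(alc[i]),
                icu_los_hours=float(np.round(icu_los[i], 1)),
                repeat_admission=False,
                outcome=SurvivalOutcome(time_days=float(time_days[i]), event=bool(event[i])),
            )
        )

    truth = SyntheticTruth(
        z=z,
        w=w,
        component_scores=comp,
        sofa_total=sofa,
        alc_score=alc_score,
        params=params,
    )
    return records, truth


def inject_exclusion_cases(
    records: Sequence[ClinicalDay1Record],
    counts: dict[str, int],
    seed: Optional[int] = None,
) -> list[ClinicalDay1Record]:
    """Append records each violating exactly one exclusion rule.

    ``counts`` maps rule name (``repeat_admission``, ``missing_28d_status``,
    ``age_under_18``, ``icu_stay_le_24h``, ``alc_missing``,
    ``alc_outlier``) to the number of violating records to add.
    """
    rng = np.random.default_rng(seed)
    known = {
        "repeat_admission",
        "missing_28d_status",
        "age_under_18",
        "icu_stay_le_24h",
        "alc_missing",
        "alc_outlier",
    }
    for rule, count in counts.items():
        if rule not in known:
            raise ValueError(f"unknown exclusion rule: {rule!r}")
        if count < 0:
            raise ValueError(f"negative count for rule {rule!r}")

    out = list(records)
    serial = 0

    def template(rule: str) -> ClinicalDay1Record:
        nonlocal serial
        serial += 1
        return ClinicalDay1Record(
            patient_id=f"inject-{rule}-{serial:04d}",
            age=float(rng.uniform(30, 80)),
            sex="female" if rng.random() < 0.5 else "male",
            pf_ratio=420.0,
            platelets=250.0,
            bilirubin=0.6,
            map=82.0,
            gcs=15,
            creatinine=0.9,
            urine_output_24h=1800.0,
            alc=1.1,
            icu_los_hours=120.0,
            outcome=SurvivalOutcome(time_days=90.0, event=False),
        )

    for rule, count in counts.items():
        for _ in range(count):
            rec = template(rule)
            if rule == "repeat_admission":
                rec = replace(rec, repeat_admission=True)
            elif rule == "missing_28d_status":
                rec = replace(rec, outcome=SurvivalOutcome(time_days=10.0, event=False))
            elif rule == "age_under_18":
                rec = replace(rec, age=17.0)
            elif rule == "icu_stay_le_24h":
                rec = replace(rec, icu_los_hours=20.0)
            elif rule == "alc_missing":
                rec = replace(rec, alc=None)
            elif rule == "alc_outlier":
                rec = replace(rec, alc=30.0)
            out.append(rec)
    return out
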