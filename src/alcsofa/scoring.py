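"""ALC-SOFA scoring: six organ-system sub-scores plus a lymphocyte score.

Each sub-score is an integer 0-4; the six-system total spans 0-24 and the
combined total (adding the lymphocyte score) spans 0-28.

Band conventions
----------------
Printed clinical bands such as "1.2-1.9 / 2.0-5.9" leave gaps on the real
line; every band here is right-open on the worst direction axis
([1.2, 2.0), [2.0, 6.0), ...), so coverage is continuous.  Other closures:

* dopamine exactly 5.0 ug/kg/min scores 2;
* PaO2/FiO2 below 200 without respiratory support caps at 2 (categories 3-4
  require support);
* lymphocyte count exactly 1.0 x10^9/L scores 0 (lymphopenia is strictly
  below 1.0).

Missing inputs other than the lymphocyte count contribute 0 and are flagged
(``strict=True`` raises instead).  A missing lymphocyte count is always an
error: such patients must be excluded upstream, never scored 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .cohort import ClinicalDay1Record, VasopressorExposure

__all__ = [
    "SofaBreakdown",
    "MissingComponentError",
    "score_respiratory",
    "score_coagulation",
    "score_hepatic",
    "score_cardiovascular",
    "score_cns",
    "score_renal",
    "score_alc",
    "compute_sofa",
    "compute_alc_sofa",
    "ALC_CUTOFFS",
]

# Lower edges of the lymphocyte bins for scores 4..1 (x10^9/L); >= 1.0 -> 0.
ALC_CUTOFFS: tuple[float, ...] = (0.36, 0.58, 0.78, 1.0)


class MissingComponentError(ValueError):
    """A required input is absent in strict mode (or ALC is absent)."""


@dataclass
class SofaBreakdown:
    """Per-system scores, totals, and provenance flags for one patient."""

    respiratory: int
    coagulation: int
    hepatic: int
    cardiovascular: int
    cns: int
    renal: int
    sofa_total: int
    alc_score: Optional[int] = None
    alc_sofa_total: Optional[int] = None
    flags: list[str] = field(default_factory=list)

    @property
    def components(self) -> tuple[int, int, int, int, int, int]:
        return (
            self.respiratory,
            self.coagulation,
            self.hepatic,
            self.cardiovascular,
            self.cns,
            self.renal,
        )


def score_respiratory(pf_ratio: Optional[float], respiratory_support: bool) -> int:
    """Respiratory sub-score from worst PaO2/FiO2 (mmHg) and support status."""
    if pf_ratio is None:
        return 0
    if pf_ratio <= 0:
        raise ValueError(f"PaO2/FiO2 must be positive, got {pf_ratio}")
    if pf_ratio >= 400:
        return 0
    if pf_ratio >= 300:
        return 1
    if not respiratory_support:
        return 2  # categories 3-4 require respiratory support
    if pf_ratio >= 200:
        return 2
    if pf_ratio >= 100:
        return 3
    return 4


def score_coagulation(platelets: Optional[float]) -> int:
    """Coagulation sub-score from worst (lowest) platelets, x10^3/uL."""
    if platelets is None:
        return 0
    if platelets < 0:
        raise ValueError(f"negative platelet count: {platelets}")
    if platelets >= 150:
        return 0
    if platelets >= 100:
        return 1
    if platelets >= 50:
        return 2
    if platelets >= 20:
        return 3
    return 4


def score_hepatic(bilirubin: Optional[float]) -> int:
    """Hepatic sub-score from worst (highest) bilirubin, mg/dL."""
    if bilirubin is None:
        return 0
    if bilirubin < 0:
        raise ValueError(f"negative bilirubin: {bilirubin}")
    if bilirubin < 1.2:
        return 0
    if bilirubin < 2.0:
        return 1
    if bilirubin < 6.0:
        return 2
    if bilirubin < 12.0:
        return 3
    return 4


def _qualifies(dose: float, ge_1h: Optional[bool]) -> bool:
    # duration flag absent -> assume the agent ran >= 1 h (permissive default)
    return dose > 0 and (ge_1h is None or ge_1h)


def score_cardiovascular(map_mmhg: Optional[float], vaso: VasopressorExposure) -> int:
    """Cardiovascular sub-score from worst (lowest) MAP and adrenergic doses.

    Doses are ug/kg/min and only count when sustained for >= 1 h; the
    highest applicable category wins.  Dopamine exactly 5.0 scores 2.
    """
    if map_mmhg is not None and map_mmhg <= 0:
        raise ValueError(f"non-positive MAP: {map_mmhg}")
    dop = vaso.dopamine if _qualifies(vaso.dopamine, vaso.dopamine_ge_1h) else 0.0
    dob = vaso.dobutamine if _qualifies(vaso.dobutamine, vaso.dobutamine_ge_1h) else 0.0
    epi = vaso.epinephrine if _qualifies(vaso.epinephrine, vaso.epinephrine_ge_1h) else 0.0
    nor = vaso.norepinephrine if _qualifies(vaso.norepinephrine, vaso.norepinephrine_ge_1h) else 0.0

    if dop > 15 or epi > 0.1 or nor > 0.1:
        return 4
    if dop > 5 or epi > 0 or nor > 0:
        return 3
    if dop > 0 or dob > 0:
        return 2
    if map_mmhg is not None and map_mmhg < 70:
        return 1
    return 0


def score_cns(gcs: Optional[int]) -> int:
    """Central-nervous-system sub-score from worst (lowest) GCS."""
    if gcs is None:
        return 0
    if not 3 <= gcs <= 15:
        raise ValueError(f"GCS out of [3,15]: {gcs}")
    if gcs == 15:
        return 0
    if gcs >= 13:
        return 1
    if gcs >= 10:
        return 2
    if gcs >= 6:
        return 3
    return 4


def score_renal(creatinine: Optional[float], urine_output_24h: Optional[float]) -> int:
    """Renal sub-score: max of the creatinine band and the urine-output band."""
    if creatinine is not None and creatinine < 0:
        raise ValueError(f"negative creatinine: {creatinine}")
    if urine_output_24h is not None and urine_output_24h < 0:
        raise ValueError(f"negative urine output: {urine_output_24h}")

    creat_score = 0
    if creatinine is not None:
        if creatinine >= 5.0:
            creat_score = 4
        elif creatinine >= 3.5:
            creat_score = 3
        elif creatinine >= 2.0:
            creat_score = 2
        elif creatinine >= 1.2:
            creat_score = 1

    urine_score = 0
    if urine_output_24h is not None:
        if urine_output_24h < 200:
            urine_score = 4
        elif urine_output_24h < 500:
            urine_score = 3

    return max(creat_score, urine_score)


def score_alc(alc: Optional[float]) -> int:
    """Lymphocyte score from the first-day minimum ALC (x10^9/L).

    >= 1.0 -> 0; [0.78, 1.0) -> 1; [0.58, 0.78) -> 2; [0.36, 0.58) -> 3;
    < 0.36 -> 4.  Absent ALC is an error (exclusion criterion, not a 0).
    """
    if alc is None:
        raise MissingComponentError("ALC is absent; such patients must be excluded, not scored")
    if alc < 0:
        raise ValueError(f"negative ALC: {alc}")
    score = 4
    for cutoff in ALC_CUTOFFS:
        if alc >= cutoff:
            score -= 1
    return score


_COMPONENT_INPUTS = {
    "respiratory": ("pf_ratio",),
    "coagulation": ("platelets",),
    "hepatic": ("bilirubin",),
    "cns": ("gcs",),
}


def compute_sofa(record: ClinicalDay1Record, strict: bool = False) -> SofaBreakdown:
    """Six-system SOFA breakdown for one patient (lymphocyte fields unset).

    With ``strict=True`` a missing component input raises
    :class:`MissingComponentError` instead of contributing 0.
    """
    flags: list[str] = []
    for component, fields in _COMPONENT_INPUTS.items():
        for name in fields:
            if getattr(record, name) is None:
                if strict:
                    raise MissingComponentError(f"{record.patient_id}: missing {name} for {component} component")
                flags.append(f"{component}: missing {name} -> 0")

    if record.creatinine is None and record.urine_output_24h is None:
        if strict:
            raise MissingComponentError(f"{record.patient_id}: missing creatinine and urine output for renal component")
        flags.append("renal: missing creatinine and urine output -> 0")
    elif record.creatinine is None:
        flags.append("renal: scored on urine output only")

    if record.map is None and not record.vasopressors.any_vasopressor:
        if strict:
            raise MissingComponentError(f"{record.patient_id}: missing MAP for cardiovascular component")
        flags.append("cardiovascular: missing map -> 0")

    components = SofaBreakdown(
        respiratory=score_respiratory(record.pf_ratio, record.respiratory_support),
        coagulation=score_coagulation(record.platelets),
        hepatic=score_hepatic(record.bilirubin),
        cardiovascular=score_cardiovascular(record.map, record.vasopressors),
        cns=score_cns(record.gcs),
        renal=score_renal(record.creatinine, record.urine_output_24h),
        sofa_total=0,
        flags=flags,
    )
    components.sofa_total = sum(components.components)
    return components


def compute_alc_sofa(record: ClinicalDay1Record, strict: bool = False) -> SofaBreakdown:
    """Full breakdown including the lymphocyte score and combined total."""
    breakdown = compute_sofa(record, strict=strict)
    breakdown.alc_score = score_alc(record.alc)
    breakdown.alc_sofa_total = breakdown.sofa_total + breakdown.alc_score
    return breakdown
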