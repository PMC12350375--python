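"""Patient-level cohort model: domain types and CSV reading/writing.

Units are fixed and never auto-converted:

* bilirubin, creatinine — mg/dL
* platelets — x10^3/uL
* absolute lymphocyte count (ALC) — x10^9/L (1.0 x10^9/L == 1000 cells/uL)
* vasopressor doses — ug/kg/min
* mean arterial pressure, PaO2/FiO2 — mmHg
* survival time — days; ICU length of stay — hours

Missing values are represented as ``None`` (empty cell in CSV), never as 0.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "VasopressorExposure",
    "SurvivalOutcome",
    "ClinicalDay1Record",
    "CohortSchemaError",
    "CohortParseError",
    "horizon_label",
    "read_cohort",
    "write_cohort",
    "CANONICAL_COLUMNS",
]


class CohortSchemaError(ValueError):
    """A required column is missing or the schema mapping is invalid."""


class CohortParseError(ValueError):
    """A cell could not be parsed; message names the row and column."""


@dataclass(frozen=True)
class VasopressorExposure:
    """Maximum sustained day-1 doses (ug/kg/min); 0 means not given.

    ``duration_ge_1h`` flags whether each adrenergic agent ran for at least
    one hour; ``None`` means unrecorded (scoring treats that permissively).
    ``any_other_vasopressor`` covers vasopressin / phenylephrine / milrinone,
    which count toward the vasopressor-use covariate but never toward the
    cardiovascular sub-score.
    """

    dopamine: float = 0.0
    dobutamine: float = 0.0
    epinephrine: float = 0.0
    norepinephrine: float = 0.0
    any_other_vasopressor: bool = False
    dopamine_ge_1h: Optional[bool] = None
    dobutamine_ge_1h: Optional[bool] = None
    epinephrine_ge_1h: Optional[bool] = None
    norepinephrine_ge_1h: Optional[bool] = None

    def __post_init__(self) -> None:
        for name in ("dopamine", "dobutamine", "epinephrine", "norepinephrine"):
            dose = getattr(self, name)
            if dose < 0:
                raise ValueError(f"negative {name} dose: {dose}")

    @property
    def any_vasopressor(self) -> bool:
        """True if any vasopressor (incl. non-scored agents) was given."""
        return (
            self.dopamine > 0
            or self.dobutamine > 0
            or self.epinephrine > 0
            or self.norepinephrine > 0
            or self.any_other_vasopressor
        )


@dataclass(frozen=True)
class SurvivalOutcome:
    """Time from ICU admission to death or last follow-up, in days."""

    time_days: float
    event: bool

    def __post_init__(self) -> None:
        if self.time_days < 0:
            raise ValueError(f"negative survival time: {self.time_days}")

    def label_at(self, horizon_days: float) -> Optional[int]:
        return horizon_label(self.time_days, self.event, horizon_days)


def horizon_label(time_days: float, event: bool, horizon_days: float) -> Optional[int]:
    """Binary death label at a horizon, or ``None`` if undefined.

    Defined iff the patient died on or before the horizon (1) or was
    followed at least to the horizon (0); censored earlier -> ``None``.
    """
    if event and time_days <= horizon_days:
        return 1
    if time_days >= horizon_days:
        return 0
    return None


@dataclass(frozen=True)
class ClinicalDay1Record:
    """One patient's first-day worst measurements, covariates and outcome.

    Worst direction per field: lowest PaO2/FiO2, platelets, MAP, GCS and
    ALC; highest bilirubin and creatinine.
    """

    patient_id: str
    age: Optional[float] = None
    sex: Optional[str] = None  # "male" | "female"
    pf_ratio: Optional[float] = None
    respiratory_support: bool = False
    platelets: Optional[float] = None
    bilirubin: Optional[float] = None
    map: Optional[float] = None
    vasopressors: VasopressorExposure = field(default_factory=VasopressorExposure)
    gcs: Optional[int] = None
    creatinine: Optional[float] = None
    urine_output_24h: Optional[float] = None
    alc: Optional[float] = None
    icu_los_hours: Optional[float] = None
    repeat_admission: bool = False
    covariates: Mapping[str, Optional[float]] = field(default_factory=dict)
    outcome: Optional[SurvivalOutcome] = None

    def __post_init__(self) -> None:
        if self.age is not None and self.age < 0:
            raise ValueError(f"negative age for {self.patient_id}")
        if self.sex is not None and self.sex not in ("male", "female"):
            raise ValueError(f"unknown sex code {self.sex!r} for {self.patient_id}")
        if self.gcs is not None and not (3 <= self.gcs <= 15):
            raise ValueError(f"GCS out of [3,15] for {self.patient_id}: {self.gcs}")
        if self.pf_ratio is not None and self.pf_ratio <= 0:
            raise ValueError(f"non-positive PaO2/FiO2 for {self.patient_id}")
        for name in ("platelets", "bilirubin", "map", "creatinine", "urine_output_24h", "alc"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"negative {name} for {self.patient_id}: {v}")


# Canonical CSV columns (in write order). Any extra column in an input file
# is carried along as a named covariate.
CANONICAL_COLUMNS: tuple[str, ...] = (
    "patient_id",
    "age",
    "sex",
    "pf_ratio",
    "respiratory_support",
    "platelets",
    "bilirubin",
    "map",
    "dopamine",
    "dobutamine",
    "epinephrine",
    "norepinephrine",
    "any_other_vasopressor",
    "dopamine_ge_1h",
    "dobutamine_ge_1h",
    "epinephrine_ge_1h",
    "norepinephrine_ge_1h",
    "gcs",
    "creatinine",
    "urine_output_24h",
    "alc",
    "icu_los_hours",
    "repeat_admission",
    "time_days",
    "event",
)

_REQUIRED = ("patient_id", "alc", "time_days", "event")

_BOOL_COLUMNS = frozenset(
    {
        "respiratory_support",
        "any_other_vasopressor",
        "dopamine_ge_1h",
        "dobutamine_ge_1h",
        "epinephrine_ge_1h",
        "norepinephrine_ge_1h",
        "repeat_admission",
        "event",
    }
)

_TRUE = {"1", "true", "t", "yes", "y"}
_FALSE = {"0", "false", "f", "no", "n"}


def _parse_float(cell: str, row: int, col: str) -> Optional[float]:
    cell = cell.strip()
    if cell == "":
        return None
    try:
        value = float(cell)
    except ValueError:
        raise CohortParseError(f"row {row}, column {col!r}: unparsable numeric value {cell!r}")
    if not math.isfinite(value):
        raise CohortParseError(f"row {row}, column {col!r}: non-finite value {cell!r}")
    return value


def _parse_bool(cell: str, row: int, col: str) -> Optional[bool]:
    cell = cell.strip().lower()
    if cell == "":
        return None
    if cell in _TRUE:
        return True
    if cell in _FALSE:
        return False
    raise CohortParseError(f"row {row}, column {col!r}: unparsable boolean value {cell!r}")


def read_cohort(
    path: str,
    schema: Optional[Mapping[str, str]] = None,
) -> list[ClinicalDay1Record]:
    """Read a cohort CSV into records.

    Parameters
    ----------
    path
        CSV file with a header row; UTF-8, comma-separated, ``.`` decimal,
        empty cell = missing.
    schema
        Optional map from canonical field name to source column name; only
        the renamed fields need to be listed.

    Raises
    ------
    CohortSchemaError
        If a required column (``patient_id``, ``alc``, ``time_days``,
        ``event``) is absent.
    CohortParseError
        On an unparsable cell, naming the row and column.
    """
    colmap = {name: name for name in CANONICAL_COLUMNS}
    if schema:
        for canonical, source in schema.items():
            if canonical not in CANONICAL_COLUMNS:
                raise CohortSchemaError(f"unknown canonical field in schema: {canonical!r}")
            colmap[canonical] = source

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames
        if header is None:
            raise CohortSchemaError(f"{path}: missing header row")
        for required in _REQUIRED:
            if colmap[required] not in header:
                raise CohortSchemaError(f"{path}: required column {colmap[required]!r} (field {required!r}) not found")
        canonical_sources = set(colmap.values())
        extra_cols = [c for c in header if c not in canonical_sources]

        records: list[ClinicalDay1Record] = []
        for i, row in enumerate(reader, start=2):  # header is line 1
            records.append(_row_to_record(row, i, colmap, extra_cols))
    return records


def _row_to_record(
    row: Mapping[str, str],
    line: int,
    colmap: Mapping[str, str],
    extra_cols: Sequence[str],
) -> ClinicalDay1Record:
    def cell(field_name: str) -> str:
        return row.get(colmap[field_name]) or ""

    def num(field_name: str) -> Optional[float]:
        return _parse_float(cell(field_name), line, colmap[field_name])

    def boolean(field_name: str) -> Optional[bool]:
        return _parse_bool(cell(field_name), line, colmap[field_name])

    sex_raw = cell("sex").strip().lower()
    if sex_raw in ("m", "male"):
        sex: Optional[str] = "male"
    elif sex_raw in ("f", "female"):
        sex = "female"
    elif sex_raw == "":
        sex = None
    else:
        raise CohortParseError(f"row {line}, column {colmap['sex']!r}: unknown sex code {sex_raw!r}")

    gcs_val = num("gcs")
    time_days = num("time_days")
    event = boolean("event")
    outcome = None
    if time_days is not None and event is not None:
        outcome = SurvivalOutcome(time_days=time_days, event=event)

    vaso = VasopressorExposure(
        dopamine=num("dopamine") or 0.0,
        dobutamine=num("dobutamine") or 0.0,
        epinephrine=num("epinephrine") or 0.0,
        norepinephrine=num("norepinephrine") or 0.0,
        any_other_vasopressor=bool(boolean("any_other_vasopressor")),
        dopamine_ge_1h=boolean("dopamine_ge_1h"),
        dobutamine_ge_1h=boolean("dobutamine_ge_1h"),
        epinephrine_ge_1h=boolean("epinephrine_ge_1h"),
        norepinephrine_ge_1h=boolean("norepinephrine_ge_1h"),
    )

    covariates = {c: _parse_float(row.get(c) or "", line, c) for c in extra_cols}

    try:
        return ClinicalDay1Record(
            patient_id=cell("patient_id").strip(),
            age=num("age"),
            sex=sex,
            pf_ratio=num("pf_ratio"),
            respiratory_support=bool(boolean("respiratory_support")),
            platelets=num("platelets"),
            bilirubin=num("bilirubin"),
            map=num("map"),
            vasopressors=vaso,
            gcs=int(gcs_val) if gcs_val is not None else None,
            creatinine=num("creatinine"),
            urine_output_24h=num("urine_output_24h"),
            alc=num("alc"),
            icu_los_hours=num("icu_los_hours"),
            repeat_admission=bool(boolean("repeat_admission")),
            covariates=covariates,
            outcome=outcome,
        )
    except ValueError as exc:
        raise CohortParseError(f"row {line}: {exc}") from exc


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float) and value.is_integer():
        return str(int(value))
    return str(value)


def write_cohort(records: Iterable[ClinicalDay1Record], path: str) -> None:
    """Write records to CSV such that ``read_cohort`` round-trips exactly."""
    records = list(records)
    covariate_cols: list[str] = []
    seen = set()
    for rec in records:
        for name in rec.covariates:
            if name not in seen:
                seen.add(name)
                covariate_cols.append(name)

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(CANONICAL_COLUMNS) + covariate_cols)
        for rec in records:
            v = rec.vasopressors
            out = rec.outcome
            row = [
                rec.patient_id,
                _fmt(rec.age),
                _fmt(rec.sex),
                _fmt(rec.pf_ratio),
                _fmt(rec.respiratory_support),
                _fmt(rec.platelets),
                _fmt(rec.bilirubin),
                _fmt(rec.map),
                _fmt(v.dopamine),
                _fmt(v.dobutamine),
                _fmt(v.epinephrine),
                _fmt(v.norepinephrine),
                _fmt(v.any_other_vasopressor),
                _fmt(v.dopamine_ge_1h),
                _fmt(v.dobutamine_ge_1h),
                _fmt(v.epinephrine_ge_1h),
                _fmt(v.norepinephrine_ge_1h),
                _fmt(rec.gcs),
                _fmt(rec.creatinine),
                _fmt(rec.urine_output_24h),
                _fmt(rec.alc),
                _fmt(rec.icu_los_hours),
                _fmt(rec.repeat_admission),
                _fmt(out.time_days if out else None),
                _fmt(out.event if out else None),
            ]
            row.extend(_fmt(rec.covariates.get(c)) for c in covariate_cols)
            writer.writerow(row)


def with_outcome(record: ClinicalDay1Record, outcome: SurvivalOutcome) -> ClinicalDay1Record:
    return replace(record, outcome=outcome)
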