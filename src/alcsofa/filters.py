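"""Cohort exclusion cascade with attrition logging.

Rules are applied sequentially, in this fixed order:

1. repeat hospital admission;
2. 28-day survival status not determinable (neither death within 28 days
   nor follow-up reaching 28 days);
3. age under 18;
4. ICU stay of 24 hours or less;
5. first-day lymphocyte count absent;
6. lymphocyte count outside Tukey's fences, with the fences computed on the
   survivors of steps 1-5 (two-sided, k = 1.5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .cohort import ClinicalDay1Record

__all__ = ["AttritionLog", "AttritionStep", "tukey_fences", "apply_exclusions"]


@dataclass(frozen=True)
class AttritionStep:
    rule: str
    n_excluded: int
    n_remaining: int


@dataclass
class AttritionLog:
    """Ordered record of each exclusion rule's effect."""

    n_input: int
    steps: list[AttritionStep]

    @property
    def n_final(self) -> int:
        return self.steps[-1].n_remaining if self.steps else self.n_input

    def as_dicts(self) -> list[dict]:
        return [
            {"rule": s.rule, "n_excluded": s.n_excluded, "n_remaining": s.n_remaining}
            for s in self.steps
        ]


def tukey_fences(values: Sequence[float], k: float = 1.5) -> tuple[float, float]:
    """Tukey's outlier fences (Q1 - k*IQR, Q3 + k*IQR).

    Quartiles use linear interpolation between order statistics (the
    common default).  Requires at least 4 finite values.
    """
    vals = list(values)
    if len(vals) < 4:
        raise ValueError(f"need at least 4 values for Tukey fences, got {len(vals)}")
    if any(not math.isfinite(v) for v in vals):
        raise ValueError("non-finite value in Tukey fence input")
    q1, q3 = np.percentile(vals, [25, 75])
    iqr = q3 - q1
    return float(q1 - k * iqr), float(q3 + k * iqr)


def _missing_28d_status(rec: ClinicalDay1Record) -> bool:
    if rec.outcome is None:
        return True
    return rec.outcome.label_at(28) is None


_RULES: list[tuple[str, Callable[[ClinicalDay1Record], bool]]] = [
    ("repeat_admission", lambda r: r.repeat_admission),
    ("missing_28d_status", _missing_28d_status),
    ("age_under_18", lambda r: r.age is not None and r.age < 18),
    ("icu_stay_le_24h", lambda r: r.icu_los_hours is not None and r.icu_los_hours <= 24),
    ("alc_missing", lambda r: r.alc is None),
]


def apply_exclusions(
    records: Sequence[ClinicalDay1Record],
    tukey_k: float = 1.5,
) -> tuple[list[ClinicalDay1Record], AttritionLog]:
    """Apply the exclusion cascade; returns kept records and the attrition log.

    Deterministic: the same input always yields the same output and log.
    An empty result is allowed (the Tukey step is skipped below 4 patients).
    """
    log = AttritionLog(n_input=len(records), steps=[])
    kept = list(records)
    for rule, predicate in _RULES:
        survivors = [r for r in kept if not predicate(r)]
        log.steps.append(AttritionStep(rule, len(kept) - len(survivors), len(survivors)))
        kept = survivors

    if len(kept) >= 4:
        lower, upper = tukey_fences([r.alc for r in kept], k=tukey_k)
        survivors = [r for r in kept if lower <= r.alc <= upper]
    else:
        survivors = kept
    log.steps.append(AttritionStep("alc_outside_tukey_fences", len(kept) - len(survivors), len(survivors)))
    return survivors, log
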