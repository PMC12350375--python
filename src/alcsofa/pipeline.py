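"""Pipeline orchestration: filter -> score -> evaluate, with a
machine-readable report.

The report JSON carries, per horizon (7/28/90 days by default) and per
subgroup, both AUROCs with the paired DeLong comparison, continuous NRI
and IDI with bootstrap CIs, and operating-point metrics for each score,
plus the attrition log, a config echo and the seed.  Identical config and
seed always produce a byte-identical report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .cohort import ClinicalDay1Record, horizon_label, read_cohort
from .discrimination import (
    SeparationError,
    auroc,
    delong_compare,
    operating_point,
    reclassification,
)
from .filters import AttritionLog, apply_exclusions
from .scoring import SofaBreakdown, compute_alc_sofa
from .survival import class_curves, mortality_at

logger = logging.getLogger("alcsofa")

SCHEMA_VERSION = "1.0"

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "evaluate_scores",
    "subgroup_evaluate",
    "score_cohort",
    "write_report",
    "validate_report",
]


@dataclass(frozen=True)
class PipelineConfig:
    input_csv: str
    out_dir: str
    horizons: tuple[float, ...] = (7.0, 28.0, 90.0)
    boot: int = 1000
    seed: int = 0
    subgroup_cols: tuple[str, ...] = ()
    strict_missing: bool = False
    min_subgroup_events: int = 10
    schema: Optional[dict[str, str]] = None


def score_cohort(records: Sequence[ClinicalDay1Record], strict: bool = False) -> list[SofaBreakdown]:
    return [compute_alc_sofa(rec, strict=strict) for rec in records]


def _horizon_labels(records: Sequence[ClinicalDay1Record], horizon: float) -> np.ndarray:
    return np.array(
        [
            -1 if r.outcome is None else
            (lambda lab: -1 if lab is None else lab)(r.outcome.label_at(horizon))
            for r in records
        ]
    )


def evaluate_scores(
    scores_new: np.ndarray,
    scores_old: np.ndarray,
    labels: np.ndarray,
    boot: int = 1000,
    seed: Optional[int] = None,
) -> dict:
    """Full discrimination block for one horizon: AUROCs, DeLong, NRI/IDI,
    and an operating point per score."""
    block: dict = {
        "n": int(labels.size),
        "n_events": int(labels.sum()),
    }
    cmp = delong_compare(scores_new, scores_old, labels)
    block["auroc"] = {
        "alc_sofa": cmp.auc_new,
        "sofa": cmp.auc_old,
        "ci_alc_sofa": list(cmp.ci_new),
        "ci_sofa": list(cmp.ci_old),
        "delong_z": cmp.z,
        "delong_p": cmp.p,
    }
    try:
        rec = reclassification(scores_new, scores_old, labels, b=boot, seed=seed)
        block["reclassification"] = {
            "nri": rec.nri,
            "nri_events": rec.nri_events,
            "nri_nonevents": rec.nri_nonevents,
            "idi": rec.idi,
            "ci_nri": list(rec.ci_nri) if rec.ci_nri else None,
            "ci_idi": list(rec.ci_idi) if rec.ci_idi else None,
            "b_replicates": rec.b_replicates,
        }
    except SeparationError as exc:
        block["reclassification"] = {"error": str(exc)}
    def finite(x: float):
        return x if np.isfinite(x) else None  # JSON-safe (e.g. PLR at specificity 1)

    block["operating_points"] = {}
    for name, s in (("alc_sofa", scores_new), ("sofa", scores_old)):
        op = operating_point(s, labels)
        block["operating_points"][name] = {
            "threshold": op.threshold,
            "sensitivity": op.sensitivity,
            "specificity": op.specificity,
            "ppv": finite(op.ppv),
            "npv": finite(op.npv),
            "plr": finite(op.plr),
            "nlr": finite(op.nlr),
        }
    return block


def subgroup_evaluate(
    scores_new: np.ndarray,
    scores_old: np.ndarray,
    labels: np.ndarray,
    subgroup: np.ndarray,
    boot: int = 0,
    seed: Optional[int] = None,
    min_events: int = 10,
) -> dict:
    """Discrimination block per subgroup level; sparse levels are skipped."""
    blocks: dict = {}
    for level in sorted(np.unique(subgroup).tolist(), key=str):
        mask = subgroup == level
        lab = labels[mask]
        if lab.size == 0 or lab.sum() < min_events or (lab == 0).sum() < min_events:
            blocks[str(level)] = {"status": "insufficient data"}
            logger.info("subgroup level %r skipped: insufficient events", level)
            continue
        blocks[str(level)] = evaluate_scores(
            scores_new[mask], scores_old[mask], lab, boot=boot, seed=seed
        )
    return blocks


def _subgroup_values(records: Sequence[ClinicalDay1Record], col: str) -> np.ndarray:
    # built-in derived subgroups, then record fields, then named covariates
    if col == "age_gt_65":
        return np.array([bool(r.age is not None and r.age > 65) for r in records])
    if col == "septic_shock":
        return np.array([r.vasopressors.any_vasopressor for r in records])
    if hasattr(ClinicalDay1Record, "__dataclass_fields__") and col in ClinicalDay1Record.__dataclass_fields__:
        return np.array([getattr(r, col) for r in records])
    return np.array([r.covariates.get(col) for r in records])


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute filter -> score -> evaluate and write all artifacts.

    Writes ``scored.csv`` (input columns plus the score breakdown),
    ``km_classes.csv`` (tidy per-class survival curves) and
    ``report.json`` into ``config.out_dir``; returns the report dict.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    raw = read_cohort(config.input_csv, schema=config.schema)
    kept, attrition = apply_exclusions(raw)
    for step in attrition.steps:
        logger.info("exclusion %s: removed %d, remaining %d", step.rule, step.n_excluded, step.n_remaining)
    if len(kept) == 0:
        raise RuntimeError("filter stage: no records remain after exclusions")

    try:
        breakdowns = score_cohort(kept, strict=config.strict_missing)
    except Exception as exc:
        raise RuntimeError(f"score stage failed: {exc}") from exc

    _write_scored_csv(kept, breakdowns, out_dir / "scored.csv")

    sofa = np.array([b.sofa_total for b in breakdowns])
    alc_sofa = np.array([b.alc_sofa_total for b in breakdowns])
    alc_scores = np.array([b.alc_score for b in breakdowns])
    outcomes = [r.outcome for r in kept]

    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "config": {
            "input_csv": str(config.input_csv),
            "horizons": list(config.horizons),
            "boot": config.boot,
            "subgroup_cols": list(config.subgroup_cols),
            "strict_missing": config.strict_missing,
        },
        "attrition": attrition.as_dicts(),
        "horizons": {},
        "subgroups": {},
    }

    for horizon in config.horizons:
        key = f"{horizon:g}d"
        labels = _horizon_labels(kept, horizon)
        defined = labels >= 0
        block: dict = {"n_unlabeled": int((~defined).sum())}
        lab = labels[defined]
        if lab.size == 0 or lab.min() == lab.max():
            block["status"] = "insufficient data"
        else:
            block.update(
                evaluate_scores(
                    alc_sofa[defined], sofa[defined], lab,
                    boot=config.boot, seed=config.seed,
                )
            )
            frac, n_labeled, n_unlab = mortality_at(outcomes, horizon)
            block["mortality"] = {"fraction": frac, "n_labeled": n_labeled, "n_excluded": n_unlab}
            block["mortality_by_alc_score"] = _mortality_by_alc_score(alc_scores, outcomes, horizon)
        report["horizons"][key] = block

    curves, lr, km_log = class_curves(alc_sofa, outcomes)
    _write_km_csv(curves, out_dir / "km_classes.csv")
    report["km_classes"] = {
        "classes": sorted(curves),
        "dropped": km_log,
        "logrank": None if lr is None else {"chi2": lr.chi2, "df": lr.df, "p": lr.p},
    }

    for col in config.subgroup_cols:
        values = _subgroup_values(kept, col)
        labels = _horizon_labels(kept, 28.0)
        defined = labels >= 0
        report["subgroups"][col] = subgroup_evaluate(
            alc_sofa[defined],
            sofa[defined],
            labels[defined],
            values[defined],
            boot=0,
            seed=config.seed,
            min_events=config.min_subgroup_events,
        )

    validate_report(report)
    write_report(report, out_dir / "report.json")
    return report


def _mortality_by_alc_score(alc_scores: np.ndarray, outcomes, horizon: float) -> list[dict]:
    rows = []
    for s in range(5):
        idx = np.flatnonzero(alc_scores == s)
        if idx.size == 0:
            rows.append({"alc_score": s, "n": 0, "mortality": None})
            continue
        labels = [horizon_label(outcomes[i].time_days, outcomes[i].event, horizon) for i in idx]
        defined = [lab for lab in labels if lab is not None]
        rows.append(
            {
                "alc_score": s,
                "n": int(idx.size),
                "mortality": (sum(defined) / len(defined)) if defined else None,
            }
        )
    return rows


def _write_scored_csv(records, breakdowns, path: Path) -> None:
    import csv as _csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = _csv.writer(fh)
        writer.writerow(
            [
                "patient_id", "respiratory", "coagulation", "hepatic", "cardiovascular",
                "cns", "renal", "sofa_total", "alc_score", "alc_sofa_total",
                "time_days", "event", "flags",
            ]
        )
        for rec, b in zip(records, breakdowns):
            writer.writerow(
                [
                    rec.patient_id, b.respiratory, b.coagulation, b.hepatic,
                    b.cardiovascular, b.cns, b.renal, b.sofa_total, b.alc_score,
                    b.alc_sofa_total, rec.outcome.time_days, int(rec.outcome.event),
                    ";".join(b.flags),
                ]
            )


def _write_km_csv(curves, path: Path) -> None:
    import csv as _csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = _csv.writer(fh)
        writer.writerow(["class", "time_days", "survival", "at_risk", "n_events"])
        for label in sorted(curves):
            curve = curves[label]
            for t, s, r, d in zip(curve.event_times, curve.survival, curve.at_risk, curve.n_events):
                writer.writerow([label, float(t), float(s), int(r), int(d)])


def write_report(report: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, allow_nan=False)
        fh.write("\n")


_REQUIRED_TOP_KEYS = ("schema_version", "seed", "config", "attrition", "horizons", "subgroups", "km_classes")


def validate_report(report: dict) -> None:
    """Structural validation of the report (schema version pinned)."""
    for key in _REQUIRED_TOP_KEYS:
        if key not in report:
            raise ValueError(f"report missing required key {key!r}")
    if report["schema_version"] != SCHEMA_VERSION:
        raise ValueError(f"unsupported report schema version {report['schema_version']!r}")
    if not isinstance(report["horizons"], dict):
        raise ValueError("report 'horizons' must be an object")
    for key, block in report["horizons"].items():
        if "status" in block:
            continue
        for sub in ("auroc", "reclassification", "operating_points"):
            if sub not in block:
                raise ValueError(f"horizon block {key!r} missing {sub!r}")
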