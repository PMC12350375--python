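"""Survival analysis: Kaplan-Meier curves, log-rank tests, horizon
mortality, and the univariate-then-multivariate Cox screening procedure.

The Kaplan-Meier and log-rank statistics are computed from first
principles (they are small and their definitions are the contract); Cox
partial-likelihood maximization is delegated to statsmodels' proportional
hazards routines with Breslow tie handling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from statsmodels.duration.hazard_regression import PHReg

from .cohort import SurvivalOutcome, horizon_label

__all__ = [
    "KMCurve",
    "LogRankResult",
    "CoxFit",
    "CoxResult",
    "km_estimate",
    "logrank_test",
    "class_curves",
    "mortality_at",
    "cox_screen",
    "ALC_SOFA_CLASS_EDGES",
]

# 5-point classes over the 0-28 combined score; last class closed at 28.
ALC_SOFA_CLASS_EDGES: tuple[int, ...] = (0, 5, 10, 15, 20, 29)


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate: one row per distinct event time."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class LogRankResult:
    chi2: float
    df: int
    p: float


@dataclass(frozen=True)
class CoxFit:
    """Hazard ratio, Wald 95% CI, and p for one covariate in one fit."""

    covariate: str
    coef: float
    hr: float
    ci: tuple[float, float]
    p: float


@dataclass
class CoxResult:
    """Univariate screen plus the joint fit on covariates passing entry."""

    univariate: dict[str, CoxFit]
    entered: list[str]
    multivariate: dict[str, CoxFit]
    skipped: list[str] = field(default_factory=list)
    entry_p: float = 0.05


def km_estimate(times: Sequence[float], events: Sequence[bool]) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    S(t) = prod over event times t_i <= t of (1 - d_i / n_i).  Patients
    censored exactly at an event time still count in the risk set at that
    time (standard convention).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValueError("empty survival input")
    if (t < 0).any():
        raise ValueError("negative survival times")

    event_times = np.unique(t[e])
    at_risk = np.array([(t >= ti).sum() for ti in event_times], dtype=int)
    n_events = np.array([((t == ti) & e).sum() for ti in event_times], dtype=int)
    if event_times.size:
        survival = np.cumprod(1.0 - n_events / at_risk)
    else:
        survival = np.array([])
    return KMCurve(event_times=event_times, survival=survival, at_risk=at_risk, n_events=n_events)


def logrank_test(groups: Sequence[tuple[Sequence[float], Sequence[bool]]]) -> LogRankResult:
    """Log-rank test across two or more groups.

    Observed-minus-expected event counts at pooled event times, with the
    hypergeometric covariance; chi-square on (groups - 1) df.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    times = [np.asarray(t, dtype=float) for t, _ in groups]
    events = [np.asarray(e, dtype=bool) for _, e in groups]
    if any(t.size == 0 for t in times):
        raise ValueError("empty group")
    if not any(e.any() for e in events):
        raise ValueError("no events in any group")

    k = len(groups)
    pooled_event_times = np.unique(np.concatenate([t[e] for t, e in zip(times, events) if e.any()]))

    o_minus_e = np.zeros(k - 1)
    cov = np.zeros((k - 1, k - 1))
    for ti in pooled_event_times:
        n_g = np.array([(t >= ti).sum() for t in times], dtype=float)
        d_g = np.array([((t == ti) & e).sum() for t, e in zip(times, events)], dtype=float)
        n_tot = n_g.sum()
        d_tot = d_g.sum()
        if n_tot <= 1 or d_tot == 0:
            continue
        expected = n_g * d_tot / n_tot
        o_minus_e += (d_g - expected)[: k - 1]
        scale = d_tot * (n_tot - d_tot) / (n_tot - 1)
        p_g = n_g / n_tot
        v = scale * (np.diag(p_g[: k - 1]) - np.outer(p_g[: k - 1], p_g[: k - 1]))
        cov += v

    # pseudo-inverse guards degenerate risk sets (e.g. a group exhausted early)
    chi2 = float(o_minus_e @ np.linalg.pinv(cov) @ o_minus_e)
    df = k - 1
    return LogRankResult(chi2=chi2, df=df, p=float(stats.chi2.sf(chi2, df)))


def class_curves(
    totals: Sequence[int],
    outcomes: Sequence[SurvivalOutcome],
    edges: Sequence[int] = ALC_SOFA_CLASS_EDGES,
) -> tuple[dict[str, KMCurve], Optional[LogRankResult], list[str]]:
    """Kaplan-Meier curve per 5-point score class, plus a log-rank test.

    Classes are [0,5), [5,10), [10,15), [15,20), [20,28]; empty classes
    are dropped and reported in the returned log.  The log-rank result is
    ``None`` when fewer than two classes are occupied.
    """
    totals = np.asarray(totals)
    log: list[str] = []
    curves: dict[str, KMCurve] = {}
    group_data = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        label = f"[{lo},{hi - 1}]" if hi == edges[-1] else f"[{lo},{hi})"
        mask = (totals >= lo) & (totals < hi)
        if not mask.any():
            log.append(f"class {label} empty; dropped")
            continue
        t = [outcomes[i].time_days for i in np.flatnonzero(mask)]
        e = [outcomes[i].event for i in np.flatnonzero(mask)]
        curves[label] = km_estimate(t, e)
        group_data.append((t, e))

    lr = None
    if len(group_data) >= 2 and any(any(e) for _, e in group_data):
        lr = logrank_test(group_data)
    return curves, lr, log


def mortality_at(outcomes: Sequence[SurvivalOutcome], horizon_days: float) -> tuple[float, int, int]:
    """(death proportion, n labeled, n unlabeled) at a horizon.

    Patients whose label is undefined at the horizon (censored before it)
    are excluded from the denominator and counted separately.
    """
    if horizon_days <= 0:
        raise ValueError("horizon must be positive")
    labels = [horizon_label(o.time_days, o.event, horizon_days) for o in outcomes]
    defined = [lab for lab in labels if lab is not None]
    n_unlabeled = len(labels) - len(defined)
    if not defined:
        raise ValueError(f"no patient has a defined label at {horizon_days} days")
    return sum(defined) / len(defined), len(defined), n_unlabeled


class CoxConvergenceError(RuntimeError):
    pass


def _phreg_fit(
    time: np.ndarray,
    event: np.ndarray,
    X: np.ndarray,
    names: Sequence[str],
) -> dict[str, CoxFit]:
    model = PHReg(time, X, status=event.astype(int), ties="breslow")
    try:
        res = model.fit(disp=0)
    except Exception as exc:  # statsmodels raises various LinAlg/optimizer errors
        raise CoxConvergenceError(f"Cox fit failed for covariates {list(names)}: {exc}") from exc
    if not np.isfinite(res.params).all() or not np.isfinite(res.bse).all():
        raise CoxConvergenceError(f"Cox fit did not converge for covariates {list(names)}")
    fits = {}
    zcrit = 1.959963984540054
    for j, name in enumerate(names):
        beta = float(res.params[j])
        se = float(res.bse[j])
        zval = beta / se if se > 0 else math.inf
        fits[name] = CoxFit(
            covariate=name,
            coef=beta,
            hr=math.exp(beta),
            ci=(math.exp(beta - zcrit * se), math.exp(beta + zcrit * se)),
            p=float(2 * stats.norm.sf(abs(zval))),
        )
    return fits


def cox_screen(
    time: Sequence[float],
    event: Sequence[bool],
    covariates: dict[str, Sequence[float]],
    entry_p: float = 0.05,
) -> CoxResult:
    """Univariate Cox per covariate, then a joint fit on those with p < entry_p.

    Hazard ratios are exponentiated partial-likelihood estimates with Wald
    CIs (Breslow tie handling).  Constant covariates are skipped with a log
    entry; non-convergence raises naming the covariate.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    univariate: dict[str, CoxFit] = {}
    skipped: list[str] = []
    for name, values in covariates.items():
        x = np.asarray(values, dtype=float)
        if np.unique(x[~np.isnan(x)]).size < 2:
            skipped.append(name)
            continue
        mask = ~np.isnan(x)
        univariate[name] = _phreg_fit(t[mask], e[mask], x[mask, None], [name])[name]

    entered = [name for name, fit in univariate.items() if fit.p < entry_p]
    multivariate: dict[str, CoxFit] = {}
    if entered:
        cols = [np.asarray(covariates[name], dtype=float) for name in entered]
        X = np.column_stack(cols)
        mask = ~np.isnan(X).any(axis=1)
        multivariate = _phreg_fit(t[mask], e[mask], X[mask], entered)
    return CoxResult(
        univariate=univariate,
        entered=entered,
        multivariate=multivariate,
        skipped=skipped,
        entry_p=entry_p,
    )
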