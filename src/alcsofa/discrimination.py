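"""Score-comparison statistics for paired severity scores.

Provides AUROC (Mann-Whitney form), the DeLong paired test for correlated
AUROCs, logistic risk calibration, continuous net reclassification
improvement (NRI), integrated discrimination improvement (IDI), percentile
bootstrap confidence intervals, and operating-point metrics at a Youden
threshold.

NRI and IDI operate on calibrated predicted risks (a univariate logistic
model per score), not on the raw scores: when one score dominates the
other pointwise, raw-score "up/down" reclassification is degenerate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats

import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

__all__ = [
    "RocComparison",
    "ReclassificationResult",
    "OperatingPoint",
    "DegenerateComparisonError",
    "SeparationError",
    "auroc",
    "delong_components",
    "delong_compare",
    "fit_score_risk",
    "continuous_nri",
    "idi",
    "bootstrap_ci",
    "reclassification",
    "operating_point",
]


class DegenerateComparisonError(ValueError):
    """DeLong variance of the AUC difference is zero with unequal AUCs."""


class SeparationError(ValueError):
    """Logistic calibration failed due to complete separation."""


@dataclass(frozen=True)
class RocComparison:
    auc_new: float
    auc_old: float
    var_new: float
    var_old: float
    cov: float
    z: float
    p: float
    ci_new: tuple[float, float]
    ci_old: tuple[float, float]


@dataclass(frozen=True)
class ReclassificationResult:
    nri: float
    nri_events: float
    nri_nonevents: float
    idi: float
    ci_nri: Optional[tuple[float, float]]
    ci_idi: Optional[tuple[float, float]]
    b_replicates: int


@dataclass(frozen=True)
class OperatingPoint:
    threshold: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    plr: float
    nlr: float


def _validate_labels(labels: np.ndarray) -> None:
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise ValueError("both outcome classes must be present")


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve via the Mann-Whitney pair statistic.

    Equals the average over all (event, nonevent) pairs of 1 if the event
    scores higher, 0.5 on a tie, 0 otherwise.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    _validate_labels(y)
    m = int((y == 1).sum())
    n = int((y == 0).sum())
    ranks = stats.rankdata(s)
    return float((ranks[y == 1].sum() - m * (m + 1) / 2) / (m * n))


def delong_components(scores: Sequence[float], labels: Sequence[int]) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus the per-event (V10) and per-nonevent (V01) placement values.

    V10[i] is the fraction of nonevents that event i outranks (ties half);
    V01[j] the fraction of events outranking nonevent j.  Their means both
    equal the AUC; their empirical covariances drive the DeLong variance.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    _validate_labels(y)
    x_ev = s[y == 1]
    x_ne = s[y == 0]
    # psi(X_i, Y_j): 1 if X>Y, 0.5 if tie, 0 if X<Y
    cmp_matrix = (x_ev[:, None] > x_ne[None, :]).astype(float)
    cmp_matrix += 0.5 * (x_ev[:, None] == x_ne[None, :])
    v10 = cmp_matrix.mean(axis=1)
    v01 = cmp_matrix.mean(axis=0)
    return float(v10.mean()), v10, v01


def delong_compare(
    scores_new: Sequence[float],
    scores_old: Sequence[float],
    labels: Sequence[int],
) -> RocComparison:
    """DeLong paired test of two correlated AUROCs on the same patients.

    Variances and the covariance come from the empirical covariance of the
    placement values, scaled by 1/m (events) and 1/n (nonevents);
    z = (AUC_new - AUC_old) / sd of the difference, two-sided normal p.
    """
    y = np.asarray(labels)
    _validate_labels(y)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least 2 events and 2 nonevents")

    auc_new, v10_new, v01_new = delong_components(scores_new, labels)
    auc_old, v10_old, v01_old = delong_components(scores_old, labels)
    m = v10_new.size
    n = v01_new.size

    s10 = np.cov(np.vstack([v10_new, v10_old]), ddof=1)
    s01 = np.cov(np.vstack([v01_new, v01_old]), ddof=1)
    var_new = s10[0, 0] / m + s01[0, 0] / n
    var_old = s10[1, 1] / m + s01[1, 1] / n
    cov = s10[0, 1] / m + s01[0, 1] / n

    var_diff = var_new + var_old - 2 * cov
    diff = auc_new - auc_old
    if var_diff <= 0:
        if abs(diff) < 1e-12:
            z, p = 0.0, 1.0
        else:
            raise DegenerateComparisonError(
                f"zero variance of AUC difference with nonzero difference {diff:.3g}"
            )
    else:
        z = diff / np.sqrt(var_diff)
        p = 2 * stats.norm.sf(abs(z))

    def ci(auc: float, var: float) -> tuple[float, float]:
        half = 1.959963984540054 * np.sqrt(max(var, 0.0))
        return (max(auc - half, 0.0), min(auc + half, 1.0))

    return RocComparison(
        auc_new=auc_new,
        auc_old=auc_old,
        var_new=float(var_new),
        var_old=float(var_old),
        cov=float(cov),
        z=float(z),
        p=float(p),
        ci_new=ci(auc_new, var_new),
        ci_old=ci(auc_old, var_old),
    )


def fit_score_risk(scores: Sequence[float], labels: Sequence[int]) -> np.ndarray:
    """Per-patient predicted risks from a univariate logistic calibration.

    risk(s) = 1/(1+exp(-(a + b*s))), (a, b) by maximum likelihood.
    Raises :class:`SeparationError` on complete separation (collapse score
    categories before retrying).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    _validate_labels(y)
    if np.unique(s).size < 2:
        raise ValueError("need at least 2 distinct score values")
    X = sm.add_constant(s)
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            fit = sm.Logit(y, X).fit(disp=0)
        except (PerfectSeparationError, PerfectSeparationWarning) as exc:
            raise SeparationError(
                "complete separation in logistic calibration; collapse score categories"
            ) from exc
    if not np.isfinite(fit.params).all():
        raise SeparationError("non-finite logistic coefficients (separation)")
    return np.asarray(fit.predict(X))


def continuous_nri(
    risk_old: Sequence[float],
    risk_new: Sequence[float],
    labels: Sequence[int],
) -> tuple[float, float, float]:
    """Continuous (category-free) NRI: (total, events part, nonevents part).

    Events part = P(risk up | event) - P(risk down | event); nonevents part
    = P(down | nonevent) - P(up | nonevent); ties count neither way.
    """
    old = np.asarray(risk_old, dtype=float)
    new = np.asarray(risk_new, dtype=float)
    y = np.asarray(labels)
    _validate_labels(y)
    up = new > old
    down = new < old
    ev = y == 1
    ne = ~ev
    nri_events = float(up[ev].mean() - down[ev].mean())
    nri_nonevents = float(down[ne].mean() - up[ne].mean())
    return nri_events + nri_nonevents, nri_events, nri_nonevents


def idi(
    risk_old: Sequence[float],
    risk_new: Sequence[float],
    labels: Sequence[int],
) -> float:
    """Integrated discrimination improvement: difference of discrimination
    slopes (mean risk in events minus mean risk in nonevents) new vs old."""
    old = np.asarray(risk_old, dtype=float)
    new = np.asarray(risk_new, dtype=float)
    y = np.asarray(labels)
    _validate_labels(y)
    ev = y == 1
    ne = ~ev
    slope_new = new[ev].mean() - new[ne].mean()
    slope_old = old[ev].mean() - old[ne].mean()
    return float(slope_new - slope_old)


def bootstrap_ci(
    statistic: Callable[..., float],
    data: Sequence[np.ndarray],
    b: int = 1000,
    seed: Optional[int] = None,
    labels_index: Optional[int] = None,
    max_failure_rate: float = 0.1,
) -> tuple[float, float]:
    """95% percentile bootstrap interval by patient-level resampling.

    ``data`` is a sequence of aligned arrays; ``statistic`` is called with
    the resampled arrays.  If ``labels_index`` points at a binary label
    array, single-class resamples are redrawn.  Deterministic given seed.
    """
    if b < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    arrays = [np.asarray(a) for a in data]
    n = arrays[0].shape[0]
    if any(a.shape[0] != n for a in arrays):
        raise ValueError("bootstrap arrays must be aligned")
    rng = np.random.default_rng(seed)
    values = np.empty(b)
    failures = 0
    redraws = 0
    for i in range(b):
        while True:
            idx = rng.integers(0, n, size=n)
            if labels_index is None:
                break
            lab = arrays[labels_index][idx]
            if lab.min() != lab.max():
                break
            redraws += 1
            if redraws > 100 * b:
                raise RuntimeError("could not draw a two-class bootstrap resample")
        try:
            values[i] = statistic(*(a[idx] for a in arrays))
        except Exception:
            failures += 1
            values[i] = np.nan
            if failures > max_failure_rate * b:
                raise RuntimeError(f"statistic failed on more than {max_failure_rate:.0%} of resamples")
    lo, hi = np.nanpercentile(values, [2.5, 97.5])
    return float(lo), float(hi)


def reclassification(
    scores_new: Sequence[float],
    scores_old: Sequence[float],
    labels: Sequence[int],
    b: int = 1000,
    seed: Optional[int] = None,
) -> ReclassificationResult:
    """NRI and IDI on logistic-calibrated risks, with bootstrap CIs.

    Each bootstrap replicate refits both calibrations on the resample, so
    the interval reflects calibration uncertainty too.  ``b=0`` skips CIs.
    """
    s_new = np.asarray(scores_new, dtype=float)
    s_old = np.asarray(scores_old, dtype=float)
    y = np.asarray(labels)
    risk_new = fit_score_risk(s_new, y)
    risk_old = fit_score_risk(s_old, y)
    nri_total, nri_ev, nri_ne = continuous_nri(risk_old, risk_new, y)
    idi_value = idi(risk_old, risk_new, y)

    ci_nri = ci_idi = None
    if b:
        def nri_stat(sn, so, yy):
            rn = fit_score_risk(sn, yy)
            ro = fit_score_risk(so, yy)
            return continuous_nri(ro, rn, yy)[0]

        def idi_stat(sn, so, yy):
            rn = fit_score_risk(sn, yy)
            ro = fit_score_risk(so, yy)
            return idi(ro, rn, yy)

        ci_nri = bootstrap_ci(nri_stat, (s_new, s_old, y), b=b, seed=seed, labels_index=2)
        ci_idi = bootstrap_ci(idi_stat, (s_new, s_old, y), b=b, seed=seed, labels_index=2)

    return ReclassificationResult(
        nri=nri_total,
        nri_events=nri_ev,
        nri_nonevents=nri_ne,
        idi=idi_value,
        ci_nri=ci_nri,
        ci_idi=ci_idi,
        b_replicates=b,
    )


def operating_point(
    scores: Sequence[float],
    labels: Sequence[int],
    criterion: str = "youden",
) -> OperatingPoint:
    """Classification metrics at the threshold maximizing Youden's J.

    Candidate thresholds are the observed score values; predicted positive
    means score >= threshold; ties on J resolve to the lowest threshold.
    """
    if criterion != "youden":
        raise ValueError(f"unknown threshold criterion: {criterion!r}")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    _validate_labels(y)
    thresholds = np.unique(s)
    best_j = -np.inf
    best = None
    for t in thresholds:
        pred = s >= t
        tp = int((pred & (y == 1)).sum())
        fp = int((pred & (y == 0)).sum())
        fn = int((~pred & (y == 1)).sum())
        tn = int((~pred & (y == 0)).sum())
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        j = sens + spec - 1
        if j > best_j + 1e-12:
            best_j = j
            best = (float(t), sens, spec, tp, fp, fn, tn)
    t, sens, spec, tp, fp, fn, tn = best
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    plr = sens / (1 - spec) if spec < 1 else float("inf")
    nlr = (1 - sens) / spec if spec > 0 else float("inf")
    return OperatingPoint(t, sens, spec, ppv, npv, plr, nlr)
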