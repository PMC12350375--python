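from __future__ import annotations

import numpy as np
import pytest

from alcsofa.discrimination import (
    DegenerateComparisonError,
    SeparationError,
    auroc,
    bootstrap_ci,
    continuous_nri,
    delong_compare,
    fit_score_risk,
    idi,
    operating_point,
    reclassification,
)


# ---------------------------------------------------------------- oracles

def brute_force_auroc(scores, labels):
    """Straight-from-definition pair counting."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    total = 0.0
    pairs = 0
    for xi in scores[labels == 1]:
        for yj in scores[labels == 0]:
            pairs += 1
            if xi > yj:
                total += 1.0
            elif xi == yj:
                total += 0.5
    return total / pairs


def brute_force_delong(s_new, s_old, labels):
    """Independent from-definition DeLong variance/covariance computation."""
    s_new = np.asarray(s_new, dtype=float)
    s_old = np.asarray(s_old, dtype=float)
    labels = np.asarray(labels)
    ev = np.flatnonzero(labels == 1)
    ne = np.flatnonzero(labels == 0)
    m, n = len(ev), len(ne)

    def psi(x, y):
        return 1.0 if x > y else (0.5 if x == y else 0.0)

    out = {}
    placements = {}
    for name, s in (("new", s_new), ("old", s_old)):
        v10 = [sum(psi(s[i], s[j]) for j in ne) / n for i in ev]
        v01 = [sum(psi(s[i], s[j]) for i in ev) / m for j in ne]
        out[name] = sum(v10) / m
        placements[name] = (v10, v01)

    def cov(a, b):
        abar, bbar = sum(a) / len(a), sum(b) / len(b)
        return sum((x - abar) * (y - bbar) for x, y in zip(a, b)) / (len(a) - 1)

    s10 = {
        (r, c): cov(placements[r][0], placements[c][0]) for r in ("new", "old") for c in ("new", "old")
    }
    s01 = {
        (r, c): cov(placements[r][1], placements[c][1]) for r in ("new", "old") for c in ("new", "old")
    }
    var_new = s10[("new", "new")] / m + s01[("new", "new")] / n
    var_old = s10[("old", "old")] / m + s01[("old", "old")] / n
    cov_no = s10[("new", "old")] / m + s01[("new", "old")] / n
    return out["new"], out["old"], var_new, var_old, cov_no


# ----------------------------------------------------------------- auroc

class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0

    def test_all_ties(self):
        assert auroc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_four_pair_enumeration(self):
        # events score {2,4}, nonevents {1,3}: wins (2>1),(4>1),(4>3); loss (2<3)
        assert auroc([1, 2, 3, 4], [0, 1, 0, 1]) == pytest.approx(0.75)

    def test_matches_brute_force_on_random_fixtures(self, rng):
        for _ in range(50):
            n = 30
            scores = rng.integers(0, 10, n).astype(float)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            assert auroc(scores, labels) == pytest.approx(brute_force_auroc(scores, labels))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([1, 2, 3], [1, 1, 1])

    def test_complement_identity_tie_free(self, rng):
        scores = rng.standard_normal(40)
        labels = np.r_[np.ones(15, int), np.zeros(25, int)]
        assert auroc(scores, labels) + auroc(-scores, labels) == pytest.approx(1.0)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.standard_normal(40)
        labels = np.r_[np.ones(20, int), np.zeros(20, int)]
        assert auroc(np.exp(scores), labels) == pytest.approx(auroc(scores, labels))


# ---------------------------------------------------------------- delong

class TestDelong:
    def test_score_vs_itself(self, rng):
        s = rng.standard_normal(30)
        y = np.r_[np.ones(10, int), np.zeros(20, int)]
        cmp = delong_compare(s, s, y)
        assert cmp.z == 0.0
        assert cmp.p == 1.0

    def test_swap_negates_z_same_p(self, rng):
        s1, s2 = rng.standard_normal(40), rng.standard_normal(40)
        y = np.r_[np.ones(15, int), np.zeros(25, int)]
        a = delong_compare(s1, s2, y)
        b = delong_compare(s2, s1, y)
        assert a.z == pytest.approx(-b.z)
        assert a.p == pytest.approx(b.p)

    def test_matches_from_definition_oracle_12_patients(self):
        s_new = [3.0, 5.0, 2.0, 8.0, 7.0, 4.0, 1.0, 6.0, 2.5, 3.5, 5.5, 0.5]
        s_old = [2.0, 6.0, 2.0, 5.0, 8.0, 3.0, 2.0, 4.0, 1.0, 3.0, 5.0, 1.5]
        y = [1, 1, 0, 1, 1, 0, 0, 1, 0, 0, 1, 0]
        auc_new, auc_old, var_new, var_old, cov = brute_force_delong(s_new, s_old, y)
        cmp = delong_compare(s_new, s_old, y)
        assert cmp.auc_new == pytest.approx(auc_new)
        assert cmp.auc_old == pytest.approx(auc_old)
        assert cmp.var_new == pytest.approx(var_new)
        assert cmp.var_old == pytest.approx(var_old)
        assert cmp.cov == pytest.approx(cov)

    def test_matches_oracle_on_random_fixtures_with_ties(self, rng):
        for _ in range(20):
            n = 14
            y = np.r_[np.ones(5, int), np.zeros(9, int)]
            s1 = rng.integers(0, 6, n).astype(float)
            s2 = rng.integers(0, 6, n).astype(float)
            o = brute_force_delong(s1, s2, y)
            cmp = delong_compare(s1, s2, y)
            assert (cmp.auc_new, cmp.auc_old) == pytest.approx(o[:2])
            assert (cmp.var_new, cmp.var_old, cmp.cov) == pytest.approx(o[2:])

    def test_degenerate_nonzero_difference_raises(self):
        # both scores separate perfectly -> zero variance, unequal AUC impossible;
        # force via constant placement values but different AUCs
        s_new = [1, 1, 1, 2, 2, 2]
        s_old = [2, 2, 2, 1, 1, 1]
        y = [0, 0, 0, 1, 1, 1]
        with pytest.raises(DegenerateComparisonError):
            delong_compare(s_new, s_old, y)

    def test_ci_contains_auc(self, rng):
        s = rng.standard_normal(60)
        y = (rng.random(60) < 0.4).astype(int)
        cmp = delong_compare(s + 0.5 * y, s, y)
        assert cmp.ci_new[0] <= cmp.auc_new <= cmp.ci_new[1]

    def test_true_null_type_i_error_calibrated(self):
        # exchangeable scores (same signal, independent noise) -> ~5% rejection
        rng = np.random.default_rng(2024)
        rejections = 0
        trials = 200
        for _ in range(trials):
            n = 400
            z = rng.standard_normal(n)
            y = (rng.random(n) < 1 / (1 + np.exp(-(z - 1.0)))).astype(int)
            if y.sum() < 2 or y.sum() > n - 2:
                continue
            s1 = z + rng.standard_normal(n)
            s2 = z + rng.standard_normal(n)
            rejections += delong_compare(s1, s2, y).p < 0.05
        assert 0.025 <= rejections / trials <= 0.075


# ------------------------------------------------------- risk calibration

class TestFitScoreRisk:
    def test_null_score_gives_prevalence(self, rng):
        scores = rng.integers(0, 10, 2000).astype(float)
        labels = (rng.random(2000) < 0.3).astype(int)
        risks = fit_score_risk(scores, labels)
        assert np.allclose(risks, labels.mean(), atol=0.05)

    def test_risks_monotone_in_score(self, rng):
        scores = np.arange(200) % 10.0
        labels = (rng.random(200) < 1 / (1 + np.exp(-(scores - 5)))).astype(int)
        risks = fit_score_risk(scores, labels)
        order = np.argsort(scores)
        assert np.all(np.diff(risks[order]) >= -1e-12)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(77)
        n = 5000
        a, b = -1.0, 0.4
        s = rng.uniform(0, 10, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(a + b * s)))).astype(int)
        risks = fit_score_risk(s, y)
        # invert two fitted risks to recover (a, b)
        lo = np.log(risks / (1 - risks))
        slope = np.polyfit(s, lo, 1)
        assert slope[0] == pytest.approx(b, abs=0.1)
        assert slope[1] == pytest.approx(a, abs=0.1)

    def test_complete_separation_raises(self):
        scores = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        labels = np.array([0, 0, 0, 1, 1, 1])
        with pytest.raises(SeparationError):
            fit_score_risk(scores, labels)

    def test_constant_score_rejected(self):
        with pytest.raises(ValueError):
            fit_score_risk([1.0, 1.0, 1.0, 1.0], [0, 1, 0, 1])


# ---------------------------------------------------------------- nri/idi

class TestContinuousNri:
    def test_identical_risks_zero(self):
        r = [0.1, 0.5, 0.9, 0.3]
        assert continuous_nri(r, r, [0, 1, 1, 0]) == (0.0, 0.0, 0.0)

    def test_everyone_up_cancels(self):
        old = [0.1, 0.2, 0.3, 0.4]
        new = [0.2, 0.3, 0.4, 0.5]
        nri, ev, ne = continuous_nri(old, new, [1, 1, 0, 0])
        assert ev == 1.0
        assert ne == -1.0
        assert nri == 0.0

    def test_maximum_is_two(self):
        old = [0.5, 0.5, 0.5, 0.5]
        new = [0.9, 0.9, 0.1, 0.1]
        assert continuous_nri(old, new, [1, 1, 0, 0])[0] == 2.0

    def test_hand_fixture_10_patients(self):
        labels = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        old = [0.8, 0.6, 0.5, 0.3, 0.4, 0.3, 0.2, 0.2, 0.1, 0.1]
        new = [0.9, 0.5, 0.6, 0.3, 0.3, 0.35, 0.1, 0.2, 0.05, 0.15]
        nri, ev, ne = continuous_nri(old, new, labels)
        # events: 2 up, 1 down, 1 tie -> 1/4; nonevents: 3 down, 2 up, 1 tie -> 1/6
        assert ev == pytest.approx(0.25)
        assert ne == pytest.approx(1 / 6)
        assert nri == pytest.approx(0.25 + 1 / 6)

    def test_bounds(self, rng):
        for _ in range(20):
            old = rng.random(30)
            new = rng.random(30)
            y = np.r_[np.ones(10, int), np.zeros(20, int)]
            nri, _, _ = continuous_nri(old, new, y)
            assert -2.0 <= nri <= 2.0


class TestIdi:
    def test_identical_risks_zero(self):
        r = [0.1, 0.5, 0.9, 0.3]
        assert idi(r, r, [0, 1, 1, 0]) == 0.0

    def test_perfect_vs_constant_is_one(self):
        labels = [1, 1, 0, 0, 0]
        new = [1.0, 1.0, 0.0, 0.0, 0.0]
        old = [0.4] * 5
        assert idi(old, new, labels) == pytest.approx(1.0)

    def test_hand_fixture_10_patients(self):
        labels = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        old = [0.8, 0.6, 0.5, 0.3, 0.4, 0.3, 0.2, 0.2, 0.1, 0.1]
        new = [0.9, 0.5, 0.6, 0.3, 0.3, 0.35, 0.1, 0.2, 0.05, 0.15]
        # slopes: new 0.575 - 1.15/6; old 0.55 - 1.3/6; difference = 0.05
        assert idi(old, new, labels) == pytest.approx(0.05)

    def test_bounds(self, rng):
        for _ in range(20):
            old = rng.random(30)
            new = rng.random(30)
            y = np.r_[np.ones(10, int), np.zeros(20, int)]
            assert -1.0 <= idi(old, new, y) <= 1.0


# -------------------------------------------------------------- bootstrap

class TestBootstrapCi:
    def test_constant_statistic(self, rng):
        data = (rng.standard_normal(50),)
        lo, hi = bootstrap_ci(lambda x: 3.14, data, b=200, seed=0)
        assert lo == hi == 3.14

    def test_same_seed_identical(self, rng):
        data = (rng.standard_normal(100),)
        a = bootstrap_ci(lambda x: float(np.mean(x)), data, b=300, seed=42)
        b = bootstrap_ci(lambda x: float(np.mean(x)), data, b=300, seed=42)
        assert a == b

    def test_mean_interval_width_close_to_normal_theory(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(200)
        lo, hi = bootstrap_ci(lambda v: float(np.mean(v)), (x,), b=1000, seed=1)
        expected_width = 2 * 1.96 / np.sqrt(200)
        assert abs((hi - lo) - expected_width) / expected_width < 0.2

    def test_single_class_resamples_redrawn(self, rng):
        # 1 event among 12: single-class resamples are common and must be redrawn
        labels = np.r_[np.ones(1, int), np.zeros(11, int)]
        scores = rng.standard_normal(12)
        lo, hi = bootstrap_ci(
            lambda s, y: auroc(s, y), (scores, labels), b=150, seed=3, labels_index=1
        )
        assert np.isfinite(lo) and np.isfinite(hi)

    def test_too_few_replicates_rejected(self, rng):
        with pytest.raises(ValueError):
            bootstrap_ci(lambda x: 0.0, (rng.standard_normal(10),), b=50, seed=0)

    def test_failing_statistic_raises(self, rng):
        def bad(x):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError):
            bootstrap_ci(bad, (rng.standard_normal(10),), b=100, seed=0)


class TestReclassification:
    def test_result_consistency(self, rng):
        n = 400
        z = rng.standard_normal(n)
        y = (rng.random(n) < 1 / (1 + np.exp(-z))).astype(int)
        s_old = z + rng.standard_normal(n)
        s_new = s_old + 0.5 * rng.standard_normal(n) + y
        res = reclassification(s_new, s_old, y, b=150, seed=5)
        assert res.nri == pytest.approx(res.nri_events + res.nri_nonevents)
        assert res.b_replicates == 150
        assert res.ci_nri[0] <= res.ci_nri[1]
        assert res.ci_idi[0] <= res.ci_idi[1]


# --------------------------------------------------------- operating point

class TestOperatingPoint:
    def test_perfect_separation(self):
        op = operating_point([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert op.sensitivity == 1.0
        assert op.specificity == 1.0
        assert op.threshold == 10.0

    def test_known_2x2_table(self):
        # threshold 5: events 9 above/1 below; nonevents 1 above/9 below
        scores = [6] * 9 + [4] + [6] + [4] * 9
        labels = [1] * 10 + [0] * 10
        op = operating_point(scores, labels)
        assert op.threshold == 6.0
        assert op.sensitivity == pytest.approx(0.9)
        assert op.specificity == pytest.approx(0.9)
        assert op.ppv == pytest.approx(0.9)
        assert op.npv == pytest.approx(0.9)
        assert op.plr == pytest.approx(9.0)
        assert op.nlr == pytest.approx(1 / 9)

    def test_all_ties_returns_lowest_threshold(self):
        op = operating_point([3, 3, 3, 3], [0, 1, 0, 1])
        assert op.threshold == 3.0
        assert op.sensitivity + op.specificity - 1 == pytest.approx(0.0)

    def test_plr_nlr_identities(self, rng):
        scores = rng.integers(0, 15, 100).astype(float)
        labels = (rng.random(100) < 0.3).astype(int)
        op = operating_point(scores, labels)
        if op.specificity < 1:
            assert op.plr == pytest.approx(op.sensitivity / (1 - op.specificity))
        if op.specificity > 0:
            assert op.nlr == pytest.approx((1 - op.sensitivity) / op.specificity)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            operating_point([1, 2, 3], [1, 1, 1])
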